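"""Tree-ensemble rankings: random forest and gradient boosting.

Random forest
    A classification forest is tuned over (mtry, nodesize) grids by
    out-of-bag (OOB) misclassification.  Two importance views are computed
    from the tuned forest:

    * minimal depth — per tree, the depth of the shallowest node splitting
      on a feature (features absent from a tree score that tree's max depth
      plus one), averaged over trees; smaller = more important;
    * OOB permutation importance — the increase in a tree's OOB
      misclassification when the feature's OOB values are permuted,
      averaged over all trees (Breiman/Ishwaran accuracy importance).

    The default ranking orders by descending permutation importance with
    ascending minimal depth as tie-break; a config switch ranks purely by
    minimal depth, and an optional selection gate imputes features whose
    average minimal depth exceeds the forest-average depth threshold.

Gradient boosting
    A logistic-loss XGBoost model tuned by stratified 5-fold CV
    misclassification over a small (max_depth, learning_rate) grid with
    early stopping; features are ranked by fractional total gain (a
    feature's share of the summed split gain), unused features imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .containers import AbundanceMatrix, MethodRanking, SampleMetadata, rank_descending


@dataclass
class ForestModel:
    """A tuned random forest plus the tuning trace."""

    forest: RandomForestClassifier
    mtry: int
    nodesize: int
    oob_error: float
    seed: int
    tuning_trace: list[dict] = field(default_factory=list)


@dataclass
class BoostedModel:
    """A tuned XGBoost classifier plus gains and the CV trace."""

    booster: xgb.Booster
    rounds: int
    learning_rate: float
    max_depth: int
    total_gain: np.ndarray
    cv_error: float
    seed: int
    tuning_trace: list[dict] = field(default_factory=list)


def _resolve_mtry_grid(p: int, mtry_grid) -> list[int]:
    if mtry_grid is None:
        mtry_grid = sorted({max(1, int(np.sqrt(p))), max(1, p // 10), max(1, p // 3)})
    return [int(m) for m in mtry_grid]


def tune_and_fit_forest(
    X: AbundanceMatrix,
    meta: SampleMetadata,
    mtry_grid=None,
    nodesize_grid=(5, 15, 50),
    n_trees: int = 500,
    seed: int = 0,
) -> ForestModel:
    """Grid-search (mtry, nodesize) by OOB misclassification; keep the best fit.

    Ties prefer the smaller mtry, then the larger nodesize (the more
    regularized model).  The same seed is used for every grid point, so the
    winning model is the refit-on-all-data model.
    """
    meta = meta.aligned_to(X)
    y = meta.outcome
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if n_trees < 50:
        raise ValueError("n_trees must be >= 50")
    p = X.n_features
    mtry_grid = _resolve_mtry_grid(p, mtry_grid)
    nodesize_grid = [int(s) for s in nodesize_grid]
    if not mtry_grid or not nodesize_grid:
        raise ValueError("tuning grids must be non-empty")

    best = None
    trace = []
    for mtry in sorted(mtry_grid):
        for nodesize in sorted(nodesize_grid, reverse=True):
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_features=min(mtry, p),
                min_samples_leaf=nodesize, oob_score=True, bootstrap=True,
                random_state=seed, n_jobs=1,
            )
            rf.fit(X.values, y)
            err = 1.0 - rf.oob_score_
            trace.append({"mtry": mtry, "nodesize": nodesize, "oob_error": err})
            if best is None or err < best[0]:
                best = (err, mtry, nodesize, rf)
    err, mtry, nodesize, rf = best
    return ForestModel(rf, mtry, nodesize, err, seed, trace)


def _tree_min_depths(tree, p: int) -> tuple[np.ndarray, int]:
    """Per-feature minimal split depth in one fitted sklearn tree.

    Returns (depths with np.inf for absent features, max node depth).
    """
    t = tree.tree_
    depth = np.zeros(t.node_count, dtype=int)
    stack = [(0, 0)]
    while stack:
        node, d = stack.pop()
        depth[node] = d
        left, right = t.children_left[node], t.children_right[node]
        if left != -1:
            stack.append((left, d + 1))
            stack.append((right, d + 1))
    out = np.full(p, np.inf)
    internal = t.children_left != -1
    for node in np.flatnonzero(internal):
        f = t.feature[node]
        if depth[node] < out[f]:
            out[f] = depth[node]
    return out, int(depth.max())


def minimal_depth(model: ForestModel) -> np.ndarray:
    """Average minimal depth per feature over the forest's trees.

    A feature absent from a tree is assigned that tree's max depth + 1, the
    standard penalty convention; smaller average = more important.
    """
    trees = model.forest.estimators_
    if not trees:
        raise ValueError("empty forest")
    p = model.forest.n_features_in_
    total = np.zeros(p)
    for est in trees:
        d, dmax = _tree_min_depths(est, p)
        d = np.where(np.isinf(d), dmax + 1, d)
        total += d
    return total / len(trees)


def _oob_mask(estimator_seed: int, n: int) -> np.ndarray:
    """Out-of-bag mask for one tree of a bootstrap forest.

    Reproduces the forest's per-tree bootstrap draw (each tree's integer
    random_state seeds an n-draw with replacement); validated in the test
    suite against the forest's own aggregated OOB predictions.
    """
    try:  # scikit-learn's own helper, when importable
        from sklearn.ensemble._forest import _generate_unsampled_indices

        unsampled = _generate_unsampled_indices(estimator_seed, n, n, None)
        mask = np.zeros(n, dtype=bool)
        mask[unsampled] = True
        return mask
    except (ImportError, TypeError):
        inbag = np.random.RandomState(estimator_seed).randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[inbag] = False
        return mask


def forest_importance(model: ForestModel, X: AbundanceMatrix,
                      meta: SampleMetadata, seed: int | None = None) -> np.ndarray:
    """OOB permutation importance (Ishwaran/Breiman accuracy importance).

    Per tree: misclassification on the tree's OOB samples after permuting a
    feature's OOB column, minus the unpermuted OOB misclassification;
    averaged over all trees (features unused by a tree contribute 0).
    Permutations are seeded, so reruns are identical.
    """
    meta = meta.aligned_to(X)
    y = meta.outcome
    n, p = X.values.shape
    rng = np.random.default_rng(model.seed if seed is None else seed)
    total = np.zeros(p)
    for est in model.forest.estimators_:
        oob = _oob_mask(est.random_state, n)
        m = int(oob.sum())
        if m == 0:
            continue
        Xo, yo = X.values[oob], y[oob]
        base_err = np.mean(est.predict(Xo) != yo)
        used = np.unique(est.tree_.feature[est.tree_.feature >= 0])
        perm = rng.permutation(m)
        for f in used:
            Xp = Xo.copy()
            Xp[:, f] = Xo[perm, f]
            total[f] += np.mean(est.predict(Xp) != yo) - base_err
    return total / len(model.forest.estimators_)


def rank_forest(minimal_depths: np.ndarray, importances: np.ndarray,
                feature_ids: list[str], by: str = "importance",
                selection: bool = False) -> MethodRanking:
    """Forest ranking: descending importance, minimal depth as tie-break.

    ``by="minimal_depth"`` ranks purely by ascending minimal depth.  With
    ``selection=True``, features whose average minimal depth exceeds the
    forest-average depth threshold (mean of the minimal-depth vector) are
    marked unselected and imputed.
    """
    md = np.asarray(minimal_depths, dtype=float)
    imp = np.asarray(importances, dtype=float)
    if md.shape != imp.shape or len(md) != len(feature_ids):
        raise ValueError("minimal depths / importances / feature ids must align")
    p = len(feature_ids)
    selected = np.ones(p, dtype=bool)
    if selection:
        selected = md <= md.mean()
    if by == "importance":
        key = lambda i: (-imp[i], md[i], feature_ids[i])
    elif by == "minimal_depth":
        key = lambda i: (md[i], -imp[i], feature_ids[i])
    else:
        raise ValueError("by must be 'importance' or 'minimal_depth'")
    order = sorted(np.flatnonzero(selected), key=key)
    rank = np.full(p, p, dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    score = imp if by == "importance" else -md
    score = np.where(selected, score, np.nan)
    return MethodRanking("random_forest", list(feature_ids), score, rank, ~selected)


DEFAULT_XGB_GRID = tuple(
    {"max_depth": d, "learning_rate": lr} for d in (2, 4, 6) for lr in (0.05, 0.1, 0.3)
)


def tune_and_fit_xgb(
    X: AbundanceMatrix,
    meta: SampleMetadata,
    param_grid=DEFAULT_XGB_GRID,
    folds: int = 5,
    seed: int = 0,
    max_rounds: int = 500,
    early_stopping_rounds: int = 20,
) -> BoostedModel:
    """Logistic-loss boosting tuned by stratified k-fold CV classification error.

    For each grid point the round count is chosen by early stopping on the
    CV folds; the grid point minimizing the CV error at its best round wins
    (ties keep the earlier grid point).  The final model is trained on all
    data for the winning round count.
    """
    meta = meta.aligned_to(X)
    y = meta.outcome
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if not param_grid:
        raise ValueError("param_grid must be non-empty")
    feature_names = list(X.feature_ids)
    dall = xgb.DMatrix(X.values, label=y, feature_names=feature_names)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_idx = list(skf.split(X.values, y))

    best = None
    trace = []
    for gi, params in enumerate(param_grid):
        full = {
            "objective": "binary:logistic", "eval_metric": "error",
            "max_depth": int(params["max_depth"]),
            "learning_rate": float(params["learning_rate"]),
            "seed": seed, "nthread": 1,
        }
        cv = xgb.cv(
            full, dall, num_boost_round=max_rounds, folds=fold_idx,
            early_stopping_rounds=early_stopping_rounds, shuffle=False,
        )
        err = float(cv["test-error-mean"].min())
        rounds = int(cv["test-error-mean"].idxmin()) + 1
        trace.append({**params, "cv_error": err, "rounds": rounds})
        if best is None or err < best[0]:
            best = (err, gi, rounds, full)

    err, gi, rounds, full = best
    booster = xgb.train(full, dall, num_boost_round=rounds)
    gains = booster.get_score(importance_type="total_gain")
    total_gain = np.array([gains.get(f, 0.0) for f in feature_names])
    return BoostedModel(booster, rounds, full["learning_rate"], full["max_depth"],
                        total_gain, err, seed, trace)


def rank_xgb_gain(model: BoostedModel, feature_ids: list[str]) -> MethodRanking:
    """Fractional total gain, descending; unused features imputed.

    Scores are each feature's share of the summed split gain and sum to 1
    over the used features.
    """
    gain = np.asarray(model.total_gain, dtype=float)
    if gain.sum() <= 0:
        raise ValueError("model has no splits; gains are all zero")
    frac = gain / gain.sum()
    return rank_descending(feature_ids, frac, gain > 0, "xgboost")
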