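"""Cross-method rank aggregation: integrated, difference, and variance ranks.

After imputing every missing/unselected feature at rank ``n_total`` (the
total feature count), three per-feature agreement statistics are computed
over the features x methods rank matrix:

* integrated rank — the row sum, a consensus importance (smaller = better);
* difference rank — row max minus row min, the widest disagreement;
* variance rank — the row sample variance (n-1 denominator), the overall
  level of disagreement among methods.

``difference == 0`` exactly when ``variance == 0`` (all methods agree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MethodRanking


@dataclass
class AggregateRanking:
    """Per-feature rank matrix and the three aggregation statistics."""

    feature_ids: list[str]
    methods: list[str]
    matrix: np.ndarray               # features x methods, after imputation
    integrated: np.ndarray
    difference: np.ndarray
    variance: np.ndarray
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.methods)
        df.insert(0, "feature_id", self.feature_ids)
        df["integrated"] = self.integrated
        df["difference"] = self.difference
        df["variance"] = self.variance
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def best_by_integrated(self, n: int) -> list[str]:
        order = sorted(range(len(self.feature_ids)),
                       key=lambda i: (self.integrated[i], self.feature_ids[i]))
        return [self.feature_ids[i] for i in order[:n]]


def impute_missing_ranks(rankings: list[MethodRanking], n_total: int | None = None) -> pd.DataFrame:
    """Features x methods rank matrix with unscored features at rank n_total.

    All rankings must share one feature universe; ``n_total`` defaults to
    the size of that universe and must be at least the largest observed
    rank.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    universe = rankings[0].feature_ids
    for r in rankings[1:]:
        if r.feature_ids != universe:
            raise ValueError("rankings cover inconsistent feature universes")
    if n_total is None:
        n_total = len(universe)
    max_obs = max(int(r.rank[~r.imputed].max()) if r.n_scored else 0 for r in rankings)
    if n_total < max_obs or n_total < len(universe):
        raise ValueError(f"n_total={n_total} below max observed rank {max_obs} "
                         f"or universe size {len(universe)}")
    cols = {}
    for r in rankings:
        col = np.where(r.imputed, n_total, r.rank)
        cols[r.method] = col
    return pd.DataFrame(cols, index=universe)


def integrated_rank(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Row sums of the imputed rank matrix; ascending = most important."""
    return np.asarray(matrix, dtype=float).sum(axis=1)


def difference_rank(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Row max minus row min."""
    m = np.asarray(matrix, dtype=float)
    return m.max(axis=1) - m.min(axis=1)


def variance_rank(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Row sample variance (n-1 denominator); needs >= 2 methods."""
    m = np.asarray(matrix, dtype=float)
    if m.shape[1] < 2:
        raise ValueError("variance rank needs at least two methods")
    return m.var(axis=1, ddof=1)


def aggregate(rankings: list[MethodRanking], n_total: int | None = None) -> AggregateRanking:
    """Impute and compute all three aggregation statistics."""
    df = impute_missing_ranks(rankings, n_total)
    m = df.to_numpy(dtype=float)
    return AggregateRanking(
        feature_ids=list(df.index),
        methods=list(df.columns),
        matrix=m.astype(int),
        integrated=integrated_rank(m),
        difference=difference_rank(m),
        variance=variance_rank(m),
        n_total=n_total if n_total is not None else len(df.index),
    )


def focus_top(agg: AggregateRanking, n: int = 500) -> AggregateRanking:
    """Restrict to the n best features by integrated rank.

    Boundary ties are broken by feature id, so the restriction is
    deterministic.
    """
    if n > len(agg.feature_ids):
        raise ValueError("n exceeds the feature count")
    keep_ids = agg.best_by_integrated(n)
    pos = {f: i for i, f in enumerate(agg.feature_ids)}
    idx = np.array([pos[f] for f in keep_ids], dtype=int)
    return AggregateRanking(
        feature_ids=keep_ids,
        methods=list(agg.methods),
        matrix=agg.matrix[idx],
        integrated=agg.integrated[idx],
        difference=agg.difference[idx],
        variance=agg.variance[idx],
        n_total=agg.n_total,
    )
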