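"""End-to-end orchestration: preprocess -> 7 rankings -> aggregation -> diagnostics.

The seven ranking columns are bonferroni, fdr (both from the univariate
screen), lasso, elastic_net, random_forest, sda, and xgboost.  A run writes
per-method ranking TSVs, the aggregate rank table, per-method convergence
summaries, a cohort table, a log, and a machine-readable manifest into the
run directory.  Reruns with identical config and seeds are byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import convergence as conv_mod
from .aggregate import aggregate as aggregate_rankings
from .aggregate import focus_top
from .cohort import cohort_summary
from .containers import METHODS, AbundanceMatrix, MethodRanking, SampleMetadata
from .penalized import (DEFAULT_ALPHA_GRID, fit_elastic_net_cv, fit_lasso_cv,
                        rank_by_abs_coefficients)
from .preprocess import preprocess
from .sda import cat_scan, rank_by_abs_cat
from .simulate import SyntheticConfig, generate_dataset, write_dataset
from .trees import (forest_importance, minimal_depth, rank_forest, rank_xgb_gain,
                    tune_and_fit_forest, tune_and_fit_xgb)
from .univariate import rank_bonferroni, rank_fdr, univariate_scan

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, serializable to/from YAML."""

    outdir: str = "run"
    abundance_path: str | None = None     # None -> simulate
    phenotypes_path: str | None = None
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 20230628
    # aggregation / diagnostics
    k: int = 50
    n_focus: int = 500
    high_threshold: float = 0.4
    rule_threshold: float = 0.5
    # penalized models
    penalized_folds: int = 10
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    cv_loss: str = "deviance"
    covariates_in_penalized: bool = True
    # forest
    mtry_grid: tuple | None = None
    nodesize_grid: tuple = (5, 15, 50)
    n_trees: int = 500
    forest_rank_by: str = "importance"
    forest_selection: bool = False
    # boosting
    xgb_grid: tuple | None = None
    xgb_folds: int = 5
    schema_version: int = SCHEMA_VERSION

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("alpha_grid", "nodesize_grid", "mtry_grid", "xgb_grid"):
            if d.get(key) is not None:
                d[key] = [dict(v) if isinstance(v, dict) else v for v in d[key]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = SyntheticConfig(**d["simulate"])
        for key in ("alpha_grid", "nodesize_grid", "mtry_grid", "xgb_grid"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d, schema_version=version)


def compute_rankings(Xs: AbundanceMatrix, meta: SampleMetadata, cfg: PipelineConfig,
                     methods: tuple[str, ...] = METHODS,
                     details: dict | None = None) -> dict[str, MethodRanking]:
    """Run the requested ranking methods on a preprocessed (scaled) matrix.

    Passing a dict as ``details`` collects per-method fitting metadata
    (CV traces, tuning grids, shrinkage intensities) for serialization.
    """
    out: dict[str, MethodRanking] = {}
    fids = list(Xs.feature_ids)
    if details is None:
        details = {}
    if "bonferroni" in methods or "fdr" in methods:
        scan = univariate_scan(Xs, meta)
        n_fit = int(scan.fitted.sum())
        if "bonferroni" in methods:
            out["bonferroni"] = rank_bonferroni(scan)
            details["bonferroni"] = {"n_tested": n_fit,
                                     "n_separated": int(scan.separated.sum())}
        if "fdr" in methods:
            out["fdr"] = rank_fdr(scan)
            details["fdr"] = {"n_tested": n_fit}
    if "lasso" in methods:
        beta, cv = fit_lasso_cv(Xs, meta, folds=cfg.penalized_folds, seed=cfg.seed,
                                covariates=cfg.covariates_in_penalized,
                                n_lambda=cfg.n_lambda,
                                lambda_min_ratio=cfg.lambda_min_ratio, loss=cfg.cv_loss)
        out["lasso"] = rank_by_abs_coefficients(beta, fids, "lasso")
        details["lasso"] = cv.to_dict()
    if "elastic_net" in methods:
        beta, cv = fit_elastic_net_cv(Xs, meta, alpha_grid=cfg.alpha_grid,
                                      folds=cfg.penalized_folds, seed=cfg.seed,
                                      covariates=cfg.covariates_in_penalized,
                                      n_lambda=cfg.n_lambda,
                                      lambda_min_ratio=cfg.lambda_min_ratio,
                                      loss=cfg.cv_loss)
        out["elastic_net"] = rank_by_abs_coefficients(beta, fids, "elastic_net")
        details["elastic_net"] = cv.to_dict()
    if "random_forest" in methods:
        model = tune_and_fit_forest(Xs, meta, mtry_grid=cfg.mtry_grid,
                                    nodesize_grid=cfg.nodesize_grid,
                                    n_trees=cfg.n_trees, seed=cfg.seed)
        md = minimal_depth(model)
        imp = forest_importance(model, Xs, meta)
        out["random_forest"] = rank_forest(md, imp, fids, by=cfg.forest_rank_by,
                                           selection=cfg.forest_selection)
        details["random_forest"] = {"mtry": model.mtry, "nodesize": model.nodesize,
                                    "oob_error": model.oob_error,
                                    "tuning_trace": model.tuning_trace}
    if "sda" in methods:
        res = cat_scan(Xs, meta)
        out["sda"] = rank_by_abs_cat(res, fids)
        details["sda"] = {"lambda_corr": res.lambda_corr,
                          "lambda_var": res.lambda_var}
    if "xgboost" in methods:
        kwargs = {} if cfg.xgb_grid is None else {"param_grid": cfg.xgb_grid}
        model = tune_and_fit_xgb(Xs, meta, folds=cfg.xgb_folds, seed=cfg.seed, **kwargs)
        out["xgboost"] = rank_xgb_gain(model, fids)
        details["xgboost"] = {"rounds": model.rounds, "max_depth": model.max_depth,
                              "learning_rate": model.learning_rate,
                              "cv_error": model.cv_error,
                              "tuning_trace": model.tuning_trace}
    return out


def _load_inputs(cfg: PipelineConfig, outdir: Path) -> tuple[AbundanceMatrix, SampleMetadata]:
    if cfg.abundance_path and cfg.phenotypes_path:
        m = AbundanceMatrix.read_tsv(cfg.abundance_path, stage="raw")
        meta = SampleMetadata.read_tsv(cfg.phenotypes_path)
        return m, meta
    m, meta = generate_dataset(cfg.simulate)
    write_dataset(outdir / "simulated", m, meta, cfg.simulate)
    return m, meta


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure aborts with the stage name and cause; artifacts of
    completed stages are retained.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("metaborank")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {"stages": [], "outputs": {}, "seed": cfg.seed,
                      "python": sys.version.split()[0], "platform": platform.platform(),
                      "schema_version": cfg.schema_version}
    cfg.to_yaml(outdir / "config.yaml")
    stage = "load_inputs"
    try:
        logger.info("stage %s", stage)
        raw, meta = _load_inputs(cfg, outdir)
        meta = meta.aligned_to(raw)
        manifest["stages"].append(stage)

        stage = "preprocess"
        logger.info("stage %s", stage)
        Xs = preprocess(raw, meta)
        manifest["stages"].append(stage)

        stage = "rankings"
        logger.info("stage %s", stage)
        details: dict = {}
        rankings = compute_rankings(Xs, meta, cfg, details=details)
        rank_paths = {}
        for name, r in rankings.items():
            path = outdir / f"ranking_{name}.tsv"
            r.write_tsv(path)
            rank_paths[name] = str(path)
        with open(outdir / "fit_details.json", "w") as fh:
            json.dump(details, fh, indent=2)
        manifest["outputs"]["rankings"] = rank_paths
        manifest["outputs"]["fit_details"] = str(outdir / "fit_details.json")
        manifest["stages"].append(stage)

        stage = "aggregation"
        logger.info("stage %s", stage)
        ordered = [rankings[m] for m in METHODS if m in rankings]
        agg = aggregate_rankings(ordered)
        agg.write_tsv(outdir / "aggregate.tsv")
        focus_n = min(cfg.n_focus, len(agg.feature_ids))
        if focus_n < cfg.n_focus:
            logger.warning("n_focus=%d exceeds feature count; using %d",
                           cfg.n_focus, focus_n)
        focused = focus_top(agg, focus_n)
        focused.write_tsv(outdir / "aggregate_top.tsv")
        manifest["outputs"]["aggregate"] = str(outdir / "aggregate.tsv")
        manifest["stages"].append(stage)

        stage = "convergence"
        logger.info("stage %s", stage)
        conv_paths = {}
        summaries = {}
        for name, r in rankings.items():
            if r.n_scored < 2:
                logger.warning("method %s scored %d features; convergence "
                               "diagnostic skipped", name, r.n_scored)
                continue
            k = min(cfg.k, r.n_scored)
            summary = conv_mod.summarize(Xs, r, k=max(k, 2),
                                         high_threshold=cfg.high_threshold,
                                         rule_threshold=cfg.rule_threshold)
            summaries[name] = summary
            cpath = outdir / f"convergence_{name}.json"
            with open(cpath, "w") as fh:
                json.dump(summary.to_dict(), fh, indent=2)
            np.savetxt(outdir / f"correlation_{name}.tsv", summary.corr,
                       delimiter="\t", fmt="%.6f")
            conv_paths[name] = str(cpath)
        manifest["outputs"]["convergence"] = conv_paths
        manifest["stages"].append(stage)

        stage = "cohort_table"
        logger.info("stage %s", stage)
        table = cohort_summary(meta)
        table.to_csv(outdir / "cohort_table.tsv", sep="\t", index=False)
        manifest["outputs"]["cohort_table"] = str(outdir / "cohort_table.tsv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    root.removeHandler(handler)
    handler.close()
    return outdir
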