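"""Convergence/divergence diagnostics of each method's top-k selections.

For every ranking method, take the k best-ranked features (k = 50 by
default), compute the k x k Pearson correlation matrix of their preprocessed
abundances, and summarize how intercorrelated the selection is:

* ``frac_high_pairs`` — share of unordered off-diagonal pairs with
  |R| >= high_threshold;
* ``frac_high_features`` — share of the selected features participating in
  at least one such pair.

A method whose top list is dominated by mutually correlated features
("convergent" — plausibly one pathway or chemical class) is distinguished
from one whose top list spans near-orthogonal features ("divergent") by a
simple participation rule: convergent if the feature-participation fraction
is at least ``rule_threshold`` (default 0.5).  The |R| >= 0.4 default for
"highly correlated" and the participation reading of "% of top features"
are package conventions, both configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import AbundanceMatrix, MethodRanking

logger = logging.getLogger(__name__)

HIGH_THRESHOLD = 0.4


@dataclass
class ConvergenceSummary:
    """Top-k correlation structure of one method's selection."""

    method: str
    top_k_ids: list[str]
    corr: np.ndarray
    frac_high_pairs: float
    frac_high_features: float
    r_range: tuple[float, float]     # (min, max) off-diagonal |R|
    high_threshold: float
    label: str = ""
    degenerate_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k": len(self.top_k_ids),
            "top_k_ids": self.top_k_ids,
            "high_threshold": self.high_threshold,
            "frac_high_pairs": self.frac_high_pairs,
            "frac_high_features": self.frac_high_features,
            "r_range": list(self.r_range),
            "label": self.label,
        }


def top_k(ranking: MethodRanking, k: int = 50) -> list[str]:
    """The k best-ranked (non-imputed) feature ids.

    If the method scored fewer than k features, all scored features are
    returned with a warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if ranking.n_scored < k:
        warnings.warn(
            f"method {ranking.method!r} scored only {ranking.n_scored} features; "
            f"top-{k} truncated", stacklevel=2)
    return ranking.top_ids(k)


def correlation_matrix(m: AbundanceMatrix, ids: list[str]) -> np.ndarray:
    """Pairwise Pearson correlations of the selected feature columns.

    Degenerate (zero-variance) columns get correlation 0 with every other
    feature (flag logged); the diagonal stays 1.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    pos = {f: i for i, f in enumerate(m.feature_ids)}
    missing = [f for f in ids if f not in pos]
    if missing:
        raise ValueError(f"features absent from matrix: {missing[:5]}")
    cols = m.values[:, [pos[f] for f in ids]]
    sd = cols.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d degenerate features in correlation matrix; their "
                       "correlations are set to 0", int(degenerate.sum()))
    safe = cols.copy()
    safe[:, degenerate] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(safe, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def fraction_correlated(corr: np.ndarray,
                        high_threshold: float = HIGH_THRESHOLD) -> tuple[float, float]:
    """(pair fraction, feature-participation fraction) of |R| >= threshold.

    The pair fraction is over unordered off-diagonal pairs; the
    participation fraction is the share of features in at least one
    high-correlation pair.
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    if k < 2:
        raise ValueError("need at least 2 features")
    iu = np.triu_indices(k, 1)
    high = np.abs(corr[iu]) >= high_threshold
    pair_frac = float(high.mean())
    mask = (np.abs(corr) >= high_threshold) & ~np.eye(k, dtype=bool)
    feat_frac = float(mask.any(axis=1).mean())
    return pair_frac, feat_frac


def classify_method(frac_high_features: float, rule_threshold: float = 0.5) -> str:
    """``convergent`` if the participation fraction >= rule_threshold, else
    ``divergent`` (boundary counts as convergent)."""
    return "convergent" if frac_high_features >= rule_threshold else "divergent"


def summarize(m: AbundanceMatrix, ranking: MethodRanking, k: int = 50,
              high_threshold: float = HIGH_THRESHOLD,
              rule_threshold: float = 0.5) -> ConvergenceSummary:
    """Full convergence diagnostic of one method's top-k selection."""
    ids = top_k(ranking, k)
    corr = correlation_matrix(m, ids)
    pair_frac, feat_frac = fraction_correlated(corr, high_threshold)
    kk = corr.shape[0]
    iu = np.triu_indices(kk, 1)
    absr = np.abs(corr[iu])
    r_range = (float(absr.min()), float(absr.max())) if absr.size else (0.0, 0.0)
    pos = {f: i for i, f in enumerate(m.feature_ids)}
    degenerate = [f for f in ids if m.degenerate[pos[f]]]
    return ConvergenceSummary(
        method=ranking.method, top_k_ids=ids, corr=corr,
        frac_high_pairs=pair_frac, frac_high_features=feat_frac,
        r_range=r_range, high_threshold=high_threshold,
        label=classify_method(feat_frac, rule_threshold),
        degenerate_ids=degenerate,
    )
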