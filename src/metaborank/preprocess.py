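"""Intensity normalization: log transform, batch median/MAD normalization, scaling.

The pipeline order is fixed — log -> batch -> scale — matching common
practice for plate-based metabolomics intensity data:

1. natural log of strictly positive raw intensities;
2. per feature and per batch, subtract the batch median and divide by the
   batch MAD (median absolute deviation times the 1.4826 normal-consistency
   constant), removing plate-to-plate location/scale drift;
3. global feature standardization to mean 0, unit (n-1) SD.

Zero-spread (degenerate) features are set to all zeros and flagged rather
than dropped, so feature indexing stays stable across ranking methods.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import AbundanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)

#: Normal-consistency constant putting the MAD on the SD scale.
MAD_CONSISTENCY = 1.4826


def log_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise natural log of raw intensities.

    Raises ``ValueError`` naming the first offending feature if any value
    is non-positive.
    """
    if m.stage != "raw":
        raise ValueError(f"log_transform expects stage 'raw', got {m.stage!r}")
    bad = ~(m.values > 0)
    if bad.any():
        j = int(np.argmax(bad.any(axis=0)))
        raise ValueError(
            f"non-positive intensity in feature {m.feature_ids[j]!r}; "
            "log transform requires strictly positive values"
        )
    return AbundanceMatrix(np.log(m.values), m.sample_ids, m.feature_ids,
                           stage="logged", degenerate=m.degenerate.copy())


def batch_median_mad_normalize(
    m: AbundanceMatrix,
    meta: SampleMetadata,
    mad_consistency: float = MAD_CONSISTENCY,
) -> AbundanceMatrix:
    """Per feature and batch: subtract the batch median, divide by batch MAD.

    The MAD is scaled by ``mad_consistency`` (1.4826) so it estimates the SD
    under normality.  A feature whose batch MAD is zero falls back to the
    feature's global MAD (warning logged); if that is also zero the feature
    is degenerate and set to all zeros.
    """
    if m.stage != "logged":
        raise ValueError(f"batch normalization expects stage 'logged', got {m.stage!r}")
    meta = meta.aligned_to(m)
    batches = meta.batch
    values = m.values.copy()
    degenerate = m.degenerate.copy()

    global_median = np.median(values, axis=0)
    global_mad = mad_consistency * np.median(np.abs(values - global_median), axis=0)

    out = np.empty_like(values)
    fallback_features: set[int] = set()
    for b in np.unique(batches):
        rows = batches == b
        block = values[rows]
        med = np.median(block, axis=0)
        mad = mad_consistency * np.median(np.abs(block - med), axis=0)
        zero = mad == 0
        if zero.any():
            fallback_features.update(np.flatnonzero(zero).tolist())
            # fall back to the global scale for those features in this batch
            mad = np.where(zero, global_mad, mad)
        # mad == 0 here means the global MAD is also zero; those features are
        # zeroed wholesale below once flagged degenerate.
        safe = np.where(mad == 0, 1.0, mad)
        out[rows] = (block - med) / safe

    if fallback_features:
        ids = [m.feature_ids[j] for j in sorted(fallback_features)]
        logger.warning(
            "batch MAD was zero for %d feature/batch combinations; used the "
            "global MAD instead (features: %s%s)",
            len(ids), ", ".join(ids[:5]), "..." if len(ids) > 5 else "",
        )
    newly_degenerate = global_mad == 0
    if newly_degenerate.any():
        out[:, newly_degenerate] = 0.0
        degenerate |= newly_degenerate
        logger.warning("%d features degenerate (global MAD zero); set to zeros",
                       int(newly_degenerate.sum()))
    return AbundanceMatrix(out, m.sample_ids, m.feature_ids,
                           stage="batch_normalized", degenerate=degenerate)


def scale_features(m: AbundanceMatrix) -> AbundanceMatrix:
    """Standardize every feature to sample mean 0 and unbiased (n-1) SD 1.

    Idempotent within floating tolerance; zero-variance features become zero
    columns with the degenerate flag set.
    """
    if m.stage not in ("batch_normalized", "scaled"):
        raise ValueError(f"scale_features expects stage 'batch_normalized', got {m.stage!r}")
    values = m.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = m.degenerate | (sd == 0)
    safe = np.where(sd == 0, 1.0, sd)
    out = (values - mean) / safe
    out[:, degenerate] = 0.0
    return AbundanceMatrix(out, m.sample_ids, m.feature_ids,
                           stage="scaled", degenerate=degenerate)


def preprocess(m: AbundanceMatrix, meta: SampleMetadata,
               mad_consistency: float = MAD_CONSISTENCY) -> AbundanceMatrix:
    """Full fixed-order pipeline: log -> batch median/MAD -> scale."""
    return scale_features(batch_median_mad_normalize(log_transform(m), meta,
                                                     mad_consistency=mad_consistency))
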