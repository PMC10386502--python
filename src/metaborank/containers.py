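"""Core data containers shared by every pipeline stage.

The common currency of the pipeline is an :class:`AbundanceMatrix`
(samples x metabolite features) together with a :class:`SampleMetadata`
table (binary outcome, age, sex, batch).  Every ranking method produces a
:class:`MethodRanking`: a per-feature score plus an integer rank where
1 = most important and features a method did not score/select carry an
imputed rank equal to the total feature count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("raw", "logged", "batch_normalized", "scaled")

#: Canonical method labels, in pipeline order.  Bonferroni and BH-FDR are
#: counted as separate methods throughout (they are tabulated separately
#: even though both derive from the same univariate fits).
METHODS = ("bonferroni", "fdr", "lasso", "elastic_net", "random_forest", "sda", "xgboost")


@dataclass
class AbundanceMatrix:
    """Samples x features intensity matrix with a processing-stage label.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float array.  Raw intensities must be
        strictly positive; from stage ``logged`` onwards all values must be
        finite.
    sample_ids, feature_ids
        Ordered, unique identifiers matching the matrix dimensions.
    stage
        One of ``raw``, ``logged``, ``batch_normalized``, ``scaled``.
    degenerate
        Boolean flag per feature, set when a feature had zero spread and was
        forced to all zeros during normalization/scaling.  Degenerate
        features are retained as zero columns so feature indexing is stable
        across methods.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    stage: str = "raw"
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match {len(self.sample_ids)} "
                f"sample ids / {len(self.feature_ids)} feature ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicated feature ids")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage != "raw" and not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values at stage {self.stage!r}")
        if self.degenerate is None:
            self.degenerate = np.zeros(p, dtype=bool)
        else:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)
            if self.degenerate.shape != (p,):
                raise ValueError("degenerate flag length must equal n_features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.feature_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stage: str = "raw") -> "AbundanceMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), stage=stage)

    @classmethod
    def read_tsv(cls, path: str | Path, stage: str = "raw") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df, stage=stage)


@dataclass
class SampleMetadata:
    """Per-sample phenotype table: binary outcome, age, sex, batch.

    The outcome encodes the clinical contrast (1 = idiopathic PAH,
    0 = non-idiopathic PAH in the motivating application); age is in years,
    sex and batch are categorical labels.
    """

    table: pd.DataFrame
    signal_features: list[str] = field(default_factory=list)

    REQUIRED = ("sample_id", "outcome", "age", "sex", "batch")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicated sample ids in metadata")
        outcome = df["outcome"].to_numpy()
        if not np.isin(outcome, [0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        age = df["age"].to_numpy(dtype=float)
        if np.any((age <= 0) | (age >= 120)):
            raise ValueError("age must lie in (0, 120)")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"].astype(str))

    @property
    def outcome(self) -> np.ndarray:
        return self.table["outcome"].to_numpy(dtype=int)

    @property
    def age(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=float)

    @property
    def sex_indicator(self) -> np.ndarray:
        """Sex as a 0/1 indicator (1 = female) for model design matrices."""
        sex = self.table["sex"]
        if sex.dtype.kind in "if":
            return sex.to_numpy(dtype=float)
        return (sex.astype(str).str.upper().isin(["F", "FEMALE", "1"])).to_numpy(dtype=float)

    @property
    def batch(self) -> np.ndarray:
        return self.table["batch"].to_numpy()

    def aligned_to(self, m: AbundanceMatrix) -> "SampleMetadata":
        """Reorder rows to match the abundance matrix's sample order."""
        idx = self.table.set_index(self.table["sample_id"].astype(str))
        missing = [s for s in m.sample_ids if s not in idx.index]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing[:5]}")
        out = idx.loc[m.sample_ids].reset_index(drop=True)
        return SampleMetadata(out, signal_features=list(self.signal_features))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class MethodRanking:
    """One method's per-feature score and rank (1 = most important).

    Features the method did not score or select are flagged ``imputed`` and
    all share the rank ``n_total`` (the total feature count), so that rank
    aggregation is defined over the full feature universe.  Non-imputed
    features carry the integers ``1..s`` (s = number scored) after the
    method's documented tie-breaks.
    """

    method: str
    feature_ids: list[str]
    score: np.ndarray
    rank: np.ndarray
    imputed: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.score = np.asarray(self.score, dtype=float)
        self.rank = np.asarray(self.rank, dtype=int)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        p = len(self.feature_ids)
        if not (self.score.shape == self.rank.shape == self.imputed.shape == (p,)):
            raise ValueError("score/rank/imputed must align with feature_ids")
        s = int((~self.imputed).sum())
        got = np.sort(self.rank[~self.imputed])
        if s and not np.array_equal(got, np.arange(1, s + 1)):
            raise ValueError("non-imputed ranks must be the integers 1..s")
        if np.any(self.imputed) and not np.all(self.rank[self.imputed] == p):
            raise ValueError("imputed features must share rank = total feature count")
        if s and not np.all(np.isfinite(self.score[~self.imputed])):
            raise ValueError("non-imputed scores must be finite")

    @property
    def n_scored(self) -> int:
        return int((~self.imputed).sum())

    def top_ids(self, k: int) -> list[str]:
        order = np.argsort(self.rank, kind="stable")
        keep = [i for i in order if not self.imputed[i]][:k]
        return [self.feature_ids[i] for i in keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": self.feature_ids,
            "score": self.score,
            "rank": self.rank,
            "imputed": self.imputed,
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, method: str) -> "MethodRanking":
        df = pd.read_csv(path, sep="\t")
        return cls(method, list(df["feature_id"].astype(str)), df["score"].to_numpy(),
                   df["rank"].to_numpy(), df["imputed"].to_numpy(dtype=bool))


def rank_descending(feature_ids: list[str], score: np.ndarray, selected: np.ndarray,
                    method: str) -> MethodRanking:
    """Build a MethodRanking by descending score among selected features.

    Ties in the score are broken lexicographically by feature id so reruns
    are bit-identical; unselected features are imputed at rank = total
    feature count.
    """
    score = np.asarray(score, dtype=float)
    selected = np.asarray(selected, dtype=bool)
    p = len(feature_ids)
    rank = np.full(p, p, dtype=int)
    idx = np.flatnonzero(selected)
    # sort by (-score, feature_id)
    order = sorted(idx, key=lambda i: (-score[i], feature_ids[i]))
    for r, i in enumerate(order, start=1):
        rank[i] = r
    out_score = np.where(selected, score, np.nan)
    return MethodRanking(method, list(feature_ids), out_score, rank, ~selected)
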