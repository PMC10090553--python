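"""SCN-score stratification of cell lines and HI/LO group comparison.

Cell lines carry a continuous small-cell-neuroendocrine (SCN) phenotype score
(from a published PLSR model; consumed as input, never re-derived here) and a
lineage label.  A single cutoff partitions lines into SCN HI (score >= cutoff)
and SCN LO; per-line quantities (expression, dependency) are compared between
the groups with a two-sided Mann-Whitney rank-sum test.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class ScnAnnotation:
    """Per-cell-line annotation: index = cell-line id; columns ``scn_score``
    (finite float) and ``lineage`` (label).  Synthetic annotations carry an
    extra ``truth_group`` column."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.empty:
            raise ValidationError("annotation is empty")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell-line ids: {dup[:5]}")
        for col in ("scn_score", "lineage"):
            if col not in df.columns:
                raise ValidationError(f"annotation lacks column {col!r}")
        scores = df["scn_score"].to_numpy(dtype=float)
        bad = ~np.isfinite(scores)
        if bad.any():
            raise ValidationError(
                f"non-finite SCN score for line {df.index[bad.argmax()]!r}")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.table.index)

    @property
    def scores(self) -> pd.Series:
        return self.table["scn_score"].astype(float)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScnAnnotation":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(df)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t")
        return path


@dataclass(frozen=True)
class GroupPartition:
    """Exhaustive, exclusive HI/LO split of the annotated lines."""

    hi: tuple[str, ...]
    lo: tuple[str, ...]
    cutoff: float

    def __post_init__(self) -> None:
        if set(self.hi) & set(self.lo):
            raise ValidationError("HI and LO groups overlap")

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.hi), len(self.lo)


def classify_scn(annotation: ScnAnnotation, cutoff: float) -> GroupPartition:
    """HI iff scn_score >= cutoff, else LO (boundary is inclusive on the HI
    side).  Order within each group follows the annotation order."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    scores = annotation.scores
    hi = tuple(scores.index[scores >= cutoff])
    lo = tuple(scores.index[scores < cutoff])
    return GroupPartition(hi=hi, lo=lo, cutoff=float(cutoff))


def cutoff_support(
    annotation: ScnAnnotation, lineage: str, cutoff: float
) -> tuple[float, int, int]:
    """Fraction of lines of one lineage at or above the cutoff.

    Used to justify a cutoff choice from a reference lineage's score
    distribution (e.g. the share of small-cell lung lines above it).
    """
    tab = annotation.table
    sel = tab["lineage"] == lineage
    n_total = int(sel.sum())
    if n_total == 0:
        raise ValidationError(f"no cell line carries lineage {lineage!r}")
    n_above = int((tab.loc[sel, "scn_score"].astype(float) >= cutoff).sum())
    return n_above / n_total, n_above, n_total


def rank_sum_compare(
    values: Mapping[str, float] | pd.Series, partition: GroupPartition
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided Mann-Whitney U comparing a per-line quantity between HI and LO.

    Midrank tie handling throughout.  The null is enumerated exactly when both
    groups have <= 8 non-missing values and the pooled sample is tie-free;
    otherwise the normal approximation with tie correction is used.  Returns
    (U for the HI sample, two-sided p, (median_hi, median_lo)).
    """
    series = pd.Series(values, dtype=float)
    hi_vals = series.reindex(list(partition.hi)).dropna().to_numpy()
    lo_vals = series.reindex(list(partition.lo)).dropna().to_numpy()
    if hi_vals.size == 0 or lo_vals.size == 0:
        raise ValidationError("a group has no non-missing values")
    pooled = np.concatenate([hi_vals, lo_vals])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.max() == pooled.min():
        # all observations identical: U is its null mean, no evidence either way
        return hi_vals.size * lo_vals.size / 2.0, 1.0, (float(np.median(hi_vals)),
                                                        float(np.median(lo_vals)))
    method = "exact" if (hi_vals.size <= 8 and lo_vals.size <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(hi_vals, lo_vals, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), p, (float(np.median(hi_vals)), float(np.median(lo_vals)))
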