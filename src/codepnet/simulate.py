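"""Synthetic data with planted, recorded ground truth.

Every downstream stage of the pipeline is testable without downloads: this
module generates SCN annotations, dependency-score matrices with planted
anchor co-dependencies, two-cohort expression matrices with planted
correlation blocks, gene-set collections with planted enrichment, and
transcription-factor lists.  All generators are pure functions of their
parameters and an explicit seed.

Noise model.  Gaussian throughout: planted anchor correlations use the
bivariate-normal construction ``y = rho * x + noise_sd * sqrt(1 - rho^2) * eps``
and planted blocks the equicorrelated one-factor construction
``x_g = sqrt(rho) * f + noise_sd * sqrt(1 - rho) * eps_g``, so at the default
``noise_sd = 1.0`` the expected sample correlation equals the planted value
exactly, and ``noise_sd = 0`` degenerates to perfect correlation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneSet, GeneSetCollection, MatrixTable
from .scn import ScnAnnotation


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DependencyTruth:
    """Planted anchor correlations per gene and group, plus TF flags."""

    anchor: str
    rho_hi: dict[str, float]
    rho_lo: dict[str, float]
    tf_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.rho_hi) != set(self.rho_lo):
            raise ValidationError("rho_hi and rho_lo cover different gene sets")
        if self.anchor not in self.rho_hi:
            raise ValidationError("anchor missing from truth gene universe")
        for table in (self.rho_hi, self.rho_lo):
            if abs(table[self.anchor] - 1.0) > 0:
                raise ValidationError("anchor's planted self-correlation must be 1")
            for g, rho in table.items():
                if not -1.0 <= rho <= 1.0:
                    raise ValidationError(f"planted rho for {g!r} outside [-1, 1]: {rho}")
        unknown_tfs = set(self.tf_genes) - set(self.rho_hi)
        if unknown_tfs:
            raise ValidationError(f"TF genes outside universe: {sorted(unknown_tfs)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.rho_hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rho_hi": pd.Series(self.rho_hi),
            "rho_lo": pd.Series(self.rho_lo),
            "tf": pd.Series({g: g in self.tf_genes for g in self.rho_hi}),
        }).rename_axis("gene")

    @classmethod
    def build(
        cls,
        genes: Sequence[str],
        anchor: str,
        rho_hi: Mapping[str, float] | None = None,
        rho_lo: Mapping[str, float] | None = None,
        tf_genes: Sequence[str] = (),
    ) -> "DependencyTruth":
        """Universe-wide truth with 0 as the default planted value."""
        hi = {g: 0.0 for g in genes}
        lo = {g: 0.0 for g in genes}
        hi.update(rho_hi or {})
        lo.update(rho_lo or {})
        hi[anchor] = lo[anchor] = 1.0
        return cls(anchor=anchor, rho_hi=hi, rho_lo=lo, tf_genes=tuple(tf_genes))


@dataclass(frozen=True)
class CohortBlockSpec:
    """Block structure for one cohort: gene -> block id and block -> target
    correlation.  Singleton blocks (or unassigned genes) are independent."""

    assignments: dict[str, str]
    block_rho: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.assignments.values()) - set(self.block_rho)
        if missing:
            raise ValidationError(f"blocks without a target rho: {sorted(missing)[:5]}")
        for bid, rho in self.block_rho.items():
            if not -1.0 < rho < 1.0:
                raise ValidationError(f"block {bid!r} target outside (-1, 1): {rho}")
            m = sum(1 for b in self.assignments.values() if b == bid)
            if m > 1 and rho < -1.0 / (m - 1):
                raise ValidationError(
                    f"block {bid!r}: rho={rho} infeasible (not PSD) for size {m}")

    @property
    def genes(self) -> list[str]:
        return list(self.assignments)


@dataclass(frozen=True)
class NetworkTruth:
    """Two-cohort planted correlation structure with shared anchors."""

    cohorts: dict[str, CohortBlockSpec]
    anchors: tuple[str, ...] = ()

    def spec(self, cohort: str) -> CohortBlockSpec:
        if cohort not in self.cohorts:
            raise ValidationError(f"unknown cohort {cohort!r}")
        return self.cohorts[cohort]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_scn_annotation(
    n_hi: int,
    n_lo: int,
    hi_center: float,
    lo_center: float,
    spread: float,
    seed: int,
    cutoff: float = 1.1,
    hi_lineage: str = "SCNC",
    lo_lineage: str = "NON_SCN",
) -> ScnAnnotation:
    """Cell-line annotation with scores drawn from two Gaussians.

    Truth labels go into a ``truth_group`` column.  A warning is recorded when
    a group centre sits within one ``spread`` of the intended cutoff (the two
    score distributions then overlap it materially).
    """
    if n_hi <= 0 or n_lo <= 0:
        raise ValidationError("group counts must be positive")
    if spread <= 0:
        raise ValidationError("spread must be positive")
    if hi_center < cutoff + spread or lo_center > cutoff - spread:
        warnings.warn(
            f"group centres ({hi_center}, {lo_center}) overlap the cutoff {cutoff} "
            f"within one spread ({spread}); truth recovery will be imperfect",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    scores = np.concatenate([
        rng.normal(hi_center, spread, size=n_hi),
        rng.normal(lo_center, spread, size=n_lo),
    ])
    n = n_hi + n_lo
    ids = [f"CL{i:04d}" for i in range(1, n + 1)]
    table = pd.DataFrame(
        {
            "scn_score": scores,
            "lineage": [hi_lineage] * n_hi + [lo_lineage] * n_lo,
            "truth_group": ["HI"] * n_hi + ["LO"] * n_lo,
        },
        index=pd.Index(ids, name="cell_line"),
    )
    return ScnAnnotation(table)


def gen_dependency_matrix(
    truth: DependencyTruth,
    annotation: ScnAnnotation,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    n_genes: int | None = None,
) -> MatrixTable:
    """Dependency-score matrix with planted per-group anchor correlations.

    Within each truth group the anchor's scores are standard normal and every
    other gene follows the bivariate-normal construction, so at the default
    ``noise_sd`` the expected sample correlation with the anchor equals the
    planted value.  Missing cells are inserted completely at random at
    ``missing_rate``.
    """
    if n_genes is not None and n_genes != len(truth.genes):
        raise ValidationError(
            f"n_genes={n_genes} does not match truth universe ({len(truth.genes)})")
    if not 0.0 <= missing_rate < 1.0:
        raise ValidationError(f"missing_rate must be in [0, 1), got {missing_rate}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if "truth_group" not in annotation.table.columns:
        raise ValidationError("annotation lacks the truth_group column")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    others = [g for g in genes if g != truth.anchor]
    cols: list[np.ndarray] = []
    lines: list[str] = []
    for group, rho_map in (("HI", truth.rho_hi), ("LO", truth.rho_lo)):
        members = annotation.table.index[annotation.table["truth_group"] == group]
        if len(members) == 0:
            continue
        m = len(members)
        x = rng.standard_normal(m)
        eps = rng.standard_normal((len(others), m))
        rho = np.array([rho_map[g] for g in others])[:, None]
        block = rho * x[None, :] + noise_sd * np.sqrt(1.0 - rho**2) * eps
        full = np.empty((len(genes), m))
        full[genes.index(truth.anchor)] = x
        oi = [i for i, g in enumerate(genes) if g != truth.anchor]
        full[oi] = block
        cols.append(full)
        lines.extend(members)
    values = np.concatenate(cols, axis=1)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=lines)
    return MatrixTable(df)


def gen_cohort_expression(
    spec: CohortBlockSpec,
    n_samples: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    sample_prefix: str = "S",
) -> MatrixTable:
    """Expression matrix with equicorrelated planted blocks.

    Genes in one block share a latent factor (expected pairwise correlation =
    the block target at ``noise_sd = 1``); genes in different blocks are
    independent.  Negative block targets use the Cholesky factor of the
    equicorrelation matrix and require ``noise_sd = 1``.
    """
    if n_samples < 3:
        raise ValidationError("need n_samples >= 3")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = spec.genes
    values = np.empty((len(genes), n_samples))
    by_block: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_block.setdefault(spec.assignments[g], []).append(i)
    for bid, idx in sorted(by_block.items()):
        rho = spec.block_rho[bid]
        m = len(idx)
        if m == 1 or rho == 0.0:
            values[idx] = rng.standard_normal((m, n_samples))
        elif rho > 0:
            f = rng.standard_normal(n_samples)
            eps = rng.standard_normal((m, n_samples))
            values[idx] = np.sqrt(rho) * f[None, :] + noise_sd * np.sqrt(1.0 - rho) * eps
        else:
            if noise_sd != 1.0:
                raise ValidationError(
                    "negative block correlations are supported only at noise_sd=1")
            cov = np.full((m, m), rho)
            np.fill_diagonal(cov, 1.0)
            chol = np.linalg.cholesky(cov)
            values[idx] = chol @ rng.standard_normal((m, n_samples))
    cols = [f"{sample_prefix}{i:03d}" for i in range(1, n_samples + 1)]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=cols)
    return MatrixTable(df)


def gen_gene_sets(
    profile_truth: Mapping[str, float] | pd.Series,
    n_sets: int,
    set_size: int,
    n_enriched: int,
    seed: int,
    top_fraction: float = 0.1,
) -> tuple[GeneSetCollection, dict[str, bool]]:
    """Gene-set collection with ``n_enriched`` sets planted at the top of a
    truth profile and the rest drawn uniformly (null).

    Enriched members come uniformly from the top ``top_fraction`` of the
    profile (at least ``set_size`` genes).  Returns the collection and a
    set-name -> is-enriched truth map.
    """
    truth = pd.Series(profile_truth, dtype=float).sort_values(ascending=False)
    universe = list(truth.index)
    if set_size >= len(universe):
        raise ValidationError(
            f"set_size={set_size} must be smaller than the gene universe ({len(universe)})")
    if not 0 <= n_enriched <= n_sets:
        raise ValidationError("need 0 <= n_enriched <= n_sets")
    rng = np.random.default_rng(seed)
    pool_size = max(set_size, int(np.ceil(top_fraction * len(universe))))
    top_pool = universe[:pool_size]
    coll = GeneSetCollection()
    labels: dict[str, bool] = {}
    width = max(3, len(str(n_sets)))
    for i in range(1, n_sets + 1):
        name = f"GS{i:0{width}d}"
        enriched = i <= n_enriched
        source = top_pool if enriched else universe
        members = tuple(rng.choice(source, size=set_size, replace=False))
        coll.add(GeneSet(name, "synthetic", members))
        labels[name] = enriched
    return coll, labels


def gen_tf_list(truth: DependencyTruth) -> list[str]:
    """The planted transcription-factor symbols, in universe order."""
    if not truth.tf_genes:
        raise ValidationError("truth carries no TF genes")
    return list(truth.tf_genes)
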