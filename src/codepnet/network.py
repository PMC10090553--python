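"""Per-cohort correlation gene networks and differential-network ranking.

A "gene network" here is the vector of correlation coefficients between one
anchor gene's expression profile and every other gene's, within one cohort.
Networks are computed anchor-wise (one row of the correlation matrix at a
time); the full all-pairs matrix is materialised only on request, for small
instances and brute-force cross-checks.

A network signature collects the genes correlated above a cutoff (strictly,
signed) with EVERY anchor in one cohort; cross-state assessment measures how
those genes' correlations collapse in the other cohort; the differential
profile ranks all common genes by delta = r(cohort B) - r(cohort A), the
substrate for preranked enrichment and extreme-annotation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import masked_pearson, masked_spearman
from .errors import ValidationError
from .io import MatrixTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneNetwork:
    """Anchor-centred correlation vector in one cohort.

    ``coefficients`` is indexed by gene and includes the anchor itself with
    value 1.0; genes whose correlation is undefined (constant within the
    cohort) are absent and listed in ``dropped``.
    """

    cohort: str
    anchor: str
    coefficients: pd.Series
    method: str = "pearson"
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.coefficients.to_numpy(dtype=float)
        if np.any(np.isnan(vals)) or np.any(np.abs(vals) > 1.0 + 1e-12):
            raise ValidationError("network coefficients must be defined and in [-1, 1]")
        if self.anchor not in self.coefficients.index:
            raise ValidationError("anchor missing from its own network")

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients.index)


@dataclass(frozen=True)
class NetworkSignature:
    """Genes correlated above ``cutoff`` with every anchor in one cohort."""

    anchors: tuple[str, ...]
    cohort: str
    cutoff: float
    members: tuple[str, ...]


@dataclass(frozen=True)
class DifferentialNetworkProfile:
    """Per common gene: delta = r(B) - r(A) with a deterministic descending
    rank (ties broken lexicographically)."""

    anchor: str
    cohort_a: str
    cohort_b: str
    table: pd.DataFrame  # index gene; columns delta, rank; sorted by rank

    @property
    def n_common(self) -> int:
        return len(self.table)

    @property
    def deltas(self) -> pd.Series:
        return self.table["delta"]


def build_network(
    expr: MatrixTable,
    anchor: str,
    method: str = "pearson",
    cohort: str = "",
) -> GeneNetwork:
    """Correlate every gene against the anchor across all cohort samples."""
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if anchor not in expr.data.index:
        raise ValidationError(f"anchor {anchor!r} not in expression matrix")
    if expr.shape[1] < 3:
        raise ValidationError("need at least 3 samples to build a network")
    y = expr.data.loc[anchor].to_numpy(dtype=float)
    finite_y = y[np.isfinite(y)]
    if finite_y.size < 3 or finite_y.max() == finite_y.min():
        raise ValidationError(f"anchor {anchor!r} is constant or too sparse")
    genes = expr.row_ids
    X = expr.values
    kernel = masked_pearson if method == "pearson" else masked_spearman
    r, _, _ = kernel(X, y)
    coeff = pd.Series(r, index=pd.Index(genes, name="gene"))
    dropped = tuple(coeff.index[coeff.isna()])
    coeff = coeff.dropna()
    coeff.loc[anchor] = 1.0  # exact by definition
    if dropped:
        log.info("build_network(%s/%s): dropped %d constant genes",
                 cohort, anchor, len(dropped))
    return GeneNetwork(cohort=cohort, anchor=anchor, coefficients=coeff,
                       method=method, dropped=dropped)


def correlation_matrix(expr: MatrixTable, method: str = "pearson") -> pd.DataFrame:
    """Explicit all-pairs correlation matrix (small instances only)."""
    meth = "pearson" if method == "pearson" else "spearman"
    return expr.data.T.corr(method=meth, min_periods=3)


def extract_signature(
    networks: Sequence[GeneNetwork], cutoff: float
) -> NetworkSignature:
    """Genes with coefficient strictly above ``cutoff`` in every anchor
    network; anchors themselves are excluded.  Members are ordered by
    descending minimum coefficient across anchors (ties: symbol)."""
    if not networks:
        raise ValidationError("need at least one anchor network")
    if not (-1.0 < cutoff < 1.0):
        raise ValidationError(f"cutoff must lie in (-1, 1), got {cutoff}")
    cohorts = {net.cohort for net in networks}
    if len(cohorts) != 1:
        raise ValidationError(f"networks come from different cohorts: {sorted(cohorts)}")
    anchors = tuple(net.anchor for net in networks)
    common = set(networks[0].genes)
    for net in networks[1:]:
        common &= set(net.genes)
    common -= set(anchors)
    min_coeff = {
        g: min(float(net.coefficients[g]) for net in networks) for g in common
    }
    members = tuple(
        g for g in sorted(common, key=lambda g: (-min_coeff[g], g))
        if min_coeff[g] > cutoff
    )
    return NetworkSignature(anchors=anchors, cohort=networks[0].cohort,
                            cutoff=float(cutoff), members=members)


def cross_state_assessment(
    signature: NetworkSignature,
    other: Mapping[str, GeneNetwork] | Sequence[GeneNetwork],
) -> pd.DataFrame:
    """How a signature from one cohort behaves in the other cohort.

    For each anchor: the fraction of signature members whose coefficient in
    the other cohort's network falls strictly below the signature cutoff, and
    a five-number summary of those coefficients (the violin plot reduced to
    numbers).  Returns a DataFrame indexed by anchor.
    """
    if not isinstance(other, Mapping):
        other = {net.anchor: net for net in other}
    rows = []
    for anchor in signature.anchors:
        if anchor not in other:
            raise ValidationError(f"no other-cohort network for anchor {anchor!r}")
        net = other[anchor]
        coeffs = net.coefficients.reindex(list(signature.members)).dropna()
        if coeffs.empty:
            raise ValidationError(
                f"signature members and other-cohort network for {anchor!r} are disjoint")
        vals = coeffs.to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(dict(
            anchor=anchor,
            fraction_below=float((vals < signature.cutoff).mean()),
            n_members=len(signature.members),
            n_evaluated=int(vals.size),
            min=float(vals.min()), q1=float(q1), median=float(med),
            q3=float(q3), max=float(vals.max()),
        ))
    return pd.DataFrame(rows).set_index("anchor")


def differential_profile(
    net_b: GeneNetwork, net_a: GeneNetwork
) -> DifferentialNetworkProfile:
    """delta = r(B) - r(A) on the genes present in both networks, ranked
    descending (rank 1 = most B-specific association)."""
    if net_b.anchor != net_a.anchor:
        raise ValidationError(
            f"anchor mismatch: {net_b.anchor!r} vs {net_a.anchor!r}")
    common = net_b.coefficients.index.intersection(net_a.coefficients.index)
    if len(common) < 2:
        raise ValidationError("fewer than 2 genes common to both networks")
    delta = (net_b.coefficients[common] - net_a.coefficients[common]).astype(float)
    tab = pd.DataFrame({"delta": delta})
    tab["symbol"] = tab.index
    tab = tab.sort_values(["delta", "symbol"], ascending=[False, True]).drop(columns="symbol")
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab.index.name = "gene"
    log.info("differential_profile(%s): %d common genes", net_b.anchor, len(tab))
    return DifferentialNetworkProfile(
        anchor=net_b.anchor, cohort_a=net_a.cohort, cohort_b=net_b.cohort, table=tab)


def annotate_extremes(
    profile: DifferentialNetworkProfile,
    gene_set: Sequence[str],
    top_n: int,
) -> tuple[int, int, tuple[str, ...], tuple[str, ...]]:
    """Count gene-set members among the top_n highest- and lowest-delta genes.

    Returns (count_top, count_bottom, members_top, members_bottom), the
    members in profile rank order.
    """
    n = profile.n_common
    if top_n > n / 2:
        raise ValidationError(f"top_n={top_n} exceeds half the profiled genes ({n})")
    genes_sorted = list(profile.table.index)  # already rank order
    wanted = set(gene_set)
    top = tuple(g for g in genes_sorted[:top_n] if g in wanted)
    bottom = tuple(g for g in genes_sorted[-top_n:] if g in wanted)
    return len(top), len(bottom), top, bottom
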