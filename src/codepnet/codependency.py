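"""Anchored co-dependency screening of gene-perturbation score matrices.

Given a dependency matrix (genes x cell lines; DEMETER2/CERES-style, lower =
more dependent) and an anchor gene, every other gene's profile is correlated
with the anchor's across a chosen group of cell lines (pairwise-complete
Pearson and Spearman).  The candidate funnel then keeps genes that are
significantly correlated in the SCN HI group, rank in the top K positively
correlated genes, belong to a transcription-factor list, and are NOT also
significant-positive co-dependencies in the SCN LO group.

A "co-dependency in LO" is operationalised as (p < alpha AND r > 0), mirroring
the HI-side definition; the per-gene provenance records which funnel stage
eliminated each non-candidate so the rule can be audited.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from ._stats import masked_pearson, masked_spearman, pearson_pair, spearman_pair
from .errors import ValidationError
from .io import MatrixTable

log = logging.getLogger(__name__)

#: columns of a co-dependency table, one row per screened gene
CODEP_COLUMNS = ["pearson_r", "pearson_p", "pearson_q", "spearman_rho",
                 "spearman_p", "n_used", "rank_positive"]


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with two-sided t-test p (df = n - 2).

    Raises :class:`ValidationError` when fewer than 3 complete pairs exist or
    either vector is constant on the complete pairs.
    """
    r, p, n = pearson_pair(np.asarray(x, float), np.asarray(y, float))
    if np.isnan(r):
        raise ValidationError(
            f"correlation undefined: n_complete={n}, constant or too short")
    return r, p, n


def spearman_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pairwise-complete Spearman rho (Pearson on midranks) with t-approx p."""
    rho, p, n = spearman_pair(np.asarray(x, float), np.asarray(y, float))
    if np.isnan(rho):
        raise ValidationError(
            f"correlation undefined: n_complete={n}, constant or too short")
    return rho, p, n


def screen(
    dep: MatrixTable,
    anchor: str,
    lines: Sequence[str],
    alpha: float = 0.05,
    min_n: int = 10,
) -> pd.DataFrame:
    """Correlate every non-anchor gene against the anchor within a line group.

    Returns a DataFrame indexed by gene with columns :data:`CODEP_COLUMNS`.
    ``rank_positive`` is 1..K over genes with pearson_p < alpha and
    pearson_r > 0, ordered by descending r (ties: smaller p, then symbol);
    other genes get <NA>.  ``pearson_q`` is a Benjamini-Hochberg column for
    transparency; it does not gate the funnel.  Genes with fewer than
    ``min_n`` complete pairs or an undefined correlation are excluded and
    recorded in ``result.attrs["excluded"]``.
    """
    if anchor not in dep.data.index:
        raise ValidationError(f"anchor {anchor!r} not present in dependency matrix")
    sub = dep.subset_cols(lines)
    genes = [g for g in sub.row_ids if g != anchor]
    X = sub.data.loc[genes].to_numpy(dtype=float)
    y = sub.data.loc[anchor].to_numpy(dtype=float)
    r, p, n = masked_pearson(X, y)
    rho, sp, _ = masked_spearman(X, y)

    keep = (~np.isnan(r)) & (~np.isnan(rho)) & (n >= min_n)
    excluded = {}
    for i, g in enumerate(genes):
        if not keep[i]:
            excluded[g] = "n_below_min" if n[i] < min_n else "undefined_correlation"
    if excluded:
        log.info("screen(%s): excluded %d genes", anchor, len(excluded))

    kept = np.asarray(genes, dtype=object)[keep]
    out = pd.DataFrame(
        {
            "pearson_r": r[keep],
            "pearson_p": p[keep],
            "pearson_q": false_discovery_control(p[keep]) if keep.any() else [],
            "spearman_rho": rho[keep],
            "spearman_p": sp[keep],
            "n_used": n[keep].astype(int),
        },
        index=pd.Index(kept, name="gene"),
    )
    out["rank_positive"] = pd.array([pd.NA] * len(out), dtype="Int64")
    sig_pos = out.index[(out["pearson_p"] < alpha) & (out["pearson_r"] > 0)]
    if len(sig_pos):
        block = out.loc[sig_pos, ["pearson_r", "pearson_p"]].copy()
        block["symbol"] = block.index
        order = block.sort_values(
            ["pearson_r", "pearson_p", "symbol"], ascending=[False, True, True]
        ).index
        out.loc[order, "rank_positive"] = np.arange(1, len(order) + 1)
    out.attrs["anchor"] = anchor
    out.attrs["alpha"] = float(alpha)
    out.attrs["min_n"] = int(min_n)
    out.attrs["n_lines"] = len(list(lines))
    out.attrs["excluded"] = excluded
    return out


@dataclass(frozen=True)
class CandidateReport:
    """Funnel outcome: ordered candidates plus per-TF provenance.

    ``table`` has one row per transcription factor present in the HI screen,
    with HI/LO statistics, the boolean funnel predicates, and ``excluded_by``
    naming the first failed stage (or <NA> for candidates).
    """

    candidates: tuple[str, ...]
    table: pd.DataFrame
    top_k: int
    alpha: float


def candidate_filter(
    hi: pd.DataFrame,
    lo: pd.DataFrame,
    tf_list: Sequence[str],
    top_k: int = 100,
    alpha: float = 0.05,
) -> CandidateReport:
    """Apply the four-stage candidate funnel to HI and LO screen tables.

    A candidate must be (1) significant in HI (pearson_p < alpha), (2) ranked
    in the top ``top_k`` positively correlated genes in HI, (3) a member of
    ``tf_list``, and (4) not a significant-positive co-dependency in LO.
    """
    tf_list = list(dict.fromkeys(tf_list))
    if not tf_list:
        raise ValidationError("transcription-factor list is empty")
    rows = []
    for gene in tf_list:
        in_hi = gene in hi.index
        r_hi = hi.at[gene, "pearson_r"] if in_hi else np.nan
        p_hi = hi.at[gene, "pearson_p"] if in_hi else np.nan
        rank = hi.at[gene, "rank_positive"] if in_hi else pd.NA
        in_lo = gene in lo.index
        r_lo = lo.at[gene, "pearson_r"] if in_lo else np.nan
        p_lo = lo.at[gene, "pearson_p"] if in_lo else np.nan
        sig_hi = bool(in_hi and p_hi < alpha)
        rank_ok = bool(rank is not pd.NA and not pd.isna(rank) and rank <= top_k)
        lo_codep = bool(in_lo and p_lo < alpha and r_lo > 0)
        if not in_hi:
            excluded = "not_screened"
        elif not sig_hi:
            excluded = "significance"
        elif not rank_ok:
            excluded = "rank"
        elif lo_codep:
            excluded = "lo_codependency"
        else:
            excluded = pd.NA
        rows.append(
            dict(gene=gene, r_hi=r_hi, p_hi=p_hi, rank_hi=rank, r_lo=r_lo,
                 p_lo=p_lo, tf=True, significant_hi=sig_hi, top_k_hi=rank_ok,
                 lo_codependency=lo_codep, selected=pd.isna(excluded),
                 excluded_by=excluded)
        )
    table = pd.DataFrame(rows).set_index("gene")
    selected = table.index[table["selected"]]
    ordered = sorted(selected, key=lambda g: (int(table.at[g, "rank_hi"]), g))
    return CandidateReport(candidates=tuple(ordered), table=table,
                           top_k=int(top_k), alpha=float(alpha))


def codependency_concordance(
    hi_a: pd.DataFrame, hi_b: pd.DataFrame, gene: str
) -> tuple[float, float, bool]:
    """Compare one gene's anchor correlation between two screens (e.g. an
    RNAi-derived and a CRISPR-derived matrix): (r_a, r_b, same sign)."""
    for name, tab in (("first", hi_a), ("second", hi_b)):
        if gene not in tab.index:
            raise ValidationError(f"gene {gene!r} missing from {name} screen table")
    r_a = float(hi_a.at[gene, "pearson_r"])
    r_b = float(hi_b.at[gene, "pearson_r"])
    return r_a, r_b, bool(np.sign(r_a) == np.sign(r_b))
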