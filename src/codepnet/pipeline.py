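"""End-to-end orchestration: simulate -> classify -> codep -> network ->
diffnet -> gsea, with per-stage seeds, provenance headers and a run manifest.

Stage seeds derive deterministically from the master seed; every output file
gets a '#'-prefixed provenance block (tool version, config hash, stage seed)
and is hashed into the manifest, so a re-run under the same configuration is
byte-identical (the manifest's wall-stamp aside).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .codependency import candidate_filter, screen
from .config import RunConfig, ScenarioConfig
from .errors import ValidationError
from .gsea import RankedProfile, gsea
from .io import (
    MatrixTable,
    read_gmt,
    read_matrix,
    read_symbol_list,
    write_gmt,
    write_matrix,
    write_symbol_list,
    write_table,
)
from .network import (
    annotate_extremes,
    build_network,
    cross_state_assessment,
    differential_profile,
    extract_signature,
)
from .scn import ScnAnnotation, classify_scn, cutoff_support
from .simulate import (
    CohortBlockSpec,
    DependencyTruth,
    NetworkTruth,
    gen_cohort_expression,
    gen_dependency_matrix,
    gen_gene_sets,
    gen_scn_annotation,
)

log = logging.getLogger(__name__)

COHORT_A = "ADCA"
COHORT_B = "NEPC"


def stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage 31-bit seeds derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def config_hash(config: RunConfig) -> str:
    """Hash of the analysis parameters (the output location is not one)."""
    d = config.to_dict()
    d.pop("outdir", None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_scenario_truth(sc: ScenarioConfig, anchor: str) -> dict[str, Any]:
    """Materialise the planted ground truth implied by a ScenarioConfig.

    Dependency side: ``n_tfs`` transcription factors planted as strong HI
    co-dependencies of the anchor, of which ``n_tf_excluded`` are also
    positive LO co-dependencies (to be excluded by the funnel) and the rest
    carry a weakly negative LO association; all remaining genes are null.

    Expression side: the anchor sits in a strong block in each cohort — a
    ``block_size_a``-gene block in cohort A only and a ``block_size_b``-gene
    block in cohort B only — against an independent background, so the
    differential profile has planted top (B-specific) and bottom
    (A-specific) extremes.
    """
    tfs = [f"TF{i:02d}" for i in range(1, sc.n_tfs + 1)]
    n_bg = sc.n_genes - 1 - sc.n_tfs
    dep_genes = [anchor, *tfs, *[f"D{i:04d}" for i in range(1, n_bg + 1)]]
    excluded = tfs[: sc.n_tf_excluded]
    retained = tfs[sc.n_tf_excluded:]
    dep_truth = DependencyTruth.build(
        genes=dep_genes,
        anchor=anchor,
        rho_hi={tf: sc.rho_tf_hi for tf in tfs},
        rho_lo={**{tf: sc.rho_tf_lo_excluded for tf in excluded},
                **{tf: sc.rho_tf_lo_retained for tf in retained}},
        tf_genes=tfs,
    )

    gain_b = [f"N{i:04d}" for i in range(1, sc.block_size_b + 1)]   # B-specific
    gain_a = [f"A{i:04d}" for i in range(1, sc.block_size_a + 1)]   # A-specific
    n_singletons = sc.n_expr_genes - 1 - len(gain_a) - len(gain_b)
    singles = [f"B{i:04d}" for i in range(1, n_singletons + 1)]
    expr_genes = [anchor, *gain_a, *gain_b, *singles]

    def _spec(block_genes: list[str], rho: float, block_id: str) -> CohortBlockSpec:
        assignments = {anchor: block_id}
        for g in block_genes:
            assignments[g] = block_id
        for g in expr_genes:
            assignments.setdefault(g, f"single_{g}")
        block_rho = {block_id: rho}
        block_rho.update({f"single_{g}": 0.0 for g in expr_genes
                          if assignments[g] == f"single_{g}"})
        return CohortBlockSpec(assignments=assignments, block_rho=block_rho)

    net_truth = NetworkTruth(
        cohorts={
            COHORT_A: _spec(gain_a, sc.block_rho_a, "blockA"),
            COHORT_B: _spec(gain_b, sc.block_rho_b, "blockB"),
        },
        anchors=(anchor,),
    )
    # planted differential (B - A) truth, used to seed the gene-set fixture
    delta_truth = pd.Series(0.0, index=pd.Index(expr_genes, name="gene"))
    delta_truth[gain_b] = sc.block_rho_b
    delta_truth[gain_a] = -sc.block_rho_a
    return dict(dep_truth=dep_truth, net_truth=net_truth, delta_truth=delta_truth,
                tfs=tfs, retained_tfs=retained, gain_a=gain_a, gain_b=gain_b)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in dependency order and write a manifest.

    Returns the manifest dict; every stage entry records its parameters,
    seed, and input/output file hashes.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    chash = config_hash(config)
    manifest: dict[str, Any] = {
        "tool": "codepnet",
        "version": __version__,
        "config_hash": chash,
        "master_seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }

    def _prov(stage: str, seed: int | None = None) -> dict[str, Any]:
        p: dict[str, Any] = {"tool": f"codepnet {__version__}",
                             "config_hash": chash, "stage": stage}
        if seed is not None:
            p["seed"] = seed
        return p

    def _record(stage: str, params: dict[str, Any], inputs: list[Path],
                outputs: list[Path], seed: int | None = None) -> None:
        manifest["stages"][stage] = {
            "parameters": params,
            "seed": seed,
            "inputs": {str(p.relative_to(outdir)): _sha256(p) for p in inputs},
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        }

    # ------------------------------------------------------------------ simulate
    indir = outdir / "inputs"
    indir.mkdir(exist_ok=True)
    if config.inputs.provided:
        dep = read_matrix(config.inputs.dependency)
        annotation = ScnAnnotation.from_tsv(config.inputs.annotation)
        expr_a = read_matrix(config.inputs.expr_a)
        expr_b = read_matrix(config.inputs.expr_b)
        sets = read_gmt(config.inputs.gmt)
        tf_list = read_symbol_list(config.inputs.tf_list)
        tracked_a: list[str] = []
        tracked_b: list[str] = []
    else:
        sc = config.scenario
        truth = build_scenario_truth(sc, config.anchor)
        annotation = gen_scn_annotation(
            sc.n_hi, sc.n_lo, sc.hi_center, sc.lo_center, sc.spread,
            seed=seeds[0], cutoff=config.cutoff)
        dep = gen_dependency_matrix(
            truth["dep_truth"], annotation, missing_rate=sc.missing_rate,
            seed=seeds[1])
        expr_a = gen_cohort_expression(
            truth["net_truth"].spec(COHORT_A), sc.n_cohort_a,
            seed=seeds[2], sample_prefix="A")
        expr_b = gen_cohort_expression(
            truth["net_truth"].spec(COHORT_B), sc.n_cohort_b,
            seed=seeds[3], sample_prefix="B")
        sets, set_labels = gen_gene_sets(
            truth["delta_truth"], sc.n_sets, sc.set_size, sc.n_enriched,
            seed=seeds[4])
        tf_list = truth["tfs"]
        tracked_a, tracked_b = truth["gain_a"], truth["gain_b"]

        outputs = [
            write_matrix(dep, indir / "dependency.csv"),
            annotation.to_tsv(indir / "annotation.tsv"),
            write_matrix(expr_a, indir / "expr_adca.tsv"),
            write_matrix(expr_b, indir / "expr_nepc.tsv"),
            write_gmt(sets, indir / "gene_sets.gmt"),
            write_symbol_list(tf_list, indir / "tf_list.txt"),
            write_table(truth["dep_truth"].to_frame(), indir / "dependency_truth.tsv",
                        provenance=_prov("simulate", seeds[1])),
            write_table(pd.DataFrame({"enriched": pd.Series(set_labels)})
                        .rename_axis("set"), indir / "set_truth.tsv",
                        provenance=_prov("simulate", seeds[4])),
        ]
        _record("simulate", dataclasses.asdict(sc), [], outputs, seed=seeds[0])

    # ------------------------------------------------------------------ classify
    partition = classify_scn(annotation, config.cutoff)
    part_df = pd.DataFrame(
        {"group": ["HI"] * len(partition.hi) + ["LO"] * len(partition.lo)},
        index=pd.Index([*partition.hi, *partition.lo], name="cell_line"),
    )
    support_rows = []
    for lineage in sorted(annotation.table["lineage"].unique()):
        frac, n_above, n_total = cutoff_support(annotation, lineage, config.cutoff)
        support_rows.append(dict(lineage=lineage, fraction_above=frac,
                                 n_above=n_above, n_total=n_total))
    out_part = write_table(part_df, outdir / "partition.tsv", provenance=_prov("classify"))
    out_sup = write_table(pd.DataFrame(support_rows).set_index("lineage"),
                          outdir / "cutoff_support.tsv", provenance=_prov("classify"))
    _record("classify", {"cutoff": config.cutoff, "n_hi": len(partition.hi),
                         "n_lo": len(partition.lo)}, [], [out_part, out_sup])

    # ------------------------------------------------------------------ codep
    hi_lines = [l for l in partition.hi if l in dep.data.columns]
    lo_lines = [l for l in partition.lo if l in dep.data.columns]
    hi_tab = screen(dep, config.anchor, hi_lines, alpha=config.alpha, min_n=config.min_n)
    lo_tab = screen(dep, config.anchor, lo_lines, alpha=config.alpha, min_n=config.min_n)
    report = candidate_filter(hi_tab, lo_tab, tf_list,
                              top_k=config.top_k, alpha=config.alpha)
    outputs = [
        write_table(hi_tab, outdir / "codep_hi.tsv", provenance=_prov("codep")),
        write_table(lo_tab, outdir / "codep_lo.tsv", provenance=_prov("codep")),
        write_table(report.table, outdir / "candidates.tsv", provenance=_prov("codep")),
    ]
    n_sig_hi = int((hi_tab["pearson_p"] < config.alpha).sum())
    _record("codep", {"anchor": config.anchor, "alpha": config.alpha,
                      "top_k": config.top_k, "min_n": config.min_n,
                      "n_screened_hi": len(hi_tab), "n_significant_hi": n_sig_hi,
                      "n_tfs": len(tf_list),
                      "n_candidates": len(report.candidates),
                      "candidates": list(report.candidates)},
            [], outputs)

    # ------------------------------------------------------------------ network
    net_a = build_network(expr_a, config.anchor, method=config.method, cohort=COHORT_A)
    net_b = build_network(expr_b, config.anchor, method=config.method, cohort=COHORT_B)
    sig_a = extract_signature([net_a], config.network_cutoff)
    sig_b = extract_signature([net_b], config.network_cutoff)
    outputs = [
        write_table(net_a.coefficients.rename("coefficient").to_frame(),
                    outdir / "network_adca.tsv", provenance=_prov("network")),
        write_table(net_b.coefficients.rename("coefficient").to_frame(),
                    outdir / "network_nepc.tsv", provenance=_prov("network")),
    ]
    cross: dict[str, pd.DataFrame] = {}
    for label, sig, other in ((f"{COHORT_A.lower()}_in_{COHORT_B.lower()}", sig_a, net_b),
                              (f"{COHORT_B.lower()}_in_{COHORT_A.lower()}", sig_b, net_a)):
        if sig.members:
            assessment = cross_state_assessment(sig, [other])
            cross[label] = assessment
            outputs.append(write_table(assessment, outdir / f"crossstate_{label}.tsv",
                                       provenance=_prov("network")))
    _record("network", {"method": config.method,
                        "network_cutoff": config.network_cutoff,
                        "signature_sizes": {COHORT_A: len(sig_a.members),
                                            COHORT_B: len(sig_b.members)}},
            [], outputs)

    # ------------------------------------------------------------------ diffnet
    profile = differential_profile(net_b, net_a)
    outputs = [write_table(profile.table, outdir / "diffnet.tsv",
                           provenance=_prov("diffnet"))]
    extreme_rows = []
    for name, genes in (("planted_a_specific", tracked_a),
                        ("planted_b_specific", tracked_b)):
        if genes:
            c_top, c_bot, m_top, m_bot = annotate_extremes(
                profile, genes, config.top_n_extremes)
            extreme_rows.append(dict(gene_set=name, count_top=c_top,
                                     count_bottom=c_bot,
                                     members_top=",".join(m_top),
                                     members_bottom=",".join(m_bot)))
    if extreme_rows:
        outputs.append(write_table(pd.DataFrame(extreme_rows).set_index("gene_set"),
                                   outdir / "extremes.tsv", provenance=_prov("diffnet")))
    _record("diffnet", {"n_common": profile.n_common,
                        "top_n_extremes": config.top_n_extremes}, [], outputs)

    # ------------------------------------------------------------------ gsea
    ranked = RankedProfile.from_differential(profile)
    gsea_tab = gsea(ranked, sets, weight_p=config.weight_p, n_perm=config.n_perm,
                    seed=seeds[5], min_hits=config.min_hits,
                    max_hits=config.max_hits)
    out_gsea = write_table(gsea_tab, outdir / "gsea.tsv",
                           provenance=_prov("gsea", seeds[5]))
    _record("gsea", {"weight_p": config.weight_p, "n_perm": config.n_perm,
                     "min_hits": config.min_hits, "max_hits": config.max_hits,
                     "n_sets_tested": len(gsea_tab),
                     "n_sets_excluded": len(gsea_tab.attrs.get("excluded", {}))},
            [], [out_gsea], seed=seeds[5])

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("pipeline finished: %s", outdir)
    return manifest
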