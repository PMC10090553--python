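# Methods

## Scope and model

`codepnet` implements a four-stage informatic procedure for nominating
context-specific gene vulnerabilities from perturbation screens and tumour
transcriptomes:

1. **Phenotype stratification.** Cell lines carry a continuous small-cell
   neuroendocrine (SCN) phenotype score (unitless, PLSR-derived; consumed as
   input — the score model is out of scope). Lines with score ≥ c form the
   SCN HI group, the rest SCN LO. The boundary is inclusive on the HI side.
   The default c = 1.1 lives in configuration, not code: it is fixed by
   inspection of a reference lineage's score distribution, which is a data
   choice, and `cutoff_support` reports the fraction of a lineage at or above
   any candidate cutoff to support that choice. Group comparisons of a
   per-line quantity use a two-sided Mann–Whitney U with midranks; the null
   is enumerated exactly when both groups have ≤ 8 tie-free values and uses
   the tie-corrected normal approximation otherwise (a completely tied pooled
   sample short-circuits to U = n₁n₂/2, p = 1).

2. **Anchored co-dependency screen.** Within a line group, every gene's
   dependency profile (DEMETER2/CERES-style scores; lower = more dependent)
   is correlated against an anchor gene's profile. Correlations are
   pairwise-complete Pearson (and Spearman, i.e. Pearson on midranks
   recomputed per gene over exactly the pairs present for that gene); the
   two-sided p comes from t = r·√((n−2)/(1−r²)) on n−2 df. Genes with fewer
   than `min_n` (default 10) complete pairs or a constant profile are
   excluded with a recorded reason. The candidate funnel keeps genes that
   are (i) significant in HI at raw p < α (default 0.05 — no
   multiple-testing gate, matching the procedure being reproduced; a
   Benjamini–Hochberg column is emitted for transparency), (ii) ranked in
   the top K (default 100) positively correlated genes by descending r
   (ties: smaller p, then symbol), (iii) members of a transcription-factor
   list, and (iv) **not** significant-positive co-dependencies in the LO
   group — "co-dependency in LO" mirrors the HI definition (p < α and
   r > 0); the per-gene provenance records which stage removed each
   non-candidate so the convention is auditable.

3. **Correlation gene networks and differential ranking.** In each cohort,
   the anchor's "gene network" is the vector of its expression-correlation
   coefficients with every other gene, computed anchor-wise so the ~20k×20k
   all-pairs matrix is never materialised (an explicit `correlation_matrix`
   exists for small instances and brute-force cross-checks). Pearson is the
   default method; Spearman is a flag. Genes constant within a cohort are
   dropped from that cohort's network, which naturally yields unequal
   per-cohort universes and a common core for differential profiling. A
   *network signature* is the set of genes with coefficient strictly above
   the cutoff (default 0.7, signed) with **every** anchor; cross-state
   assessment reports, per anchor, the fraction of signature members falling
   strictly below that cutoff in the other cohort plus a five-number summary
   (the violin plot reduced to numbers). The differential profile is
   Δ = r(cohort B) − r(cohort A) per common gene, ranked descending with
   lexicographic tie-break; `annotate_extremes` counts a gene set's members
   in the top/bottom N of that ranking.

4. **Preranked GSEA.** Re-implemented from the running-sum definition:
   walking the Δ-ranked list, hits add |Δ|^p (normalised to total 1 over
   hits; p defaults to 1, the classic weighting) and misses subtract
   1/(N−N_hits); ES is the signed extremum of the walk (a positive/negative
   tie resolves to the positive excursion, with a 10⁻¹² guard so exact ties
   are not decided by rounding order). All-zero hit weights fall back to the
   unweighted statistic. The null is gene-label permutation — n_perm
   (default 1000) random same-size draws per set — the only valid null for a
   preranked list, which is already a derived statistic. p is the one-tailed
   fraction of matching-sign null ES at least as extreme, with +1 smoothing
   (so p ≥ 1/(n_perm+1)); NES divides ES by the mean null ES of matching
   sign; FDR q follows the sign-stratified pooled-null NES procedure of the
   original GSEA method, with plain BH on nominal p available as a
   cross-check flag. Sets overlapping the profile outside
   [min_hits, max_hits] = [5, 500] are skipped with a recorded reason.

Two small effect-size helpers round out the reporting:
relative percent reduction (c−t)·100/c (computed in that order so that
decimally printed inputs give exact printed outputs) and a
reference-normalised ratio (a/b)/ref, both with positivity validation.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, with recorded
ground truth:

- **SCN annotations** draw HI/LO scores from two Gaussians (defaults:
  46 vs 445 lines, centres 2.0/0.0, spread 0.2 around cutoff 1.1) and keep
  the truth label alongside; a warning fires if a centre sits within one
  spread of the cutoff.
- **Dependency matrices** plant per-group anchor correlations by the
  bivariate-normal construction y = ρ·x + noise_sd·√(1−ρ²)·ε. At the
  default noise_sd = 1 the expected sample correlation equals ρ exactly;
  noise_sd scales only the idiosyncratic part (0 degenerates to perfect
  correlation). Missingness is completely at random (default 2%) —
  structured screen artefacts (seed effects, copy-number confounding) are
  deliberately not modelled; scores are simulated directly.
- **Cohort expression** uses equicorrelated one-factor blocks
  x_g = √ρ·f + noise_sd·√(1−ρ)·ε_g (negative ρ via Cholesky of the
  equicorrelation matrix, feasible down to −1/(m−1)); cohort sizes default
  to 33 and 14. Real tumour covariance (library-size effects, heavy tails,
  overlapping modules) is not emulated, so passing tests demonstrate
  correctness of the machinery and its statistical calibration under
  Gaussianity, not robustness to real-data pathologies.
- **Gene sets**: n_enriched sets drawn uniformly from the top decile of a
  truth profile (pool never smaller than the set size), the rest uniform
  from the whole universe; 237 sets of 25 by default, mirroring a
  50-hallmark + 187-oncogenic collection in shape.

The default end-to-end scenario plants: six TFs at ρ_HI = 0.7 with the
anchor, three of which carry ρ_LO = 0.4 (to be excluded by the funnel) and
three ρ_LO = −0.1 (retained); an anchor block of 10 genes at ρ = 0.85 in
cohort A only and one of 40 genes at ρ = 0.8 in cohort B only, against an
independent background of 500 dependency / 300 expression genes. Effect
sizes encode the funnel's *categorical* structure deliberately strongly: at
n_LO = 445 the sampling sd of r is ≈ 0.047, so ρ_LO = −0.1 makes "not a
co-dependency" unambiguous, whereas a borderline value would turn the
6 → 3 exclusion into a coin flip; the separate effect-size-recovery check
uses the moderate planted value 0.412 at n = 46, where detection power at
α = 0.05 is ≈ 0.8.

## Numerical choices

- Symbol canonicalisation is uppercase + strip everywhere (matrices, GMT,
  TF lists); an optional flag strips trailing "(ENTREZ)" tokens from
  screen-portal headers. Duplicates after canonicalisation are integrity
  errors, not silent merges.
- Matrix writes use the shortest round-trip float repr and "NA" for
  missing; reads parse via numpy's correctly-rounded string→float64
  conversion, so write→read is bit-exact.
- Constant-vector detection uses the exact range of the masked values, not
  a variance tolerance.
- Correlation p-values are floored at the smallest positive double so the
  open-interval contract p ∈ (0, 1] holds even at |r| = 1.
- All rankings (positive-rank in the screen, Δ ranking, profile ordering)
  break ties deterministically by symbol; every generator and the GSEA
  permutation null are pure functions of (parameters, seed), with per-stage
  seeds derived from the master seed via a seed sequence.
- Pipeline outputs carry a provenance header (tool version, hash of the
  analysis parameters, stage seed) and are hashed into a run manifest;
  re-running a configuration reproduces every output byte-identically (the
  manifest's wall-stamp is the one intentionally non-reproducible field).

## Problem sizes

Tests and the acceptance script run the study at desk scale: screens of
500 genes × 491 lines (46/445), cohorts of 300 genes × 33/14 samples, 237
gene sets at 1000 permutations, 50–200 replicate simulations per
calibration check. These sizes were chosen so that sampling-noise targets
(e.g. a ±0.05 band on a median correlation over 200 replicates) are
statistically meaningful while a full run stays in the minutes range on one
core.

## Known limitations

- The cross-state divergence check has an intrinsic power ceiling at the
  14-sample cohort size: a null correlation estimated from 14 samples has
  sd ≈ 0.28, so any single dissolved-block gene escapes the bottom decile
  of the differential profile with probability ≈ 6–7% per realisation.
  Requiring *all* block genes in the bottom decile therefore cannot succeed
  in ≳ 93% of realisations for any block size (measured ≈ 72% for a
  4-gene block); the corresponding test records this honestly rather than
  relaxing the planted conditions. The fraction-below-cutoff statistic is
  robust at the same sizes (≥ 0.9 in ≈ 99% of realisations).
- Raw p-values gate the funnel by design; users screening genome-scale
  matrices should read the emitted BH column before interpreting the 695-of-
  16,810-style counts such screens produce.
- Whether the 0.7 signature cutoff applies to signed or absolute
  coefficients was an open convention; signed (> 0.7) is implemented, so
  strong negative associations never enter a signature but do appear in
  cross-state summaries.
- No graph-topology analytics, partial correlations, batch correction, or
  normalisation: expression input is assumed pre-normalised log-scale.
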