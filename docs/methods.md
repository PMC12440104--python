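# Methods

This note documents the models, defaults, and numerical choices behind
`pgin`, and what the synthetic-data tests do and do not establish.

## Filter cascade

Stages run in a fixed order: quality → artefact exclusion → rarity and
recurrence → damaging classification. Every threshold is a strict
inequality exactly as stated for the underlying tools (DP>10, GQ>20, QD>5,
MQ>40, ReadPosRankSum>−3, MQRankSum>−10, FS<200, QUAL>50; depth > preset;
MAX_AF < 0.01; recurrence > 70% / > 50% / > 33%). Two policies are
deliberate and configurable:

- **Missing quality metrics pass vacuously** (`strict_missing_quality`
  off by default). RNA-seq callers omit rank-sum statistics at homozygous
  sites; discarding on absence would silently empty real data. Strict mode
  drops any record missing a metric.
- **Missing MAX_AF counts as rare** (`missing_af_is_rare`, default on).
  Absence from a population catalog is itself evidence of rarity; the
  alternative reading is one switch away, and the difference is testable
  because the reader never coerces a blank cell to 0.

Recurrence denominators are the number of samples in the analysis set, not
the number of samples bearing variants; variant identity across samples is
(chrom, pos, ref, alt). The damaging rule defaults to the *union* reading
(PolyPhen damaging OR SIFT deleterious OR nonsense/nonstop, ClinVar-benign
veto); the *intersection* reading (PolyPhen AND SIFT) is implemented and
selectable because the wording of such cascades is genuinely ambiguous.
The WGS cell-line preset applies only the variant-level recurrence cut
(33%); its gene-level threshold is set to 1.0, i.e. disabled.

A rare-but-not-damaging variant reports `stage_failed="damaging"`, so
`stage_failed is None` is exactly equivalent to surviving every stage.

## Genomic instability

Burden = rare variants / covered megabases, where the covered region is
the sample's own genome positions at depth ≥ threshold (50× placental,
10× circulating, 30× WGS) from its `genomecov` histogram. Note the
asymmetry, mirrored from how each cut is stated: the *denominator* uses
≥ threshold, the variant *depth filter* uses strictly >. Indels count in
the numerator by default (`include_indels_in_burden`); the investigation
covers single-nucleotide and insertion/deletion variants alike, and an
SNV-only mode exists for sensitivity analyses. A sample with zero covered
positions raises an error rather than returning 0 or NaN — it has failed
coverage QC and its score is undefined.

## Mutational signatures

The 96 channels follow the standard COSMIC ordering (six pyrimidine
substitution classes × 16 flank pairs, flanks alphabetical) and the order
is written into every catalog file; reference matching refuses catalogs
whose channel order differs, because silent order mismatch is the classic
failure mode. Purine-reference SNVs are folded by reverse complement (ref,
alt, and both flanks complemented, flanks swapped). SNVs lacking flank
context are dropped with a logged count.

Extraction is NMF under the Frobenius objective with multiplicative
updates (tolerance 1e-6 relative change, max 5000 iterations), best of 10
random restarts, fully seeded. Signatures are normalized to probability
vectors with exposures rescaled, ordered by total exposure, and labelled
SBSA, SBSB, … Rank is user-chosen (`signature_rank`, default 3); the rank
question is left to the user because reconstruction-error/stability scans
across strata can legitimately pick different K per stratum.

In the end-to-end pipeline, catalogs are built from the post-quality,
post-artefact **somatic** SNV set, not the rare subset: signature
characterization operates on the variant calls before rarity filtering,
and a few dozen rare SNVs per sample is too sparse for a stable
factorization.

**Packaged reference.** `data/synthetic_sbs_reference.tsv` contains four
*synthetic analog* probability vectors reproducing the shape motifs of
SBS1 (NpCpG C>T spikes), SBS5 (flat clock-like), SBS18 (C>A, oxidative
damage), and SBS34 (T>A at A/T homopolymer boundaries), with pairwise
cosines ≤ 0.30. They are suitable for testing and for demonstrating the
matching machinery; they are not the published vectors, and production
analyses should pass a real catalog via `reference_signature_path`.

## Hypoxia scoring

Per-gene cohort median (even n → mean of the middle two), +1 strictly
above, −1 otherwise. Exact ties take the −1 branch by default — this
implements the printed "greater than median" predicate as a binary split —
with `hypoxia_tie_score: 0` available since the tie case is genuinely
unspecified. Per-signature sums and the combined (three-signature) sum are
both emitted; downstream stages use the combined sum by default. Because
only within-gene ranks matter, any per-sample-normalized abundance (TPM,
logCPM) is acceptable; cross-sample normalization is the caller's
responsibility. The packaged gene lists are synthetic placeholders for
testing; real signature lists are supplied as two-column TSV.

## Outcome statistics

- **Groups.** Early preterm is strictly gestational age < 34.0 weeks,
  composed with the PE flag into EP-N / NTT-N / EP-PE / NTT-PE.
- **Rank tests.** Mann-Whitney U via SciPy, exact when group sizes permit
  and no ties are present; BH correction is applied across the family of
  pairs tested in one call, never across calls.
- **Enrichment.** Two-sided Fisher p sums all tables with probability ≤
  the observed table's (the dominant convention). Both the conditional-MLE
  odds ratio with its exact CI and the cross-product (sample) OR are
  reported, since published tables rarely say which they print. An empty
  margin flags the OR undefined but still returns p.
- **Cox.** Penalizer chosen from {0, 0.01, 0.1, 1} by mean held-out
  partial log-likelihood over 5 deterministic folds (own fold split;
  seeded). Proportionality is checked per feature by the
  scaled-Schoenfeld-residual score test at p < 0.05; failing features are
  squared and the model refit exactly once (no iteration). Partial-effect
  curves evaluate the fitted model at a feature's 10th/90th percentiles
  (original scale, squared after transform) with other features at their
  means, as cumulative incidence 1 − S(t) with proper step-function
  semantics (survival is 1 before the first observed event).

## Prediction

KNN with k = 5, uniform weights, Euclidean distance. Features are **not**
standardized by default — that is the documented behaviour of the default
configuration, and it means raw feature scales weight the metric; a
`standardize` switch (fit on training folds only) is provided and its
effect should be checked when feature scales differ by orders of
magnitude. Fetal sex is encoded 0/1 (female/male). Discovery performance
is pooled out-of-fold over seeded stratified folds, giving one
reproducible ROC per feature set; external validation fits once on the
full training table and scores the held-out table once, with nothing from
the test table entering any fitted quantity. Accuracy uses a fixed ≥ 0.5
decision rule. Per-outcome feature sets: burden + hypoxia + fetal sex for
PE and MVM; maternal age joins for SGA.

## Synthetic cohort generator

The generator's defaults encode the study design the package targets:
112 samples in groups 23 EP-N / 30 NTT-N / 20 EP-PE / 39 NTT-PE;
~120 detected variants per sample scaled by covered megabases (30–60 Mb
at the 50× threshold, which yields cohort rare/damaging counts of the
same order as a real placental cohort); 40% of variants rare, 25% of rare
variants damaging; small per-metric quality-failure fractions; planted
per-group signature mixtures over the packaged analogs (EP-PE dominated
by the oxidative C>A shape with a minor T>A component, EP-N by the flat
clock-like background); a one-log-unit expression up-shift on hypoxia
genes per unit of the hypoxia latent; and planted log hazard ratios
ln(1.7) (instability) and ln(1.3) (hypoxia) on gestational-age-to-event.

Gestational ages come from a shifted-exponential proportional-hazards
model (baseline 0.04 events/week past week 20, censoring at 42). Two
labelling schemes exist: *fixed counts* (default) draws event times
truncated to each group's gestational-age window, with a 0.01-week margin
so rounding cannot cross the 34-week boundary — group sizes are then
exact; *hazard* (`group_counts: null`) draws event times freely, and is
the scheme used for hazard-ratio recovery and calibration tests because
truncation distorts the likelihood the Cox model assumes. Per-sample
signature mixtures drift toward the clock-like analog as the instability
latent grows, planting the positive contribution–burden rank correlation
the pipeline measures. A recurrent hotspot variant (~80% of samples) and
a recurrent gene (~60%) are planted so the recurrence filters always have
work to do. One root seed fans out to independent substreams (groups,
variants, coverage, expression, survival), making bundles byte-identical
across runs.

What the generator does **not** emulate: alignment artefacts, true
RNA-editing biology (flags are drawn as labelled booleans), linkage
between sites, expression–variant coupling beyond the planted latents,
and any particular VAF distribution (VAF is a Beta(2,2) draw with no
claim of matching observed ranges). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to real-data artefacts.

## Replicate-test design

Cox calibration tests run the real generator with the variant loop scaled
to zero (`mean_variants_per_sample=0`) and minimal expression genes,
because only the survival component is consumed: null rejection rate uses
1000 replicates at n = 120 (Monte Carlo SE ≈ 0.007 around the nominal
0.05), CI coverage 100 replicates at n = 150, and the n = 500 recovery
check a single seeded cohort (estimator SD ≈ 0.06, verified unbiased).
The acceptance script averages the n = 500 recovery over 10 replicate
cohorts to report the estimator's behaviour rather than one draw.

## Known limitations

- The duplication-invariance of the Cox point estimate holds exactly only
  under Breslow tie handling; lifelines uses Efron, so duplicating a
  cohort shifts estimates by O(1/n) (tested at 1% tolerance).
- `extract_signatures` is a local optimizer; restarts mitigate but do not
  eliminate dependence on initialization, and closely collinear planted
  mixtures (as in realistic cohorts) yield mixed factors — the controlled
  recovery guarantees hold for well-separated signatures (pairwise cosine
  < 0.5).
- The minimal-VCF reader targets single-sample VCF 4.2 with annotations in
  INFO keys; multi-sample VCFs must be split upstream.
- KNN probability ties at exactly 0.5 classify positive under the ≥ 0.5
  rule, which can make accuracy asymmetric on tiny balanced cohorts.
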