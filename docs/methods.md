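# Methods

This note documents the models and procedures implemented in `ccfmtdna`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions used throughout. Coordinates are
0-based and half-open everywhere in the API; the only 1-based output is the
POS column of exported VCF.

## NUMT scanning (`numtscan`)

**Model.** The mitochondrial genome is circular; every one of its *L*
positions indexes a window of odd width *W* (default 101 bp) centred there,
wrapping across the origin, so a circular genome yields exactly *L* windows
with consecutive overlap *W* − 1. For each window the minimum Hamming
distance is the smallest mismatch count between the window *or its reverse
complement* and any ungapped placement along the nuclear genome. Low values
flag sequence that exists (near-)verbatim in the nucleus — candidate NUMTs
and unsafe PCR targets; `select_target_regions` returns maximal runs with
d_min at or above a threshold and at least a minimum length, merging runs
across the circular origin (a wrapped region is reported with `end > L`,
coordinates mod *L*).

**Algorithm.** The scan is exact, replacing heuristic alignment with an
exhaustive contract. Two code paths return identical values (this is
tested): a per-window strided comparison used for single queries, and a
diagonal sweep used for whole-genome profiles — along each diagonal of the
(window start × nuclear offset) grid the per-base equality indicator is a
1-D array whose length-*W* sliding sums give all match counts on that
diagonal, for O((L + N) · min(L, N)) vectorised byte operations per strand.
A 16.3-kb circle against a 50-kb nuclear genome profiles in seconds.
Reverse-complement hits are found by also scanning the reverse-complemented
nuclear sequence, which covers the same placement set.

**Conventions.** Any comparison involving N counts as a mismatch (even N vs
N) — conservative for primer design. Ties for the best match are irrelevant
since only the minimum is reported.

## Synthetic data (`synthdata`)

All generators draw from `numpy.random.default_rng(seed)` and are
bit-reproducible.

* **Genomes.** Background bases are i.i.d. uniform ACGT — the simplest null
  for Hamming-distance baselines. Planted NUMT copies receive exactly
  `n_mismatches` substitutions at positions sampled without replacement,
  each to a uniformly chosen different base, so the planted distance is
  exact by construction; overlapping inserts are rejected.
* **cfDNA fragments.** Fragment lengths follow a two-component truncated
  normal mixture; the defaults — means (95, 170) bp, SDs (20, 30), weights
  (0.22, 0.78), truncation [30, 500] bp — were chosen so that about 15% of
  fragments fall below 100 bp and about 40% below 150 bp, the fragmentation
  signature of plasma cfDNA after injury. Fragment starts are uniform on
  the circle (origin-wrapping fragments are kept; pileups count modulo
  *L*). A planted heteroplasmy is a molecule-level draw: each covering
  fragment carries the alternate base with probability equal to the allele
  fraction, before sequencing error, which substitutes each base
  independently (uniform over the other three bases). Strands are assigned
  independently with probability 1/2. Base qualities are a constant Q37 so
  quality filters are exercised by explicit low-quality injection in tests,
  not by noise. Not emulated: indels, chimeric reads, duplicates, GC or
  position-dependent error profiles — so passing tests demonstrate the
  logic of the filters, not robustness to real error structure.
* **Droplets.** Each droplet is positive independently with probability
  1 − exp(−conc × volume); the simulated assay carries `dilution=1`
  because the generating concentration is reaction-scale.
* **Metabolite matrices.** Per-metabolite baseline log₂ abundances are
  N(17, 1.5); per-entry noise is N(0, `noise_sd`) on the log₂ scale
  (lognormal intensities); the first `n_affected` metabolites are shifted by
  `effect_log2fc` in the second group; entries are missing completely at
  random. Real LC-MS features not emulated: intensity-dependent
  missingness, correlated metabolite blocks, batch effects.

## Fragmentomics (`fragmentomics`)

Fragment length = last aligned base − first aligned base + 1 of the pair.
The pair span runs from the minimum of both mates' first aligned bases to
the maximum of their last; unpaired or discordant reads are dropped with a
logged count. `fraction_below` is strict (<) and `fraction_in` is closed on
both ends, mirroring the way size fractions are quoted ("less than 100
bp"). The mapping-quality filter (default 30) applies to reads before
pairing; the base-quality threshold belongs to pileup construction, not to
length computation. The SAM writer emits proper pure-match read pairs whose
mates stretch to cover the whole span (so sequence and qualities round-trip
exactly); fragments wrapping the circular origin have no pure-match linear
representation and are skipped with a logged count — the TSV dialect
carries them faithfully.

## Heteroplasmy calling (`heteroplasmy`)

A site passes iff, in order: coverage **strictly greater than 400**
quality-passing bases; alt fraction ≥ 0.01; per-strand alt fraction ≥ 0.006
on both strands (denominator: that strand's quality-passing coverage); and
a two-sided Fisher exact test on the [alt, ref] × [+, −] table retains the
site at p ≥ α = 0.05. The evaluated alternate is the most abundant
non-reference base (ties broken toward the alphabetically first), and the
reported MAF is that base's fraction of total site coverage — multi-allelic
residue is ignored, matching a SNP-only report. Rejections carry the first
failed criterion, which makes threshold boundary behaviour directly
testable.

The strand-balance test and its α are a design choice: Fisher's exact test
is exact at the low per-strand counts that dominate near the 0.6% strand
threshold. Its discreteness means the realised type-I rate per balanced
site is ~3–5%, which bounds attainable end-to-end sensitivity: a planted
SNP must survive the strand test in every sample it is called in.

## Tissue of origin (`tissue_origin`)

Match key = identical (position, alternate allele); allele fractions are
not compared, since presence/absence is the reported evidence. Both plasma
and tissue sites must pass the identical calling criteria. Tissues with
zero passing sites are retained with count 0 (the leukocyte/buffy-coat
control). Categories partition the plasma set: unique + multiple +
unmatched = |plasma|.

## ddPCR quantification (`ddpcr_quant`)

λ = −ln(1 − p) is the Poisson-occupancy correction — the standard
instrument model and the only one consistent with absolute quantification;
`poisson=False` gives the raw-fraction alternative for comparison.
Droplet volume defaults to 0.00085 µL (nominal for the QX-class readers)
and the sample dilution to ×20; both are parameters. All-positive wells
are a saturation error, not an estimate. In the small-p limit the corrected
and raw estimates agree within 1% for p ≤ 0.02.

## Metabolomics (`metabolomics`)

* **KNN imputation** is feature-wise: neighbours are metabolites, distance
  is the root-mean-square difference over co-observed samples, and a
  missing entry is the mean of the k = 10 nearest metabolites observed in
  that sample (fallback: the metabolite's observed mean if no candidate
  shares samples).
* **Autoscaling** uses the n − 1 (sample) standard deviation — declared
  because software conventions differ.
* **PLS-DA** is single-response NIPALS with y ∈ {−1, +1}, mean-centred;
  weights are unit-norm, scores orthogonal across components; default
  A = 2 components (the usual score-plot configuration), configurable.
  Per-component explained response sum of squares SS_a = q_a² ·
  t_aᵀt_a weights the VIP score
  VIP_j = sqrt(p · Σ_a SS_a w_aj² / Σ_a SS_a), so Σ_j VIP_j² = p exactly.
  An independent cross-check against scikit-learn's PLSRegression (same
  model, different implementation) runs in the test suite.
* **LOOCV Q²** = 1 − PRESS/TSS with each sample predicted by a model refit
  without it (X and y re-centred per fold) and TSS about the overall mean.
  The matrix is autoscaled once before cross-validation, matching the
  transform-then-validate pipeline convention.
* **Volcano.** Fold change is the raw-scale group-mean ratio case/control
  (control = first label in order of appearance, overridable); the gate is
  direction-agnostic and inclusive (max(r, 1/r) ≥ 1.2), the q gate strict
  (BH q < 0.05); p-values are Welch two-sample t on log₂ data.
* **Pathway impact** I_p = VIP sum of significant members / VIP sum of all
  members ∈ [0, 1]; the per-tissue total is Σ_p I_p. The significant set
  defaults to the volcano result; a VIP > 1.5 cut can be supplied instead,
  since both criteria are in common use.

## Problem sizes and degenerate inputs

Simulation-based tests run at deliberately modest scale, chosen as the
smallest sizes at which the asserted statistics are stable: a 3-kb circular
mt genome at ~1000× coverage (≈20,000 fragments) for heteroplasmy recovery
and tissue-of-origin; 50,000 fragments for the size-distribution
convergence check (Kolmogorov–Smirnov distance < 0.05 against the
generating mixture; integer rounding of lengths contributes ≲0.005);
100-metabolite matrices with 10 samples per group for the PLS-DA/Q²
recovery suites; 20,000 droplets per simulated well. Degenerate inputs
fail loudly rather than silently: empty length sets, saturated wells,
all-missing metabolites, zero-variance columns, constant responses,
overlapping NUMT inserts, and unknown contigs all raise with specific
messages.

## Known limitations

* The Hamming scan is ungapped by design; an indel-containing NUMT copy
  appears as two high-distance halves rather than one low-distance hit.
* Heteroplasmy calling has no probabilistic genotype model; at allele
  fractions near the 1% threshold, sensitivity is governed directly by the
  binomial counts and the Fisher strand test's discreteness.
* Tissue-of-origin matching is presence/absence; it cannot apportion
  fractional contributions when several tissues share a variant.
* Q² values from real LC-MS experiments depend on the measured data and are
  not reproduced by simulation; the package asserts recovery behaviour
  (high Q² with planted separation, near-zero without), not specific
  values.
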