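# Methods

## Scope and data model

`mrdseq` analyzes tumor-informed MRD cohorts downstream of variant calling
and methylation quantification: its inputs are per-sample methylation-block
count tables (BED-like, 0-based half-open), per-patient tumor-tissue
methylation rates, a healthy-donor plasma panel, mutation call tables
(1-based coordinates, allelic fractions stored as fractions in [0, 1]), and
a longitudinal manifest with clinical metadata. Upstream steps — UMI
consensus calling, bisulfite alignment, clonal-hematopoiesis removal via
paired lymphocytes — are out of scope; the last is represented by a
`chip_filtered` flag that downstream summaries require (or explicitly
override).

## Block selection

A patient enters MRD scoring only if the resected tissue's tumor content is
at least 30%; below that, the tissue methylation profile is too diluted by
stroma to define tumor-specific blocks, and the boundary value itself is
eligible (the exclusion is strictly "less than").

With a single tumor observation per patient, a two-sample test against the
donor panel is not possible, so significance is a one-sided empirical rank
p-value: p = (1 + #{donors at least as extreme}) / (N + 1). Ties count as
extreme, p is in (0, 1], and a panel needs at least 20 donors before
p < 0.05 is attainable — the default simulated panel has 30. Selection
requires p < 0.05 *and* a tumor-vs-panel-mean shift of at least
`min_delta = 0.1` (configurable); the floor guards against consistent but
tiny technical shifts that a pure rank test would flag. The default
direction is tumor-hypermethylated blocks, the conventional signal for
plasma methylation MRD panels; hypomethylation tracking is a flag away. The
background rate attached to each selected block is the donor mean, clamped
to [1e-6, 1 − 1e-6] so that fully (un)methylated blocks cannot produce
log(0) downstream.

## The mixture likelihood and the MRD score

Plasma cfDNA is modeled as a two-component mixture with tumor fraction
α ∈ [0, 1] (the MD ratio). Per selected block j the methylated read count is
k_j ~ Binomial(n_j, θ_j(α)) with θ_j(α) = α·p_T,j + (1 − α)·p_N,j. Because
θ_j is linear in α and the binomial log-likelihood is concave in θ, the
summed log-likelihood is concave in α: the bounded scalar optimizer (Brent,
xatol = 1e-6) finds the global maximum, and a 1e-4 grid search is kept in
the package as an independent oracle (`grid_search_md_ratio`) that the
optimizer must match within 1e-3.

Numerical conventions:

* all rates and mixture probabilities are clamped to [1e-6, 1 − 1e-6];
* blocks with zero plasma reads are dropped before fitting (they contribute
  nothing) but counted in the fit's bookkeeping; a sample whose blocks have
  no reads at all is an error, not a zero;
* a likelihood flat in α (every p_T ≈ p_N) returns the null point α̂ = 0
  with infinite variance, and flat ties in general resolve to the smallest
  maximizing α — conservative toward the null.

The variance of α̂ is the inverse Fisher information evaluated at the
estimate, I(α) = Σ_j n_j (p_T,j − p_N,j)² / (θ_j (1 − θ_j)) — the
conventional plug-in Wald construction. The MRD score is α̂·√I(α̂) and a
sample is called positive when the score strictly exceeds 1.96, the
standard-normal upper-2.5% quantile. Since α is constrained to [0, 1] the
score is never negative, and under α = 0 it follows a half-normal boundary
null, so the 1.96 cutoff implies a ≈2.5% false-positive rate rather than 5%;
the test suite asserts the simulated rate stays below 5%.

## Mutation tracking

maxAF is the largest allelic fraction among a plasma sample's calls; an
undetected sample carries *no* maxAF rather than 0, so detection rates and
correlations never conflate "absent" with "zero". Variants match across
materials on (chrom, pos, ref, alt); rearrangements without point
coordinates match on (gene, alt-label). Patient-level tissue–plasma
concordance means the plasma shares at least one tissue variant. ctDNA
clearance is defined only for patients mutation-positive at baseline:
cleared when the follow-up has no detectable panel mutation, otherwise not
cleared; baseline-negative patients are not applicable.

## Cohort statistics

Per-timepoint detection rates count only patients actually assayed there —
cfDNA dropouts and purity-excluded patients leave explicit "not assayed"
holes — which is why mutation and methylation denominators differ at the
same timepoint. Rate contrasts use a two-sided Fisher exact test implemented
as hypergeometric-pmf summation over all tables with the observed margins
(1e-7 relative tolerance for probability ties; p = 1 when a margin is
empty), validated against a binomial-coefficient enumeration oracle and
scipy. Group comparisons use the Wilcoxon rank-sum test (exact when the
smaller group has ≤ 10 values without ties, normal approximation with tie
correction otherwise). The maxAF–MD association uses Spearman rank
correlation: both quantities are heavily right-skewed and only their
monotone relation is of interest.

Recurrence lead time is the gap, in months of 30.4375 days (the calendar
average), between the earliest postoperative Wald-positive methylation call
at or before the recurrence day and the radiologic recurrence, reported to
0.1 month; an alternative "increase over the previous assayed score"
anchor is available behind `mode="increase"`. Patients with no qualifying
call get no lead time rather than a sentinel value.

## The synthetic cohort generator

The generator emulates the cohort structure the pipeline expects, at a desk
scale: per-block mean plasma read depth 100 (the assay's nominal 10,000×
panel-wide depth spread over blocks), tissue rates observed at 1,000×,
mutation depth 10,000× with a 0.05% / 3-alternate-read caller floor, 30
donors, 2,000 blocks of which 5% are tumor-hyper by default, 65 patients
with ~12% recurrence. Distributional choices (no published distributions
exist for these): block backgrounds Beta(1,19) for hyper-block loci
(mean 0.05) and Beta(5,5) for neutral loci; donors scatter around each
block's background with concentration 100, so the panel mean is a
per-block-consistent estimate of the rate that generates plasma reads;
tumor-hyper rates Beta(18,2) (mean 0.9, margin ≈ 0.85 with overlap in the
tails); non-hyper tumor rates jitter around the block background
(concentration 50) so that any block the selector picks up remains
model-faithful in plasma. Baseline ctDNA fractions are log-uniform on
[0.001, 0.05] — the 0.1–5% range typical of resectable disease — and
post-operative fractions are 0 except for recurring patients, whose α ramps
geometrically (default start 0.002, doubling) over the last one or two
follow-ups before a recurrence day drawn from days 150–420; sampling stops
at recurrence. Ten percent of follow-up assays drop out independently per
assay, reproducing the varying denominators of real longitudinal tables.

Everything is driven by one `numpy` Generator seeded from the config, and a
fixed seed yields byte-identical written cohorts. What the generator does
*not* emulate: fragmentomics, batch effects between sequencing runs,
copy-number distortion of allelic fractions, clonal-hematopoiesis
contamination, or read-level methylation haplotypes. Passing tests therefore
demonstrate correctness of the estimator and bookkeeping under the stated
binomial-mixture assumptions, not robustness to those real-data
complications.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` validate: the detection-rate and
clearance arithmetic on fixture cohorts that encode known positive/assayed
counts (methylation positivity in those fixtures is produced by actually
fitting strong-signal vs background-level block counts, not by assigning
flags); optimizer-vs-grid agreement on 200 random instances (≤ 20 blocks,
depth ≤ 500); the Fisher-information closed form against numerical curvature
of the expected log-likelihood (within 1%); MD-ratio recovery at spiked
α ∈ {0.005, 0.01, 0.05} with 1,000 informative blocks at depth 100 over 500
replicates (mean within ±20% of truth; observed bias is ≤ ~4%); the boundary
type-I rate over 5,000 null replicates; exact-test agreement with full
enumeration (every 2×2 table with cells ≤ 12; every 4-vs-4 rank split); and,
end to end, that on a simulated cohort with ~1,000 informative blocks and
ramps reaching α ≥ 0.01 before recurrence, the earliest Wald-positive
follow-up precedes the recurrence day in ≥ 80% of recurring, scorable
patients. These problem sizes keep the full suite under a minute of compute
while leaving the Monte-Carlo standard errors well inside the asserted
margins.

## Known limitations

* The binomial mixture ignores overdispersion between reads from the same
  molecule family and any per-block error-rate structure; a beta-binomial
  extension would be the natural next step.
* The Wald interval degrades near α̂ = 0; the score is still well-behaved
  (half-normal null) but no confidence intervals beyond the Wald SE are
  offered.
* Multi-sample joint estimation across a patient's timepoints, survival
  modeling, and multiple-testing correction across cohort contrasts are
  deliberately out of scope.
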