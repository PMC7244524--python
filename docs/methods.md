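# Methods

This note records the statistical models, the defaults and why they are
set where they are, what the synthetic data does and does not emulate,
and the numerical choices a maintainer would want explained. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Design and notation

Everything is indexed by a full factorial design: strain *j*, medium
*k*, culture time *l*, biological replicate *m*; a sample is one
(j,k,l,m) cell, and the default study layout is 2×2×3×4 = 48 samples
with 12 strain × medium × time combinations. All fixed effects use
sum-to-zero coding, so μ is the grand mean and every effect array sums
to zero over each of its axes; this makes planted effects directly
identifiable in recovery tests.

## Synthetic data

`lfqdiff.simulate` generates log10 peptide-charge intensities as

    I = μ + fixed effects + R_m + peptide offset + θ(protein, sample)
        + rt_bias(sample, RT) + ε(peptide, sample)

with defaults chosen to look like a well-behaved Orbitrap label-free
experiment: μ = 5.0 log10 units, σ_θ = 0.1 (between-run technical
spread), σ_ε = 0.2 (residual peptide-level noise), peptide ionization
offsets with SD 0.3, retention times uniform over a 180-minute gradient
(0–10 800 s) with 3 s per-sample jitter, and optional missingness
(completely at random by default; an intensity-dependent MNAR mode
exists because real low-intensity peptides drop out first, but no
mechanism is asserted by default). Spectral counts are Poisson with the
same factorial structure on the natural-log rate. θ is drawn once per
(protein, sample) and shared by that protein's peptides; ε is drawn per
(peptide, sample). The printed model notation gives θ and ε the same
subscripts; this per-protein-per-sample reading of θ is the only one
under which the two are separately identifiable, and it matches the
physical meaning of "technical variation due to sample handling and
injection".

What the generator does *not* emulate: raw spectra, chromatographic peak
shapes, identification error, peptide-level interference, and
correlations between missingness and the factorial structure. Passing
tests therefore validate the statistical machinery under the stated
model, not robustness to every artifact of real LC-MS data.

Promoter fixtures are i.i.d. background sequences with configurable GC
(default 0.72, typical of *Streptomyces* genomes) into which Pho boxes
are written exactly, on either strand, with a requested number of
mismatches outside the conserved CA dinucleotide.

## Retention-time-local normalization

For each sample, deviations d = log10 I_sample − log10 I_reference on
the peptide-charges shared with the reference are ordered by the
sample's retention times and smoothed; the smoothed curve, evaluated at
each peptide's RT (constant-extrapolated beyond the shared support), is
subtracted. The reference defaults to the sample with the most
quantified peptide-charges (ties to the lexicographically smallest id).

The default smoother is a least-squares cubic B-spline with interior
knots at RT quantiles, one knot per ~15 minutes of RT span (bounded
4–20, and at most n/10): chromatographic drift and electrospray
instability vary on the scale of many minutes, and a denser basis
mostly chases per-peptide noise. Because the knots depend only on the RT
support, the smoother is a projection, which makes normalization exactly
idempotent — re-normalizing an already-normalized table refits a curve
of zero to machine precision. A penalized smoothing spline with
GCV-chosen penalty is available (`smoothing="gcv"`), but a penalized
smoother is not a projection and re-shrinks residual noise on every
pass, so it is not the default.

The least-squares fit is made robust by bisquare reweighting (IRLS,
tuning constant 4.685 × MAD, iterated to its fixed point so the weighted
projection stays idempotent). This matters because the curve must track
the systematic drift of the *unchanged* majority of peptides: peptides
of genuinely differential proteins sit at fixed RTs and deviate from the
reference by their biology, and an unweighted fit leaks that biology
into the correction — measurably creating strain-aligned artifacts in
background proteins when a large fraction of peptides is differential.
Corollary: reference-based normalization assumes abundance changes
roughly balance out across the proteome; datasets where most changes go
one way violate it, robust fit or not.

Degenerate inputs: fewer than `min_shared` (default 50) shared
peptide-charges, or fewer than 4 distinct RT points, degrade the curve
to a constant median correction with a warning. Duplicate RTs are
aggregated by mean deviation before fitting.

## Peptide QC ladder

Fixed order: RT stability (drop peptide-charges with across-sample RT SD
> 20 s; sample SD, ddof = 1), shared-peptide removal (any peptide mapped
to ≥ 2 accessions, whether encoded in a delimited field or across rows),
reproducibility (quantified in ≥ 2 replicates of *every* strain × medium
× time combination; applied at the peptide-charge level, the same unit
normalization uses), and intra-protein correlation (per protein, Pearson
correlations on pairwise-complete profiles; the reference peptide is the
one with the most significant correlations at α = 0.05 two-sided — a
standard t-test, since no other definition of "significant" presents
itself — with ties broken by highest mean pairwise r, then
lexicographically; survivors are the reference plus peptides with r >
0.75 to it). Pairs with fewer than 3 complete observations have
undefined correlation and are logged. Each stage is idempotent and emits
a report that reconciles row counts exactly.

## Differential abundance

**Spectral counts.** Proteins first need a range ≥ 10 spectra across the
12 combination means. Each retained protein gets a Poisson GLM (log
link, statsmodels) on the full factorial plus the replicate block;
per-term p-values are Type-II analyses of deviance: for term X, the
model with all terms not containing X is compared against the same model
plus X by likelihood-ratio chi-square. All counts identical short-cuts
to p = 1 for every term.

**XIC.** Each protein's normalized log10 intensities get a linear mixed
model: full factorial + replicate + a fixed per-peptide offset (the
printed equation omits a peptide term, but peptides differ
systematically in ionization efficiency; the offset is toggleable), and
a random intercept per sample. The REML/ML fitter profiles the
likelihood over the single variance ratio λ = σ_θ²/σ_ε²: for each λ the
model whitens per group (subtract c_s × group mean with
c_s = 1 − 1/√(1 + n_s λ)) and reduces to least squares, leaving a 1-D
bounded search over log λ (tolerance 1e-8, log λ ∈ [−14, 10], with the
λ = 0 boundary checked explicitly and returned when it wins — a zero
variance component is a valid boundary estimate, not an error). The
implementation agrees with statsmodels MixedLM to ~1e-5 in
log-likelihood and with closed-form balanced ANOVA estimators to 1e-6;
both checks are in the test suite.

Per-term p-values are Type-II F-tests computed in the between-sample
stratum. The factorial terms and the replicate block are constant within
a sample, and the marginal model of the per-sample means is
ȳ_s ~ N(fixed_s, σ_θ² + σ_ε²/p_s); the tests use weighted least squares
on these means (weights from the REML components; equal under balance)
with denominator df = samples − sample-level parameters (48 − 15 = 33 in
the full layout). Under the balanced design this is exact classical
ANOVA for any value of the variance ratio. Likelihood-ratio tests
against a chi-square reference were tried first and rejected: with ~48
samples they are anti-conservative (roughly 9–11% of null proteins below
p = 0.05 in calibration runs), which would inflate the FDR the pipeline
promises to control. Estimated peptide offsets are subtracted before
averaging so unbalanced sample means stay comparable. Single-peptide
proteins fall back to fixed-effects least squares with a note (θ and ε
are confounded at one observation per sample).

Effect summaries come from the fitted cell means via the classical
sum-to-zero decomposition: main effects are reported signed (first level
minus last — for two strains, the log10 or log fold difference),
interactions as the unsigned range of their effect array.

**Multiplicity and merging.** Raw p-values are BH-adjusted per term
across proteins, separately within each method family (the family is not
stated anywhere authoritative; per-term-within-method is declared here).
A protein is significant when any adjusted p < 0.05; "changes between
strains" means any of the strain-involving terms. When both routes call
a protein, the XIC estimates and p-values are reported. The merge also
returns the Venn partition (both / SC-only / XIC-only / union and
per-method totals).

## Sample QC and clustering

Samples are flagged when their quantified peptide-charge count falls
below a threshold (default 40 000, the scale of real runs; synthetic
studies pass a smaller value) or when their (PC1, PC2) scores — from
covariance PCA (SVD of the centered per-sample protein-abundance
matrix; the correlation variant is not used) — sit more than 3 pooled
within-cell SDs from their design-cell centroid.

Hierarchical clustering uses Euclidean distances (scipy linkage;
complete linkage by default, configurable; the brute-force O(n³)
agglomerator that verifies it lives in the tests). Profiles are z-scored
per protein (population SD; constant rows are dropped with a log note).
SOTA clustering grows a binary tree from a single cell: the leaf with
the largest resource (mean squared member distance) splits into two
children — one at the parent vector, one at the farthest member, a
seeding that guarantees the total objective never increases — refined by
winner-take-all assignment and centroid updates within the split cell.
Growth stops at `max_clusters` leaves or when every resource is at or
below `growth_threshold`. Deterministic given the seed. For heatmap
inputs, proteins quantified by both methods use their XIC values.

## Pho-box scanning

A unit is the 8-mer consensus GTTCACCC whose CA (offsets 4–5) must match
exactly; up to `max_mismatch_per_unit` mismatches (default 2 — the
repeats are described as "rather conserved", with no numeric threshold
to inherit) are allowed at the other six positions, and N never matches.
A canonical box is two units whose CA starts are 9 bp apart (direct
repeats with one spacer base; CA-start spacing equals unit-start
spacing), with a configurable tolerance (default 0). Units in no
canonical pair are half boxes; a single mismatch budget covers both
classes. Minus-strand hits come from scanning the reverse complement and
mapping back; coordinates are 1-based inclusive on the forward strand
with `start` the leftmost base of the span, which makes
reverse-complementing the input an exact involution on the hit set.
Positional annotation against a TSS classifies hits as
upstream-activator (entirely upstream of the −35 region, taken as TSS −
40), promoter-overlap (the repressor position), or downstream-roadblock
(past the TSS).

## qRT-PCR

Reference candidates are ranked by the geNorm stability value M — the
mean SD across samples of pairwise log2 expression differences with the
other candidates (expression −Ct·log2 E) — replacing the proprietary
tool-based selection with a published, testable equivalent; the five
most stable genes' mean Ct is the per-sample normalization factor
(geometric mean of expression in linear space). ΔCt = Ct_target − NF per
replicate; ΔΔCt is the difference of condition means against the
control; ratio = E^(−ΔΔCt) with E defaulting to 2 (perfect doubling;
per-gene values from standard curves can be supplied); significance by
two-sided Student t across replicates. Standardization (log transform,
mean centering, autoscaling) is applied per gene to the replicate-level
log2 ratios across conditions — the text does not say whether it applies
to ΔΔCt values or ratios, and on the log2-ratio scale the two coincide
up to sign and scale.

## Problem sizes

The validation benchmarks run at sizes chosen to estimate their
quantities stably on a single CPU in well under a minute each: the null
calibration uses 500 proteins × 4 peptides × 48 samples, effect recovery
200 proteins, normalization 400 proteins × 4 peptides over 8 samples,
and the analysis-script study 120 proteins (a quarter differential, in
both directions, as in typical comparative proteomes). Desk-scale
caveat: with a few hundred peptides per sample, normalization-curve
estimation noise is visible (RMS bias removal ~83–87% rather than the
asymptotic limit); real runs carry tens of thousands of peptide-charges
per sample.

## Known limitations

Shared-peptide protein inference, absolute quantification,
empirical-Bayes moderation across proteins, chromatogram alignment, PWM
training for the motif scanner, and standard-curve fitting for qRT-PCR
efficiencies are out of scope. The mixed model assumes Gaussian
residuals on the log10 scale and a single technical variance shared
across samples; heavy-tailed runs are only partially absorbed by the
robust normalization upstream.
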