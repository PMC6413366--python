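# Methods

## Event simulation

Each synthetic specimen is a mixture of cell-cycle populations over a PI-H
channel axis in arbitrary units, anchored by `diploid_channel` (default
1×10⁵), the G0/G1 position of a diploid cell.  A population is specified by
its DNA index (G0/G1 content relative to diploid), its share of non-debris
events, a percent CV, and G0/G1 / S / G2/M phase fractions.  A non-debris
singlet draws

  PI-H ~ Normal(diploid_channel · DI · m, (CV/100) · diploid_channel · DI)

with phase multiplier m = 1 (G0/G1), 2 (G2/M), or uniform on (1, 2) for S —
the "zero-order" S model in which DNA synthesis is uniform across the
compartment before measurement spread.  The Gaussian σ is per-population
(proportional to the G0/G1 channel), not per-phase; G2/M peaks therefore
share their cycle's absolute width, which matches how the deconvolution
model is parameterized and is a reasonable approximation of dye/instrument
behavior.

**Debris.** A debris event takes PI = parent × B, where the parent is an
independent non-debris draw and B follows the arcsine density
p(b) = 1/(π√(b(1−b))) on (0, 1) — the classical sliced-nucleus fragment
distribution (a random planar cut through a sphere).  The kernel is
configurable (`uniform_low` confines fragments below 45% of the parent,
useful for constructing threshold-separable debris).

**Doublets.** PI-H is the sum of two singlet draws; FSC-A is the sum of the
parents' FSC-A; FSC-H = 0.6 × FSC-A (ratio configurable).  Aggregate pulse
height grows sublinearly with area, so a ratio gate separates doublets from
singlets (whose ratio is ~0.8 ± 0.016).

**Scatter and PI-A.** FSC-A is lognormal (median 10⁵, σ = 0.3); these are
nuisance structure only.  PI-A = PI-H × Normal(1, 0.02).

**Determinism.** All randomness flows from one integer seed through
`numpy.random.SeedSequence`; identical specs give byte-identical tables.

**Testis presets.** Whole-testis profiles are two populations: haploid
spermatozoa at DNA index 0.5 and a germline/stromal population at index 1.0
whose G0/G1, S and G2/M phases play the roles of the 2C, S and 4C
compartments.  The default compartment shares per genotype (wild type
55/20/8/17; *tp53* 50/27/7/16; *brca2* 1/25/24/50; *brca2;tp53* 1/60/14/25
for 1C/2C/S/4C) are presets chosen to satisfy the qualitative genotype
profiles — 1C modal with intact spermatogenesis, 4C modal with < 2% 1C and
elevated S under meiotic arrest, 2C modal with < 2% 1C under the combined
mutations — because the underlying per-compartment percentages are
published only graphically.  They are configuration, not measured claims.

**Cohort generator.** Fish-level records draw sex (P(F) = 0.5), tumor
location (genotype-specific frequencies, coelom-dominant), age at diagnosis
(lognormal about the genotype median — 8.2 or 10.8 months, σ = 0.15, which
reproduces the published ranges), and a ploidy category from sex-specific
aneuploidy probabilities (0.67 female, 0.48 male), with aneuploid subtypes
at their pooled study frequencies.  Ages are treated as survival times with
all events observed, since the study design euthanizes at diagnosis;
censoring support is retained throughout.

## Gating and marker quantification

The singlet gate keeps events with FSC-H/FSC-A in a band (default
(0.7, 0.9)); rows with FSC-A = 0 are dropped and counted in the gate
report.  The debris gate thresholds PI-A and FSC-A (default 0 = identity).
Gates are idempotent and their in/out counts are recorded on the table.

Marker placement detects histogram peaks (moving-average smoothing over 5
bins, local maxima above 5% prominence for marker placement and 3% for fit
initialization, ties toward the lower channel), then finds the 1C/2C pair
by a channel ratio ≈ 2; for profiles without a haploid population the 2C
anchor is supplied (in practice, from the matched reference).  Markers are
half-open intervals centered at ±2.5σ, with σ measured from each peak's
FWHM; the 4C marker sits at twice the 2C channel (its width taken from a
detected peak when one is present near that position, since G2/M peaks
broaden less than a naive doubling), and the S interval spans the gap
between the 2C and 4C markers.  Events between markers count toward the
gated total but no compartment; percentages may sum below 100.

Marker gates undercount S by construction (the S tails under the 2C and 4C
markers are counted there); with CV ≤ 4% and well-separated peaks the
error stays within ~2 points per compartment, but for strongly S-elevated
profiles (the meiotic-arrest preset) the S/4C split is distorted by several
points.  Only the qualitative claims are made for those profiles.

## Histogram deconvolution

The default histogram is 1,024 half-open bins over [0, 1.05 × max PI-H]
(fitting uses 512 for speed; the model integrates Gaussian bin masses
analytically, so bin width is not a resolution limit).  The model for 1–3
cycles plus debris is as in the README; the debris component applies the
arcsine kernel's closed-form bin mass (2/π)(asin√(hi/m) − asin√(lo/m)) to
delta parents at each cycle's G0/G1, G2/M and S-midpoint positions
(weighted by fitted amplitudes) and convolves it with the cycle's Gaussian
width.  The commercial "sliced nuclei" background formula is proprietary;
this kernel carries the same construction, is documented, and is swappable.

**Estimation.** Bounded nonlinear least squares (`scipy.optimize.
least_squares`, trf, tolerances 1e-8) over per-cycle (μ, CV, r) and
amplitude parameters, initialized from detected peaks, with up to 5
deterministic jittered restarts.  Weights are Poisson-motivated: a first
pass uses 1/√max(observed, 1), then one reweighting pass uses the expected
counts from the first fit.  The reweighting matters: observed-count weights
over-weight downward-fluctuating sparse bins and bias the S plateau and
debris fraction low by 2–3 points at 10,000 events; the two-stage scheme is
unbiased to the Monte-Carlo error.  A soft mass-conservation residual
(total fitted amplitude vs histogrammed events) prevents a degenerate
solution in which an out-of-range component acts as a free-form background
through the debris parent weights.  The reduced chi-square uses
expected-count denominators over bins with expected ≥ 1, minus the free
parameter count.

**G2/M-vs-aneuploid arbitration.** A tumor peak near twice the reference
channel alongside a diploid peak can be a diploid G2/M or a tetraploid-range
G0/G1.  Both topologies are fitted and the lower RCS wins; a gap below 0.05
marks the fit ambiguous, which routes the ploidy call through the
predominant-diploid rule (below).  Harmonic filtering of detected peaks
requires a 2× channel ratio *and* height below half the lower peak's — a
genuine tetraploid G0/G1 is broadened (σ scales with DNA index) and would
otherwise be mistaken for a harmonic.

## Ploidy decision tree

QC: somatic G0/G1 CV > 6.0 (strict inequality), fewer than 1,000 fitted
events in either specimen (configurable; the fitter itself only warns), or
an undefinable somatic diploid population exclude the pair.  Reference
selection and DNA-index computation follow the README; the
internal-diploid match tolerance is 5% of the somatic peak (the comparison
is published without a number), the minor-population threshold is 20%, and
"distinct" complex peaks must be separated by > 3 pooled σ and not at 2× one
another.  For minor or ambiguous aneuploid populations the index is
computed from the predominant diploid peak against the somatic reference,
which lands near 1 and yields a diploid call — the coherent reading of the
predominant-diploid rule.  The diploid band δ = 0.05 and tetraploid band
δ_t = 0.10 are explicit configuration with conservative defaults near
instrument CV; the study's exact numeric cut-offs are not published in the
main text.

## Statistics

scipy.stats supplies the chi-square, Welch t (Satterthwaite df) and
Shapiro–Wilk tests; lifelines supplies Kaplan–Meier, log-rank and Cox PH
(Efron ties).  Both Pearson X² and likelihood-ratio G are always computed
for contingency tables because statistics packages print both and published
p-values may quote either; on this study's printed tables the
likelihood-ratio variant reproduces the published values to four decimals
(0.1877 genotype×ploidy; 0.0477 sex×ploidy) while Pearson differs in the
third decimal, so the G statistic is evidently what was quoted.  The default
display remains Pearson.  No continuity correction, and no multiple-testing
adjustment (matching the per-test α ≤ 0.05 design).  A self-contained Cox
score test at β = 0 provides the algebraic cross-check score ≡ log-rank for
a binary covariate without ties.  A Monte-Carlo permutation p for 2×2
tables (hypergeometric sampling of fixed-margin tables) supports exact
small-sample inference; it is validated against full enumeration.  The
asymptotic chi-square p is *not* expected to match exact conditional p at
n ≤ 12 (differences up to ~0.3 are normal) and is not asserted against it.

## Reconstructed study cohort

`ploidyflow.datasets.study_cohort()` rebuilds a 103-tumor record table
consistent with every published marginal simultaneously (fish and tumor
counts, sex, location and ploidy-category margins, the coelomic
diploid/aneuploid splits, the two-tumor fish with their ploidy
concordance).  Allocations not pinned by any marginal are fixed arbitrarily
but deterministically; ages are deterministic lognormal quantile grids
matched to the published medians and are display structure, not data.

## Evaluation sizes and numerical choices

Recovery and classification studies use 10,000 events per specimen (a
typical acquisition target), 100 one-cycle simulations (CV 3–5%, debris
0–15%) for parameter recovery, 200 matched pairs across DNA index
{0.85, 1.0, 1.2, 1.5, 2.0} with aneuploid shares 0.35–0.8 for
classification, and 10,000 replicates for test-size calibration.  Fits are
deterministic given (histogram, init); restart jitter uses a fixed
generator.

## What passing tests do and do not show

The generator draws exactly from the model family the fitter assumes
(Gaussian peaks, flat S, arcsine debris), so recovery results demonstrate
correctness of the estimation machinery, not robustness to real-cytometer
artifacts: fluorescence nonlinearity, inter-experiment intensity drift
(observed in the source data and deliberately not simulated by default),
aggregate (> 2-cell) clumps, asymmetric peak shapes and carryover are all
outside the synthetic family.  Marker-gate quantification inherits the
S-undercount noted above.  The reconstructed cohort reproduces published
*summaries*; record-level structure beyond the printed marginals is
invented.  Cross-specimen ratios (DNA index) are robust to the overall
intensity scale, which the scale-equivariance tests verify exactly.
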