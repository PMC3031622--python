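# Methods

This note documents the models, defaults and numerical choices behind
`cogassoc`, and what the synthetic cohort does and does not establish
about real data.

## Study design being emulated

A family-based candidate-SNP design: euthymic bipolar-disorder patients
(n = 46), unaffected first-degree relatives (n = 73) and unrelated
controls (n = 67), genotyped at one rare biallelic SNP (risk allele T,
MAF 0.067). At that frequency roughly 24 of 186 participants carry T
and at most one TT homozygote is expected, so every analysis collapses
TT with CT into a single carrier class. Cognitive outcomes are a
degraded-stimulus CPT (trial level) plus summary scores for IQ, Stroop
interference, WCST, eight WMS-III indices and IGT emotional learning.

## Synthetic cohort generator

**Genotypes.** Patients and controls are Hardy–Weinberg draws at the
configured MAF. Each relative belongs to exactly one patient's family
(1–2 relatives per family); an implied parental genotype pair is drawn
from its Hardy–Weinberg posterior given the patient, and relatives are
siblings drawn by Mendelian transmission from that pair, so relatives
of carrier patients are realistically enriched for the allele while the
*marginal* relative genotype distribution stays at Hardy–Weinberg.

**Clinical scores.** BPRS (24-item, floor 24) is truncated normal with
per-status-by-carrier-class means/sds taken from the emulated design's
demographic table; HDRS and YMRS are generated as ancillaries
correlated with BPRS (r ≈ 0.73) and are unused downstream.

**CPT response model.** Each subject responds under an equal-variance
Gaussian signal-detection skeleton parameterised on the probit scale:

    z_hit(i)      = a0 + shift_h(status) + b_i
    z_fa(i, blk)  = f0(blk) + shift_f(status) + κ·b_i − u_i + ν_i + Δ(blk)·carrier

with shared criterion-placement heterogeneity `b_i` (σ = 0.85),
subject sensitivity `u_i` (σ = 0.22), residual criterion drift `ν_i`
(σ = 0.25) and coupling κ = 0.70 expressing that the effective
criterion drifts between trial contexts rather than moving rigidly.
Block baselines `f0` rise slightly across blocks (vigilance decrement
expressed as growing false alarms). Responses are Bernoulli per trial;
the 160 practice trials use block-1 parameters. Targets are placed 20
per 80-trial segment, uniformly over the non-adjacent subsets (a
stars-and-bars bijection), giving the 25% quasi-random schedule.
Reaction times are log-normal around a subject mean (430 ± 40 ms, 6 ms
slowing per block) and genotype-independent.

**The carrier deficit is hit-rate-preserving by construction.** The
separation loss Δ enters the false-alarm channel only: the criterion
tracks the degraded target distribution, so carriers keep their hit
rate while false alarms rise and sensitivity (A′) falls. This is a
deliberate deviation from the naive "fixed criterion, reduced δ" model,
which would move *hit rate* and leave false alarms untouched — the
opposite of the deficit pattern the design targets. One geometric
consequence cannot be engineered away: A′ and B″D are both functions of
the same (H, F) pair, so a false-alarm mean shift necessarily drags the
scored criterion index by a fraction of the latent shift. With the
default heterogeneity the residual criterion effect is d ≈ 0.3 when the
false-alarm effect is d ≈ 0.83 — matching the emulated study's own
report of a "small" criterion effect (d < 0.25) next to large
sensitivity/false-alarm effects. An exactly null scored criterion
alongside a d ≈ 0.8 false-alarm shift is mathematically impossible in
any latent-threshold model, which is why the selectivity test below
bounds criterion rejections at 0.40 rather than at the nominal level.

**Calibration.** Per-block carrier effects are specified as Cohen's d
on the *scored* block variables (defaults ramp linearly to 0.92 for
sensitivity and 0.83 for false alarms at block 4, the emulated study's
observed values). A cached Monte-Carlo calibration (20,000 virtual
subjects per group, common random numbers, fixed internal seed,
Brent root-finding) maps these targets onto latent shifts Δ(blk),
balancing the sensitivity and false-alarm targets when both are set.
The pooled SD in the calibration is weighted by the Hardy–Weinberg
carrier fraction, mirroring the pooled-SD Cohen's d an analyst computes
when carriers are the small group (the carrier group's variance is
larger, so equal weighting would overshoot by ~10%).

**Other outcomes.** Summary outcomes are normal (index scores 100 ± 15
style) except WCST categories (integer 0–6) and WCST perseverative
errors, which are log-normal (right-skewed) to exercise the permutation
path. Carrier effects default to the emulated study's observed d values
(working memory 0.35, Stroop 0.44, 0.02–0.17 elsewhere); affection
status carries moderate main effects (patients ~0.3–0.5 SD deficits,
relatives intermediate).

**What passing tests show — and don't.** Monte-Carlo recovery tests
show the generator hits its own effect-size targets and that the
pipeline detects them selectively. Real CPT data differ in ways the
generator does not model: medication and illness-course effects,
practice/fatigue interactions beyond a linear decrement, RT–accuracy
coupling, non-Gaussian evidence distributions, and ascertainment of
families. Passing here validates the *statistical machinery*, not any
biological claim.

## ANOVA / ANCOVA engine

Between-subject models use sum-to-zero (effects) coding and Type III
sums of squares by default: each term's SS is the RSS increase from
deleting its columns from the otherwise-full model, the right choice
for the heavily unbalanced carrier split (a 2×3 ANCOVA with one
covariate on n = 184 leaves the familiar 177 residual df). Type II is
available. Rank deficiency raises an error naming an aliased term;
constant outcomes return F = 0; listwise deletion handles missing
values.

The repeated-measures path is the classical split-plot: between terms
tested on subject means; within terms (block and its interactions,
including block×covariate with the covariate centered) on orthonormal
polynomial contrasts, pooled in the averaged-F fashion (df 3·q, 3·n_e).
Greenhouse–Geisser ε comes from the eigenvalues of the *residual*
contrast covariance (the SPSS/SAS convention — pingouin's grand-
covariance ε differs slightly, which the cross-check tests respect),
with 1/(k−1) ≤ ε ≤ 1 enforced; Mauchly's test at α = 0.05 decides
whether the GG-corrected df pair is the headline p, and both are always
stored. Note the folklore claim "GG-corrected p ≥ uncorrected p" is
only guaranteed in the F > 1 regime; deflating both dfs can cross the
p-values by a hair when F < 1.

The linear block-trend test collapses each subject's four blocks with
weights (−3, −1, 1, 3)/√20 and runs the factor ANCOVA on trend scores;
this is the polynomial block-by-genotype interaction contrast.

Normality screening is one-sample KS with estimated parameters and
Lilliefors-calibrated p-values (via statsmodels); naive KS p-values
would be grossly conservative with estimated parameters.

## Permutation engine

Genotype labels are permuted across individuals (optionally within
affection-status strata); everything else stays fixed. The empirical
p-value uses the add-one estimator (count_ge + 1)/(B + 1), which never
returns zero and is the standard Monte-Carlo test correction; ties
count toward the numerator (conservative). Family relatedness is
deliberately ignored during permutation, mirroring the emulated
design's own analysis; a warning is logged once when related
individuals are present. The asymptomatic variant applies a strict
BPRS < 27 filter (a score of exactly 27 is excluded).

The default permuted model is the main-effects ANCOVA
(carrier + status [+ BPRS]); with a single-df carrier term this admits
an exact Frisch–Waugh–Lovell fast path: the fixed design is
residualised once by QR, and each permuted F is an inner product, so
B = 100,000 takes well under a second at n = 186. The fast path is
bit-compatible with the general refit loop (tested), and an exhaustive
engine enumerates all distinct assignments (via the same projection)
for small instances, serving as the engine's own oracle. Degenerate
assignments — a permutation making the carrier indicator coincide with
a whole status class — are rank deficient and are redrawn (sampling)
or skipped (enumeration), with a log record.

## Power and effect sizes

`power_at_n` gives the noncentral-F power of the 1-df genotype test
with λ = N·r²/(1−r²) and denominator df N − 2 (intercept + genotype);
a chi-square likelihood-ratio variant with λ = N·ln(1/(1−r²)) — the
calculus classic genetic power calculators use — agrees within ~1% and
is available as `method="lrt"`. `sample_size_for_power` brackets and
bisects the monotone power curve, with a 10⁷ ceiling raising a bounded-
search error. Given r², N is independent of MAF and genetic model;
those enter only in `allele_effect`, the per-allele β implied by r²
(additive variance 2pq·β²). Dominant and recessive conversions are
included for completeness. The Monte-Carlo validation grid uses
N ≥ 200, where conditioning on the expected genotype variance is
accurate to < 0.015 in power.

Effect sizes are pooled-SD Cohen's d (positive = carrier deficit);
`variance_explained` exposes both partial η² = F·df1/(F·df1 + df2) and
the point-biserial conversion r² = d²q(1−q)/(d²q(1−q)+1). The two
conversions genuinely disagree for the same data (≈5.6% vs ≈7.9% for a
block-4 sensitivity deficit of d = 0.92 with F(1,177) = 10.45); the
pipeline's power table uses the point-biserial route and treats any
externally printed variance fraction as authoritative input.

## Pipeline and reproducibility

Per outcome: KS screen → if non-normal, attempt log transform and
re-screen → parametric ANCOVA if (transformed-)normal, else both
permutation variants, reported side by side and never pooled. CPT
block variables are routed to the permutation path by default (their
bounded, skewed distributions rarely pass the screen) and additionally
receive the split-plot ANCOVA and the linear trend contrast.
Participants without a genotype call are excluded from association but
retained, flagged, in demographics; every filter count lands in the run
log. All stage seeds derive from one master seed via SeedSequence with
CRC-hashed stage labels, and two runs with the same configuration
produce byte-identical JSON reports.

Default problem sizes in the test suite (e.g. 150–200 replicate
cohorts for effect-recovery and selectivity checks, B = 1000 for
calibration studies, 2000 null replicates for the type-I check) were
chosen to keep Monte-Carlo error comfortably inside the asserted
tolerances while the full suite runs in a few minutes on one core.
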