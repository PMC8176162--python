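# Methods

## Dynamic preload indices

Pulse pressure variation and stroke volume variation are computed strictly
per respiratory cycle from the extreme beat values,

    PPV = 100 · (PPmax − PPmin) / ((PPmax + PPmin)/2)  [%],

and analogously for SVV, then averaged over k = 3 *consecutive* valid
cycles. Cycle windows are half-open `[mark_k, mark_{k+1})`, so a beat
exactly on a mark belongs to the later cycle — a deterministic assignment
rule. Windows with fewer than two beats cannot define an excursion; they
are flagged invalid and excluded (never imputed), and they break the
consecutive run required for the k-cycle average. Some bedside monitors use
moving windows longer than one respiratory cycle; we deliberately compute
per cycle and average, which is the construction the index definitions
describe. No arrhythmic-beat rejection is implemented — the clinical
protocol this models excludes arrhythmia — but per-window validity flags
are exposed for callers that need them.

The PEEP-challenge deltas are plain signed differences, ΔPPV = PPV(T2) −
PPV(T1), not clamped at zero: a negative delta (typical of non-responders)
is informative.

## Responder definition

A fluid responder is a patient whose stroke volume rises by at least 10%
after the fluid bolus, measured from the second baseline T3 (after PEEP
withdrawal) to T4 — T3 is the denominator because it is the state the
bolus acts on. The boundary case of exactly +10% is a responder. Patients
with missing stroke volume are flagged unclassifiable and retained, never
silently dropped.

## Synthetic cohorts

Patient-level data for this design are not public, so the generator is the
test bed for everything downstream. Per group (18 responders, 22
non-responders by default) each variable-by-time-point vector is
multivariate normal with the published marginal means/SDs packaged in
`data/default_distributions.csv`.

Correlation structure. The published tables print the SD of the
within-patient *change* as well as the two marginal SDs, which pins the
within-variable correlation across a challenge pair exactly:

    corr(X1, X2) = (s1² + s2² − sΔ²) / (2 s1 s2).

All implied correlations under the packaged defaults lie in (0.57, 0.98).
Using them makes the simulated deltas reproduce the printed change
distributions — e.g. responder ΔSVV ~ Normal(2.3, 1.7) — which is what
drives every AUC result; deltas are always computed from the drawn T1/T2
values, never drawn separately. The PPV–SVV cross-correlation is not
published; since both indices reflect the same cyclic preload variation we
default it to ρ = 0.6 (configurable) within each challenge phase. The two
challenge phases (T1/T2 and T3/T4) are drawn independently of each other —
nothing is published about their coupling, and no reported quantity
depends on it. Covariance matrices are factored by eigendecomposition with
eigenvalues clipped at zero, so degenerate (sd = 0) specs reproduce means
exactly.

Negative index draws. Under the packaged parameters a few percent of
non-responder SVV draws fall at or below zero — the tail of the normal
approximation. We keep them by default: clamping would bias the delta
distributions (it shifts the large-sample ΔSVV AUC by ≈ +0.008) while
rank-based analysis is indifferent to impossible-but-ordered values. A
`truncate_indices_at` floor is available (with logged truncation counts)
for users who need physically admissible values, and beat-simulation
targets are always clamped at 0.1% because the modulation model requires a
non-negative amplitude.

One known inconsistency in the published summaries: non-responder SVV at
T1/T2 (5.0, 4.4) implies a change mean of −0.6, while the printed change
column says −0.5 (rounding). The generator reproduces the marginals, so
its implied delta mean is −0.6; simulation checks that start from the
printed change parameters use −0.5. Both are exercised in the tests.

Beat-level simulation. Beat i occurs at i·60/HR s; cycle marks at
multiples of 60/RR (HR/RR ≈ 6 under the study's ventilation settings, and
must be ≥ 2 to resolve a cycle). Pulse pressure is modulated sinusoidally,

    PP_i = PP0 · (1 + (target/200) · sin(2π f_resp t_i + φ)) + ε_i,

so the noise-free envelope's normalized range equals the target index
exactly. The phase φ is randomized per series; an "aligned" mode pins the
first beat of each cycle to the modulation crest, giving exact recovery
whenever beats-per-cycle is an even integer (used by the recovery tests).
With random phase and b beats per cycle the computed index underestimates
the envelope by at most a factor 1 − cos(π/b) — about 5% of the target at
b = 6, under 0.5% at b = 32. Gaussian beat noise is specified as a fraction
of baseline.

What the generator does *not* emulate: arrhythmia and measurement
artifacts, drift within a time point, covariate structure (age, operation
time, ...), any coupling between the hemodynamic state and ventilation
mechanics, and non-normal marginals. Passing tests therefore demonstrate
the statistical machinery on the published group structure, not robustness
of the indices to real-world signal quality.

## ROC analysis

The positive-call convention is score **strictly greater than** cutoff,
matching how the cutoffs are reported (e.g. "> 0%"). Thresholds are the
distinct observed values plus a −∞ endpoint; no mid-point refinement
between observed values is applied (some commercial packages do this; it
only relabels the same operating points). The trapezoid AUC is identical
to the tie-corrected Mann-Whitney U/(n_pos·n_neg) — a property test holds
this to 1e−12 — with between-class ties contributing ½.

Uncertainty uses the Hanley–McNeil closed form

    SE² = [θ(1−θ) + (n₊−1)(Q1−θ²) + (n₋−1)(Q2−θ²)] / (n₊ n₋),
    Q1 = θ/(2−θ),  Q2 = 2θ²/(1+θ),

with normal CIs truncated to [0, 1]; the p-value against θ₀ = 0.5 uses the
SE at the null, two-sided. This is an approximate method: its measured 95%
CI coverage under the study's ΔSVV configuration at n = 18/22 is 92.7%
(400,000-replicate estimate), which the acceptance suite checks against a
92% floor. DeLong-type variance is deliberately not the primary method;
the permutation comparison below is the model-free cross-check.

Paired AUC comparison: z = (θ_a − θ_b)/√(SE_a² + SE_b² − 2 r SE_a SE_b).
The correlation r between the two empirical AUCs is obtained from the
average of the within-class Spearman correlations of the two markers
(mapped to a latent Pearson ρ via 2·sin(π r_s/6)) and the average AUC,
through the bivariate binormal model: r = Cov(Φ(X₁), Φ(X₂))/Var(Φ(X)) with
(X₁, X₂) bivariate normal at correlation ρ and common mean √2·Φ⁻¹(θ),
evaluated by Gauss–Hermite quadrature. This is the population version of
the classical lookup-table for this correction (by symmetry the positive-
and negative-class terms coincide, so group sizes cancel); it matches
Monte-Carlo AUC correlations to ~0.01. A per-patient marker-swap
permutation test is provided as an assumption-free alternative.

Operating points maximize Youden's J = Se + Sp − 1 over observed cutoffs
(the −∞ endpoint is excluded: "call everyone positive" is not a usable
threshold), ties broken toward the smallest cutoff. Se/Sp/PPV/NPV are
reported in percent with Wald CIs truncated to [0, 100] — the truncated-
Wald style matches how such tables are conventionally printed; predictive
values use the sample prevalence and are reported as missing (not 0) when
a denominator is empty.

Sample size: the smallest n per group (allocation configurable) with
|θ₁ − θ₀| ≥ z_{1−α/2}·SE(θ₀) + z_{1−β}·SE(θ₁), both SEs Hanley–McNeil at
the candidate sizes. For θ₁ = 0.8 vs 0.5, α = 0.05 two-sided, power 0.9,
1:1 this gives 17/group (34 total; 14/group one-sided). Commercial
sample-size software reports slightly different totals for the same inputs
(its internal variance model is not disclosed); this implementation
documents its inequality rather than reverse-engineering that.

## Gray zones

Two constructions, reported side by side (no merge rule is defined, and
they answer different questions):

- **Bootstrap CI**: B = 1,000 resamples stratified by responder status
  (unstratified resampling at n = 40 can lose a class), Youden cutoff per
  replicate, zone = 2.5th–97.5th percentile with linear-interpolation
  quantiles (pinned so zones are bit-reproducible under a fixed seed).
- **Split-curve**: low = largest cutoff with Se ≥ 90%, high = smallest
  cutoff with Sp ≥ 90%; between them neither criterion holds. Floors are
  parameters; if the branches cross, the zone is empty and collapses to
  the crossing midpoint.

Patient counts inside a zone use the closed interval [low, high], matching
the "between a and b" reading of reported zones.

## Group statistics

Between groups: Shapiro-Wilk at α = 0.05 per group screens continuous
variables into Student's t vs Mann-Whitney (the published analysis does
not state its normality criterion; this one is explicit and data-driven).
Categorical variables use chi-square without continuity correction,
auto-substituted by Fisher's exact test when any expected cell is below
5 — on the published gender table (16/2 vs 14/8) that rule selects Fisher,
whose p = 0.082 reproduces the printed value exactly. Within-group pre/post
comparisons use the paired t-test when the differences pass the screen,
else Wilcoxon signed-rank; the reported change column is exactly the
(after − before) sample mean ± SD. No multiplicity adjustment is applied,
matching the original analysis. These tests are scipy-backed; the module's
contract is the selection logic and table shaping.

## Pipeline determinism and problem sizes

A single top-level seed is fanned out through `numpy.random.SeedSequence`
to independent child seeds per stage (simulation, then one per predictor's
bootstrap), so stages are independently re-runnable yet the whole
simulate-analyze path is byte-reproducible; results JSON is written with
sorted keys at full precision, and rounding happens only in the report
renderer.

Simulation sizes used by the test and acceptance suites are chosen to make
Monte-Carlo error small relative to each check's margin: 1,000 replicate
cohorts for the mean-AUC checks (MC error ~3e−4 on the mean), 10,000
cohorts for CI coverage (MC error ~0.003 against a 0.007 margin), 50,000
per group for the large-sample AUC limit (tolerance 0.005), and 200
patients for beat-level parameter recovery.

## Known limitations

- The Hanley–McNeil SE assumes the exponential-model Q1/Q2 approximation;
  its CI is mildly anticonservative (92.7% coverage) at n = 40.
- The paired-AUC correlation model assumes bivariate binormal scores; for
  heavily tied or highly non-normal predictors prefer the permutation test.
- The generator's normal marginals admit (rare) negative index values; see
  above for why they are kept by default.
- Published patient-level quantities (exact AUCs, cutoffs, gray-zone
  endpoints) are not reproducible without the original data; the package
  targets the published *group structure* and the method's properties.
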