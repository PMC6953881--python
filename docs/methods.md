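# Methods

## Problem and pipeline

`actidays` estimates how many wear days a 24-h wrist-accelerometry
protocol needs for reliable habitual-PA estimates. The pipeline has four
stages: (1) raw tri-axial signal → calibrated, artifact-screened,
wear-flagged ENMO epoch series; (2) epoch series → per-day constructs
(overall PA, LPA minutes, bouted MVPA minutes) with valid-day and
analytical-sample filters; (3) balanced subjects × days matrices → one-way
ICC, Spearman–Brown reliability curves, minimum days at a target;
(4) day-of-week descriptive medians with rank tests. A synthetic-data
module generates inputs with known ground truth at three fidelity tiers.

## Signal stage

**Autocalibration.** Still windows (non-overlapping 10 s, per-axis
SD < 13 mg on all three axes) sample quasi-static gravity vectors, which
should lie on the unit sphere. Per-axis offset and gain are fit by
iterating: project calibrated points onto the sphere, refit the per-axis
linear map by least squares, stop when the mean absolute magnitude error
changes by < 0.01 mg (≤ 100 iterations). Identifiability requires
orientation coverage: if fewer than 10 still windows are found, or the
still orientations fail to span both signs (beyond ±0.1 g) on any axis,
the identity model is returned with `converged=False` rather than an
ill-conditioned fit. Offsets injected by the generator are recovered to
well within ±0.01 g on two hours of varied-orientation still signal.

**Abnormal values.** Samples beyond the device's ±8 g dynamic range are
flagged and clipped; an epoch is abnormal when more than half its samples
are flagged (a majority rule chosen as the simplest deterministic
propagation; exposed via `compute_enmo`).

**ENMO.** Per sample, `‖v‖ − 1 g`, negatives truncated to zero, averaged
per epoch, in mg. Truncation is the canonical definition used by the
standard open-source toolchain; a `negatives="absolute"` switch retains
the absolute-value variant for sensitivity analyses. Because
85.7 Hz × 5 s = 428.5 is not an integer, samples are binned to epochs by
timestamp (`floor(t / epoch_len)`), so epochs hold 428 or 429 samples and
no drift accumulates; the precondition only requires the cadence to divide
the epoch within one sample. The trailing partial epoch is dropped.

**Non-wear.** Sliding 60-min windows at 15-min steps (plus one window
anchored at the recording tail) vote non-wear when per-axis SD < 13 mg
*and* range < 50 mg on at least 2 of 3 axes; every epoch covered by a
voting window is non-wear, and `wear = ¬non-wear ∧ ¬abnormal`. These
thresholds are the established raw-accelerometry defaults and are all
configurable. When only an ENMO epoch series exists (no per-axis raw
data), a deliberately strict fallback flags windows whose ENMO mean and SD
are both < 3 mg — only a removed, motionless device produces a flat zero
signal, whereas quiet sleep retains sensor noise; this epoch-level dialect
is used by the epoch-fidelity pipeline and is documented as such.

## Constructs stage

Cut-points: MVPA strictly above 100 mg; LPA 50–100 mg with both
boundaries assigned to LPA (the 100 mg boundary cannot be MVPA because
MVPA is defined strictly above it; 50 mg is read inclusively). Bouts: a
candidate starts at an MVPA epoch and is the longest window from there
that spans ≥ 10 min, keeps the MVPA fraction ≥ 80 %, ends on an MVPA
epoch, and contains no non-MVPA run longer than 20 % of the minimum bout
(2 min at defaults); non-wear breaks bouts unconditionally; accepted bouts
are non-overlapping and the scan resumes after each. These concrete scan
rules are this package's specification of the loosely-stated 10-min/80 %
criterion; they are verified exhaustively against a brute-force
all-windows oracle. Days are calendar days midnight-to-midnight in local
time (required for day-of-week analyses); partial first/last days are
dropped; overall PA averages ENMO over wear epochs only, with no
imputation of non-wear time — a documented dialect choice. Valid days
need ≥ 16 h wear; the analytical sample keeps subjects with ≥ 6 valid
days and retains the first 6 chronologically, yielding balanced matrices.

## Reliability stage

The one-way random-effects single-measure ICC is used because the
prophecy's "single day → k days" logic treats days as exchangeable
replicates, which is exactly the one-way model; two-way forms would
attribute systematic day effects differently. Negative ICC estimates are
returned as-is and flagged, but excluded from the prophecy (a domain
error) rather than clamped — transparency over convenience. The minimum
days uses a strict `>` comparison at the 0.70 target; the closed-form
inversion is always verified by direct curve evaluation. Serialized
reports round coefficients to two decimals half-away-from-zero alongside
the raw values. The `SpearmanBrownReliability` estimator packages this as
a scikit-learn-style `fit`/`predict` object so it composes with sklearn
tooling; module functions are thin wrappers.

## Descriptives stage

Medians by day of week (Monday=1) over valid subject-days, pooled across
subjects without clustering adjustment — a deliberate replication of the
simple descriptive convention, and a documented limitation since repeated
days per subject are not independent. Kruskal–Wallis (chi-squared
distributed) tests the 7-day contrast; a two-sided Mann–Whitney U tests
weekday (Mon–Fri) vs weekend (Sat–Sun). Degenerate cases (identical
values, empty day categories) yield flagged NaN p-values instead of
spurious significance.

## Synthetic data: what it emulates, and what it does not

**Construct tier** draws `value[i,j] = μ + b_i + d_j + w_ij` with
`b_i ~ N(0, σ_b²)`, `w_ij ~ N(0, σ_w²)` and fixed day-of-week/weekend
offsets `d_j`. Offsets are fixed, not random, so the ground-truth one-way
ICC stays closed-form: `σ_b²/(σ_b² + σ_w²)` with offsets removed, and
`σ_b²/(σ_b² + σ_w² + Var(d))` when they are folded into within-subject
variance; the generator reports both. Negative-value truncation is off by
default so the closed form holds exactly.

**Epoch tier** drives a minute-resolution Markov chain over
{sleep, sedentary, light, MVPA} with separate day and night transition
matrices (night 22:00–06:00 pulls strongly to sleep, giving the diurnal
trough), mean state ENMO levels of 3/15/70/180 mg, a lognormal
(σ = 0.25) subject-level activity multiplier providing between-subject
heterogeneity, a weekend factor (default 0.7) scaling transitions into
light/MVPA on Saturdays and Sundays, per-epoch Gaussian noise (8 mg,
truncated at zero) and exact-zero non-wear gaps (probability 0.1 per
subject-day, 1–6 h). These defaults were chosen once to give
overall-PA day means of roughly 25–45 mg, tens of LPA minutes, sparse
bouted MVPA, and single-day ICCs in the 0.35–0.65 range typical of
day-replicate PA data.

**Raw tier** renders epochs to device-cadence samples: a
piecewise-constant random orientation unit vector (exponential holds, mean
5 min) scaled by (1 + true ENMO), plus 10 mg per-axis white noise.
Miscalibration is injected as `observed = true/gain + offset`; non-wear
windows are perfectly still and noise-free; spikes overwrite single
samples at ±10 g. The noise scale is chosen so still windows pass the
13 mg SD gate while worn windows fail the 50 mg range gate, and so the
sample-level truncation bias at zero activity (≈ 0.4σ ≈ 4 mg) keeps
ENMO recovery under 5 mg mean absolute error.

None of the tiers simulates realistic gait/posture waveforms, postural
transitions, temperature effects, or sociodemographic covariates, and
day-to-day variation is exchangeable white noise rather than
autocorrelated behaviour. Passing tests therefore demonstrate that the
algorithms recover known truth under the stated measurement model — not
that real cohorts have these variance components.

**Reproducibility.** One root seed per generator; `SeedSequence.spawn`
derives one child stream per subject in subject order, so the first
subjects of a cohort are unchanged when the cohort grows, and equal seeds
give bit-identical output end to end (the `all` subcommand is
byte-identical across runs).

## Problem sizes and numerical choices

The test suite and examples run the cohort pipeline at 100 subjects ×
7 days of 5-s epochs (≈ 12 M epochs, ~30 s single-threaded, held in
memory; epoch CSVs are only serialised by the file-based subcommands at
smaller scales), raw-signal tests at 10–25 Hz over hours-to-one-day
spans, and ICC recovery at 500 subjects × 6 days across seed batches.
Tie-breaks and edge cases: bout fraction comparisons use a 1e-12
tolerance so exact-80 % windows qualify on both the greedy and oracle
paths; zero-wear days carry NaN overall PA and are invalid; a constant
matrix raises rather than returning ICC 0/0; reported coefficients round
half-away-from-zero.

## Known limitations

The original processing chain's exact non-wear parameterisation and bout
interruption rules are version-dependent upstream and unstated in typical
reports; ours are fixed, documented and configurable, which is a dialect
risk when comparing absolute construct values against other toolchains.
Confidence intervals for minimum days (e.g. bootstrap over subjects) are
not provided. Sleep periods are intentionally not excluded, matching the
24-h wear convention. Weekend days are treated exchangeably with weekdays
in the reliability analysis.
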