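# Methods

This note documents the models, conventions, numerical choices and
limitations behind `copkit`, in the order the pipeline runs.

## Coordinate conventions and CoP computation

The plate travel axis is the anterior–posterior (AP) axis, positive
anterior (the direction the subject faces); forward (FW) plate motion is
+AP. Medio-lateral (ML) is positive toward the subject's right. CoP is
reported in centimetres; the AP-window scores (FP, ΔCoPMax, PPV) in
millimetres, since they are sub-centimetre quantities.

The CoP follows the standard force-plate equations with the sensor
origin a distance `z0` below the plate surface:

    ap = 100·(Mx − Fy·z0)/Fz    ml = 100·(−My + Fx·z0)/Fz   [cm]

These are the moment-balance solution `M = r × F` for the ground
reaction force acting at the surface point `(ml, ap, z0)`, under an
AMTI-style sign convention for the moments; `moment_sign=-1` accommodates
plates wired the opposite way. `z0` defaults to 0 (vendor-specific
offsets vary and are often folded into the plate's own output); the
conversion refuses to run when `Fz ≤ 10 N` anywhere, since an unloaded
plate has no defined CoP.

Filtering: a zero-phase (forward–backward) 4th-order Butterworth low-pass
at 10 Hz is applied to the CoP by default. Postural responses live well
below 10 Hz, while unfiltered CoP differentiation (Unit Path) is
noise-dominated; the filter is configurable and can be disabled.

## Perturbation point and response window

The PP is detected from the plate-position channel: with `μ0, σ0` the
mean and SD over the first 5 s (assumed quiescent), the PP is the first
index from which `|pos − μ0| > 6σ0` holds for 3 consecutive samples.
`σ0` is floored at 0.05 mm (a typical potentiometer resolution) so that
noise-free synthetic signals do not produce a zero threshold. A signal
that never trips the rule is a valid *no-perturbation* outcome (`None`),
matching the protocol's catch trials. When the position channel is
missing, an explicit onset in the trial metadata is accepted instead.
The threshold rule is a documented operational choice; at the protocol's
slowest ramp (100 mm/s) the 0.3 mm worst-case threshold is crossed
within one 200 Hz sample of true onset, and under 0.1 mm sensor noise
detection stays within 15 ms (verified by seeded simulation).

The analysis window is the half-open interval (PP, PP + 2.5 s], selected
by sample-index arithmetic so the PP sample itself (pre-motion) is
excluded: 500 samples at 200 Hz. The AP baseline is the mean over the
2.5 s immediately preceding the PP — the protocol only fixes "before the
PP"; a window symmetric with the analysis window is the default and both
spans are configurable.

## The five scores

* **Area95** uses the chi-square form `π·χ²₀.₉₅,₂·√det S` (χ² quantile
  5.9915) on the sample covariance (divisor n−1). The small-sample
  F-form `2π·(n−1)/(n−2)·F₀.₉₅;₂,ₙ₋₂·√det S` is available behind a
  switch for cross-lab comparison; at n = 500 they differ by < 1%.
* **Unit Path** sums planar distances between consecutive window samples
  and divides by the window duration.
* **FP** is the *global* maximum of `s·d(t)` over the window, not the
  first local peak: in observed traces the first excursion is the
  largest, and the global rule is deterministic and noise-robust. The
  expected-sign map is FW → −1 (initial posterior excursion), BW → +1 —
  configurable, since the excursion polarity is a convention. A response
  that never moves in the expected direction scores FP = 0 and is
  flagged rather than reported negative.
* **SP** is searched strictly after `t_FP` (the counterbalance follows
  the first reaction); ΔCoPMax = FP + SP identically.
* **PPV** is the sample SD (n−1) of `d` over the window; subtracting the
  baseline does not change it but keeps the quantity interpretable.

## Inverted-pendulum simulator

Sagittal single inverted pendulum pivoting at the ankle on a translating
base:

    I·θ̈ = m·g·h·sin θ − m·h·ü(t)·cos θ − T(t)
    T(t) = Kp·θ(t−τ) + Kd·θ̇(t−τ) + noise

| parameter | default | meaning |
|---|---|---|
| m, H | 62.5 kg, 1.70 m | cohort mean body mass and stature |
| h | 0.55·H | CoM height above the ankle |
| I | (4/3)·m·h² | inertia about the ankle |
| Kp | 1.3·m·g·h | ankle stiffness; upright stability needs Kp > m·g·h |
| Kd | 0.25·Kp s | ankle damping — stable, underdamped, damped-oscillatory CoP |
| τ | 150 ms | feedback delay, in the physiological long-latency range |
| cop_offset_ap | 5.5 cm | quiet-stance CoP ahead of the ankle (the CoM projects 50–60 mm in front of the ankle in bipedal stance) |
| σ_torque | 0.7 N·m | white motor noise → mm-scale quiet-stance sway |
| σ_meas, σ_plate | 0.05 N / N·m, 0.02 mm | channel and potentiometer noise |

Numerics: fixed-step classical 4th-order Runge–Kutta at 1 kHz with a
transport delay buffer; the delayed torque and plate acceleration are
held over each step. Plate acceleration is the per-step finite
difference of the analytic ramp/half-cosine velocity profile, so the
ramp's velocity discontinuities become one-step impulses whose time
integral is exact. Output is decimated to 200 Hz. The vertical force is
quasi-static (`Fz = m·g`; vertical CoM acceleration is second order for
these translations), which makes the emitted moments encode the CoP
exactly — `ap = T/(m·g) + offset` — so the simulator doubles as an exact
pipeline oracle. A lean beyond 30° raises a fall error: outside the
feet-in-place regime the protocol (and the model) no longer applies.

The FW/BW asymmetry and the ramp-rate trend emerge from the physics: the
onset impulse scales with ramp rate, and a forward base translation
throws the CoM backward, driving a posterior CoP excursion. The
simulator is sagittal-only: the ML CoP carries measurement noise but no
dynamics, so simulated Area95 values are far smaller than real ones
(real subjects sway medio-laterally too). No quantitative response
traces were available to calibrate against, so simulator realism is
qualitative: damped oscillation of plausible magnitude and timing.

## Parametric response generator and synthetic studies

For statistical work the damped-sinusoid generator emits
`d(t) = s·a·sin(2πf·(t−PP))·e^(−λ(t−PP))` mm plus white noise, encoded
into force-plate channels the same way. Its ground truth is closed-form:
extrema where `tan(2πf t) = 2πf/λ`, PPV from a dense 2 kHz grid of the
noiseless response. Defaults a ≈ 20 mm, f = 0.8 Hz, λ = 0.9 s⁻¹ give
first/second peaks near 23/13 mm — the scale seen in perturbed-stance
CoP traces.

`generate_study` reproduces the protocol's shape: n subjects × 2
sessions × (12 perturbation conditions + 3 catch trials) in per-session
randomized order, onset uniform in 20–40 s of a 60 s trial (shorter
trials tighten the range proportionally, keeping ≥ 7.5 s before and
> 2.5 s after the onset). Condition structure is multiplicative on the
amplitude: direction × rate × displacement multipliers (defaults 0.7/1.0,
0.7/1.0, 0.75/0.9/1.0 — responses grow with rate and displacement, FW
smaller than BW), log-normal subject (σ = 0.15) and trial (σ = 0.10)
multipliers, and 0.3 mm CoP noise. All multipliers at 1 gives an exact
null study. Whole-study generation uses this parametric source rather
than the pendulum: per-trial ground truth is exact and generation is
orders of magnitude faster, which the Monte-Carlo calibration needs; the
pendulum remains the physics validation path. Every trial's seed derives
from the single study seed and is recorded in the manifest.

What passing tests on these synthetics do **not** show: robustness to
real-world artifacts (drift, plate ringing, voluntary steps, hip
strategies, ML dynamics, non-Gaussian sensor noise) or the realism of
any particular amplitude model.

## Statistical chain

The subjects × 12 condition table averages the available repetitions per
cell; subjects with any empty cell are dropped with a warning (≥ 2
complete subjects required). The three-way RM-ANOVA decomposes the
within-subject sum of squares by orthogonal mean-centering: for effect
S, collapse the factors outside S by averaging, center each factor in S,
then split into the across-subject mean (effect SS) and residual
(subject×S error SS). Each effect is tested against its own
subject-interaction term (the standard univariate RM-ANOVA; no pooled
error), `F = (SS_eff/df1)/(SS_err/df2)` with `df1 = Π(levels−1)`,
`df2 = (n−1)·df1`, and `η²p = SS_eff/(SS_eff + SS_err)` — identically
equal to `F·df1/(F·df1 + df2)`.

For every effect with df1 > 1 (those involving the three-level
displacement factor), the per-subject orthonormal Helmert-contrast
scores give the covariance used for Mauchly's W (chi-square
approximation) and the Greenhouse–Geisser ε (eigenvalue form, clamped to
[1/df1, 1]). GG is applied — p recomputed at ε-scaled dfs, F and η²p
untouched — only when Mauchly's p < 0.05; two-level effects satisfy
sphericity trivially. The implementation is verified to 8+ significant
digits against an independent inclusion–exclusion brute-force
decomposition, against statsmodels' `AnovaRM` (F, p), and against
pingouin (W, ε, GG p); a single two-level factor reduces exactly to the
paired t-test (F = t²).

Degenerate inputs are flagged, not raised: all-constant data reports
SS = 0, η²p = 0, F undefined; zero error SS with a nonzero effect
reports F undefined with η²p = 1.

Post hocs: paired t-tests on subject-level marginal means within each
factor, Bonferroni family = that factor's level pairs (m = 3 for
displacement, m = 1 otherwise), `p_bonf = min(1, m·p)`. Cohen's d is the
paired `d_z = mean(diff)/SD(diff)` — the convention of common RM-ANOVA
software — with its 95% CI from inverting the noncentral-t CDF at
`t = d√n` (Brent root-finding, tolerance 1e−10); the mean-difference CI
(measurement units) is reported alongside, since published tables mix
the two conventions. A zero-variance difference yields a signed infinite
d with a flag.

## Problem sizes used in validation

The Monte-Carlo suites scale the trial length, not the protocol
structure: calibration studies use 12 s trials (onset 7.5–9.4 s) —
window, baseline and detection settings identical to the 60 s protocol —
with 500 seeded null studies of 10 subjects for type-I error (expected
per-effect rate 0.05, accepted 0.03–0.07) and 50 replicates for the
power/selectivity check of a rate-only effect (ramp-rate multiplier
1 vs 1.3). Parameter recovery runs a 4×3×3×3 grid of amplitudes
(5–40 mm), frequencies (0.4–1.5 Hz), decays (0.3–1.5 s⁻¹) and noise
(0–0.5 mm); the accepted FP/SP error is one sampling interval's worth of
signal change per trial, PP within 15 ms, noise-free PPV within 1%.
Pendulum checks use 12–13 s trials with 5 seeds per grid cell.

## Known limitations

* Single-plate, sagittal-perturbation protocol only; no hip-strategy or
  stepping-response modelling, and the scores cannot discriminate ankle
  from hip strategy.
* Linear time-domain CoP measures only (no frequency-domain or
  non-linear stabilogram descriptors).
* The PP detection rule is an operational definition; hardware trigger
  channels, where available, are preferable (supply `pp_time` metadata).
* C3D and vendor binary formats are out of scope; export to delimited
  text first.
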