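"""Synthetic perturbed-stance trials with known ground truth.

Two generators:

* :func:`simulate_trial` — a physics-based simulator. The standing body is
  a single inverted pendulum pivoting at the ankle, stabilised by delayed
  proportional-derivative ankle torque, standing on a platform that
  translates with a ramp (or half-cosine) displacement profile. It emits
  the six force-plate channels plus the plate-position channel, so the
  whole analysis pipeline runs on its output unchanged.

* :func:`generate_parametric` — a closed-form damped-sinusoid CoP
  response whose first peak, second peak and variability are known
  exactly, used as a recovery oracle and as the fast trial source for
  whole-study generation (:func:`generate_study`).

All randomness flows from a single integer seed.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from . import cop_metrics, trial_io
from .trial_io import (CopkitError, Direction, ForcePlateTrial,
                       ParameterError, TrialMeta)

G = 9.81  # m/s^2


class FallError(CopkitError):
    """The pendulum left the feet-in-place regime (|angle| > threshold)."""


class Waveform(str, enum.Enum):
    RAMP = "RAMP"
    SINE = "SINE"


# ---------------------------------------------------------------------------
# Plate motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateProfile:
    """Support-surface translation: direction, extent, speed, onset.

    RAMP moves at a constant ``ramp_rate`` (mm/s) for
    ``displacement/ramp_rate`` seconds; SINE reaches the same endpoint in
    the same time along a half-cosine. FW motion is positive, BW negative.
    """

    direction: Direction
    displacement: Optional[float] = None  # mm
    ramp_rate: Optional[float] = None     # mm/s
    onset: float = 30.0                   # s
    waveform: Waveform = Waveform.RAMP

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "waveform", Waveform(self.waveform))
        if self.direction is not Direction.NONE:
            if self.displacement is None or self.ramp_rate is None:
                raise ParameterError("perturbed profiles need displacement and ramp_rate")
            if self.displacement <= 0 or self.ramp_rate <= 0:
                raise ParameterError("displacement and ramp_rate must be positive")
        if self.onset < 0:
            raise ParameterError("onset must be non-negative")

    @property
    def sign(self) -> int:
        return {Direction.FW: +1, Direction.BW: -1, Direction.NONE: 0}[self.direction]

    @property
    def ramp_duration(self) -> float:
        if self.direction is Direction.NONE:
            return 0.0
        return self.displacement / self.ramp_rate


def plate_position(profile: PlateProfile, t) -> np.ndarray:
    """Plate position (mm) at time(s) ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    if profile.direction is Direction.NONE:
        return np.zeros_like(t)
    T = profile.ramp_duration
    tau = np.clip(t - profile.onset, 0.0, T)
    if profile.waveform is Waveform.RAMP:
        u = profile.ramp_rate * tau
    else:  # SINE: half-cosine from 0 to displacement over T
        u = profile.displacement / 2.0 * (1.0 - np.cos(np.pi * tau / T))
    return profile.sign * u


def plate_velocity(profile: PlateProfile, t) -> np.ndarray:
    """Plate velocity (mm/s) at time(s) ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    if profile.direction is Direction.NONE:
        return np.zeros_like(t)
    T = profile.ramp_duration
    tau = t - profile.onset
    moving = (tau >= 0) & (tau <= T)
    if profile.waveform is Waveform.RAMP:
        v = np.where(moving, profile.ramp_rate, 0.0)
    else:
        v = np.where(
            moving,
            profile.displacement * np.pi / (2.0 * T) * np.sin(np.pi * np.clip(tau, 0, T) / T),
            0.0,
        )
    return profile.sign * v


# ---------------------------------------------------------------------------
# Inverted-pendulum simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PendulumConfig:
    """Single-inverted-pendulum body and controller parameters.

    Anthropometrics default to the assessed cohort (62.5 kg, 1.70 m) with
    the centre of mass at 0.55 of stature and the pendulum inertia about
    the ankle ``(4/3) m h^2``. Ankle torque is delayed
    proportional-derivative feedback ``Kp*theta(t-tau) + Kd*dtheta(t-tau)``
    plus white motor noise; defaults ``Kp = 1.3 m g h`` (stable, since
    upright stability needs Kp > m g h) and ``Kd = 0.25 Kp`` s give an
    underdamped, damped-oscillatory CoP response. The quiet-stance CoP
    sits ``cop_offset_ap`` ahead of the ankle (the centre of mass projects
    50–60 mm in front of the ankle joint in bipedal stance).
    """

    m: float = 62.5          # body mass, kg
    H: float = 1.70          # stature, m
    h: Optional[float] = None        # CoM height, m (default 0.55*H)
    I: Optional[float] = None        # inertia about ankle, kg m^2 (default 4/3 m h^2)
    Kp: Optional[float] = None       # ankle stiffness, N m/rad (default 1.3 m g h)
    Kd: Optional[float] = None       # ankle damping, N m s/rad (default 0.25*Kp)
    tau: float = 0.15        # feedback delay, s
    sigma_torque: float = 0.7   # motor-noise SD, N m
    sigma_meas: float = 0.05    # force/moment channel noise SD, N / N m
    sigma_plate: float = 0.02   # plate-position channel noise SD, mm
    cop_offset_ap: float = 5.5  # quiet-stance CoP ahead of ankle, cm
    theta0: float = 0.0      # initial lean, rad
    sim_rate: float = 1000.0    # integrator rate, Hz
    out_rate: float = 200.0     # emitted sampling rate, Hz
    fall_deg: float = 30.0      # feet-in-place limit, deg
    seed: int = 0

    def __post_init__(self) -> None:
        h = 0.55 * self.H if self.h is None else self.h
        object.__setattr__(self, "h", h)
        if self.I is None:
            object.__setattr__(self, "I", self.m * h * h * 4.0 / 3.0)
        if self.Kp is None:
            object.__setattr__(self, "Kp", 1.3 * self.m * G * h)
        if self.Kd is None:
            object.__setattr__(self, "Kd", 0.25 * self.Kp)
        if self.Kp <= self.m * G * h:
            raise ParameterError(
                f"Kp = {self.Kp:g} N·m/rad does not exceed m·g·h = "
                f"{self.m * G * h:g}: upright posture unstable"
            )
        if self.tau < 0:
            raise ParameterError("feedback delay tau must be >= 0")
        ratio = self.sim_rate / self.out_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError("sim_rate must be an integer multiple of out_rate")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth attached to a synthetic trial.

    The parametric generator knows its first/second peak and variability
    in closed form; the physics simulator only guarantees the onset time.
    """

    pp_true: Optional[float]
    fp_true: Optional[float] = None
    sp_true: Optional[float] = None
    ppv_true: Optional[float] = None
    amplitude: Optional[float] = None
    frequency: Optional[float] = None
    decay: Optional[float] = None


def simulate_trial(
    plate: PlateProfile,
    body: PendulumConfig = PendulumConfig(),
    duration: float = 60.0,
    meta: Optional[TrialMeta] = None,
) -> tuple[ForcePlateTrial, GroundTruth]:
    """Integrate the perturbed inverted pendulum and emit a trial.

    Dynamics: ``I*theta'' = m*g*h*sin(theta) - m*h*u''(t)*cos(theta) - T(t)``
    with delayed feedback torque ``T(t) = Kp*theta(t-tau) + Kd*theta'(t-tau)
    + noise`` and ``u(t)`` the plate position. Fixed-step 4th-order
    Runge-Kutta at ``sim_rate`` with a transport delay buffer; the delayed
    torque and the plate acceleration are held over each step. The vertical
    force is quasi-static (``Fz = m g``) and the AP CoP is
    ``T/(m g) + cop_offset``, so the emitted moments encode the CoP
    exactly. Raises :class:`FallError` beyond ``fall_deg``.
    """
    m, h, I = body.m, body.h, body.I
    Kp, Kd = body.Kp, body.Kd
    dt = 1.0 / body.sim_rate
    n_sim = int(round(duration * body.sim_rate))
    stride = int(round(body.sim_rate / body.out_rate))
    n_out = n_sim // stride

    rng = np.random.default_rng(body.seed)
    t_grid = np.arange(n_sim + 1) * dt
    v_mm = plate_velocity(plate, t_grid)
    udd = np.diff(v_mm) / dt / 1000.0  # plate acceleration, m/s^2, per step
    noise = (rng.normal(0.0, body.sigma_torque, n_sim)
             if body.sigma_torque > 0 else np.zeros(n_sim))

    d_steps = int(round(body.tau * body.sim_rate))
    th = np.empty(n_sim + 1)
    w = np.empty(n_sim + 1)
    th[0], w[0] = body.theta0, 0.0
    torque = np.empty(n_sim)
    fall_rad = math.radians(body.fall_deg)
    mgh = m * G * h
    mh = m * h
    sin, cos = math.sin, math.cos

    for i in range(n_sim):
        j = i - d_steps
        th_d = th[j] if j >= 0 else body.theta0
        w_d = w[j] if j >= 0 else 0.0
        T = Kp * th_d + Kd * w_d + noise[i]
        torque[i] = T
        a = udd[i]

        def f(theta, omega):
            return (mgh * sin(theta) - mh * a * cos(theta) - T) / I

        t1, w1 = th[i], w[i]
        k1w = f(t1, w1)
        k2w = f(t1 + 0.5 * dt * w1, w1 + 0.5 * dt * k1w)
        t2 = t1 + 0.5 * dt * w1 + 0.125 * dt * dt * k1w
        k3w = f(t2, w1 + 0.5 * dt * k2w)
        t3 = t1 + dt * w1 + 0.5 * dt * dt * k2w
        k4w = f(t3, w1 + dt * k3w)
        th[i + 1] = t1 + dt * w1 + dt * dt / 6.0 * (k1w + k2w + k3w)
        w[i + 1] = w1 + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
        if abs(th[i + 1]) > fall_rad:
            raise FallError(
                f"pendulum exceeded {body.fall_deg:g} deg at t = "
                f"{(i + 1) * dt:.2f} s (direction={plate.direction.value}, "
                f"displacement={plate.displacement}, ramp_rate={plate.ramp_rate}, "
                f"Kp={Kp:.4g}, Kd={Kd:.4g})"
            )

    out_idx = np.arange(n_out) * stride
    t_out = out_idx * dt
    cop_ap_m = torque[out_idx] / (m * G) + body.cop_offset_ap / 100.0
    fz = m * G

    def ch_noise():
        return (rng.normal(0.0, body.sigma_meas, n_out)
                if body.sigma_meas > 0 else np.zeros(n_out))

    Fz = fz + ch_noise()
    Mx = fz * cop_ap_m + ch_noise()
    My = np.zeros(n_out) + ch_noise()
    u_out = plate_position(plate, t_out)
    if body.sigma_plate > 0:
        u_out = u_out + rng.normal(0.0, body.sigma_plate, n_out)

    if meta is None:
        meta = TrialMeta(
            subject_id="sim", repetition=1, direction=plate.direction,
            displacement=plate.displacement if plate.direction is not Direction.NONE else None,
            ramp_rate=plate.ramp_rate if plate.direction is not Direction.NONE else None,
            sampling_rate=body.out_rate,
        )
    trial = ForcePlateTrial(
        t=t_out, Fx=np.zeros(n_out) + ch_noise(), Fy=np.zeros(n_out) + ch_noise(),
        Fz=Fz, Mx=Mx, My=My, Mz=np.zeros(n_out) + ch_noise(),
        plate_pos=u_out, meta=meta,
    )
    pp_true = plate.onset if plate.direction is not Direction.NONE else None
    return trial, GroundTruth(pp_true=pp_true)


# ---------------------------------------------------------------------------
# Parametric damped-sinusoid generator
# ---------------------------------------------------------------------------

def _damped_extrema(a: float, f: float, lam: float,
                    post_s: float) -> tuple[float, float, float, float]:
    """Closed-form FP/SP of ``d(t) = a sin(2 pi f t) exp(-lam t)`` on (0, post_s].

    Interior extrema satisfy ``tan(2 pi f t) = 2 pi f / lam``; the window
    endpoint caps the search. Returns (fp, t_fp, sp, t_sp) with sp=0 /
    t_sp=nan when no counterswing fits in the window.
    """
    if a == 0.0 or f <= 0.0:
        return 0.0, float("nan"), 0.0, float("nan")
    w = 2.0 * math.pi * f

    def d(t):
        return a * math.sin(w * t) * math.exp(-lam * t)

    t1 = math.atan2(w, lam) / w  # first maximum of +d
    if t1 >= post_s:
        return max(d(post_s), 0.0), post_s, 0.0, float("nan")
    fp, t_fp = d(t1), t1
    t2 = t1 + math.pi / w        # first minimum (counterswing)
    if t2 <= post_s:
        sp, t_sp = -d(t2), t2
    else:
        sp, t_sp = max(-d(post_s), 0.0), post_s
        if sp == 0.0:
            t_sp = float("nan")
    return fp, t_fp, sp, t_sp


def generate_parametric(
    profile: PlateProfile,
    a: float,
    f: float = 0.8,
    lam: float = 0.9,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_ap: float = 5.5,
    duration: float = 60.0,
    fs: float = trial_io.DEFAULT_SAMPLING_RATE,
    mass: float = 62.5,
    post_s: float = 2.5,
    meta: Optional[TrialMeta] = None,
) -> tuple[ForcePlateTrial, GroundTruth]:
    """Emit a trial whose AP CoP response is a known damped sinusoid.

    After the onset the baseline-referenced AP displacement (mm) is
    ``s * a * sin(2 pi f (t-PP)) * exp(-lam (t-PP))`` with ``s`` the
    direction's expected excursion sign, plus white Gaussian noise of SD
    ``noise_sd`` mm on both CoP axes. The CoP is encoded exactly into the
    force/moment channels (quasi-static ``Fz = m g``), and the plate
    profile provides the position channel, so the full pipeline applies.
    Ground-truth FP/SP come from the closed-form extrema; the ground-truth
    PPV is evaluated on a dense (2 kHz) grid of the noiseless response.
    """
    if a < 0 or lam < 0:
        raise ParameterError("amplitude and decay must be non-negative")
    if a > 0 and f <= 0:
        raise ParameterError("frequency must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    perturbed = profile.direction is not Direction.NONE
    s = cop_metrics.DEFAULT_SIGN[profile.direction] if perturbed else 0

    d_mm = np.zeros(n)
    if perturbed and a > 0:
        rel = t - profile.onset
        post = rel > 0
        d_mm[post] = s * a * np.sin(2 * np.pi * f * rel[post]) * np.exp(-lam * rel[post])
    ap_cm = baseline_ap + d_mm / 10.0
    ml_cm = np.zeros(n)
    if noise_sd > 0:
        ap_cm = ap_cm + rng.normal(0.0, noise_sd / 10.0, n)
        ml_cm = ml_cm + rng.normal(0.0, noise_sd / 10.0, n)

    fz = mass * G
    trial = ForcePlateTrial(
        t=t,
        Fx=np.zeros(n), Fy=np.zeros(n), Fz=np.full(n, fz),
        Mx=fz * ap_cm / 100.0, My=-fz * ml_cm / 100.0, Mz=np.zeros(n),
        plate_pos=plate_position(profile, t),
        meta=meta if meta is not None else TrialMeta(
            subject_id="sim", repetition=1, direction=profile.direction,
            displacement=profile.displacement if perturbed else None,
            ramp_rate=profile.ramp_rate if perturbed else None,
            sampling_rate=fs,
        ),
    )

    if perturbed:
        fp, _, sp, _ = _damped_extrema(a, f, lam, post_s)
        dense = np.arange(1, int(round(post_s * 2000)) + 1) / 2000.0
        d_dense = a * np.sin(2 * np.pi * f * dense) * np.exp(-lam * dense)
        truth = GroundTruth(
            pp_true=profile.onset, fp_true=fp, sp_true=sp,
            ppv_true=float(np.std(d_dense, ddof=1)),
            amplitude=a, frequency=f, decay=lam,
        )
    else:
        truth = GroundTruth(pp_true=None, amplitude=0.0)
    return trial, truth


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyEffects:
    """Condition and variance structure of a synthetic study.

    The response amplitude of a trial is
    ``base_amplitude * direction_mult * rate_mult * displacement_mult *
    subject_effect * trial_jitter`` (mm), with log-normal subject and
    trial multipliers. The default multipliers reproduce the observed
    effect directions: responses grow with ramp rate and displacement and
    are smaller for forward than backward translations. Setting every
    multiplier to 1 (:meth:`null`) yields a null study.
    """

    direction: dict = field(default_factory=lambda: {"FW": 0.7, "BW": 1.0})
    ramp_rate: dict = field(default_factory=lambda: {100.0: 0.7, 200.0: 1.0})
    displacement: dict = field(
        default_factory=lambda: {25.0: 0.75, 50.0: 0.9, 100.0: 1.0})
    base_amplitude: float = 20.0   # mm
    base_frequency: float = 0.8    # Hz
    base_decay: float = 0.9        # 1/s
    subject_sd: float = 0.15       # log-scale SD of the subject multiplier
    trial_sd: float = 0.10         # log-scale SD of the trial multiplier
    noise_sd: float = 0.3          # CoP measurement noise, mm
    baseline_ap: float = 5.5       # quiet-stance AP CoP, cm

    @classmethod
    def null(cls, **kwargs) -> "StudyEffects":
        """All condition multipliers at unity: no true effects."""
        return cls(direction={"FW": 1.0, "BW": 1.0},
                   ramp_rate={100.0: 1.0, 200.0: 1.0},
                   displacement={25.0: 1.0, 50.0: 1.0, 100.0: 1.0},
                   **kwargs)

    @classmethod
    def rate_only(cls, contrast: float = 0.3, **kwargs) -> "StudyEffects":
        """Only the ramp-rate effect active (multiplier 1 vs 1+contrast)."""
        return cls(direction={"FW": 1.0, "BW": 1.0},
                   ramp_rate={100.0: 1.0, 200.0: 1.0 + contrast},
                   displacement={25.0: 1.0, 50.0: 1.0, 100.0: 1.0},
                   **kwargs)


#: the 12 perturbation conditions of one session
CONDITION_GRID = tuple(
    (d, r, x)
    for d in (Direction.FW, Direction.BW)
    for r in trial_io.RAMP_RATES_MM_S
    for x in trial_io.DISPLACEMENTS_MM
)
N_CATCH_TRIALS = 3
N_REPETITIONS = 2


def default_onset_range(duration: float) -> tuple[float, float]:
    """Onset window for a trial length: (20, 40) s for the full 60 s
    protocol, proportionally tightened for shorter trials while keeping
    the 7.5 s pre-onset minimum (PP-detection baseline + pre-PP window)
    and >2.5 s of post-onset data."""
    lo = max(7.5, min(20.0, duration / 3.0))
    hi = min(40.0, duration - 2.6)
    if hi <= lo:
        raise ParameterError(
            f"duration {duration:g} s is too short for a perturbation trial"
        )
    return lo, hi


def iter_study_trials(
    n_subjects: int = 20,
    effects: Optional[StudyEffects] = None,
    seed: int = 0,
    duration: float = 60.0,
    onset_range: Optional[tuple[float, float]] = None,
    fs: float = trial_io.DEFAULT_SAMPLING_RATE,
) -> Iterator[tuple[ForcePlateTrial, GroundTruth, int]]:
    """Yield the trials of a synthetic study one at a time.

    Each subject performs two sessions of 15 trials (the 12 perturbation
    conditions plus 3 catch trials) in a per-session random order, with
    the onset drawn uniformly from ``onset_range`` (default: 20-40 s into
    a 60 s trial) so the subject cannot anticipate it. Yields
    ``(trial, ground_truth, trial_seed)``.
    """
    if n_subjects < 2:
        raise ParameterError("a study needs at least 2 subjects")
    lo, hi = onset_range if onset_range is not None else default_onset_range(duration)
    if lo < 7.5 or hi + 2.6 > duration:
        raise ParameterError(
            "onset_range must leave >= 7.5 s before (PP detection baseline + "
            "pre-PP window) and > 2.5 s after the onset"
        )
    eff = effects if effects is not None else StudyEffects()
    master = np.random.default_rng(seed)

    for si in range(n_subjects):
        subj = f"S{si + 1:02d}"
        subj_amp = float(np.exp(master.normal(0.0, eff.subject_sd)))
        subj_f = eff.base_frequency * float(np.exp(master.normal(0.0, 0.05)))
        subj_lam = eff.base_decay * float(np.exp(master.normal(0.0, 0.10)))
        for rep in range(1, N_REPETITIONS + 1):
            conditions: list[Optional[tuple]] = list(CONDITION_GRID) + [None] * N_CATCH_TRIALS
            order = master.permutation(len(conditions))
            for trial_idx, ci in enumerate(order, start=1):
                cond = conditions[ci]
                trial_seed = int(master.integers(2 ** 31))
                onset = float(master.uniform(lo, hi))
                if cond is None:
                    meta = TrialMeta(subject_id=subj, repetition=rep,
                                     direction=Direction.NONE, sampling_rate=fs)
                    profile = PlateProfile(direction=Direction.NONE, onset=onset)
                    trial, truth = generate_parametric(
                        profile, a=0.0, noise_sd=eff.noise_sd, seed=trial_seed,
                        baseline_ap=eff.baseline_ap, duration=duration, fs=fs,
                        meta=meta)
                else:
                    d, r, x = cond
                    amp = (eff.base_amplitude * eff.direction[d.value]
                           * eff.ramp_rate[r] * eff.displacement[x] * subj_amp
                           * float(np.exp(master.normal(0.0, eff.trial_sd))))
                    meta = TrialMeta(subject_id=subj, repetition=rep,
                                     direction=d, displacement=x, ramp_rate=r,
                                     sampling_rate=fs)
                    profile = PlateProfile(direction=d, displacement=x,
                                           ramp_rate=r, onset=onset)
                    trial, truth = generate_parametric(
                        profile, a=amp, f=subj_f, lam=subj_lam,
                        noise_sd=eff.noise_sd, seed=trial_seed,
                        baseline_ap=eff.baseline_ap, duration=duration, fs=fs,
                        meta=meta)
                yield trial, truth, trial_seed


def generate_study(
    n_subjects: int = 20,
    effects: Optional[StudyEffects] = None,
    seed: int = 0,
    out_dir=None,
    duration: float = 60.0,
    onset_range: Optional[tuple[float, float]] = None,
    fs: float = trial_io.DEFAULT_SAMPLING_RATE,
) -> pd.DataFrame:
    """Generate a full synthetic study; optionally write it to disk.

    Returns the manifest (one row per trial: file name, metadata, the
    trial seed and the generator ground truth). With ``out_dir`` set,
    writes one CSV per trial plus ``manifest.csv``.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict[tuple, int] = {}
    for trial, truth, trial_seed in iter_study_trials(
            n_subjects, effects, seed, duration, onset_range, fs):
        meta = trial.meta
        key = (meta.subject_id, meta.repetition)
        counters[key] = counters.get(key, 0) + 1
        fname = f"{meta.subject_id}_rep{meta.repetition}_trial{counters[key]:02d}.csv"
        if out is not None:
            trial_io.write_trial(trial, out / fname)
        rows.append({
            "file": fname,
            "subject_id": meta.subject_id,
            "repetition": meta.repetition,
            "trial_index": counters[key],
            "direction": meta.direction.value,
            "displacement": meta.displacement,
            "ramp_rate": meta.ramp_rate,
            "sampling_rate": meta.sampling_rate,
            "seed": trial_seed,
            "onset_true": truth.pp_true,
            "fp_true": truth.fp_true,
            "sp_true": truth.sp_true,
            "ppv_true": truth.ppv_true,
        })
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def study_results(
    n_subjects: int = 20,
    effects: Optional[StudyEffects] = None,
    seed: int = 0,
    config: Optional[cop_metrics.AnalysisConfig] = None,
    duration: float = 60.0,
    onset_range: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Generate a study in memory and run the per-trial analysis on it.

    Convenience path for Monte-Carlo work: same trials as
    :func:`generate_study`, analysed with :func:`~copkit.cop_metrics.
    analyze_trial`, returned as the trial-results table.
    """
    cfg = config if config is not None else cop_metrics.AnalysisConfig()
    records = [
        cop_metrics.analyze_trial(trial, cfg)
        for trial, _, _ in iter_study_trials(
            n_subjects, effects, seed, duration, onset_range)
    ]
    return cop_metrics.results_to_frame(records)
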