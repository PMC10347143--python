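"""Perturbation-onset detection and the post-perturbation response window.

The perturbation point (PP) is the instant the movable support surface
starts to translate. It is detected from the plate-position channel by a
threshold rule on the deviation from the quiescent baseline, or taken from
trial metadata when the position channel is unavailable. All balance
scores are computed over the 2.5 s window immediately following the PP,
with the anterior–posterior CoP referenced to its pre-PP mean.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trial_io import CoPTrajectory, Direction, ParameterError, CopkitError


class WindowError(CopkitError):
    """The trial does not contain enough data around the PP."""


class PPSource(str, enum.Enum):
    PLATE_SIGNAL = "PLATE_SIGNAL"
    METADATA = "METADATA"


@dataclass(frozen=True)
class PerturbationEvent:
    """Detected (or declared) perturbation onset."""

    pp_time: float
    pp_index: int
    source: PPSource


# Detection defaults: deviation threshold in baseline SDs, required
# consecutive samples above threshold, quiescent-baseline span, and the
# instrument-resolution floor on the baseline SD (handles noise-free
# synthetic position signals whose SD would otherwise be zero).
DEFAULT_K_SIGMA = 6.0
DEFAULT_MIN_RUN = 3
DEFAULT_QUIET_S = 5.0
DEFAULT_SIGMA_FLOOR_MM = 0.05


def detect_pp(
    plate_pos: np.ndarray,
    t: np.ndarray,
    k_sigma: float = DEFAULT_K_SIGMA,
    min_run: int = DEFAULT_MIN_RUN,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR_MM,
    quiet_s: float = DEFAULT_QUIET_S,
) -> Optional[PerturbationEvent]:
    """Find the first sustained excursion of the plate-position signal.

    The mean and SD of ``plate_pos`` (mm) over the initial ``quiet_s``
    seconds define the quiescent baseline; the PP is the first sample
    index ``i`` such that ``|plate_pos - mean| > k_sigma*SD`` holds for
    ``min_run`` consecutive samples starting at ``i``. The SD is floored
    at ``sigma_floor`` mm.

    Returns ``None`` when no sample satisfies the rule — the
    no-perturbation outcome, a valid result for catch trials.
    """
    plate_pos = np.asarray(plate_pos, dtype=float)
    t = np.asarray(t, dtype=float)
    if plate_pos.shape != t.shape:
        raise ParameterError("plate_pos and t must have equal length")
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    fs = 1.0 / np.median(np.diff(t))
    n0 = int(round(quiet_s * fs))
    if n0 < 2 or n0 > plate_pos.size:
        raise ParameterError(
            f"need at least {quiet_s:g} s of quiescent signal for the baseline"
        )
    mu0 = plate_pos[:n0].mean()
    sig0 = max(plate_pos[:n0].std(ddof=1), sigma_floor)
    above = np.abs(plate_pos - mu0) > k_sigma * sig0
    if min_run > 1:
        run = np.convolve(above.astype(int), np.ones(min_run, dtype=int),
                          mode="valid") == min_run
    else:
        run = above
    hits = np.flatnonzero(run)
    if hits.size == 0:
        return None
    i = int(hits[0])
    return PerturbationEvent(pp_time=float(t[i]), pp_index=i,
                             source=PPSource.PLATE_SIGNAL)


def event_from_metadata(pp_time: float, sampling_rate: float,
                        t0: float = 0.0) -> PerturbationEvent:
    """Build a PP event from a declared onset time (seconds)."""
    idx = int(round((pp_time - t0) * sampling_rate))
    return PerturbationEvent(pp_time=float(pp_time), pp_index=idx,
                             source=PPSource.METADATA)


DEFAULT_POST_S = 2.5
DEFAULT_BASELINE_S = 2.5


@dataclass
class ResponseWindow:
    """Baseline-referenced CoP segment covering (PP, PP + post_s].

    ``d`` is the anterior–posterior CoP displacement relative to the
    pre-PP baseline mean, in millimetres: ``d = 10*(ap - baseline_ap)``.
    ``t_rel`` is time since the PP, so the first sample sits one sample
    interval after the PP (the PP sample itself is pre-motion and
    excluded).
    """

    t_rel: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    baseline_ap: float
    d: np.ndarray
    sampling_rate: float
    direction: Direction

    def __len__(self) -> int:
        return self.t_rel.size


def extract_window(
    cop: CoPTrajectory,
    event: PerturbationEvent,
    direction: Direction,
    post_s: float = DEFAULT_POST_S,
    baseline_s: float = DEFAULT_BASELINE_S,
) -> ResponseWindow:
    """Cut the post-PP analysis window and subtract the pre-PP baseline.

    The baseline is the mean AP CoP over ``[pp - baseline_s, pp)``; the
    window holds the samples in ``(pp, pp + post_s]``, selected by sample
    index arithmetic. Raises :class:`WindowError` if either side of the
    PP is too short.
    """
    fs = cop.sampling_rate
    n_post = int(round(post_s * fs))
    n_base = int(round(baseline_s * fs))
    i0 = event.pp_index
    n = cop.t.size
    if i0 - n_base < 0:
        raise WindowError(
            f"only {i0 / fs:.3g} s of data before the PP; "
            f"{baseline_s:g} s baseline required"
        )
    if i0 + n_post >= n:
        raise WindowError(
            f"only {(n - 1 - i0) / fs:.3g} s of data after the PP; "
            f"{post_s:g} s window required"
        )
    baseline_ap = float(cop.ap[i0 - n_base:i0].mean())
    sl = slice(i0 + 1, i0 + n_post + 1)
    ap = cop.ap[sl].copy()
    ml = cop.ml[sl].copy()
    t_rel = np.arange(1, n_post + 1) / fs
    d = 10.0 * (ap - baseline_ap)
    return ResponseWindow(
        t_rel=t_rel, ap=ap, ml=ml, baseline_ap=baseline_ap, d=d,
        sampling_rate=fs, direction=Direction(direction),
    )
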