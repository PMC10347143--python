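"""Force-plate trial I/O and center-of-pressure (CoP) computation.

A trial is a 60 s, 200 Hz recording of the six force-plate channels
(Fx, Fy, Fz, Mx, My, Mz) while a subject stands on a translatable support
surface, optionally accompanied by the plate-position channel of the linear
potentiometer. This module defines the trial containers, reads/writes them
as delimited text, and converts ground reaction forces and moments into the
CoP trajectory on the plate surface.

Coordinate convention: the plate travel axis is the anterior–posterior (AP)
axis, positive anterior (the direction the subject faces); forward (FW)
plate motion is +AP. Medio-lateral (ML) is positive toward the subject's
right. CoP is reported in centimetres.
"""
from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import signal


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CopkitError(Exception):
    """Base class for all copkit errors."""


class FormatError(CopkitError):
    """A trial file or manifest does not have the expected layout."""


class SamplingError(CopkitError):
    """The time vector is inconsistent with the declared sampling rate."""


class UnloadedPlateError(CopkitError):
    """Vertical force fell below the loading threshold; CoP is undefined."""


class ParameterError(CopkitError):
    """An analysis parameter is out of its valid range."""


# ---------------------------------------------------------------------------
# Metadata and containers
# ---------------------------------------------------------------------------

class Direction(str, enum.Enum):
    """Plate translation direction relative to the subject's facing."""

    FW = "FW"
    BW = "BW"
    NONE = "NONE"


#: Plate settings used in the perturbation protocol.
DISPLACEMENTS_MM = (25.0, 50.0, 100.0)
RAMP_RATES_MM_S = (100.0, 200.0)
DEFAULT_SAMPLING_RATE = 200.0


@dataclass(frozen=True)
class TrialMeta:
    """Per-trial metadata: who, which repetition, and the plate settings.

    ``displacement`` (mm) and ``ramp_rate`` (mm/s) must be present exactly
    when ``direction`` is FW or BW; no-perturbation trials carry neither.
    ``pp_time`` optionally records an externally known perturbation onset
    (seconds) for recordings that lack the plate-position channel.
    """

    subject_id: str
    repetition: int = 1
    direction: Direction = Direction.NONE
    displacement: Optional[float] = None
    ramp_rate: Optional[float] = None
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    plate_z_offset: float = 0.0
    pp_time: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        perturbed = self.direction is not Direction.NONE
        has_settings = self.displacement is not None and self.ramp_rate is not None
        if perturbed and not has_settings:
            raise ParameterError(
                "displacement and ramp_rate are required when direction is "
                f"{self.direction.value}"
            )
        if not perturbed and (self.displacement is not None or self.ramp_rate is not None):
            raise ParameterError(
                "displacement/ramp_rate must be absent for no-perturbation trials"
            )
        if perturbed and (self.displacement <= 0 or self.ramp_rate <= 0):
            raise ParameterError("displacement and ramp_rate must be positive")

    def to_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "repetition": self.repetition,
            "direction": self.direction.value,
            "displacement": self.displacement,
            "ramp_rate": self.ramp_rate,
            "sampling_rate": self.sampling_rate,
            "plate_z_offset": self.plate_z_offset,
        }
        if self.pp_time is not None:
            d["pp_time"] = self.pp_time
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialMeta":
        def _opt(key):
            v = d.get(key)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        return cls(
            subject_id=str(d["subject_id"]),
            repetition=int(d.get("repetition", 1)),
            direction=Direction(d.get("direction", "NONE")),
            displacement=_opt("displacement"),
            ramp_rate=_opt("ramp_rate"),
            sampling_rate=float(d.get("sampling_rate", DEFAULT_SAMPLING_RATE)),
            plate_z_offset=float(d.get("plate_z_offset", 0.0) or 0.0),
            pp_time=_opt("pp_time"),
        )


def _as_array(x, name: str, n: Optional[int] = None) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise FormatError(f"channel {name} must be one-dimensional")
    if n is not None and a.size != n:
        raise FormatError(f"channel {name} has length {a.size}, expected {n}")
    return a


# relative tolerance on the sample interval before a SamplingError is raised
_DT_RTOL = 0.01


@dataclass
class ForcePlateTrial:
    """Raw 6-channel force/moment time series plus optional plate position.

    Forces in newtons, moments in newton-metres, plate position in
    millimetres, time in seconds sampled uniformly at ``meta.sampling_rate``.
    """

    t: np.ndarray
    Fx: np.ndarray
    Fy: np.ndarray
    Fz: np.ndarray
    Mx: np.ndarray
    My: np.ndarray
    Mz: np.ndarray
    meta: TrialMeta
    plate_pos: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = _as_array(self.t, "time")
        n = self.t.size
        if n < 2:
            raise FormatError("a trial needs at least two samples")
        for name in ("Fx", "Fy", "Fz", "Mx", "My", "Mz"):
            setattr(self, name, _as_array(getattr(self, name), name, n))
        if self.plate_pos is not None:
            self.plate_pos = _as_array(self.plate_pos, "plate_pos", n)
        dt_nominal = 1.0 / self.meta.sampling_rate
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise SamplingError("time vector must be strictly increasing")
        if np.max(np.abs(dts - dt_nominal)) > _DT_RTOL * dt_nominal:
            raise SamplingError(
                "non-uniform time step: max deviation "
                f"{np.max(np.abs(dts - dt_nominal)):.3g} s exceeds 1% of "
                f"1/{self.meta.sampling_rate:g} s"
            )

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n samples at the sampling rate)."""
        return self.n_samples / self.meta.sampling_rate


@dataclass
class CoPTrajectory:
    """CoP time series on the plate surface, in centimetres."""

    t: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.t = _as_array(self.t, "time")
        self.ap = _as_array(self.ap, "ap", self.t.size)
        self.ml = _as_array(self.ml, "ml", self.t.size)
        if not (np.all(np.isfinite(self.ap)) and np.all(np.isfinite(self.ml))):
            raise FormatError("CoP channels must be finite")


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_CANONICAL = {
    "time": "time", "t": "time",
    "fx": "Fx", "fy": "Fy", "fz": "Fz",
    "mx": "Mx", "my": "My", "mz": "Mz",
    "plate_pos": "plate_pos", "platepos": "plate_pos", "plate_position": "plate_pos",
}
_REQUIRED = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")


def read_trial(path, meta: TrialMeta) -> ForcePlateTrial:
    """Read a delimited trial file (comma/tab/semicolon auto-detected).

    The header must name at least Fx,Fy,Fz,Mx,My,Mz (case-insensitive);
    a missing ``time`` column is rebuilt from ``meta.sampling_rate``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {}
    for c in df.columns:
        key = str(c).strip().lower()
        if key in _CANONICAL:
            cols[_CANONICAL[key]] = c
    missing = [name for name in _REQUIRED if name not in cols]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    n = len(df)
    if "time" in cols:
        t = df[cols["time"]].to_numpy(dtype=float)
    else:
        t = np.arange(n) / meta.sampling_rate
    kwargs = {name: df[cols[name]].to_numpy(dtype=float) for name in _REQUIRED}
    plate_pos = (
        df[cols["plate_pos"]].to_numpy(dtype=float) if "plate_pos" in cols else None
    )
    return ForcePlateTrial(t=t, meta=meta, plate_pos=plate_pos, **kwargs)


def write_trial(trial: ForcePlateTrial, path) -> None:
    """Write a trial as CSV with the canonical column names."""
    data = {"time": trial.t}
    for name in _REQUIRED:
        data[name] = getattr(trial, name)
    if trial.plate_pos is not None:
        data["plate_pos"] = trial.plate_pos
    pd.DataFrame(data).to_csv(path, index=False)


def write_meta(meta: TrialMeta, path) -> None:
    """Write a YAML/JSON metadata sidecar (format chosen by extension)."""
    path = Path(path)
    d = meta.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d))


def read_meta(path) -> TrialMeta:
    """Read a YAML or JSON metadata sidecar."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(d, dict):
        raise FormatError(f"{path}: metadata must be a mapping")
    return TrialMeta.from_dict(d)


MANIFEST_COLUMNS = (
    "file", "subject_id", "repetition", "direction",
    "displacement", "ramp_rate", "sampling_rate",
)


def read_manifest(path) -> pd.DataFrame:
    """Read a study manifest (one row per trial file, TrialMeta columns)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in ("file", "subject_id", "direction") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s): {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# CoP computation
# ---------------------------------------------------------------------------

#: minimum vertical load (N) for the CoP to be considered defined
DEFAULT_FZ_EPS = 10.0


def compute_cop(
    trial: ForcePlateTrial,
    eps: float = DEFAULT_FZ_EPS,
    moment_sign: float = 1.0,
) -> CoPTrajectory:
    """Convert forces and moments into the CoP trajectory (cm).

    Standard force-plate CoP equations with the moments referenced to a
    sensor origin a distance ``z0 = meta.plate_z_offset`` (m) below the
    plate surface::

        ap = 100 * (Mx - Fy*z0) / Fz        [cm]
        ml = 100 * (-My + Fx*z0) / Fz       [cm]

    An AMTI-style sign convention is assumed for the moments;
    ``moment_sign=-1`` flips Mx/My for plates wired the opposite way.
    Raises :class:`UnloadedPlateError` if Fz ever falls to ``eps`` or below.
    """
    fz = trial.Fz
    bad = np.flatnonzero(fz <= eps)
    if bad.size:
        raise UnloadedPlateError(
            f"Fz <= {eps:g} N at sample {bad[0]} "
            f"(Fz = {fz[bad[0]]:.3g} N): plate unloaded"
        )
    z0 = trial.meta.plate_z_offset
    mx = moment_sign * trial.Mx
    my = moment_sign * trial.My
    ap = 100.0 * (mx - trial.Fy * z0) / fz
    ml = 100.0 * (-my + trial.Fx * z0) / fz
    return CoPTrajectory(t=trial.t, ap=ap, ml=ml,
                         sampling_rate=trial.meta.sampling_rate)


DEFAULT_CUTOFF_HZ = 10.0


def lowpass(cop: CoPTrajectory, cutoff: float = DEFAULT_CUTOFF_HZ,
            order: int = 4) -> CoPTrajectory:
    """Zero-phase Butterworth low-pass filter of the CoP (new copy).

    The default 4th-order, 10 Hz filter keeps the postural band while
    removing sensor noise; effective order is doubled by the
    forward-backward pass.
    """
    nyq = cop.sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(
            f"cutoff must lie in (0, {nyq:g}) Hz, got {cutoff:g}"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=cop.sampling_rate,
                        output="sos")
    return CoPTrajectory(
        t=cop.t.copy(),
        ap=signal.sosfiltfilt(sos, cop.ap),
        ml=signal.sosfiltfilt(sos, cop.ml),
        sampling_rate=cop.sampling_rate,
    )
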