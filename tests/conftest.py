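import numpy as np
import pytest

from copkit import Direction, ForcePlateTrial, TrialMeta
from copkit.perturbation import ResponseWindow


def make_window(d_mm=None, ap_cm=None, ml_cm=None, fs=200.0,
                baseline_ap=0.0, direction=Direction.BW) -> ResponseWindow:
    """Build a ResponseWindow directly from arrays (test helper)."""
    if d_mm is not None:
        d = np.asarray(d_mm, dtype=float)
        ap = baseline_ap + d / 10.0
    else:
        ap = np.asarray(ap_cm, dtype=float)
        d = 10.0 * (ap - baseline_ap)
    ml = np.zeros_like(ap) if ml_cm is None else np.asarray(ml_cm, dtype=float)
    n = ap.size
    return ResponseWindow(
        t_rel=np.arange(1, n + 1) / fs, ap=ap, ml=ml,
        baseline_ap=baseline_ap, d=d, sampling_rate=fs,
        direction=Direction(direction),
    )


def damped_sinusoid(a=30.0, f=0.8, lam=0.9, fs=200.0, post_s=2.5):
    """Sampled d(t) = a*sin(2*pi*f*t)*exp(-lam*t) on (0, post_s], mm."""
    t = np.arange(1, int(round(post_s * fs)) + 1) / fs
    return a * np.sin(2 * np.pi * f * t) * np.exp(-lam * t)


def constant_trial(n=1200, fs=200.0, fz=600.0, mx=30.0, my=-15.0,
                   meta=None, **kwargs) -> ForcePlateTrial:
    """Trial with constant channels (test helper)."""
    if meta is None:
        meta = TrialMeta(subject_id="T", sampling_rate=fs)
    z = np.zeros(n)
    ch = dict(Fx=z, Fy=z, Fz=np.full(n, fz), Mx=np.full(n, mx),
              My=np.full(n, my), Mz=z)
    ch.update({k: np.asarray(v, dtype=float) for k, v in kwargs.items()})
    return ForcePlateTrial(t=np.arange(n) / fs, meta=meta, **ch)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
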