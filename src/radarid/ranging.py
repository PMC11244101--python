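"""Range processing: IF cube -> clutter-free range/slow-time matrix -> thorax bin.

The chain is strictly ordered and tracked by stage tags:

    raw -> dc_removed -> static_removed -> dynamic_removed

* DC removal subtracts each range bin's slow-time mean.
* Static clutter is removed by adaptive background subtraction (ABS): an
  exponentially weighted running background B[n] = lam*B[n-1] + (1-lam)*Q[n]
  (B[0] = Q[0]) is subtracted per range bin, a causal one-pole high-pass.
* Dynamic clutter is suppressed by keeping only the dominant singular triple of
  the matrix (rank-1 Eckart-Young approximation); after DC/ABS removal the
  chest echo is the dominant component, so it is what survives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .simulate import RadarCube

__all__ = [
    "RangeSlowTimeMatrix",
    "NoTargetError",
    "range_fft",
    "remove_dc",
    "remove_static_clutter",
    "remove_dynamic_clutter",
    "locate_chest",
    "preprocess_cube",
]

_STAGES = ("raw", "dc_removed", "static_removed", "dynamic_removed")


class NoTargetError(ValueError):
    """Raised when the range/slow-time matrix carries no detectable target."""


@dataclass
class RangeSlowTimeMatrix:
    """Complex [M range bins x N frames] matrix with processing-stage tag."""

    values: np.ndarray
    range_resolution: float
    frame_rate: float
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be [M x N]")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values")

    def _require(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(f"expected stage {stage!r}, got {self.stage!r} "
                             "(pipeline order raw -> dc_removed -> static_removed "
                             "-> dynamic_removed)")


def range_fft(cube: RadarCube, chirp: int = 0) -> RangeSlowTimeMatrix:
    """Unwindowed, unpadded fast-time FFT of one chirp per frame.

    Column n of the result is frame n's range profile; bin index k maps to
    range k*c/(2B).
    """
    if cube.samples.size == 0:
        raise ValueError("empty cube")
    fast = cube.samples[:, chirp, :]                      # [N frames x M samples]
    profiles = np.fft.fft(fast, axis=1)                   # length M, no window
    return RangeSlowTimeMatrix(profiles.T.copy(), cube.config.range_resolution,
                               cube.config.frame_rate, stage="raw")


def remove_dc(m: RangeSlowTimeMatrix) -> RangeSlowTimeMatrix:
    """Subtract each range bin's slow-time mean (DC bias elimination)."""
    m._require("raw")
    if m.values.shape[1] == 0:
        raise ValueError("no frames")
    out = m.values - m.values.mean(axis=1, keepdims=True)
    return replace(m, values=out, stage="dc_removed")


def remove_static_clutter(m: RangeSlowTimeMatrix, lam: float = 0.9) -> RangeSlowTimeMatrix:
    """Adaptive background subtraction with weight ``lam`` in (0, 1).

    Per range bin m: B[m,0] = Q[m,0]; B[m,n] = lam*B[m,n-1] + (1-lam)*Q[m,n];
    output is Q - B.  Causal: frame n depends only on frames <= n.
    """
    m._require("dc_removed")
    if not (0.0 < lam < 1.0):
        raise ValueError("lambda must lie in (0, 1)")
    q = m.values
    # One-pole recursion via lfilter; zi chosen so that B[:, 0] == Q[:, 0].
    zi = (lam * q[:, 0])[:, None]
    bg, _ = scipy.signal.lfilter([1.0 - lam], [1.0, -lam], q, axis=1, zi=zi)
    return replace(m, values=q - bg, stage="static_removed")


def remove_dynamic_clutter(m: RangeSlowTimeMatrix) -> RangeSlowTimeMatrix:
    """Best rank-1 approximation: keep the largest singular triple only."""
    m._require("static_removed")
    u, s, vh = np.linalg.svd(m.values, full_matrices=False)
    out = s[0] * np.outer(u[:, 0], vh[0, :])
    return replace(m, values=out, stage="dynamic_removed")


def locate_chest(m: RangeSlowTimeMatrix) -> int:
    """Range bin maximizing the slow-time sum of |Q|; ties -> smaller index."""
    m._require("dynamic_removed")
    power = np.abs(m.values).sum(axis=1)
    if not np.any(power > 0):
        raise NoTargetError("all-zero matrix: no target present")
    return int(np.argmax(power))   # np.argmax returns the first (smallest) index


def preprocess_cube(cube: RadarCube, lam: float = 0.9) -> tuple[RangeSlowTimeMatrix, int]:
    """Full chain: FFT -> DC -> ABS -> SVD; returns the matrix and thorax bin."""
    m = remove_dynamic_clutter(
        remove_static_clutter(remove_dc(range_fft(cube)), lam=lam))
    return m, locate_chest(m)
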