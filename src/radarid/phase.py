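"""Interferometric phase extraction around the thoracic range bin.

A block of K adjacent range bins centered on the located thorax bin is kept as
parallel rows (the chest is an extended target whose echo spreads over
neighboring bins).  Each complex row is converted to its four-quadrant angle,
unwrapped along slow time, and first-order differenced; the differenced phase
is the raw vital-sign signal handed to modal separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .ranging import RangeSlowTimeMatrix

__all__ = ["PhaseMatrix", "select_bins", "extract_phase", "unwrap_phase",
           "diff_phase", "phase_from_matrix"]

_PHASE_STAGES = ("wrapped", "unwrapped", "differenced")


@dataclass
class PhaseMatrix:
    """Real [K bins x T frames] phase matrix (radians) with stage tag."""

    values: np.ndarray
    center_bin: int
    frame_rate: float
    stage: str = "wrapped"

    def __post_init__(self) -> None:
        if self.stage not in _PHASE_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be [K x T]")

    def _require(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(f"expected stage {stage!r}, got {self.stage!r}")


def select_bins(m: RangeSlowTimeMatrix, index: int, k: int = 7) -> np.ndarray:
    """K adjacent rows centered on ``index``; edge windows shift inward.

    k must be odd so the window is symmetric around the thorax bin.
    """
    n_rows = m.values.shape[0]
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd count")
    if k > n_rows:
        raise ValueError(f"k={k} exceeds matrix rows M={n_rows}")
    half = (k - 1) // 2
    lo = min(max(index - half, 0), n_rows - k)
    return m.values[lo:lo + k, :]


def extract_phase(sub: np.ndarray, frame_rate: float = 50.0,
                  center_bin: int = 0) -> PhaseMatrix:
    """Element-wise four-quadrant angle of I/R, in (-pi, pi].

    Zero-magnitude samples carry no phase; they are flagged and the previous
    frame's phase is carried forward (0 for a zero first frame).
    """
    sub = np.asarray(sub)
    ang = np.angle(sub)
    # np.angle returns values in (-pi, pi]; map -pi (if produced by rounding) up.
    ang = np.where(ang <= -np.pi, np.pi, ang)
    dead = np.abs(sub) == 0
    if dead.any():
        warnings.warn("zero-magnitude samples: phase carried forward",
                      RuntimeWarning, stacklevel=2)
        ang = ang.copy()
        for i, j in zip(*np.nonzero(dead)):
            ang[i, j] = ang[i, j - 1] if j > 0 else 0.0
    return PhaseMatrix(ang, center_bin, frame_rate, stage="wrapped")


def unwrap_phase(p: PhaseMatrix) -> PhaseMatrix:
    """Per row, add 2*pi multiples so successive differences stay in (-pi, pi]."""
    p._require("wrapped")
    return replace(p, values=np.unwrap(p.values, axis=1), stage="unwrapped")


def diff_phase(p: PhaseMatrix) -> PhaseMatrix:
    """First-order forward difference per row: out[t] = phi[t+1] - phi[t]."""
    p._require("unwrapped")
    if p.values.shape[1] < 2:
        raise ValueError("need at least 2 frames to difference")
    return replace(p, values=np.diff(p.values, axis=1), stage="differenced")


def phase_from_matrix(m: RangeSlowTimeMatrix, index: int, k: int = 7) -> PhaseMatrix:
    """Convenience: select K bins, extract, unwrap and difference the phase."""
    sub = select_bins(m, index, k)
    return diff_phase(unwrap_phase(extract_phase(sub, m.frame_rate, index)))
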