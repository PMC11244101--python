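"""Modal separation, normalization, and sliding-window segmentation.

The differenced phase matrix is split into three modalities:

* respiration — zero-phase 2nd-order Butterworth bandpass, 0.15-0.4 Hz;
* heartbeat   — zero-phase 2nd-order Butterworth bandpass, 0.8-1.5 Hz;
* phase       — the unfiltered differenced phase itself (it keeps the harmonic
  and intermodulation content the bandpass filters discard).

Each modality is cut into sliding windows (default 10.24 s / 512 frames, step
1 s) and z-scored per window, per modality, per range bin, so every training
sample is scale-free regardless of record-level drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .phase import PhaseMatrix

__all__ = ["ModalWindowSet", "BREATH_BAND", "HEART_BAND", "separate_modalities",
           "zscore", "slide_windows", "n_windows", "butter_bandpass_sos",
           "estimate_rates"]

BREATH_BAND = (0.15, 0.4)   # Hz
HEART_BAND = (0.8, 1.5)     # Hz
MODALITIES = ("respiration", "heartbeat", "phase")


@dataclass
class ModalWindowSet:
    """Windows [W x 3 modalities x K bins x L frames] plus per-window labels."""

    windows: np.ndarray
    labels: np.ndarray            # subject label per window
    record_ids: np.ndarray        # source record per window
    window_length: int
    step: int
    modality_order: tuple[str, str, str] = MODALITIES

    def __post_init__(self) -> None:
        if self.windows.ndim != 4 or self.windows.shape[1] != 3:
            raise ValueError("windows must be [W x 3 x K x L]")
        if len(self.labels) != len(self.windows) or len(self.record_ids) != len(self.windows):
            raise ValueError("labels/record_ids must match window count")

    @staticmethod
    def concatenate(sets: list["ModalWindowSet"]) -> "ModalWindowSet":
        first = sets[0]
        return ModalWindowSet(
            np.concatenate([s.windows for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.record_ids for s in sets]),
            first.window_length, first.step, first.modality_order)


def butter_bandpass_sos(band: tuple[float, float], fs: float, order: int = 2):
    """2nd-order (prototype) Butterworth bandpass in SOS form."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz >= Nyquist {fs / 2} Hz")
    return scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def separate_modalities(p: PhaseMatrix, fs: float | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(respiration, heartbeat, phase) matrices, each [K x T].

    Filtering is zero-phase (forward-backward) per bin row so the three
    modalities stay time-aligned; the phase modality is passed through
    untouched.
    """
    p._require("differenced")
    fs = p.frame_rate if fs is None else fs
    if fs <= 3.0:
        raise ValueError("frame rate must exceed 3 Hz (Nyquist above 1.5 Hz)")
    x = np.asarray(p.values, dtype=float)
    resp = scipy.signal.sosfiltfilt(butter_bandpass_sos(BREATH_BAND, fs), x, axis=1)
    heart = scipy.signal.sosfiltfilt(butter_bandpass_sos(HEART_BAND, fs), x, axis=1)
    return resp, heart, x.copy()


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Z-score with population (divide-by-n) standard deviation.

    Constant input has no scale; it maps to zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    # rounding can leave a ~1e-16 std on a constant row; treat that as zero
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    if degenerate.any():
        warnings.warn("degenerate (constant) window row: z-score set to zeros",
                      RuntimeWarning, stacklevel=2)
    return np.where(degenerate, 0.0, (x - mu) / np.where(degenerate, 1.0, sd))


def estimate_rates(resp: np.ndarray, heart: np.ndarray, fs: float,
                   nfft: int = 1 << 16, harmonic_guard: float = 0.04
                   ) -> tuple[float, float]:
    """Validation utility: spectral-peak breath and heart rates [Hz].

    The breath rate is the in-band peak of the respiration channel.  For the
    heart rate, bins within ``harmonic_guard`` Hz of respiration harmonics
    (k*f_b, k >= 2) are excluded before taking the in-band peak — respiration
    harmonics of the differenced phase commonly out-power the sub-mm cardiac
    line inside 0.8-1.5 Hz, and masking them is the standard remedy.
    """
    f = np.fft.rfftfreq(nfft, d=1.0 / fs)
    spec_r = np.abs(np.fft.rfft(np.asarray(resp, dtype=float), n=nfft))
    in_b = (f >= BREATH_BAND[0]) & (f <= BREATH_BAND[1])
    f_b = float(f[in_b][spec_r[in_b].argmax()])

    spec_h = np.abs(np.fft.rfft(np.asarray(heart, dtype=float), n=nfft))
    in_h = (f >= HEART_BAND[0]) & (f <= HEART_BAND[1])
    # Only low-order harmonics (k <= 4) carry enough power to compete with
    # the cardiac line; masking higher orders would needlessly blank the band.
    keep = in_h.copy()
    for k in range(2, 5):
        keep &= np.abs(f - k * f_b) > harmonic_guard
    if not keep.any():          # degenerate: harmonics blanket the whole band
        keep = in_h
    f_h = float(f[keep][spec_h[keep].argmax()])
    return f_b, f_h


def n_windows(t: int, length: int, step: int) -> int:
    """Number of sliding windows: floor((T - L)/S) + 1 (requires T >= L)."""
    if length < 1 or step < 1:
        raise ValueError("window length and step must be >= 1")
    if t < length:
        raise ValueError(f"record length {t} shorter than window {length}")
    return (t - length) // step + 1


def slide_windows(modalities: tuple[np.ndarray, np.ndarray, np.ndarray],
                  length: int, step: int, label: str, record_id: str
                  ) -> ModalWindowSet | None:
    """Cut one record's three [K x T] modalities into normalized windows.

    Returns None (with a warning) when the record is shorter than one window.
    Each emitted window row is z-scored after windowing.
    """
    stack = np.stack(modalities)                 # [3 x K x T]
    t = stack.shape[-1]
    if t < length:
        warnings.warn(f"record {record_id!r}: T={t} < L={length}, skipped",
                      RuntimeWarning, stacklevel=2)
        return None
    w = n_windows(t, length, step)
    starts = np.arange(w) * step
    windows = np.empty((w, 3, stack.shape[1], length), dtype=np.float32)
    for i, s in enumerate(starts):
        windows[i] = zscore(stack[:, :, s:s + length], axis=-1)
    return ModalWindowSet(windows, np.repeat(label, w), np.repeat(record_id, w),
                          length, step)
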