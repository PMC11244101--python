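"""Physics-based FMCW vital-sign radar simulator.

Generates labeled intermediate-frequency (IF) data cubes whose slow-time phase
encodes per-subject chest displacement (respiration + heartbeat), together with
the nuisance terms the downstream pipeline must remove: DC bias, static
reflectors, a slowly wandering dynamic-clutter target, oscillator phase noise
and thermal noise.

Signal model
------------
A point target at range ``R`` produces, at fast-time sample ``n`` of a chirp,

    a * exp(j * (2*pi * k_R * n / N  +  4*pi * R(t) / lambda_c))

with ``k_R = 2*B*R0/c`` the beat-frequency bin index, ``N`` the number of ADC
samples and ``lambda_c = c/fc`` the carrier wavelength.  The chest displacement
``d(t)`` modulates only the carrier-phase term (``R(t) = R0 + d(t)``): the beat
frequency is held at the nominal range ``R0`` because mm-scale displacement is
far below the range resolution ``c/(2B)`` (~3.8 cm), the usual stop-and-hop
assumption.  This makes the slow-time phase at the target's range bin exactly
``4*pi*(R0 + d(t))/lambda_c`` in the noise-free case.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

C_LIGHT = 299_792_458.0

__all__ = [
    "C_LIGHT",
    "RadarConfig",
    "SubjectProfile",
    "SceneConfig",
    "RadarCube",
    "chest_displacement",
    "synthesize_cube",
    "generate_cohort",
    "iter_cohort",
    "draw_profiles",
    "save_cube",
    "load_cube",
]


@dataclass(frozen=True)
class RadarConfig:
    """FMCW front-end geometry (77 GHz automotive-band radar defaults)."""

    carrier_frequency: float = 77e9     # fc [Hz]
    bandwidth: float = 3.99e9           # B [Hz]
    chirp_duration: float = 60e-6       # Tc [s]; bin<->range mapping is Tc-invariant
    adc_samples_per_chirp: int = 256
    chirps_per_frame: int = 1
    frame_period: float = 0.02          # [s] -> 50 Hz slow-time rate
    n_frames: int = 3000                # one-minute record at 50 Hz
    tx_amplitude: float = 1.0
    if_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.bandwidth <= 0 or self.carrier_frequency <= self.bandwidth:
            raise ValueError("require fc > B > 0")
        if self.adc_samples_per_chirp < 2:
            raise ValueError("adc_samples_per_chirp must be >= 2")
        if self.chirps_per_frame < 1 or self.n_frames < 1:
            raise ValueError("chirps_per_frame and n_frames must be >= 1")
        if self.frame_period <= 0 or self.chirp_duration <= 0:
            raise ValueError("frame_period and chirp_duration must be positive")

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_period

    @property
    def wavelength(self) -> float:
        return C_LIGHT / self.carrier_frequency

    @property
    def range_resolution(self) -> float:
        """Range-bin width c/(2B) [m]."""
        return C_LIGHT / (2.0 * self.bandwidth)

    @property
    def max_range(self) -> float:
        """Unambiguous range spanned by the fast-time FFT [m]."""
        return self.adc_samples_per_chirp * self.range_resolution

    def range_to_bin(self, r: float) -> float:
        """Fractional range-bin index k = 2*B*r/c."""
        return r / self.range_resolution


@dataclass(frozen=True)
class SubjectProfile:
    """Kinematic identity of one subject's chest motion.

    Respiration is a unit-amplitude asymmetric periodic waveform scaled by
    ``breath_amplitude``; the heartbeat is a harmonic series (fundamental plus
    overtones) scaled by ``heart_amplitude``.  ``breath_waveform_shape`` in
    [0, 1] skews the inhale/exhale durations (0 = pure sinusoid).
    ``phase_offsets[0]`` is the respiration phase; the remaining entries phase
    the heartbeat harmonics.
    """

    subject_id: str
    nominal_range: float = 1.0          # R0 [m]; subjects sit ~1 m from the radar
    breath_rate: float = 0.25           # f_b [Hz]
    breath_amplitude: float = 2e-3      # A_b [m]
    breath_waveform_shape: float = 0.0
    heart_rate: float = 1.1             # f_h [Hz]
    heart_amplitude: float = 1e-4       # A_h [m]
    heart_harmonic_weights: tuple[float, ...] = (1.0, 0.4, 0.15)
    phase_offsets: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vals = [self.nominal_range, self.breath_rate, self.breath_amplitude,
                self.breath_waveform_shape, self.heart_rate, self.heart_amplitude,
                *self.heart_harmonic_weights, *self.phase_offsets]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("subject profile parameters must be finite")
        if not (0.15 <= self.breath_rate <= 0.4):
            raise ValueError("breath_rate must lie in the 0.15-0.4 Hz band")
        if not (0.8 <= self.heart_rate <= 1.5):
            raise ValueError("heart_rate must lie in the 0.8-1.5 Hz band")
        if not (self.breath_amplitude > self.heart_amplitude >= 0):
            raise ValueError("require A_b > A_h >= 0")
        if self.nominal_range <= 0:
            raise ValueError("nominal_range must be positive")
        if not (0.0 <= self.breath_waveform_shape <= 1.0):
            raise ValueError("breath_waveform_shape must lie in [0, 1]")


@dataclass(frozen=True)
class SceneConfig:
    """Environment nuisances injected into every frame."""

    dc_bias: complex = 0j
    static_reflectors: tuple[tuple[float, float], ...] = ()   # (range m, amplitude)
    dynamic_clutter: tuple[float, float, float] | None = None  # (range m, amplitude, step std m)
    phase_noise_std: float = 0.0        # [rad], per frame, common to all echoes
    thermal_noise_std: float = 0.0      # per-sample complex noise std
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_noise_std < 0 or self.thermal_noise_std < 0:
            raise ValueError("noise std values must be >= 0")
        if self.dynamic_clutter is not None and self.dynamic_clutter[2] < 0:
            raise ValueError("dynamic clutter step std must be >= 0")


@dataclass
class RadarCube:
    """Complex IF samples [n_frames x chirps_per_frame x adc_samples_per_chirp]."""

    samples: np.ndarray
    config: RadarConfig
    subject_id: str
    record_id: str

    def __post_init__(self) -> None:
        expect = (self.config.n_frames, self.config.chirps_per_frame,
                  self.config.adc_samples_per_chirp)
        if self.samples.shape != expect:
            raise ValueError(f"cube shape {self.samples.shape} != config shape {expect}")
        if not np.isfinite(self.samples).all():
            raise ValueError("cube contains non-finite samples")


def _breath_waveform(phase_cycles: np.ndarray, shape: float) -> np.ndarray:
    """Unit-amplitude periodic breath waveform with inhale/exhale asymmetry.

    A smoothly time-warped sine, sin(2*pi*u + shape/2 * sin(2*pi*u)): the warp
    skews inhale vs exhale duration while keeping the waveform C-infinity, so
    its harmonics fall off fast — real breathing is smooth, and its harmonic
    ladder must not bury the sub-mm heartbeat line in the 0.8-1.5 Hz band.
    ``shape=0`` reduces to sin(2*pi*u).
    """
    theta = 2.0 * np.pi * np.mod(phase_cycles, 1.0)
    return np.sin(theta + 0.5 * shape * np.sin(theta))


def chest_displacement(profile: SubjectProfile, t: np.ndarray) -> np.ndarray:
    """Chest displacement d(t) [m] on a monotonically increasing time grid [s]."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t must be a 1-D monotonically increasing grid")
    off = np.asarray(profile.phase_offsets, dtype=float)
    breath = profile.breath_amplitude * _breath_waveform(
        profile.breath_rate * t + off[0] / (2.0 * np.pi), profile.breath_waveform_shape
    )
    heart = np.zeros_like(t)
    for k, w in enumerate(profile.heart_harmonic_weights, start=1):
        phi = off[k] if k < off.size else 0.0
        heart += w * np.sin(2.0 * np.pi * k * profile.heart_rate * t + phi)
    return breath + profile.heart_amplitude * heart


def synthesize_cube(
    profile: SubjectProfile,
    scene: SceneConfig,
    config: RadarConfig,
    record_id: str = "rec0",
) -> RadarCube:
    """Render one labeled IF data cube (seeded, bit-reproducible)."""
    rng = np.random.default_rng(scene.rng_seed)
    n_adc = config.adc_samples_per_chirp
    n_fr = config.n_frames
    lam = config.wavelength

    for r in [profile.nominal_range] + [r for r, _ in scene.static_reflectors] + (
        [scene.dynamic_clutter[0]] if scene.dynamic_clutter else []
    ):
        if not (0 < r < config.max_range):
            raise ValueError(f"target range {r} m outside unambiguous range "
                             f"(0, {config.max_range:.2f}) m")

    t_f = np.arange(n_fr) * config.frame_period
    n = np.arange(n_adc)

    # Per-frame common oscillator phase noise on reflected echoes.
    dphi = (rng.normal(0.0, scene.phase_noise_std, n_fr)
            if scene.phase_noise_std > 0 else np.zeros(n_fr))

    def echo(amp: float, r_beat: float, r_phase: np.ndarray) -> np.ndarray:
        k_r = config.range_to_bin(r_beat)
        fast = np.exp(2j * np.pi * k_r * n / n_adc)                      # [n_adc]
        slow = amp * np.exp(1j * (4.0 * np.pi * r_phase / lam + dphi))   # [n_fr]
        return slow[:, None] * fast[None, :]

    d = chest_displacement(profile, t_f)
    frame = echo(config.if_amplitude, profile.nominal_range, profile.nominal_range + d)
    for r, a in scene.static_reflectors:
        frame += echo(a, r, np.full(n_fr, r))
    if scene.dynamic_clutter is not None:
        r0, a, step = scene.dynamic_clutter
        walk = r0 + np.cumsum(rng.normal(0.0, step, n_fr)) if step > 0 else np.full(n_fr, r0)
        frame += echo(a, r0, walk)
    frame += scene.dc_bias
    if scene.thermal_noise_std > 0:
        frame += (rng.normal(0.0, scene.thermal_noise_std, (n_fr, n_adc))
                  + 1j * rng.normal(0.0, scene.thermal_noise_std, (n_fr, n_adc)))

    # One virtual channel replicated across the chirps_per_frame axis.
    # complex128 in memory keeps sub-microradian phase fidelity; the on-disk
    # container is complex64.
    samples = np.repeat(frame[:, None, :], config.chirps_per_frame, axis=1)
    return RadarCube(samples, config, profile.subject_id, record_id)


# ---------------------------------------------------------------------------
# Cohort generation

_DEFAULT_SCENE = SceneConfig(
    dc_bias=5.0 + 5.0j,
    static_reflectors=((0.45, 2.0), (2.2, 1.5)),
    dynamic_clutter=(1.6, 0.3, 1e-4),
    phase_noise_std=0.05,
    thermal_noise_std=0.1,
)


def draw_profiles(n_subjects: int, rng: np.random.Generator,
                  subject_ids: Sequence[str] | None = None) -> list[SubjectProfile]:
    """Draw per-subject kinematic profiles spanning realistic adult ranges."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if subject_ids is None:
        subject_ids = [f"S{i:02d}" for i in range(n_subjects)]
    if len(set(subject_ids)) != len(subject_ids) or len(subject_ids) != n_subjects:
        raise ValueError("subject labels must be unique, one per subject")
    profiles = []
    for sid in subject_ids:
        profiles.append(SubjectProfile(
            subject_id=sid,
            nominal_range=1.0,
            breath_rate=float(rng.uniform(0.18, 0.38)),
            breath_amplitude=float(rng.uniform(1e-3, 3e-3)),
            breath_waveform_shape=float(rng.uniform(0.0, 1.0)),
            heart_rate=float(rng.uniform(0.85, 1.45)),
            heart_amplitude=float(rng.uniform(1e-4, 3e-4)),
            heart_harmonic_weights=(1.0, float(rng.uniform(0.25, 0.55)),
                                    float(rng.uniform(0.05, 0.25))),
            phase_offsets=tuple(rng.uniform(0.0, 2.0 * np.pi, 4)),
        ))
    return profiles


def _jitter_profile(p: SubjectProfile, rng: np.random.Generator) -> SubjectProfile:
    """Within-subject record-to-record variation: rates drift, amplitudes fixed."""
    return SubjectProfile(
        subject_id=p.subject_id,
        nominal_range=float(np.clip(p.nominal_range + rng.uniform(-0.02, 0.02), 0.1, None)),
        breath_rate=float(np.clip(p.breath_rate + rng.normal(0.0, 0.01), 0.15, 0.4)),
        breath_amplitude=p.breath_amplitude,
        breath_waveform_shape=p.breath_waveform_shape,
        heart_rate=float(np.clip(p.heart_rate + rng.normal(0.0, 0.02), 0.8, 1.5)),
        heart_amplitude=p.heart_amplitude,
        heart_harmonic_weights=p.heart_harmonic_weights,
        phase_offsets=tuple(rng.uniform(0.0, 2.0 * np.pi, 4)),
    )


def iter_cohort(
    n_subjects: int,
    records_per_subject: int = 20,
    config: RadarConfig = RadarConfig(),
    scene: SceneConfig = _DEFAULT_SCENE,
    master_seed: int = 0,
    subject_ids: Sequence[str] | None = None,
) -> Iterator[RadarCube]:
    """Yield labeled cubes one at a time (memory-friendly for long cohorts)."""
    rng = np.random.default_rng(master_seed)
    profiles = draw_profiles(n_subjects, rng, subject_ids)
    for prof in profiles:
        for rec in range(records_per_subject):
            jp = _jitter_profile(prof, rng)
            seed = int(rng.integers(0, 2**31 - 1))
            rec_scene = SceneConfig(**{**asdict(scene), "rng_seed": seed})
            yield synthesize_cube(jp, rec_scene, config,
                                  record_id=f"{prof.subject_id}_r{rec:02d}")


def generate_cohort(
    n_subjects: int,
    records_per_subject: int = 20,
    config: RadarConfig = RadarConfig(),
    scene: SceneConfig = _DEFAULT_SCENE,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    subject_ids: Sequence[str] | None = None,
) -> tuple[list[RadarCube] | None, pd.DataFrame]:
    """Generate a labeled cohort and its manifest.

    With ``out_dir`` set, cubes are written to disk (``.bin`` + JSON sidecar)
    and only the manifest is returned; otherwise cubes are kept in memory.
    """
    rows = []
    cubes: list[RadarCube] | None = None if out_dir is not None else []
    for cube in iter_cohort(n_subjects, records_per_subject, config, scene,
                            master_seed, subject_ids):
        path = ""
        if out_dir is not None:
            path = str(Path(out_dir) / f"{cube.record_id}.bin")
            save_cube(cube, path)
        else:
            cubes.append(cube)
        rows.append({"record_id": cube.record_id, "subject_id": cube.subject_id,
                     "path": path, "split": ""})
    manifest = pd.DataFrame(rows, columns=["record_id", "subject_id", "path", "split"])
    return cubes, manifest


# ---------------------------------------------------------------------------
# Raw container I/O: little-endian complex64 + JSON sidecar

def save_cube(cube: RadarCube, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cube.samples.astype("<c8").tofile(path)
    sidecar = {
        "dims": list(cube.samples.shape),
        "dtype": "<c8",
        "config": asdict(cube.config),
        "subject_id": cube.subject_id,
        "record_id": cube.record_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_cube(path: str | Path) -> RadarCube:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = RadarConfig(**meta["config"])
    samples = np.fromfile(path, dtype="<c8").reshape(meta["dims"])
    return RadarCube(samples, config, meta["subject_id"], meta["record_id"])
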