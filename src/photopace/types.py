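"""Core containers for the muscular-thin-film (MTF) analysis pipelines.

Everything is SI internally: metres, seconds, pascals.  Reporting layers
(CLI, analysis drivers) convert to kPa, cm/s and degrees where that is the
conventional unit of the assay.

The containers are thin, validated dataclasses rather than behaviour-rich
objects; the pipelines in :mod:`photopace.contractility`,
:mod:`photopace.optical_mapping` and friends operate on them functionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "StressTrace",
    "MechanicalSpec",
    "Movie",
    "StimulusTrain",
    "ActivationField",
    "OrientationSet",
    "ActivationMap",
    "VelocityField",
    "WavefrontReport",
    "TwitchSummary",
    "ComparisonResult",
    "OrientationSummary",
    "ProtocolSchedule",
    "ProtocolBlock",
    "RosResult",
]


def _as_float_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return a


@dataclass(frozen=True)
class StressTrace:
    """Time course of film stress σ(t) on a uniform frame grid.

    Attributes
    ----------
    times : ndarray, seconds
        Strictly increasing uniform grid with step ``1/frame_rate``.
    stress : ndarray, Pa
        Film stress at each time; finite and non-negative.
    frame_rate : float, Hz
    """

    times: np.ndarray
    stress: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        stress = _as_float_array(self.stress, "stress")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "stress", stress)
        if times.size != stress.size:
            raise ValueError("times and stress must have equal length")
        if times.size < 2:
            raise ValueError("a stress trace needs at least two samples")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.frame_rate, rtol=1e-6, atol=0):
            raise ValueError("times must be uniform with step 1/frame_rate")
        if not np.all(np.isfinite(stress)) or np.any(stress < 0):
            raise ValueError("stress must be finite and non-negative")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0] + 1.0 / self.frame_rate)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class MechanicalSpec:
    """Cantilever and substrate mechanics entering the Stoney relation.

    The film stress of a bilayer cantilever of gel substrate (modulus ``E_s``,
    thickness ``h_s``, Poisson ratio ``ν_s``) carrying a thin contractile
    tissue layer (thickness ``h_f``) follows from its curvature κ as

        σ = C · E_s · h_s² · κ / (6 · h_f · (1 − ν_s))

    ``correction_factor_C`` is a pluggable multiplicative correction for
    finite film/substrate thickness ratio; ``C = 1`` is the classical Stoney
    thin-film limit.
    """

    free_length_L: float = 3.0e-3
    width: float = 4.0e-3
    substrate_modulus_Es: float = 15.0e3
    substrate_poisson_nu: float = 0.5
    substrate_thickness_hs: float = 100.0e-6
    film_thickness_hf: float = 5.0e-6
    correction_factor_C: float = 1.0

    def __post_init__(self) -> None:
        for name in ("free_length_L", "width", "substrate_thickness_hs", "film_thickness_hf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.substrate_modulus_Es <= 0:
            raise ValueError("substrate_modulus_Es must be positive")
        # nu = 0.5 allowed: incompressible gel.
        if not (0.0 <= self.substrate_poisson_nu <= 0.5 + 1e-9):
            raise ValueError("substrate_poisson_nu must lie in [0, 0.5]")
        if self.correction_factor_C <= 0:
            raise ValueError("correction_factor_C must be positive")

    @property
    def stress_per_curvature(self) -> float:
        """dσ/dκ in Pa·m — the (linear) Stoney slope."""
        return (
            self.correction_factor_C
            * self.substrate_modulus_Es
            * self.substrate_thickness_hs**2
            / (6.0 * self.film_thickness_hf * (1.0 - self.substrate_poisson_nu))
        )


MovieKind = Literal["binary_mask", "fluorescence"]


@dataclass(frozen=True)
class Movie:
    """A time-lapse stack: ``frames`` is (time, rows, cols).

    ``kind`` distinguishes thresholded cantilever silhouettes
    (``binary_mask``, values in {0, 1}) from graded calcium fluorescence.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float
    kind: MovieKind = "fluorescence"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) stack")
        if frames.shape[0] < 2:
            raise ValueError("a movie needs at least two frames")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be positive")
        if self.kind not in ("binary_mask", "fluorescence"):
            raise ValueError(f"unknown movie kind {self.kind!r}")
        if self.kind == "binary_mask":
            vals = np.unique(frames)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary_mask frames must contain only {0, 1}")
        elif np.any(np.asarray(frames, dtype=float) < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class StimulusTrain:
    """Periodic light-pulse train: frequency f, duty cycle d, pulse width d/f."""

    frequency_f: float
    duty_cycle_d: float
    duration: float
    irradiance: float = 60.0  # mW/cm^2
    pulse_onsets: np.ndarray = field(init=False)
    pulse_width: float = field(init=False)

    def __post_init__(self) -> None:
        if self.frequency_f <= 0:
            raise ValueError("frequency must be positive")
        if not (0.0 < self.duty_cycle_d < 1.0):
            raise ValueError(
                "duty cycle must lie strictly in (0, 1); continuous light is not a train"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        n = int(math.floor(self.duration * self.frequency_f + 1e-12))
        onsets = np.arange(n, dtype=float) / self.frequency_f
        object.__setattr__(self, "pulse_onsets", onsets)
        object.__setattr__(self, "pulse_width", self.duty_cycle_d / self.frequency_f)

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_onsets.size)

    @property
    def cumulative_on_time(self) -> float:
        return self.n_pulses * self.pulse_width


@dataclass(frozen=True)
class ActivationField:
    """Ground-truth per-pixel activation time for one propagating beat."""

    T: np.ndarray
    source_kind: Literal["edge", "point"]
    source_location: tuple[int, int]
    speed_v: float
    pixel_size: float
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        object.__setattr__(self, "T", T)
        if T.ndim != 2:
            raise ValueError("T must be a 2-D field")
        mask = self.mask
        mask = np.ones(T.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
        object.__setattr__(self, "mask", mask)
        if self.speed_v <= 0:
            raise ValueError("speed_v must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(T[mask] < 0):
            raise ValueError("activation times must be non-negative on the mask")
        if not np.isclose(T[mask].min(), 0.0, atol=1e-12):
            raise ValueError("the source (T = 0) must lie on the mask")


@dataclass(frozen=True)
class OrientationSet:
    """Axial (180°-periodic) angles, canonicalized to [−90°, 90°) relative
    to the micro-molded pattern direction."""

    angles: np.ndarray
    pattern_direction: float = 0.0

    def __post_init__(self) -> None:
        angles = _as_float_array(self.angles, "angles")
        object.__setattr__(self, "angles", angles)
        if angles.size < 1:
            raise ValueError("need at least one angle")
        if np.any(angles < -90.0) or np.any(angles >= 90.0):
            raise ValueError("angles must be canonicalized to [-90, 90)")

    @property
    def n(self) -> int:
        return int(self.angles.size)


@dataclass(frozen=True)
class ActivationMap:
    """Measured per-pixel activation times for one beat, with validity mask."""

    T: np.ndarray
    valid: np.ndarray
    frame_rate: float
    pixel_size: float
    beat_index: int = 0
    method: Literal["half_amplitude", "max_derivative"] = "half_amplitude"

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "valid", valid)
        if T.shape != valid.shape or T.ndim != 2:
            raise ValueError("T and valid must be matching 2-D arrays")
        if not np.all(np.isfinite(T[valid])):
            raise ValueError("activation times must be finite on valid pixels")


@dataclass(frozen=True)
class VelocityField:
    """Per-pixel conduction velocity derived from an activation map."""

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    valid: np.ndarray
    mean_speed: float
    median_speed: float

    def __post_init__(self) -> None:
        if not (self.vx.shape == self.vy.shape == self.speed.shape == self.valid.shape):
            raise ValueError("velocity component shapes must match")


@dataclass(frozen=True)
class WavefrontReport:
    """Origin count and classification of propagating wavefronts."""

    n_origins: int
    n_fronts: int
    origin_columns: tuple[int, ...]
    classification: Literal["edge_wave", "point_source_double_wave", "multiple_sources"]
    profile: np.ndarray


@dataclass(frozen=True)
class TwitchSummary:
    """Per-cantilever contraction statistics from one stress trace."""

    diastolic_stress: float
    systolic_stress: float
    twitch_stress: float
    contraction_frequency: float
    n_beats: int
    per_beat_table: tuple[tuple[float, float, float], ...]  # (peak_time, peak, baseline)

    def __post_init__(self) -> None:
        if self.n_beats != len(self.per_beat_table):
            raise ValueError("n_beats must equal the per-beat table length")
        if not math.isclose(
            self.twitch_stress,
            self.systolic_stress - self.diastolic_stress,
            rel_tol=1e-9,
            abs_tol=1e-9,
        ):
            raise ValueError("twitch stress must equal systolic - diastolic")
        if self.contraction_frequency < 0:
            raise ValueError("frequency must be non-negative")
        if self.n_beats < 2 and self.contraction_frequency != 0.0:
            raise ValueError("frequency is defined only with >= 2 beats")


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison (Student's or Welch's t), mean ± s.e.m. style."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    variant: Literal["student", "welch"] = "welch"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def stars(self) -> str:
        from .contractility import significance_stars

        return significance_stars(self.p_value)


@dataclass(frozen=True)
class OrientationSummary:
    """Axial circular statistics of an orientation sample."""

    mean_angle: float
    sem: float
    resultant_length: float
    order_parameter: float
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray
    mean_defined: bool = True


@dataclass(frozen=True)
class ProtocolBlock:
    kind: Literal["stimulate", "record"]
    duration: float
    train: StimulusTrain | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("block duration must be positive")
        if self.kind == "record" and self.train is not None:
            raise ValueError("record blocks carry no stimulus train")
        if self.kind == "stimulate" and self.train is None:
            raise ValueError("stimulate blocks require a stimulus train")


@dataclass(frozen=True)
class ProtocolSchedule:
    """Alternating stimulate/record schedule; recording never overlaps light."""

    blocks: tuple[ProtocolBlock, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a schedule needs at least one block")

    @property
    def total_duration(self) -> float:
        return float(sum(b.duration for b in self.blocks))

    @property
    def cumulative_stimulation(self) -> float:
        return float(sum(b.duration for b in self.blocks if b.kind == "stimulate"))


@dataclass(frozen=True)
class RosResult:
    """Background-corrected, per-nucleus-normalized CellROX intensity."""

    condition: str
    raw_intensity: float
    background: float
    n_nuclei: int
    normalized: float
    negative_flag: bool = False

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be at least 1")
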