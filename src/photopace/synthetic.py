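"""Forward models with known ground truth.

The study's raw videos were never deposited, so every inverse pipeline in
this package is verified by parameter recovery against these generators:

* a periodic twitch-stress trace drives a constant-curvature cantilever arc
  whose horizontal projection is rasterized into a binary movie (the inverse
  of the contractility pipeline);
* a planar or radial activation-time field drives a rise-and-decay calcium
  fluorescence kernel per pixel (the inverse of the optical-mapping
  pipeline);
* axial nuclear orientations are drawn from a doubled-angle von Mises law;
* light-pulse trains implement the frequency / duty-cycle arithmetic.

All stochastic operations take an explicit integer seed and are bit-wise
reproducible.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats

from .types import ActivationField, MechanicalSpec, Movie, OrientationSet, StimulusTrain, StressTrace

__all__ = [
    "make_stress_trace",
    "curvature_from_stress",
    "projected_length",
    "render_cantilever_movie",
    "make_activation_field",
    "render_calcium_movie",
    "sample_orientations",
    "concentration_for_sem",
    "make_stimulus_train",
]


def make_stress_trace(
    frequency: float,
    diastolic: float,
    twitch_amplitude: float,
    duration: float,
    frame_rate: float,
    upstroke_fraction: float = 0.2,
) -> StressTrace:
    """Periodic twitch-stress trace σ(t) with exact planted statistics.

    Each beat is a compact pulse on a flat diastolic baseline: a half-cosine
    rise lasting ``upstroke_fraction`` of the beat period followed by a
    half-cosine decay lasting twice as long (fast rise, slower decay), then
    baseline until the next beat.  Beats start at k/frequency for every k
    whose full period fits inside ``duration``, so a 30 s trace at 0.78 Hz
    contains floor(30·0.78) = 23 complete beats.

    Parameters
    ----------
    frequency : Hz
        Beat rate; ``frame_rate`` must be at least 10× this.
    diastolic : Pa
        Baseline stress.
    twitch_amplitude : Pa
        Peak-minus-baseline stress of each twitch (may be 0).
    duration : s
    frame_rate : Hz
    upstroke_fraction : fraction of the period spent rising, in (0, 1/3].
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if twitch_amplitude < 0:
        raise ValueError("twitch_amplitude must be non-negative")
    if diastolic < 0:
        raise ValueError("diastolic stress must be non-negative")
    if frame_rate < 10.0 * frequency:
        raise ValueError(
            f"frame_rate {frame_rate} Hz is below the 10x-frequency (Nyquist-safe) "
            f"floor needed to resolve a {frequency} Hz twitch"
        )
    if not (0.0 < upstroke_fraction <= 1.0 / 3.0):
        raise ValueError("upstroke_fraction must lie in (0, 1/3]")

    n_samples = int(round(duration * frame_rate))
    times = np.arange(n_samples, dtype=float) / frame_rate
    stress = np.full(n_samples, float(diastolic))

    period = 1.0 / frequency
    t_rise = upstroke_fraction * period
    t_decay = 2.0 * t_rise
    n_beats = int(math.floor(duration * frequency + 1e-9))
    for k in range(n_beats):
        s = times - k * period
        rising = (s >= 0) & (s < t_rise)
        falling = (s >= t_rise) & (s < t_rise + t_decay)
        stress[rising] += twitch_amplitude * 0.5 * (1.0 - np.cos(np.pi * s[rising] / t_rise))
        stress[falling] += twitch_amplitude * 0.5 * (
            1.0 + np.cos(np.pi * (s[falling] - t_rise) / t_decay)
        )
    return StressTrace(times=times, stress=stress, frame_rate=frame_rate)


def curvature_from_stress(stress, spec: MechanicalSpec):
    """Invert the Stoney relation: κ = 6·h_f·(1−ν_s)·σ / (C·E_s·h_s²)."""
    return np.asarray(stress, dtype=float) / spec.stress_per_curvature


def projected_length(kappa, L: float):
    """Horizontal extent of a circular-arc cantilever: x = L·sin(κL)/(κL).

    The arc has uniform curvature κ and is tangent to the substrate plane at
    its base; the camera above sees the chord projection.  x → L as κ → 0.
    Only κL < π is physical for this analysis (beyond it the projection is
    no longer injective).
    """
    kappa = np.asarray(kappa, dtype=float)
    # np.sinc(u) = sin(pi u)/(pi u), exact at 0
    return L * np.sinc(kappa * L / np.pi)


def render_cantilever_movie(
    trace: StressTrace,
    spec: MechanicalSpec,
    pixel_size: float,
    rows: int = 24,
    cols: int | None = None,
    base_col: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Movie:
    """Rasterize the bending cantilever as a binary silhouette movie.

    Per frame the planted stress is converted to curvature by inverting the
    Stoney relation, the curvature to a projected length x = L·sin(κL)/(κL),
    and the silhouette drawn as a rectangle of ``round(x / pixel_size)``
    columns extending from the fixed base.  Optional zero-mean Gaussian
    intensity noise is added and the frame re-binarized at 0.5.

    Raises if any frame over-curls (κL ≥ π) or projects to fewer than
    2 pixels, or if the free length does not fit in the field of view.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    L = spec.free_length_L
    rest_px = int(round(L / pixel_size))
    if cols is None:
        cols = base_col + rest_px + 8
    if base_col + rest_px > cols - 1:
        raise ValueError("free length not representable: widen the field of view")
    if rows < 9:
        raise ValueError("need at least 9 rows to draw the film band")

    kappa = curvature_from_stress(trace.stress, spec)
    theta = kappa * L
    if np.any(theta >= np.pi):
        raise ValueError(
            "over-curl: kappa*L >= pi in at least one frame; the x-projection "
            "is no longer injective"
        )
    x = projected_length(kappa, L)
    extent_px = np.round(x / pixel_size).astype(int)
    if np.any(extent_px < 2):
        raise ValueError("projection collapses below 2 pixels: resolution failure")

    r0, r1 = 4, rows - 4
    frames = np.zeros((len(trace), rows, cols), dtype=np.uint8)
    for i, n_px in enumerate(extent_px):
        frames[i, r0:r1, base_col : base_col + n_px] = 1

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = frames + rng.normal(0.0, noise_sd, size=frames.shape)
        frames = (noisy > 0.5).astype(np.uint8)

    return Movie(frames=frames, frame_rate=trace.frame_rate, pixel_size=pixel_size, kind="binary_mask")


def make_activation_field(
    rows: int,
    cols: int,
    pixel_size: float,
    source_kind: str,
    source_location: tuple[int, int],
    speed_v: float,
) -> ActivationField:
    """Ground-truth activation-time field T(p) = dist(source, p) / v.

    ``edge`` sources excite the whole image edge through ``source_location``
    (a planar wave, T monotone along the normal axis); ``point`` sources
    excite a single interior pixel (a radial wave — two counter-propagating
    fronts along the long axis).
    """
    if speed_v <= 0:
        raise ValueError("speed_v must be positive")
    r0, c0 = source_location
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError("source_location must lie inside the image")
    rr, cc = np.mgrid[0:rows, 0:cols]
    if source_kind == "edge":
        if c0 == 0:
            dist = cc * pixel_size
        elif c0 == cols - 1:
            dist = (cols - 1 - cc) * pixel_size
        elif r0 == 0:
            dist = rr * pixel_size
        elif r0 == rows - 1:
            dist = (rows - 1 - rr) * pixel_size
        else:
            raise ValueError("edge source must lie on an image boundary")
    elif source_kind == "point":
        dist = np.hypot(rr - r0, cc - c0) * pixel_size
    else:
        raise ValueError(f"unknown source_kind {source_kind!r}")
    return ActivationField(
        T=dist / speed_v,
        source_kind=source_kind,  # type: ignore[arg-type]
        source_location=(int(r0), int(c0)),
        speed_v=speed_v,
        pixel_size=pixel_size,
    )


def _calcium_kernel(s: np.ndarray, rise_time: float, decay_tau: float) -> np.ndarray:
    """Normalized transient: linear rise to 1 over rise_time, then exp decay."""
    out = np.zeros_like(s)
    rising = (s >= 0) & (s < rise_time)
    out[rising] = s[rising] / rise_time
    falling = s >= rise_time
    out[falling] = np.exp(-(s[falling] - rise_time) / decay_tau)
    return out


def render_calcium_movie(
    field: ActivationField,
    frame_rate: float = 400.0,
    n_beats: int = 3,
    beat_period: float = 1.0,
    rise_time: float = 0.02,
    decay_tau: float = 0.2,
    baseline_F0: float = 100.0,
    amplitude_dF: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Movie:
    """Render a fluorescence movie from an activation field.

    Each pixel's trace is F0 + dF · Σ_k K(t − T(p) − k·beat_period) with K a
    linear-rise / exponential-decay transient, plus seeded Gaussian noise.
    Negative post-noise intensities are clipped to zero; a warning is issued
    if clipping touches more than 1% of samples.
    """
    if rise_time >= beat_period:
        raise ValueError("rise_time must be shorter than the beat period")
    if n_beats < 1:
        raise ValueError("need at least one beat")
    if float(field.T.max()) + rise_time >= beat_period:
        raise ValueError("activation spread exceeds one beat period; slow the pacing")

    n_frames = int(round(n_beats * beat_period * frame_rate))
    t = np.arange(n_frames, dtype=float) / frame_rate
    T = field.T
    frames = np.zeros((n_frames, *T.shape))
    for k in range(n_beats):
        s = t[:, None, None] - T[None, :, :] - k * beat_period
        frames += _calcium_kernel(s, rise_time, decay_tau)
    frames = baseline_F0 + amplitude_dF * frames

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    n_clipped = int(np.count_nonzero(frames < 0))
    if n_clipped:
        np.clip(frames, 0.0, None, out=frames)
        if n_clipped > 0.01 * frames.size:
            warnings.warn(
                f"clipped {n_clipped} negative samples "
                f"({100 * n_clipped / frames.size:.1f}% of the movie)",
                stacklevel=2,
            )
    return Movie(
        frames=frames.astype(np.float32),
        frame_rate=frame_rate,
        pixel_size=field.pixel_size,
        kind="fluorescence",
    )


def canonicalize_axial(angles_deg, pattern_direction: float = 0.0) -> np.ndarray:
    """Map axial angles into [−90°, 90°) relative to the pattern direction."""
    a = np.asarray(angles_deg, dtype=float) - pattern_direction
    return (a + 90.0) % 180.0 - 90.0


def sample_orientations(
    n: int,
    mean_angle: float,
    concentration: float,
    pattern_direction: float = 0.0,
    seed: int = 0,
) -> OrientationSet:
    """Draw axial nuclear orientations from a doubled-angle von Mises law.

    The doubled angles 2θ follow a von Mises distribution with mean
    2·mean_angle and the given concentration κ; κ = 0 degenerates to the
    uniform axial distribution.  Angles are returned canonicalized to
    [−90°, 90°) relative to ``pattern_direction``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    if concentration == 0:
        doubled = rng.uniform(-np.pi, np.pi, size=n)
    else:
        doubled = scipy.stats.vonmises.rvs(
            kappa=concentration,
            loc=np.deg2rad(2.0 * (mean_angle - pattern_direction)),
            size=n,
            random_state=rng,
        )
    angles = canonicalize_axial(np.rad2deg(doubled) / 2.0 + pattern_direction, pattern_direction)
    return OrientationSet(angles=angles, pattern_direction=pattern_direction)


def concentration_for_sem(sem_deg: float, n: int) -> float:
    """Von Mises concentration whose axial circular s.e.m. matches a target.

    Inverts sem = (√(−2 ln R₂)/2)/√n (in degrees) through the von Mises
    mean-resultant-length R(κ) = I₁(κ)/I₀(κ).
    """
    if sem_deg <= 0 or n < 1:
        raise ValueError("sem_deg must be positive and n >= 1")
    sd_rad = np.deg2rad(sem_deg * math.sqrt(n))
    r_target = math.exp(-2.0 * sd_rad**2)

    def resultant(kappa: float) -> float:
        return scipy.special.i1e(kappa) / scipy.special.i0e(kappa)

    return float(
        scipy.optimize.brentq(lambda k: resultant(k) - r_target, 1e-6, 1e6, xtol=1e-10)
    )


def make_stimulus_train(
    frequency_f: float,
    duty_cycle_d: float,
    duration: float,
    irradiance: float = 60.0,
) -> StimulusTrain:
    """Light-pulse train: width = duty/frequency, onsets at k/frequency.

    At 1 Hz a 50% duty cycle gives a 500 ms pulse and 15% gives 150 ms; the
    arithmetic is exact in floating point.
    """
    return StimulusTrain(
        frequency_f=frequency_f,
        duty_cycle_d=duty_cycle_d,
        duration=duration,
        irradiance=irradiance,
    )
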