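"""Calcium optical-mapping post-processing.

From a raw fluorescence movie to conduction velocity: 3×3 spatial mean
filter, per-pixel ΔF/F normalization, beat segmentation on the field-mean
trace, per-pixel activation times (50%-upstroke crossing with sub-frame
interpolation, or maximum derivative), and conduction velocity from the
activation-time gradient, v = g/|g|² so that speed = 1/|∇T|.  A projection
of the activation map onto the long axis counts wavefront origins and
distinguishes a single edge-born wave from the double wave launched by an
interior light spot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .types import ActivationMap, Movie, VelocityField, WavefrontReport

__all__ = [
    "spatial_filter",
    "normalize_dff",
    "segment_beats",
    "activation_times",
    "conduction_velocity",
    "count_wavefronts",
    "analyze_calcium_movie",
    "CalciumAnalysis",
]


def spatial_filter(movie: Movie) -> Movie:
    """3×3 per-frame uniform mean filter (reflected borders) for S/N."""
    if movie.frames.shape[1] < 3 or movie.frames.shape[2] < 3:
        raise ValueError("movie smaller than the 3x3 filter support")
    filtered = scipy.ndimage.uniform_filter(
        np.asarray(movie.frames, dtype=float), size=(1, 3, 3), mode="reflect"
    )
    return Movie(frames=filtered, frame_rate=movie.frame_rate, pixel_size=movie.pixel_size,
                 kind="fluorescence")


def normalize_dff(movie: Movie, baseline_percentile: float = 10.0) -> Movie:
    """Per-pixel ΔF/F: (F − F0)/F0 with F0 the given percentile of the trace.

    Pixels whose baseline is non-positive carry no usable signal; they are
    zeroed out with a warning rather than propagating infinities.
    """
    frames = np.asarray(movie.frames, dtype=float)
    f0 = np.percentile(frames, baseline_percentile, axis=0)
    bad = f0 <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} pixels have non-positive baseline F0; masked out",
            stacklevel=2,
        )
        f0 = np.where(bad, 1.0, f0)
    dff = (frames - f0[None]) / f0[None]
    dff[:, bad] = 0.0
    # Movie intensities are non-negative by contract; noise pushes ΔF/F a
    # hair below 0 around the baseline.  Clip — the activation detector uses
    # in-window amplitude and is unaffected by a floor at the noise level.
    np.clip(dff, 0.0, None, out=dff)
    return Movie(frames=dff, frame_rate=movie.frame_rate, pixel_size=movie.pixel_size,
                 kind="fluorescence")


def segment_beats(movie: Movie, pacing_frequency: float | None = None) -> list[tuple[int, int]]:
    """Frame windows, one per beat, from the spatially averaged trace.

    Peaks require prominence of at least 20% of the mean trace's range.
    Without pacing information the windows run between midpoints of
    consecutive peaks; with a pacing frequency each window is snapped to one
    stimulus period centered on its peak.  Windows are disjoint and ordered.
    """
    mean_trace = np.asarray(movie.frames, dtype=float).mean(axis=(1, 2))
    rng = float(np.ptp(mean_trace))
    if rng == 0.0:
        raise ValueError("no beats found: flat field-mean trace")
    peaks, _ = scipy.signal.find_peaks(mean_trace, prominence=0.2 * rng)
    if peaks.size == 0:
        raise ValueError("no beats found in the field-mean trace")
    n = movie.n_frames
    windows: list[tuple[int, int]] = []
    if pacing_frequency is not None:
        period = int(round(movie.frame_rate / pacing_frequency))
        prev_end = 0
        for p in peaks:
            start = max(prev_end, int(p) - period // 2)
            end = min(n, start + period)
            if end - start < 3:
                continue
            windows.append((start, end))
            prev_end = end
    else:
        mids = [0] + [int((peaks[i] + peaks[i + 1]) // 2) for i in range(peaks.size - 1)] + [n]
        windows = [(mids[i], mids[i + 1]) for i in range(peaks.size)]
    return windows


def activation_times(
    movie: Movie,
    window: tuple[int, int],
    method: str = "half_amplitude",
    min_amplitude_fraction: float = 0.2,
    beat_index: int = 0,
) -> ActivationMap:
    """Per-pixel activation time inside one beat window.

    ``half_amplitude``: first upward crossing of 50% of the pixel's
    in-window amplitude, linearly interpolated between frames (sub-frame
    resolution).  ``max_derivative``: argmax of the centered first
    difference.  Pixels whose amplitude is below
    ``min_amplitude_fraction`` × the frame-wide median amplitude are marked
    invalid.
    """
    start, end = window
    sub = np.asarray(movie.frames[start:end], dtype=float)
    if sub.shape[0] < 3:
        raise ValueError("beat window is empty or too short")
    lo = sub.min(axis=0)
    amp = sub.max(axis=0) - lo
    med_amp = float(np.median(amp))
    valid = amp >= min_amplitude_fraction * med_amp
    if med_amp <= 0 or not valid.any():
        raise ValueError("all pixels invalid: no upstroke in this window")

    if method == "half_amplitude":
        thr = lo + 0.5 * amp
        above = sub >= thr[None]
        idx = above.argmax(axis=0)
        t_frames = idx.astype(float)
        interp = idx > 0
        rr, cc = np.nonzero(interp)
        i = idx[rr, cc]
        f_prev = sub[i - 1, rr, cc]
        f_next = sub[i, rr, cc]
        denom = f_next - f_prev
        frac = np.where(denom > 0, (thr[rr, cc] - f_prev) / np.where(denom > 0, denom, 1.0), 0.0)
        t_frames[rr, cc] = i - 1 + frac
    elif method == "max_derivative":
        deriv = (sub[2:] - sub[:-2]) * 0.5
        t_frames = deriv.argmax(axis=0).astype(float) + 1.0
    else:
        raise ValueError(f"unknown activation method {method!r}")

    T = (start + t_frames) / movie.frame_rate
    return ActivationMap(
        T=T, valid=valid, frame_rate=movie.frame_rate, pixel_size=movie.pixel_size,
        beat_index=beat_index, method=method,  # type: ignore[arg-type]
    )


def _shift(a: np.ndarray, step: int, axis: int, fill) -> np.ndarray:
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step > 0:
        src[axis] = slice(0, a.shape[axis] - step)
        dst[axis] = slice(step, None)
    else:
        src[axis] = slice(-step, None)
        dst[axis] = slice(0, a.shape[axis] + step)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _masked_gradient(T: np.ndarray, valid: np.ndarray, h: float, axis: int):
    """Central differences where both neighbors are valid, one-sided at
    valid-region borders, undefined elsewhere."""
    nxt_T = _shift(T, -1, axis, np.nan)
    prv_T = _shift(T, +1, axis, np.nan)
    nxt_v = _shift(valid, -1, axis, False)
    prv_v = _shift(valid, +1, axis, False)
    g = np.full(T.shape, np.nan)
    central = valid & nxt_v & prv_v
    g[central] = (nxt_T[central] - prv_T[central]) / (2.0 * h)
    fwd = valid & nxt_v & ~prv_v
    g[fwd] = (nxt_T[fwd] - T[fwd]) / h
    bwd = valid & ~nxt_v & prv_v
    g[bwd] = (T[bwd] - prv_T[bwd]) / h
    return g, central | fwd | bwd


def conduction_velocity(
    amap: ActivationMap,
    pixel_size: float | None = None,
    v_min: float = 1e-3,
    v_max: float = 1.0,
) -> VelocityField:
    """Conduction velocity from the activation-time gradient.

    With g = ∇T (x- and y-directional change rates of the activation time),
    the front velocity is v = g/|g|², i.e. it points along the propagation
    direction with speed 1/|g|.  Pixels whose gradient magnitude is below
    half of 1/v_max (a quasi-simultaneous plateau) or above 1/v_min
    (quasi-stationary) are invalidated.
    """
    h = pixel_size if pixel_size is not None else amap.pixel_size
    if int(amap.valid.sum()) < 9:
        raise ValueError("fewer than 9 valid pixels")
    gx, okx = _masked_gradient(amap.T, amap.valid, h, axis=1)  # x = column axis
    gy, oky = _masked_gradient(amap.T, amap.valid, h, axis=0)
    ok = amap.valid & okx & oky
    gmag = np.hypot(np.where(ok, gx, 0.0), np.where(ok, gy, 0.0))
    g_floor = 0.5 / v_max
    g_ceil = 1.0 / v_min
    ok &= (gmag >= g_floor) & (gmag <= g_ceil)
    if not ok.any():
        raise ValueError("no propagating front: every gradient outside the speed bounds")

    with np.errstate(divide="ignore", invalid="ignore"):
        vx = np.where(ok, gx / gmag**2, np.nan)
        vy = np.where(ok, gy / gmag**2, np.nan)
        speed = np.where(ok, 1.0 / gmag, np.nan)
    return VelocityField(
        vx=vx, vy=vy, speed=speed, valid=ok,
        mean_speed=float(np.nanmean(speed[ok])),
        median_speed=float(np.nanmedian(speed[ok])),
    )


def count_wavefronts(
    amap: ActivationMap,
    long_axis: str = "x",
    smooth_window: int = 5,
    merge_distance: int = 2,
) -> WavefrontReport:
    """Count wavefront origins along the cantilever's long axis.

    The activation map is projected onto the long axis (per-column minimum
    over valid rows), smoothed with a 5-column moving average, and its
    strict local minima counted (minima closer than ``merge_distance``
    columns are merged).  One minimum at the boundary classifies as a single
    edge-born wave; one interior minimum as a point-source double wave (two
    counter-propagating fronts); two or more separated minima as multiple
    sources.
    """
    T = amap.T if long_axis == "x" else amap.T.T
    valid = amap.valid if long_axis == "x" else amap.valid.T
    has = valid.any(axis=0)
    cols = np.flatnonzero(has)
    if cols.size < smooth_window:
        raise ValueError("valid region narrower than the smoothing window")
    profile = np.array([np.min(T[valid[:, c], c]) for c in cols])
    smooth = scipy.ndimage.uniform_filter1d(profile, size=smooth_window, mode="nearest")

    minima: list[int] = []
    n = smooth.size
    for i in range(n):
        left = smooth[i - 1] if i > 0 else np.inf
        right = smooth[i + 1] if i < n - 1 else np.inf
        if smooth[i] < left and smooth[i] < right:
            minima.append(i)
    merged: list[int] = []
    for m in minima:
        if merged and m - merged[-1] <= merge_distance:
            if smooth[m] < smooth[merged[-1]]:
                merged[-1] = m
        else:
            merged.append(m)
    if not merged:  # monotone profile: the minimum sits at a boundary
        merged = [int(np.argmin(smooth))]

    origin_cols = tuple(int(cols[m]) for m in merged)
    boundary = {0, n - 1}
    if len(merged) == 1:
        if merged[0] in boundary:
            classification, n_fronts = "edge_wave", 1
        else:
            classification, n_fronts = "point_source_double_wave", 2
    else:
        classification = "multiple_sources"
        n_fronts = sum(1 if m in boundary else 2 for m in merged)
    return WavefrontReport(
        n_origins=len(merged), n_fronts=n_fronts, origin_columns=origin_cols,
        classification=classification, profile=smooth,  # type: ignore[arg-type]
    )


@dataclass(frozen=True)
class CalciumAnalysis:
    """End-to-end optical-mapping result for one movie."""

    maps: tuple[ActivationMap, ...]
    velocities: tuple[VelocityField, ...]
    wavefront: WavefrontReport
    speed: float  # median over pixels, then mean over pulses (m/s)

    @property
    def speed_cm_s(self) -> float:
        return 100.0 * self.speed


def analyze_calcium_movie(
    movie: Movie,
    pacing_frequency: float | None = None,
    method: str = "half_amplitude",
    long_axis: str = "x",
) -> CalciumAnalysis:
    """Filter → ΔF/F → beat windows → per-beat activation and velocity.

    The reported speed is the median over pixels within each pulse, averaged
    over pulses; the wavefront classification comes from the first beat.
    """
    filtered = spatial_filter(movie)
    dff = normalize_dff(filtered)
    windows = segment_beats(dff, pacing_frequency=pacing_frequency)
    maps, fields = [], []
    for k, win in enumerate(windows):
        amap = activation_times(dff, win, method=method, beat_index=k)
        maps.append(amap)
        fields.append(conduction_velocity(amap))
    speed = float(np.mean([vf.median_speed for vf in fields]))
    wavefront = count_wavefronts(maps[0], long_axis=long_axis)
    return CalciumAnalysis(
        maps=tuple(maps), velocities=tuple(fields), wavefront=wavefront, speed=speed
    )
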