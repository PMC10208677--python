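"""Cantilever-movie → stress-trace → twitch-statistics pipeline.

The muscular-thin-film readout chain: threshold the movie, measure the
horizontal x-projection of the curled film per frame, invert the
circular-arc projection x = L·sin(κL)/(κL) for the curvature κ, and convert
κ to film stress with the Stoney relation.  Peak detection on the stress
trace then yields diastolic / systolic / twitch stresses and the
contraction frequency.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.optimize
import scipy.signal
import scipy.stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .types import ComparisonResult, MechanicalSpec, Movie, StressTrace, TwitchSummary

__all__ = [
    "threshold_movie",
    "x_projection",
    "curvature_from_projection",
    "stoney_stress",
    "extract_stress_trace",
    "detect_twitches",
    "compare_conditions",
    "significance_stars",
]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = cc_label(mask, return_num=True, connectivity=2)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(np.argmax(sizes))


def threshold_movie(movie: Movie, method: str = "otsu", fixed_level: float | None = None) -> Movie:
    """Binarize a grayscale cantilever movie.

    The Otsu level is computed on the first frame and reused for every frame
    so that per-frame threshold jitter cannot masquerade as contraction.
    After binarization only the largest connected foreground component of
    each frame is kept.  Already-binary movies pass through unchanged.
    """
    if movie.kind == "binary_mask":
        return movie
    frames = np.asarray(movie.frames, dtype=float)
    if method == "otsu":
        first = frames[0]
        if np.ptp(first) == 0:
            raise ValueError("frame 0 has empty or full foreground (constant image)")
        level = float(threshold_otsu(first))
    elif method == "fixed":
        if fixed_level is None:
            raise ValueError("fixed thresholding requires fixed_level")
        level = float(fixed_level)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    out = np.zeros(frames.shape, dtype=np.uint8)
    for i, frame in enumerate(frames):
        mask = frame > level
        if not mask.any() or mask.all():
            raise ValueError(f"empty or full foreground after thresholding frame {i}")
        out[i] = _largest_component(mask)
    return Movie(frames=out, frame_rate=movie.frame_rate, pixel_size=movie.pixel_size, kind="binary_mask")


def x_projection(mask_movie: Movie, base_column: int | None = None) -> np.ndarray:
    """Per-frame projected length of the film along the bending (column) axis.

    x = (max foreground column − base column + 1) · pixel_size.  The fixed
    cantilever base defaults to the column of maximal temporal occupancy
    (the leftmost always-occupied column in practice).  A foreground that
    touches the far image border is censored and aborts the measurement.
    """
    if mask_movie.kind != "binary_mask":
        raise ValueError("x_projection expects a binary mask movie")
    frames = mask_movie.frames.astype(bool)
    col_any = frames.any(axis=1)  # (time, cols)
    if base_column is None:
        occupancy = col_any.mean(axis=0)
        base_column = int(np.argmax(occupancy))
    n_cols = frames.shape[2]
    lengths = np.empty(frames.shape[0], dtype=float)
    for i, cols_present in enumerate(col_any):
        idx = np.flatnonzero(cols_present)
        if idx.size == 0:
            raise ValueError(f"frame {i}: empty foreground")
        far = int(idx[-1])
        if far == n_cols - 1:
            raise ValueError(
                f"frame {i}: foreground touches the far image border — projection "
                "censored; the field of view is too small"
            )
        lengths[i] = (far - base_column + 1) * mask_movie.pixel_size
    return lengths


def curvature_from_projection(x: float, L: float) -> float:
    """Curvature κ of the circular arc whose horizontal projection is x.

    Solves x = L·sin(θ)/θ for θ = κL on (0, π), where sin(θ)/θ is strictly
    decreasing, by bracketed root finding to |Δθ| < 1e−12; κ = 0 when x = L.
    """
    if x <= 0:
        raise ValueError("projection must be positive")
    if x > L:
        raise ValueError(f"impossible projection: x = {x} exceeds the free length {L}")
    ratio = x / L
    if ratio >= 1.0:
        return 0.0
    theta = scipy.optimize.brentq(
        lambda th: math.sin(th) / th - ratio, 1e-12, math.pi - 1e-12, xtol=1e-13, rtol=8.9e-16
    )
    return theta / L


def stoney_stress(kappa, spec: MechanicalSpec):
    """Film stress from curvature: σ = C·E_s·h_s²·κ / (6·h_f·(1−ν_s)).

    Classical Stoney with a pluggable thickness-correction factor C
    (C = 1 by default); exactly linear in κ.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("curvature must be non-negative")
    sigma = kappa * spec.stress_per_curvature
    return float(sigma) if sigma.ndim == 0 else sigma


def extract_stress_trace(
    movie: Movie,
    spec: MechanicalSpec,
    threshold_method: str = "otsu",
    fixed_level: float | None = None,
    base_column: int | None = None,
) -> StressTrace:
    """Full inverse chain: threshold → x-projection → curvature → Stoney.

    Projections that exceed the free length by at most one pixel (pure
    rasterization round-off) are clipped to L; larger excesses abort.
    """
    mask = threshold_movie(movie, method=threshold_method, fixed_level=fixed_level)
    x = x_projection(mask, base_column=base_column)
    L = spec.free_length_L
    too_long = x > L + movie.pixel_size
    if np.any(too_long):
        i = int(np.argmax(too_long))
        raise ValueError(f"frame {i}: projection {x[i]:.3e} m exceeds the free length {L:.3e} m")
    x = np.minimum(x, L)
    kappa = np.array([curvature_from_projection(xi, L) for xi in x])
    stress = stoney_stress(kappa, spec)
    times = np.arange(movie.n_frames) / movie.frame_rate
    return StressTrace(times=times, stress=stress, frame_rate=movie.frame_rate)


def detect_twitches(
    trace: StressTrace,
    min_prominence_fraction: float = 0.2,
    analysis_window: float = 30.0,
) -> TwitchSummary:
    """Beat statistics from a stress trace.

    Peaks are required to have prominence of at least
    ``min_prominence_fraction`` of the trace's dynamic range.  Each beat's
    baseline is the 5th percentile of the inter-peak segment preceding the
    peak; the diastolic stress is the mean baseline, the systolic stress the
    mean peak, and the twitch stress their difference.  The contraction
    frequency is the reciprocal median inter-peak interval (robust to one
    missed beat) and 0 when fewer than two beats are present.  A flat trace
    yields an empty summary, not an error.
    """
    if trace.duration < 2.0:
        raise ValueError("trace too short: need at least 2 s")
    sel = trace.times - trace.times[0] < analysis_window
    times = trace.times[sel]
    stress = trace.stress[sel]

    dynamic_range = float(np.ptp(stress))
    empty = TwitchSummary(
        diastolic_stress=float(np.mean(stress)),
        systolic_stress=float(np.mean(stress)),
        twitch_stress=0.0,
        contraction_frequency=0.0,
        n_beats=0,
        per_beat_table=(),
    )
    if dynamic_range == 0.0:
        return empty
    peaks, _ = scipy.signal.find_peaks(stress, prominence=min_prominence_fraction * dynamic_range)
    if peaks.size == 0:
        return empty

    table = []
    prev = 0
    for p in peaks:
        segment = stress[prev:p] if p > prev else stress[max(p - 1, 0) : p + 1]
        baseline = float(np.percentile(segment, 5))
        table.append((float(times[p]), float(stress[p]), baseline))
        prev = p
    baselines = np.array([b for *_, b in table])
    peak_values = np.array([v for _, v, _ in table])
    diastolic = float(baselines.mean())
    systolic = float(peak_values.mean())
    if peaks.size >= 2:
        frequency = float(1.0 / np.median(np.diff(times[peaks])))
    else:
        frequency = 0.0
    return TwitchSummary(
        diastolic_stress=diastolic,
        systolic_stress=systolic,
        twitch_stress=systolic - diastolic,
        contraction_frequency=frequency,
        n_beats=int(peaks.size),
        per_beat_table=tuple(table),
    )


def significance_stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001 (strict), else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_conditions(values_a, values_b, variant: str = "welch") -> ComparisonResult:
    """Two-sided two-sample t-test between two condition groups.

    ``welch`` (default) does not assume equal variances — appropriate for
    the unequal group sizes of the assay; ``student`` is the pooled-variance
    test.  Degenerate zero-variance inputs follow the conventions: equal
    constant samples give t = 0, p = 1; distinct constants give |t| = ∞,
    p = 0; both are flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    sem_a = float(a.std(ddof=1) / math.sqrt(a.size))
    sem_b = float(b.std(ddof=1) / math.sqrt(b.size))

    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t = math.inf if mean_a > mean_b else -math.inf
            p = 0.0
        return ComparisonResult(
            mean_a=mean_a, mean_b=mean_b, sem_a=sem_a, sem_b=sem_b,
            t_statistic=t, p_value=p, n_a=int(a.size), n_b=int(b.size),
            variant=variant, degenerate=True,  # type: ignore[arg-type]
        )

    res = scipy.stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return ComparisonResult(
        mean_a=mean_a, mean_b=mean_b, sem_a=sem_a, sem_b=sem_b,
        t_statistic=float(res.statistic), p_value=float(res.pvalue),
        n_a=int(a.size), n_b=int(b.size), variant=variant,  # type: ignore[arg-type]
    )
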