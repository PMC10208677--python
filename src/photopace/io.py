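"""Reading and writing movies, traces and summaries.

Movies travel as multi-page TIFF (one page per frame; 8-bit for binary
masks, 16-bit unsigned for fluorescence) with a JSON sidecar carrying the
acquisition metadata the TIFF cannot: frame rate, pixel size and kind.
Ground-truth parameters of synthetic fixtures go to ``truth.json`` next to
the movie.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import Movie, StressTrace, TwitchSummary

__all__ = [
    "write_movie",
    "read_movie",
    "write_truth",
    "read_truth",
    "write_stress_trace",
    "read_stress_trace",
    "write_twitch_summary",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: Movie, path) -> None:
    path = Path(path)
    if movie.kind == "binary_mask":
        data = (movie.frames.astype(np.uint8) * 255).astype(np.uint8)
    else:
        data = np.clip(np.round(movie.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "frame_rate_hz": movie.frame_rate,
        "pixel_size_m": movie.pixel_size,
        "kind": movie.kind,
    }
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")


def read_movie(path) -> Movie:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    kind = meta["kind"]
    frames = (data > 127).astype(np.uint8) if kind == "binary_mask" else data.astype(float)
    return Movie(
        frames=frames,
        frame_rate=float(meta["frame_rate_hz"]),
        pixel_size=float(meta["pixel_size_m"]),
        kind=kind,
    )


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, sort_keys=True, indent=2) + "\n")


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_stress_trace(trace: StressTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "stress_Pa": trace.stress}).to_csv(path, index=False)


def read_stress_trace(path) -> StressTrace:
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy()
    frame_rate = 1.0 / float(np.median(np.diff(times)))
    return StressTrace(times=times, stress=df["stress_Pa"].to_numpy(), frame_rate=frame_rate)


def write_twitch_summary(summary: TwitchSummary, path) -> None:
    row = {
        "diastolic_stress_Pa": summary.diastolic_stress,
        "systolic_stress_Pa": summary.systolic_stress,
        "twitch_stress_Pa": summary.twitch_stress,
        "contraction_frequency_Hz": summary.contraction_frequency,
        "n_beats": summary.n_beats,
    }
    pd.DataFrame([row]).to_csv(path, index=False)
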