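"""Stimulation-protocol accounting, ROS normalization, and report assembly.

The photostimulation experiment alternates light-on blocks (the movie
cannot be recorded during illumination — optical interference) with short
recording blocks; this module encodes that schedule, the CellROX
per-nucleus normalization, and a deterministic machine- plus human-readable
experiment report.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .contractility import significance_stars
from .types import (
    ComparisonResult,
    ProtocolBlock,
    ProtocolSchedule,
    RosResult,
    StimulusTrain,
    TwitchSummary,
)

__all__ = [
    "build_protocol",
    "ros_normalize",
    "experiment_report",
    "render_report_text",
    "write_report",
]


def build_protocol(
    cycles: int,
    train: StimulusTrain,
    stim_minutes: float = 3.0,
    record_seconds: float = 30.0,
) -> ProtocolSchedule:
    """Alternating stimulate/record schedule.

    Each cycle is ``stim_minutes`` of pulsed light followed by
    ``record_seconds`` of video without photostimulation; two cycles at the
    3-minute default accumulate 6 minutes of stimulation.
    """
    if cycles < 1:
        raise ValueError("cycles must be at least 1")
    blocks: list[ProtocolBlock] = []
    for _ in range(cycles):
        blocks.append(ProtocolBlock(kind="stimulate", duration=stim_minutes * 60.0, train=train))
        blocks.append(ProtocolBlock(kind="record", duration=record_seconds))
    return ProtocolSchedule(blocks=tuple(blocks))


def ros_normalize(
    raw_intensity: float,
    background: float,
    n_nuclei: int,
    condition: str = "",
) -> RosResult:
    """Background-corrected CellROX intensity per Hoechst-positive nucleus.

    normalized = (raw − background) / n_nuclei; a negative result (background
    exceeding signal) is flagged rather than rejected.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be at least 1")
    if raw_intensity < 0:
        raise ValueError("raw intensity must be non-negative")
    normalized = (raw_intensity - background) / n_nuclei
    return RosResult(
        condition=condition,
        raw_intensity=float(raw_intensity),
        background=float(background),
        n_nuclei=int(n_nuclei),
        normalized=float(normalized),
        negative_flag=normalized < 0,
    )


def _mean_sem(values: Sequence[float]) -> dict:
    a = np.asarray(values, dtype=float)
    sem = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
    return {"mean": float(a.mean()), "sem": sem, "n": int(a.size)}


def experiment_report(
    twitch_summaries: Mapping[str, Sequence[TwitchSummary]],
    velocity_summaries: Mapping[str, Sequence[float]] | None = None,
    comparisons: Sequence[tuple[str, str, ComparisonResult]] = (),
    config: Mapping | None = None,
    seeds: Sequence[int] = (),
) -> dict:
    """Assemble a deterministic report dictionary.

    Per condition: mean ± s.e.m. of contraction frequency (Hz), twitch
    stress (kPa) and, when given, conduction speed (cm/s).  Pairwise
    comparisons carry the t statistic, p-value and star annotation.
    Provenance records the config hash, the seeds used, and the package
    version; with fixed seeds and config the report is byte-identical
    across reruns.
    """
    if not twitch_summaries:
        raise ValueError("need at least one condition")
    conditions = {}
    for name in sorted(twitch_summaries):
        summaries = twitch_summaries[name]
        conditions[name] = {
            "contraction_frequency_Hz": _mean_sem([s.contraction_frequency for s in summaries]),
            "twitch_stress_kPa": _mean_sem([s.twitch_stress / 1e3 for s in summaries]),
            "diastolic_stress_kPa": _mean_sem([s.diastolic_stress / 1e3 for s in summaries]),
            "systolic_stress_kPa": _mean_sem([s.systolic_stress / 1e3 for s in summaries]),
            "n_cantilevers": len(summaries),
        }
    if velocity_summaries:
        for name in sorted(velocity_summaries):
            conditions.setdefault(name, {})["conduction_speed_cm_s"] = _mean_sem(
                [100.0 * v for v in velocity_summaries[name]]
            )
    comp_rows = []
    for label_a, label_b, res in comparisons:
        comp_rows.append(
            {
                "a": label_a,
                "b": label_b,
                "t": res.t_statistic,
                "p": res.p_value,
                "stars": significance_stars(res.p_value),
                "variant": res.variant,
                "n_a": res.n_a,
                "n_b": res.n_b,
            }
        )
    config_blob = json.dumps(config or {}, sort_keys=True).encode()
    return {
        "conditions": conditions,
        "comparisons": comp_rows,
        "provenance": {
            "config_sha256": hashlib.sha256(config_blob).hexdigest(),
            "seeds": list(seeds),
            "photopace_version": __version__,
        },
    }


def render_report_text(report: dict) -> str:
    """Human-readable summary of an experiment report."""
    lines = []
    for name, cond in report["conditions"].items():
        lines.append(f"[{name}]")
        for key, stats in cond.items():
            if isinstance(stats, dict) and "mean" in stats:
                lines.append(
                    f"  {key}: {stats['mean']:.3g} ± {stats['sem']:.3g} (n={stats['n']})"
                )
    for row in report["comparisons"]:
        lines.append(
            f"{row['a']} vs {row['b']}: t = {row['t']:.3f}, p = {row['p']:.3g} {row['stars']}"
        )
    return "\n".join(lines) + "\n"


def write_report(report: dict, path) -> None:
    """Serialize the report as canonical (sorted, indented) JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
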