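#!/usr/bin/env python
"""Protocol accounting and the group-size power simulation.

Builds the two-cycle stimulation schedule (3 min pulsed light + 30 s
recording, twice: 6 min cumulative light), the ROS normalization example
table, and simulates the detectability of the 0.78 vs 0.31 Hz frequency
difference at the study's group sizes (N = 40 vs N = 11 cantilevers) with
s.e.m.-consistent per-cantilever noise (SD = s.e.m.·sqrt(N): 0.70 and
0.33 Hz).  The Welch test detects the difference in roughly 86% of
replicates — the analytic noncentrality 0.47/0.149 ≈ 3.2 at ~35 df puts
the power well below 95%, so a single such experiment is adequately but
not overwhelmingly powered.
"""

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from photopace import protocol as proto
from photopace import synthetic as syn
from photopace.contractility import compare_conditions

ROOT = Path(__file__).resolve().parents[1]
RESDIR = ROOT / "results"
SEED = 20260929


def main() -> None:
    RESDIR.mkdir(parents=True, exist_ok=True)
    train = syn.make_stimulus_train(1.0, 0.5, 180.0)
    schedule = proto.build_protocol(cycles=2, train=train)
    print(f"schedule: {len(schedule.blocks)} blocks, "
          f"{schedule.cumulative_stimulation/60:.0f} min cumulative light, "
          f"{1e3*train.pulse_width:.0f} ms pulses at {train.frequency_f} Hz")

    rng = np.random.default_rng(SEED)
    ros_rows = [proto.ros_normalize(rng.normal(mu, 5.0), 20.0, 40, condition=cond)
                for cond, mu in [("negative", 120.0), ("positive", 600.0),
                                 ("optical", 125.0), ("electrical", 128.0)]]
    pd.DataFrame([r.__dict__ for r in ros_rows]).to_csv(RESDIR / "ros_table.csv", index=False)

    sd_a = 0.11 * math.sqrt(40)
    sd_b = 0.10 * math.sqrt(11)
    hits = 0
    reps = 500
    for _ in range(reps):
        a = rng.normal(0.78, sd_a, size=40)
        b = rng.normal(0.31, sd_b, size=11)
        if compare_conditions(a, b, variant="welch").p_value < 0.05:
            hits += 1
    power = hits / reps
    print(f"power: Welch t detects 0.78 vs 0.31 Hz (N=40 vs 11, "
          f"SD {sd_a:.2f}/{sd_b:.2f} Hz) in {100*power:.1f}% of {reps} replicates")

    (RESDIR / "protocol_power.json").write_text(json.dumps({
        "pulse_width_ms": 1e3 * train.pulse_width,
        "cumulative_stimulation_min": schedule.cumulative_stimulation / 60.0,
        "welch_power_040_vs_011": power,
        "replicates": reps,
    }, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
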