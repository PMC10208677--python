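#!/usr/bin/env python
"""Generate the synthetic study fixtures with known ground truth.

Writes the movies (large, binary) to scratch/fixtures/ and the ground-truth
parameters plus stimulus accounting to results/.  The planted values are the
study conditions: spontaneous 0.31 Hz and photopaced 0.78 Hz beating, 5.4 /
4.8 kPa twitch stresses, 4.2 cm/s edge-born and 3.9 cm/s point-source
calcium waves, and a 130-nucleus orientation sample around 8.89 deg.
"""

import json
from pathlib import Path

import pandas as pd

from photopace import io as pio
from photopace import synthetic as syn
from photopace.types import MechanicalSpec

ROOT = Path(__file__).resolve().parents[1]
FIXDIR = ROOT / "scratch" / "fixtures"
RESDIR = ROOT / "results"
SEED = 20260929


def main() -> None:
    FIXDIR.mkdir(parents=True, exist_ok=True)
    RESDIR.mkdir(parents=True, exist_ok=True)
    mech = MechanicalSpec()
    px = mech.free_length_L / 500.0

    truth = {}
    for name, freq, twitch, seed in [
        ("spontaneous", 0.31, 5.4e3, SEED + 1),
        ("photopaced", 0.78, 5.4e3, SEED + 2),
        ("electrical", 1.00, 4.8e3, SEED + 3),
    ]:
        trace = syn.make_stress_trace(freq, 1e3, twitch, 30.0, 100.0)
        movie = syn.render_cantilever_movie(trace, mech, pixel_size=px,
                                            noise_sd=0.02, seed=seed)
        pio.write_movie(movie, FIXDIR / f"cantilever_{name}.tiff")
        truth[f"cantilever_{name}"] = {
            "frequency_hz": freq, "diastolic_pa": 1e3, "twitch_pa": twitch,
            "seed": seed, "n_frames": movie.n_frames,
        }
        print(f"cantilever_{name}: {freq} Hz, {twitch/1e3} kPa twitch, "
              f"{movie.n_frames} frames")

    for name, kind, speed, seed in [
        ("edge", "edge", 0.042, SEED + 4),
        ("point", "point", 0.039, SEED + 5),
    ]:
        loc = (12, 0) if kind == "edge" else (12, 25)
        field = syn.make_activation_field(24, 50, 1e-4, kind, loc, speed)
        movie = syn.render_calcium_movie(field, noise_sd=5.0, seed=seed)
        pio.write_movie(movie, FIXDIR / f"calcium_{name}.tiff")
        truth[f"calcium_{name}"] = {
            "speed_cm_s": 100 * speed, "source": kind, "seed": seed,
            "n_frames": movie.n_frames,
        }
        print(f"calcium_{name}: {100*speed} cm/s {kind} wave, {movie.n_frames} frames")

    kappa = syn.concentration_for_sem(0.75, 130)
    oset = syn.sample_orientations(130, 8.89, kappa, seed=SEED + 6)
    pd.DataFrame({"angle_deg": oset.angles}).to_csv(FIXDIR / "orientations.csv", index=False)
    truth["orientations"] = {"n": 130, "mean_deg": 8.89, "concentration": kappa,
                             "seed": SEED + 6}
    print(f"orientations: n=130, mean 8.89 deg, von Mises concentration {kappa:.2f}")

    rows = []
    for duty in (0.50, 0.15):
        train = syn.make_stimulus_train(1.0, duty, 180.0)
        rows.append({"frequency_hz": 1.0, "duty_cycle": duty,
                     "pulse_width_ms": 1e3 * train.pulse_width,
                     "n_pulses": train.n_pulses,
                     "light_on_s": train.cumulative_on_time})
        print(f"stimulus 1 Hz @ {duty:.0%} duty -> {1e3*train.pulse_width:.0f} ms pulses")
    pd.DataFrame(rows).to_csv(RESDIR / "stimulus_trains.csv", index=False)

    (RESDIR / "fixture_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    print(f"\nmovies in {FIXDIR}, truth in {RESDIR/'fixture_truth.json'}")


if __name__ == "__main__":
    main()
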