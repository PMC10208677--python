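import numpy as np
import pytest

from photopace import MechanicalSpec
from photopace import synthetic as syn


@pytest.fixture(scope="session")
def mech() -> MechanicalSpec:
    return MechanicalSpec()


def make_cantilever_fixture(
    mech: MechanicalSpec,
    frequency: float = 1.0,
    diastolic: float = 1e3,
    twitch: float = 5.4e3,
    duration: float = 30.0,
    frame_rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Render a cantilever movie from a known stress trace (truth returned)."""
    trace = syn.make_stress_trace(frequency, diastolic, twitch, duration, frame_rate)
    movie = syn.render_cantilever_movie(
        trace, mech, pixel_size=mech.free_length_L / 500.0, noise_sd=noise_sd, seed=seed
    )
    return trace, movie


def make_calcium_fixture(
    speed: float = 0.042,
    source_kind: str = "edge",
    rows: int = 24,
    cols: int = 50,
    pixel_size: float = 1e-4,
    noise_sd: float = 5.0,
    seed: int = 0,
    n_beats: int = 3,
):
    """Render a calcium movie from a known activation field (truth returned)."""
    loc = (rows // 2, 0) if source_kind == "edge" else (rows // 2, cols // 2)
    field = syn.make_activation_field(rows, cols, pixel_size, source_kind, loc, speed)
    movie = syn.render_calcium_movie(field, n_beats=n_beats, noise_sd=noise_sd, seed=seed)
    return field, movie


@pytest.fixture(scope="session")
def edge_calcium():
    return make_calcium_fixture(speed=0.042, source_kind="edge", seed=3)


@pytest.fixture(scope="session")
def point_calcium():
    return make_calcium_fixture(speed=0.039, source_kind="point", seed=4)


def axial_difference(a: float, b: float) -> float:
    """Smallest signed axial (180°-periodic) angular difference a − b."""
    return float((np.asarray(a) - b + 90.0) % 180.0 - 90.0)
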