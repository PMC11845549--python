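import numpy as np
import pytest

from vrgaze.io import GazeRecording


def make_recording(
    t,
    hit_points=None,
    eye_origin=None,
    eye_dir=None,
    valid=None,
    hit_object=None,
    rate=90.0,
):
    """Build a small recording with sensible defaults for unit tests."""
    t = np.asarray(t, dtype=float)
    n = t.size
    if eye_origin is None:
        eye_origin = np.zeros((n, 3))
    eye_origin = np.asarray(eye_origin, dtype=float)
    if hit_points is None:
        hit_points = np.tile([0.0, 0.0, 10.0], (n, 1))
    hit_points = np.asarray(hit_points, dtype=float)
    if eye_dir is None:
        vec = hit_points - eye_origin
        with np.errstate(invalid="ignore"):
            eye_dir = vec / np.linalg.norm(vec, axis=1, keepdims=True)
        eye_dir[np.any(np.isnan(eye_dir), axis=1)] = [0.0, 0.0, 1.0]
    if valid is None:
        valid = np.ones(n, dtype=bool)
    if hit_object is None:
        hit_object = np.full(n, "wall", dtype=object)
        hit_object[np.any(np.isnan(hit_points), axis=1)] = None
    return GazeRecording(
        t=t,
        eye_origin=eye_origin,
        eye_dir=np.asarray(eye_dir, dtype=float),
        head_pos=eye_origin.copy(),
        head_dir=np.asarray(eye_dir, dtype=float).copy(),
        hit_point=hit_points,
        hit_object=np.asarray(hit_object, dtype=object),
        valid=np.asarray(valid, dtype=bool),
        provenance=np.zeros(n, dtype=np.int8),
        nominal_rate=rate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A 60-s clean simulated recording shared across tests."""
    from vrgaze.synthetic import SimulationConfig, simulate_scanpath

    cfg = SimulationConfig(duration=60.0, seed=7)
    rec, truth = simulate_scanpath(cfg)
    return cfg, rec, truth
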