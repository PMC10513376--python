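import numpy as np
import pytest

from kinapse.track_io import Dataset, Track


def make_track(
    n_points=10,
    track_id="c0",
    experiment_id="exp0",
    start=(0.0, 0.0, 0.0),
    step=(1.0, 0.0, 0.0),
    labels=None,
    first_frame=1,
    rng=None,
    noise=0.0,
):
    """Straight-line track with optional positional noise."""
    pos = np.asarray(start, dtype=float) + np.outer(
        np.arange(n_points), np.asarray(step, dtype=float)
    )
    if noise and rng is not None:
        pos = pos + rng.normal(0.0, noise, pos.shape)
    if labels is not None and isinstance(labels, str):
        labels = [labels] * n_points
    return Track(
        track_id=track_id,
        experiment_id=experiment_id,
        frames=np.arange(first_frame, first_frame + n_points),
        positions=pos,
        labels=None if labels is None else np.asarray(labels, dtype=object),
    )


def random_track(rng, n_points=12, track_id="c0", experiment_id="exp0", scale=3.0):
    pos = np.cumsum(rng.normal(0.0, scale, (n_points, 3)), axis=0)
    return Track(
        track_id=track_id,
        experiment_id=experiment_id,
        frames=np.arange(1, n_points + 1),
        positions=pos,
        labels=np.asarray(["scanning"] * n_points, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset():
    return Dataset(
        [
            make_track(10, "c0", "expA", labels="poking"),
            make_track(10, "c1", "expA", start=(5.0, 5.0, 0.0), labels="scanning"),
            make_track(8, "c0", "expB", start=(1.0, 2.0, 0.0), labels="dancing"),
        ],
        name="small",
    )
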