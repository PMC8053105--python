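import numpy as np
import pandas as pd
import pytest

from rmdynamics.simulate.tracks import TrackSet


def make_trackset(coords, frame_interval=0.02, cell_id="cell0", geometries=None):
    """Build a TrackSet from {track_id: [(x, y), ...]} literals."""
    frames = []
    for tid, xy in coords.items():
        xy = np.asarray(xy, dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "cell_id": cell_id,
                    "frame": np.arange(len(xy)),
                    "t_s": np.arange(len(xy)) * frame_interval,
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                }
            )
        )
    return TrackSet(
        table=pd.concat(frames, ignore_index=True),
        frame_interval=frame_interval,
        geometries=geometries or {},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
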