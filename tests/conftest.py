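import numpy as np
import pandas as pd
import pytest

from myxoquant.datatypes import TRACK_COLUMNS, TrajectorySet


def make_trajectory_set(rows, frame_interval=10.0, arena=None,
                        provenance="ground_truth"):
    """Build a TrajectorySet from (track_id, frame, x, y, length, width) tuples."""
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                     "length_um", "width_um"])
    df["orientation_rad"] = 0.0
    df["area_um2"] = np.nan
    df["speed_um_min"] = np.nan
    df["gap_flag"] = False
    return TrajectorySet(data=df[TRACK_COLUMNS], frame_interval=frame_interval,
                         arena=arena, provenance=provenance)


@pytest.fixture
def empty_trajectories():
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in TRACK_COLUMNS})
    df["gap_flag"] = df["gap_flag"].astype(bool)
    return TrajectorySet(data=df, frame_interval=10.0, arena=(50.0, 50.0))
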