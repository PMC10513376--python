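"""The 90-feature sliding-window representation of cell motion.

Each (cell, timepoint) sample carries 29 per-timepoint base features
(kinematics from the track positions plus nearest-neighbor distances
within the experiment's field) and 61 engineered features from a 5-point
moving window centered on the timepoint: the mean and variance of every
base feature, the net displacement across the window, the cumulative path
length inside it, and the coast coefficient — the fraction of window
points whose speed is below a fixed threshold of 1/30 um/s.

Edge rule: timepoints too close to a track's ends to own a full window
copy the first/last fully computed window's values.

Canonical feature order is base block, mean block, variance block, then
the three window scalars; ``FEATURE_NAMES`` is the single source of truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from kinapse.track_io import Dataset, Track

logger = logging.getLogger(__name__)

#: default coasting speed threshold, um/s (= 2 um/min at 1 frame/min)
COAST_THRESHOLD = 1.0 / 30.0

#: the 29 per-timepoint base features, canonical order
BASE_FEATURES: list[str] = [
    "acceleration_x",
    "acceleration_y",
    "acceleration_z",
    "acceleration_global",
    "delta_displacement_x",
    "delta_displacement_y",
    "delta_displacement_z",
    "delta_displacement_length",
    "displacement_x",
    "displacement_y",
    "displacement_z",
    "displacement_length",
    "distance_from_origin",
    "position_x",
    "position_y",
    "position_z",
    "elapsed_time_track",
    "elapsed_time_prev",
    "velocity_x",
    "velocity_y",
    "velocity_z",
    "speed",
    "velocity_angle_x",
    "velocity_angle_y",
    "velocity_angle_z",
    "dist_nearest_1",
    "avg_dist_nearest_3",
    "avg_dist_nearest_5",
    "avg_dist_nearest_9",
]

WINDOW_SCALARS: list[str] = [
    "total_window_displacement",
    "cumulative_track_length",
    "coast_coefficient",
]

#: all 90 features: 29 base + 29 window means + 29 window variances + 3 scalars
FEATURE_NAMES: list[str] = (
    BASE_FEATURES
    + [f"mean_{f}" for f in BASE_FEATURES]
    + [f"var_{f}" for f in BASE_FEATURES]
    + WINDOW_SCALARS
)

KEY_COLUMNS = ["experiment_id", "track_id", "frame"]


@dataclass(frozen=True)
class WindowSpec:
    """Centered moving window over a track: 5 points wide, 1-point step."""

    width_points: int = 5
    center: bool = True
    step_points: int = 1

    def __post_init__(self) -> None:
        if self.width_points < 1 or self.width_points % 2 == 0:
            raise ValueError(f"width_points must be odd and >= 1, got {self.width_points}")
        if self.step_points < 1:
            raise ValueError(f"step_points must be >= 1, got {self.step_points}")


@dataclass
class FeatureMatrix:
    """One row per retained (track, timepoint); exactly 90 feature columns.

    ``data`` holds the key columns (experiment_id, track_id, frame), an
    optional ``label`` column, and the features in canonical order.
    """

    data: pd.DataFrame
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray | None:
        if "label" not in self.data.columns or self.data["label"].isna().all():
            return None
        return self.data["label"].to_numpy(dtype=object)

    @property
    def groups(self) -> np.ndarray:
        return self.data["experiment_id"].to_numpy(dtype=object)

    def restrict(self, experiment_ids) -> "FeatureMatrix":
        mask = self.data["experiment_id"].isin(set(experiment_ids))
        return FeatureMatrix(self.data.loc[mask].reset_index(drop=True), list(self.feature_names))

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write the matrix; the sidecar lists feature names in canonical order."""
        self.data.to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                fh.write("\n".join(self.feature_names) + "\n")

    @classmethod
    def from_csv(cls, path, sidecar_path=None) -> "FeatureMatrix":
        data = pd.read_csv(
            path, dtype={"experiment_id": str, "track_id": str}
        )
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                names = [ln.strip() for ln in fh if ln.strip()]
        else:
            names = [c for c in data.columns if c in set(FEATURE_NAMES)]
        return cls(data, names)


def compute_kinematics(track: Track) -> pd.DataFrame:
    """Per-timepoint kinematic features of one track (neighbor columns unset).

    Velocity is a central difference at interior points and one-sided at the
    endpoints; acceleration applies the same scheme to velocity.  Velocity
    angles are the angle (degrees, [0, 180]) between the velocity vector and
    each axis; where speed is zero the angle is undefined and a 90-degree
    sentinel is used.
    """
    if track.n_points < 2:
        raise ValueError(
            f"track {track.track_id!r} has {track.n_points} point(s); "
            "need >= 2 to define velocity (short tracks should be filtered)"
        )
    pos = track.positions
    t = track.times

    vel = np.gradient(pos, t, axis=0)
    acc = np.gradient(vel, t, axis=0)
    speed = np.linalg.norm(vel, axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = np.clip(vel / speed[:, None], -1.0, 1.0)
    angles = np.degrees(np.arccos(cosines))
    angles[speed == 0.0] = 90.0  # undefined direction: sentinel

    delta = np.diff(pos, axis=0, prepend=pos[:1])
    disp = pos - pos[0]
    elapsed_prev = np.diff(t, prepend=t[0])
    elapsed_prev[0] = track.frame_interval_s  # nominal interval at track start

    out = pd.DataFrame(
        {
            "acceleration_x": acc[:, 0],
            "acceleration_y": acc[:, 1],
            "acceleration_z": acc[:, 2],
            "acceleration_global": np.linalg.norm(acc, axis=1),
            "delta_displacement_x": delta[:, 0],
            "delta_displacement_y": delta[:, 1],
            "delta_displacement_z": delta[:, 2],
            "delta_displacement_length": np.linalg.norm(delta, axis=1),
            "displacement_x": disp[:, 0],
            "displacement_y": disp[:, 1],
            "displacement_z": disp[:, 2],
            "displacement_length": np.linalg.norm(disp, axis=1),
            "distance_from_origin": np.linalg.norm(disp, axis=1),
            "position_x": pos[:, 0],
            "position_y": pos[:, 1],
            "position_z": pos[:, 2],
            "elapsed_time_track": t - t[0],
            "elapsed_time_prev": elapsed_prev,
            "velocity_x": vel[:, 0],
            "velocity_y": vel[:, 1],
            "velocity_z": vel[:, 2],
            "speed": speed,
            "velocity_angle_x": angles[:, 0],
            "velocity_angle_y": angles[:, 1],
            "velocity_angle_z": angles[:, 2],
        }
    )
    return out


def compute_neighbor_features(ds: Dataset, fallback: float | None = None) -> pd.DataFrame:
    """Distances from each cell to its nearest neighbors, per (track, frame).

    Neighbors are the other cells of the same experiment present at the same
    frame.  ``avg_dist_nearest_k`` averages the k smallest distances, or all
    available when fewer than k neighbors exist.  A cell alone in its frame
    takes ``fallback`` for every neighbor feature (default: the diagonal of
    the experiment's positional bounding box).
    """
    rows = []
    for t in ds.tracks:
        rows.append(
            pd.DataFrame(
                {
                    "experiment_id": t.experiment_id,
                    "track_id": t.track_id,
                    "frame": t.frames,
                    "_x": t.positions[:, 0],
                    "_y": t.positions[:, 1],
                    "_z": t.positions[:, 2],
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=KEY_COLUMNS + ["dist_nearest_1", "avg_dist_nearest_3",
                                   "avg_dist_nearest_5", "avg_dist_nearest_9"]
        )
    long = pd.concat(rows, ignore_index=True)

    ks = (3, 5, 9)
    cols = {k: np.empty(len(long)) for k in (1, *ks)}

    for exp_id, exp_df in long.groupby("experiment_id", sort=False):
        if fallback is None:
            p = exp_df[["_x", "_y", "_z"]].to_numpy()
            exp_fallback = float(np.linalg.norm(p.max(axis=0) - p.min(axis=0)))
        else:
            exp_fallback = float(fallback)
        for _, frame_df in exp_df.groupby("frame", sort=False):
            idx = frame_df.index.to_numpy()
            m = len(idx)
            if m == 1:
                for k in (1, *ks):
                    cols[k][idx] = exp_fallback
                continue
            p = frame_df[["_x", "_y", "_z"]].to_numpy()
            d = cdist(p, p)
            np.fill_diagonal(d, np.inf)
            d.sort(axis=1)
            cols[1][idx] = d[:, 0]
            for k in ks:
                kk = min(k, m - 1)
                cols[k][idx] = d[:, :kk].mean(axis=1)

    out = long[KEY_COLUMNS].copy()
    out["dist_nearest_1"] = cols[1]
    for k in ks:
        out[f"avg_dist_nearest_{k}"] = cols[k]
    return out


def window_aggregate(
    base: pd.DataFrame,
    spec: WindowSpec | None = None,
    coast_threshold: float = COAST_THRESHOLD,
) -> pd.DataFrame:
    """Engineered window features for one track's base-feature table.

    ``base`` must carry all 29 base features for one track, one row per
    timepoint in frame order.  Returns a frame with the 61 engineered
    columns aligned with ``base`` (every ``step_points``-th row when the
    step exceeds 1).  Window variance uses the n-1 divisor.
    """
    spec = spec or WindowSpec()
    w = spec.width_points
    n = len(base)
    if n < w:
        raise ValueError(f"track has {n} points; window needs >= {w}")
    missing = [c for c in BASE_FEATURES if c not in base.columns]
    if missing:
        raise ValueError(f"base feature table missing columns: {missing}")

    half = w // 2
    feats = base[BASE_FEATURES]
    roll = feats.rolling(w, center=True, min_periods=w)
    means = roll.mean()
    variances = roll.var(ddof=1)
    means.columns = [f"mean_{c}" for c in BASE_FEATURES]
    variances.columns = [f"var_{c}" for c in BASE_FEATURES]

    pos = base[["position_x", "position_y", "position_z"]].to_numpy(dtype=np.float64)
    twd = np.full(n, np.nan)
    twd[half : n - half] = np.linalg.norm(pos[w - 1 :] - pos[: n - w + 1], axis=1)

    ctl = (
        base["delta_displacement_length"]
        .rolling(w, center=True, min_periods=w)
        .sum()
        .to_numpy()
    )
    coast = (
        (base["speed"] < coast_threshold)
        .astype(np.float64)
        .rolling(w, center=True, min_periods=w)
        .mean()
        .to_numpy()
    )

    out = pd.concat(
        [
            means.reset_index(drop=True),
            variances.reset_index(drop=True),
            pd.DataFrame(
                {
                    "total_window_displacement": twd,
                    "cumulative_track_length": ctl,
                    "coast_coefficient": coast,
                }
            ),
        ],
        axis=1,
    )
    # edge rows copy the first/last fully computed window
    out = out.bfill().ffill()
    if spec.step_points > 1:
        out = out.iloc[:: spec.step_points].reset_index(drop=True)
    return out


def assemble_feature_matrix(
    ds: Dataset,
    spec: WindowSpec | None = None,
    coast_threshold: float = COAST_THRESHOLD,
    neighbor_fallback: float | None = None,
    require_labels: bool = False,
) -> FeatureMatrix:
    """Full 90-feature matrix for a filtered dataset.

    Expects every track to have at least the window width's worth of
    points (apply :func:`kinapse.track_io.filter_short_tracks` first).
    With ``require_labels`` every timepoint must carry a behavior label
    (training mode); otherwise labels are attached where present.
    """
    spec = spec or WindowSpec()
    neigh = compute_neighbor_features(ds, fallback=neighbor_fallback)
    neigh = neigh.set_index(KEY_COLUMNS)

    blocks = []
    for t in ds.sorted_tracks():
        kin = compute_kinematics(t)
        key = pd.MultiIndex.from_arrays(
            [np.repeat(t.experiment_id, t.n_points),
             np.repeat(t.track_id, t.n_points),
             t.frames],
            names=KEY_COLUMNS,
        )
        base = pd.concat([kin.set_axis(key), neigh.loc[key]], axis=1)
        base = base.reset_index(drop=True)
        eng = window_aggregate(base, spec, coast_threshold)
        step = spec.step_points
        keys = pd.DataFrame(
            {
                "experiment_id": t.experiment_id,
                "track_id": t.track_id,
                "frame": t.frames[::step],
            }
        )
        if t.labels is not None:
            keys["label"] = t.labels[::step]
        else:
            if require_labels:
                raise ValueError(
                    f"track {t.track_id!r} (experiment {t.experiment_id!r}) is "
                    "unlabeled but labels are required"
                )
            keys["label"] = pd.NA
        block = pd.concat(
            [keys, base.iloc[::step].reset_index(drop=True), eng], axis=1
        )
        if require_labels and block["label"].isna().any():
            raise ValueError(
                f"track {t.track_id!r} has unlabeled timepoints but labels are required"
            )
        blocks.append(block)

    if not blocks:
        data = pd.DataFrame(columns=KEY_COLUMNS + ["label"] + FEATURE_NAMES)
    else:
        data = pd.concat(blocks, ignore_index=True)
    data = data[KEY_COLUMNS + ["label"] + FEATURE_NAMES]
    return FeatureMatrix(data, list(FEATURE_NAMES))
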