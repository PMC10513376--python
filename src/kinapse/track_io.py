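"""Reading, merging, filtering and labeling of cell-track tables.

Tracks arrive as CSV files in an Imaris-export-like dialect: one row per
(track, timepoint) with positions in micrometers and an optional behavior
annotation.  This module enforces the data model that every downstream
stage assumes: frames within a track are consecutive and unique, time is
track-relative seconds at a nominal 1-minute frame interval, and
(experiment, track) pairs are unique within a dataset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: raw behavior annotations accepted on input
RAW_LABELS = frozenset({"poking", "round", "dancing", "scanning"})
#: the three visually identified behaviors used for classification
THREE_CLASS_LABELS = ("poking", "dancing", "scanning")
#: established contact classes
BINARY_LABELS = ("synapse", "kinapse")

#: raw label -> three-class behavior ("round" cells are morphologically
#: distinct poking cells; positional features cannot separate them)
THREE_CLASS_MAP = {
    "poking": "poking",
    "round": "poking",
    "dancing": "dancing",
    "scanning": "scanning",
}
#: raw label -> binary contact class
BINARY_MAP = {
    "poking": "synapse",
    "round": "synapse",
    "dancing": "kinapse",
    "scanning": "kinapse",
}


class TrackFormatError(ValueError):
    """A required column is missing or the file cannot be parsed."""


class TrackValidationError(ValueError):
    """A track violates the frame ordering/uniqueness invariants."""


class MergeError(ValueError):
    """Two datasets collide on an (experiment_id, track_id) pair."""


class LabelError(ValueError):
    """An unrecognized behavior label was encountered."""


@dataclass(frozen=True)
class DialectConfig:
    """Column naming and layout of the track CSV dialect.

    ``header_rows`` counts header lines before the data; only the first is
    used for column names.  Columns whose name matches ``channel_pattern``
    (fluorescence channel statistics) are dropped on read.
    """

    track_id: str = "TrackID"
    frame: str = "Frame"
    x: str = "PositionX"
    y: str = "PositionY"
    z: str = "PositionZ"
    behavior: str = "Behavior"
    experiment: str = "ExperimentID"
    donor: str = "DonorID"
    disease: str = "Disease"
    treatment: str = "Treatment"
    header_rows: int = 1
    channel_pattern: str = r"Channel|Intensity"
    frame_interval_s: float = 60.0

    @classmethod
    def from_dict(cls, d: dict) -> "DialectConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class Track:
    """One cell's ordered positional samples plus metadata.

    ``times`` holds track-relative seconds: ``60 * (frame - first_frame)``
    at the nominal 1-minute interval (wall-clock offsets are discarded).
    ``labels`` is ``None`` for unlabeled tracks, else one behavior string
    per timepoint (behavior may change along a track).
    """

    track_id: str
    experiment_id: str
    frames: np.ndarray
    positions: np.ndarray
    labels: np.ndarray | None = None
    donor_id: str = ""
    disease: str = ""
    treatment: str = ""
    frame_interval_s: float = 60.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrackValidationError(
                f"track {self.track_id!r}: positions must be (n, 3), "
                f"got {self.positions.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.frames):
                raise TrackValidationError(
                    f"track {self.track_id!r}: {len(self.labels)} labels for "
                    f"{len(self.frames)} frames"
                )
        self.validate()

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Track-relative seconds since the track's first frame."""
        return self.frame_interval_s * (self.frames - self.frames[0]).astype(np.float64)

    def validate(self) -> None:
        if self.n_points == 0:
            raise TrackValidationError(f"track {self.track_id!r}: empty")
        diffs = np.diff(self.frames)
        if np.any(diffs <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r} (experiment {self.experiment_id!r}): "
                "frames not strictly increasing"
            )
        if np.any(diffs != 1):
            raise TrackValidationError(
                f"track {self.track_id!r} (experiment {self.experiment_id!r}): "
                "gap in frame sequence"
            )

    def copy(self) -> "Track":
        return replace(
            self,
            frames=self.frames.copy(),
            positions=self.positions.copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )


@dataclass
class Dataset:
    """A named collection of tracks with unique (experiment, track) keys."""

    tracks: list[Track] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        keys = [(t.experiment_id, t.track_id) for t in self.tracks]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str]] = set()
            for k in keys:
                if k in seen:
                    raise MergeError(f"duplicate (experiment, track) pair: {k}")
                seen.add(k)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def experiment_ids(self) -> list[str]:
        return sorted({t.experiment_id for t in self.tracks})

    def sorted_tracks(self) -> list[Track]:
        return sorted(self.tracks, key=lambda t: (t.experiment_id, t.track_id))

    def copy(self, name: str | None = None) -> "Dataset":
        return Dataset([t.copy() for t in self.tracks], name=name or self.name)


def read_tracks(
    path, dialect: DialectConfig | None = None, name: str | None = None
) -> Dataset:
    """Read a track CSV into a :class:`Dataset`.

    Rows are grouped by (experiment, track) and sorted by frame; columns
    matching the dialect's channel pattern are dropped.  Missing z is
    accepted (filled with 0, for 2-D acquisitions); missing experiment id
    defaults to ``"exp0"``.
    """
    dialect = dialect or DialectConfig()
    skip = max(dialect.header_rows - 1, 0)
    df = pd.read_csv(path, skiprows=range(1, 1 + skip) if skip else None)

    chan_re = re.compile(dialect.channel_pattern)
    dropped = [c for c in df.columns if chan_re.search(str(c))]
    if dropped:
        df = df.drop(columns=dropped)
        logger.debug("dropped %d channel-related columns: %s", len(dropped), dropped)

    for col in (dialect.track_id, dialect.frame, dialect.x, dialect.y):
        if col not in df.columns:
            raise TrackFormatError(f"missing required column {col!r} in {path}")
    if dialect.z not in df.columns:
        logger.warning("no %r column; assuming 2-D acquisition, z = 0", dialect.z)
        df[dialect.z] = 0.0
    if dialect.experiment not in df.columns:
        df[dialect.experiment] = "exp0"

    def _meta(g: pd.DataFrame, col: str) -> str:
        return str(g[col].iloc[0]) if col in g.columns else ""

    tracks = []
    for (exp_id, tid), g in df.groupby([dialect.experiment, dialect.track_id], sort=True):
        g = g.sort_values(dialect.frame)
        frames = g[dialect.frame].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) == 0):
            raise TrackValidationError(
                f"track {tid!r} (experiment {exp_id!r}): duplicated frames"
            )
        labels = None
        if dialect.behavior in g.columns and g[dialect.behavior].notna().any():
            labels = g[dialect.behavior].astype(object).to_numpy()
        tracks.append(
            Track(
                track_id=str(tid),
                experiment_id=str(exp_id),
                frames=frames,
                positions=g[[dialect.x, dialect.y, dialect.z]].to_numpy(dtype=np.float64),
                labels=labels,
                donor_id=_meta(g, dialect.donor),
                disease=_meta(g, dialect.disease),
                treatment=_meta(g, dialect.treatment),
                frame_interval_s=dialect.frame_interval_s,
            )
        )
    import os

    return Dataset(tracks, name=name or os.path.splitext(os.path.basename(str(path)))[0])


def to_frame(ds: Dataset, dialect: DialectConfig | None = None) -> pd.DataFrame:
    """Flatten a dataset to the one-row-per-(track, timepoint) table."""
    dialect = dialect or DialectConfig()
    parts = []
    for t in ds.sorted_tracks():
        part = pd.DataFrame(
            {
                dialect.experiment: t.experiment_id,
                dialect.track_id: t.track_id,
                dialect.frame: t.frames,
                dialect.x: t.positions[:, 0],
                dialect.y: t.positions[:, 1],
                dialect.z: t.positions[:, 2],
                dialect.donor: t.donor_id,
                dialect.disease: t.disease,
                dialect.treatment: t.treatment,
            }
        )
        part[dialect.behavior] = t.labels if t.labels is not None else pd.NA
        parts.append(part)
    if not parts:
        cols = [
            dialect.experiment, dialect.track_id, dialect.frame,
            dialect.x, dialect.y, dialect.z,
            dialect.donor, dialect.disease, dialect.treatment, dialect.behavior,
        ]
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)


def write_tracks(ds: Dataset, path, dialect: DialectConfig | None = None) -> None:
    """Write a dataset as CSV in the configured dialect (round-trips read_tracks)."""
    to_frame(ds, dialect).to_csv(path, index=False)


def filter_short_tracks(ds: Dataset, min_points: int = 5) -> Dataset:
    """Drop tracks shorter than ``min_points`` timepoints (< 300 s at 1 frame/min)."""
    if min_points < 1:
        raise ValueError(f"min_points must be >= 1, got {min_points}")
    kept = [t.copy() for t in ds.tracks if t.n_points >= min_points]
    return Dataset(kept, name=ds.name)


def merge_datasets(ds_list: list[Dataset], name: str = "merged") -> Dataset:
    """Union of tracks across datasets; (experiment, track) collisions are errors."""
    seen: set[tuple[str, str]] = set()
    tracks: list[Track] = []
    for ds in ds_list:
        for t in ds.tracks:
            key = (t.experiment_id, t.track_id)
            if key in seen:
                raise MergeError(f"(experiment, track) collision on {key}")
            seen.add(key)
            tracks.append(t.copy())
    return Dataset(tracks, name=name)


def map_labels(ds: Dataset, scheme: str) -> Dataset:
    """Remap raw behavior labels to a classification scheme.

    ``three_class``: round -> poking, others unchanged.
    ``binary``: poking/round -> synapse; dancing/scanning -> kinapse.
    Unlabeled tracks pass through untouched.
    """
    if scheme not in ("binary", "three_class"):
        raise ValueError(f"unknown scheme {scheme!r}")
    mapping = BINARY_MAP if scheme == "binary" else THREE_CLASS_MAP
    out = []
    for t in ds.tracks:
        t = t.copy()
        if t.labels is not None:
            mapped = []
            for lab in t.labels:
                lab = str(lab).strip().lower()
                if lab not in mapping:
                    raise LabelError(f"unknown behavior label {lab!r} in track {t.track_id!r}")
                mapped.append(mapping[lab])
            t.labels = np.asarray(mapped, dtype=object)
        out.append(t)
    return Dataset(out, name=ds.name)
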