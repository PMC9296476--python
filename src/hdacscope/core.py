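"""Shared in-memory containers for images, frame schedules and kinetic parameters.

Conventions used throughout the package:

* world coordinates are RAS+ and voxel indices 0-based;
* images that must be combined (dynamic data, label maps, masks) are required
  to share their grid exactly — no implicit resampling is ever performed;
* missing values are NaN inside arrays/files and an explicit boolean mask in
  memory;
* all times are seconds unless a name says otherwise (SRTM rate constants are
  conventionally quoted per minute and carry ``_per_min`` or are documented).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "LabelMap",
    "StatImage",
    "KineticParams",
    "martinostat_frame_schedule",
]


def _as_affine(affine) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered acquisition frames of a dynamic scan.

    Parameters
    ----------
    starts : array of frame start times, seconds.
    durations : array of frame durations, seconds.

    Starts must be non-decreasing, durations positive and frames must not
    overlap.  Mid-frame times are derived, not stored.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise ValueError("starts and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ValueError("schedule needs at least one frame")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(starts) < 0):
            raise ValueError("frame starts must be non-decreasing")
        ends = starts + durations
        if np.any(starts[1:] - ends[:-1] < -1e-9):
            raise ValueError("frames must not overlap")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def mid_times(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    def to_array(self) -> np.ndarray:
        """(n_frames, 2) array of (start, duration), seconds."""
        return np.column_stack([self.starts, self.durations])

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        durations = np.asarray(durations, dtype=float)
        starts = t0 + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)


def martinostat_frame_schedule() -> FrameSchedule:
    """The 26-frame binning of a 0–90 min dynamic acquisition.

    6x10 s, 6x20 s, 2x30 s, 1x60 s, 5x300 s, 6x600 s — 26 frames covering
    5400 s in total; both counts are asserted on construction.
    """
    durations = np.concatenate(
        [
            np.full(6, 10.0),
            np.full(6, 20.0),
            np.full(2, 30.0),
            np.full(1, 60.0),
            np.full(5, 300.0),
            np.full(6, 600.0),
        ]
    )
    sched = FrameSchedule.from_durations(durations)
    assert sched.n_frames == 26
    assert sched.total_duration == 5400.0
    return sched


@dataclass
class DynamicImage:
    """4-D voxel array (x, y, z, frame) with its frame schedule and affine."""

    data: np.ndarray
    affine: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic data must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis ({self.data.shape[3]}) does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )
        self.affine = _as_affine(self.affine)

    @property
    def shape3d(self) -> tuple:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def frame_weighted_mean(self, frame_indices=None) -> np.ndarray:
        """Duration-weighted mean image over (a subset of) frames."""
        if frame_indices is None:
            frame_indices = np.arange(self.schedule.n_frames)
        frame_indices = np.asarray(frame_indices, dtype=int)
        w = self.schedule.durations[frame_indices]
        return np.tensordot(self.data[..., frame_indices], w / w.sum(), axes=(3, 0))


@dataclass
class LabelMap:
    """3-D integer region image; 0 is background."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("label map must be 3-D")
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(rounded, data):
                raise ValueError("label map must contain integers")
            data = rounded.astype(np.int32)
        if data.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.data = data
        self.affine = _as_affine(self.affine)

    @property
    def labels(self) -> np.ndarray:
        """Sorted non-background labels present in the map."""
        labs = np.unique(self.data)
        return labs[labs > 0]

    def mask(self, label) -> np.ndarray:
        labels = np.atleast_1d(label)
        return np.isin(self.data, labels)

    def voxel_count(self, label) -> int:
        return int(self.mask(label).sum())

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


# semantic tags a StatImage may carry
STAT_TAGS = ("SUVR", "R1", "k2", "BP", "t", "p", "beta", "AUC", "z", "activity")


@dataclass
class StatImage:
    """3-D float map with an explicit analysis mask and a semantic tag.

    Out-of-mask voxels are NaN in ``data``; ``mask`` is authoritative.
    """

    data: np.ndarray
    affine: np.ndarray
    tag: str = "activity"
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stat image must be 3-D")
        self.affine = _as_affine(self.affine)
        if self.tag not in STAT_TAGS:
            raise ValueError(f"unknown tag {self.tag!r}; expected one of {STAT_TAGS}")
        if self.mask is None:
            self.mask = np.isfinite(self.data)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data")
            self.data = np.where(self.mask, self.data, np.nan)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def in_mask(self) -> np.ndarray:
        """1-D array of in-mask voxel values."""
        return self.data[self.mask]


@dataclass(frozen=True)
class KineticParams:
    """SRTM parameter triplet.

    R1 is the target/reference ratio of the delivery constant K1 (unitless),
    k2 the target efflux rate (1/min), BP the binding potential (unitless).
    The apparent efflux rate k2a = k2 / (1 + BP) is derived.
    """

    R1: float
    k2_per_min: float
    BP: float
    degenerate: bool = False

    def __post_init__(self):
        if not np.isfinite(self.R1):
            raise ValueError("R1 must be finite")
        if self.BP <= -1.0:
            raise ValueError("BP must exceed -1 for k2a to be defined")

    @property
    def k2a_per_min(self) -> float:
        return self.k2_per_min / (1.0 + self.BP)


def check_same_grid(*objs) -> None:
    """Raise if any pair of images/maps differs in shape or affine."""
    shapes = []
    affines = []
    for o in objs:
        shape = o.shape3d if hasattr(o, "shape3d") else o.data.shape[:3]
        shapes.append(shape)
        affines.append(o.affine)
    for s, a in zip(shapes[1:], affines[1:]):
        if s != shapes[0]:
            raise ValueError(f"grid shape mismatch: {s} vs {shapes[0]}")
        if not np.allclose(a, affines[0], atol=1e-6):
            raise ValueError("affine mismatch between paired inputs")
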