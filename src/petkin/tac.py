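"""Time-activity curves (TACs), frame schedules, ROI extraction and CSV I/O.

Conventions
-----------
* Frame timing is supplied by the user in **seconds**; all model mathematics
  runs in **minutes**.  The conversion happens in exactly one place: the
  ``midtimes_min`` / ``duration_min`` properties of :class:`FrameSchedule`.
* Activity values are decay-corrected concentrations (typically kBq/mL); they
  may be negative due to reconstruction noise and no model here assumes
  positivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .exceptions import DimensionError, FormatError, ScheduleError

__all__ = [
    "FrameSchedule",
    "TAC",
    "RegionalTACSet",
    "extract_regional_tacs",
    "midtimes_minutes",
    "frame_average_values",
    "read_tac_csv",
    "write_tac_csv",
]

#: tolerance (seconds) below which consecutive frames count as contiguous
_GAP_TOL_S = 1e-9


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame acquisition windows, in seconds post injection.

    Frames must be strictly increasing and non-overlapping
    (``start[i] < end[i] <= start[i+1]``); gaps between consecutive frames are
    allowed and represent dual-time-window acquisitions.
    """

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        end = np.asarray(self.end_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if start.ndim != 1 or end.ndim != 1 or start.size != end.size:
            raise ScheduleError("frame start/end must be parallel 1-D sequences")
        if start.size < 1:
            raise ScheduleError("schedule needs at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(end)):
            raise ScheduleError("frame times must be finite")
        if np.any(start < 0):
            raise ScheduleError("frame start times must be >= 0 s")
        if not np.all(start < end):
            raise ScheduleError("each frame must satisfy start < end")
        if start.size > 1 and not np.all(end[:-1] <= start[1:] + _GAP_TOL_S):
            raise ScheduleError("frames overlap: end[i] must be <= start[i+1]")

    # -- derived quantities -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    @property
    def duration_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0

    @property
    def midtimes_min(self) -> np.ndarray:
        """Frame mid-times in minutes, ``(start+end)/2/60``."""
        return (self.start_s + self.end_s) / 2.0 / 60.0

    @property
    def start_min(self) -> np.ndarray:
        return self.start_s / 60.0

    @property
    def end_min(self) -> np.ndarray:
        return self.end_s / 60.0

    @property
    def gaps_s(self) -> list[Tuple[float, float]]:
        """Intervals ``(end[i], start[i+1])`` in seconds where data is missing."""
        out = []
        for i in range(self.n_frames - 1):
            if self.start_s[i + 1] - self.end_s[i] > _GAP_TOL_S:
                out.append((float(self.end_s[i]), float(self.start_s[i + 1])))
        return out

    @property
    def has_gap(self) -> bool:
        return len(self.gaps_s) > 0

    def subset(self, index) -> "FrameSchedule":
        """Schedule restricted to the selected frames (boolean mask or indices)."""
        return FrameSchedule(self.start_s[index], self.end_s[index])

    def __len__(self) -> int:
        return self.n_frames


def midtimes_minutes(schedule: FrameSchedule) -> np.ndarray:
    """Frame mid-times in minutes (strictly increasing)."""
    return schedule.midtimes_min


@dataclass(frozen=True)
class TAC:
    """A time-activity curve: one activity value per frame of a schedule."""

    schedule: FrameSchedule
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise DimensionError(
                f"TAC has {values.size} values for {self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(values)):
            raise FormatError("TAC values must be finite")

    @property
    def midtimes_min(self) -> np.ndarray:
        return self.schedule.midtimes_min

    def subset(self, index) -> "TAC":
        return TAC(self.schedule.subset(index), self.values[index])

    def __len__(self) -> int:
        return self.schedule.n_frames


@dataclass(frozen=True)
class RegionalTACSet(Mapping):
    """Integer region label -> TAC, all sharing one schedule."""

    tacs: Dict[int, TAC]
    schedule: FrameSchedule = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.tacs:
            raise FormatError("RegionalTACSet needs at least one region")
        schedule = self.schedule
        if schedule is None:
            schedule = next(iter(self.tacs.values())).schedule
            object.__setattr__(self, "schedule", schedule)
        for label, tac in self.tacs.items():
            if not np.array_equal(tac.schedule.start_s, schedule.start_s) or not np.array_equal(
                tac.schedule.end_s, schedule.end_s
            ):
                raise ScheduleError(f"region {label} does not share the common schedule")

    @property
    def labels(self) -> list[int]:
        return sorted(self.tacs)

    def __getitem__(self, label: int) -> TAC:
        return self.tacs[label]

    def __iter__(self) -> Iterator[int]:
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.tacs)


def extract_regional_tacs(
    image4d: np.ndarray,
    parcellation: np.ndarray,
    schedule: FrameSchedule,
    labels: Sequence[int] | None = None,
) -> RegionalTACSet:
    """Mean TAC per parcellation label from a 4-D dynamic image.

    The regional value for each frame is the unweighted arithmetic mean over
    all voxels carrying that label.  Label 0 is background and ignored.

    Parameters
    ----------
    image4d : (X, Y, Z, T) array
    parcellation : (X, Y, Z) integer array on the same voxel grid
    schedule : frame timing; ``schedule.n_frames`` must equal T
    labels : optional explicit label list; defaults to all nonzero labels
        present in the parcellation.  Requested labels with no voxels are
        skipped with a warning.
    """
    image4d = np.asarray(image4d, dtype=float)
    parcellation = np.asarray(parcellation)
    if image4d.ndim != 4:
        raise DimensionError("image4d must be 4-dimensional")
    if parcellation.shape != image4d.shape[:3]:
        raise DimensionError(
            f"parcellation grid {parcellation.shape} does not match image grid "
            f"{image4d.shape[:3]}"
        )
    if image4d.shape[3] != schedule.n_frames:
        raise DimensionError(
            f"image has {image4d.shape[3]} frames but schedule has {schedule.n_frames}"
        )
    flat = image4d.reshape(-1, image4d.shape[3])
    lab = parcellation.ravel().astype(np.int64)
    if labels is None:
        wanted = [int(v) for v in np.unique(lab) if v != 0]
    else:
        wanted = [int(v) for v in labels]
    tacs: Dict[int, TAC] = {}
    for label in wanted:
        mask = lab == label
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"label {label} has no voxels; skipped", stacklevel=2)
            continue
        tacs[label] = TAC(schedule, flat[mask].sum(axis=0) / n)
    if not tacs:
        raise FormatError("no nonzero labels with voxels found")
    return RegionalTACSet(tacs, schedule)


def frame_average_values(t: np.ndarray, y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a piecewise-linear signal ``y(t)`` over each frame window.

    ``t`` is in minutes and should cover the schedule; outside its range the
    signal is held constant.  Frame boundaries are inserted as exact nodes so
    the trapezoidal average is exact for piecewise-linear ``y``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    s = schedule.start_min
    e = schedule.end_min
    grid = np.union1d(t, np.concatenate([s, e]))
    yg = np.interp(grid, t, y)
    big = cumulative_trapezoid(yg, grid, initial=0.0)
    fs = np.interp(s, grid, big)
    fe = np.interp(e, grid, big)
    return (fe - fs) / (e - s)


# -- CSV I/O ----------------------------------------------------------------

_CSV_COLUMNS = ("frame_start_s", "frame_end_s", "value")


def read_tac_csv(path) -> TAC:
    """Read a TAC from CSV with columns frame_start_s, frame_end_s, value."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse TAC CSV {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"TAC CSV {path} is missing columns: {missing}")
    schedule = FrameSchedule(df["frame_start_s"].to_numpy(float), df["frame_end_s"].to_numpy(float))
    return TAC(schedule, df["value"].to_numpy(float))


def write_tac_csv(tac: TAC, path) -> None:
    """Write a TAC to CSV; lossless round trip for finite doubles."""
    df = pd.DataFrame(
        {
            "frame_start_s": tac.schedule.start_s,
            "frame_end_s": tac.schedule.end_s,
            "value": tac.values,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
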