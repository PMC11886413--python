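"""Detection events and the occasions × cameras sampling grid.

Synchronised timelapse photography turns a camera fleet into a set of
instantaneous sampling occasions: every ``step`` (10 min in the reference
design) each active camera reports whether at least one animal of the
target classes is in its viewshed.  The resulting presence/absence grid,
together with per-camera sampled areas and an activity mask (deployment
intervals, theft, fire-damage outages), is everything the space-to-event
estimator needs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diel import DielPeriod, SolarDay, classify_timestamps


class AnimalClass(str, Enum):
    ADULT_FEMALE = "adult_female"
    ADULT_MALE = "adult_male"
    FAWN = "fawn"
    UNKNOWN_DEER = "unknown_deer"
    OTHER = "other"
    NONE = "none"


#: Classes pooled for an "all deer" density fit (unknown deer included).
DEER_CLASSES = frozenset(
    {
        AnimalClass.ADULT_FEMALE,
        AnimalClass.ADULT_MALE,
        AnimalClass.FAWN,
        AnimalClass.UNKNOWN_DEER,
    }
)


@dataclass(frozen=True)
class DetectionEvent:
    """One tagged timelapse image row: camera, timestamp, class, count."""

    camera_id: str
    timestamp: dt.datetime
    klass: AnimalClass
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "klass", AnimalClass(self.klass))
        if self.klass is AnimalClass.NONE:
            if self.count != 0:
                raise ValueError(
                    f"'none' rows carry count 0, got {self.count}"
                )
        elif self.count < 1:
            raise ValueError(
                f"count must be >= 1 for class {self.klass.value}, got {self.count}"
            )


@dataclass(frozen=True)
class Outage:
    """A declared window during which a camera was not sampling."""

    camera_id: str
    start: dt.datetime
    end: dt.datetime
    reason: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"outage end {self.end} not after start {self.start}")


class OccasionError(ValueError):
    """Invalid occasion-grid construction or filtering."""


@dataclass
class OccasionTable:
    """Occasions × cameras grid of presence, activity, and sampled areas.

    Attributes
    ----------
    occasion_times
        Strictly increasing local timestamps on a fixed step grid.
    camera_ids
        Ordered camera identifiers (deployment order).
    areas_m2
        Sampled area per camera, aligned with ``camera_ids``.
    active
        Boolean (n_occasions, n_cameras): camera operating at that occasion.
    presence
        Boolean (n_occasions, n_cameras): >= 1 target-class animal in view.
    """

    occasion_times: pd.DatetimeIndex
    camera_ids: list[str]
    areas_m2: np.ndarray
    active: np.ndarray
    presence: np.ndarray
    step: dt.timedelta = dt.timedelta(minutes=10)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.occasion_times = pd.DatetimeIndex(self.occasion_times)
        self.areas_m2 = np.asarray(self.areas_m2, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        self.presence = np.asarray(self.presence, dtype=bool)
        n_occ, n_cam = len(self.occasion_times), len(self.camera_ids)
        if self.areas_m2.shape != (n_cam,):
            raise OccasionError("areas_m2 must have one entry per camera")
        if self.active.shape != (n_occ, n_cam) or self.presence.shape != (n_occ, n_cam):
            raise OccasionError("active/presence must be (n_occasions, n_cameras)")
        if n_occ > 1:
            diffs = np.diff(self.occasion_times.view("int64"))
            if not (diffs > 0).all():
                raise OccasionError("occasion_times must be strictly increasing")
        if np.any(self.presence & ~self.active):
            raise OccasionError("presence recorded on an inactive camera-occasion")
        ever_active = self.active.any(axis=0)
        if np.any(ever_active & ~(self.areas_m2 > 0)):
            bad = [c for c, e, a in zip(self.camera_ids, ever_active, self.areas_m2)
                   if e and not a > 0]
            raise OccasionError(f"active cameras with non-positive area: {bad}")

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_times)

    @property
    def n_cameras(self) -> int:
        return len(self.camera_ids)

    def exposure_per_occasion(self) -> np.ndarray:
        """Total active sampled area A_j per occasion (m²)."""
        return self.active @ self.areas_m2

    def with_area_override(self, constant_area_m2: float) -> "OccasionTable":
        """Replace every camera's area with one constant (assumed viewshed).

        Models the no-field-measurement workflow: a single manufacturer-spec
        sector area applied fleet-wide regardless of landscape structure.
        """
        if not constant_area_m2 > 0:
            raise OccasionError(
                f"override area must be > 0, got {constant_area_m2!r}"
            )
        return replace(
            self,
            areas_m2=np.full(self.n_cameras, float(constant_area_m2)),
            meta={**self.meta, "area_override_m2": float(constant_area_m2)},
        )

    def filter_by_period(
        self,
        allowed: Iterable[DielPeriod | str],
        solar_days: Mapping[dt.date, SolarDay],
        buffer: dt.timedelta = dt.timedelta(hours=1),
    ) -> "OccasionTable":
        """Keep only occasions whose diel period is in ``allowed``.

        Cameras and areas are unchanged; an empty result is legal here and
        only errors at fit time.
        """
        allowed_set = {DielPeriod(p) for p in allowed}
        periods = classify_timestamps(
            self.occasion_times.to_pydatetime(), solar_days, buffer
        )
        keep = np.array([p in allowed_set for p in periods], dtype=bool)
        return replace(
            self,
            occasion_times=self.occasion_times[keep],
            active=self.active[keep],
            presence=self.presence[keep],
            meta={**self.meta, "period_filter": sorted(p.value for p in allowed_set)},
        )

    def subset_cameras(self, indices: Sequence[int]) -> "OccasionTable":
        """Restrict to the cameras at ``indices`` (order preserved, repeats
        allowed for bootstrap resampling)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise OccasionError("camera subset must be non-empty")
        if idx.min() < 0 or idx.max() >= self.n_cameras:
            raise OccasionError("camera subset index out of range")
        return replace(
            self,
            camera_ids=[self.camera_ids[i] for i in idx],
            areas_m2=self.areas_m2[idx],
            active=self.active[:, idx],
            presence=self.presence[:, idx],
        )


def occasion_grid(
    start: dt.datetime, end: dt.datetime, step: dt.timedelta = dt.timedelta(minutes=10)
) -> pd.DatetimeIndex:
    """Fixed-step occasion timestamps in [start, end]."""
    if step <= dt.timedelta(0):
        raise OccasionError(f"step must be positive, got {step!r}")
    return pd.date_range(start, end, freq=step)


def build_occasion_table(
    detections: Sequence[DetectionEvent],
    viewshed_areas_m2: Mapping[str, float],
    schedule: tuple[dt.datetime, dt.datetime, dt.timedelta],
    target_classes: Iterable[AnimalClass | str] = DEER_CLASSES,
    match_tolerance: dt.timedelta = dt.timedelta(seconds=60),
    active_intervals: Mapping[str, tuple[dt.datetime, dt.datetime]] | None = None,
    outages: Sequence[Outage] = (),
) -> OccasionTable:
    """Assemble the occasions × cameras grid from tagged timelapse rows.

    A detection marks presence at the occasion whose timestamp is within
    ``match_tolerance`` of it (timelapse stamps should land exactly on the
    grid; the tolerance absorbs clock drift).  Duplicate detections at one
    camera-occasion merge.  Cells outside a camera's active interval or
    inside a declared outage window are inactive, carry no exposure, and may
    not carry presence; detections falling there are dropped.

    ``viewshed_areas_m2`` keys define the fleet and its column order.
    """
    start, end, step = schedule
    times = occasion_grid(start, end, step)
    camera_ids = list(viewshed_areas_m2.keys())
    cam_index = {c: i for i, c in enumerate(camera_ids)}
    areas = np.array([float(viewshed_areas_m2[c]) for c in camera_ids])
    n_occ, n_cam = len(times), len(camera_ids)

    active = np.ones((n_occ, n_cam), dtype=bool)
    times_ns = times.view("int64")
    if active_intervals:
        for cam, (a_start, a_end) in active_intervals.items():
            if cam not in cam_index:
                raise OccasionError(f"active interval for unknown camera {cam!r}")
            col = cam_index[cam]
            mask = (times_ns >= pd.Timestamp(a_start).value) & (
                times_ns <= pd.Timestamp(a_end).value
            )
            active[:, col] &= mask
    for outage in outages:
        if outage.camera_id not in cam_index:
            raise OccasionError(f"outage for unknown camera {outage.camera_id!r}")
        col = cam_index[outage.camera_id]
        mask = (times_ns >= pd.Timestamp(outage.start).value) & (
            times_ns <= pd.Timestamp(outage.end).value
        )
        active[mask, col] = False

    targets = {AnimalClass(c) for c in target_classes}
    presence = np.zeros((n_occ, n_cam), dtype=bool)
    tol_ns = int(match_tolerance.total_seconds() * 1e9)
    for det in detections:
        if det.camera_id not in cam_index:
            raise OccasionError(
                f"detection references unknown camera {det.camera_id!r}"
            )
        if det.klass not in targets:
            continue
        t_ns = pd.Timestamp(det.timestamp).value
        pos = int(np.searchsorted(times_ns, t_ns))
        best, best_diff = None, tol_ns + 1
        for cand in (pos - 1, pos):
            if 0 <= cand < n_occ:
                diff = abs(int(times_ns[cand]) - t_ns)
                if diff < best_diff:
                    best, best_diff = cand, diff
        if best is not None and best_diff <= tol_ns:
            col = cam_index[det.camera_id]
            if active[best, col]:
                presence[best, col] = True

    return OccasionTable(
        occasion_times=times,
        camera_ids=camera_ids,
        areas_m2=areas,
        active=active,
        presence=presence,
        step=step,
        meta={"target_classes": sorted(t.value for t in targets)},
    )


def filter_by_period(
    table: OccasionTable,
    allowed: Iterable[DielPeriod | str],
    solar_days: Mapping[dt.date, SolarDay],
    buffer: dt.timedelta = dt.timedelta(hours=1),
) -> OccasionTable:
    """Functional alias for :meth:`OccasionTable.filter_by_period`."""
    return table.filter_by_period(allowed, solar_days, buffer)


def apply_area_override(table: OccasionTable, constant_area_m2: float) -> OccasionTable:
    """Functional alias for :meth:`OccasionTable.with_area_override`."""
    return table.with_area_override(constant_area_m2)
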