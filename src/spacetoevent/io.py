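"""CSV/YAML readers and writers for the camera-trap data dialects.

Everything is plain CSV with a header row, the lingua franca of camera-trap
workflows:

detections
    ``camera_id, datetime, class, count`` — one row per tagged image, local
    ISO 8601 timestamps; class strings are mapped through a documented
    vocabulary (``AF`` → adult_female, ...).
viewsheds
    ``camera_id, phase, lens_angle_deg, r1..r6`` — one row per camera per
    measurement phase (deployment / retrieval), radii in metres.
cameras
    ``camera_id, lat, lon, active_start, active_end``.
outages
    ``camera_id, start, end, reason`` — declared non-sampling windows
    (theft, fire damage); outages are explicit input, never inferred.
sun times (optional)
    ``date, sunrise, sunset`` — accepted in place of computed solar events.

Writers emit byte-stable row ordering (camera id, then time).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .diel import SolarDay
from .occasions import AnimalClass, DetectionEvent, Outage
from .viewshed import MeasurementPhase, ViewshedError, ViewshedMeasurement

#: Documented class vocabulary for detection exports.  Keys are matched
#: case-insensitively; canonical enum values map to themselves.
CLASS_VOCABULARY: dict[str, AnimalClass] = {
    "af": AnimalClass.ADULT_FEMALE,
    "adult female": AnimalClass.ADULT_FEMALE,
    "adult_female": AnimalClass.ADULT_FEMALE,
    "am": AnimalClass.ADULT_MALE,
    "adult male": AnimalClass.ADULT_MALE,
    "adult_male": AnimalClass.ADULT_MALE,
    "f": AnimalClass.FAWN,
    "fawn": AnimalClass.FAWN,
    "ud": AnimalClass.UNKNOWN_DEER,
    "unknown deer": AnimalClass.UNKNOWN_DEER,
    "unknown_deer": AnimalClass.UNKNOWN_DEER,
    "o": AnimalClass.OTHER,
    "other": AnimalClass.OTHER,
    "none": AnimalClass.NONE,
    "blank": AnimalClass.NONE,
}


class DataFormatError(ValueError):
    """Malformed input file; message carries the offending row number."""


def _map_class(raw: str, row: int, vocabulary: Mapping[str, AnimalClass]) -> AnimalClass:
    key = str(raw).strip().lower()
    if key not in vocabulary:
        raise DataFormatError(f"row {row}: unknown class {raw!r}")
    return vocabulary[key]


def read_detections(
    path: str | Path,
    vocabulary: Mapping[str, AnimalClass] = CLASS_VOCABULARY,
) -> list[DetectionEvent]:
    """Read a detections CSV into typed, validated records."""
    df = pd.read_csv(path, dtype={"camera_id": str})
    required = {"camera_id", "datetime", "class", "count"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"detections file missing columns {sorted(missing)}")
    events = []
    rows = df[["camera_id", "datetime", "class", "count"]].itertuples(
        index=False, name=None
    )
    for row_no, (camera_id, raw_ts, raw_class, count) in enumerate(rows, start=2):
        try:
            ts = dt.datetime.fromisoformat(str(raw_ts))
        except ValueError:
            raise DataFormatError(
                f"row {row_no}: malformed timestamp {raw_ts!r}"
            ) from None
        klass = _map_class(raw_class, row_no, vocabulary)
        try:
            events.append(
                DetectionEvent(
                    camera_id=str(camera_id),
                    timestamp=ts,
                    klass=klass,
                    count=int(count),
                )
            )
        except ValueError as exc:
            raise DataFormatError(f"row {row_no}: {exc}") from None
    return events


def write_detections(events: Sequence[DetectionEvent], path: str | Path) -> None:
    rows = sorted(events, key=lambda e: (e.camera_id, e.timestamp, e.klass.value))
    df = pd.DataFrame(
        {
            "camera_id": [e.camera_id for e in rows],
            "datetime": [e.timestamp.isoformat() for e in rows],
            "class": [e.klass.value for e in rows],
            "count": [e.count for e in rows],
        }
    )
    df.to_csv(path, index=False)


def read_viewsheds(path: str | Path, n_sectors: int = 6) -> list[ViewshedMeasurement]:
    """Read a viewshed measurement CSV (one row per camera per phase)."""
    df = pd.read_csv(path, dtype={"camera_id": str})
    radius_cols = [f"r{j}" for j in range(1, n_sectors + 1)]
    required = {"camera_id", "phase", "lens_angle_deg", *radius_cols}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"viewshed file missing columns {sorted(missing)}")
    measurements = []
    for row_no, rec in df.iterrows():
        radii = []
        for j, col in enumerate(radius_cols, start=1):
            r = float(rec[col])
            if r < 0:
                raise DataFormatError(
                    f"row {row_no + 2}: camera {rec['camera_id']} sector {j} "
                    f"has negative radius {r}"
                )
            radii.append(r)
        try:
            measurements.append(
                ViewshedMeasurement(
                    camera_id=str(rec["camera_id"]),
                    lens_angle_deg=float(rec["lens_angle_deg"]),
                    sector_radii_m=tuple(radii),
                    phase=MeasurementPhase(str(rec["phase"]).strip().lower()),
                )
            )
        except (ValueError, ViewshedError) as exc:
            raise DataFormatError(f"row {row_no + 2}: {exc}") from None
    return measurements


def write_viewsheds(
    measurements: Sequence[ViewshedMeasurement], path: str | Path
) -> None:
    rows = sorted(measurements, key=lambda m: (m.camera_id, m.phase.value))
    records = []
    for m in rows:
        rec = {
            "camera_id": m.camera_id,
            "phase": m.phase.value,
            "lens_angle_deg": m.lens_angle_deg,
        }
        rec.update({f"r{j + 1}": r for j, r in enumerate(m.sector_radii_m)})
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def read_cameras(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"camera_id": str})
    required = {"camera_id", "lat", "lon", "active_start", "active_end"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"camera file missing columns {sorted(missing)}")
    for col in ("active_start", "active_end"):
        df[col] = pd.to_datetime(df[col])
    return df


def write_cameras(cameras: pd.DataFrame, path: str | Path) -> None:
    cameras.sort_values("camera_id").to_csv(path, index=False)


def read_outages(path: str | Path) -> list[Outage]:
    df = pd.read_csv(path, dtype={"camera_id": str})
    required = {"camera_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"outage file missing columns {sorted(missing)}")
    out = []
    for row_no, rec in df.iterrows():
        try:
            out.append(
                Outage(
                    camera_id=str(rec["camera_id"]),
                    start=dt.datetime.fromisoformat(str(rec["start"])),
                    end=dt.datetime.fromisoformat(str(rec["end"])),
                    reason=str(rec.get("reason", "")),
                )
            )
        except ValueError as exc:
            raise DataFormatError(f"row {row_no + 2}: {exc}") from None
    return out


def read_sun_times(
    path: str | Path, latitude: float, longitude: float, utc_offset: float
) -> dict[dt.date, SolarDay]:
    """Read a precomputed sun-times CSV (date, sunrise, sunset), yielding
    SolarDay objects bit-compatible with the computed ones."""
    df = pd.read_csv(path)
    required = {"date", "sunrise", "sunset"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"sun-times file missing columns {sorted(missing)}")
    days = {}
    for row_no, rec in df.iterrows():
        try:
            date = dt.date.fromisoformat(str(rec["date"]))
            days[date] = SolarDay(
                date=date,
                sunrise=dt.datetime.fromisoformat(str(rec["sunrise"])),
                sunset=dt.datetime.fromisoformat(str(rec["sunset"])),
                latitude=latitude,
                longitude=longitude,
                utc_offset=utc_offset,
            )
        except ValueError as exc:
            raise DataFormatError(f"row {row_no + 2}: {exc}") from None
    return days


def write_sun_times(days: Mapping[dt.date, SolarDay], path: str | Path) -> None:
    records = [
        {
            "date": d.isoformat(),
            "sunrise": s.sunrise.isoformat(),
            "sunset": s.sunset.isoformat(),
        }
        for d, s in sorted(days.items())
    ]
    pd.DataFrame(records).to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


@dataclass
class RunConfig:
    """Declarative run configuration for the CLI workflows."""

    study_area_km2: float = 86.41
    timestep_minutes: float = 10.0
    diel_buffer_minutes: float = 60.0
    likelihood_variant: str = "interval_censored"
    period_mode: str = "diel"  # diel | peak | explicit
    periods: dict[str, list[str]] = field(default_factory=dict)  # class -> periods
    target_classes: list[str] = field(
        default_factory=lambda: ["adult_female", "adult_male", "fawn", "unknown_deer"]
    )
    include_unknown_in_class_fits: bool = False
    latitude: float = 35.0
    longitude: float = -95.5
    utc_offset: float = -5.0
    seed: int = 0
    n_permutations: int = 1
    viewshed_policy: str = "deployment"
    viewshed_flag_ratio: float = 3.0
    area_override_m2: float | None = None
    match_tolerance_seconds: float = 60.0
    start: str | None = None  # ISO datetimes; default from camera intervals
    end: str | None = None
    detections: str | None = None
    viewsheds: str | None = None
    cameras: str | None = None
    outages: str | None = None
    sun_times: str | None = None

    @property
    def step(self) -> dt.timedelta:
        return dt.timedelta(minutes=self.timestep_minutes)

    @property
    def diel_buffer(self) -> dt.timedelta:
        return dt.timedelta(minutes=self.diel_buffer_minutes)

    @property
    def match_tolerance(self) -> dt.timedelta:
        return dt.timedelta(seconds=self.match_tolerance_seconds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
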