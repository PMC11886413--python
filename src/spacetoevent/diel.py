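"""Solar events and diel-period classification.

Density estimators that treat every timelapse occasion as an independent
snapshot assume all animals are *available* for detection at every occasion.
Crepuscular ungulates violate that assumption over the full 24-h cycle:
midday bedding and near-zero nocturnal detectability (reduced activity plus
a flash-limited nighttime viewshed) pull full-diel density estimates low.
The remedy is to restrict sampling occasions to the diel period of peak
activity, which requires classifying each occasion timestamp as
crepuscular (within a buffer, 1 h by default, of sunrise or sunset),
diurnal, or nocturnal.

Sunrise and sunset are computed with the NOAA solar position algorithm
using zenith 90.833° (solar disc radius plus standard atmospheric
refraction), in local civil time under a fixed per-run UTC offset.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping


class DielPeriod(str, Enum):
    CREPUSCULAR = "crepuscular"
    DIURNAL = "diurnal"
    NOCTURNAL = "nocturnal"


#: Tie-break precedence for peak-activity selection.
PERIOD_PRECEDENCE = (DielPeriod.CREPUSCULAR, DielPeriod.DIURNAL, DielPeriod.NOCTURNAL)

POLAR_LATITUDE = 66.5


class SolarError(ValueError):
    """Unsupported location or date for solar computations."""


@dataclass(frozen=True)
class SolarDay:
    """Sunrise and sunset (local civil time) for one date at one site."""

    date: dt.date
    sunrise: dt.datetime
    sunset: dt.datetime
    latitude: float
    longitude: float
    utc_offset: float

    def __post_init__(self) -> None:
        if self.sunrise >= self.sunset:
            raise SolarError(
                f"{self.date}: sunrise {self.sunrise} not before sunset "
                f"{self.sunset}"
            )


def _julian_day(moment_utc: dt.datetime) -> float:
    epoch = dt.datetime(1970, 1, 1)
    return 2440587.5 + (moment_utc - epoch).total_seconds() / 86400.0


def solar_events(
    latitude: float,
    longitude: float,
    date: dt.date,
    utc_offset: float,
    zenith_deg: float = 90.833,
) -> SolarDay:
    """Sunrise/sunset for ``date`` from the NOAA solar position algorithm.

    Longitude is positive east; ``utc_offset`` is the fixed local-clock
    offset in hours (e.g. -5 for CDT).  Accurate to about a minute at
    mid-latitudes, well inside the few-minute spread among published solar
    calculators.

    Raises
    ------
    SolarError
        For latitudes poleward of the polar circles (polar day/night is out
        of scope) or dates outside 1900-2100.
    """
    if abs(latitude) >= POLAR_LATITUDE:
        raise SolarError(
            f"latitude {latitude} is poleward of +/-{POLAR_LATITUDE}; polar "
            "day/night handling is unsupported"
        )
    if not 1900 <= date.year <= 2100:
        raise SolarError(f"date {date} outside supported range 1900-2100")

    # Evaluate the solar ephemeris at local solar noon (single pass, as in
    # the NOAA spreadsheet; the intra-day drift is < 1 min).
    local_noon = dt.datetime.combine(date, dt.time(12)) - dt.timedelta(
        hours=utc_offset
    )
    jc = (_julian_day(local_noon) - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m = math.radians(geom_mean_anom)
    eq_center = (
        math.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    declination = math.asin(
        math.sin(math.radians(obliq)) * math.sin(math.radians(app_long))
    )

    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    l0 = math.radians(geom_mean_long)
    eq_time_min = 4.0 * math.degrees(
        var_y * math.sin(2 * l0)
        - 2 * ecc * math.sin(m)
        + 4 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * var_y**2 * math.sin(4 * l0)
        - 1.25 * ecc**2 * math.sin(2 * m)
    )

    lat = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(zenith_deg)) / (math.cos(lat) * math.cos(declination))
        - math.tan(lat) * math.tan(declination)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise SolarError(
            f"sun does not rise/set at latitude {latitude} on {date}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))

    solar_noon_min = 720.0 - 4.0 * longitude - eq_time_min + 60.0 * utc_offset
    sunrise_min = solar_noon_min - 4.0 * ha_deg
    sunset_min = solar_noon_min + 4.0 * ha_deg
    midnight = dt.datetime.combine(date, dt.time(0))
    return SolarDay(
        date=date,
        sunrise=midnight + dt.timedelta(minutes=sunrise_min),
        sunset=midnight + dt.timedelta(minutes=sunset_min),
        latitude=latitude,
        longitude=longitude,
        utc_offset=utc_offset,
    )


def solar_days_for_range(
    latitude: float,
    longitude: float,
    start: dt.date,
    end: dt.date,
    utc_offset: float,
) -> dict[dt.date, SolarDay]:
    """SolarDay for every date in [start, end] (inclusive)."""
    days: dict[dt.date, SolarDay] = {}
    d = start
    while d <= end:
        days[d] = solar_events(latitude, longitude, d, utc_offset)
        d += dt.timedelta(days=1)
    return days


def classify_period(
    timestamp: dt.datetime,
    solar: SolarDay,
    buffer: dt.timedelta = dt.timedelta(hours=1),
) -> DielPeriod:
    """Classify a local timestamp as crepuscular, diurnal, or nocturnal.

    Crepuscular iff within ``buffer`` (closed interval) of sunrise or
    sunset; diurnal iff strictly between sunrise+buffer and sunset-buffer;
    nocturnal otherwise.  The three classes partition the diel cycle.
    """
    if timestamp.date() != solar.date:
        raise SolarError(
            f"timestamp date {timestamp.date()} does not match solar day "
            f"{solar.date}"
        )
    if abs(timestamp - solar.sunrise) <= buffer or abs(timestamp - solar.sunset) <= buffer:
        return DielPeriod.CREPUSCULAR
    if solar.sunrise + buffer < timestamp < solar.sunset - buffer:
        return DielPeriod.DIURNAL
    return DielPeriod.NOCTURNAL


@dataclass
class PeakActivity:
    """Effort-normalised detection rates per diel period and the peak period."""

    period: DielPeriod
    rates: dict[DielPeriod, float]
    detections: dict[DielPeriod, int]
    occasions: dict[DielPeriod, int]


class NoDetectionsError(ValueError):
    """Raised when a class has no detections in any diel period."""


def peak_activity_period(
    detection_counts_by_period: Mapping[DielPeriod | str, int],
    occasion_counts_by_period: Mapping[DielPeriod | str, int],
) -> PeakActivity:
    """Select the diel period of peak activity for a class.

    The peak period maximises the effort-normalised detection rate
    (detections per sampling occasion) — raw counts would favour the longer
    periods.  Ties break by precedence crepuscular > diurnal > nocturnal.
    """
    detections = {DielPeriod(k): int(v) for k, v in detection_counts_by_period.items()}
    occasions = {DielPeriod(k): int(v) for k, v in occasion_counts_by_period.items()}
    for period, n_occ in occasions.items():
        if n_occ <= 0:
            raise ValueError(f"occasion count for {period.value} must be > 0")
    rates = {p: detections.get(p, 0) / occasions[p] for p in occasions}
    if all(detections.get(p, 0) == 0 for p in occasions):
        raise NoDetectionsError("no detections in any diel period")
    best_rate = max(rates.values())
    for p in PERIOD_PRECEDENCE:
        if p in rates and rates[p] == best_rate:
            return PeakActivity(
                period=p, rates=rates, detections=detections, occasions=occasions
            )
    raise AssertionError("unreachable: some period attains the maximum")


def classify_timestamps(
    timestamps: Iterable[dt.datetime],
    solar_days: Mapping[dt.date, SolarDay],
    buffer: dt.timedelta = dt.timedelta(hours=1),
) -> list[DielPeriod]:
    """Vector version of :func:`classify_period` over a timestamp sequence."""
    out = []
    for ts in timestamps:
        try:
            solar = solar_days[ts.date()]
        except KeyError:
            raise SolarError(f"no solar day provided for {ts.date()}") from None
        out.append(classify_period(ts, solar, buffer))
    return out
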