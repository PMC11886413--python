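"""Synthetic camera-trap fleets and timelapse detection histories.

The generator realises exactly the probability model the STE estimator
assumes, with known truth, so every pipeline stage is testable without
field data: animals of each stage/sex class form a homogeneous spatial
Poisson process over the study region, redistribute independently between
occasions, and are *available* for detection with a per-class, per-diel-
period probability (crepuscular peak, reduced diurnal, near-zero nocturnal
— the availability structure that biases full-diel density estimates low).

Default study conditions mirror a late-summer deer survey in southeast
Oklahoma: 50 cameras over a ~86 km² management area, a 10-min timelapse
grid from 1 Aug to 30 Sep (61 days × 144 occasions/day), 38.72° lens
angle with six-sector viewsheds drawn from a habitat scenario
("open-forest": mean camera area ≈ 300 m²; "dense-understory": ≈ 75 m²),
and class densities summing to 3 deer km⁻².

Two placement modes produce detection histories under the same model:

``point-process``
    Drop each available animal uniformly in the region and test containment
    in each camera's sector-wedge viewshed (explicit geometry; slower).
``bernoulli-thinning``
    Draw presence at camera i directly as Bernoulli(1 − exp(−λ_avail·a_i)),
    the exact per-camera marginal of the same Poisson model (fast; the two
    modes are statistically indistinguishable).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .diel import DielPeriod, classify_timestamps, solar_days_for_range
from .occasions import AnimalClass, DetectionEvent, occasion_grid
from .viewshed import MeasurementPhase, ViewshedMeasurement, camera_area


@dataclass(frozen=True)
class ViewshedScenario:
    """Lognormal sector-radius distribution for a habitat structure type."""

    name: str
    log_mean: float  # of radius in metres
    log_sd: float
    r_max_m: float


#: Habitat scenarios: open, fire-maintained understory (cameras see far)
#: versus dense unmanaged regeneration (views obstructed within metres).
SCENARIOS = {
    "open-forest": ViewshedScenario("open-forest", log_mean=3.07, log_sd=0.6, r_max_m=75.0),
    "dense-understory": ViewshedScenario(
        "dense-understory", log_mean=2.21, log_sd=0.7, r_max_m=40.0
    ),
}

#: Per-class diel availability: probability an animal present in the study
#: area is detectable at an occasion of that period.  Adults peak at
#: crepuscular hours; fawns peak diurnally; nocturnal timelapse
#: detectability is zero (low activity plus flash-limited viewsheds).
DEFAULT_AVAILABILITY: dict[str, dict[str, float]] = {
    "adult_female": {"crepuscular": 1.0, "diurnal": 0.3, "nocturnal": 0.0},
    "adult_male": {"crepuscular": 1.0, "diurnal": 0.3, "nocturnal": 0.0},
    "unknown_deer": {"crepuscular": 1.0, "diurnal": 0.3, "nocturnal": 0.0},
    "fawn": {"crepuscular": 0.3, "diurnal": 1.0, "nocturnal": 0.0},
}

DEFAULT_DENSITIES: dict[str, float] = {
    "adult_female": 1.5,
    "adult_male": 0.8,
    "fawn": 0.4,
    "unknown_deer": 0.3,
}


@dataclass
class SimConfig:
    """Generator parameters: the study conditions plus all seeds."""

    study_area_km2: float = 86.41
    true_density_per_km2: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    n_cameras: int = 50
    lens_angle_deg: float = 38.72
    n_sectors: int = 6
    viewshed_scenario: str | ViewshedScenario = "open-forest"
    start: dt.datetime = dt.datetime(2021, 8, 1, 0, 0)
    end: dt.datetime = dt.datetime(2021, 9, 30, 23, 50)
    step: dt.timedelta = dt.timedelta(minutes=10)
    availability: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AVAILABILITY.items()}
    )
    latitude: float = 35.0
    longitude: float = -95.5
    utc_offset: float = -5.0
    diel_buffer: dt.timedelta = dt.timedelta(hours=1)
    placement_mode: str = "bernoulli-thinning"
    include_blank_rows: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cameras < 1:
            raise ValueError("n_cameras must be >= 1")
        if not self.study_area_km2 > 0:
            raise ValueError("study area must be > 0")
        for klass, d in self.true_density_per_km2.items():
            AnimalClass(klass)
            if d < 0:
                raise ValueError(f"density for {klass} must be >= 0")
        for klass, periods in self.availability.items():
            for period, p in periods.items():
                DielPeriod(period)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"availability[{klass}][{period}] = {p} outside [0, 1]"
                    )
        if self.placement_mode not in ("point-process", "bernoulli-thinning"):
            raise ValueError(f"unknown placement mode {self.placement_mode!r}")

    @property
    def scenario(self) -> ViewshedScenario:
        if isinstance(self.viewshed_scenario, ViewshedScenario):
            return self.viewshed_scenario
        return SCENARIOS[self.viewshed_scenario]

    def availability_at(self, klass: str, period: DielPeriod) -> float:
        """Availability for a class at a diel period (default 1.0)."""
        return self.availability.get(klass, {}).get(period.value, 1.0)


@dataclass
class SimTruth:
    """Ground truth and provenance sufficient to regenerate the dataset."""

    config: SimConfig
    camera_areas_m2: dict[str, float]
    expected_event_prob: dict[str, dict[str, float]]
    camera_seed: int
    history_seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        cfg = d["config"]
        cfg["start"] = self.config.start.isoformat()
        cfg["end"] = self.config.end.isoformat()
        cfg["step"] = self.config.step.total_seconds()
        cfg["diel_buffer"] = self.config.diel_buffer.total_seconds()
        cfg["viewshed_scenario"] = self.config.scenario.name
        return d


class DegenerateViewshedError(ValueError):
    """All simulated viewshed areas are zero (e.g., r_max = 0)."""


def _child_seeds(seed: int) -> tuple[int, int]:
    s = np.random.SeedSequence(seed).generate_state(2) >> 1
    return int(s[0]), int(s[1])


def generate_cameras(
    config: SimConfig,
) -> tuple[pd.DataFrame, list[ViewshedMeasurement]]:
    """Place cameras uniformly in the study region and draw their viewsheds.

    Cameras sit at least the scenario's maximum radius from the region edge
    so every viewshed lies wholly inside the region (keeps the two placement
    modes exactly equivalent).  Returns a metadata frame (id, x/y in metres,
    derived lat/lon, orientation, active interval) and one six-sector
    deployment measurement per camera.  Deterministic given ``config.seed``.
    """
    scenario = config.scenario
    camera_seed, _ = _child_seeds(config.seed)
    rng = np.random.default_rng(camera_seed)
    side_m = math.sqrt(config.study_area_km2 * 1e6)
    margin = min(scenario.r_max_m, side_m / 4)
    if side_m <= 0:
        raise ValueError("zero-area study region")

    xs = rng.uniform(margin, side_m - margin, size=config.n_cameras)
    ys = rng.uniform(margin, side_m - margin, size=config.n_cameras)
    radii = rng.lognormal(
        scenario.log_mean, scenario.log_sd, size=(config.n_cameras, config.n_sectors)
    )
    radii = np.minimum(radii, scenario.r_max_m)

    measurements = []
    rows = []
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * math.cos(math.radians(config.latitude))
    for i in range(config.n_cameras):
        cam_id = f"CAM{i + 1:03d}"
        m = ViewshedMeasurement(
            camera_id=cam_id,
            lens_angle_deg=config.lens_angle_deg,
            sector_radii_m=tuple(radii[i]),
            phase=MeasurementPhase.DEPLOYMENT,
        )
        measurements.append(m)
        rows.append(
            {
                "camera_id": cam_id,
                "x_m": xs[i],
                "y_m": ys[i],
                "lat": config.latitude + (ys[i] - side_m / 2) / m_per_deg_lat,
                "lon": config.longitude + (xs[i] - side_m / 2) / m_per_deg_lon,
                "orientation_deg": 0.0,  # all cameras face north
                "active_start": config.start,
                "active_end": config.end,
            }
        )
    cameras = pd.DataFrame(rows)
    if not any(camera_area(m) > 0 for m in measurements):
        raise DegenerateViewshedError(
            "all simulated viewshed areas are zero; check scenario r_max"
        )
    return cameras, measurements


def _wedge_presence(
    animal_xy: np.ndarray,
    cam_x: float,
    cam_y: float,
    orientation_deg: float,
    lens_angle_deg: float,
    radii: np.ndarray,
) -> bool:
    """Is any animal inside this camera's sector-wedge viewshed?"""
    if animal_xy.size == 0:
        return False
    dx = animal_xy[:, 0] - cam_x
    dy = animal_xy[:, 1] - cam_y
    r = np.hypot(dx, dy)
    bearing = np.degrees(np.arctan2(dx, dy))  # 0 = north, clockwise
    rel = (bearing - orientation_deg + 180.0) % 360.0 - 180.0
    half = lens_angle_deg / 2.0
    k = len(radii)
    in_lens = np.abs(rel) <= half
    if not in_lens.any():
        return False
    sector = np.clip(
        ((rel[in_lens] + half) / (lens_angle_deg / k)).astype(int), 0, k - 1
    )
    return bool(np.any(r[in_lens] <= radii[sector]))


def simulate_detection_history(
    config: SimConfig,
    cameras: pd.DataFrame,
    viewsheds: list[ViewshedMeasurement],
) -> tuple[list[DetectionEvent], SimTruth]:
    """Simulate the tagged timelapse export for a fleet.

    Per occasion and class the available population is Poisson with mean
    (true density × study area × availability for the occasion's diel
    period); placement follows ``config.placement_mode``.  Emits one row per
    camera × occasion × class with >= 1 animal in view (count 1; the STE
    event is presence, not group size), plus explicit blank rows if
    configured.  Deterministic given ``config.seed``.
    """
    _, history_seed = _child_seeds(config.seed)
    rng = np.random.default_rng(history_seed)
    times = occasion_grid(config.start, config.end, config.step)
    solar = solar_days_for_range(
        config.latitude,
        config.longitude,
        config.start.date(),
        config.end.date(),
        config.utc_offset,
    )
    periods = classify_timestamps(times.to_pydatetime(), solar, config.diel_buffer)
    period_codes = np.array([p.value for p in periods])

    areas = np.array([camera_area(m) for m in viewsheds])
    cam_ids = list(cameras["camera_id"])
    n_occ, n_cam = len(times), len(cam_ids)
    area_m2 = config.study_area_km2 * 1e6

    events: list[DetectionEvent] = []
    any_detection = np.zeros((n_occ, n_cam), dtype=bool)
    expected: dict[str, dict[str, float]] = {}

    for klass, density in sorted(config.true_density_per_km2.items()):
        lam = density / 1e6  # animals per m²
        avail = np.array(
            [config.availability_at(klass, DielPeriod(p)) for p in period_codes]
        )
        expected[klass] = {
            p.value: float(
                1.0
                - math.exp(-lam * config.availability_at(klass, p) * areas.sum())
            )
            for p in DielPeriod
        }
        if density == 0 or not avail.any():
            continue
        if config.placement_mode == "bernoulli-thinning":
            prob = 1.0 - np.exp(-lam * avail[:, None] * areas[None, :])
            presence = rng.random((n_occ, n_cam)) < prob
        else:
            presence = np.zeros((n_occ, n_cam), dtype=bool)
            cam_x = cameras["x_m"].to_numpy()
            cam_y = cameras["y_m"].to_numpy()
            orient = cameras["orientation_deg"].to_numpy()
            side_m = math.sqrt(area_m2)
            n_avail = rng.poisson(density * config.study_area_km2 * avail)
            for o in range(n_occ):
                if n_avail[o] == 0:
                    continue
                xy = rng.uniform(0.0, side_m, size=(n_avail[o], 2))
                for c in range(n_cam):
                    presence[o, c] = _wedge_presence(
                        xy,
                        cam_x[c],
                        cam_y[c],
                        orient[c],
                        config.lens_angle_deg,
                        np.asarray(viewsheds[c].sector_radii_m),
                    )
        any_detection |= presence
        occ_idx, cam_idx = np.nonzero(presence)
        for o, c in zip(occ_idx, cam_idx):
            events.append(
                DetectionEvent(
                    camera_id=cam_ids[c],
                    timestamp=times[o].to_pydatetime(),
                    klass=AnimalClass(klass),
                    count=1,
                )
            )

    if config.include_blank_rows:
        occ_idx, cam_idx = np.nonzero(~any_detection)
        for o, c in zip(occ_idx, cam_idx):
            events.append(
                DetectionEvent(
                    camera_id=cam_ids[c],
                    timestamp=times[o].to_pydatetime(),
                    klass=AnimalClass.NONE,
                    count=0,
                )
            )

    events.sort(key=lambda e: (e.camera_id, e.timestamp, e.klass.value))
    truth = SimTruth(
        config=config,
        camera_areas_m2={cid: float(a) for cid, a in zip(cam_ids, areas)},
        expected_event_prob=expected,
        camera_seed=_child_seeds(config.seed)[0],
        history_seed=history_seed,
    )
    return events, truth


def simulate_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, list[ViewshedMeasurement], list[DetectionEvent], SimTruth]:
    """Convenience: cameras + viewsheds + detection history in one call."""
    cameras, viewsheds = generate_cameras(config)
    events, truth = simulate_detection_history(config, cameras, viewsheds)
    return cameras, viewsheds, events, truth
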