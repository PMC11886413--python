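"""Per-camera viewshed (sampled-area) geometry.

A timelapse camera samples a circular sector whose central angle is the lens
field of view.  In structurally complex habitat the maximum viewable distance
varies across that sector, so the sector is split into ``k`` equal wedges
(six by default) and the maximum viewable distance is measured per wedge; the
camera's sampled area ``a_i`` is the sum of the wedge areas

    a_i = sum_j  pi * r_ij**2 * (theta_i / k) / 360

with ``theta_i`` the lens angle in degrees and ``r_ij`` the wedge radii in
metres.  When every radius equals ``r`` this collapses to the single-sector
formula ``pi * r**2 * theta_i / 360``.

Viewsheds are typically measured at deployment and, optionally, re-measured
at retrieval; :func:`select_viewshed` reconciles the two and flags cameras
whose measured area changed implausibly (vegetation growth, mismeasurement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class MeasurementPhase(str, Enum):
    DEPLOYMENT = "deployment"
    RETRIEVAL = "retrieval"


class ViewshedError(ValueError):
    """Invalid viewshed measurement or geometry parameters."""


def sector_area(radius_m: float, sector_angle_deg: float) -> float:
    """Area in m² of a circular sector of given radius and central angle.

    Parameters
    ----------
    radius_m
        Maximum viewable distance in metres; must be >= 0.
    sector_angle_deg
        Central angle in degrees; must lie in (0, 360].

    Returns
    -------
    float
        ``pi * r**2 * angle / 360``; zero iff the radius is zero.
    """
    if not math.isfinite(radius_m) or radius_m < 0:
        raise ViewshedError(f"radius must be finite and >= 0, got {radius_m!r}")
    if not 0 < sector_angle_deg <= 360:
        raise ViewshedError(
            f"sector angle must be in (0, 360] degrees, got {sector_angle_deg!r}"
        )
    return math.pi * radius_m**2 * sector_angle_deg / 360.0


@dataclass(frozen=True)
class ViewshedMeasurement:
    """One camera's lens angle and per-wedge maximum viewable distances.

    Attributes
    ----------
    camera_id
        Camera identifier.
    lens_angle_deg
        Lens field-of-view angle in degrees, in (0, 360).
    sector_radii_m
        Ordered maximum viewable distances, one per wedge (six by default);
        each wedge spans ``lens_angle_deg / k`` degrees.
    phase
        Whether the measurement was taken at deployment or retrieval.
    """

    camera_id: str
    lens_angle_deg: float
    sector_radii_m: tuple[float, ...]
    phase: MeasurementPhase = MeasurementPhase.DEPLOYMENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "sector_radii_m", tuple(self.sector_radii_m))
        object.__setattr__(self, "phase", MeasurementPhase(self.phase))
        if not 0 < self.lens_angle_deg < 360:
            raise ViewshedError(
                f"camera {self.camera_id}: lens angle must be in (0, 360), "
                f"got {self.lens_angle_deg!r}"
            )
        if len(self.sector_radii_m) < 1:
            raise ViewshedError(f"camera {self.camera_id}: empty radii list")
        for j, r in enumerate(self.sector_radii_m, start=1):
            if not math.isfinite(r) or r < 0:
                raise ViewshedError(
                    f"camera {self.camera_id}: sector {j} radius must be "
                    f"finite and >= 0, got {r!r}"
                )

    @property
    def n_sectors(self) -> int:
        return len(self.sector_radii_m)

    @property
    def sector_angle_deg(self) -> float:
        """Per-wedge angle: the exact division lens_angle / k (not rounded)."""
        return self.lens_angle_deg / self.n_sectors

    @property
    def area_m2(self) -> float:
        return camera_area(self)


def camera_area(measurement: ViewshedMeasurement) -> float:
    """Total sampled area ``a_i`` in m²: the sum of the wedge sector areas."""
    theta = measurement.sector_angle_deg
    return sum(sector_area(r, theta) for r in measurement.sector_radii_m)


@dataclass
class ViewshedSelection:
    """Outcome of reconciling deployment and retrieval measurements."""

    measurement: ViewshedMeasurement
    flags: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.flags)


def select_viewshed(
    deployment: ViewshedMeasurement,
    retrieval: ViewshedMeasurement | None = None,
    policy: str = "retrieval",
    flag_ratio: float = 3.0,
    override_phase: str | None = None,
    radius_cap_m: float | None = None,
) -> ViewshedSelection:
    """Choose the viewshed measurement to use for a camera and flag anomalies.

    Policies: ``"deployment"`` / ``"retrieval"`` keep that phase's
    measurement (``"retrieval"`` falls back to deployment only when no
    retrieval measurement exists and raises otherwise if it is absent —
    callers wanting the fallback pass ``policy="deployment"`` per camera);
    ``"minimum"`` keeps the smaller-area measurement; ``"override"`` keeps
    the phase named by ``override_phase``.

    Any camera whose deployment/retrieval area ratio (larger ÷ smaller)
    exceeds ``flag_ratio`` is flagged: an implausible change usually means a
    mismeasured or vegetation-altered viewshed (the failure mode that can
    swing a site density estimate severalfold).  Radii above ``radius_cap_m``
    are flagged, never rejected.
    """
    if retrieval is not None and retrieval.camera_id != deployment.camera_id:
        raise ViewshedError(
            f"mismatched camera ids: {deployment.camera_id!r} vs "
            f"{retrieval.camera_id!r}"
        )
    if policy not in ("deployment", "retrieval", "minimum", "override"):
        raise ViewshedError(f"unknown selection policy {policy!r}")
    if flag_ratio <= 0:
        raise ViewshedError(f"flag_ratio must be positive, got {flag_ratio!r}")

    flags: list[str] = []

    if retrieval is None:
        if policy == "retrieval":
            raise ViewshedError(
                f"camera {deployment.camera_id}: policy 'retrieval' but no "
                "retrieval measurement"
            )
        chosen = deployment
    else:
        a_dep, a_ret = camera_area(deployment), camera_area(retrieval)
        lo, hi = min(a_dep, a_ret), max(a_dep, a_ret)
        ratio = math.inf if lo == 0 and hi > 0 else (hi / lo if lo > 0 else 1.0)
        if ratio > flag_ratio:
            flags.append(
                f"camera {deployment.camera_id}: deployment/retrieval area "
                f"ratio {ratio:.3g} exceeds {flag_ratio:g} "
                f"({a_dep:.0f} m² vs {a_ret:.0f} m²)"
            )
        if policy == "deployment":
            chosen = deployment
        elif policy == "retrieval":
            chosen = retrieval
        elif policy == "minimum":
            chosen = deployment if a_dep <= a_ret else retrieval
        else:  # override
            if override_phase not in ("deployment", "retrieval"):
                raise ViewshedError(
                    "policy 'override' requires override_phase "
                    "'deployment' or 'retrieval'"
                )
            chosen = deployment if override_phase == "deployment" else retrieval

    if radius_cap_m is not None:
        for j, r in enumerate(chosen.sector_radii_m, start=1):
            if r > radius_cap_m:
                flags.append(
                    f"camera {chosen.camera_id}: sector {j} radius "
                    f"{r:g} m exceeds cap {radius_cap_m:g} m"
                )
    return ViewshedSelection(measurement=chosen, flags=flags)


def fleet_areas(
    measurements: Sequence[ViewshedMeasurement],
) -> dict[str, float]:
    """Map camera id -> sampled area m² for a list of measurements."""
    areas: dict[str, float] = {}
    for m in measurements:
        if m.camera_id in areas:
            raise ViewshedError(f"duplicate measurement for camera {m.camera_id}")
        areas[m.camera_id] = camera_area(m)
    return areas
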