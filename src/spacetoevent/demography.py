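"""Abundance extrapolation, fawn recruitment, and camera-effort analyses.

A fitted STE density extrapolates linearly to abundance over the management
unit: N̂ = D̂ × area, with the CI endpoints scaled identically.  Recruitment
is the ratio of the fawn density to the adult-female density fitted from the
same camera array (each class over its own peak-activity window when diel
availability differs by class); its standard error is an
independence-assumed delta-method extension — the ratio itself is the
conventional field statistic.  Camera-quantity subset curves and a
camera-level bootstrap quantify how estimate and precision respond to fleet
size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import NoEventsError, STEModel, STEResults
from .occasions import OccasionTable


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding (0.5 rounds away from zero), used only at
    report time; machine-readable output keeps full precision."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (half-up)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)


@dataclass
class AbundanceEstimate:
    """Abundance over a study area extrapolated from a density fit."""

    n_hat: float
    lci: float
    uci: float
    study_area_km2: float
    source_fit: STEResults | None = None

    @property
    def n_reported(self) -> int:
        """Integer abundance as conventionally reported (half-up)."""
        return int(round_half_up(self.n_hat))


def extrapolate_abundance(
    fit: STEResults | float,
    study_area_km2: float,
    lci_per_km2: float | None = None,
    uci_per_km2: float | None = None,
) -> AbundanceEstimate:
    """N̂ = density × study area (km²); CI endpoints scale identically.

    ``fit`` may be a fitted results object or a bare density per km² (with
    optional explicit CI endpoints), the latter for re-deriving abundances
    from published density tables.
    """
    if not study_area_km2 > 0:
        raise ValueError(f"study area must be > 0 km², got {study_area_km2!r}")
    if isinstance(fit, STEResults):
        density = fit.density_per_km2
        lci, uci = fit.conf_int()
        source = fit
    else:
        density = float(fit)
        lci = density if lci_per_km2 is None else lci_per_km2
        uci = density if uci_per_km2 is None else uci_per_km2
        source = None
    if density < 0:
        raise ValueError("density must be non-negative")
    return AbundanceEstimate(
        n_hat=density * study_area_km2,
        lci=lci * study_area_km2,
        uci=uci * study_area_km2,
        study_area_km2=study_area_km2,
        source_fit=source,
    )


class UndefinedRatioError(ValueError):
    """Adult-female density is zero; the recruitment ratio is undefined."""


@dataclass
class RecruitmentEstimate:
    """Fawns per adult female, with a delta-method SE.

    The point ratio is the standard recruitment index; the SE (delta method
    under independence of the two fits, se = ratio·√(cv_f² + cv_af²)) is an
    extension beyond conventional reporting and is labelled as such in
    ``summary()``.
    """

    ratio: float
    se: float
    fawn_fit: STEResults | None = None
    adult_female_fit: STEResults | None = None
    sampling_periods: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def ratio_reported(self) -> float:
        """Two-significant-figure ratio as conventionally reported."""
        return round_sig(self.ratio, 2)

    def summary(self) -> str:
        lines = [
            "Fawn recruitment (fawns per adult female)",
            f"  ratio: {self.ratio:.4f}  (reported: {self.ratio_reported:g})",
            f"  delta-method SE (extension, not a conventional output): {self.se:.4f}",
            f"  sampling periods: {self.sampling_periods}",
        ]
        lines += [f"  warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def recruitment_ratio(
    fawn_fit: STEResults | float,
    adult_female_fit: STEResults | float,
    fawn_period: str = "",
    adult_female_period: str = "",
) -> RecruitmentEstimate:
    """Recruitment as fawn density ÷ adult-female density.

    The ratio is identical whether densities or abundances over the same
    area are used.  Classes may be fitted over different peak-activity
    windows; the window labels are recorded.  Bare floats are accepted for
    re-deriving published ratios (their SE contribution is then zero).
    """

    def density_cv(fit: STEResults | float) -> tuple[float, float]:
        if isinstance(fit, STEResults):
            d = fit.density_per_km2
            return d, (fit.se_per_km2 / d if d > 0 else 0.0)
        return float(fit), 0.0

    d_f, cv_f = density_cv(fawn_fit)
    d_af, cv_af = density_cv(adult_female_fit)
    if not d_af > 0:
        raise UndefinedRatioError("adult-female density is zero; ratio undefined")
    warns = []
    if d_f == 0:
        warns.append("no fawn detections: recruitment ratio is 0")
    ratio = d_f / d_af
    se = ratio * math.sqrt(cv_f**2 + cv_af**2)
    periods = {}
    if fawn_period:
        periods["fawn"] = fawn_period
    if adult_female_period:
        periods["adult_female"] = adult_female_period
    return RecruitmentEstimate(
        ratio=ratio,
        se=se,
        fawn_fit=fawn_fit if isinstance(fawn_fit, STEResults) else None,
        adult_female_fit=adult_female_fit
        if isinstance(adult_female_fit, STEResults)
        else None,
        sampling_periods=periods,
        warnings=warns,
    )


@dataclass
class SubsetResult:
    size: int
    fit: STEResults
    abundance: AbundanceEstimate


def camera_subset_curve(
    table: OccasionTable,
    sizes: Sequence[int],
    study_area_km2: float,
    seed: int = 0,
    variant: str = "interval_censored",
    order: Sequence[int] | None = None,
) -> list[SubsetResult]:
    """Refit STE on nested camera subsets of increasing size.

    The size-k subset is the first k cameras in deployment order (or in
    ``order`` if given): size 40 means the last 10 deployed cameras are
    removed.  Each subset is refit independently under the same seed policy.
    """
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValueError("sizes must be sorted ascending")
    if order is None:
        order = list(range(table.n_cameras))
    if len(order) != table.n_cameras or sorted(order) != list(range(table.n_cameras)):
        raise ValueError("order must be a permutation of all camera indices")
    results = []
    for k in sizes:
        if not 1 <= k <= table.n_cameras:
            raise ValueError(
                f"subset size {k} outside [1, {table.n_cameras}]"
            )
        sub = table.subset_cameras(list(order[:k]))
        fit = STEModel(sub, variant=variant).fit(seed=seed)
        results.append(
            SubsetResult(size=k, fit=fit, abundance=fit.abundance(study_area_km2))
        )
    return results


def plot_subset_curve(results: Sequence[SubsetResult], ax=None):
    """Abundance vs camera quantity with 95% CIs (matplotlib errorbar)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sizes = [r.size for r in results]
    n = [r.abundance.n_hat for r in results]
    lo = [r.abundance.n_hat - r.abundance.lci for r in results]
    hi = [r.abundance.uci - r.abundance.n_hat for r in results]
    ax.errorbar(sizes, n, yerr=[lo, hi], fmt="o", capsize=4)
    ax.set_xlabel("Camera quantity")
    ax.set_ylabel("Abundance (N)")
    return ax


@dataclass
class BootstrapSummary:
    """Camera-level bootstrap distribution of the fitted density (km⁻²)."""

    mean_density_per_km2: float
    sd_density_per_km2: float
    lci_per_km2: float
    uci_per_km2: float
    n_boot: int
    n_failed: int
    seed: int
    replicate_seeds: list[int]
    densities_per_km2: np.ndarray


def _resample_replicate(
    table: OccasionTable, idx: np.ndarray, rng: np.random.Generator
) -> OccasionTable:
    """Bootstrap-replicate occasion table for camera draws ``idx``.

    First occurrences keep their original occasion alignment; later copies
    of the same camera get an independent occasion permutation of their
    (active, presence) column.
    """
    import dataclasses

    active = table.active[:, idx].copy()
    presence = table.presence[:, idx].copy()
    seen: set[int] = set()
    for col, cam in enumerate(idx):
        if int(cam) in seen:
            perm = rng.permutation(table.n_occasions)
            active[:, col] = active[perm, col]
            presence[:, col] = presence[perm, col]
        seen.add(int(cam))
    return dataclasses.replace(
        table,
        camera_ids=[table.camera_ids[i] for i in idx],
        areas_m2=table.areas_m2[idx],
        active=active,
        presence=presence,
    )


def bootstrap_cameras(
    table: OccasionTable,
    n_boot: int,
    seed: int,
    variant: str = "interval_censored",
    ci_level: float = 0.95,
) -> BootstrapSummary:
    """Resample cameras with replacement and refit each replicate.

    Because occasions are independent snapshots under the model, a camera
    drawn more than once must not carry its history in lockstep with its
    copies: identical columns share every within-occasion detection, which
    deflates replicate event counts (they scale with the *unique* resampled
    area) while exposure scales with the full resampled area, biasing every
    replicate low by roughly 1/e.  Second and later copies of a duplicated
    camera therefore have their occasion history independently permuted —
    each camera's marginal detection frequency is preserved exactly, and
    the copies become exchangeable draws as the bootstrap intends.  An
    identity resample reproduces the point fit exactly.

    Replicates whose resampled fleet yields zero detection events are
    recorded as failures, counted, and excluded from the summaries.  Each
    replicate (camera resample, copy permutations, and camera-ordering seed
    alike) is fully determined by its logged replicate seed, so any
    replicate can be regenerated in isolation.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if table.n_cameras < 2:
        raise ValueError("bootstrap needs at least 2 cameras")
    rep_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_boot) >> 1]
    densities = []
    n_failed = 0
    for rs in rep_seeds:
        resample_seed, perm_seed = (
            int(s) for s in np.random.SeedSequence(rs).generate_state(2) >> 1
        )
        rng = np.random.default_rng(resample_seed)
        idx = rng.integers(0, table.n_cameras, size=table.n_cameras)
        sub = _resample_replicate(table, idx, rng)
        try:
            fit = STEModel(sub, variant=variant).fit(seed=perm_seed)
        except NoEventsError:
            n_failed += 1
            continue
        densities.append(fit.density_per_km2)
    dens = np.array(densities)
    if dens.size == 0:
        raise NoEventsError("every bootstrap replicate had zero events")
    alpha = (1.0 - ci_level) / 2.0
    lci, uci = np.quantile(dens, [alpha, 1.0 - alpha])
    return BootstrapSummary(
        mean_density_per_km2=float(dens.mean()),
        sd_density_per_km2=float(dens.std(ddof=1)) if dens.size > 1 else 0.0,
        lci_per_km2=float(lci),
        uci_per_km2=float(uci),
        n_boot=n_boot,
        n_failed=n_failed,
        seed=int(seed),
        replicate_seeds=rep_seeds,
        densities_per_km2=dens,
    )
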