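"""Abundance extrapolation, recruitment, subset curves, camera bootstrap."""

import dataclasses

import numpy as np
import pytest

from spacetoevent.demography import (
    BootstrapSummary,
    UndefinedRatioError,
    bootstrap_cameras,
    camera_subset_curve,
    extrapolate_abundance,
    recruitment_ratio,
    round_half_up,
    round_sig,
)
from spacetoevent.model import STEModel, STEResults, fit_ste

from conftest import make_table, simulated_table


def results_from_density(density_per_km2, n_events=100):
    """A results object with a given density (for arithmetic-level checks)."""
    return STEResults(
        lambda_per_m2=density_per_km2 / 1e6,
        n_events=n_events,
        n_occasions=1000,
        total_exposure_m2=1e7,
        likelihood_variant="exponential_approx",
        seed=0,
        permutation_seeds=[0],
    )


class TestAbundance:
    @pytest.mark.parametrize(
        "density, area_km2, expected_n",
        [(4.16, 86.41, 359), (2.34, 30.77, 72)],
    )
    def test_reported_integer_abundance(self, density, area_km2, expected_n):
        est = extrapolate_abundance(results_from_density(density), area_km2)
        assert est.n_reported == expected_n

    def test_zero_density_zero_abundance(self):
        est = extrapolate_abundance(0.0, 50.0)
        assert est.n_hat == 0.0 and est.n_reported == 0

    def test_ci_endpoints_scale_with_density(self):
        fit = results_from_density(3.0, n_events=25)
        est = fit.abundance(100.0)
        lci, uci = fit.conf_int()
        assert est.lci == pytest.approx(lci * 100.0)
        assert est.uci == pytest.approx(uci * 100.0)
        assert est.lci <= est.n_hat <= est.uci

    def test_linear_in_area(self):
        fit = results_from_density(3.0)
        one = extrapolate_abundance(fit, 40.0)
        two = extrapolate_abundance(fit, 80.0)
        assert two.n_hat == pytest.approx(2 * one.n_hat)
        assert two.lci == pytest.approx(2 * one.lci)
        assert two.uci == pytest.approx(2 * one.uci)

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_abundance(results_from_density(3.0), 0.0)


class TestRounding:
    def test_half_up(self):
        assert round_half_up(196.5) == 197
        assert round_half_up(196.4999) == 196

    def test_two_significant_figures(self):
        assert round_sig(0.1473, 2) == 0.15
        assert round_sig(0.0659, 2) == 0.066
        assert round_sig(0.0205, 2) == 0.021
        assert round_sig(0.0, 2) == 0.0


class TestRecruitment:
    def test_reported_ratio_from_abundances(self):
        # fawn N = 14, adult female N = 95 over the same area
        rec = recruitment_ratio(14 / 86.41, 95 / 86.41)
        assert rec.ratio_reported == 0.15

    def test_equal_densities_give_unity(self):
        rec = recruitment_ratio(2.5, 2.5)
        assert rec.ratio == pytest.approx(1.0)

    def test_density_vs_abundance_invariance(self):
        f, af = results_from_density(0.4, 30), results_from_density(1.5, 200)
        by_density = f.density_per_km2 / af.density_per_km2
        area = 86.41
        by_abundance = f.abundance(area).n_hat / af.abundance(area).n_hat
        assert by_density == pytest.approx(by_abundance, rel=1e-12)
        assert recruitment_ratio(f, af).ratio == pytest.approx(by_density)

    def test_zero_adult_female_density_undefined(self):
        with pytest.raises(UndefinedRatioError):
            recruitment_ratio(0.4, 0.0)

    def test_zero_fawn_density_warns_and_returns_zero(self):
        rec = recruitment_ratio(0.0, 1.5)
        assert rec.ratio == 0.0
        assert any("no fawn" in w for w in rec.warnings)

    def test_period_labels_recorded(self):
        rec = recruitment_ratio(
            0.3, 1.5, fawn_period="diurnal", adult_female_period="crepuscular"
        )
        assert rec.sampling_periods == {
            "fawn": "diurnal",
            "adult_female": "crepuscular",
        }

    def test_delta_method_se_matches_parametric_bootstrap(self):
        """Delta-method SE within 15% of a 1000-draw parametric bootstrap
        from the two lognormal sampling distributions."""
        f = results_from_density(0.4, n_events=30)
        af = results_from_density(1.5, n_events=200)
        rec = recruitment_ratio(f, af)
        rng = np.random.default_rng(8)
        sd_f = f.se_per_km2 / f.density_per_km2
        sd_af = af.se_per_km2 / af.density_per_km2
        draws_f = f.density_per_km2 * np.exp(rng.normal(0, sd_f, 1000))
        draws_af = af.density_per_km2 * np.exp(rng.normal(0, sd_af, 1000))
        boot_se = np.std(draws_f / draws_af, ddof=1)
        assert rec.se == pytest.approx(boot_se, rel=0.15)


@pytest.fixture(scope="module")
def medium_table():
    _, table, _ = simulated_table(density=6.0, seed=31)
    return table


class TestSubsetCurve:
    def test_full_fleet_subset_identical_to_full_fit(self, medium_table):
        full = fit_ste(medium_table, seed=4)
        curve = camera_subset_curve(
            medium_table, [medium_table.n_cameras], study_area_km2=86.41, seed=4
        )
        assert curve[0].fit.lambda_per_m2 == pytest.approx(full.lambda_per_m2)

    def test_nested_subsets_exposure_monotone(self, medium_table):
        curve = camera_subset_curve(
            medium_table, [10, 20, 30, 40, 50], study_area_km2=86.41, seed=0
        )
        exposures = [r.fit.total_exposure_m2 for r in curve]
        assert all(a <= b for a, b in zip(exposures, exposures[1:]))

    def test_sizes_must_be_sorted_and_in_range(self, medium_table):
        with pytest.raises(ValueError):
            camera_subset_curve(medium_table, [20, 10], study_area_km2=86.41)
        with pytest.raises(ValueError):
            camera_subset_curve(medium_table, [60], study_area_km2=86.41)

    def test_ci_width_shrinks_with_camera_quantity_on_average(self):
        """Mean CI width is non-increasing from 10 to 50 cameras over 20
        simulated replicates (the precision-vs-effort trend)."""
        widths = {10: [], 50: []}
        for rep in range(20):
            _, table, _ = simulated_table(density=6.0, seed=1000 + rep)
            curve = camera_subset_curve(
                table, [10, 50], study_area_km2=86.41, seed=rep
            )
            for r in curve:
                lci, uci = r.fit.conf_int()
                widths[r.size].append(uci - lci)
        assert np.mean(widths[50]) < np.mean(widths[10])


class TestBootstrap:
    def test_replicates_reproducible_from_logged_seeds(self, medium_table):
        from spacetoevent.demography import _resample_replicate

        summary = bootstrap_cameras(medium_table, n_boot=3, seed=17)
        rs = summary.replicate_seeds[0]
        resample_seed, perm_seed = (
            int(s) for s in np.random.SeedSequence(rs).generate_state(2) >> 1
        )
        rng = np.random.default_rng(resample_seed)
        idx = rng.integers(0, medium_table.n_cameras, size=medium_table.n_cameras)
        refit = STEModel(_resample_replicate(medium_table, idx, rng)).fit(
            seed=perm_seed
        )
        assert refit.density_per_km2 == pytest.approx(
            summary.densities_per_km2[0]
        )

    def test_identity_resample_equals_point_fit(self, medium_table):
        point = STEModel(medium_table).fit(seed=5)
        refit = STEModel(
            medium_table.subset_cameras(range(medium_table.n_cameras))
        ).fit(seed=5)
        assert refit.density_per_km2 == pytest.approx(point.density_per_km2)

    def test_bootstrap_mean_consistent_with_point_estimate(self, medium_table):
        point = STEModel(medium_table).fit(seed=0)
        summary = bootstrap_cameras(medium_table, n_boot=200, seed=3)
        se_mean = summary.sd_density_per_km2 / np.sqrt(
            summary.n_boot - summary.n_failed
        )
        assert abs(summary.mean_density_per_km2 - point.density_per_km2) < (
            2 * summary.sd_density_per_km2
        )
        assert isinstance(summary, BootstrapSummary)
        assert summary.n_failed == 0
        assert se_mean > 0

    def test_invalid_n_boot_rejected(self, medium_table):
        with pytest.raises(ValueError):
            bootstrap_cameras(medium_table, n_boot=0, seed=0)
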