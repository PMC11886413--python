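"""STE sampling, likelihood, and maximum-likelihood fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spacetoevent.model import (
    NoEventsError,
    STEData,
    STEModel,
    fit_ste,
    space_to_event_sample,
    ste_log_likelihood,
)

from conftest import make_table


def ste_data(events, censored_exposures, seed=0):
    """Build STEData from explicit (pre_event, detecting_area) event pairs
    and censored exposures."""
    n_ev, n_cens = len(events), len(censored_exposures)
    event = np.array([True] * n_ev + [False] * n_cens)
    pre = np.array([p for p, _ in events] + [np.nan] * n_cens)
    a = np.array([d for _, d in events] + [np.nan] * n_cens)
    s = pre + a
    # exposure must dominate s for events; make it s plus slack
    exposure = np.concatenate([s[:n_ev] + 50.0, np.asarray(censored_exposures, float)])
    return STEData(
        event=event,
        s_m2=s,
        pre_event_m2=pre,
        detecting_area_m2=a,
        exposure_m2=exposure,
        permutation_seed=seed,
    )


class TestSpaceToEventSample:
    def test_event_records_inclusive_cumulative_area(self):
        # one occasion, presence at C1 (100 m²) only; C2 has 200 m²
        table = make_table([100.0, 200.0], [[True, False]])
        for seed in range(20):
            data = space_to_event_sample(table, seed)
            assert data.event[0]
            order_first_c1 = data.s_m2[0] == pytest.approx(100.0)
            order_first_c2 = data.s_m2[0] == pytest.approx(300.0)
            assert order_first_c1 or order_first_c2
            if order_first_c2:
                assert data.pre_event_m2[0] == pytest.approx(200.0)
            else:
                assert data.pre_event_m2[0] == pytest.approx(0.0)
            assert data.detecting_area_m2[0] == pytest.approx(100.0)

    def test_both_orders_occur_across_seeds(self):
        table = make_table([100.0, 200.0], [[True, False]])
        s_values = {
            round(space_to_event_sample(table, seed).s_m2[0]) for seed in range(40)
        }
        assert s_values == {100, 300}

    def test_censored_occasion_carries_total_exposure(self):
        table = make_table([100.0, 200.0], [[False, False]])
        data = space_to_event_sample(table, 0)
        assert not data.event[0]
        assert data.exposure_m2[0] == pytest.approx(300.0)

    def test_presence_at_first_permuted_camera(self):
        table = make_table([200.0], [[True]])
        data = space_to_event_sample(table, 0)
        assert data.s_m2[0] == pytest.approx(200.0)
        assert data.pre_event_m2[0] == pytest.approx(0.0)

    def test_zero_active_occasions_dropped(self):
        table = make_table(
            [100.0, 200.0],
            [[False, False], [True, False]],
            active=[[False, False], [True, True]],
        )
        data = space_to_event_sample(table, 0)
        assert data.n_occasions == 1
        assert data.n_dropped == 1

    def test_reproducible_given_seed(self):
        table = make_table(
            np.linspace(50, 500, 10),
            np.random.default_rng(3).random((40, 10)) < 0.2,
        )
        d1 = space_to_event_sample(table, 99)
        d2 = space_to_event_sample(table, 99)
        np.testing.assert_array_equal(d1.s_m2, d2.s_m2)


class TestLogLikelihood:
    def test_pure_survival_closed_form(self):
        data = ste_data([], [600.0, 400.0])
        for lam in (1e-4, 1e-3, 1e-2):
            for variant in ("exponential_approx", "interval_censored"):
                assert ste_log_likelihood(lam, data, variant) == pytest.approx(
                    -lam * 1000.0
                )

    def test_single_event_hand_value(self):
        # one event with s = 100, no censoring, lambda = 0.01:
        # exponential form gives ln(0.01) - 1
        data = ste_data([(0.0, 100.0)], [])
        ll = ste_log_likelihood(0.01, data, "exponential_approx")
        assert ll == pytest.approx(math.log(0.01) - 1.0)

    def test_interval_censored_hand_value(self):
        data = ste_data([(40.0, 60.0)], [500.0])
        lam = 2e-3
        expected = -lam * 40.0 + math.log(1 - math.exp(-lam * 60.0)) - lam * 500.0
        assert ste_log_likelihood(lam, data, "interval_censored") == pytest.approx(
            expected
        )

    def test_non_positive_lambda_rejected(self):
        data = ste_data([(0.0, 100.0)], [])
        with pytest.raises(ValueError):
            ste_log_likelihood(0.0, data)
        with pytest.raises(ValueError):
            ste_log_likelihood(-1e-3, data)

    def test_variants_agree_at_small_lambda_a(self):
        """When max(λ·a) < 0.01 the interval-censored and exponential forms
        agree in value and curvature on a dense λ grid."""
        rng = np.random.default_rng(7)
        events = [(float(p), float(a)) for p, a in
                  zip(rng.uniform(0, 2000, 30), rng.uniform(50, 400, 30))]
        data = ste_data(events, list(rng.uniform(2000, 5000, 70)))
        lam_grid = np.linspace(5e-6, 2e-5, 201)  # max λ·a = 0.008
        ll_exp = np.array([
            ste_log_likelihood(l, data, "exponential_approx") for l in lam_grid
        ])
        ll_ic = np.array([
            ste_log_likelihood(l, data, "interval_censored") for l in lam_grid
        ])
        curv_exp = np.diff(ll_exp, 2)
        curv_ic = np.diff(ll_ic, 2)
        np.testing.assert_allclose(curv_ic, curv_exp, rtol=0.01)


def random_ste_data(rng):
    n_ev = int(rng.integers(1, 40))
    n_cens = int(rng.integers(0, 200))
    pre = rng.uniform(0, 3000, n_ev)
    a = rng.uniform(10, 500, n_ev)
    return ste_data(
        [(float(p), float(x)) for p, x in zip(pre, a)],
        list(rng.uniform(500, 6000, n_cens)),
    )


class TestFit:
    def test_closed_form_example(self):
        # events s = [100, 300], one censored occasion A = 600:
        # λ̂ = 2 / (100 + 300 + 600) = 0.002
        data = ste_data([(0.0, 100.0), (200.0, 100.0)], [600.0])
        from spacetoevent.model import _mle

        lam = _mle(data, "exponential_approx")
        assert lam == pytest.approx(2.0 / 1000.0, rel=1e-9)

    def test_lognormal_ci_hand_value(self):
        """With 2 events, exp(1.96/sqrt(2)) ≈ 4.0, so the CI is roughly
        (λ̂/4, λ̂·4)."""
        table = make_table(
            [100.0] * 2, [[True, False], [False, True], [False, False]]
        )
        fit = fit_ste(table, seed=0, variant="exponential_approx")
        lci, uci = fit.conf_int()
        factor = math.exp(1.96 / math.sqrt(2))
        assert uci / fit.density_per_km2 == pytest.approx(factor, rel=1e-9)
        assert fit.density_per_km2 / lci == pytest.approx(factor, rel=1e-9)

    def test_numerical_mle_equals_closed_form_randomised(self):
        from spacetoevent.model import _mle

        rng = np.random.default_rng(11)
        for _ in range(200):
            data = random_ste_data(rng)
            ev = data.event
            closed = data.n_events / (
                data.s_m2[ev].sum() + data.exposure_m2[~ev].sum()
            )
            assert _mle(data, "exponential_approx") == pytest.approx(
                closed, rel=1e-6
            )

    def test_interval_censored_matches_grid_search_oracle(self):
        from spacetoevent.model import _mle

        rng = np.random.default_rng(5)
        for _ in range(20):
            data = random_ste_data(rng)
            lam_hat = _mle(data, "interval_censored")
            grid = np.linspace(lam_hat * 0.5, lam_hat * 1.5, 10_001)
            ll = [ste_log_likelihood(l, data, "interval_censored") for l in grid]
            lam_grid = grid[int(np.argmax(ll))]
            assert abs(lam_hat - lam_grid) <= (grid[1] - grid[0])

    def test_area_scaling_identity(self):
        table = make_table(
            np.linspace(100, 400, 4),
            np.random.default_rng(0).random((200, 4)) < 0.1,
        )
        base = fit_ste(table, seed=3, variant="exponential_approx")
        for c in (0.5, 10.0):
            scaled_table = make_table(np.linspace(100, 400, 4) * c, table.presence)
            scaled = fit_ste(scaled_table, seed=3, variant="exponential_approx")
            assert scaled.lambda_per_m2 * c == pytest.approx(
                base.lambda_per_m2, rel=1e-9
            )

    def test_zero_events_raises(self):
        table = make_table([100.0, 200.0], np.zeros((5, 2), dtype=bool))
        with pytest.raises(NoEventsError):
            fit_ste(table, seed=0)

    def test_single_event_warns_wide_ci(self):
        table = make_table([100.0], [[True], [False], [False]])
        with pytest.warns(UserWarning, match="single detection event"):
            fit_ste(table, seed=0)

    def test_ci_asymmetry_lognormal(self):
        table = make_table(
            np.linspace(100, 400, 4),
            np.random.default_rng(1).random((300, 4)) < 0.08,
        )
        fit = fit_ste(table, seed=0)
        lci, uci = fit.conf_int()
        assert uci - fit.density_per_km2 > fit.density_per_km2 - lci

    def test_se_matches_numerical_hessian(self):
        """Analytic Fisher SE λ̂/√n agrees with the numerical Hessian of
        the exponential log-likelihood at the MLE."""
        rng = np.random.default_rng(21)
        data = random_ste_data(rng)
        from spacetoevent.model import _mle

        lam = _mle(data, "exponential_approx")
        h = lam * 1e-4
        ll = lambda l: ste_log_likelihood(l, data, "exponential_approx")
        hess = (ll(lam + h) - 2 * ll(lam) + ll(lam - h)) / h**2
        se_numeric = math.sqrt(-1.0 / hess)
        se_analytic = lam / math.sqrt(data.n_events)
        assert se_numeric == pytest.approx(se_analytic, rel=1e-3)

    def test_multi_permutation_mean_and_seed_logging(self):
        table = make_table(
            np.linspace(100, 400, 6),
            np.random.default_rng(2).random((400, 6)) < 0.1,
        )
        fit = fit_ste(table, seed=42, n_permutations=8)
        assert len(fit.permutation_seeds) == 8
        assert len(set(fit.permutation_seeds)) == 8
        assert fit.lambda_per_m2 == pytest.approx(
            np.mean(fit.permutation_estimates)
        )

    def test_permutation_stability_on_large_simulated_dataset(self, big_sim_table):
        """Across 50 permutation seeds on a dataset with hundreds of events
        the estimate's coefficient of variation stays below 5%."""
        _, table, _ = big_sim_table
        model = STEModel(table)
        estimates = [
            model.fit(seed=seed).lambda_per_m2 for seed in range(50)
        ]
        n_events = model.sample(0).n_events
        assert n_events >= 300
        cv = np.std(estimates) / np.mean(estimates)
        assert cv < 0.05
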