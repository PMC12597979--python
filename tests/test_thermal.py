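"""Thermal performance curves, AUTPC, Arrhenius activation energy."""

import numpy as np
import pytest
from scipy import stats

import phytotraits as pt
from phytotraits.thermal import K_BOLTZMANN

from conftest import DEFAULT_T_LEVELS

TRUE = dict(a=0.2, b=0.05, t_ref=18.0, w=30.0)


def forward_rates(reps=4, **params):
    p = {**TRUE, **params}
    T = np.tile(DEFAULT_T_LEVELS, reps)
    return T, pt.thomas_tpc(T, p["a"], p["b"], p["t_ref"], p["w"])


class TestFitTPC:
    def test_exact_recovery_from_forward_simulation(self):
        T, mu = forward_rates()
        fit = pt.fit_tpc(T, mu, n_starts=60, seed=1)
        assert fit.ok
        assert fit.rss < 1e-10
        assert fit.a == pytest.approx(TRUE["a"], rel=1e-4)
        assert fit.b == pytest.approx(TRUE["b"], rel=1e-4)
        assert fit.t_ref == pytest.approx(TRUE["t_ref"], rel=1e-4)
        assert fit.w == pytest.approx(TRUE["w"], rel=1e-4)

    def test_structural_zeros_at_niche_edges(self):
        T, mu = forward_rates()
        fit = pt.fit_tpc(T, mu, n_starts=60, seed=1)
        for edge in (fit.t_ref - fit.w / 2, fit.t_ref + fit.w / 2):
            assert float(fit(edge)) == pytest.approx(0.0, abs=1e-10)

    def test_all_negative_rates_non_estimable(self):
        fit = pt.fit_tpc(DEFAULT_T_LEVELS, -np.ones(6), n_starts=5, seed=0)
        assert not fit.ok

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        T, mu = forward_rates()
        mu = mu + rng.normal(0, 0.05, mu.size)
        f1 = pt.fit_tpc(T, mu, n_starts=40, seed=11)
        f2 = pt.fit_tpc(T, mu, n_starts=40, seed=11)
        assert (f1.a, f1.b, f1.t_ref, f1.w) == (f2.a, f2.b, f2.t_ref, f2.w)

    def test_multistart_never_worse_than_default_start(self):
        rng = np.random.default_rng(8)
        T, mu = forward_rates()
        mu = mu + rng.normal(0, 0.1, mu.size)
        single = pt.fit_tpc(T, mu, n_starts=0, seed=0)
        multi = pt.fit_tpc(T, mu, n_starts=80, seed=0)
        assert multi.rss <= single.rss + 1e-12

    def test_too_few_temperatures_error(self):
        with pytest.raises(ValueError):
            pt.fit_tpc([12, 16, 20], [0.1, 0.2, 0.3], n_starts=5, seed=0)


class TestTopt:
    def test_b_zero_gives_t_ref(self):
        fit = pt.TPCFit(a=0.2, b=0.0, t_ref=18.0, w=30.0, rss=0, n=6)
        assert pt.tpc_topt(fit) == pytest.approx(18.0)

    def test_matches_numeric_argmax(self):
        fit = pt.TPCFit(a=0.2, b=0.05, t_ref=18.0, w=30.0, rss=0, n=6)
        grid = np.arange(fit.t_ref - fit.w / 2, fit.t_ref + fit.w / 2, 1e-3)
        numeric = grid[int(np.argmax(fit(grid)))]
        assert abs(pt.tpc_topt(fit) - numeric) < 1e-2

    def test_negative_b_puts_topt_below_t_ref(self):
        fit = pt.TPCFit(a=0.2, b=-0.05, t_ref=18.0, w=30.0, rss=0, n=6)
        assert pt.tpc_topt(fit) < 18.0


class TestAutpc:
    def test_constant_curve_rectangle(self):
        assert pt.autpc(lambda T: np.ones_like(T), 12.0, 26.0) == 14.0

    def test_linear_curve_exact_for_trapezoid(self):
        assert pt.autpc(lambda T: T, 0.0, 2.0) == pytest.approx(2.0)

    def test_grid_refinement_converges(self):
        fit = pt.TPCFit(**TRUE, rss=0, n=6)
        coarse = pt.autpc(fit, grid_step=0.1)
        fine = pt.autpc(fit, grid_step=0.001)
        assert abs(coarse - fine) / abs(fine) < 1e-3

    def test_monotone_under_pointwise_dominance(self):
        hi = pt.TPCFit(**TRUE, rss=0, n=6)
        lo = pt.TPCFit(**{**TRUE, "a": 0.9 * TRUE["a"]}, rss=0, n=6)
        assert pt.autpc(hi) >= pt.autpc(lo)


class TestBootstrapTPC:
    def test_zero_noise_band_degenerate(self):
        T, mu = forward_rates()
        band = pt.bootstrap_tpc(T, mu, B=30, seed=4, n_starts=3)
        assert np.max(band.upper - band.lower) < 1e-4

    def test_same_seed_identical_bands(self):
        rng = np.random.default_rng(9)
        T, mu = forward_rates()
        mu = mu + rng.normal(0, 0.05, mu.size)
        b1 = pt.bootstrap_tpc(T, mu, B=25, seed=13, n_starts=3)
        b2 = pt.bootstrap_tpc(T, mu, B=25, seed=13, n_starts=3)
        assert np.array_equal(b1.lower, b2.lower)
        assert np.array_equal(b1.upper, b2.upper)
        assert b1.autpc_interval == b2.autpc_interval

    def test_band_covers_true_curve_in_most_replicates(self):
        """Pointwise 95% band contains the generating curve at a mid-range
        temperature in about 95% of simulated experiments."""
        hits = 0
        n_rep = 30
        t_check = 20.0
        truth = pt.thomas_tpc(t_check, **TRUE)
        for i in range(n_rep):
            rng = np.random.default_rng(40_000 + i)
            T, mu = forward_rates()
            mu = mu + rng.normal(0, 0.04, mu.size)
            band = pt.bootstrap_tpc(T, mu, B=60, seed=50_000 + i, n_starts=3)
            k = int(np.argmin(np.abs(band.grid - t_check)))
            hits += band.lower[k] <= truth <= band.upper[k]
        assert 0.80 <= hits / n_rep <= 1.0


class TestRisingPart:
    def test_monotonic_tpc_keeps_all_positive(self):
        # T_opt of the generating curve is 23 C; shift t_ref so it exceeds 26
        T, mu = forward_rates(t_ref=24.0)
        fit = pt.fit_tpc(T, mu, n_starts=60, seed=2)
        t_r, mu_r = pt.rising_part(T, mu, fit)
        assert t_r.size == np.sum(mu > 0)

    def test_all_negative_leaves_nothing(self):
        fit = pt.TPCFit(**TRUE, rss=0, n=6)
        t_r, mu_r = pt.rising_part(DEFAULT_T_LEVELS, -np.ones(6), fit)
        assert t_r.size == 0

    def test_levels_above_topt_excluded(self):
        # (a, b, t_ref, w) = (0.2, 0.05, 18, 30) has T_opt = 23.0 exactly
        T, mu = forward_rates()
        fit = pt.fit_tpc(T, mu, n_starts=60, seed=3)
        assert pt.tpc_topt(fit) == pytest.approx(23.0, abs=1e-3)
        t_r, _ = pt.rising_part(T, mu, fit)
        assert set(np.unique(t_r)) == {12.0, 16.0, 20.0, 22.0}


class TestArrhenius:
    def test_noiseless_recovery(self):
        T_k = np.array([285.0, 290.0, 295.0, 300.0])
        mu = 2.0 * np.exp(-0.32 / (K_BOLTZMANN * T_k))
        fit = pt.fit_arrhenius(T_k - 273.15, mu)
        assert fit.ea == pytest.approx(0.32, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_rates_zero_ea(self):
        fit = pt.fit_arrhenius([12.0, 18.0, 24.0], [0.5, 0.5, 0.5])
        assert fit.ea == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_value_on_collinear_data(self):
        # slope through (T=285 K, mu=1), (T=295 K, mu=2):
        # Ea = k * ln 2 / (1/285 - 1/295) ~= 0.502 eV; a third point placed
        # exactly on that line leaves the OLS slope unchanged.
        x1, x2 = 1 / (K_BOLTZMANN * 285.0), 1 / (K_BOLTZMANN * 295.0)
        expected = np.log(2.0) / (x1 - x2)
        x3 = (x1 + x2) / 2
        t3_k = 1 / (K_BOLTZMANN * x3)
        fit = pt.fit_arrhenius(
            np.array([285.0, t3_k, 295.0]) - 273.15,
            np.array([1.0, np.sqrt(2.0), 2.0]))
        assert fit.ea == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.502, abs=5e-4)

    def test_rescaling_rates_changes_only_prefactor(self):
        T_c = np.array([12.0, 16.0, 20.0, 24.0])
        mu = np.array([0.2, 0.3, 0.45, 0.6])
        f0 = pt.fit_arrhenius(T_c, mu)
        f1 = pt.fit_arrhenius(T_c, 10 * mu)
        assert f1.ea == pytest.approx(f0.ea, abs=1e-12)
        assert f1.ln_a - f0.ln_a == pytest.approx(np.log(10), abs=1e-9)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            pt.fit_arrhenius([12, 16, 20], [0.5, -0.1, 0.6])


class TestEaSummary:
    def test_all_at_reference(self):
        s = pt.ea_summary([0.32, 0.32, 0.32])
        assert s.t_stat == 0.0 and s.p_value == 1.0

    def test_symmetric_about_reference(self):
        s = pt.ea_summary([0.22, 0.42, 0.32])
        assert s.mean_ea == pytest.approx(0.32)
        assert s.t_stat == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_t_and_p(self):
        vals = np.array([0.5, 0.6, 0.7])
        mean, sd = vals.mean(), vals.std(ddof=1)
        t_hand = (mean - 0.32) / (sd / np.sqrt(3))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=2)
        s = pt.ea_summary(vals)
        assert s.t_stat == pytest.approx(t_hand, abs=1e-12)
        assert s.p_value == pytest.approx(p_hand, abs=1e-12)

    def test_single_value_gives_summary_without_test(self):
        s = pt.ea_summary([0.4])
        assert s.mean_ea == 0.4 and np.isnan(s.t_stat)
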