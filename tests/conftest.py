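import numpy as np
import pytest

import phytotraits as pt

DEFAULT_S_LEVELS = np.array([1.94, 3.87, 7.75, 15.50, 31.00, 47.47])
DEFAULT_T_LEVELS = np.array([12.0, 16.0, 20.0, 22.0, 24.0, 26.0])


@pytest.fixture(scope="session")
def design():
    return pt.ExperimentDesign()


@pytest.fixture(scope="session")
def timegrid():
    """The 11-measurement / 6-day observation grid."""
    return np.array([0, 0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 6], dtype=float)


def make_series(times, rfu, strain="s", temperature=20.0, phosphorus=10.0,
                replicate=1):
    return pt.FluorescenceSeries(strain, temperature, phosphorus, replicate,
                                 np.asarray(times, float),
                                 np.asarray(rfu, float))


def simulate_monod_rates(seed, true_mu=1.0, true_ks=5.0, noise_cv=0.10,
                         timegrid=None):
    """Per-well growth rates estimated from simulated fluorescence series.

    One Monod curve's worth of data: the six experimental phosphorus levels
    x 4 replicate wells, each an 11-point RFU series at the generator's
    default 10% CV multiplicative noise, passed through detection filtering
    and AICc growth-model selection — i.e. the rates the pipeline's Monod
    stage actually sees (their error is close to homoscedastic because the
    log-slope error does not scale with the rate).
    """
    t = (np.array([0, 0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 6], dtype=float)
         if timegrid is None else timegrid)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    S_out, mu_out = [], []
    for s in DEFAULT_S_LEVELS:
        rate = float(pt.monod(s, true_mu, true_ks))
        for rep in range(4):
            rfu = 10 * np.exp(rate * t) * np.exp(
                rng.normal(-0.5 * sigma ** 2, sigma, t.size))
            series = pt.FluorescenceSeries("x", 20.0, float(s), rep, t, rfu)
            best = pt.select_best(
                pt.fit_growth_models(pt.filter_series(series, 2.25)))
            S_out.append(s)
            mu_out.append(best.mu)
    return np.array(S_out), np.array(mu_out)


@pytest.fixture(scope="session")
def monod_recovery_study():
    """Monod fits and bootstrap intervals over 200 simulated experiments.

    Truth μ_max = 1.0 day⁻¹, K_s = 5.0 μmol·L⁻¹; each replicate experiment
    yields n = 24 estimated rates (6 levels x 4 wells) from series at the
    default 10% CV noise.  Shared by the recovery and interval-coverage
    checks.
    """
    true_mu, true_ks, m = 1.0, 5.0, 0.1
    fits, boots = [], []
    for i in range(200):
        S, mu_obs = simulate_monod_rates(10_000 + i, true_mu, true_ks)
        fits.append(pt.fit_monod(S, mu_obs, n_starts=20, seed=20_000 + i))
        boots.append(pt.bootstrap_monod(S, mu_obs, B=200, seed=30_000 + i,
                                        n_starts=2))
    return {"true_mu_max": true_mu, "true_ks": true_ks,
            "true_p_star": pt.pstar(true_ks, true_mu, m),
            "fits": fits, "boots": boots}


def _trend_slopes(strength, n_rep=200):
    design = pt.ExperimentDesign()
    trends = []
    for rep in range(n_rep):
        truths = pt.make_truth(8, strength, seed=100_000 + rep)
        _, trend = pt.run_adaptation_analysis(truths, design,
                                              seed=200_000 + rep)
        trends.append(trend.trend_slope)
    return np.array(trends)


@pytest.fixture(scope="session")
def planted_trends():
    """Stage-2 trend slopes from 200 end-to-end runs, planted signal."""
    return _trend_slopes(1.0)


@pytest.fixture(scope="session")
def null_trends():
    """Stage-2 trend slopes from 200 end-to-end runs with no planted
    adaptation (adaptation_strength = 0)."""
    return _trend_slopes(0.0)
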