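"""Growth-rate estimation: detection filtering, segmented fits, AICc."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phytotraits as pt
from phytotraits.growth import TooFewPointsError

from conftest import make_series


class TestDetectionLimit:
    @pytest.mark.parametrize("blanks,expected", [
        ([4.0, 4.5, 5.0], 2.25),
        ([3.0, 3.0, 3.0, 3.0], 1.5),
        ([1.0, 2.0, 100.0], 1.0),     # median is robust to the outlier
    ])
    def test_half_of_median(self, blanks, expected):
        assert pt.compute_detection_limit(blanks) == pytest.approx(expected)

    def test_empty_blanks_error(self):
        with pytest.raises(ValueError):
            pt.compute_detection_limit([])


class TestFilterSeries:
    def test_all_above_threshold_unchanged(self, timegrid):
        s = make_series(timegrid, np.linspace(3, 30, timegrid.size))
        out = pt.filter_series(s, 2.25)
        assert np.array_equal(out.rfu, s.rfu)
        assert out.strain == s.strain and out.replicate == s.replicate

    def test_all_below_threshold_empty(self, timegrid):
        out = pt.filter_series(make_series(timegrid,
                                           np.full(timegrid.size, 1.0)), 2.25)
        assert len(out) == 0

    def test_strictly_less_comparison_and_order(self, timegrid):
        rfu = np.linspace(3, 30, timegrid.size)
        rfu[[0, 4, 7]] = [1.0, 2.0, 2.24]        # 3 points below 2.25
        rfu[1] = 2.25                            # exactly at threshold: kept
        out = pt.filter_series(make_series(timegrid, rfu), 2.25)
        assert len(out) == 8
        assert np.all(np.diff(out.times) > 0)

    def test_nonpositive_threshold_rejected(self, timegrid):
        s = make_series(timegrid, np.full(timegrid.size, 5.0))
        with pytest.raises(ValueError):
            pt.filter_series(s, 0.0)


class TestSegmentedFits:
    def test_noiseless_exponential_all_models_agree(self, timegrid):
        s = make_series(timegrid, 10 * np.exp(0.8 * timegrid))
        fits = pt.fit_growth_models(s)
        assert {f.model for f in fits} == {"exponential", "lag",
                                           "saturation", "lag_saturation"}
        for f in fits:
            assert f.mu == pytest.approx(0.8, abs=1e-9)
        assert pt.select_best(fits).model == "exponential"

    def test_lag_breakpoint_recovered(self, timegrid):
        rfu = np.where(timegrid <= 1.0, 10.0, 10 * np.exp(0.5 * (timegrid - 1)))
        fits = pt.fit_growth_models(make_series(timegrid, rfu))
        lag = next(f for f in fits if f.model == "lag")
        assert lag.mu == pytest.approx(0.5, abs=1e-9)
        assert lag.lag_time == pytest.approx(1.0)
        assert pt.select_best(fits).model == "lag"

    def test_saturation_breakpoint_recovered(self, timegrid):
        rfu = 10 * np.exp(0.6 * np.minimum(timegrid, 3.0))
        fits = pt.fit_growth_models(make_series(timegrid, rfu))
        sat = next(f for f in fits if f.model == "saturation")
        assert sat.mu == pytest.approx(0.6, abs=1e-9)
        assert sat.sat_time == pytest.approx(3.0)
        assert pt.select_best(fits).model == "saturation"

    def test_three_points_only_single_line(self):
        fits = pt.fit_growth_models(make_series([0, 1, 2], [10, 20, 40]))
        assert [f.model for f in fits] == ["exponential"]
        assert pt.select_best(fits).model == "exponential"

    def test_too_few_points_error(self):
        with pytest.raises(TooFewPointsError):
            pt.fit_growth_models(make_series([0, 1], [10, 20]))

    def test_rescaling_rfu_only_shifts_intercept(self, timegrid):
        rng = np.random.default_rng(3)
        rfu = 10 * np.exp(0.4 * timegrid) * np.exp(rng.normal(0, 0.05, 11))
        base = pt.fit_growth_models(make_series(timegrid, rfu))
        scaled = pt.fit_growth_models(make_series(timegrid, 3.7 * rfu))
        for f0, f1 in zip(base, scaled):
            assert f1.mu == pytest.approx(f0.mu, abs=1e-12)
            assert f1.intercept - f0.intercept == pytest.approx(
                math.log(3.7), abs=1e-9)

    def test_negative_growth_propagated(self, timegrid):
        fits = pt.fit_growth_models(
            make_series(timegrid, 30 * np.exp(-0.3 * timegrid)))
        assert pt.select_best(fits).mu == pytest.approx(-0.3, abs=1e-9)


class TestAicc:
    def test_hand_computed_value(self):
        # n*ln(rss/n) + 2p + 2p(p+1)/(n-p-1) at rss=1, n=10, p=2
        expected = 10 * math.log(0.1) + 4 + 12 / 7
        assert pt.aicc(1.0, 10, 2) == pytest.approx(expected, abs=1e-12)

    def test_penalty_monotone_in_p(self):
        assert pt.aicc(1.0, 10, 3) > pt.aicc(1.0, 10, 2)

    def test_converges_to_aic_for_large_n(self):
        n, p = 10_000, 3
        aic = n * math.log(1.0 / n) + 2 * p
        assert abs(pt.aicc(1.0, n, p) - aic) < 0.01

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            pt.aicc(1.0, 3, 2)


class TestSelectBest:
    def test_tie_broken_toward_fewer_parameters(self):
        f2 = pt.GrowthFit("exponential", 0.5, 0.0, None, None, 1.0, -3.0, 11)
        f3 = pt.GrowthFit("lag", 0.5, 0.0, 1.0, None, 1.0, -3.0, 11)
        assert pt.select_best([f3, f2]).model == "exponential"

    def test_empty_error(self):
        with pytest.raises(ValueError):
            pt.select_best([])


def brute_force_best(t, y):
    """Independent enumeration of every admissible segment partition.

    Scans all partitions of the observed grid with >= 2 points per segment,
    fitting each segment separately with numpy.linalg.lstsq / plain means,
    and returns the minimum total RSS and line slope per model.
    """
    n = t.size

    def ols(lo, hi):
        A = np.column_stack([np.ones(hi - lo), t[lo:hi]])
        beta, *_ = np.linalg.lstsq(A, y[lo:hi], rcond=None)
        resid = y[lo:hi] - A @ beta
        return float(resid @ resid), float(beta[1])

    def flat(lo, hi):
        seg = y[lo:hi]
        return float(np.sum((seg - seg.mean()) ** 2))

    out = {"exponential": ols(0, n)}
    best = None
    for i in range(1, n - 2):
        rss_l, mu = ols(i + 1, n)
        rss = flat(0, i + 1) + rss_l
        if best is None or rss < best[0]:
            best = (rss, mu)
    if n >= 5:
        out["lag"] = best
    best = None
    for j in range(1, n - 2):
        rss_l, mu = ols(0, j + 1)
        rss = rss_l + flat(j + 1, n)
        if best is None or rss < best[0]:
            best = (rss, mu)
    if n >= 5:
        out["saturation"] = best
    best = None
    for i in range(1, n - 4):
        for j in range(i + 2, n - 2):
            rss_l, mu = ols(i + 1, j + 1)
            rss = flat(0, i + 1) + rss_l + flat(j + 1, n)
            if best is None or rss < best[0]:
                best = (rss, mu)
    if n >= 6 and best is not None:
        out["lag_saturation"] = best
    return out


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("n", [5, 7, 9, 11])
def test_breakpoint_search_matches_brute_force(seed, n):
    """The grid-restricted least-squares search equals exhaustive
    enumeration of admissible breakpoints on short series."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 6, n))
    t[0] = 0.0
    y = 2.0 + 0.5 * np.clip(t, 0.7, 4.5) + rng.normal(0, 0.15, n)
    fits = pt.fit_growth_models(make_series(t, np.exp(y)))
    oracle = brute_force_best(t, y)
    for f in fits:
        rss_o, mu_o = oracle[f.model]
        assert f.rss == pytest.approx(rss_o, abs=1e-9)
        assert f.mu == pytest.approx(mu_o, abs=1e-7)


@settings(deadline=None, max_examples=25)
@given(mu=st.floats(-1, 1.5), scale=st.floats(0.1, 50),
       seed=st.integers(0, 10_000))
def test_mu_invariant_to_rfu_rescaling(mu, scale, seed):
    t = np.array([0, 0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 6])
    rng = np.random.default_rng(seed)
    rfu = 10 * np.exp(mu * t + rng.normal(0, 0.1, t.size))
    best0 = pt.select_best(pt.fit_growth_models(make_series(t, rfu)))
    best1 = pt.select_best(pt.fit_growth_models(make_series(t, scale * rfu)))
    assert best1.model == best0.model
    assert best1.mu == pytest.approx(best0.mu, abs=1e-10)
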