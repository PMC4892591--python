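import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrosync.chronology import (
    Chronology,
    GrowthCurveFit,
    biweight_mean,
    build_chronology,
    detrend_to_index,
    eps_statistic,
    fit_growth_curve,
    mean_sensitivity,
    sss_profile,
    truncate_by_sss,
)
from dendrosync.tucson import RingWidthSeries
from dendrosync.simulate import NetworkSimConfig, generate_network
from conftest import network_chronologies


def series_of(widths, core="c", site="s", first=1900):
    return RingWidthSeries(core, site, first, np.asarray(widths, dtype=float))


# ---------------------------------------------------------------- growth curves

class TestGrowthCurve:
    def test_noise_free_negative_exponential_recovered(self):
        t = np.arange(150)
        s = series_of(2.0 * np.exp(-0.05 * t) + 0.3)
        fit = fit_growth_curve(s)
        assert fit.model == "negative_exponential"
        for name, true in (("a", 2.0), ("b", 0.05), ("k", 0.3)):
            assert abs(fit.parameters[name] - true) / true < 1e-3

    def test_constant_series_takes_zero_slope_line(self):
        fit = fit_growth_curve(series_of(np.full(40, 1.3)))
        assert fit.model == "straight_line"
        assert abs(fit.parameters["slope"]) < 1e-9
        np.testing.assert_allclose(fit.fitted_values, 1.3)

    def test_increasing_series_forces_spline(self):
        fit = fit_growth_curve(series_of(0.5 + 0.01 * np.arange(80)))
        assert fit.model == "smoothing_spline"
        assert np.all(fit.fitted_values > 0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="10 years"):
            fit_growth_curve(series_of(np.full(5, 1.0)))


class TestDetrend:
    def test_series_equal_to_fit_gives_unit_indices(self):
        w = 1.5 * np.exp(-0.02 * np.arange(60)) + 0.4
        s = series_of(w)
        fit = GrowthCurveFit("negative_exponential", {}, w.copy())
        np.testing.assert_allclose(detrend_to_index(s, fit).indices, 1.0)

    def test_doubling_widths_doubles_indices(self):
        w = np.linspace(2.0, 0.5, 50)
        fit = GrowthCurveFit("straight_line", {}, np.full(50, 1.0))
        i1 = detrend_to_index(series_of(w), fit).indices
        i2 = detrend_to_index(series_of(2 * w), fit).indices
        np.testing.assert_allclose(i2, 2 * i1)

    def test_fit_at_width_floor_rejected(self):
        s = series_of(np.full(20, 0.5))
        fit = GrowthCurveFit("straight_line", {}, np.full(20, 0.005))
        with pytest.raises(ValueError, match="floor"):
            detrend_to_index(s, fit)


# ---------------------------------------------------------------- biweight mean

def reference_biweight(values, c=9.0, tol=1e-6, max_iter=50):
    """Independently coded biweight location (loop/if style, no vectorization)."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    if n == 2:
        return (xs[0] + xs[1]) / 2.0
    med = xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2.0
    m = med
    for _ in range(max_iter):
        devs = sorted(abs(v - m) for v in xs)
        mad = devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2.0
        if mad == 0.0:
            return m
        num = den = 0.0
        for v in xs:
            u = (v - m) / (c * mad)
            if abs(u) < 1.0:
                w = (1.0 - u * u) ** 2
                num += w * v
                den += w
        if den == 0.0:
            return m
        m_new = num / den
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


class TestBiweight:
    def test_symmetric_triple(self):
        assert biweight_mean([0.9, 1.0, 1.1]) == pytest.approx(1.0)

    def test_outlier_downweighted_and_matches_reference(self):
        vals = [1.0, 1.0, 1.0, 1.0, 5.0]
        m = biweight_mean(vals)
        assert abs(m - 1.0) < abs(np.mean(vals) - 1.0)
        assert m == pytest.approx(reference_biweight(vals), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(1.0, 0.3, 17)
        vals[0] += 3.0
        assert biweight_mean(vals) == pytest.approx(reference_biweight(vals), abs=1e-9)

    def test_single_value(self):
        assert biweight_mean([0.73]) == 0.73

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            biweight_mean([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20),
           st.floats(-5, 5), st.floats(0.1, 3))
    def test_shift_scale_equivariant_and_bounded(self, vals, shift, scale):
        m = biweight_mean(vals)
        assert min(vals) - 1e-9 <= m <= max(vals) + 1e-9
        m2 = biweight_mean([scale * v + shift for v in vals])
        assert m2 == pytest.approx(scale * m + shift, abs=1e-4 * scale + 1e-9)


# ---------------------------------------------------------------- SSS / EPS / MS

class TestSignalStrength:
    def test_hand_evaluated_value(self):
        # n(1 + (N-1) rbar) / (N (1 + (n-1) rbar)) at rbar=.3, n=5, N=40
        got = sss_profile(0.3, np.array([5]), 40)[0]
        assert got == pytest.approx(5 * (1 + 39 * 0.3) / (40 * (1 + 4 * 0.3)), abs=1e-12)
        assert got == pytest.approx(0.7216, abs=5e-5)

    def test_full_depth_and_perfect_correlation_give_one(self):
        assert sss_profile(0.37, np.array([12]), 12)[0] == pytest.approx(1.0)
        np.testing.assert_allclose(sss_profile(1.0, np.arange(1, 9), 8), 1.0)

    def test_monotone_in_depth(self):
        for rbar in (0.1, 0.3, 0.5, 0.7, 0.9):
            prof = sss_profile(rbar, np.arange(1, 41), 40)
            assert np.all(np.diff(prof) > 0)
            assert prof[-1] == pytest.approx(1.0)
            assert np.all((0 < prof) & (prof <= 1))

    def test_nonpositive_rbar_rejected(self):
        with pytest.raises(ValueError):
            sss_profile(0.0, np.array([3]), 10)

    def test_eps_formula(self):
        assert eps_statistic(0.3, 40) == pytest.approx(40 * 0.3 / (40 * 0.3 + 0.7))


class TestMeanSensitivity:
    def test_constant_is_zero(self):
        assert mean_sensitivity(np.full(30, 1.7)) == 0.0

    def test_hand_examples(self):
        assert mean_sensitivity([1, 2]) == pytest.approx(2 / 3)
        assert mean_sensitivity([1, 2, 1]) == pytest.approx(2 / 3)

    def test_zero_sum_pair_rejected(self):
        with pytest.raises(ValueError):
            mean_sensitivity([1.0, -1.0, 1.0])


# ---------------------------------------------------------------- chronology build

def index_series(vals, core="c1", site="s", first=1950):
    from dendrosync.chronology import IndexSeries
    return IndexSeries(core, site, first, np.asarray(vals, dtype=float))


class TestBuildChronology:
    def test_single_core_identity(self):
        vals = np.random.default_rng(0).uniform(0.5, 1.5, 40)
        ch = build_chronology([index_series(vals)])
        np.testing.assert_allclose(ch.index, vals)
        assert np.isnan(ch.rbar)

    def test_identical_cores_give_shared_series_and_unit_rbar(self):
        vals = np.random.default_rng(1).uniform(0.5, 1.5, 50)
        cores = [index_series(vals, core=f"c{i}") for i in range(4)]
        ch = build_chronology(cores)
        np.testing.assert_allclose(ch.index, vals, atol=1e-9)
        assert ch.rbar == pytest.approx(1.0)
        np.testing.assert_allclose(ch.sss, 1.0)

    def test_noise_free_bundle_recovers_common_signal(self):
        cfg = NetworkSimConfig(n_sites=3, cores_per_site=4, first_year=1900,
                               last_year=2000, site_noise_sd=0.0,
                               common_signal_fraction=1 - 1e-12,
                               extreme_year_prob=0.0, stagger_fraction=0.0, seed=5)
        series, truth = generate_network(cfg)
        a, b, k = cfg.age_trend
        idx = []
        for s in series[:4]:  # one site
            age = np.arange(len(s), dtype=float)
            fit = GrowthCurveFit("negative_exponential", {}, a * np.exp(-b * age) + k)
            idx.append(detrend_to_index(s, fit))
        ch = build_chronology(idx)
        np.testing.assert_allclose(ch.index, 1.0 + truth.common_signal, atol=1e-6)

    def test_one_factor_rbar_matches_covariance_algebra(self):
        # cores of one site share the common AND the site-level term, so their
        # pairwise covariance is the full interannual variance sigma^2
        f, sigma, core_sd, n_cores = 0.5, 0.15, 0.1, 12
        expected_rbar = sigma**2 / (sigma**2 + core_sd**2)
        rbars = []
        for seed in range(30):
            cfg = NetworkSimConfig(n_sites=1, cores_per_site=n_cores,
                                   first_year=1850, last_year=2005,
                                   common_signal_fraction=f, interannual_sd=sigma,
                                   site_noise_sd=core_sd, extreme_year_prob=0.0,
                                   stagger_fraction=0.0, seed=seed)
            series, truth = generate_network(cfg)
            a, b, k = cfg.age_trend
            idx = []
            for s in series:
                age = np.arange(len(s), dtype=float)
                fit = GrowthCurveFit("negative_exponential", {}, a * np.exp(-b * age) + k)
                idx.append(detrend_to_index(s, fit))
            rbars.append(build_chronology(idx).rbar)
        mc_sd = np.std(rbars, ddof=1) / np.sqrt(len(rbars))
        assert abs(np.mean(rbars) - expected_rbar) < max(2 * mc_sd, 0.01)

    def test_index_means_near_one_on_default_noise(self):
        df = network_chronologies(NetworkSimConfig(n_sites=4, cores_per_site=5,
                                                   seed=11), detrend="fit")
        means = df.mean()
        assert ((means > 0.8) & (means < 1.2)).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_chronology([])


class TestTruncateBySSS:
    def make(self, depth, rbar=0.4, first=1800, n_total=None):
        depth = np.asarray(depth)
        years = np.arange(first, first + len(depth))
        if n_total is None:
            n_total = int(depth.max())
        sss = sss_profile(rbar, depth, n_total)
        return Chronology("x", years, np.ones(len(depth)), depth, rbar,
                          eps_statistic(rbar, n_total), sss, n_total, 0.1)

    def test_no_truncation_when_all_reliable(self):
        ch = self.make([8, 8, 8, 8, 8])
        out = truncate_by_sss(ch)
        assert out.reliable_span == (1800, 1804)
        assert len(out.years) == 5

    def test_cut_year_matches_exhaustive_scan(self):
        depth = np.array([1, 1, 2, 4, 8, 8, 8, 8, 8, 8])
        ch = self.make(depth)
        out = truncate_by_sss(ch, 0.85)
        # brute force: earliest year from which SSS >= .85 holds to the end
        sss = ch.sss
        expected = None
        for i in range(len(sss)):
            if all(s >= 0.85 for s in sss[i:]):
                expected = ch.years[i]
                break
        assert out.reliable_span[0] == expected
        np.testing.assert_array_equal(out.full_depth, depth)

    def test_no_reliable_year_reports_max(self):
        ch = self.make([1, 1, 1], rbar=0.1, n_total=4)
        with pytest.raises(ValueError, match="max SSS"):
            truncate_by_sss(ch, 0.85)


def test_export_chronology_writes_year_index_depth_sss(tmp_path):
    import pandas as pd
    from dendrosync.chronology import export_chronology
    vals = np.random.default_rng(3).uniform(0.8, 1.2, 40)
    cores = [index_series(vals + 0.01 * i, core=f"c{i}") for i in range(4)]
    ch = build_chronology(cores)
    p = tmp_path / "site.tsv"
    export_chronology(ch, p)
    back = pd.read_csv(p, sep="\t")
    assert list(back.columns) == ["year", "index", "depth", "sss"]
    np.testing.assert_allclose(back["index"], ch.index, atol=1e-6)
    assert (back["depth"] == 4).all()
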