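import numpy as np
import pandas as pd
import pytest

from dendrosync.chronology import GrowthCurveFit, build_chronology, detrend_to_index
from dendrosync.climate import read_climate_table
from dendrosync.simulate import (
    ClimateSimConfig,
    NetworkSimConfig,
    generate_climate,
    generate_network,
    simulate_threshold_study,
    write_fixture_bundle,
)
from dendrosync.synchrony import correlation_pca
from dendrosync.tucson import read_rwl
from conftest import network_chronologies


class TestGenerateNetwork:
    def test_same_seed_identical_output(self):
        cfg = NetworkSimConfig(n_sites=3, cores_per_site=3, seed=9)
        s1, t1 = generate_network(cfg)
        s2, t2 = generate_network(cfg)
        for a, b in zip(s1, s2):
            assert a.core_id == b.core_id and a.first_year == b.first_year
            np.testing.assert_array_equal(a.widths, b.widths)
        np.testing.assert_array_equal(t1.common_signal, t2.common_signal)
        assert t1.extreme_years == t2.extreme_years

    def test_near_degenerate_no_noise_case_gives_full_pc1(self):
        cfg = NetworkSimConfig(n_sites=5, cores_per_site=2, first_year=1900,
                               last_year=2000, site_noise_sd=0.0,
                               common_signal_fraction=0.99,
                               extreme_year_prob=0.0, stagger_fraction=0.0, seed=1)
        df = network_chronologies(cfg, detrend="truth")
        share = correlation_pca(df).shares[0]
        assert share > 97.0

    def test_pc1_share_matches_one_factor_covariance_algebra(self):
        f = 0.5
        shares = []
        cfg0 = None
        for seed in range(25):
            cfg = NetworkSimConfig(n_sites=10, cores_per_site=6, first_year=1825,
                                   last_year=2005, common_signal_fraction=f,
                                   extreme_year_prob=0.0, stagger_fraction=0.0,
                                   seed=seed)
            cfg0 = cfg
            df = network_chronologies(cfg, detrend="truth")
            shares.append(correlation_pca(df).shares[0])
        _, truth = generate_network(cfg0)
        expected = truth.expected_pc1_share()   # f + (1-f)/p, core-noise attenuated
        mc_sd = np.std(shares, ddof=1) / np.sqrt(len(shares))
        assert abs(np.mean(shares) - expected) < max(2 * mc_sd, 0.7)

    def test_site_regression_recovers_signal_fraction(self):
        f = 0.4
        r2s = []
        expected = None
        for seed in range(50):
            cfg = NetworkSimConfig(n_sites=1, cores_per_site=8, first_year=1850,
                                   last_year=2005, common_signal_fraction=f,
                                   extreme_year_prob=0.0, stagger_fraction=0.0,
                                   seed=seed)
            series, truth = generate_network(cfg)
            expected = truth.expected_site_r2()
            a, b, k = cfg.age_trend
            idx = []
            for s in series:
                age = np.arange(len(s), dtype=float)
                fit = GrowthCurveFit("negative_exponential", {}, a * np.exp(-b * age) + k)
                idx.append(detrend_to_index(s, fit))
            ch = build_chronology(idx)
            r2s.append(np.corrcoef(ch.index, truth.common_signal)[0, 1] ** 2)
        mc_sd = np.std(r2s, ddof=1) / np.sqrt(len(r2s))
        assert abs(np.mean(r2s) - expected) < max(2 * mc_sd, 0.02)

    def test_extreme_years_recorded_and_propagated(self):
        cfg = NetworkSimConfig(n_sites=2, cores_per_site=2, extreme_year_prob=0.05,
                               site_noise_sd=0.0, stagger_fraction=0.0, seed=3)
        _, truth = generate_network(cfg)
        assert truth.extreme_years
        pos = np.searchsorted(truth.years, truth.extreme_years)
        z = truth.signal_z[pos]
        np.testing.assert_allclose(np.abs(z), cfg.extreme_shock)

    def test_width_floor_config_rejected(self):
        cfg = NetworkSimConfig(n_sites=2, cores_per_site=2, seed=4,
                               age_trend=(0.02, 0.1, 0.0), interannual_sd=0.3)
        with pytest.raises(ValueError, match="floor"):
            generate_network(cfg)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            generate_network(NetworkSimConfig(common_signal_fraction=1.0, seed=0))

    def test_staggered_depth_grows_toward_present(self):
        cfg = NetworkSimConfig(n_sites=1, cores_per_site=12, seed=6)
        series, _ = generate_network(cfg)
        starts = [s.first_year for s in series]
        assert len(set(starts)) > 1
        assert all(s.last_year == cfg.last_year for s in series)


class TestGenerateClimate:
    def test_constant_configuration(self):
        cfg = ClimateSimConfig(variables=("tmp",), first_year=1950, last_year=1960,
                               ar1_coefficient={"tmp": 0.0}, anomaly_sd={"tmp": 0.0},
                               seed=0)
        clim = generate_climate(cfg)
        jan = clim[clim["month"] == 1]["tmp"]
        assert jan.nunique() == 1

    def test_ar1_coefficient_reproduced(self):
        cfg = ClimateSimConfig(variables=("tmp",), first_year=1500, last_year=2000,
                               ar1_coefficient={"tmp": 0.5}, seed=1)
        clim = generate_climate(cfg)
        # remove the seasonal cycle, then check lag-1 autocorrelation
        anom = clim.groupby("month")["tmp"].transform(lambda s: s - s.mean())
        x = anom.to_numpy()
        r = np.corrcoef(x[1:], x[:-1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_coupling_correlation_within_sampling_band(self):
        net = NetworkSimConfig(n_sites=2, cores_per_site=2, first_year=1801,
                               last_year=2000, extreme_year_prob=0.0, seed=2)
        _, truth = generate_network(net)
        cfg = ClimateSimConfig(first_year=1801, last_year=2000, seed=3,
                               coupling=("tmn", 1, 0.6))
        clim = generate_climate(cfg, truth)
        jan = clim[clim["month"] == 1].set_index("year")["tmn"]
        r = np.corrcoef(jan.loc[truth.years], truth.common_signal)[0, 1]
        assert 0.5 <= r <= 0.7

    def test_same_seed_identical_table(self):
        cfg = ClimateSimConfig(first_year=1950, last_year=2000, seed=4)
        pd.testing.assert_frame_equal(generate_climate(cfg), generate_climate(cfg))

    def test_coupling_without_truth_rejected(self):
        cfg = ClimateSimConfig(first_year=1950, last_year=2000,
                               coupling=("tmn", 1, 0.5), seed=5)
        with pytest.raises(ValueError, match="network"):
            generate_climate(cfg)

    def test_trend_segment_applied(self):
        cfg = ClimateSimConfig(variables=("tmp",), first_year=1900, last_year=2000,
                               ar1_coefficient={"tmp": 0.0}, anomaly_sd={"tmp": 0.0},
                               trend_segments={"tmp": [((1950, 2000), 0.05)]}, seed=6)
        clim = generate_climate(cfg)
        jul = clim[clim["month"] == 7].set_index("year")["tmp"]
        assert jul.loc[1950] == jul.loc[1900]
        assert jul.loc[2000] - jul.loc[1950] == pytest.approx(0.05 * 50)


class TestFixtureBundle:
    def test_round_trip_at_format_precision(self, tmp_path):
        cfg = NetworkSimConfig(n_sites=2, cores_per_site=3, seed=7)
        series, truth = generate_network(cfg)
        clim = generate_climate(ClimateSimConfig(first_year=1950, last_year=2005,
                                                 seed=8), truth)
        manifest = write_fixture_bundle(series, clim, truth, tmp_path)
        assert set(manifest["rwl"]) == {"s01", "s02"}
        back = read_rwl(tmp_path / "s01.rwl")
        orig = [s for s in series if s.site_id == "s01"]
        for a, b in zip(orig, back):
            np.testing.assert_allclose(a.widths, b.widths, atol=0.005)
        clim_back = read_climate_table(tmp_path / "climate.tsv")
        assert len(clim_back) == len(clim)
        assert (tmp_path / "truth.txt").exists()
        assert (tmp_path / "manifest.json").exists()

    def test_seventeen_site_bundle_matches_network_scale(self, tmp_path, step_network):
        cfg, series, truth = step_network
        manifest = write_fixture_bundle(series, None, truth, tmp_path / "b")
        assert len(manifest["rwl"]) == 17
        assert truth.years[0] == 1825 and truth.years[-1] == 2005

    def test_empty_network_rejected(self, tmp_path):
        cfg = NetworkSimConfig(n_sites=1, cores_per_site=1, seed=9)
        _, truth = generate_network(cfg)
        with pytest.raises(ValueError, match="empty"):
            write_fixture_bundle([], None, truth, tmp_path / "x")
        assert not (tmp_path / "x").exists()


def test_threshold_study_is_seeded_and_kinked():
    X1, y1, t1 = simulate_threshold_study(seed=5)
    X2, y2, _ = simulate_threshold_study(seed=5)
    pd.testing.assert_frame_equal(X1, X2)
    pd.testing.assert_series_equal(y1, y2)
    assert t1["theta"] == -7.0
    # cold years respond more weakly than warm years
    cold = X1["jan"] < -8.5
    warm = X1["jan"] > -5.5
    slope_cold = np.polyfit(X1.loc[cold, "jan"], y1[cold], 1)[0]
    slope_warm = np.polyfit(X1.loc[warm, "jan"], y1[warm], 1)[0]
    assert slope_warm > 2 * slope_cold


def test_structured_sim_config_round_trip(tmp_path):
    import yaml
    from dendrosync.simulate import load_sim_config
    cfg = {
        "network": {
            "n_sites": 4, "cores_per_site": 3, "seed": 5,
            "common_signal_fraction": {"before": 0.3, "after": 0.6, "year": 1955},
            "group_contrast_fraction": 0.1,
        },
        "climate": {
            "first_year": 1950, "last_year": 2005, "seed": 6,
            "coupling": ["tmn", 1, 0.6],
            "trend_segments": {"tmn": [[[1970, 2005], 0.03]]},
        },
    }
    p = tmp_path / "sim.yaml"
    p.write_text(yaml.safe_dump(cfg))
    net, clim = load_sim_config(p)
    prof = net.fraction_profile()
    assert prof[0] == 0.3 and prof[-1] == 0.6
    assert net.n_sites == 4 and clim.coupling == ("tmn", 1, 0.6)
    series, truth = generate_network(net)
    table = generate_climate(clim, truth)
    assert len(series) == 12 and len(table) == 56 * 12


def test_unknown_sim_config_key_rejected(tmp_path):
    import pytest as _pytest
    import yaml
    from dendrosync.simulate import load_sim_config
    p = tmp_path / "sim.yaml"
    p.write_text(yaml.safe_dump({"network": {"bogus": 1}}))
    with _pytest.raises(ValueError, match="bogus"):
        load_sim_config(p)
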