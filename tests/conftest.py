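import numpy as np
import pandas as pd
import pytest

from dendrosync.chronology import build_chronology, detrend_to_index, fit_growth_curve
from dendrosync.simulate import NetworkSimConfig, generate_network


def network_chronologies(config: NetworkSimConfig, detrend: str = "fit") -> pd.DataFrame:
    """Simulate a network and build one chronology per site.

    ``detrend="truth"`` divides by the exact generating age curve (no
    fitting), ``"fit"`` runs the full conservative-curve fitting chain.
    """
    series, truth = generate_network(config)
    a, b, k = config.age_trend
    by_site: dict[str, list] = {}
    for s in series:
        by_site.setdefault(s.site_id, []).append(s)
    frames = {}
    for site, cores in by_site.items():
        msl = float(np.mean([len(c) for c in cores]))
        idx = []
        for core in cores:
            if detrend == "truth":
                from dendrosync.chronology import GrowthCurveFit
                age = np.arange(len(core), dtype=float)
                fit = GrowthCurveFit("negative_exponential", {"a": a, "b": b, "k": k},
                                     a * np.exp(-b * age) + k)
            else:
                fit = fit_growth_curve(core, mean_segment_length=msl)
            idx.append(detrend_to_index(core, fit))
        chron = build_chronology(idx)
        frames[site] = pd.Series(chron.index, index=chron.years)
    df = pd.DataFrame(frames)
    df.index.name = "year"
    return df


@pytest.fixture(scope="session")
def step_network():
    """17-site network whose common-signal fraction steps 0.3 -> 0.6 in 1955
    (the study-period synchrony rise), with its ground truth."""
    cfg = NetworkSimConfig(
        n_sites=17, cores_per_site=5, seed=20160603,
        common_signal_fraction=lambda y: 0.3 + 0.3 * (y >= 1955),
    )
    series, truth = generate_network(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def step_chronologies(step_network):
    cfg, _, _ = step_network
    return network_chronologies(cfg)
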