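"""Synthetic ring-width networks and monthly climate with known ground truth.

The growth model is multiplicative and one-factor at the site level:

    width(core i, site j, year t) = age_trend(age) × index,
    index = 1 + a_t·sqrt(f_t)·σ·C_t + a_t·sqrt(g_t)·σ·G_j·D_t
              + sqrt(1−f_0−g_0)·σ·S_jt + ε_ijt,
    a_t = sqrt((1−f_0−g_0) / (1−f_t−g_t))

with C a network-wide standard-normal common signal, S site-specific noise,
ε per-core noise (SD ``site_noise_sd``), σ the baseline site-level
interannual SD (``interannual_sd``) and f_t the common-signal fraction of
site-level variance, possibly changing through time. An optional two-group
contrast term (fraction g_t, sites alternating between groups ±1) lets site
responses cluster. The idiosyncratic variance is held constant through
time, so a rising common fraction also raises the total interannual
variance — intensifying forcing makes rings more extreme, not just more
synchronous. Extreme years are injected as shocks to the common signal so
they propagate to network-wide extreme-ring frequency. Core start years are
staggered so sample depth grows toward the present. Monthly climate carries a seasonal cycle, piecewise-linear trend
segments and AR(1) anomalies; one named month of one variable can be
coupled to the network common signal at a configured correlation.

Everything is driven by a single integer seed: identical configurations and
seeds give identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .tucson import RingWidthSeries, write_rwl
from .climate import CLIMATE_VARIABLES, write_climate_table

log = logging.getLogger(__name__)

__all__ = [
    "NetworkSimConfig",
    "ClimateSimConfig",
    "SimTruth",
    "generate_network",
    "generate_climate",
    "write_fixture_bundle",
    "simulate_threshold_study",
    "load_sim_config",
]


@dataclass
class NetworkSimConfig:
    """Configuration of a simulated multi-site, multi-core ring-width network."""

    n_sites: int = 17
    cores_per_site: int = 5
    first_year: int = 1825
    last_year: int = 2005
    age_trend: tuple[float, float, float] = (1.2, 0.008, 0.25)  # a, b, k (mm)
    common_signal_fraction: float | Callable[[np.ndarray], np.ndarray] = 0.4
    #: variance fraction of a two-group contrast signal (sites alternate
    #: between groups +1/-1); lets site responses cluster, with a strength
    #: that may change through time as temperature sensitivity waxes
    group_contrast_fraction: float | Callable[[np.ndarray], np.ndarray] = 0.0
    interannual_sd: float = 0.15
    site_noise_sd: float = 0.10          # per-core noise SD
    extreme_year_prob: float = 0.02
    extreme_shock: float = 3.0           # shock size in common-signal SD units
    stagger_fraction: float = 0.6        # cores start within this early fraction of the span
    seed: int | None = None

    def validate(self) -> None:
        if self.last_year <= self.first_year:
            raise ValueError("last_year must exceed first_year")
        if self.n_sites < 1 or self.cores_per_site < 1:
            raise ValueError("need at least one site and one core per site")
        a, b, k = self.age_trend
        if a <= 0 or b < 0 or k < 0:
            raise ValueError("age trend needs a > 0, b >= 0, k >= 0")
        f = self.fraction_profile()
        if np.any(f < 0) or np.any(f >= 1):
            raise ValueError("common_signal_fraction must lie in [0, 1) for all years")
        g = self.contrast_profile()
        if np.any(g < 0) or np.any(f + g >= 1):
            raise ValueError("common + group-contrast fractions must stay below 1")

    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def fraction_profile(self) -> np.ndarray:
        yrs = self.years()
        if callable(self.common_signal_fraction):
            return np.asarray(self.common_signal_fraction(yrs), dtype=float)
        return np.full(len(yrs), float(self.common_signal_fraction))

    def contrast_profile(self) -> np.ndarray:
        yrs = self.years()
        if callable(self.group_contrast_fraction):
            return np.asarray(self.group_contrast_fraction(yrs), dtype=float)
        return np.full(len(yrs), float(self.group_contrast_fraction))


@dataclass
class ClimateSimConfig:
    """Configuration of simulated monthly climate series."""

    variables: tuple[str, ...] = ("tmp", "tmx", "tmn", "pre")
    first_year: int | None = None       # default: the co-generated network span
    last_year: int | None = None
    ar1_coefficient: dict = field(default_factory=lambda: {"tmp": 0.3, "tmx": 0.3,
                                                           "tmn": 0.3, "pre": 0.1})
    trend_segments: dict = field(default_factory=dict)  # var -> [((y0, y1), slope/yr)]
    coupling: tuple[str, int, float] | None = None       # (variable, month, correlation)
    anomaly_sd: dict = field(default_factory=lambda: {"tmp": 1.2, "tmx": 1.2,
                                                      "tmn": 1.4, "pre": 25.0})
    seed: int | None = None

    def validate(self) -> None:
        for v in self.variables:
            if v not in CLIMATE_VARIABLES:
                raise ValueError(f"unknown climate variable {v!r}")
            phi = self.ar1_coefficient.get(v, 0.0)
            if not -1 < phi < 1:
                raise ValueError(f"AR(1) coefficient for {v} outside (-1, 1)")
        if self.coupling is not None:
            var, month, rho = self.coupling
            if var not in self.variables or not 1 <= month <= 12 or not -1 <= rho <= 1:
                raise ValueError(f"invalid coupling {self.coupling!r}")


@dataclass
class SimTruth:
    """Ground truth stored alongside every simulated bundle."""

    years: np.ndarray
    common_signal: np.ndarray            # index units: sqrt(f_t)·σ·C_t
    signal_z: np.ndarray                 # the underlying standard-normal C_t (with shocks)
    fraction: np.ndarray                 # f_t per year
    interannual_sd: float
    site_noise_sd: float
    cores_per_site: int
    n_sites: int
    core_start_years: dict[str, int]
    extreme_years: list[int]
    clip_events: int
    coupling: tuple[str, int, float] | None = None
    threshold: float | None = None
    seed: int | None = None
    site_groups: dict[str, int] = field(default_factory=dict)   # +1 / -1
    contrast_fraction: np.ndarray | None = None
    contrast_signal: np.ndarray | None = None

    def expected_site_r2(self) -> float:
        """Variance fraction of a site chronology explained by the common
        signal under the generating model (core-noise attenuated; valid for
        zero group contrast)."""
        f = float(np.mean(self.fraction))
        s2 = self.interannual_sd**2
        core = self.site_noise_sd**2 / self.cores_per_site
        return f * s2 / (s2 + core)

    def expected_pc1_share(self) -> float:
        """Leading eigenvalue share of the equicorrelated site-chronology
        correlation matrix implied by the model."""
        rho = self.expected_site_r2()
        p = self.n_sites
        return 100.0 * (1.0 + (p - 1) * rho) / p


def generate_network(config: NetworkSimConfig) -> tuple[list[RingWidthSeries], SimTruth]:
    """Simulate the ring-width network; see the module docstring for the model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    yrs = config.years()
    n_years = len(yrs)
    f = config.fraction_profile()
    sigma = config.interannual_sd

    z = rng.standard_normal(n_years)
    extreme_mask = rng.random(n_years) < config.extreme_year_prob
    shock_sign = np.where(rng.random(n_years) < 0.5, -1.0, 1.0)
    z = np.where(extreme_mask, shock_sign * config.extreme_shock, z)
    g = config.contrast_profile()
    # The idiosyncratic (site + core) variance is held constant through time;
    # time variation of the common/contrast fractions is carried entirely by
    # the shared components, so intensifying synchrony also raises the total
    # interannual variance (and with it the extreme-ring frequency), while
    # the variance *fractions* at every year remain exactly f(t) and g(t).
    # The fractions at the first simulated year anchor the baseline variance
    # sigma^2.
    f0, g0 = f[0], g[0]
    amp = np.sqrt((1.0 - f0 - g0) / (1.0 - f - g))
    common = amp * np.sqrt(f) * sigma * z
    contrast = rng.standard_normal(n_years)
    contrast_sd = amp * np.sqrt(g) * sigma

    a, b, k = config.age_trend
    span = n_years
    max_start = max(int(config.stagger_fraction * span) - 1, 0)
    series: list[RingWidthSeries] = []
    starts: dict[str, int] = {}
    clipped = total = 0
    groups: dict[str, int] = {}
    for j in range(config.n_sites):
        site_id = f"s{j+1:02d}"
        group = 1 if j % 2 == 0 else -1
        groups[site_id] = group
        site_part = (group * contrast_sd * contrast
                     + np.sqrt(1.0 - f0 - g0) * sigma * rng.standard_normal(n_years))
        for i in range(config.cores_per_site):
            # anchor two cores at the span start so the truncated chronology
            # can stay reliable from the first year; the rest are staggered
            offset = 0 if i < 2 else int(rng.integers(0, max_start + 1))
            start = config.first_year + offset
            length = config.last_year - start + 1
            sl = slice(offset, offset + length)
            eps = rng.normal(0.0, config.site_noise_sd, length)
            index = 1.0 + common[sl] + site_part[sl] + eps
            age = np.arange(length, dtype=float)
            trend = a * np.exp(-b * age) + k
            widths = trend * index
            nclip = int(np.sum(widths < 0.01))
            clipped += nclip
            total += length
            widths = np.maximum(widths, 0.01)
            core_id = f"{site_id}c{i+1:02d}"
            starts[core_id] = start
            series.append(RingWidthSeries(core_id=core_id, site_id=site_id,
                                          first_year=start, widths=widths))
    if clipped > 0.05 * total:
        raise ValueError(
            f"config rejected: {clipped}/{total} widths hit the 0.01 mm floor (> 5%)"
        )
    if clipped:
        log.info("clipped %d of %d widths at the 0.01 mm floor", clipped, total)
    truth = SimTruth(
        years=yrs, common_signal=common, signal_z=z, fraction=f,
        interannual_sd=sigma, site_noise_sd=config.site_noise_sd,
        cores_per_site=config.cores_per_site, n_sites=config.n_sites,
        core_start_years=starts, extreme_years=list(yrs[extreme_mask]),
        site_groups=groups, contrast_fraction=g,
        contrast_signal=contrast_sd * contrast,
        clip_events=clipped, seed=config.seed,
    )
    return series, truth


# seasonal cycles for a highland continental climate: cold dry winters,
# cool wet summers (tmp/tmx/tmn in degC, pre in mm/month)
_CLIMATOLOGY = {
    "tmp": np.array([-5.5, -3.5, 0.5, 4.5, 8.5, 11.5, 12.5, 12.0, 10.0, 5.0, -0.5, -4.5]),
    "tmx": np.array([2.5, 4.5, 8.5, 12.5, 16.5, 19.0, 20.0, 19.5, 17.5, 12.5, 7.0, 3.5]),
    "tmn": np.array([-13.0, -11.0, -7.0, -3.0, 1.0, 4.5, 6.0, 5.5, 3.0, -2.0, -8.0, -12.0]),
    "pre": np.array([5.0, 8.0, 15.0, 30.0, 60.0, 110.0, 140.0, 130.0, 90.0, 40.0, 10.0, 4.0]),
}


def generate_climate(config: ClimateSimConfig, truth: SimTruth | None = None) -> pd.DataFrame:
    """Simulate the monthly climate table; couples one month of one variable
    to the network common signal when configured (requires ``truth``)."""
    config.validate()
    if config.coupling is not None and truth is None:
        raise ValueError("coupling requested without a co-generated network truth")
    if config.first_year is None or config.last_year is None:
        if truth is None:
            raise ValueError("first/last year required when no network truth is given")
        y0, y1 = int(truth.years[0]), int(truth.years[-1])
    else:
        y0, y1 = config.first_year, config.last_year
    if y1 <= y0:
        raise ValueError("climate span must cover at least two years")
    rng = np.random.default_rng(config.seed)
    years = np.arange(y0, y1 + 1)
    n = len(years)
    out = {"year": np.repeat(years, 12), "month": np.tile(np.arange(1, 13), n)}
    for v in config.variables:
        phi = float(config.ar1_coefficient.get(v, 0.0))
        innov = rng.standard_normal(12 * n + 120)
        z = np.empty_like(innov)
        z[0] = innov[0]
        scale = np.sqrt(1.0 - phi * phi)
        for t in range(1, len(innov)):
            z[t] = phi * z[t - 1] + scale * innov[t]
        z = z[120:]
        if config.coupling is not None and config.coupling[0] == v:
            _, month, rho = config.coupling
            c = truth.signal_z
            csd = c.std() or 1.0
            cz = (c - c.mean()) / csd
            # couple only the years the network truth covers
            in_truth = np.isin(years, truth.years)
            pos = (np.flatnonzero(in_truth) * 12) + (month - 1)
            tsel = np.isin(truth.years, years)
            z[pos] = rho * cz[tsel] + np.sqrt(max(1.0 - rho * rho, 0.0)) * z[pos]
        clim = np.tile(_CLIMATOLOGY[v], n)
        sd = float(config.anomaly_sd.get(v, 1.0))
        offset = _trend_offsets(years, config.trend_segments.get(v, []))
        vals = clim + np.repeat(offset, 12) + sd * z
        if v == "pre":
            vals = np.maximum(vals, 0.0)
        out[v] = vals
    if truth is not None and config.coupling is not None:
        truth.coupling = config.coupling
    return pd.DataFrame(out)


def _trend_offsets(years: np.ndarray, segments: list) -> np.ndarray:
    """Cumulative offsets of piecewise-linear trend segments ((y0, y1), slope)."""
    offsets = np.zeros(len(years), dtype=float)
    for (s0, s1), slope in segments:
        ramp = np.clip(years - s0, 0, s1 - s0).astype(float)
        offsets += slope * ramp
    return offsets


def write_fixture_bundle(network: list[RingWidthSeries], climate: pd.DataFrame | None,
                         truth: SimTruth, directory: str | Path) -> dict:
    """Write one .rwl per site, a climate table and a truth file; returns the
    manifest (also written as manifest.json)."""
    if not network:
        raise ValueError("empty network; nothing written")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_site: dict[str, list[RingWidthSeries]] = {}
    for s in network:
        by_site.setdefault(s.site_id, []).append(s)
    names = [f"{site}.rwl" for site in by_site]
    if len(set(names)) != len(names):
        raise ValueError("overlapping fixture filenames")
    paths = {}
    for site, series in by_site.items():
        p = directory / f"{site}.rwl"
        write_rwl(series, p)
        paths[site] = str(p)
    manifest = {"seed": truth.seed, "rwl": paths}
    if climate is not None:
        cp = directory / "climate.tsv"
        write_climate_table(climate, cp)
        manifest["climate"] = str(cp)
    tp = directory / "truth.txt"
    _write_truth(truth, tp)
    manifest["truth"] = str(tp)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_truth(truth: SimTruth, path: Path) -> None:
    lines = [
        f"seed={truth.seed}",
        f"n_sites={truth.n_sites}",
        f"cores_per_site={truth.cores_per_site}",
        f"interannual_sd={truth.interannual_sd}",
        f"site_noise_sd={truth.site_noise_sd}",
        f"clip_events={truth.clip_events}",
        f"coupling={truth.coupling}",
        f"threshold={truth.threshold}",
        "years=" + ",".join(str(int(y)) for y in truth.years),
        "common_signal=" + ",".join(f"{v:.6f}" for v in truth.common_signal),
        "fraction=" + ",".join(f"{v:.4f}" for v in truth.fraction),
        "extreme_years=" + ",".join(str(int(y)) for y in truth.extreme_years),
    ]
    path.write_text("\n".join(lines) + "\n")


def simulate_threshold_study(
    n_years: int = 55,
    theta: float = -7.0,
    slope_above: float = 0.10,
    slope_below: float = 0.02,
    novdec_slope: float = 0.03,
    noise_sd: float = 0.05,
    jan_mean: float = -7.4,
    jan_sd: float = 1.6,
    novdec_mean: float = -5.4,
    novdec_sd: float = 0.7,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Growth with a built-in winter-temperature sensitivity threshold.

    Growth responds to January temperature with ``slope_above`` index/°C
    above ``theta`` and only ``slope_below`` beneath it (saturation in
    freezing winters), plus a weak linear Nov–Dec term and observation
    noise. Returns (predictors, growth, truth) with predictors in columns
    (novdec, jan) matching :class:`~dendrosync.ann.GrowthANN` conventions.
    """
    rng = np.random.default_rng(seed)
    jan = jan_mean + jan_sd * rng.standard_normal(n_years)
    novdec = novdec_mean + novdec_sd * rng.standard_normal(n_years)
    growth = (
        1.0
        + slope_above * np.maximum(jan - theta, 0.0)
        + slope_below * np.minimum(jan - theta, 0.0)
        + novdec_slope * (novdec - novdec_mean)
        + noise_sd * rng.standard_normal(n_years)
    )
    years = pd.Index(np.arange(1951, 1951 + n_years), name="year")
    predictors = pd.DataFrame({"novdec": novdec, "jan": jan}, index=years)
    target = pd.Series(growth, index=years, name="growth")
    truth = {"theta": theta, "slope_above": slope_above, "slope_below": slope_below,
             "novdec_slope": novdec_slope, "noise_sd": noise_sd, "seed": seed}
    return predictors, target, truth


def _profile_from_config(value):
    """A fraction profile from config: a number, or a step mapping
    ``{"before": 0.3, "after": 0.6, "year": 1955}``."""
    if isinstance(value, dict):
        before, after, year = value["before"], value["after"], value["year"]
        return lambda yrs: np.where(np.asarray(yrs) >= year, after, before)
    return float(value)


def load_sim_config(path) -> tuple[NetworkSimConfig, ClimateSimConfig]:
    """Read a structured simulation config (YAML) with ``network`` and
    ``climate`` sections whose keys mirror the two config dataclasses;
    ``common_signal_fraction`` and ``group_contrast_fraction`` may be numbers
    or step mappings, ``coupling`` a ``[variable, month, correlation]`` list,
    and ``trend_segments`` ``{variable: [[[start, end], slope], ...]}``."""
    import dataclasses

    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    net_raw = dict(raw.get("network", {}))
    for key in ("common_signal_fraction", "group_contrast_fraction"):
        if key in net_raw:
            net_raw[key] = _profile_from_config(net_raw[key])
    for key in ("age_trend",):
        if key in net_raw:
            net_raw[key] = tuple(net_raw[key])
    allowed = {f.name for f in dataclasses.fields(NetworkSimConfig)}
    unknown = set(net_raw) - allowed
    if unknown:
        raise ValueError(f"unknown network config keys: {sorted(unknown)}")
    clim_raw = dict(raw.get("climate", {}))
    if "coupling" in clim_raw and clim_raw["coupling"] is not None:
        clim_raw["coupling"] = tuple(clim_raw["coupling"])
    if "variables" in clim_raw:
        clim_raw["variables"] = tuple(clim_raw["variables"])
    if "trend_segments" in clim_raw:
        clim_raw["trend_segments"] = {
            var: [((int(a), int(b)), float(slope)) for (a, b), slope in segs]
            for var, segs in clim_raw["trend_segments"].items()}
    allowed = {f.name for f in dataclasses.fields(ClimateSimConfig)}
    unknown = set(clim_raw) - allowed
    if unknown:
        raise ValueError(f"unknown climate config keys: {sorted(unknown)}")
    return NetworkSimConfig(**net_raw), ClimateSimConfig(**clim_raw)
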