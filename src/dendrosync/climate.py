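"""Climate–growth response over the dendroclimatic year.

Monthly climate is rearranged into a 17-column "dendroclimatic year"
(previous May … previous December, current January … current September):
row *t* takes months 5–12 from calendar year *t−1* and months 1–9 from
year *t*. Correlation functions give the per-month Pearson r with two-tailed
critical values from the t distribution; moving correlation functions (MCF)
use a fixed sliding window assigned to its center year with a Fisher-z 95%
band; a seeded Monte Carlo (Gershunov-style) test asks whether the variance
of the moving correlation exceeds what stationary bivariate AR(1) surrogates
with matched persistence and overall correlation would produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

log = logging.getLogger(__name__)

__all__ = [
    "DENDRO_COLUMNS",
    "CLIMATE_VARIABLES",
    "read_climate_table",
    "write_climate_table",
    "build_dendro_matrix",
    "seasonal_mean",
    "CorrelationFunction",
    "correlation_function",
    "critical_r",
    "moving_correlation",
    "StabilityTestResult",
    "stability_test",
]

CLIMATE_VARIABLES = ("tmp", "tmx", "tmn", "pre")

_PREV = [("prev_may", 5), ("prev_jun", 6), ("prev_jul", 7), ("prev_aug", 8),
         ("prev_sep", 9), ("prev_oct", 10), ("prev_nov", 11), ("prev_dec", 12)]
_CUR = [("jan", 1), ("feb", 2), ("mar", 3), ("apr", 4), ("may", 5),
        ("jun", 6), ("jul", 7), ("aug", 8), ("sep", 9)]

#: the 17 months of the dendroclimatic year, in order
DENDRO_COLUMNS = [name for name, _ in _PREV + _CUR]


def read_climate_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited monthly climate table with columns year, month, and
    one column per variable; validates month completeness and duplicates."""
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"year", "month"}
    if not need.issubset(df.columns):
        raise ValueError(f"climate table must have columns {sorted(need)}")
    if df.duplicated(["year", "month"]).any():
        raise ValueError("duplicate year-month rows in climate table")
    counts = df.groupby("year")["month"].nunique()
    partial = counts[counts < 12]
    if len(partial):
        raise ValueError(f"incomplete months for years {list(partial.index)}")
    return df.sort_values(["year", "month"]).reset_index(drop=True)


def write_climate_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path


def build_dendro_matrix(climate: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Pivot one climate variable into the 17-column dendroclimatic layout.

    Rows (growth years) with any missing month are dropped and logged. The
    first calendar year of the record cannot form a row (it has no t−1).
    """
    if variable not in climate.columns:
        raise ValueError(f"variable {variable!r} not in climate table")
    wide = climate.pivot(index="year", columns="month", values=variable)
    years = wide.index.to_numpy()
    rows = {}
    for name, m in _PREV:
        rows[name] = wide[m].reindex(years[1:] - 1).to_numpy()
    for name, m in _CUR:
        rows[name] = wide[m].reindex(years[1:]).to_numpy()
    mat = pd.DataFrame(rows, index=pd.Index(years[1:], name="year"))
    bad = mat.isna().any(axis=1)
    if bad.any():
        log.info("dropping %d growth years with missing months: %s",
                 bad.sum(), list(mat.index[bad]))
        mat = mat[~bad]
    return mat


def seasonal_mean(matrix: pd.DataFrame, months: list[str]) -> pd.Series:
    """Unweighted mean over a contiguous run of dendroclimatic-year months."""
    if not months:
        raise ValueError("empty month set")
    try:
        idx = [DENDRO_COLUMNS.index(m) for m in months]
    except ValueError as exc:
        raise ValueError(f"unknown month label in {months!r}") from exc
    if idx != list(range(idx[0], idx[0] + len(idx))):
        raise ValueError(f"months {months!r} are not a contiguous run of the dendroclimatic year")
    return matrix[months].mean(axis=1).rename("_".join(months))


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson r at sample size n (t inversion, df = n−2)."""
    df = n - 2
    t = scipy.stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(df + t * t))


@dataclass
class CorrelationFunction:
    r: pd.Series                      # per dendroclimatic month
    n: int
    r_crit_95: float
    r_crit_99: float
    seasons: dict[str, float] = field(default_factory=dict)


def correlation_function(growth: pd.Series, matrix: pd.DataFrame,
                         seasons: dict[str, list[str]] | None = None) -> CorrelationFunction:
    """Pearson r between growth and each monthly column over the common years;
    optional composite seasons (contiguous month runs) appended."""
    common = growth.dropna().index.intersection(matrix.dropna().index)
    if len(common) < 20:
        raise ValueError(f"only {len(common)} overlapping years; need >= 20")
    g = growth.loc[common].to_numpy(dtype=float)
    n = len(common)
    r = pd.Series(
        {c: float(np.corrcoef(g, matrix.loc[common, c].to_numpy(dtype=float))[0, 1])
         for c in matrix.columns},
        name="r",
    )
    out_seasons = {}
    for name, months in (seasons or {}).items():
        sm = seasonal_mean(matrix, months).loc[common]
        out_seasons[name] = float(np.corrcoef(g, sm.to_numpy(dtype=float))[0, 1])
    return CorrelationFunction(r, n, critical_r(n, 0.05), critical_r(n, 0.01), out_seasons)


# ---------------------------------------------------------------------------
# moving correlation and its stability
# ---------------------------------------------------------------------------

def _sliding_corr(x: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Moving Pearson r for (possibly batched) rows of x against rows of y."""
    xw = np.lib.stride_tricks.sliding_window_view(x, window, axis=-1)
    yw = np.lib.stride_tricks.sliding_window_view(y, window, axis=-1)
    xm = xw - xw.mean(axis=-1, keepdims=True)
    ym = yw - yw.mean(axis=-1, keepdims=True)
    num = np.sum(xm * ym, axis=-1)
    den = np.sqrt(np.sum(xm * xm, axis=-1) * np.sum(ym * ym, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(np.where(den == 0, np.nan, r), -1.0, 1.0)


def _align(growth: pd.Series, predictor: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    common = growth.dropna().index.intersection(predictor.dropna().index)
    years = np.asarray(sorted(common))
    return (growth.loc[years].to_numpy(dtype=float),
            predictor.loc[years].to_numpy(dtype=float), years)


def moving_correlation(growth: pd.Series, predictor: pd.Series,
                       window: int = 30) -> pd.DataFrame:
    """Sliding-window Pearson r assigned to the center year (the lower-middle
    year for even windows), with a 95% Fisher-z confidence band."""
    g, p, years = _align(growth, predictor)
    if len(g) < window:
        raise ValueError(f"overlap {len(g)} shorter than window {window}")
    r = _sliding_corr(g, p, window)
    centers = years[np.arange(len(r)) + (window - 1) // 2]
    se = 1.96 / np.sqrt(window - 3)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    return pd.DataFrame(
        {"r": r, "lo": np.tanh(z - se), "hi": np.tanh(z + se)},
        index=pd.Index(centers, name="center_year"),
    )


@dataclass
class StabilityTestResult:
    observed: float                  # variance of the moving-correlation track
    null_stats: np.ndarray           # M surrogate statistics
    p_value: float
    r_full: float
    ar1: tuple[float, float]
    window: int
    M: int
    seed: int | None


def _lag1(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = np.sum(x * x)
    if denom == 0:
        raise ValueError("constant series; AR(1) undefined")
    return float(np.sum(x[1:] * x[:-1]) / denom)


def stability_test(growth: pd.Series, predictor: pd.Series, window: int = 30,
                   M: int = 1000, seed: int | None = None) -> StabilityTestResult:
    """Monte Carlo test of moving-correlation stability.

    The observed statistic is the variance of the moving-correlation track.
    The null resamples M bivariate AR(1) surrogate pairs whose lag-1
    autocorrelations are fitted from the two inputs and whose innovation
    cross-correlation reproduces the observed full-period r;
    ``p = (1 + #{null >= observed}) / (M + 1)``.
    """
    g, x, _ = _align(growth, predictor)
    n = len(g)
    if n < window + 10:
        raise ValueError(f"overlap {n} shorter than window+10 = {window + 10}")
    if M < 1:
        raise ValueError("M must be >= 1")
    a1, a2 = _lag1(g), _lag1(x)
    if abs(a1) >= 1 or abs(a2) >= 1:
        raise ValueError(f"fitted AR(1) coefficient outside (-1, 1): {a1:.3f}, {a2:.3f}")
    track = _sliding_corr(g, x, window)
    observed = float(np.var(track))
    r_full = float(np.corrcoef(g, x)[0, 1])
    # innovation correlation that yields the observed cross-correlation of the
    # stationary AR(1) pair: rho_eps = r (1 - a1 a2) / sqrt((1-a1^2)(1-a2^2))
    rho = r_full * (1.0 - a1 * a2) / np.sqrt((1.0 - a1**2) * (1.0 - a2**2))
    if abs(rho) > 0.999:
        log.warning("innovation correlation %.3f clipped to ±0.999", rho)
        rho = float(np.clip(rho, -0.999, 0.999))
    rng = np.random.default_rng(seed)
    burn = 50
    e1 = rng.standard_normal((M, n + burn))
    e2 = rho * e1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal((M, n + burn))
    xs = _ar1_filter(e1, a1)[:, burn:]
    ys = _ar1_filter(e2, a2)[:, burn:]
    null_stats = np.var(_sliding_corr(xs, ys, window), axis=-1)
    p = float((1 + np.sum(null_stats >= observed)) / (M + 1))
    return StabilityTestResult(observed, null_stats, p, r_full, (a1, a2), window, M, seed)


def _ar1_filter(innov: np.ndarray, a: float) -> np.ndarray:
    """x_t = a x_{t-1} + e_t along the last axis (zero initial state)."""
    return scipy.signal.lfilter([1.0], [1.0, -a], innov, axis=-1)
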