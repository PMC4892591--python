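"""Site chronology construction from raw ring widths.

Each core's biological growth trend is removed by a conservative curve —
a negative exponential ``a·exp(-b·t) + k`` (a>0, b>0, k≥0), falling back
to a straight line with non-positive slope, falling back to a stiff
smoothing spline whose frequency response is 0.5 at a cutoff period equal
to a fraction (default 0.67) of the site's mean segment length. Ring-width
indices are the ratios raw/fitted. Core indices are averaged per year with
a Tukey biweight robust mean into a site chronology, whose reliable span
is the period where subsample signal strength (SSS) stays at or above a
threshold (default 0.85).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg

from .tucson import RingWidthSeries, WIDTH_FLOOR_MM, read_rwl, write_rwl  # noqa: F401

log = logging.getLogger(__name__)

__all__ = [
    "GrowthCurveFit",
    "IndexSeries",
    "Chronology",
    "fit_growth_curve",
    "detrend_to_index",
    "biweight_mean",
    "build_chronology",
    "sss_profile",
    "eps_statistic",
    "truncate_by_sss",
    "mean_sensitivity",
    "export_chronology",
]


# ---------------------------------------------------------------------------
# growth-curve fitting and detrending
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurveFit:
    model: str                      # negative_exponential | straight_line | smoothing_spline
    parameters: dict
    fitted_values: np.ndarray       # strictly positive, aligned to the series

    def __post_init__(self) -> None:
        self.fitted_values = np.asarray(self.fitted_values, dtype=float)
        if np.any(self.fitted_values <= 0):
            raise ValueError("fitted growth values must be strictly positive")


@dataclass
class IndexSeries:
    core_id: str
    site_id: str
    first_year: int
    indices: np.ndarray

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.indices))


def _negexp(t, a, b, k):
    return a * np.exp(-b * t) + k


def _fit_negexp(widths: np.ndarray) -> dict | None:
    n = len(widths)
    t = np.arange(n, dtype=float)
    head = widths[: max(n // 5, 3)].mean()
    tail = widths[-max(n // 5, 3):].mean()
    p0 = (max(head - tail, 0.1 * widths.mean()), 2.0 / n, max(tail, 1e-3))
    try:
        popt, _ = scipy.optimize.curve_fit(
            _negexp, t, widths, p0=p0,
            bounds=([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None
    a, b, k = popt
    fitted = _negexp(t, a, b, k)
    # reject fits that have collapsed to a flat line (a or b at the boundary):
    # they indicate the series carries no declining age trend to remove
    if a < 1e-3 * widths.mean() or b < 1e-6 or np.any(fitted <= WIDTH_FLOOR_MM):
        return None
    return {"a": a, "b": b, "k": k, "fitted": fitted}


def _fit_line(widths: np.ndarray) -> dict | None:
    n = len(widths)
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, widths, 1)
    if slope > 1e-12:
        return None  # only non-positive slopes are admissible (conservative detrending)
    fitted = intercept + slope * t
    if np.any(fitted <= WIDTH_FLOOR_MM):
        return None
    return {"slope": slope, "intercept": intercept, "fitted": fitted}


def spline_lambda(cutoff_period: float) -> float:
    """Penalty weight of the second-difference smoother whose frequency
    response gain is 0.5 at ``cutoff_period`` (in years)."""
    if cutoff_period <= 2:
        raise ValueError("cutoff period must exceed 2 years")
    return (2.0 * np.sin(np.pi / cutoff_period)) ** -4


def _fit_spline(widths: np.ndarray, cutoff_period: float) -> dict:
    n = len(widths)
    lam = spline_lambda(cutoff_period)
    d = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    a = scipy.sparse.identity(n, format="csc") + lam * (d.T @ d)
    fitted = scipy.sparse.linalg.spsolve(a.tocsc(), widths)
    return {"cutoff_period": cutoff_period, "lambda": lam, "fitted": fitted}


def fit_growth_curve(
    series: RingWidthSeries,
    strategy: tuple[str, ...] = ("negative_exponential", "straight_line", "smoothing_spline"),
    spline_fraction: float = 0.67,
    mean_segment_length: float | None = None,
) -> GrowthCurveFit:
    """Fit the first admissible growth model in ``strategy`` to a core.

    ``mean_segment_length`` is the site-level mean series length used to set
    the spline cutoff (``spline_fraction`` × it); defaults to the length of
    this series.
    """
    widths = series.widths
    if len(widths) < 10:
        raise ValueError(f"series {series.core_id!r}: need >= 10 years to detrend")
    if mean_segment_length is None:
        mean_segment_length = float(len(widths))

    for model in strategy:
        if model == "negative_exponential":
            res = _fit_negexp(widths)
            if res is not None:
                fitted = res.pop("fitted")
                return GrowthCurveFit("negative_exponential", res, fitted)
        elif model == "straight_line":
            res = _fit_line(widths)
            if res is not None:
                fitted = res.pop("fitted")
                return GrowthCurveFit("straight_line", res, fitted)
        elif model == "smoothing_spline":
            res = _fit_spline(widths, spline_fraction * mean_segment_length)
            fitted = res.pop("fitted")
            if np.all(fitted > WIDTH_FLOOR_MM):
                return GrowthCurveFit("smoothing_spline", res, fitted)
        else:
            raise ValueError(f"unknown growth model {model!r}")
    raise ValueError(
        f"series {series.core_id!r}: no growth model produced positive fitted values"
    )


def detrend_to_index(series: RingWidthSeries, fit: GrowthCurveFit) -> IndexSeries:
    """Ratio indices: raw width / fitted growth, aligned by year."""
    if len(fit.fitted_values) != len(series.widths):
        raise ValueError("fit is not aligned to the series")
    if np.any(fit.fitted_values <= WIDTH_FLOOR_MM):
        raise ValueError("fitted values at or below the width floor; indices would blow up")
    return IndexSeries(
        core_id=series.core_id,
        site_id=series.site_id,
        first_year=series.first_year,
        indices=series.widths / fit.fitted_values,
    )


# ---------------------------------------------------------------------------
# robust mean
# ---------------------------------------------------------------------------

def biweight_mean(values, c: float = 9.0, tol: float = 1e-6, max_iter: int = 50) -> float:
    """Tukey biweight robust location estimate.

    Iterates ``m <- sum(w*x)/sum(w)`` with ``u = (x-m)/(c*MAD)``,
    ``w = (1-u^2)^2`` for |u| < 1 (else 0), MAD taken about the current
    estimate, starting from the median. With one value the value itself is
    returned; with two, their arithmetic mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("biweight_mean of empty input")
    if x.size == 1:
        return float(x[0])
    if x.size == 2:
        return float(x.mean())
    m = float(np.median(x))
    for _ in range(max_iter):
        mad = float(np.median(np.abs(x - m)))
        if mad == 0.0:
            return m
        u = (x - m) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0.0:
            return m
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def _biweight_columns(mat: np.ndarray, c: float = 9.0, tol: float = 1e-6,
                      max_iter: int = 50) -> np.ndarray:
    """Column-wise biweight mean of a 2-D array with NaNs marking absent cores.

    Vectorized across columns; semantics per column match :func:`biweight_mean`.
    """
    mat = np.asarray(mat, dtype=float)
    out = np.full(mat.shape[1], np.nan)
    counts = np.sum(~np.isnan(mat), axis=0)
    small = (counts >= 1) & (counts <= 2)
    if np.any(small):
        out[small] = np.nanmean(mat[:, small], axis=0)  # n=1 -> value, n=2 -> mean
    active = counts > 2
    if not np.any(active):
        return out
    sub = mat[:, active]
    filled = np.where(np.isnan(sub), 0.0, sub)
    ma = np.nanmedian(sub, axis=0)
    done = np.zeros(sub.shape[1], dtype=bool)
    for _ in range(max_iter):
        with np.errstate(invalid="ignore"):
            mad = np.nanmedian(np.abs(sub - ma), axis=0)
        done |= mad == 0.0  # all mass at the median: return it
        if done.all():
            break
        safe_mad = np.where(mad == 0.0, 1.0, mad)
        u = (sub - ma) / (c * safe_mad)
        with np.errstate(invalid="ignore"):
            w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        w = np.where(np.isnan(sub), 0.0, w)
        wsum = w.sum(axis=0)
        movable = ~done & (wsum > 0)
        done |= ~done & (wsum == 0)  # no in-range mass: keep current estimate
        m_new = np.where(movable, np.sum(w * filled, axis=0) / np.where(wsum == 0, 1.0, wsum), ma)
        converged = movable & (np.abs(m_new - ma) < tol)
        ma = np.where(movable, m_new, ma)
        done |= converged
        if done.all():
            break
    out[active] = ma
    return out


# ---------------------------------------------------------------------------
# chronology statistics
# ---------------------------------------------------------------------------

def eps_statistic(rbar: float, n: int) -> float:
    """Expressed population signal for ``n`` cores with mean inter-series
    correlation ``rbar``."""
    return n * rbar / (n * rbar + 1.0 - rbar)


def sss_profile(rbar: float, depth: np.ndarray, n_total: int) -> np.ndarray:
    """Subsample signal strength per year.

    ``SSS(t) = n(t)·(1 + (N-1)·rbar) / (N·(1 + (n(t)-1)·rbar))`` for a
    chronology of N cores of which n(t) are present in year t.
    """
    if not np.isfinite(rbar) or rbar <= 0 or rbar > 1:
        raise ValueError(f"SSS undefined for rbar={rbar!r}; need 0 < rbar <= 1")
    n = np.asarray(depth, dtype=float)
    if np.any(n < 1) or np.any(n > n_total):
        raise ValueError("sample depth must satisfy 1 <= n(t) <= N")
    return n * (1.0 + (n_total - 1) * rbar) / (n_total * (1.0 + (n - 1) * rbar))


def mean_sensitivity(values) -> float:
    """Mean absolute scaled year-to-year difference,
    ``MS = mean(|2(x_{t+1}-x_t)/(x_{t+1}+x_t)|)``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("mean sensitivity needs at least 2 values")
    s = x[1:] + x[:-1]
    if np.any(s == 0):
        raise ValueError("consecutive values sum to zero; MS undefined")
    return float(np.mean(np.abs(2.0 * (x[1:] - x[:-1]) / s)))


@dataclass
class Chronology:
    """Robust-mean site chronology with reliability diagnostics."""

    site_id: str
    years: np.ndarray                 # years carried by the index track
    index: np.ndarray                 # biweight mean of core indices
    depth: np.ndarray                 # sample depth n(t) on the index track
    rbar: float
    eps: float
    sss: np.ndarray                   # aligned to `years`; NaN when undefined
    n_total: int
    mean_sensitivity: float
    reliable_span: tuple[int, int] | None = None
    full_years: np.ndarray | None = None   # depth history retained after truncation
    full_depth: np.ndarray | None = None

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])


def build_chronology(
    index_series: list[IndexSeries],
    site_id: str | None = None,
    min_overlap: int = 30,
) -> Chronology:
    """Aggregate core index series into a site chronology.

    Per-year Tukey biweight mean over the cores present that year; ``rbar``
    is the mean pairwise Pearson correlation over pairs sharing at least
    ``min_overlap`` years (shorter pairs excluded and logged).
    """
    if not index_series:
        raise ValueError("no index series supplied")
    if site_id is None:
        site_id = index_series[0].site_id
    y0 = min(s.first_year for s in index_series)
    y1 = max(s.first_year + len(s.indices) - 1 for s in index_series)
    years = np.arange(y0, y1 + 1)
    mat = np.full((len(index_series), len(years)), np.nan)
    for i, s in enumerate(index_series):
        mat[i, s.first_year - y0: s.first_year - y0 + len(s.indices)] = s.indices
    depth = np.sum(~np.isnan(mat), axis=0)
    if not np.any(depth >= 1):
        raise ValueError("no year with at least one core")
    # trim to covered years (contiguous by construction of the inputs)
    cover = depth >= 1
    years, mat, depth = years[cover], mat[:, cover], depth[cover]

    index = _biweight_columns(mat)

    rs = []
    skipped = 0
    for i in range(len(index_series)):
        for j in range(i + 1, len(index_series)):
            both = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            if both.sum() < min_overlap:
                skipped += 1
                continue
            xi, xj = mat[i, both], mat[j, both]
            if xi.std() == 0 or xj.std() == 0:
                skipped += 1
                continue
            rs.append(np.corrcoef(xi, xj)[0, 1])
    if skipped:
        log.info("site %s: %d core pairs below %d-year overlap excluded from rbar",
                 site_id, skipped, min_overlap)
    rbar = float(np.mean(rs)) if rs else float("nan")

    n_total = len(index_series)
    if np.isfinite(rbar) and 0 < rbar <= 1:
        sss = sss_profile(rbar, depth, n_total)
        eps = eps_statistic(rbar, n_total)
    else:
        sss = np.full(len(years), np.nan)
        eps = float("nan")

    ms = mean_sensitivity(index)
    return Chronology(
        site_id=site_id, years=years, index=index, depth=depth,
        rbar=rbar, eps=eps, sss=sss, n_total=n_total, mean_sensitivity=ms,
    )


def truncate_by_sss(chron: Chronology, threshold: float = 0.85) -> Chronology:
    """Restrict the index track to the reliable span where SSS >= threshold
    continuously to the end; the depth history is retained in full."""
    sss = chron.sss
    if np.all(np.isnan(sss)):
        raise ValueError(f"site {chron.site_id}: SSS profile unavailable (rbar undefined)")
    ok = sss >= threshold
    if not ok.any():
        raise ValueError(
            f"site {chron.site_id}: no year reaches SSS {threshold} "
            f"(max SSS = {np.nanmax(sss):.3f})"
        )
    # earliest year from which the condition holds through the end
    bad = np.where(~ok)[0]
    start = 0 if bad.size == 0 else bad[-1] + 1
    if start >= len(chron.years):
        raise ValueError(
            f"site {chron.site_id}: SSS below {threshold} at the end of the record"
        )
    sel = slice(start, None)
    return Chronology(
        site_id=chron.site_id,
        years=chron.years[sel],
        index=chron.index[sel],
        depth=chron.depth[sel],
        rbar=chron.rbar,
        eps=chron.eps,
        sss=sss[sel],
        n_total=chron.n_total,
        mean_sensitivity=chron.mean_sensitivity,
        reliable_span=(int(chron.years[start]), int(chron.years[-1])),
        full_years=chron.years.copy(),
        full_depth=chron.depth.copy(),
    )


def export_chronology(chron: Chronology, path) -> None:
    """Write a chronology as delimited text: year, index, depth, SSS."""
    import pandas as pd
    pd.DataFrame({
        "year": chron.years,
        "index": np.round(chron.index, 6),
        "depth": chron.depth,
        "sss": np.round(chron.sss, 4),
    }).to_csv(path, sep="\t", index=False)
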