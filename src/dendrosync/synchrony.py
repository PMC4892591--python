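"""Shared variance across a chronology network.

PCA on the Pearson correlation matrix quantifies the common signal held by
the network; its evolution is tracked with a running window (default 50
years advanced by 10, the final window anchored to the period end). Extreme
growth years are flagged per chronology at mean ± k·SD (default k = 1.5)
over the full analysis period, and counted across the network per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "correlation_pca",
    "pc_scores",
    "running_pc1_share",
    "flag_extremes",
    "extreme_frequency",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending
    shares: np.ndarray               # percent of total variance, sums to 100
    loadings: pd.DataFrame           # chronology x component, scaled by sqrt(eigenvalue)
    eigenvectors: np.ndarray         # unit-norm columns, same orientation as loadings
    period: tuple[int, int]
    columns: list[str]


def _select_period(df: pd.DataFrame, period: tuple[int, int] | None) -> pd.DataFrame:
    if period is None:
        period = (int(df.index.min()), int(df.index.max()))
    sub = df.loc[period[0]: period[1]]
    missing = sub.columns[sub.isna().any()].tolist()
    wanted = np.arange(period[0], period[1] + 1)
    if len(sub) != len(wanted) or missing:
        absent = missing or ["<rows missing>"]
        raise ValueError(
            f"chronologies {absent} do not cover {period[0]}-{period[1]} completely"
        )
    return sub


def correlation_pca(chronologies: pd.DataFrame, period: tuple[int, int] | None = None) -> PCAResult:
    """Eigendecomposition of the correlation matrix of the network.

    ``chronologies`` is a year-indexed DataFrame, one column per site; all
    columns must cover ``period`` without gaps. Variance shares are
    ``100·λ_i/p``; every component is oriented so its mean loading is
    non-negative.
    """
    sub = _select_period(chronologies, period)
    p = sub.shape[1]
    if p < 2:
        raise ValueError("need at least 2 chronologies")
    corr = np.corrcoef(sub.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    signs = np.where(eigvec.mean(axis=0) < 0, -1.0, 1.0)
    eigvec = eigvec * signs
    shares = 100.0 * eigval / p
    loadings = pd.DataFrame(
        eigvec * np.sqrt(eigval),
        index=sub.columns,
        columns=[f"PC{i+1}" for i in range(p)],
    )
    per = (int(sub.index.min()), int(sub.index.max()))
    return PCAResult(eigval, shares, loadings, eigvec, per, list(sub.columns))


def pc_scores(chronologies: pd.DataFrame, pca: PCAResult | None = None,
              period: tuple[int, int] | None = None, component: int = 1) -> pd.Series:
    """Scores of one principal component (columns standardized over the period)."""
    if pca is None:
        pca = correlation_pca(chronologies, period)
    sub = _select_period(chronologies[pca.columns], period or pca.period)
    z = (sub - sub.mean()) / sub.std(ddof=1)
    vec = pca.eigenvectors[:, component - 1]
    return pd.Series(z.to_numpy() @ vec, index=sub.index, name=f"PC{component}")


def running_pc1_share(chronologies: pd.DataFrame, window: int = 50, step: int = 10,
                      period: tuple[int, int] | None = None) -> pd.DataFrame:
    """PC1 variance share in successive windows.

    Windows start at the period start and advance by ``step``; the final
    window keeps the last start but is extended to the period end, so it may
    be longer than ``window`` (e.g. an 1825–2005 span ends with the 51-year
    "1955–2005" window).
    """
    sub = _select_period(chronologies, period)
    y0, y1 = int(sub.index.min()), int(sub.index.max())
    if window > y1 - y0 + 1:
        raise ValueError(f"window {window} exceeds period length {y1 - y0 + 1}")
    starts = list(range(y0, y1 - window + 2, step))
    rows = []
    for i, s in enumerate(starts):
        e = y1 if i == len(starts) - 1 else s + window - 1
        res = correlation_pca(sub, (s, e))
        rows.append({"start": s, "end": e, "label": f"{s}–{e}",
                     "pc1_share": res.shares[0]})
    return pd.DataFrame(rows)


def flag_extremes(chronology: pd.Series, period: tuple[int, int] | None = None,
                  k: float = 1.5) -> pd.Series:
    """Per-year flags in {"wide", "narrow", "none"} at mean ± k·SD over the period."""
    s = chronology.dropna()
    if period is not None:
        s = s.loc[period[0]: period[1]]
    if len(s) < 10:
        raise ValueError("need at least 10 years to flag extremes")
    mu, sd = float(s.mean()), float(s.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation; extremes undefined")
    flags = pd.Series("none", index=s.index, name=chronology.name)
    flags[s > mu + k * sd] = "wide"
    flags[s < mu - k * sd] = "narrow"
    return flags


def extreme_frequency(flags: pd.DataFrame) -> pd.DataFrame:
    """Per-year counts of wide and narrow flags across the network."""
    wide = (flags == "wide").sum(axis=1)
    narrow = (flags == "narrow").sum(axis=1)
    return pd.DataFrame({"wide": wide, "narrow": narrow})
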