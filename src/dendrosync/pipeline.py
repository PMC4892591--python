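"""End-to-end orchestration: raw ring widths → report bundle.

Stages run in dependency order, exchange data through plain delimited text
tables in the output directory, and are skipped when their outputs already
exist (use ``force`` to regenerate). Every stochastic stage draws its seed
deterministically from the master seed, so a run is reproducible
bit-for-bit for the deterministic stages. A JSON manifest (config hash,
stage seeds, package version, warnings) is written last.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann import GrowthANN, detect_sensitivity_threshold, export_growth_ann, response_surface
from .chronology import build_chronology, detrend_to_index, fit_growth_curve, read_rwl, truncate_by_sss
from .climate import (
    build_dendro_matrix,
    correlation_function,
    moving_correlation,
    read_climate_table,
    seasonal_mean,
    stability_test,
)
from .emd import eemd
from .fcm import extract_interval_matrix, fcm, partition_summary
from .synchrony import correlation_pca, extreme_frequency, flag_extremes, pc_scores, running_pc1_share

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Finding", "ReportBundle", "validate_config", "run_pipeline"]

STAGES = ("chronology", "synchrony", "climate", "fcm", "nonlinear")


@dataclass
class PipelineConfig:
    rwl_dir: str
    climate_path: str
    out_dir: str
    period: tuple[int, int] = (1825, 2005)
    response_period: tuple[int, int] = (1951, 2005)
    window: int = 50
    step: int = 10
    extreme_k: float = 1.5
    response_variable: str = "tmn"
    season_months: tuple[str, ...] = ("prev_nov", "prev_dec", "jan")
    mcf_window: int = 30
    mcf_precip_month: str = "jun"
    fcm_cold: tuple[int, int] = (1965, 1980)
    fcm_warm: tuple[int, int] = (1990, 2005)
    fcm_m: float = 2.0
    fcm_restarts: int = 10
    stability_m: int = 1000
    eemd_ensemble: int = 100
    eemd_noise_fraction: float = 0.2
    ann_hidden: int = 4
    ann_epochs: int = 5000
    sss_threshold: float = 0.85
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("period", "response_period", "fcm_cold", "fcm_warm"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.season_months = tuple(cfg.season_months)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class Finding:
    severity: str     # "error" | "warning"
    message: str


@dataclass
class ReportBundle:
    out_dir: Path
    tables: dict[str, Path]
    manifest: dict


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Range and consistency checks; findings, not exceptions."""
    findings: list[Finding] = []
    if not Path(config.rwl_dir).is_dir():
        findings.append(Finding("error", f"rwl_dir not found: {config.rwl_dir}"))
    if not Path(config.climate_path).is_file():
        findings.append(Finding("error", f"climate table not found: {config.climate_path}"))
    y0, y1 = config.period
    if config.window > y1 - y0 + 1:
        findings.append(Finding("error",
                        f"running window {config.window} exceeds period length {y1 - y0 + 1}"))
    r0, r1 = config.response_period
    if config.mcf_window > r1 - r0 + 1:
        findings.append(Finding("error",
                        f"MCF window {config.mcf_window} exceeds response period "
                        f"length {r1 - r0 + 1}"))
    for name, (a, b) in (("cold", config.fcm_cold), ("warm", config.fcm_warm)):
        if not (y0 <= a <= b <= y1):
            findings.append(Finding("error",
                            f"FCM {name} interval {a}-{b} outside analysis period"))
    # reliable-span coverage of the FCM intervals, when chronologies are readable
    if not any(f.severity == "error" and "rwl_dir" in f.message for f in findings):
        try:
            chron = _build_chronology_table(config)
            for name, (a, b) in (("cold", config.fcm_cold), ("warm", config.fcm_warm)):
                short = [c for c in chron.columns
                         if chron[c].reindex(np.arange(a, b + 1)).isna().any()]
                if short:
                    findings.append(Finding("error",
                                    f"FCM {name} interval {a}-{b} not covered by sites {short}"))
        except Exception as exc:  # diagnostics only — never raise from validation
            findings.append(Finding("warning", f"could not verify chronology coverage: {exc}"))
    return findings


# ---------------------------------------------------------------------------
# stage implementations (file-based dataflow)
# ---------------------------------------------------------------------------

def _build_chronology_table(config: PipelineConfig) -> pd.DataFrame:
    frames = {}
    for path in sorted(Path(config.rwl_dir).glob("*.rwl")):
        cores = read_rwl(path)
        msl = float(np.mean([len(c) for c in cores]))
        idx = []
        for core in cores:
            fit = fit_growth_curve(core, mean_segment_length=msl)
            idx.append(detrend_to_index(core, fit))
        chron = truncate_by_sss(build_chronology(idx), config.sss_threshold)
        frames[chron.site_id] = pd.Series(chron.index, index=chron.years)
    if not frames:
        raise ValueError(f"no .rwl files in {config.rwl_dir}")
    df = pd.DataFrame(frames)
    df.index.name = "year"
    return df


def _stage_chronology(config: PipelineConfig, out: Path) -> dict[str, Path]:
    frames = {}
    stats = []
    details = []
    for path in sorted(Path(config.rwl_dir).glob("*.rwl")):
        cores = read_rwl(path)
        msl = float(np.mean([len(c) for c in cores]))
        idx = [detrend_to_index(c, fit_growth_curve(c, mean_segment_length=msl))
               for c in cores]
        chron = truncate_by_sss(build_chronology(idx), config.sss_threshold)
        frames[chron.site_id] = pd.Series(chron.index, index=chron.years)
        details.append(pd.DataFrame({
            "site": chron.site_id, "year": chron.years, "index": chron.index,
            "depth": chron.depth, "sss": chron.sss,
        }))
        stats.append({
            "site": chron.site_id, "n_cores": chron.n_total, "rbar": chron.rbar,
            "eps": chron.eps, "mean_sensitivity": chron.mean_sensitivity,
            "mean_segment_length": msl,
            "reliable_start": chron.reliable_span[0],
            "reliable_end": chron.reliable_span[1],
        })
    if not frames:
        raise ValueError(f"no .rwl files in {config.rwl_dir}")
    df = pd.DataFrame(frames)
    df.index.name = "year"
    p1 = out / "chronologies.tsv"
    df.to_csv(p1, sep="\t", float_format="%.6f")
    p2 = out / "chronology_stats.tsv"
    pd.DataFrame(stats).to_csv(p2, sep="\t", index=False, float_format="%.4f")
    p3 = out / "chronology_detail.tsv"
    pd.concat(details, ignore_index=True).to_csv(p3, sep="\t", index=False,
                                                 float_format="%.6f")
    return {"chronologies": p1, "chronology_stats": p2, "chronology_detail": p3}


def _read_chronologies(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "chronologies.tsv", sep="\t", index_col="year")


def _effective_period(chron: pd.DataFrame, period: tuple[int, int]) -> tuple[int, int]:
    """Clip the requested period to the span every site covers (the network
    overlap, as for the 1825–2005 common period of the full-size study)."""
    covered = chron.dropna()
    y0 = max(period[0], int(covered.index.min()))
    y1 = min(period[1], int(covered.index.max()))
    if (y0, y1) != tuple(period):
        log.info("analysis period clipped to network overlap %d-%d", y0, y1)
    return y0, y1


def _stage_synchrony(config: PipelineConfig, out: Path) -> dict[str, Path]:
    chron = _read_chronologies(out)
    period = _effective_period(chron, config.period)
    res = correlation_pca(chron, period)
    loadings = res.loadings.iloc[:, :2].copy()
    loadings["pc1_share"] = res.shares[0]
    loadings["pc2_share"] = res.shares[1]
    p1 = out / "pca_loadings.tsv"
    loadings.to_csv(p1, sep="\t", float_format="%.4f")
    track = running_pc1_share(chron, config.window, config.step, period)
    p2 = out / "running_pc1.tsv"
    track.to_csv(p2, sep="\t", index=False, float_format="%.2f")
    flags = pd.DataFrame({c: flag_extremes(chron[c], period, config.extreme_k)
                          for c in chron.columns})
    counts = extreme_frequency(flags)
    p3 = out / "extreme_counts.tsv"
    counts.to_csv(p3, sep="\t")
    return {"pca_loadings": p1, "running_pc1": p2, "extreme_counts": p3}


def _regional_growth(config: PipelineConfig, out: Path) -> pd.Series:
    """PC1 scores recomputed over the climate response period."""
    chron = _read_chronologies(out)
    r0, r1 = config.response_period
    r0 = max(r0, int(chron.index.min()))
    r1 = min(r1, int(chron.index.max()))
    return pc_scores(chron, period=(r0, r1))


def _stage_climate(config: PipelineConfig, out: Path) -> dict[str, Path]:
    climate = read_climate_table(config.climate_path)
    growth = _regional_growth(config, out)
    paths = {}
    rows = []
    for var in [v for v in ("tmp", "tmx", "tmn", "pre") if v in climate.columns]:
        mat = build_dendro_matrix(climate, var)
        cf = correlation_function(growth, mat,
                                  seasons={"season": list(config.season_months)})
        for month, r in cf.r.items():
            rows.append({"variable": var, "month": month, "r": r,
                         "n": cf.n, "r95": cf.r_crit_95, "r99": cf.r_crit_99})
        rows.append({"variable": var, "month": "+".join(config.season_months),
                     "r": cf.seasons["season"], "n": cf.n,
                     "r95": cf.r_crit_95, "r99": cf.r_crit_99})
    p1 = out / "correlation_function.tsv"
    pd.DataFrame(rows).to_csv(p1, sep="\t", index=False, float_format="%.4f")
    paths["correlation_function"] = p1

    seed = config.stage_seed("climate")
    mat = build_dendro_matrix(climate, config.response_variable)
    season = seasonal_mean(mat, list(config.season_months))
    predictors = {"season_" + config.response_variable: season}
    if "pre" in climate.columns:
        pre_mat = build_dendro_matrix(climate, "pre")
        predictors["pre_" + config.mcf_precip_month] = pre_mat[config.mcf_precip_month]
    stability_report = {}
    for name, pred in predictors.items():
        track = moving_correlation(growth, pred, config.mcf_window)
        p = out / f"moving_corr_{name}.tsv"
        track.to_csv(p, sep="\t", float_format="%.4f")
        paths[f"moving_corr_{name}"] = p
        st = stability_test(growth, pred, config.mcf_window,
                            M=config.stability_m, seed=seed)
        stability_report[name] = {
            "observed_variance": st.observed, "p_value": st.p_value,
            "r_full": st.r_full, "ar1": list(st.ar1),
            "window": st.window, "M": st.M, "seed": seed,
        }
    p2 = out / "stability_test.json"
    p2.write_text(json.dumps(stability_report, indent=2, sort_keys=True))
    paths["stability_test"] = p2
    return paths


def _stage_fcm(config: PipelineConfig, out: Path) -> dict[str, Path]:
    chron = _read_chronologies(out)
    seed = config.stage_seed("fcm")
    results = {}
    paths = {}
    for name, interval in (("cold", config.fcm_cold), ("warm", config.fcm_warm)):
        X = extract_interval_matrix(chron, interval)
        res = fcm(X, k=2, m=config.fcm_m, restarts=config.fcm_restarts, seed=seed)
        results[name] = res
        p = out / f"fcm_memberships_{name}.tsv"
        res.memberships.to_csv(p, sep="\t", float_format="%.4f")
        paths[f"fcm_memberships_{name}"] = p
    summary = partition_summary(results["cold"], results["warm"])
    p = out / "fcm_summary.tsv"
    summary.to_csv(p, sep="\t", float_format="%.4f")
    paths["fcm_summary"] = p
    return paths


def _stage_nonlinear(config: PipelineConfig, out: Path) -> dict[str, Path]:
    climate = read_climate_table(config.climate_path)
    growth = _regional_growth(config, out)
    mat = build_dendro_matrix(climate, config.response_variable)
    season = seasonal_mean(mat, list(config.season_months)).dropna()
    paths = {}
    seed = config.stage_seed("nonlinear")
    res = eemd(season.to_numpy(), config.eemd_ensemble,
               config.eemd_noise_fraction, seed=seed)
    trend_df = pd.DataFrame({"year": season.index, "input": season.to_numpy(),
                             "trend": res.trend})
    p1 = out / "eemd_trend.tsv"
    trend_df.to_csv(p1, sep="\t", index=False, float_format="%.4f")
    paths["eemd_trend"] = p1

    novdec = seasonal_mean(mat, ["prev_nov", "prev_dec"])
    jan = mat["jan"]
    common = growth.index.intersection(novdec.dropna().index).intersection(jan.dropna().index)
    X = pd.DataFrame({"novdec": novdec.loc[common], "jan": jan.loc[common]})
    model = GrowthANN(hidden=config.ann_hidden, epochs=config.ann_epochs,
                      random_state=seed).fit(X.to_numpy(), growth.loc[common].to_numpy())
    # evaluate only where the training data give support (sigmoid outputs
    # saturate in the unsampled tails and would fake curvature)
    jan_lo, jan_hi = jan.loc[common].quantile([0.05, 0.95])
    nd_lo, nd_hi = novdec.loc[common].quantile([0.05, 0.95])
    surf = response_surface(model, (float(jan_lo), float(jan_hi)),
                            (float(nd_lo), float(nd_hi)), step=0.1)
    grid = pd.DataFrame(
        [(j, n, surf.values[i_n, i_j])
         for i_n, n in enumerate(surf.novdec_grid)
         for i_j, j in enumerate(surf.jan_grid)],
        columns=["jan_temp", "novdec_temp", "predicted_index"],
    )
    p2 = out / "response_surface.tsv"
    grid.to_csv(p2, sep="\t", index=False, float_format="%.4f")
    paths["response_surface"] = p2
    pw = out / "ann_model.json"
    export_growth_ann(model, pw)
    paths["ann_model"] = pw
    est = detect_sensitivity_threshold(surf)
    p3 = out / "threshold.json"
    p3.write_text(json.dumps({
        "breakpoint_degC": est.breakpoint, "slope_below": est.slope_below,
        "slope_above": est.slope_above, "slope_ratio": est.slope_ratio,
        "identifiable": est.identifiable, "validation_r2": model.validation_score_,
        "seed": seed,
    }, indent=2))
    paths["threshold"] = p3
    return paths


_STAGE_FUNCS = {
    "chronology": _stage_chronology,
    "synchrony": _stage_synchrony,
    "climate": _stage_climate,
    "fcm": _stage_fcm,
    "nonlinear": _stage_nonlinear,
}

_STAGE_OUTPUTS = {
    "chronology": ["chronologies.tsv", "chronology_stats.tsv", "chronology_detail.tsv"],
    "synchrony": ["pca_loadings.tsv", "running_pc1.tsv", "extreme_counts.tsv"],
    "climate": ["correlation_function.tsv", "stability_test.json"],
    "fcm": ["fcm_summary.tsv"],
    "nonlinear": ["eemd_trend.tsv", "response_surface.tsv", "ann_model.json",
                  "threshold.json"],
}

#: stages whose failure degrades to a warning instead of aborting the run
_OPTIONAL_STAGES = {"nonlinear"}


def run_pipeline(config: PipelineConfig, force: bool = False,
                 stages: tuple[str, ...] | None = None) -> ReportBundle:
    """Run the analysis stages in order, skipping stages whose outputs exist.

    Raises on errors in required stages; failures in optional stages (the
    ANN/EEMD diagnostics) degrade to manifest warnings. The manifest is
    written last.
    """
    findings = validate_config(config)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(f.message for f in errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wanted = stages or STAGES
    tables: dict[str, Path] = {}
    warnings = [f.message for f in findings if f.severity == "warning"]
    ran = []
    for stage in STAGES:
        if stage not in wanted:
            continue
        if not force and all((out / f).exists() for f in _STAGE_OUTPUTS[stage]):
            log.info("stage %s: outputs present, skipped", stage)
            continue
        try:
            tables.update(_STAGE_FUNCS[stage](config, out))
            ran.append(stage)
        except Exception as exc:
            if stage in _OPTIONAL_STAGES:
                warnings.append(f"optional stage {stage} failed: {exc}")
                log.warning("optional stage %s failed: %s", stage, exc)
            else:
                raise
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "stages_run": ran,
        "version": __version__,
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ReportBundle(out, tables, manifest)
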