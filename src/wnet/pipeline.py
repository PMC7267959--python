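"""End-to-end pipeline: simulate -> connectivity -> threshold -> metrics ->
density -> stats -> classify, driven by one validated config.

Every stochastic stage draws its seed deterministically from the single
master seed, so re-running the same config reproduces identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import classify as clf
from . import connectivity as conn
from . import density as dens
from . import io as wio
from . import metrics as met
from . import network as net
from . import stats as wstats
from ._utils import derive_seed
from .exceptions import InvalidArgumentError
from .synthetic import BANDS, CouplingSpec, GroupSpec, generate_cohort, generate_layout

STAGES = ("simulate", "connectivity", "threshold", "metrics",
          "density", "stats", "classify")


class CouplingConfig(BaseModel):
    band: str
    edges: list[tuple[int, int]] = Field(default_factory=list)
    strengths: list[float] = Field(default_factory=list)
    lags: list[float] = Field(default_factory=list)
    noise_sd: float = 0.2


class GroupConfig(BaseModel):
    name: str
    n_subjects: int = 8
    attenuation: dict[str, float] = Field(default_factory=dict)
    clinical_means: dict[str, float] = Field(default_factory=dict)
    clinical_sds: dict[str, float] = Field(default_factory=dict)
    planted_rho: dict[str, float] = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Schema-validated configuration for a full pipeline run."""

    seed: int = 0
    n_channels: int = 32
    n_epochs: int = 6
    fs: float = 256.0
    bands: list[str] = Field(default_factory=lambda: list(BANDS))
    pt_lo: float = 3.0
    pt_hi: float = 60.0
    pt_step: float = 1.0
    modes: list[str] = Field(default_factory=lambda: ["binary", "weighted"])
    metrics: list[str] = Field(default_factory=lambda: ["degree", "clustering", "path_length"])
    n_surrogates: int = 0  # > 0 adds surrogate-normalised C/L and sigma
    n_perm: int = 1000
    nbs_threshold: float = 8.0
    groups: list[GroupConfig] = Field(default_factory=list)
    coupling: list[CouplingConfig] = Field(default_factory=list)
    classify_groups: tuple[str, str] | None = None
    classify_folds: int = 6
    classify_repeats: int = 10
    classify_trees: int = 500

    @field_validator("bands")
    @classmethod
    def _bands_known(cls, v):
        for b in v:
            if b not in BANDS:
                raise ValueError(f"unknown band {b!r}")
        return v


def demo_config(seed: int = 0) -> RunConfig:
    """Four-group, 32-channel demo cohort with attenuated alpha coupling in
    the dementia-like groups and an extra beta attenuation in the DLB-like
    group (plus a planted negative hallucination-score correlation)."""
    edges = [(0, 16), (1, 17), (2, 18), (3, 19), (4, 20), (5, 21)]
    coupling = [
        CouplingConfig(band="alpha", edges=edges, strengths=[0.8] * 6,
                       lags=[np.pi / 2] * 6, noise_sd=0.3),
        CouplingConfig(band="beta", edges=edges, strengths=[0.7] * 6,
                       lags=[np.pi / 2] * 6, noise_sd=0.3),
        CouplingConfig(band="theta", edges=edges, strengths=[0.6] * 6,
                       lags=[np.pi / 2] * 6, noise_sd=0.3),
    ]
    clin = {"MMSE": 25.0, "NPI_hall": 3.0}
    sds = {"MMSE": 3.0, "NPI_hall": 2.0}
    groups = [
        GroupConfig(name="HC", n_subjects=8, clinical_means={"MMSE": 29.0, "NPI_hall": 0.2},
                    clinical_sds=sds),
        GroupConfig(name="AD", n_subjects=8, attenuation={"alpha": 0.55},
                    clinical_means=clin, clinical_sds=sds),
        GroupConfig(name="DLB", n_subjects=8, attenuation={"alpha": 0.55, "beta": 0.45},
                    clinical_means=clin, clinical_sds=sds,
                    planted_rho={"NPI_hall": -0.6}),
        GroupConfig(name="PDD", n_subjects=8, attenuation={"alpha": 0.55, "beta": 0.7},
                    clinical_means=clin, clinical_sds=sds),
    ]
    return RunConfig(seed=seed, groups=groups, coupling=coupling,
                     classify_groups=("DLB", "AD"), n_perm=200,
                     classify_repeats=3, classify_trees=100)


def _to_specs(cfg: RunConfig) -> list[CouplingSpec]:
    return [CouplingSpec(band=c.band, edge_list=tuple(map(tuple, c.edges)),
                         coupling_strength=tuple(c.strengths),
                         phase_lag=tuple(c.lags), noise_sd=c.noise_sd)
            for c in cfg.coupling]


def _to_groups(cfg: RunConfig) -> list[GroupSpec]:
    return [GroupSpec(name=g.name, n_subjects=g.n_subjects, attenuation=g.attenuation,
                      clinical_means=g.clinical_means, clinical_sds=g.clinical_sds,
                      planted_rho=g.planted_rho)
            for g in cfg.groups]


def run_all(config: RunConfig, out_dir) -> Path:
    """Run every pipeline stage; returns the run directory.

    Writes per-subject epoch files, layout.tsv, clinical.csv, per-band
    matrices, a long-format metrics.csv, density_report.json, stats
    outputs and classification.json, plus a manifest recording config
    hash, versions, per-stage status and runtimes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json()
    manifest = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "stages": {},
    }
    (out / "config.json").write_text(cfg_json)

    def _finish(stage, t0, **extra):
        manifest["stages"][stage] = {"status": "ok", "runtime_s": round(time.time() - t0, 3),
                                     **extra}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def _fail(stage, exc):
        manifest["stages"][stage] = {"status": f"failed: {exc}"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- simulate ---------------------------------------------------------
    t0 = time.time()
    try:
        layout = generate_layout(config.n_channels, seed=derive_seed(config.seed, "layout"))
        recordings, clinical = generate_cohort(
            _to_groups(config), layout, _to_specs(config),
            seed=derive_seed(config.seed, "cohort"),
            n_epochs=config.n_epochs, fs=config.fs)
        wio.write_layout(layout, out / "layout.tsv")
        clinical.to_csv(out / "clinical.csv", index=False)
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for r in recordings:
            wio.write_epochs(r, rec_dir / f"{r.subject_id}.npz")
    except Exception as exc:
        _fail("simulate", exc)
    _finish("simulate", t0, n_subjects=len(recordings))
    group_of = dict(zip(clinical["subject_id"], clinical["group"]))

    # -- connectivity -----------------------------------------------------
    t0 = time.time()
    try:
        mat_dir = out / "matrices"
        mat_dir.mkdir(exist_ok=True)
        matrices: dict[str, dict[str, conn.ConnectivityMatrix]] = {}
        for r in recordings:
            matrices[r.subject_id] = conn.band_matrices(r, bands=tuple(config.bands))
            for band, m in matrices[r.subject_id].items():
                wio.write_matrix(m, mat_dir / f"{r.subject_id}_{band}.tsv")
    except Exception as exc:
        _fail("connectivity", exc)
    _finish("connectivity", t0, n_matrices=len(recordings) * len(config.bands))

    # -- threshold + metrics ---------------------------------------------
    t0 = time.time()
    rows = []
    try:
        curves: dict = {}
        for sid, per_band in matrices.items():
            for band, m in per_band.items():
                normed = net.normalize_weights(m)
                for mode in config.modes:
                    sweep = net.pt_sweep(normed, config.pt_lo, config.pt_hi,
                                         config.pt_step, mode=mode)
                    for metric in config.metrics:
                        kw = {}
                        if metric in ("modularity", "sigma"):
                            kw = {"seed": derive_seed(config.seed, "metric", sid, band, mode)}
                        if metric == "sigma":
                            kw["n_surrogates"] = max(config.n_surrogates, 1)
                        curve = dens.metric_curve(sweep, metric, **kw)
                        curves[(sid, band, mode, metric)] = curve
                        for pt, v in zip(curve.pt_levels, curve.values):
                            rows.append({"subject_id": sid, "group": group_of[sid],
                                         "band": band, "pt": pt, "mode": mode,
                                         "metric": metric, "value": v})
        metrics_df = pd.DataFrame(rows)
        metrics_df.to_csv(out / "metrics.csv", index=False)
    except Exception as exc:
        _fail("metrics", exc)
    manifest["stages"]["threshold"] = {"status": "ok", "runtime_s": 0.0,
                                       "note": "folded into metrics stage"}
    _finish("metrics", t0, n_rows=len(rows))

    # -- density ----------------------------------------------------------
    t0 = time.time()
    try:
        report = {}
        for metric in config.metrics:
            report[metric] = {}
            fits = {}
            for mode in config.modes:
                pooled = [c for (sid, b, md, mt), c in curves.items()
                          if md == mode and mt == metric]
                dd = dens.density_dependence(pooled, n_perm=config.n_perm,
                                             seed=derive_seed(config.seed, "density", metric, mode))
                # group-mean curve for the power-law fit
                mean_curve = dens.MetricCurve(
                    pt_levels=pooled[0].pt_levels,
                    values=np.mean([c.values for c in pooled], axis=0),
                    metric=metric, mode=mode)
                try:
                    fit = dens.fit_power_law(mean_curve)
                    fits[mode] = fit
                    fit_out = {"scale": fit.scale, "exponent": fit.exponent,
                               "offset": fit.offset, "sse": fit.sse, "ci95": fit.ci95}
                except Exception as fe:  # fit failure is reported, not fatal
                    fit_out = {"error": str(fe)}
                report[metric][mode] = {"rho": dd.rho, "significant": dd.significant,
                                        "p_null": dd.p_null, "fit": fit_out}
            if "binary" in fits and "weighted" in fits:
                try:
                    iv = dens.derivative_ratio_condition(fits["binary"], fits["weighted"])
                    report[metric]["weighted_flatter_interval"] = (
                        None if iv.empty else [iv.lower, iv.upper])
                except InvalidArgumentError as ie:
                    report[metric]["weighted_flatter_interval"] = f"undefined: {ie}"
        (out / "density_report.json").write_text(json.dumps(report, indent=1))
    except Exception as exc:
        _fail("density", exc)
    _finish("density", t0)

    # -- stats ------------------------------------------------------------
    t0 = time.time()
    try:
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        glabels = [g.name for g in config.groups]
        subj_groups = clinical.set_index("subject_id")["group"]
        # threshold-averaged measures: KW + MWU/Holm per band/metric/mode
        avg = metrics_df.groupby(["subject_id", "group", "band", "mode", "metric"])["value"] \
            .mean().reset_index()
        test_rows = []
        for (band, mode, metric), sub in avg.groupby(["band", "mode", "metric"]):
            per_group = [sub.loc[sub["group"] == g, "value"].to_numpy() for g in glabels]
            kw = wstats.kruskal_wallis(per_group, labels=glabels)
            test_rows.append({"band": band, "mode": mode, "metric": metric,
                              "test": "kruskal_wallis", "comparison": "omnibus",
                              "statistic": kw.statistic, "p_raw": kw.p_raw,
                              "p_adjusted": kw.p_adjusted})
            for r in wstats.mann_whitney_posthoc(per_group, labels=glabels):
                test_rows.append({"band": band, "mode": mode, "metric": metric,
                                  "test": "mann_whitney", "comparison": "-".join(r.comparison),
                                  "statistic": r.statistic, "p_raw": r.p_raw,
                                  "p_adjusted": r.p_adjusted})
        pd.DataFrame(test_rows).to_csv(stats_dir / "group_tests.csv", index=False)
        # mean WPLI + NBS per band
        nbs_out = {}
        for band in config.bands:
            sids = list(matrices)
            mats = [matrices[s][band] for s in sids]
            design = [subj_groups[s] for s in sids]
            res = wstats.nbs(mats, design, stat="F", threshold=config.nbs_threshold,
                             n_perm=config.n_perm,
                             seed=derive_seed(config.seed, "nbs", band))
            nbs_out[band] = {"components": res.component_labels,
                             "sizes": res.component_sizes, "p": res.component_p,
                             "threshold": res.threshold, "n_perm": res.n_perm}
        (stats_dir / "nbs.json").write_text(json.dumps(nbs_out, indent=1))
        # clinical correlations on threshold-averaged weighted measures
        meas = avg[avg["mode"] == "weighted"].rename(columns={"value": "value"})
        cc = wstats.clinical_correlations(
            meas[["subject_id", "group", "band", "metric", "value"]]
            .rename(columns={"metric": "measure"}), clinical)
        cc.to_csv(stats_dir / "clinical_correlations.csv", index=False)
    except Exception as exc:
        _fail("stats", exc)
    _finish("stats", t0)

    # -- classify ---------------------------------------------------------
    t0 = time.time()
    try:
        if config.classify_groups:
            ga, gb = config.classify_groups
            feats = avg[avg["mode"] == "weighted"].pivot_table(
                index=["subject_id", "group"], columns=["band", "metric"], values="value")
            feats.columns = [f"{b}_{m}" for b, m in feats.columns]
            feats = feats.reset_index()
            mask = feats["group"].isin([ga, gb])
            report = clf.rf_crossval(
                feats.loc[mask, feats.columns.difference(["subject_id", "group"])],
                feats.loc[mask, "group"].to_numpy(),
                folds=config.classify_folds, repeats=config.classify_repeats,
                seed=derive_seed(config.seed, "classify"),
                n_estimators=config.classify_trees)
            (out / "classification.json").write_text(json.dumps({
                "scenario": [ga, gb],
                "metrics": {k: list(v) for k, v in report.metrics.items()},
                "auroc": [report.auroc_mean, report.auroc_sd],
                "optimal_point": list(report.optimal_point),
                "importance": report.importance[:10],
            }, indent=1))
            status_extra = {"auroc": report.auroc_mean}
        else:
            status_extra = {"note": "no classification scenario configured"}
    except Exception as exc:
        _fail("classify", exc)
    _finish("classify", t0, **status_extra)
    return out
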