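"""End-to-end orchestration: detection -> availability -> rates -> models.

``run`` executes the full analysis on an input bundle (in memory, or read
from a directory of text artifacts): visit detection with the moving
circle, the water-buffer filter, the pooled home range with CSR
availability sampling, covariate extraction with the analysis transforms,
NDVI season segmentation, per-season revisitation rates, subsampled
used-vs-available Kolmogorov comparisons, binned quadratic regressions per
variable, and backward-AIC mixed-model selection per sex x season stratum.
Every stochastic stage derives its generator from the single pipeline
seed, so a rerun with the same config reproduces the report exactly; each
stage logs its input/output row counts so the filter cascade is auditable.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import environment as env
from .environment import DynamicSeries, StaticLayer, WaterFeatures, read_ascii_grid
from .home_range import alocoh, sample_available
from .rate_models import (
    DEFAULT_INTERACTIONS,
    add_interactions,
    backward_aic,
    bin_means,
    nakagawa_r2,
    quad_regression,
    revisitation_rate,
    scale_columns,
    quadratic_term,
)
from .recursion import RecursionConfig, filter_water_sites, revisitation_table, select_radius
from .seasonality import assign_season, season_cutpoints, standardize_ndvi
from .selection_stats import fit_rate_distribution, subsampled_ks
from .trajectories import read_trajectories, tracking_span

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "load_bundle_dir", "build_site_table"]

MODEL_VARS = ("dist_water", "evi", "phosphorus", "temperature", "slope")
SCREEN_VARS = ("dist_water", "evi", "phosphorus", "nitrogen", "temperature", "slope", "precipitation")


@dataclass
class PipelineConfig:
    recursion: RecursionConfig = field(default_factory=RecursionConfig)
    choose_radius: bool = False          # run the variance-peak scan first
    centre_stride: int = 1
    water_buffer: float = 500.0
    availability_n: int = 100_000
    home_range_thin: int = 10            # every k-th fix enters the a-LoCoH
    ks_n_iter: int = 10_000
    ks_m: int = 100
    ks_alpha: float = 0.05
    n_bins: int = 1000
    screen_threshold: float = 0.5
    interactions: tuple = DEFAULT_INTERACTIONS
    r2_resamples: int = 100
    resample_n_strata: int = 10
    resample_per_stratum: int = 50
    min_stratum_rows: int = 30           # skip model strata with fewer records
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a pipeline configuration from a YAML mapping.

        Recursion parameters nest under a ``recursion`` key
        (``radius``, ``min_time_away_h``, ``candidate_radii``); everything
        else maps directly onto the dataclass fields.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rec = raw.pop("recursion", None)
        kw = dict(raw)
        if rec is not None:
            rkw = {}
            if "radius" in rec:
                rkw["radius"] = float(rec["radius"])
            if "min_time_away_h" in rec:
                rkw["min_time_away_s"] = float(rec["min_time_away_h"]) * 3600.0
            if "candidate_radii" in rec:
                rkw["candidate_radii"] = tuple(float(r) for r in rec["candidate_radii"])
            kw["recursion"] = RecursionConfig(**rkw)
        if "interactions" in kw:
            kw["interactions"] = tuple(tuple(p) for p in kw["interactions"])
        return cls(**kw)


def load_bundle_dir(directory):
    """Read a bundle directory written by :meth:`StudyBundle.write`."""
    trajset = read_trajectories(os.path.join(directory, "fixes.csv"))
    static = {}
    for name in ("phosphorus", "nitrogen", "elevation"):
        path = os.path.join(directory, f"{name}.asc")
        if os.path.exists(path):
            static[name] = read_ascii_grid(path, name=name)
    dynamic = {}
    for name in ("evi", "temperature", "precipitation"):
        idx = os.path.join(directory, f"{name}_index.csv")
        if os.path.exists(idx):
            dynamic[name] = DynamicSeries.read(idx, name=name)
    water_path = os.path.join(directory, "water.geojson")
    if not os.path.exists(water_path):
        raise FileNotFoundError(water_path)
    water = WaterFeatures.from_geojson(water_path)
    ndvi = pd.read_csv(os.path.join(directory, "ndvi.csv"))
    ndvi_t = pd.to_datetime(ndvi["timestamp"], utc=True).astype("int64").to_numpy() / 1e9
    return trajset, static, dynamic, water, (ndvi_t, ndvi["value"].to_numpy(float))


def _stage(name):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def build_site_table(sites, trajset, static, dynamic, water, season_table) -> pd.DataFrame:
    """One row per site x season with the revisitation rate and covariates.

    Static covariates are extracted at the site centre; dynamic covariates
    are extracted at the last record at or before each visit entry time and
    averaged over the visits of that site-season.  Transforms applied here
    are the modelling conventions: sqrt distance to water, log1p slope in
    degrees.
    """
    slope_layer = env.slope_from_elevation(static["elevation"]) if "elevation" in static else None
    spans = {ind: tuple(ts.timestamp() for ts in tracking_span(trajset[ind]))
             for ind in trajset.ids()}
    xs = np.array([s.cx for s in sites])
    ys = np.array([s.cy for s in sites])
    static_vals = {name: env.extract_static(layer, xs, ys) for name, layer in static.items()}
    if slope_layer is not None:
        slope_deg = env.extract_static(slope_layer, xs, ys)
    dwater, dwater_sqrt = env.distance_to_water(xs, ys, water)

    # per-site-season rate rows
    rows = []
    for i, site in enumerate(sites):
        for season, rate in revisitation_rate(site, season_table, spans[site.individual_id]).items():
            rows.append((i, site.site_id, site.individual_id, site.sex, season,
                         site.n_visits, rate))
    if not rows:
        return pd.DataFrame()
    rec = pd.DataFrame(rows, columns=["_i", "site_id", "individual_id", "sex", "season",
                                      "n_visits", "rate"])
    rec["log_rate"] = np.log(rec["rate"].to_numpy())
    rec["dist_water_raw"] = dwater[rec["_i"]]
    rec["dist_water"] = dwater_sqrt[rec["_i"]]
    for name, vals in static_vals.items():
        rec[name] = vals[rec["_i"]]
    if slope_layer is not None:
        rec["slope_deg"] = slope_deg[rec["_i"]]
        rec["slope"] = np.log1p(rec["slope_deg"].to_numpy())

    # dynamic covariates: one flat extraction over all (visit entry, site) pairs,
    # then the per-site-season mean
    c0, c1 = season_table.coverage
    v_site = []
    v_t = []
    for i, site in enumerate(sites):
        for t in site.entry_times:
            v_site.append(i)
            v_t.append(t)
    v_site = np.asarray(v_site)
    v_t = np.asarray(v_t, float)
    in_cov = (v_t >= c0) & (v_t <= c1)
    v_season = np.full(len(v_t), "", dtype=object)
    v_season[in_cov] = assign_season(v_t[in_cov], season_table)
    vx = xs[v_site]
    vy = ys[v_site]
    key = pd.MultiIndex.from_arrays([v_site, v_season], names=["_i", "season"])
    for name, series in dynamic.items():
        vals = env.extract_dynamic(series, vx, vy, v_t)
        means = pd.Series(vals, index=key).groupby(level=["_i", "season"]).mean()
        rec[name] = means.reindex(
            pd.MultiIndex.from_frame(rec[["_i", "season"]])).to_numpy()
    return rec.drop(columns=["_i"])


def _available_table(points, static, dynamic, water) -> pd.DataFrame:
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    ts = np.array([p.stamped_time for p in points])
    out = {"x": xs, "y": ys, "stamped_time": ts}
    for name, layer in static.items():
        out[name] = env.extract_static(layer, xs, ys)
    if "elevation" in static:
        slope_layer = env.slope_from_elevation(static["elevation"])
        out["slope"] = np.log1p(env.extract_static(slope_layer, xs, ys))
    dwater, dwater_sqrt = env.distance_to_water(xs, ys, water)
    out["dist_water_raw"] = dwater
    out["dist_water"] = dwater_sqrt
    for name, series in dynamic.items():
        out[name] = env.extract_dynamic(series, xs, ys, ts)
    return pd.DataFrame(out)


def run(cfg: PipelineConfig, bundle=None, bundle_dir=None) -> dict:
    """Execute the full pipeline; returns the run report as a nested dict.

    Provide either an in-memory :class:`~revisit.synthetic.StudyBundle` or
    a directory of bundle artifacts.  With ``cfg.out_dir`` set, the site
    table, availability table, AIC tables and the JSON report are written
    there.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
    report: dict = {"stages": {}, "seed": cfg.seed}

    with _stage("load-inputs"):
        if bundle is not None:
            trajset = bundle.trajset
            static, dynamic = dict(bundle.static), dict(bundle.dynamic)
            water = bundle.water
            ndvi_t, ndvi_v = bundle.ndvi_series()
        elif bundle_dir is not None:
            trajset, static, dynamic, water, (ndvi_t, ndvi_v) = load_bundle_dir(bundle_dir)
        else:
            raise ValueError("need bundle or bundle_dir")
        dynamic = {k: v for k, v in dynamic.items() if k != "ndvi"}
        n_fixes = sum(len(t) for t in trajset)
        report["stages"]["load"] = {"individuals": len(trajset), "fixes": n_fixes}

    with _stage("detect-revisits"):
        rcfg = cfg.recursion
        if cfg.choose_radius:
            r = select_radius(trajset, rcfg, centre_stride=max(cfg.centre_stride, 4))
            rcfg = RecursionConfig(radius=r, min_time_away_s=rcfg.min_time_away_s,
                                   candidate_radii=rcfg.candidate_radii)
        sites = revisitation_table(trajset, rcfg, centre_stride=cfg.centre_stride)
        report["stages"]["detect"] = {"radius_m": rcfg.radius, "sites": len(sites)}

    with _stage("water-filter"):
        sites = filter_water_sites(sites, water, cfg.water_buffer)
        report["stages"]["water_filter"] = {"sites_kept": len(sites), "buffer_m": cfg.water_buffer}
        if not sites:
            raise ValueError("no sites outside the water buffer")

    with _stage("seasons"):
        t, z = standardize_ndvi(ndvi_t, ndvi_v)
        season_table = season_cutpoints(t, z)
        report["stages"]["seasons"] = {
            "years": [y.label for y in season_table.years],
            "fallback_years": [y.label for y in season_table.years if y.fallback],
        }

    with _stage("site-table"):
        records = build_site_table(sites, trajset, static, dynamic, water, season_table)
        report["stages"]["site_table"] = {"rows": len(records)}
        if records.empty:
            raise ValueError("no site-season records")

    with _stage("rate-distribution"):
        fits = fit_rate_distribution(records["rate"].to_numpy())
        report["rate_distribution"] = [
            {"family": f.family, "aic": f.aic, "loglik": f.loglik} for f in fits
        ]

    with _stage("home-range-availability"):
        pts = np.concatenate([np.column_stack([tr.x, tr.y])[:: cfg.home_range_thin]
                              for tr in trajset])
        hr = alocoh(pts, a=None, isopleth=1.0)
        entry_times = np.concatenate([s.entry_times for s in sites])
        avail_pts = sample_available(hr, water, cfg.water_buffer, cfg.availability_n,
                                     entry_times, seed=rng.integers(2 ** 31))
        avail = _available_table(avail_pts, static, dynamic, water)
        report["stages"]["availability"] = {
            "home_range_area_km2": hr.area / 1e6, "n_points": len(avail),
        }

    with _stage("used-vs-available-ks"):
        ks_report = {}
        screen_vars = [v for v in SCREEN_VARS if v in records.columns and v in avail.columns]
        for (sex, season), sub in records.groupby(["sex", "season"]):
            key = f"{sex}:{season}"
            ks_report[key] = {}
            for var in screen_vars:
                used_v = sub[var].dropna().to_numpy()
                avail_v = avail[var].dropna().to_numpy()
                m = min(cfg.ks_m, len(used_v), len(avail_v))
                if m < 10:
                    continue
                res = subsampled_ks(used_v, avail_v, n_iter=cfg.ks_n_iter, m=m,
                                    alpha=cfg.ks_alpha, seed=int(rng.integers(2 ** 31)))
                ks_report[key][var] = res.to_dict()
        report["ks"] = ks_report

    with _stage("correlation-screen"):
        cols = [v for v in SCREEN_VARS if v in records.columns]
        retained, corr = env.correlation_screen(records[cols], cfg.screen_threshold,
                                               priority=list(MODEL_VARS) + ["nitrogen", "precipitation"])
        report["screen"] = {"retained": retained,
                            "correlations": corr.round(3).to_dict()}

    with _stage("binned-regressions"):
        binned = {}
        bin_vars = [v for v in SCREEN_VARS if v in records.columns]
        for (sex, season), sub in records.groupby(["sex", "season"]):
            key = f"{sex}:{season}"
            binned[key] = {}
            for var in bin_vars:
                try:
                    bt = bin_means(sub[var], sub["log_rate"], n_bins=cfg.n_bins, variable=var)
                    qf = quad_regression(bt)
                except ValueError:
                    continue
                binned[key][var] = {"x": qf.b_x, "x2": qf.b_x2, "r2": qf.r2,
                                    "n_bins_nonempty": len(bt.centres)}
        report["binned"] = binned

    with _stage("mixed-models"):
        # precipitation stops here: exploratory only, not a mixed-model candidate
        model_vars = [v for v in retained if v in MODEL_VARS]
        models = {}
        for (sex, season), sub in records.groupby(["sex", "season"]):
            key = f"{sex}:{season}"
            sub = sub.dropna(subset=model_vars + ["log_rate"])
            if len(sub) < cfg.min_stratum_rows or sub["individual_id"].nunique() < 2:
                models[key] = {"skipped": f"{len(sub)} rows, "
                               f"{sub['individual_id'].nunique()} individuals (need >= 2)"}
                continue
            scaled = scale_columns(sub.reset_index(drop=True), model_vars)
            terms = list(model_vars) + [quadratic_term(v) for v in model_vars]
            rkw = {"n_strata": cfg.resample_n_strata,
                   "per_stratum": cfg.resample_per_stratum}
            sel = backward_aic(terms, scaled, n_rep=cfg.r2_resamples, resample_kw=rkw,
                               seed=int(rng.integers(2 ** 31)))
            sel = add_interactions(sel, cfg.interactions, scaled,
                                   n_rep=cfg.r2_resamples, resample_kw=rkw,
                                   seed=int(rng.integers(2 ** 31)))
            rm2, rc2 = nakagawa_r2(sel.chosen_fit)
            models[key] = {
                "chosen_terms": list(sel.chosen_terms),
                "coefficients": sel.chosen_fit.coefficients,
                "delta_aic": sel.delta_aic,
                "sigma_a2": sel.chosen_fit.sigma_a2,
                "sigma_e2": sel.chosen_fit.sigma_e2,
                "rm2": rm2, "rc2": rc2,
                "rm2_resampled": [sel.rm2_mean, sel.rm2_sd],
                "rc2_resampled": [sel.rc2_mean, sel.rc2_sd],
                "n": int(sel.chosen_fit.n),
            }
        report["models"] = models

    if cfg.out_dir:
        with _stage("write-outputs"):
            os.makedirs(cfg.out_dir, exist_ok=True)
            records.to_csv(os.path.join(cfg.out_dir, "site_records.csv"), index=False)
            avail.to_csv(os.path.join(cfg.out_dir, "available.csv"), index=False)
            with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
                json.dump(_jsonable(report), fh, indent=1)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
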