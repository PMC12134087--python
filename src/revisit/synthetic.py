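"""Synthetic study generator: covariate fields, water, and hotspot foragers.

Generates a complete, self-consistent input bundle for the revisitation
pipeline — smooth covariate rasters, a river-plus-waterholes water layer,
seasonal EVI/NDVI/temperature/precipitation series, and multi-month hourly
trajectories of individuals that alternate between travelling to discrete
foraging hotspots and dwelling at them.  Hotspot locations and visit
weights are a planted log-linear (with quadratic terms) function of the
transformed covariates, so the ground truth the pipeline should recover
(which covariates matter, and the sign of their quadratic terms) is known
exactly and recorded in the bundle.

Default parameters describe the emulated study system: hourly fixes,
multi-month spans per individual, a ~250 m spatial scale of revisited
sites, soil phosphorus and nitrogen fields correlated at rho = 0.8, a
November-April wet season, and concave (intermediate-optimum) planted
effects of phosphorus and of square-root distance to water.

The entire bundle is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point

from .environment import DynamicSeries, StaticLayer, WaterFeatures, distance_to_water
from .trajectories import Trajectory, TrajectorySet, write_trajectories

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyBundle", "gen_fields", "gen_water",
           "gen_hotspots", "gen_trajectory", "gen_study"]

DAY = 86400.0
YEAR_DAYS = 365.0


@dataclass
class StudyConfig:
    """Parameters of the synthetic study (defaults are the study conditions)."""

    domain: tuple[float, float] = (8_000.0, 8_000.0)     # metres
    cell: float = 100.0                                   # raster cell, metres
    n_bulls: int = 3
    n_cows: int = 2
    start: str = "2019-07-01"                             # season-year aligned
    duration_days: float = 365.0
    fix_interval_h: float = 1.0
    # hotspot attraction: {covariate: (beta_linear, beta_quadratic)} on the
    # standardised transformed covariate (sqrt distance for water)
    beta: dict = field(default_factory=lambda: {
        "phosphorus": (1.0, -1.2),
        "dist_water": (0.6, -1.0),
    })
    n_hotspots: int = 80
    hotspot_scale: float = 250.0                          # patch radius, metres
    hotspot_min_spacing: float = 600.0                    # centre-to-centre, metres
    hotspot_quality_sd: float = 1.0                       # unmeasured per-patch quality (log scale)
    hotspot_min_water_dist: float = 700.0                 # keep sites outside the 500 m buffer
    # movement
    travel_step_mean: float = 1_200.0                     # metres per hour while travelling
    travel_step_shape: float = 3.0
    target_range: float = 350.0                           # distance decay of hotspot choice, metres
    persistence: float = 0.6                              # heading memory while travelling
    heading_noise_sd: float = 0.35                        # radians
    dwell_mean_h: float = 20.0
    dwell_shape: float = 2.0
    dwell_ar: float = 0.7                                 # dwell-wander autocorrelation
    dwell_noise_sd: float = 35.0                          # metres, around the bout anchor
    # fields
    smoothing_length: float = 1_200.0                     # metres
    elevation_smoothing: float = 3_000.0
    pn_rho: float = 0.8                                   # phosphorus-nitrogen correlation
    wet_peak_doy: int = 15                                # mid-January greenness peak
    waterhole_intensity_km2: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.smoothing_length < self.cell:
            raise ValueError("smoothing length must be >= cell size")
        if 24.0 % self.fix_interval_h != 0:
            raise ValueError("fix interval must divide 24 h")
        if self.hotspot_scale <= 0 or self.cell <= 0:
            raise ValueError("scales must be positive")

    @property
    def n_individuals(self) -> int:
        return self.n_bulls + self.n_cows

    @property
    def start_s(self) -> float:
        return pd.Timestamp(self.start, tz="UTC").timestamp()


@dataclass
class StudyBundle:
    config: StudyConfig
    trajset: TrajectorySet
    static: dict          # name -> StaticLayer
    dynamic: dict         # name -> DynamicSeries
    water: WaterFeatures
    hotspots: pd.DataFrame   # x, y, eta, weight + covariate truth columns

    def ndvi_series(self) -> tuple[np.ndarray, np.ndarray]:
        """Domain-mean NDVI as a 1-D (times, values) season driver."""
        s = self.dynamic["ndvi"]
        vals = np.array([np.nanmean(l.grid) for l in s.layers])
        return s.times.copy(), vals

    def write(self, directory) -> None:
        """Write the bundle in the pipeline's text input formats."""
        os.makedirs(directory, exist_ok=True)
        write_trajectories(self.trajset, os.path.join(directory, "fixes.csv"))
        for name, layer in self.static.items():
            layer.write_ascii(os.path.join(directory, f"{name}.asc"))
        for name, series in self.dynamic.items():
            series.write(directory, prefix=name)
        self.water.to_geojson(os.path.join(directory, "water.geojson"))
        t, v = self.ndvi_series()
        pd.DataFrame({
            "timestamp": [pd.Timestamp(x, unit="s", tz="UTC").isoformat() for x in t],
            "value": v,
        }).to_csv(os.path.join(directory, "ndvi.csv"), index=False)
        truth = {
            "beta": {k: list(v) for k, v in self.config.beta.items()},
            "hotspots": self.hotspots.to_dict(orient="list"),
            "seed": self.config.seed,
        }
        with open(os.path.join(directory, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)


def _smooth_field(rng, shape, sigma_cells: float) -> np.ndarray:
    z = gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="reflect")
    z -= z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _season_cycle(times_s: np.ndarray, cfg: StudyConfig) -> np.ndarray:
    """Annual greenness cycle, +1 at the wet peak, -1 at the dry trough."""
    doy = (times_s / DAY) % YEAR_DAYS
    return np.cos(2 * np.pi * (doy - _peak_doy_epoch(cfg)) / YEAR_DAYS)


def _peak_doy_epoch(cfg: StudyConfig) -> float:
    # day-of-epoch-year of the configured calendar peak day
    ref = pd.Timestamp("2019-01-01", tz="UTC").timestamp() / DAY + (cfg.wet_peak_doy - 1)
    return ref % YEAR_DAYS


def _series_times(cfg: StudyConfig, cadence_days: float, pad_days: float = 40.0) -> np.ndarray:
    t0 = cfg.start_s - pad_days * DAY
    t1 = cfg.start_s + (cfg.duration_days + pad_days) * DAY
    return np.arange(t0, t1 + 1.0, cadence_days * DAY)


def gen_fields(cfg: StudyConfig, seed=None) -> tuple[dict, dict]:
    """Static covariate rasters and dynamic raster series.

    Phosphorus, elevation and the temperature/EVI/NDVI spatial baselines
    are Gaussian-smoothed white noise; nitrogen is built as
    ``rho * z(P) + sqrt(1 - rho^2) * independent`` so the planted P-N
    correlation is controllable.  Dynamic series add an annual sinusoid
    (wet-season peak) and observation noise at each layer's cadence.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed if seed is None else seed, 1]))
    ncol = int(round(cfg.domain[0] / cfg.cell))
    nrow = int(round(cfg.domain[1] / cfg.cell))
    sig = cfg.smoothing_length / cfg.cell
    x0, y0 = 0.0, cfg.domain[1]

    zP = _smooth_field(rng, (nrow, ncol), sig)
    zQ = _smooth_field(rng, (nrow, ncol), sig)
    rho = cfg.pn_rho
    zN = rho * zP + np.sqrt(1 - rho ** 2) * zQ
    zE = _smooth_field(rng, (nrow, ncol), cfg.elevation_smoothing / cfg.cell)
    zT = _smooth_field(rng, (nrow, ncol), sig)
    zV = _smooth_field(rng, (nrow, ncol), sig)

    static = {
        "phosphorus": StaticLayer("phosphorus", 8.0 + 3.0 * zP, x0, y0, cfg.cell, units="ppm"),
        "nitrogen": StaticLayer("nitrogen", 1.0 + 0.3 * zN, x0, y0, cfg.cell, units="g/kg"),
        "elevation": StaticLayer("elevation", 320.0 + 120.0 * zE, x0, y0, cfg.cell, units="m"),
    }

    def dyn(name, cadence, base, amp_season, amp_noise, spatial, units, clip=None, coarsen=1):
        times = _series_times(cfg, cadence)
        cyc = _season_cycle(times, cfg)
        layers = []
        for t, c in zip(times, cyc):
            g = base + spatial + amp_season * c + amp_noise * rng.standard_normal(spatial.shape)
            if clip is not None:
                g = np.clip(g, *clip)
            if coarsen > 1:
                g = g[::coarsen, ::coarsen].repeat(coarsen, 0).repeat(coarsen, 1)[:nrow, :ncol]
            layers.append(StaticLayer(name, g, x0, y0, cfg.cell, units=units))
        return DynamicSeries(name, times, layers, cadence_days=cadence)

    dynamic = {
        "evi": dyn("evi", 16, 0.30, 0.15, 0.02, 0.08 * zV, "", clip=(0.0, 1.0)),
        "temperature": dyn("temperature", 8, 302.0, -6.0, 1.0, 4.0 * zT, "K"),
        "ndvi": dyn("ndvi", 16, 0.40, 0.20, 0.01, 0.05 * zV, "", clip=(0.0, 1.0)),
    }
    # precipitation: seasonal sinusoid with multiplicative noise, 5-day cadence
    times = _series_times(cfg, 5)
    cyc = _season_cycle(times, cfg)
    layers = []
    for t, c in zip(times, cyc):
        mean = 15.0 * max(c + 1.0, 0.05)
        g = mean * np.exp(0.4 * rng.standard_normal((nrow, ncol)) - 0.08)
        layers.append(StaticLayer("precipitation", g, x0, y0, cfg.cell, units="mm/5d"))
    dynamic["precipitation"] = DynamicSeries("precipitation", times, layers, cadence_days=5)
    return static, dynamic


def gen_water(cfg: StudyConfig, seed=None) -> WaterFeatures:
    """One sinuous river crossing the domain plus Poisson-scattered waterholes."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed if seed is None else seed, 2]))
    W, H = cfg.domain
    xs = np.linspace(0.0, W, 60)
    wobble = np.cumsum(rng.normal(0, H / 60, len(xs)))
    wobble -= np.linspace(wobble[0], wobble[-1], len(xs))
    ys = H * 0.5 + H * 0.15 * np.sin(2 * np.pi * xs / W) + wobble
    ys = np.clip(ys, 0.02 * H, 0.98 * H)
    river = LineString(np.column_stack([xs, ys]))
    n_holes = rng.poisson(cfg.waterhole_intensity_km2 * (W * H / 1e6))
    holes = [Point(rng.uniform(0, W), rng.uniform(0, H)) for _ in range(max(n_holes, 1))]
    return WaterFeatures([river] + holes)


def gen_hotspots(static: dict, water: WaterFeatures, cfg: StudyConfig, seed=None) -> pd.DataFrame:
    """Sample hotspot cells with probability proportional to exp(eta).

    ``eta`` is the planted log-attractiveness: a linear + quadratic form in
    the standardised transformed covariates (phosphorus in ppm;
    square-root distance to water).  Each hotspot's visit weight is
    proportional to exp(eta).  Cells closer to water than
    ``hotspot_min_water_dist`` are not candidates, so planted sites survive
    the downstream water-buffer filter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed if seed is None else seed, 3]))
    p_layer = static["phosphorus"]
    xs, ys = p_layer.cell_centres()
    gx, gy = np.meshgrid(xs, ys)
    gx = gx.ravel()
    gy = gy.ravel()
    dw, dw_sqrt = distance_to_water(gx, gy, water)
    ok = dw >= cfg.hotspot_min_water_dist
    if int(ok.sum()) < cfg.n_hotspots:
        raise ValueError("n_hotspots exceeds candidate cells away from water")
    gx, gy, dw_sqrt = gx[ok], gy[ok], dw_sqrt[ok]

    def z(v):
        return (v - v.mean()) / v.std()

    covs = {
        "phosphorus": z(p_layer.grid.ravel()[ok]),
        "dist_water": z(dw_sqrt),
    }
    if "evi" in cfg.beta or "temperature" in cfg.beta or "slope" in cfg.beta:
        raise ValueError("planted effects are supported for phosphorus and dist_water")
    eta = np.zeros(len(gx))
    for name, (b1, b2) in cfg.beta.items():
        eta += b1 * covs[name] + b2 * covs[name] ** 2

    # Gumbel-ranked weighted sampling without replacement, thinned so no two
    # patches sit closer than the minimum spacing (patches must not overlap,
    # or small-radius counts double up)
    keys = eta + rng.gumbel(size=len(eta))
    order = np.argsort(keys)[::-1]
    pick = []
    min_sp2 = cfg.hotspot_min_spacing ** 2
    for idx in order:
        if len(pick) == cfg.n_hotspots:
            break
        if pick:
            arr = np.asarray(pick)
            if np.min((gx[arr] - gx[idx]) ** 2 + (gy[arr] - gy[idx]) ** 2) < min_sp2:
                continue
        pick.append(int(idx))
    if len(pick) < cfg.n_hotspots:
        raise ValueError("n_hotspots exceeds what the spacing rule allows; "
                         "reduce n_hotspots or hotspot_min_spacing")
    pick = np.asarray(pick)
    # unmeasured patch quality: independent log-scale jitter on attractiveness,
    # so nearby patches are not perfectly alike however smooth the fields are
    eta_k = eta[pick] + rng.normal(0.0, cfg.hotspot_quality_sd, cfg.n_hotspots)
    w = np.exp(eta_k)
    w /= w.sum()
    out = pd.DataFrame({
        "x": gx[pick], "y": gy[pick], "eta": eta_k, "weight": w,
        "eta_planted": eta[pick],
        "phosphorus_z": covs["phosphorus"][pick], "dist_water_z": covs["dist_water"][pick],
    })
    return out.reset_index(drop=True)


def gen_trajectory(hotspots: pd.DataFrame, cfg: StudyConfig, individual: str,
                   sex: str | None = None, seed=None) -> Trajectory:
    """Hourly trajectory of one hotspot-attracted forager.

    The individual alternates between travelling to a target hotspot
    (biased correlated random walk: heading is a persistence-weighted mix
    of the previous heading and the bearing to the target, with wrapped
    normal noise and gamma step lengths) and a foraging bout at it.  A
    hotspot is a patch of radius ``hotspot_scale``: each bout works one
    random sub-location of the patch (a uniform-in-disc anchor) with a
    tight AR(1) wander around that anchor, for a gamma-distributed dwell
    time — successive visits to the same patch therefore revisit the patch,
    not the exact spot.  The next target is chosen with probability
    proportional to hotspot weight times a distance-decay accessibility
    kernel, excluding the current hotspot.
    """
    if len(hotspots) < 2:
        raise ValueError("need at least 2 hotspots")
    rng = np.random.default_rng(seed)
    hx = hotspots["x"].to_numpy()
    hy = hotspots["y"].to_numpy()
    w = hotspots["weight"].to_numpy().copy()
    W, H = cfg.domain
    if np.any((hx < 0) | (hx > W) | (hy < 0) | (hy > H)):
        raise ValueError("hotspot outside domain")
    dt_h = cfg.fix_interval_h
    n_steps = int(round(cfg.duration_days * 24.0 / dt_h))
    t = cfg.start_s + np.arange(n_steps) * dt_h * 3600.0

    def bout_anchor(k):
        # uniform in the patch disc
        rad = cfg.hotspot_scale * np.sqrt(rng.random())
        th = rng.uniform(0, 2 * np.pi)
        return np.array([hx[k] + rad * np.cos(th), hy[k] + rad * np.sin(th)])

    cur = int(rng.choice(len(w), p=w / w.sum()))
    anchor = bout_anchor(cur)
    pos = anchor.copy()
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    mode = "dwell"
    dwell_left = rng.gamma(cfg.dwell_shape, cfg.dwell_mean_h / cfg.dwell_shape)
    heading = rng.uniform(0, 2 * np.pi)
    target = cur
    step_scale = cfg.travel_step_mean / cfg.travel_step_shape

    for i in range(n_steps):
        if mode == "dwell":
            pos = anchor + cfg.dwell_ar * (pos - anchor) + rng.normal(0, cfg.dwell_noise_sd, 2)
            pos = np.clip(pos, [0.0, 0.0], [W, H])
            dwell_left -= dt_h
            if dwell_left <= 0:
                # next target: weight times a distance-decay accessibility kernel
                d = np.hypot(hx - pos[0], hy - pos[1])
                probs = w * np.exp(-d / cfg.target_range)
                probs[cur] = 0.0
                probs /= probs.sum()
                target = int(rng.choice(len(w), p=probs))
                heading = np.arctan2(hy[target] - pos[1], hx[target] - pos[0])
                mode = "travel"
        else:
            bearing = np.arctan2(hy[target] - pos[1], hx[target] - pos[0])
            # circular persistence-weighted mean of previous heading and bearing
            vx = cfg.persistence * np.cos(heading) + (1 - cfg.persistence) * np.cos(bearing)
            vy = cfg.persistence * np.sin(heading) + (1 - cfg.persistence) * np.sin(bearing)
            heading = np.arctan2(vy, vx) + rng.normal(0, cfg.heading_noise_sd)
            step = rng.gamma(cfg.travel_step_shape, step_scale) * dt_h
            dist = np.hypot(hx[target] - pos[0], hy[target] - pos[1])
            if step >= dist:
                pos = np.array([hx[target], hy[target]])
            else:
                pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
            pos = np.clip(pos, [0.0, 0.0], [W, H])  # domain is closed; rasters cover edges
            if np.hypot(hx[target] - pos[0], hy[target] - pos[1]) <= cfg.hotspot_scale:
                cur = target
                anchor = bout_anchor(cur)
                mode = "dwell"
                dwell_left = rng.gamma(cfg.dwell_shape, cfg.dwell_mean_h / cfg.dwell_shape)
        xs[i] = pos[0]
        ys[i] = pos[1]

    return Trajectory(individual, t, xs, ys, sex=sex)


def gen_study(cfg: StudyConfig) -> StudyBundle:
    """Generate the full bundle: fields, water, hotspots, trajectories, truth."""
    static, dynamic = gen_fields(cfg)
    water = gen_water(cfg)
    hotspots = gen_hotspots(static, water, cfg)
    trajset = TrajectorySet(crs="synthetic-metres")
    for i in range(cfg.n_individuals):
        sex = "bull" if i < cfg.n_bulls else "cow"
        name = f"{sex}{i:02d}"
        rng_seed = np.random.SeedSequence([cfg.seed, 4, i])
        trajset.add(gen_trajectory(hotspots, cfg, name, sex=sex, seed=rng_seed))
    logger.info("study: %d individuals, %d hotspots, %.0f days",
                cfg.n_individuals, len(hotspots), cfg.duration_days)
    return StudyBundle(cfg, trajset, static, dynamic, water, hotspots)
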