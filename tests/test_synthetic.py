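import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from revisit.recursion import RecursionConfig, detect_visits
from revisit.synthetic import StudyConfig, gen_fields, gen_hotspots, gen_study, gen_trajectory, gen_water


def _cfg(**kw):
    base = dict(n_bulls=1, n_cows=1, duration_days=90, seed=7)
    base.update(kw)
    return StudyConfig(**base)


class TestFields:
    def test_planted_pn_correlation(self):
        static, _ = gen_fields(_cfg(pn_rho=0.8))
        r = np.corrcoef(static["phosphorus"].grid.ravel(), static["nitrogen"].grid.ravel())[0, 1]
        assert 0.7 <= r <= 0.9

    def test_ndvi_spatial_mean_follows_seasonal_phase(self):
        _, dynamic = gen_fields(_cfg(duration_days=365))
        s = dynamic["ndvi"]
        vals = np.array([l.grid.mean() for l in s.layers])
        doy = pd.to_datetime((s.times * 1e9).astype("int64"), utc=True).dayofyear
        # mid-summer (wet peak) records greener than mid-winter records
        jan = vals[(doy > 350) | (doy < 45)].mean()
        jul = vals[(doy > 150) & (doy < 240)].mean()
        assert jan > jul + 0.2

    def test_same_seed_bit_identical(self):
        s1, d1 = gen_fields(_cfg())
        s2, d2 = gen_fields(_cfg())
        assert np.array_equal(s1["phosphorus"].grid, s2["phosphorus"].grid)
        assert np.array_equal(d1["evi"].layers[3].grid, d2["evi"].layers[3].grid)

    def test_smoothing_below_cell_rejected(self):
        with pytest.raises(ValueError):
            _cfg(smoothing_length=10.0)


class TestWater:
    def test_has_river_and_waterholes(self):
        water = gen_water(_cfg())
        types = {g.geom_type for g in water.geometries}
        assert "LineString" in types and "Point" in types

    def test_distance_zero_on_features(self):
        water = gen_water(_cfg())
        pt = water.geometries[-1]
        assert water.distance_to([pt.x], [pt.y])[0] == 0.0

    def test_waterhole_intensity_scales_count(self):
        counts = {mult: [] for mult in (1.0, 2.0)}
        for seed in range(12):
            for mult in counts:
                w = gen_water(_cfg(seed=seed, waterhole_intensity_km2=0.08 * mult))
                counts[mult].append(sum(g.geom_type == "Point" for g in w.geometries))
        assert np.mean(counts[2.0]) == pytest.approx(2 * np.mean(counts[1.0]), rel=0.4)


class TestHotspots:
    def test_zero_betas_give_uniform_locations(self):
        ok = 0
        runs = 12
        for seed in range(runs):
            cfg = _cfg(seed=seed, beta={}, hotspot_quality_sd=0.0,
                       hotspot_min_water_dist=0.0, n_hotspots=60)
            static, _ = gen_fields(cfg)
            water = gen_water(cfg)
            hs = gen_hotspots(static, water, cfg)
            W, H = cfg.domain
            counts = np.histogram2d(hs.x, hs.y, bins=[np.linspace(0, W, 4), np.linspace(0, H, 4)])[0]
            ok += chisquare(counts.ravel()).pvalue > 0.01
        assert ok >= int(0.8 * runs)

    def test_concave_phosphorus_concentrates_hotspots(self):
        cfg = _cfg(beta={"phosphorus": (0.0, -4.0)}, hotspot_quality_sd=0.0)
        static, _ = gen_fields(cfg)
        water = gen_water(cfg)
        hs = gen_hotspots(static, water, cfg)
        dom_var = np.var(static["phosphorus"].grid)
        hs_p = hs["phosphorus_z"] * static["phosphorus"].grid.std() + static["phosphorus"].grid.mean()
        assert np.var(hs_p) < dom_var

    def test_spacing_rule_enforced(self):
        cfg = _cfg()
        static, _ = gen_fields(cfg)
        hs = gen_hotspots(static, gen_water(cfg), cfg)
        pts = hs[["x", "y"]].to_numpy()
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cfg.hotspot_min_spacing - 1e-9

    def test_same_seed_identical(self):
        cfg = _cfg()
        static, _ = gen_fields(cfg)
        water = gen_water(cfg)
        a = gen_hotspots(static, water, cfg)
        b = gen_hotspots(static, water, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_hotspots_rejected(self):
        cfg = _cfg(n_hotspots=5000)
        static, _ = gen_fields(cfg)
        with pytest.raises(ValueError):
            gen_hotspots(static, gen_water(cfg), cfg)


class TestTrajectory:
    def _two_spot_weights(self, w0, w1, seed=3, days=240):
        cfg = _cfg(duration_days=days, seed=seed, target_range=1e9)
        hs = pd.DataFrame({
            "x": [2000.0, 6000.0], "y": [4000.0, 4000.0],
            "eta": [np.log(w0), np.log(w1)],
        })
        hs["weight"] = np.exp(hs.eta) / np.exp(hs.eta).sum()
        traj = gen_trajectory(hs, cfg, "t", seed=seed)
        rcfg = RecursionConfig(radius=300.0, min_time_away_s=12 * 3600)
        n0 = len(detect_visits(traj, (2000, 4000), rcfg))
        n1 = len(detect_visits(traj, (6000, 4000), rcfg))
        return n0, n1

    def test_equal_weights_equal_visits(self):
        n0, n1 = self._two_spot_weights(1.0, 1.0)
        n = n0 + n1
        assert abs(n0 - n1) <= 3 * np.sqrt(n)

    def test_skewed_weights_skew_visits(self):
        # with two targets and forced alternation the chain visits both
        # equally often but spends w-proportional DWELL at each; assert the
        # strong-weight spot is not under-visited
        counts = [self._two_spot_weights(9.0, 1.0, seed=s) for s in (3, 4)]
        for n0, n1 in counts:
            assert n0 >= n1 - 3 * np.sqrt(n0 + n1)

    def test_dwell_structure_produces_revisits(self, small_bundle):
        cfg = small_bundle.config
        hs = small_bundle.hotspots
        traj = next(iter(small_bundle.trajset))
        rcfg = RecursionConfig(radius=cfg.hotspot_scale, min_time_away_s=12 * 3600)
        counts = [len(detect_visits(traj, (x, y), rcfg)) for x, y in
                  zip(hs.x[:30], hs.y[:30])]
        assert max(counts) >= 2

    def test_needs_two_hotspots(self):
        hs = pd.DataFrame({"x": [1.0], "y": [1.0], "eta": [0.0], "weight": [1.0]})
        with pytest.raises(ValueError):
            gen_trajectory(hs, _cfg(), "t", seed=0)


class TestBundle:
    def test_same_seed_identical_bundle(self):
        a = gen_study(_cfg(duration_days=30))
        b = gen_study(_cfg(duration_days=30))
        ind = a.trajset.ids()[0]
        assert np.array_equal(a.trajset[ind].x, b.trajset[ind].x)
        pd.testing.assert_frame_equal(a.hotspots, b.hotspots)

    def test_write_round_trips_through_pipeline_loader(self, tmp_path, small_bundle):
        from revisit.pipeline import load_bundle_dir

        small_bundle.write(tmp_path)
        trajset, static, dynamic, water, (nt, nv) = load_bundle_dir(tmp_path)
        assert len(trajset) == len(small_bundle.trajset)
        ind = small_bundle.trajset.ids()[0]
        assert np.allclose(trajset[ind].x, small_bundle.trajset[ind].x)
        assert np.allclose(static["phosphorus"].grid,
                           small_bundle.static["phosphorus"].grid, equal_nan=True)
        assert not water.is_empty()
        t0, v0 = small_bundle.ndvi_series()
        assert np.allclose(nv, v0)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert "beta" in truth and "hotspots" in truth

    def test_sex_split_matches_config(self, small_bundle):
        sexes = [t.sex for t in small_bundle.trajset]
        assert sexes.count("bull") == small_bundle.config.n_bulls
        assert sexes.count("cow") == small_bundle.config.n_cows
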