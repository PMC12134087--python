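import itertools

import numpy as np
import pandas as pd
import pytest

from revisit.lmm import fit_random_intercept
from revisit.rate_models import (
    add_interactions,
    backward_aic,
    bin_means,
    build_design,
    fit_lmm,
    nakagawa_r2,
    quad_regression,
    quadratic_term,
    revisitation_rate,
    scale_columns,
    stratified_resample,
)
from revisit.recursion import RevisitSite, Visit
from revisit.seasonality import SeasonTable, SeasonYear

DAY = 86400.0
YEAR = 365.0 * DAY


def _season_table(n_years=2, year0=0.0):
    """Years of length 365 d; wet season days 120-300 of each year."""
    years = []
    for k in range(n_years):
        s = year0 + k * YEAR
        years.append(SeasonYear(f"y{k}", s, s + YEAR, s + 120 * DAY, s + 300 * DAY))
    return SeasonTable(years)


def _site(entry_days, ind="a"):
    visits = [Visit(d * DAY, d * DAY + 3600) for d in entry_days]
    return RevisitSite("s", ind, 0.0, 0.0, visits)


class TestRevisitationRate:
    def test_six_dry_visits_over_two_dry_seasons(self):
        st = _season_table(2)
        # dry = days [0,120) and [300,365) of each year
        entries = [10, 30, 50, 70, 90, 110]
        rates = revisitation_rate(_site(entries), st, (0.0, 2 * YEAR))
        assert rates["dry"] == pytest.approx(3.0)
        assert "wet" not in rates

    def test_one_wet_visit_in_one_full_season(self):
        st = _season_table(1)
        rates = revisitation_rate(_site([200]), st, (0.0, YEAR))
        assert rates["wet"] == pytest.approx(1.0)

    def test_fractional_season_overlap_scales_denominator(self):
        st = _season_table(1)
        # span covers only the first half of the wet season (days 120-210)
        rates = revisitation_rate(_site([150]), st, (0.0, 210 * DAY))
        assert rates["wet"] == pytest.approx(2.0)  # 1 visit / 0.5 period

    def test_no_visits_in_a_season_yields_no_record(self):
        st = _season_table(1)
        rates = revisitation_rate(_site([150]), st, (0.0, YEAR))
        assert set(rates) == {"wet"}

    def test_rate_invariant_to_halving_stationary_data(self):
        st = _season_table(4)
        entries = [10 + 365 * k for k in range(4)]  # one dry visit per year
        full = revisitation_rate(_site(entries), st, (0.0, 4 * YEAR))
        half = revisitation_rate(_site(entries[:2]), st, (0.0, 2 * YEAR))
        assert full["dry"] == pytest.approx(half["dry"])


class TestBinnedRegression:
    def test_two_bin_means(self):
        bt = bin_means([0.1, 0.4, 0.6, 0.9], [1, 3, 5, 7], n_bins=2)
        assert bt.means.tolist() == [2.0, 6.0]

    def test_max_value_lands_in_last_bin(self):
        bt = bin_means([0.0, 1.0], [1.0, 2.0], n_bins=10)
        assert bt.counts.sum() == 2

    def test_empty_bins_omitted(self):
        bt = bin_means([0.0, 1.0], [1.0, 2.0], n_bins=1000)
        assert len(bt.centres) == 2

    def test_grand_mean_is_conserved(self, rng):
        x = rng.uniform(0, 1, 500)
        y = rng.normal(size=500)
        bt = bin_means(x, y, n_bins=40)
        assert np.average(bt.means, weights=bt.counts) == pytest.approx(y.mean())

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bin_means([1.0, 1.0], [1.0, 2.0])

    def test_noiseless_quadratic_recovered_exactly(self):
        from revisit.rate_models import BinnedTable

        x = np.linspace(-1, 1, 50)
        bt = BinnedTable("v", np.array([]), x, 2 * x - 3 * x ** 2, np.ones(50))
        qf = quad_regression(bt)
        assert qf.b_x == pytest.approx(2.0, abs=1e-9)
        assert qf.b_x2 == pytest.approx(-3.0, abs=1e-9)
        assert qf.r2 == pytest.approx(1.0)

    def test_pure_noise_has_low_r2(self, rng):
        x = rng.uniform(0, 1, 5000)
        y = rng.normal(size=5000)
        qf = quad_regression(bin_means(x, y, n_bins=500))
        assert qf.r2 < 0.1

    def test_concave_relation_gives_negative_quadratic(self, rng):
        hits = 0
        for _ in range(20):
            x = rng.uniform(-1, 1, 2000)
            y = 1 + x - 2 * x ** 2 + rng.normal(0, 0.8, 2000)
            qf = quad_regression(bin_means(x, y, n_bins=200))
            hits += qf.b_x2 < 0
        assert hits >= 19

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            quad_regression(bin_means([0.0, 1.0], [1.0, 2.0], n_bins=2))


class TestNakagawaR2:
    def test_closed_form_case(self):
        fit = fit_random_intercept  # namespace only; construct directly
        from revisit.lmm import RandomInterceptFit

        f = RandomInterceptFit({}, sigma_a2=1.0, sigma_e2=1.0, sigma_f2=2.0,
                               loglik=0.0, aic=4.0, n=10, n_groups=2, method="ML")
        rm, rc = nakagawa_r2(f)
        assert rm == pytest.approx(0.5)
        assert rc == pytest.approx(0.75)

    def test_no_random_variance_makes_them_equal(self):
        from revisit.lmm import RandomInterceptFit

        f = RandomInterceptFit({}, sigma_a2=0.0, sigma_e2=1.0, sigma_f2=3.0,
                               loglik=0.0, aic=4.0, n=10, n_groups=2, method="ML")
        rm, rc = nakagawa_r2(f)
        assert rm == rc

    def test_marginal_never_exceeds_conditional_on_fits(self, rng):
        for _ in range(10):
            n_g, n_per = 8, 30
            g = np.repeat(np.arange(n_g), n_per)
            X = np.column_stack([np.ones(n_g * n_per), rng.normal(size=n_g * n_per)])
            y = X @ [0.0, 1.0] + rng.normal(0, 1, n_g)[g] + rng.normal(size=n_g * n_per)
            rm, rc = nakagawa_r2(fit_random_intercept(X, y, g))
            assert rm <= rc + 1e-12

    def test_all_zero_variances_rejected(self):
        from revisit.lmm import RandomInterceptFit

        f = RandomInterceptFit({}, sigma_a2=0.0, sigma_e2=0.0, sigma_f2=0.0,
                               loglik=0.0, aic=4.0, n=10, n_groups=2, method="ML")
        with pytest.raises(ValueError):
            nakagawa_r2(f)


def _model_data(rng, n_groups=8, n_per=120, noise=1.0, interaction=0.0):
    n = n_groups * n_per
    g = np.repeat([f"e{i}" for i in range(n_groups)], n_per)
    df = pd.DataFrame({
        "individual_id": g,
        "x": rng.normal(size=n),
        "z": rng.normal(size=n),
    })
    u = dict(zip(np.unique(g), rng.normal(0, 0.5, n_groups)))
    z_main = 0.5 if interaction else 0.0  # interactions come with their main effect
    eta = 1.0 + 0.8 * df.x - 0.7 * df.x ** 2 + z_main * df.z + interaction * df.x * df.z
    df["log_rate"] = eta + np.array([u[k] for k in g]) + rng.normal(0, noise, n)
    return df


class TestBackwardSelection:
    def test_chosen_model_within_two_aic_of_exhaustive_best(self, rng):
        # 3 candidate terms -> compare against all 2^3 models
        for rep in range(8):
            df = _model_data(rng, n_groups=6, n_per=60)
            terms = ["x", quadratic_term("x"), "z"]
            sel = backward_aic(terms, df, n_rep=0)
            best = np.inf
            for k in range(4):
                for combo in itertools.combinations(terms, k):
                    if quadratic_term("x") in combo and "x" not in combo:
                        continue  # marginality, as in the search itself
                    fit = fit_lmm(list(combo), df)
                    best = min(best, fit.aic)
            chosen_aic = dict((tuple(sorted(t)), a) for t, a in sel.visited)[sel.chosen_terms]
            assert chosen_aic <= best + 2.0

    def test_planted_quadratic_recovered_noise_terms_dropped(self, rng):
        hits = 0
        for rep in range(20):
            df = _model_data(rng)
            terms = ["x", "z", quadratic_term("x"), quadratic_term("z")]
            sel = backward_aic(terms, df, n_rep=0)
            ok = ("x" in sel.chosen_terms and quadratic_term("x") in sel.chosen_terms
                  and "z" not in sel.chosen_terms and quadratic_term("z") not in sel.chosen_terms)
            hits += ok
        assert hits >= 18

    def test_marginality_quadratic_blocks_linear_removal(self, rng):
        df = _model_data(rng)
        sel = backward_aic(["x", quadratic_term("x")], df, n_rep=0)
        # every visited model containing x^2 must contain x
        for terms, _ in sel.visited:
            if quadratic_term("x") in terms:
                assert "x" in terms

    def test_deterministic_given_data(self, rng):
        df = _model_data(rng)
        t = ["x", "z", quadratic_term("x")]
        s1 = backward_aic(t, df, n_rep=0)
        s2 = backward_aic(t, df, n_rep=0)
        assert s1.chosen_terms == s2.chosen_terms
        assert s1.visited == s2.visited

    def test_r2_resampling_reports_mean_and_sd(self, rng):
        df = _model_data(rng)
        sel = backward_aic(["x", quadratic_term("x")], df, n_rep=10,
                           resample_kw={"per_stratum": 40}, seed=3)
        assert 0 <= sel.rm2_mean <= 1
        assert sel.rm2_mean <= sel.rc2_mean
        assert sel.rm2_sd >= 0


class TestScalingInvariance:
    def test_rescaled_covariate_changes_nothing(self, rng):
        df = _model_data(rng)
        df2 = df.copy()
        df2["x"] = df2["x"] * 1234.5  # raw rescale, then standardise
        terms = ["x", quadratic_term("x"), "z"]
        a = fit_lmm(terms, scale_columns(df, ["x", "z"]))
        b = fit_lmm(terms, scale_columns(df2, ["x", "z"]))
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)
        assert a.aic == pytest.approx(b.aic, abs=1e-6)
        assert np.allclose(a.beta, b.beta, atol=1e-6)
        assert nakagawa_r2(a) == pytest.approx(nakagawa_r2(b), abs=1e-6)


class TestStratifiedResample:
    def test_same_seed_same_subset(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=300)})
        a = stratified_resample(df, ["x"], seed=5)
        b = stratified_resample(df, ["x"], seed=5)
        assert a.index.tolist() == b.index.tolist()

    def test_uniform_data_keeps_uniform_coverage(self, rng):
        df = pd.DataFrame({"x": rng.uniform(0, 1, 1000)})
        out = stratified_resample(df, ["x"], n_strata=10, per_stratum=30, seed=1)
        counts = np.histogram(out["x"], bins=np.linspace(0, 1, 11))[0]
        assert counts.max() / counts.min() <= 1.5

    def test_peaked_data_flattened_across_strata(self, rng):
        df = pd.DataFrame({"x": np.clip(rng.normal(0.5, 0.12, 4000), 0, 1)})
        out = stratified_resample(df, ["x"], n_strata=10, seed=2)
        edges = np.linspace(df.x.min(), df.x.max(), 11)
        counts = np.histogram(out["x"], bins=edges)[0]
        counts = counts[counts > 0]
        assert counts.max() / counts.min() <= 1.5


class TestInteractions:
    def test_empty_allow_list_returns_base(self, rng):
        df = _model_data(rng)
        base = backward_aic(["x", quadratic_term("x")], df, n_rep=0)
        out = add_interactions(base, [], df, n_rep=0)
        assert out is base

    def test_interaction_without_main_effect_skipped(self, rng, caplog):
        df = _model_data(rng)
        base = backward_aic(["x", quadratic_term("x")], df, n_rep=0)
        out = add_interactions(base, [("x", "z")], df, n_rep=0)  # z not in base
        assert out is base

    def test_planted_interaction_retained(self, rng):
        hits = 0
        for rep in range(10):
            df = _model_data(rng, interaction=0.6)
            base = backward_aic(["x", "z", quadratic_term("x")], df, n_rep=0)
            if not ("x" in base.chosen_terms and "z" in base.chosen_terms):
                continue
            out = add_interactions(base, [("x", "z")], df, n_rep=0)
            hits += "x:z" in out.chosen_terms
        assert hits >= 8

    def test_absent_interaction_rarely_included(self, rng):
        included = 0
        total = 0
        for rep in range(10):
            df = _model_data(rng, interaction=0.0)
            base = backward_aic(["x", "z", quadratic_term("x")], df, n_rep=0)
            if not ("x" in base.chosen_terms and "z" in base.chosen_terms):
                continue
            out = add_interactions(base, [("x", "z")], df, n_rep=0)
            total += 1
            included += "x:z" in out.chosen_terms
        if total:
            assert included <= max(1, int(0.2 * total) + 1)


def test_build_design_terms(rng):
    df = pd.DataFrame({"a": rng.normal(size=5), "b": rng.normal(size=5)})
    X = build_design(df, ["a", "I(a^2)", "a:b"])
    assert np.allclose(X[:, 0], 1.0)
    assert np.allclose(X[:, 2], df.a ** 2)
    assert np.allclose(X[:, 3], df.a * df.b)
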