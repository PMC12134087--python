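"""Revisitation-rate response and environmental models.

The response is the *revisitation rate*: visits to a site per seasonal
period of a given type (wet or dry), which rescales raw counts for
individuals tracked over different periods.  Its distribution is
right-skewed, so models work on the log rate.

Two modelling stages mirror the analysis workflow:

* exploratory per-variable regressions — the site table is collapsed into
  equal-width bins over each covariate (mean log-rate per bin, default
  1000 bins) so the sparse extremes of the gradient are not swamped by the
  data-dense middle, and a quadratic OLS is fitted to the bin means;
* a linear mixed model of log rate on all (scaled) covariates with linear
  and quadratic terms and a per-individual random intercept, reduced by
  backward AIC selection under marginality constraints, with the most
  parsimonious model within 2 AIC of the best retained.  Marginal and
  conditional R² (fixed-effects-only vs fixed-plus-random variance
  fractions) are averaged over stratified resamples of the covariate
  gradients.

Quadratic model terms are written ``I(name^2)`` and interactions
``a:b``; both are built from the scaled (zero-mean, unit-variance)
covariates — scale first, then square or multiply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import RandomInterceptFit, fit_random_intercept
from .recursion import RevisitSite
from .seasonality import SeasonTable

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "SelectionResult",
    "BinnedTable",
    "QuadFit",
    "revisitation_rate",
    "bin_means",
    "quad_regression",
    "scale_columns",
    "build_design",
    "fit_lmm",
    "nakagawa_r2",
    "backward_aic",
    "stratified_resample",
    "add_interactions",
    "DEFAULT_INTERACTIONS",
]

ModelFit = RandomInterceptFit  # the fitted-model container used throughout

DEFAULT_INTERACTIONS = (
    ("evi", "slope"),
    ("dist_water", "slope"),
    ("evi", "phosphorus"),
    ("dist_water", "phosphorus"),
)


# ---------------------------------------------------------------- response

def _overlap(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def revisitation_rate(site: RevisitSite, st: SeasonTable, span) -> dict:
    """Visits per seasonal period for each season type at one site.

    For season type *s* the rate is the number of visits whose entry time
    falls in type-*s* intervals, divided by the number of type-*s* seasonal
    periods the individual's tracking span overlaps (fractional periods
    count fractionally).  Season types with zero visits or zero overlapped
    duration yield no entry.

    Returns a dict with keys among {"wet", "dry"} mapping to positive rates.
    """
    t0, t1 = float(span[0]), float(span[1])
    entries = site.entry_times
    out = {}
    for season, per_year in (("wet", _wet_by_year(st)), ("dry", _dry_by_year(st))):
        periods = 0.0
        n_visits = 0
        for parts in per_year:
            total = sum(b - a for a, b in parts)
            if total <= 0:
                continue
            got = sum(_overlap(t0, t1, a, b) for a, b in parts)
            periods += got / total
            for a, b in parts:
                n_visits += int(np.count_nonzero((entries >= a) & (entries <= b)))
        if periods > 0 and n_visits > 0:
            out[season] = n_visits / periods
        elif periods == 0 and n_visits:
            logger.debug("site %s: visits in %s seasons but zero overlap", site.site_id, season)
    return out


def _wet_by_year(st: SeasonTable):
    return [[(y.wet_start, y.wet_end)] for y in st.years]


def _dry_by_year(st: SeasonTable):
    out = []
    for y in st.years:
        parts = []
        if y.wet_start > y.start:
            parts.append((y.start, y.wet_start))
        if y.wet_end < y.end:
            parts.append((y.wet_end, y.end))
        out.append(parts)
    return out


# ------------------------------------------------------- binned regressions

@dataclass
class BinnedTable:
    variable: str
    edges: np.ndarray
    centres: np.ndarray       # non-empty bins only
    means: np.ndarray
    counts: np.ndarray


def bin_means(x, y, n_bins: int = 1000, variable: str = "") -> BinnedTable:
    """Mean of ``y`` in equal-width bins over the range of ``x``.

    The final bin is right-closed so ``max(x)`` belongs to it; empty bins
    are omitted from the output.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) == 0:
        raise ValueError("no finite (x, y) pairs")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("constant x: cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.minimum(((x - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    nonempty = counts > 0
    centres = 0.5 * (edges[:-1] + edges[1:])
    return BinnedTable(variable, edges, centres[nonempty],
                       sums[nonempty] / counts[nonempty], counts[nonempty])


@dataclass
class QuadFit:
    intercept: float
    b_x: float
    b_x2: float
    r2: float


def quad_regression(bt: BinnedTable) -> QuadFit:
    """OLS of the bin means on bin centre and its square."""
    if len(bt.centres) < 3:
        raise ValueError("need at least 3 non-empty bins")
    X = np.column_stack([np.ones_like(bt.centres), bt.centres, bt.centres ** 2])
    beta, *_ = np.linalg.lstsq(X, bt.means, rcond=None)
    resid = bt.means - X @ beta
    sst = float(np.sum((bt.means - bt.means.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return QuadFit(float(beta[0]), float(beta[1]), float(beta[2]), r2)


# --------------------------------------------------------- design building

def scale_columns(data: pd.DataFrame, columns) -> pd.DataFrame:
    """Zero-mean, unit-variance copies of the named columns (sample sd)."""
    out = data.copy()
    for c in columns:
        v = out[c].to_numpy(float)
        sd = np.std(v, ddof=1)
        if sd == 0:
            raise ValueError(f"column {c!r} is constant, cannot scale")
        out[c] = (v - v.mean()) / sd
    return out


def quadratic_term(name: str) -> str:
    return f"I({name}^2)"


def _term_columns(term: str) -> list[str]:
    if term.startswith("I(") and term.endswith("^2)"):
        return [term[2:-3]]
    if ":" in term:
        return term.split(":")
    return [term]


def build_design(data: pd.DataFrame, terms) -> np.ndarray:
    """Design matrix [1 | term columns] from already-scaled covariates."""
    cols = [np.ones(len(data))]
    for term in terms:
        if term.startswith("I(") and term.endswith("^2)"):
            cols.append(data[term[2:-3]].to_numpy(float) ** 2)
        elif ":" in term:
            a, b = term.split(":")
            cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
        else:
            cols.append(data[term].to_numpy(float))
    return np.column_stack(cols)


def fit_lmm(terms, data: pd.DataFrame, response: str = "log_rate",
            group: str = "individual_id", reml: bool = False) -> ModelFit:
    """Random-intercept mixed model of the response on the given terms.

    ``terms`` are fixed-effect term names (an intercept is always
    included); the grouping column supplies the random intercept.  ML is
    the default so AIC values are comparable across fixed structures.
    """
    terms = list(terms)
    X = build_design(data, terms)
    return fit_random_intercept(X, data[response].to_numpy(float),
                                data[group].to_numpy(), reml=reml,
                                column_names=["(Intercept)"] + terms)


def nakagawa_r2(fit) -> tuple[float, float]:
    """Marginal and conditional R² of a random-intercept fit.

    Rm² = s2_f / (s2_f + s2_a + s2_e) — fixed effects only;
    Rc² = (s2_f + s2_a) / (s2_f + s2_a + s2_e) — fixed plus random.
    """
    tot = fit.sigma_f2 + fit.sigma_a2 + fit.sigma_e2
    if tot <= 0:
        raise ValueError("all variance components are zero: R² undefined")
    return fit.sigma_f2 / tot, (fit.sigma_f2 + fit.sigma_a2) / tot


# ------------------------------------------------------------- selection

@dataclass
class SelectionResult:
    visited: list                 # (sorted term tuple, aic) for every fitted model
    best_aic: float
    chosen_terms: tuple
    chosen_fit: ModelFit          # REML refit of the chosen model
    delta_aic: float              # chosen model's AIC - best AIC (<= 2)
    rm2_mean: float = np.nan
    rm2_sd: float = np.nan
    rc2_mean: float = np.nan
    rc2_sd: float = np.nan

    def aic_table(self) -> pd.DataFrame:
        rows = [{"terms": " + ".join(t) or "(intercept)", "n_terms": len(t), "aic": a}
                for t, a in sorted(self.visited, key=lambda v: v[1])]
        return pd.DataFrame(rows)


def _removable(terms) -> list[str]:
    """Terms droppable without violating marginality.

    A quadratic blocks its linear term; an interaction blocks both its main
    effects; quadratics and interactions themselves are always droppable.
    """
    terms = list(terms)
    blocked = set()
    for t in terms:
        if ":" in t or t.startswith("I("):
            blocked.update(_term_columns(t))
    out = []
    for t in terms:
        if ":" in t or t.startswith("I("):
            out.append(t)
        elif t not in blocked:
            out.append(t)
    return out


def backward_aic(full_terms, data: pd.DataFrame, response: str = "log_rate",
                 group: str = "individual_id", n_rep: int = 100,
                 resample_kw: dict | None = None, seed=None) -> SelectionResult:
    """Backward AIC selection with the 2-ΔAIC parsimony rule.

    Starting from the full term set, the removable term whose removal
    yields the lowest AIC is dropped, and the elimination continues all the
    way down to the intercept-only model (descending past local minima, so
    a noise quadratic that happens to look informative cannot trap its main
    effect in the model).  Among *all* models fitted along the way whose
    AIC is within 2 of the best, the one with the fewest fixed-effect terms
    is chosen (ties break lexicographically).  The chosen model is refit by
    REML, and its marginal/conditional R² are averaged over ``n_rep``
    stratified resamples of the covariate gradients.
    """
    full_terms = list(full_terms)
    visited: dict[tuple, float] = {}
    failed: set[tuple] = set()

    def aic_of(terms) -> float | None:
        key = tuple(sorted(terms))
        if key in visited:
            return visited[key]
        if key in failed:
            return None
        try:
            fit = fit_lmm(terms, data, response=response, group=group, reml=False)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("fit failed for %s: %s", key, exc)
            failed.add(key)
            return None
        if not fit.converged:
            logger.warning("non-convergent fit for %s excluded from selection", key)
            failed.add(key)
            return None
        visited[key] = fit.aic
        return fit.aic

    current = list(full_terms)
    if aic_of(current) is None:
        raise ValueError("full model failed to fit")
    while current:
        candidates = []
        for t in _removable(current):
            trial = [u for u in current if u != t]
            a = aic_of(trial)
            if a is not None:
                candidates.append((a, trial))
        if not candidates:
            break
        _, current = min(candidates, key=lambda c: (c[0], tuple(sorted(c[1]))))

    best_aic = min(visited.values())
    eligible = [(k, a) for k, a in visited.items() if a - best_aic <= 2.0]
    chosen_terms, chosen_aic = min(eligible, key=lambda e: (len(e[0]), e[0]))
    chosen_fit = fit_lmm(chosen_terms, data, response=response, group=group, reml=True)

    rm, rc = _resampled_r2(chosen_terms, data, response, group, n_rep,
                           resample_kw or {}, seed)
    return SelectionResult(
        visited=sorted(visited.items(), key=lambda v: v[1]),
        best_aic=best_aic, chosen_terms=chosen_terms, chosen_fit=chosen_fit,
        delta_aic=chosen_aic - best_aic,
        rm2_mean=float(np.mean(rm)) if len(rm) else np.nan,
        rm2_sd=float(np.std(rm, ddof=1)) if len(rm) > 1 else np.nan,
        rc2_mean=float(np.mean(rc)) if len(rc) else np.nan,
        rc2_sd=float(np.std(rc, ddof=1)) if len(rc) > 1 else np.nan,
    )


def _resampled_r2(terms, data, response, group, n_rep, resample_kw, seed):
    if n_rep < 1:
        return np.empty(0), np.empty(0)
    resample_kw = dict(resample_kw)
    focal = resample_kw.pop("focal", None)
    if focal is None:
        focal = sorted({c for t in terms for c in _term_columns(t)}) or None
    rng = np.random.default_rng(seed)
    rm, rc = [], []
    for _ in range(n_rep):
        if focal is None:
            sub = data
        else:
            sub = stratified_resample(data, focal, seed=rng.integers(2 ** 31), **resample_kw)
        try:
            fit = fit_lmm(terms, sub, response=response, group=group, reml=True)
        except (np.linalg.LinAlgError, ValueError):
            continue
        a, b = nakagawa_r2(fit)
        rm.append(a)
        rc.append(b)
    return np.asarray(rm), np.asarray(rc)


def stratified_resample(data: pd.DataFrame, focal, n_strata: int = 10,
                        per_stratum: int | None = None, seed=None) -> pd.DataFrame:
    """Resample rows so every stratum of each focal gradient contributes equally.

    Each focal variable's range is cut into ``n_strata`` equal-width
    strata; ``per_stratum`` rows are drawn from every non-empty stratum
    (without replacement where the stratum is large enough, with
    replacement otherwise).  The union over focal variables is
    deduplicated.  ``per_stratum`` defaults to the smallest non-empty
    stratum count over all focal variables, which makes all draws
    replacement-free and the stratum contributions exactly equal.
    """
    if len(data) == 0:
        raise ValueError("empty data")
    rng = np.random.default_rng(seed)
    focal = list(focal)
    strata_idx = {}
    min_count = len(data)
    for var in focal:
        x = data[var].to_numpy(float)
        lo, hi = x.min(), x.max()
        if hi <= lo:
            continue
        bins = np.minimum(((x - lo) / (hi - lo) * n_strata).astype(int), n_strata - 1)
        groups = [np.flatnonzero(bins == k) for k in range(n_strata)]
        groups = [g for g in groups if len(g)]
        strata_idx[var] = groups
        min_count = min(min_count, min(len(g) for g in groups))
    if per_stratum is None:
        per_stratum = max(1, min_count)
    chosen: list[np.ndarray] = []
    for var in focal:
        for g in strata_idx.get(var, []):
            replace = len(g) < per_stratum
            chosen.append(rng.choice(g, size=per_stratum, replace=replace))
    if not chosen:
        return data
    idx = np.unique(np.concatenate(chosen))
    return data.iloc[idx]


def add_interactions(base: SelectionResult, allow_list, data: pd.DataFrame,
                     response: str = "log_rate", group: str = "individual_id",
                     n_rep: int = 100, resample_kw: dict | None = None,
                     seed=None) -> SelectionResult:
    """Augment a selected model with allow-listed interactions and reselect.

    Interactions whose main effects are not both in the base model are
    skipped with a warning (marginality); with nothing to add the base
    selection is returned unchanged.
    """
    base_terms = list(base.chosen_terms)
    added = []
    for a, b in allow_list:
        if a in base_terms and b in base_terms:
            added.append(f"{a}:{b}")
        else:
            logger.warning("interaction %s:%s skipped: main effect missing from base model", a, b)
    if not added:
        return base
    return backward_aic(base_terms + added, data, response=response, group=group,
                        n_rep=n_rep, resample_kw=resample_kw, seed=seed)
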