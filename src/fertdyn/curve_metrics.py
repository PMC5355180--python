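"""Dose-response curve analysis of fertilization trials.

Total fertilization (TF) and abnormal fertilization (AbnF) are modelled on
the logit scale as cubic polynomials of log10 sperm concentration, with
fixed effects for every site x pH-treatment cell, random intercepts by pair
and by treatment-within-pair, and an observation-level Gaussian logit term
absorbing overdispersion.  From a pair of fitted TF/AbnF curves the module
derives the expected normal-fertilization function NF = TF * (1 - AbnF)
and numerically solves three sperm-requirement metrics:

* ``S_NF50``  -- sperm/ul to reach 50% normal fertilization (ascending limb),
* ``S_OptNF`` -- sperm/ul at the normal-fertilization peak,
* ``S_AbnF25``-- sperm/ul at which abnormal fertilization reaches 25%.

Uncertainty and within-site treatment contrasts come from a fully
parametric bootstrap: fixed-effect vectors are redrawn from the fitted
multivariate-normal (estimate, covariance), the metrics are recomputed per
draw, and contrast p-values are two-tailed bootstrap tail proportions with
Bonferroni grouping at alpha = 0.05/3.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit
from scipy.stats import chi2

from ._glmm import GLMMError, drop_collinear, fit_binomial_glmm
from .trial_model import ANALYSIS_WINDOWS, TrialRecord, filter_analysis_window, score_vial

BONFERRONI_ALPHA = 0.05 / 3  # three within-site treatment comparisons

METRICS = ("S_NF50", "S_OptNF", "S_AbnF25")


class CurveError(RuntimeError):
    pass


@dataclass(frozen=True)
class GLMMSpec:
    """Model specification for one response (TF or AbnF)."""

    response: str = "TF"
    degree: int = 3
    coding: str = "cells"  # "cells" (site x treatment cell-means) or "factorial"
    random_pair: bool = True
    random_pair_treatment: bool = True
    olre: bool = True
    window: tuple | None = None  # defaults to the response's analysis window

    def __post_init__(self) -> None:
        if self.response not in ("TF", "AbnF"):
            raise ValueError("response must be 'TF' or 'AbnF'")
        if self.coding not in ("cells", "factorial"):
            raise ValueError("coding must be 'cells' or 'factorial'")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


@dataclass
class FittedCurve:
    """A fitted logit-scale polynomial fertilization function."""

    response: str
    coding: str
    degree: int
    coef: np.ndarray
    coef_names: list
    cov: np.ndarray
    varcomps: dict
    loglik: float
    n_obs: int
    cells: list
    x_range: dict  # cell -> (xmin, xmax) of fitted log10 concentrations
    terms: dict = field(default_factory=dict)  # factorial: term -> column indices
    converged: bool = True
    message: str = ""

    def cell_coefs(self, site: str, treatment: str, coef: np.ndarray | None = None) -> np.ndarray:
        if self.coding != "cells":
            raise CurveError("cell_coefs requires cell-means coding")
        coef = self.coef if coef is None else coef
        prefix = f"{site}|{treatment}|"
        idx = [i for i, nm in enumerate(self.coef_names) if nm.startswith(prefix)]
        if not idx:
            raise CurveError(f"cell ({site}, {treatment}) not present in fit")
        return coef[idx]

    def logit_curve(self, site: str, treatment: str, x, coef: np.ndarray | None = None):
        c = self.cell_coefs(site, treatment, coef)
        return np.polyval(c[::-1], np.asarray(x, float))


@dataclass(frozen=True)
class MetricEstimate:
    metric: str
    site: str
    treatment: str
    sperm_conc: float  # sperm/ul; NaN when unattainable
    attainable: bool
    peak_nf: float = math.nan  # NF level at S_OptNF
    ci_low: float = math.nan
    ci_high: float = math.nan
    ci_unstable: bool = False


@dataclass(frozen=True)
class ContrastResult:
    site: str
    metric: str
    treatment_a: str
    treatment_b: str
    p_value: float
    significant: bool
    n_effective: int


@dataclass(frozen=True)
class LRTResult:
    term: str
    chisq: float
    df: int
    p_value: float
    full_terms: tuple
    null_terms: tuple


@dataclass(frozen=True)
class VariancePartition:
    fixed_total: float
    fixed_shares: dict
    random_shares: dict
    olre_share: float
    distribution_share: float
    marginal_r2: float
    conditional_r2: float


# ---------------------------------------------------------------------------
# data preparation and design matrices


def _response_frame(records: Sequence[TrialRecord], response: str,
                    window: tuple | None) -> pd.DataFrame:
    windows = dict(ANALYSIS_WINDOWS)
    if window is not None:
        windows[response] = window
    kept = filter_analysis_window(records, response, windows)
    rows = []
    for r in kept:
        if response == "TF":
            y, n = r.counts.n_fertilized, r.counts.n_scored
        else:
            if r.counts.n_fertilized == 0:
                continue  # AbnF undefined; excluded from the fit
            y, n = r.counts.n_tight + r.counts.n_abn_dev, r.counts.n_fertilized
        rows.append({
            "site": r.site, "treatment": r.ph_treatment,
            "pair": (r.site, r.pair_id), "x": math.log10(r.sperm_conc),
            "y": y, "n": n,
        })
    if not rows:
        raise CurveError(f"no records remain for {response} after window filtering")
    return pd.DataFrame(rows)


def _cells_design(df: pd.DataFrame, degree: int):
    cells = sorted(set(zip(df.site, df.treatment)))
    names, cols = [], []
    for site, trt in cells:
        mask = ((df.site == site) & (df.treatment == trt)).to_numpy(float)
        for k in range(degree + 1):
            cols.append(mask * df.x.to_numpy() ** k)
            names.append(f"{site}|{trt}|x{k}")
    return np.column_stack(cols), names, cells


def _dummies(series: pd.Series, prefix: str):
    levels = sorted(series.unique())
    cols, names = [], []
    for lev in levels[1:]:  # drop-first coding
        cols.append((series == lev).to_numpy(float))
        names.append(f"{prefix}[{lev}]")
    return cols, names


def _factorial_design(df: pd.DataFrame, terms: Sequence[str], degree: int):
    """Model matrix for the requested terms (always includes an intercept).

    Interaction columns are products of the main-effect columns; linearly
    dependent columns (the incomplete site x treatment factorial) are
    dropped by pivoted QR, so LRT degrees of freedom are rank differences.
    """
    x = df.x.to_numpy()
    sperm_cols = [x**k for k in range(1, degree + 1)]
    sperm_names = [f"x{k}" for k in range(1, degree + 1)]
    site_cols, site_names = _dummies(df.site, "site")
    ph_cols, ph_names = _dummies(df.treatment, "ph")

    def block(term):
        if term == "sperm":
            return sperm_cols, sperm_names
        if term == "site":
            return site_cols, site_names
        if term == "ph":
            return ph_cols, ph_names
        if ":" not in term:
            raise CurveError(f"unknown model term {term!r}")
        parts = term.split(":")
        base_cols, base_names = block(parts[0])
        rest_cols, rest_names = block(":".join(parts[1:]))
        cols, names = [], []
        for c1, n1 in zip(base_cols, base_names):
            for c2, n2 in zip(rest_cols, rest_names):
                cols.append(c1 * c2)
                names.append(f"{n1}:{n2}")
        return cols, names

    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    col_terms = ["(Intercept)"]
    for term in terms:
        bc, bn = block(term)
        cols.extend(bc)
        names.extend(bn)
        col_terms.extend([term] * len(bn))
    X = np.column_stack(cols)
    X2, names2, kept = drop_collinear(X, names)
    term_map: dict = {}
    for j, i in enumerate(kept):
        term_map.setdefault(col_terms[i], []).append(j)
    return X2, names2, term_map


def _groups_for(df: pd.DataFrame, spec: GLMMSpec) -> dict:
    groups = {}
    if spec.random_pair:
        levels = {p: i for i, p in enumerate(sorted(set(df.pair)))}
        groups["pair"] = np.array([levels[p] for p in df.pair])
    if spec.random_pair_treatment:
        keys = list(zip(df.pair, df.treatment))
        levels = {p: i for i, p in enumerate(sorted(set(keys)))}
        groups["pair_treatment"] = np.array([levels[p] for p in keys])
    if spec.olre:
        groups["olre"] = np.arange(len(df))
    return groups


# ---------------------------------------------------------------------------
# fitting


class FertilizationGLMM:
    """Fit-style estimator for the logit-cubic fertilization dose-response.

    Parameters mirror :class:`GLMMSpec`; after :meth:`fit` the fitted curve
    is available as ``curve_`` and the raw engine result as ``result_``.
    """

    def __init__(self, response: str = "TF", degree: int = 3,
                 coding: str = "cells", random_pair: bool = True,
                 random_pair_treatment: bool = True, olre: bool = True,
                 window: tuple | None = None,
                 factorial_terms: Sequence[str] | None = None):
        self.response = response
        self.degree = degree
        self.coding = coding
        self.random_pair = random_pair
        self.random_pair_treatment = random_pair_treatment
        self.olre = olre
        self.window = window
        self.factorial_terms = factorial_terms

    def get_params(self, deep: bool = True) -> dict:
        return {
            "response": self.response, "degree": self.degree,
            "coding": self.coding, "random_pair": self.random_pair,
            "random_pair_treatment": self.random_pair_treatment,
            "olre": self.olre, "window": self.window,
            "factorial_terms": self.factorial_terms,
        }

    def set_params(self, **params) -> "FertilizationGLMM":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _spec(self) -> GLMMSpec:
        return GLMMSpec(
            response=self.response, degree=self.degree, coding=self.coding,
            random_pair=self.random_pair,
            random_pair_treatment=self.random_pair_treatment,
            olre=self.olre, window=self.window,
        )

    def fit(self, records: Sequence[TrialRecord], seed: int | None = None
            ) -> "FertilizationGLMM":
        spec = self._spec()
        df = _response_frame(records, spec.response, spec.window)
        if spec.coding == "cells":
            X, names, cells = _cells_design(df, spec.degree)
            terms = {}
        else:
            terms_list = self.factorial_terms or [
                "sperm", "site", "ph", "site:sperm", "ph:sperm",
                "site:ph", "site:ph:sperm",
            ]
            X, names, terms = _factorial_design(df, terms_list, spec.degree)
            cells = sorted(set(zip(df.site, df.treatment)))
        groups = _groups_for(df, spec)
        result = fit_binomial_glmm(X, df.y.to_numpy(), df.n.to_numpy(),
                                   groups, coef_names=names)
        x_range = {
            cell: (float(sub.x.min()), float(sub.x.max()))
            for cell, sub in df.groupby(["site", "treatment"])
        }
        self.result_ = result
        self.frame_ = df
        self.curve_ = FittedCurve(
            response=spec.response, coding=spec.coding, degree=spec.degree,
            coef=result.coef, coef_names=result.coef_names, cov=result.cov,
            varcomps=result.varcomps, loglik=result.loglik, n_obs=result.n_obs,
            cells=cells, x_range=x_range, terms=terms,
            converged=result.converged, message=result.message,
        )
        return self


def fit_glmm(records: Sequence[TrialRecord], spec: GLMMSpec | None = None,
             seed: int | None = None) -> FittedCurve:
    """Fit the logit-polynomial mixed model; returns the fitted curve."""
    spec = spec or GLMMSpec()
    est = FertilizationGLMM(**{
        "response": spec.response, "degree": spec.degree, "coding": spec.coding,
        "random_pair": spec.random_pair,
        "random_pair_treatment": spec.random_pair_treatment,
        "olre": spec.olre, "window": spec.window,
    })
    est.fit(records, seed=seed)
    return est.curve_


# ---------------------------------------------------------------------------
# likelihood-ratio testing scheme


_MAIN_TERMS = ("sperm", "site", "ph")
_TWOWAY = ("site:sperm", "ph:sperm", "site:ph")
_THREEWAY = "site:ph:sperm"


def _fit_terms(records, response, terms, degree, window, re_kwargs):
    est = FertilizationGLMM(response=response, degree=degree,
                            coding="factorial", window=window,
                            factorial_terms=list(terms), **re_kwargs)
    est.fit(records)
    return est.curve_


def lrt_table(records: Sequence[TrialRecord], response: str,
              degree: int = 3, window: tuple | None = None,
              random_pair: bool = True, random_pair_treatment: bool = True,
              olre: bool = True) -> list:
    """Likelihood-ratio tests for each model term.

    Main effects are tested in a model without any interaction containing
    the focal effect; two-way interactions without the three-way; the
    three-way against the full model.  Degrees of freedom are rank
    differences of the (incomplete-factorial) design matrices.
    """
    results = []
    cache: dict = {}
    re_kwargs = {"random_pair": random_pair,
                 "random_pair_treatment": random_pair_treatment, "olre": olre}

    def fit(terms):
        key = tuple(terms)
        if key not in cache:
            cache[key] = _fit_terms(records, response, terms, degree, window,
                                    re_kwargs)
        return cache[key]

    def contains(interaction, main):
        return main in interaction.split(":")

    for term in _MAIN_TERMS:
        ref_terms = [t for t in _MAIN_TERMS] + [
            t for t in _TWOWAY if not contains(t, term)
        ]
        null_terms = [t for t in ref_terms if t != term]
        results.append(_lrt_pair(fit, term, ref_terms, null_terms))
    for term in _TWOWAY:
        ref_terms = list(_MAIN_TERMS) + list(_TWOWAY)
        null_terms = [t for t in ref_terms if t != term]
        results.append(_lrt_pair(fit, term, ref_terms, null_terms))
    ref_terms = list(_MAIN_TERMS) + list(_TWOWAY) + [_THREEWAY]
    null_terms = list(_MAIN_TERMS) + list(_TWOWAY)
    results.append(_lrt_pair(fit, _THREEWAY, ref_terms, null_terms))
    return results


def _lrt_pair(fit, term, ref_terms, null_terms) -> LRTResult:
    full = fit(ref_terms)
    null = fit(null_terms)
    df = len(full.coef) - len(null.coef)
    if df < 1:
        raise CurveError(
            f"term {term} contributes no estimable degrees of freedom"
        )
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return LRTResult(
        term=term, chisq=stat, df=df, p_value=float(chi2.sf(stat, df)),
        full_terms=tuple(ref_terms), null_terms=tuple(null_terms),
    )


# ---------------------------------------------------------------------------
# metric solving


def _nf_on_grid(curve_tf: FittedCurve, curve_ab: FittedCurve | None,
                site, treatment, x):
    tf = expit(curve_tf.logit_curve(site, treatment, x))
    if curve_ab is None:
        return tf, np.zeros_like(tf)
    ab = expit(curve_ab.logit_curve(site, treatment, x))
    return tf * (1.0 - ab), ab


def _first_ascending_crossing(x, f, level, refine):
    """Smallest x where f crosses `level` from below; NaN if none."""
    above = f >= level
    for i in range(1, len(x)):
        if not above[i - 1] and above[i]:
            return refine(x[i - 1], x[i])
    return math.nan


def solve_metrics(curve_tf: FittedCurve, curve_ab: FittedCurve | None,
                  site: str, treatment: str,
                  tf_coef: np.ndarray | None = None,
                  ab_coef: np.ndarray | None = None,
                  n_grid: int = 2001) -> dict:
    """Numerically solve the sperm-requirement metrics for one cell.

    NF metrics (S_NF50, S_OptNF) are searched over the TF curve's fitted
    concentration range; S_AbnF25 over the AbnF curve's range.  Ascending-
    limb roots are the smallest crossing within the range (cubic curves can
    produce spurious distal roots).  Metrics the curve never attains are
    flagged, not extrapolated.
    """
    out = {}
    lo, hi = curve_tf.x_range[(site, treatment)]
    x = np.linspace(lo, hi, n_grid)
    nf, _ = _nf_on_grid(curve_tf, curve_ab, site, treatment, x)
    if tf_coef is not None or ab_coef is not None:
        tfv = expit(curve_tf.logit_curve(site, treatment, x, tf_coef))
        abv = (expit(curve_ab.logit_curve(site, treatment, x, ab_coef))
               if curve_ab is not None else 0.0)
        nf = tfv * (1.0 - abv)

    def nf_at(xq):
        tfv = expit(curve_tf.logit_curve(site, treatment, xq, tf_coef))
        abv = (expit(curve_ab.logit_curve(site, treatment, xq, ab_coef))
               if curve_ab is not None else 0.0)
        return tfv * (1.0 - abv)

    x50 = _first_ascending_crossing(
        x, nf, 0.5, lambda a, b: brentq(lambda q: nf_at(q) - 0.5, a, b, xtol=1e-6)
    )
    out["S_NF50"] = MetricEstimate(
        "S_NF50", site, treatment,
        10.0**x50 if not math.isnan(x50) else math.nan, not math.isnan(x50),
    )

    i_max = int(np.argmax(nf))
    a = x[max(i_max - 1, 0)]
    b = x[min(i_max + 1, len(x) - 1)]
    if i_max in (0, len(x) - 1):
        x_opt, peak = x[i_max], nf[i_max]
    else:
        res = minimize_scalar(lambda q: -nf_at(q), bounds=(a, b), method="bounded",
                              options={"xatol": 1e-6})
        x_opt, peak = float(res.x), float(-res.fun)
    out["S_OptNF"] = MetricEstimate(
        "S_OptNF", site, treatment, 10.0**x_opt, True, peak_nf=peak,
    )

    if curve_ab is not None and (site, treatment) in curve_ab.x_range:
        alo, ahi = curve_ab.x_range[(site, treatment)]
        xa = np.linspace(alo, ahi, n_grid)
        ab = expit(curve_ab.logit_curve(site, treatment, xa, ab_coef))
        x25 = _first_ascending_crossing(
            xa, ab, 0.25,
            lambda a_, b_: brentq(
                lambda q: expit(curve_ab.logit_curve(site, treatment, q, ab_coef)) - 0.25,
                a_, b_, xtol=1e-6),
        )
        out["S_AbnF25"] = MetricEstimate(
            "S_AbnF25", site, treatment,
            10.0**x25 if not math.isnan(x25) else math.nan, not math.isnan(x25),
        )
    return out


# ---------------------------------------------------------------------------
# parametric bootstrap


def _draw_coefs(curve: FittedCurve, n_boot: int, rng) -> np.ndarray:
    """MVN draws from (coef, cov); eigenvalues clipped at zero for safety."""
    vals, vecs = np.linalg.eigh(curve.cov)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n_boot, len(curve.coef)))
    return curve.coef + z @ root.T


def _cell_metric_draws(curve_tf: FittedCurve, curve_ab: FittedCurve | None,
                       site, trt, tf_draws, ab_draws, n_grid=801):
    """Vectorized metric solving over bootstrap draws for one cell.

    Uses a dense grid with linear interpolation at the crossings; the grid
    resolution (range/800) is far below bootstrap Monte-Carlo error.
    Returns dict metric -> log10-concentration per draw (NaN: unattainable).
    """
    nb = tf_draws.shape[0]
    prefix = f"{site}|{trt}|"
    idx_tf = [i for i, nm in enumerate(curve_tf.coef_names) if nm.startswith(prefix)]
    lo, hi = curve_tf.x_range[(site, trt)]
    x = np.linspace(lo, hi, n_grid)
    V = x[:, None] ** np.arange(len(idx_tf))
    tf = expit(tf_draws[:, idx_tf] @ V.T)
    if curve_ab is not None:
        idx_ab = [i for i, nm in enumerate(curve_ab.coef_names) if nm.startswith(prefix)]
        ab_on_tfgrid = expit(ab_draws[:, idx_ab] @ V.T)
    else:
        ab_on_tfgrid = 0.0
    nf = tf * (1.0 - ab_on_tfgrid)

    def first_ascending(f, level, grid):
        cross = (f[:, :-1] < level) & (f[:, 1:] >= level)
        has = cross.any(axis=1)
        i = np.argmax(cross, axis=1)
        f0 = f[np.arange(nb), i]
        f1 = f[np.arange(nb), i + 1]
        frac = np.where(f1 > f0, (level - f0) / np.maximum(f1 - f0, 1e-300), 0.0)
        xc = grid[i] + frac * (grid[1] - grid[0])
        return np.where(has, xc, np.nan)

    out = {"S_NF50": first_ascending(nf, 0.5, x)}
    i_max = np.argmax(nf, axis=1)
    out["S_OptNF"] = x[i_max]
    out["peak_nf"] = nf[np.arange(nb), i_max]
    if curve_ab is not None and (site, trt) in curve_ab.x_range:
        alo, ahi = curve_ab.x_range[(site, trt)]
        xa = np.linspace(alo, ahi, n_grid)
        Va = xa[:, None] ** np.arange(len(idx_ab))
        ab = expit(ab_draws[:, idx_ab] @ Va.T)
        out["S_AbnF25"] = first_ascending(ab, 0.25, xa)
    return out


def _boot_p(diffs: np.ndarray) -> float:
    """Two-tailed bootstrap p with add-one correction.

    A degenerate (zero-variance) difference distribution carries no
    sampling evidence, so it returns 1 by convention.
    """
    nb = len(diffs)
    if nb == 0:
        return math.nan
    if np.ptp(diffs) == 0.0:
        return 1.0
    lo = (np.sum(diffs <= 0) + 1) / (nb + 1)
    hi = (np.sum(diffs >= 0) + 1) / (nb + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _letters(treatments: list, estimates: dict, sig_pairs: set) -> dict:
    """Compact letter display from pairwise significance."""
    order = sorted(treatments, key=lambda t: estimates.get(t, math.inf))
    groups = [set(order)]
    for a, b in sig_pairs:
        new_groups = []
        for g in groups:
            if a in g and b in g:
                g1, g2 = g - {a}, g - {b}
                for h in (g1, g2):
                    if h and not any(h <= other for other in new_groups + groups if other is not g):
                        new_groups.append(h)
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if not any(g <= other for other in groups):
                groups.append(g)
    groups.sort(key=lambda g: min(order.index(t) for t in g))
    labels = {}
    for letter, g in zip("abcdefgh", groups):
        for t in g:
            labels.setdefault(t, "")
            labels[t] += letter
    return labels


def bootstrap_contrasts(curve_tf: FittedCurve, curve_ab: FittedCurve | None,
                        n_boot: int = 1000, seed: int = 0,
                        alpha: float = BONFERRONI_ALPHA,
                        max_missing: float = 0.2):
    """Bootstrap CIs for all metrics and within-site treatment contrasts.

    Draws ``n_boot`` fixed-effect vectors from the fitted multivariate
    normal for TF and AbnF independently, recomputes every metric per draw,
    and reports 95% percentile CIs plus pairwise within-site contrast
    p-values (two-tailed bootstrap proportions on the log10-concentration
    difference) with Bonferroni grouping at ``alpha``.

    Returns (metrics DataFrame, contrasts DataFrame).
    """
    rng = np.random.default_rng(seed)
    tf_draws = _draw_coefs(curve_tf, n_boot, rng)
    ab_draws = _draw_coefs(curve_ab, n_boot, rng) if curve_ab is not None else None

    cells = curve_tf.cells
    point = {}
    boot: dict = {}
    for site, trt in cells:
        point[(site, trt)] = solve_metrics(curve_tf, curve_ab, site, trt)
        draws = _cell_metric_draws(curve_tf, curve_ab, site, trt,
                                   tf_draws, ab_draws)
        boot[(site, trt)] = {m: draws.get(m, np.full(n_boot, math.nan))
                             for m in METRICS}

    metric_rows = []
    for (site, trt), ests in point.items():
        for m, est in ests.items():
            draws = boot[(site, trt)][m]
            ok = draws[~np.isnan(draws)]
            missing = 1.0 - len(ok) / n_boot
            if len(ok):
                lo_v, hi_v = 10.0 ** np.quantile(ok, [0.025, 0.975])
            else:
                lo_v = hi_v = math.nan
            metric_rows.append({
                "site": site, "treatment": trt, "metric": m,
                "estimate": est.sperm_conc, "lo95": lo_v, "hi95": hi_v,
                "peak_nf": est.peak_nf, "attainable": est.attainable,
                "ci_unstable": bool(missing > max_missing),
            })
    metrics_df = pd.DataFrame(metric_rows)

    contrast_rows = []
    sites = sorted(set(s for s, _ in cells))
    for site in sites:
        trts = sorted(t for s, t in cells if s == site)
        for m in METRICS:
            sig_pairs = set()
            estimates = {}
            for trt in trts:
                est = point[(site, trt)].get(m)
                if est is not None and est.attainable:
                    estimates[trt] = math.log10(est.sperm_conc)
            for a, b in itertools.combinations(trts, 2):
                da = boot[(site, a)][m]
                db = boot[(site, b)][m]
                both = ~np.isnan(da) & ~np.isnan(db)
                p = _boot_p(da[both] - db[both])
                sig = bool(p < alpha) if not math.isnan(p) else False
                if sig:
                    sig_pairs.add((a, b))
                contrast_rows.append({
                    "site": site, "metric": m, "treatment_a": a,
                    "treatment_b": b, "p_value": p, "significant": sig,
                    "n_effective": int(both.sum()),
                })
            labels = _letters(trts, estimates, sig_pairs)
            for row in contrast_rows:
                if row["site"] == site and row["metric"] == m and "letters" not in row:
                    row["letters_a"] = labels.get(row["treatment_a"], "")
                    row["letters_b"] = labels.get(row["treatment_b"], "")
    contrasts_df = pd.DataFrame(contrast_rows)
    return metrics_df, contrasts_df


# ---------------------------------------------------------------------------
# variance partitioning


def variance_partition(curve: FittedCurve, records: Sequence[TrialRecord],
                       fixed_subsets: dict | None = None) -> VariancePartition:
    """Logit-scale variance-explained decomposition for a fitted curve.

    Marginal R2 uses the fixed-effect linear-predictor variance over the
    observed data against the total of fixed + random + overdispersion +
    distribution-specific (pi^2 / 3) variance; conditional R2 adds the
    grouping random effects (the observation-level term counts as
    residual).  ``fixed_subsets`` maps labels to term names (factorial
    coding) or coefficient-name predicates for partial fixed shares.
    """
    df = _response_frame(records, curve.response, None)
    if curve.coding == "cells":
        X, names, _ = _cells_design(df, curve.degree)
    else:
        terms = [t for t in curve.terms if t != "(Intercept)"]
        X, names, _ = _factorial_design(df, terms, curve.degree)
    if list(names) != list(curve.coef_names):
        # align by name where possible
        idx = {nm: i for i, nm in enumerate(names)}
        try:
            cols = [idx[nm] for nm in curve.coef_names]
        except KeyError as exc:
            raise CurveError(f"records do not match the fitted design: {exc}")
        X = X[:, cols]
    eta_f = X @ curve.coef
    var_f = float(np.var(eta_f))
    var_pair = curve.varcomps.get("pair", 0.0)
    var_pt = curve.varcomps.get("pair_treatment", 0.0)
    var_olre = curve.varcomps.get("olre", 0.0)
    var_dist = math.pi**2 / 3.0
    total = var_f + var_pair + var_pt + var_olre + var_dist

    shares = {}
    if fixed_subsets:
        for label, sel in fixed_subsets.items():
            if curve.coding == "factorial" and all(
                isinstance(s, str) and s in curve.terms for s in sel
            ):
                cols = [j for s in sel for j in curve.terms[s]]
            else:
                cols = [i for i, nm in enumerate(curve.coef_names)
                        if any(str(s) in nm for s in sel)]
                if not cols:
                    raise CurveError(f"subset {label!r} matches no coefficients")
            sub = np.zeros_like(curve.coef)
            sub[cols] = curve.coef[cols]
            shares[label] = float(np.var(X @ sub)) / total
    return VariancePartition(
        fixed_total=var_f,
        fixed_shares=shares,
        random_shares={"pair": var_pair / total, "pair_treatment": var_pt / total},
        olre_share=var_olre / total,
        distribution_share=var_dist / total,
        marginal_r2=var_f / total,
        conditional_r2=(var_f + var_pair + var_pt) / total,
    )
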