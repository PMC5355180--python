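"""Hierarchical Bayesian estimation of fertilization-kinetics parameters.

For every site x pH-treatment cell the model estimates population-level
sperm-egg interaction and polyspermy-block rates (on the log scale) and a
mean gamma, with pair-level heterogeneity:

    log beta_i = mu_beta[cell] + sigma_beta * z_i,   z_i ~ N(0, 1)
    log delta_i = mu_delta[cell] + sigma_delta * z_i
    gamma_i ~ TruncNormal(gamma_bar[cell], sigma_gamma) on (0.0001, 0.15)

Vial counts of normally fertilized eggs follow a beta-binomial with mean
``p = normal_fraction(beta_i, gamma_i, delta_i; S0)`` from the mechanistic
kinetics model and precision ``lambda``:

    y ~ BetaBinomial(n, lambda * p, lambda * (1 - p))

The posterior is sampled with an adaptive Metropolis-within-Gibbs scheme
(non-centered parameterisation for beta and delta; per-block step sizes
adapted during warmup only), with multiple chains and split-Rhat / ESS
diagnostics via ArviZ.  Because beta and gamma are only weakly separately
identified by 30-s trials, all reported estimates are marginal over the
(wide) gamma posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from .kinetics import DEFAULT_EGG_CONC, DEFAULT_SPERM_DECAY, GAMMA_BOUNDS, normal_fraction_grid
from .trial_model import TrialRecord

__all__ = [
    "HierModelConfig",
    "PosteriorSummary",
    "DeclineSummary",
    "HierarchicalKineticsModel",
    "fit_hierarchical",
    "decline_summary",
    "convergence_check",
]

_P_EPS = 1e-9


@dataclass(frozen=True)
class HierModelConfig:
    """Priors and sampler settings for the hierarchical kinetics model.

    Priors are vague on the scales implied by the trial design and are all
    overridable.  ``gamma_shared_per_pair`` draws one gamma per pair around
    a site-level mean instead of one per pair x treatment cell.
    ``fix_gamma`` pins gamma at the given value (no gamma sampling).
    """

    mu_beta_prior: tuple = (np.log(1e-4), 3.0)
    mu_delta_prior: tuple = (np.log(0.1), 3.0)
    gamma_bounds: tuple = GAMMA_BOUNDS
    sigma_beta_scale: float = 1.0
    sigma_delta_scale: float = 1.0
    sigma_gamma_scale: float = 0.05
    lam_scale: float = 500.0
    r: float = DEFAULT_SPERM_DECAY
    egg_conc: float = DEFAULT_EGG_CONC
    contact_time: float = 30.0
    gamma_shared_per_pair: bool = False
    fix_gamma: float | None = None
    chains: int = 2
    warmup: int = 800
    draws: int = 800
    target_accept: float = 0.35

    def __post_init__(self) -> None:
        if self.gamma_bounds[0] >= self.gamma_bounds[1]:
            raise ValueError("gamma bounds must be ordered")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.draws < 500:
            raise ValueError("at least 500 draws per chain are required")


@dataclass
class PosteriorSummary:
    """Posterior summaries for a hierarchical kinetics fit.

    ``population`` has one row per cell x parameter with posterior mean,
    median, 95% equal-tailed credible interval and convergence diagnostics;
    ``pairs`` holds pair-level posterior medians; ``draws`` maps parameter
    names to (chain, draw, ...) arrays for downstream contrasts.
    """

    population: pd.DataFrame
    pairs: pd.DataFrame
    lam: dict
    draws: dict
    cells: list
    converged: bool
    divergences: int = 0


@dataclass(frozen=True)
class DeclineSummary:
    """Percent decline of a population rate vs. a reference treatment."""

    site: str
    parameter: str
    treatment: str
    reference: str
    decline_pct: float
    ci_low: float
    ci_high: float
    prob_decline: float


def _truncnorm_logpdf(x, mu, sigma, lo, hi):
    z = (x - mu) / sigma
    norm_c = ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma)
    return -0.5 * z * z - np.log(sigma) - np.log(np.maximum(norm_c, 1e-300))


def _betabinom_loglik(y, n, p, lam, lchoose):
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    a = lam * p
    b = lam * (1.0 - p)
    return (
        lchoose
        + gammaln(y + a) + gammaln(n - y + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


class _ModelData:
    """Index structure mapping vials -> pair-cells -> cells (and gamma units)."""

    def __init__(self, records: Sequence[TrialRecord], config: HierModelConfig):
        if not records:
            raise ValueError("no records")
        rows = pd.DataFrame(
            {
                "site": [r.site for r in records],
                "treatment": [r.ph_treatment for r in records],
                "pair": [r.pair_id for r in records],
                "S0": [r.sperm_conc for r in records],
                "y": [r.counts.n_normal for r in records],
                "n": [r.counts.n_scored for r in records],
            }
        )
        self.cells = sorted(set(zip(rows.site, rows.treatment)))
        cell_index = {c: i for i, c in enumerate(self.cells)}
        paircells = sorted(set(zip(rows.site, rows.treatment, rows.pair)))
        pc_index = {pc: i for i, pc in enumerate(paircells)}
        self.paircells = paircells
        self.n_cells = len(self.cells)
        self.n_pc = len(paircells)

        counts_per_cell = pd.Series(
            [pc[:2] for pc in paircells]
        ).value_counts()
        if counts_per_cell.min() < 2:
            raise ValueError("need >= 2 pairs per site x treatment cell")

        self.vial_pc = np.array(
            [pc_index[(s, t, p)] for s, t, p in zip(rows.site, rows.treatment, rows.pair)]
        )
        self.pc_cell = np.array([cell_index[pc[:2]] for pc in paircells])
        self.vial_cell = self.pc_cell[self.vial_pc]

        if config.gamma_shared_per_pair:
            gunits = sorted(set((pc[0], pc[2]) for pc in paircells))  # (site, pair)
            gu_index = {g: i for i, g in enumerate(gunits)}
            self.pc_gamma = np.array([gu_index[(pc[0], pc[2])] for pc in paircells])
            gbar_units = sorted(set(g[0] for g in gunits))  # sites
            gb_index = {g: i for i, g in enumerate(gbar_units)}
            self.gamma_gbar = np.array([gb_index[g[0]] for g in gunits])
            self.gbar_labels = [(s, "*") for s in gbar_units]
            self.gbar_of_cell = np.array([gb_index[c[0]] for c in self.cells])
        else:
            self.pc_gamma = np.arange(self.n_pc)
            self.gamma_gbar = self.pc_cell.copy()
            self.gbar_labels = list(self.cells)
            self.gbar_of_cell = np.arange(self.n_cells)
        self.n_gamma = int(self.pc_gamma.max()) + 1
        self.n_gbar = int(self.gamma_gbar.max()) + 1

        self.S0 = rows.S0.to_numpy(float)
        self.y = rows.y.to_numpy(float)
        self.n = rows.n.to_numpy(float)
        self.lchoose = gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)


class _Sampler:
    """Adaptive Metropolis-within-Gibbs for the hierarchical model."""

    def __init__(self, data: _ModelData, config: HierModelConfig, rng):
        self.d = data
        self.c = config
        self.rng = rng
        d, c = data, config
        lo, hi = c.gamma_bounds
        # initial state near prior centres with jitter
        self.mu_beta = c.mu_beta_prior[0] + rng.normal(0, 0.5, d.n_cells)
        self.mu_delta = c.mu_delta_prior[0] + rng.normal(0, 0.5, d.n_cells)
        self.z_beta = rng.normal(0, 0.1, d.n_pc)
        self.z_delta = rng.normal(0, 0.1, d.n_pc)
        mid = 0.5 * (lo + hi)
        if c.fix_gamma is not None:
            self.gamma = np.full(d.n_gamma, float(c.fix_gamma))
        else:
            self.gamma = np.clip(mid + rng.normal(0, 0.01, d.n_gamma), lo + 1e-5, hi - 1e-5)
        self.gamma_bar = np.full(d.n_gbar, mid)
        self.log_sb = np.log(0.3)
        self.log_sd = np.log(0.3)
        self.log_sg = np.log(0.02)
        self.log_lam = np.log(100.0)
        # step sizes
        self.step_pc = np.full(d.n_pc, 0.3)
        self.step_mu_b = np.full(d.n_cells, 0.3)
        self.step_mu_d = np.full(d.n_cells, 0.3)
        self.step_gbar = np.full(d.n_gbar, 0.01)
        self.step_ridge_c = np.full(d.n_gbar, 0.3)
        self.step_ridge_p = np.full(d.n_pc, 0.3)
        self.step_scalar = {"sb": 0.2, "sd": 0.2, "sg": 0.3, "lam": 0.2,
                            "gscale": 0.5, "asis_beta": 0.3, "asis_delta": 0.3}
        self.step_asis_mu_b = np.full(d.n_cells, 0.2)
        self.step_asis_mu_d = np.full(d.n_cells, 0.2)
        self._refresh_all()

    # -- derived quantities ------------------------------------------------
    def _pc_params(self, mu_beta=None, mu_delta=None, z_beta=None, z_delta=None,
                   gamma=None, sb=None, sd=None):
        d = self.d
        mu_beta = self.mu_beta if mu_beta is None else mu_beta
        mu_delta = self.mu_delta if mu_delta is None else mu_delta
        z_beta = self.z_beta if z_beta is None else z_beta
        z_delta = self.z_delta if z_delta is None else z_delta
        gamma = self.gamma if gamma is None else gamma
        sb = np.exp(self.log_sb) if sb is None else sb
        sd = np.exp(self.log_sd) if sd is None else sd
        beta = np.exp(np.clip(mu_beta[d.pc_cell] + sb * z_beta, -60.0, 60.0))
        delta = np.exp(np.clip(mu_delta[d.pc_cell] + sd * z_delta, -60.0, 60.0))
        return beta, delta, gamma[d.pc_gamma]

    def _forward(self, beta_pc, delta_pc, gamma_pc):
        d = self.d
        return normal_fraction_grid(
            beta_pc[d.vial_pc], gamma_pc[d.vial_pc], delta_pc[d.vial_pc],
            d.S0, r=self.c.r, egg_conc=self.c.egg_conc, t=self.c.contact_time,
        )

    def _vial_ll(self, p, lam=None):
        lam = np.exp(self.log_lam) if lam is None else lam
        return _betabinom_loglik(self.d.y, self.d.n, p, lam, self.d.lchoose)

    def _refresh_all(self):
        beta, delta, gamma = self._pc_params()
        self.p = self._forward(beta, delta, gamma)
        self.ll = self._vial_ll(self.p)

    # -- update blocks -----------------------------------------------------
    def _accept_groups(self, group_of_vial, n_groups, ll_new, extra_old, extra_new):
        """Per-group MH acceptance; returns boolean mask over groups."""
        delta_ll = np.bincount(group_of_vial, ll_new - self.ll, minlength=n_groups)
        log_r = delta_ll + extra_new - extra_old
        u = np.log(self.rng.uniform(size=n_groups))
        return u < log_r

    def update_paircells(self, adapt, k):
        d, c = self.d, self.c
        lo, hi = c.gamma_bounds
        zb_new = self.z_beta + self.step_pc * self.rng.normal(size=d.n_pc)
        zd_new = self.z_delta + self.step_pc * self.rng.normal(size=d.n_pc)
        if c.fix_gamma is None and not c.gamma_shared_per_pair:
            # out-of-bounds gamma proposals fall back to the current value
            # (symmetric kernel with an atom at the current point; valid MH)
            g_new = self.gamma + self.step_pc * 0.02 * self.rng.normal(size=d.n_gamma)
            g_new = np.where((g_new > lo) & (g_new < hi), g_new, self.gamma)
        else:
            g_new = self.gamma
        beta, delta, gamma = self._pc_params(z_beta=zb_new, z_delta=zd_new, gamma=g_new)
        p_new = self._forward(beta, delta, gamma)
        ll_new = self._vial_ll(p_new)
        prior_old = -0.5 * (self.z_beta**2 + self.z_delta**2)
        prior_new = -0.5 * (zb_new**2 + zd_new**2)
        if c.fix_gamma is None and not c.gamma_shared_per_pair:
            sg = np.exp(self.log_sg)
            # pc_gamma is the identity here, so gamma priors align with pair-cells
            prior_old = prior_old + _truncnorm_logpdf(
                self.gamma, self.gamma_bar[d.gamma_gbar], sg, lo, hi)
            prior_new = prior_new + _truncnorm_logpdf(
                g_new, self.gamma_bar[d.gamma_gbar], sg, lo, hi)
        acc = self._accept_groups(d.vial_pc, d.n_pc, ll_new, prior_old, prior_new)
        vial_acc = acc[d.vial_pc]
        self.z_beta = np.where(acc, zb_new, self.z_beta)
        self.z_delta = np.where(acc, zd_new, self.z_delta)
        if c.fix_gamma is None and not c.gamma_shared_per_pair:
            self.gamma = np.where(acc, g_new, self.gamma)
        self.p = np.where(vial_acc, p_new, self.p)
        self.ll = np.where(vial_acc, ll_new, self.ll)
        if adapt:
            self.step_pc *= np.exp((acc - c.target_accept) / (k + 1) ** 0.6 * 3)

    def update_gamma_pairs(self, adapt, k):
        """Gamma update when gamma is shared per pair (site-level means)."""
        d, c = self.d, self.c
        if c.fix_gamma is not None or not c.gamma_shared_per_pair:
            return
        lo, hi = c.gamma_bounds
        g_new = self.gamma + 0.02 * self.rng.normal(size=d.n_gamma)
        g_new = np.where((g_new > lo) & (g_new < hi), g_new, self.gamma)
        beta, delta, gamma = self._pc_params(gamma=g_new)
        p_new = self._forward(beta, delta, gamma)
        ll_new = self._vial_ll(p_new)
        sg = np.exp(self.log_sg)
        gp_old = _truncnorm_logpdf(self.gamma, self.gamma_bar[d.gamma_gbar], sg, lo, hi)
        gp_new = _truncnorm_logpdf(g_new, self.gamma_bar[d.gamma_gbar], sg, lo, hi)
        group_of_vial = d.pc_gamma[d.vial_pc]
        acc = self._accept_groups(group_of_vial, d.n_gamma, ll_new, gp_old, gp_new)
        vial_acc = acc[group_of_vial]
        self.gamma = np.where(acc, g_new, self.gamma)
        self.p = np.where(vial_acc, p_new, self.p)
        self.ll = np.where(vial_acc, ll_new, self.ll)

    def _update_mu(self, which, adapt, k):
        d, c = self.d, self.c
        if which == "beta":
            mu, step, prior = self.mu_beta, self.step_mu_b, c.mu_beta_prior
        else:
            mu, step, prior = self.mu_delta, self.step_mu_d, c.mu_delta_prior
        mu_new = mu + step * self.rng.normal(size=d.n_cells)
        kwargs = {"mu_beta": mu_new} if which == "beta" else {"mu_delta": mu_new}
        beta, delta, gamma = self._pc_params(**kwargs)
        p_new = self._forward(beta, delta, gamma)
        ll_new = self._vial_ll(p_new)
        pr_old = -0.5 * ((mu - prior[0]) / prior[1]) ** 2
        pr_new = -0.5 * ((mu_new - prior[0]) / prior[1]) ** 2
        acc = self._accept_groups(d.vial_cell, d.n_cells, ll_new, pr_old, pr_new)
        vial_acc = acc[d.vial_cell]
        if which == "beta":
            self.mu_beta = np.where(acc, mu_new, mu)
        else:
            self.mu_delta = np.where(acc, mu_new, mu)
        self.p = np.where(vial_acc, p_new, self.p)
        self.ll = np.where(vial_acc, ll_new, self.ll)
        if adapt:
            step *= np.exp((acc - c.target_accept) / (k + 1) ** 0.6 * 3)

    def update_gamma_bar(self, adapt, k):
        d, c = self.d, self.c
        if c.fix_gamma is not None:
            return
        lo, hi = c.gamma_bounds
        gb_new = self.gamma_bar + self.step_gbar * self.rng.normal(size=d.n_gbar)
        gb_ok = (gb_new >= lo) & (gb_new <= hi)  # uniform prior support
        gb_new = np.where(gb_ok, gb_new, self.gamma_bar)
        sg = np.exp(self.log_sg)
        gp_old = _truncnorm_logpdf(self.gamma, self.gamma_bar[d.gamma_gbar], sg, lo, hi)
        gp_new = _truncnorm_logpdf(self.gamma, gb_new[d.gamma_gbar], sg, lo, hi)
        delta_pr = np.bincount(d.gamma_gbar, gp_new - gp_old, minlength=d.n_gbar)
        log_r = np.where(gb_ok, delta_pr, -np.inf)
        acc = np.log(self.rng.uniform(size=d.n_gbar)) < log_r
        self.gamma_bar = np.where(acc, gb_new, self.gamma_bar)
        if adapt:
            self.step_gbar *= np.exp((acc - c.target_accept) / (k + 1) ** 0.6 * 3)

    def update_ridge_cells(self, adapt, k):
        """Joint move along the beta-gamma identifiability ridge, per group.

        Shifts log beta-bar by eps while rescaling the group's gammas (and
        gamma_bar) by exp(-eps), leaving the identified product beta*gamma
        nearly unchanged; essential for mixing because the 30-s trials
        identify beta and gamma only jointly.
        """
        d, c = self.d, self.c
        if c.fix_gamma is not None:
            return
        lo, hi = c.gamma_bounds
        eps = self.step_ridge_c * self.rng.normal(size=d.n_gbar)
        scale_g = np.exp(-eps)
        mu_new = self.mu_beta + eps[d.gbar_of_cell]
        g_new = self.gamma * scale_g[d.gamma_gbar]
        gb_new = self.gamma_bar * scale_g
        in_bounds = np.bincount(
            d.gamma_gbar, ((g_new <= lo) | (g_new >= hi)).astype(float),
            minlength=d.n_gbar) == 0
        in_bounds &= (gb_new >= lo) & (gb_new <= hi)
        sg = np.exp(self.log_sg)
        beta, delta, gamma = self._pc_params(mu_beta=mu_new, gamma=g_new)
        p_new = self._forward(beta, delta, gamma)
        ll_new = self._vial_ll(p_new)
        m0, s0 = c.mu_beta_prior
        pr_old = -0.5 * ((self.mu_beta - m0) / s0) ** 2
        pr_new = -0.5 * ((mu_new - m0) / s0) ** 2
        gp_old = _truncnorm_logpdf(self.gamma, self.gamma_bar[d.gamma_gbar], sg, lo, hi)
        with np.errstate(invalid="ignore"):
            gp_new = _truncnorm_logpdf(g_new, gb_new[d.gamma_gbar], sg, lo, hi)
        n_g = np.bincount(d.gamma_gbar, minlength=d.n_gbar)
        extra_old = np.bincount(d.gbar_of_cell, pr_old, minlength=d.n_gbar) \
            + np.bincount(d.gamma_gbar, gp_old, minlength=d.n_gbar)
        extra_new = np.bincount(d.gbar_of_cell, pr_new, minlength=d.n_gbar) \
            + np.bincount(d.gamma_gbar, np.nan_to_num(gp_new, nan=-1e300), minlength=d.n_gbar) \
            - (n_g + 1) * eps  # log-Jacobian of the gamma rescalings
        group_of_vial = d.gbar_of_cell[d.vial_cell]
        acc = self._accept_groups(group_of_vial, d.n_gbar, ll_new, extra_old, extra_new)
        acc &= in_bounds
        vial_acc = acc[group_of_vial]
        cell_acc = acc[d.gbar_of_cell]
        self.mu_beta = np.where(cell_acc, mu_new, self.mu_beta)
        self.gamma = np.where(acc[d.gamma_gbar], g_new, self.gamma)
        self.gamma_bar = np.where(acc, gb_new, self.gamma_bar)
        self.p = np.where(vial_acc, p_new, self.p)
        self.ll = np.where(vial_acc, ll_new, self.ll)
        if adapt:
            self.step_ridge_c *= np.exp((acc - c.target_accept) / (k + 1) ** 0.6 * 3)

    def update_ridge_jump(self):
        """Global scaling jump along the beta-gamma ridge.

        Proposes gamma_bar fresh from its uniform support and rescales the
        group's gammas (and log beta-bar, oppositely) to keep beta*gamma
        fixed; lets the chain cross the whole weakly identified gamma range
        in one step instead of diffusing along it.
        """
        d, c = self.d, self.c
        if c.fix_gamma is not None:
            return
        lo, hi = c.gamma_bounds
        gb_new = self.rng.uniform(lo, hi, size=d.n_gbar)
        ratio = gb_new / self.gamma_bar
        log_ratio = np.log(ratio)
        mu_new = self.mu_beta - log_ratio[d.gbar_of_cell]
        g_new = self.gamma * ratio[d.gamma_gbar]
        in_bounds = np.bincount(
            d.gamma_gbar, ((g_new <= lo) | (g_new >= hi)).astype(float),
            minlength=d.n_gbar) == 0
        sg = np.exp(self.log_sg)
        beta, delta, gamma = self._pc_params(mu_beta=mu_new, gamma=g_new)
        p_new = self._forward(beta, delta, gamma)
        ll_new = self._vial_ll(p_new)
        m0, s0 = c.mu_beta_prior
        pr_old = -0.5 * ((self.mu_beta - m0) / s0) ** 2
        pr_new = -0.5 * ((mu_new - m0) / s0) ** 2
        gp_old = _truncnorm_logpdf(self.gamma, self.gamma_bar[d.gamma_gbar], sg, lo, hi)
        with np.errstate(invalid="ignore"):
            gp_new = _truncnorm_logpdf(
                np.clip(g_new, lo + 1e-12, hi - 1e-12),
                gb_new[d.gamma_gbar], sg, lo, hi)
        n_g = np.bincount(d.gamma_gbar, minlength=d.n_gbar)
        extra_old = np.bincount(d.gbar_of_cell, pr_old, minlength=d.n_gbar) \
            + np.bincount(d.gamma_gbar, gp_old, minlength=d.n_gbar)
        extra_new = np.bincount(d.gbar_of_cell, pr_new, minlength=d.n_gbar) \
            + np.bincount(d.gamma_gbar, gp_new, minlength=d.n_gbar) \
            + n_g * log_ratio  # Jacobian of the gamma rescaling
        group_of_vial = d.gbar_of_cell[d.vial_cell]
        acc = self._accept_groups(group_of_vial, d.n_gbar, ll_new, extra_old, extra_new)
        acc &= in_bounds
        vial_acc = acc[group_of_vial]
        cell_acc = acc[d.gbar_of_cell]
        self.mu_beta = np.where(cell_acc, mu_new, self.mu_beta)
        self.gamma = np.where(acc[d.gamma_gbar], g_new, self.gamma)
        self.gamma_bar = np.where(acc, gb_new, self.gamma_bar)
        self.p = np.where(vial_acc, p_new, self.p)
        self.ll = np.where(vial_acc, ll_new, self.ll)

    def update_global_scale(self, adapt, k):
        """Joint rescaling of the whole gamma level against all log beta-bars.

        Multiplies every gamma, gamma_bar and sigma_gamma by a common factor
        while shifting every log beta-bar by the opposite log amount: all
        pair z-scores and all beta*gamma products are exactly preserved, so
        acceptance is governed only by priors, bounds and truncation
        normalisations.  Mixes the (weakly identified) absolute gamma scale.
        """
        d, c = self.d, self.c
        if c.fix_gamma is not None:
            return
        lo, hi = c.gamma_bounds
        log_r = self.step_scalar["gscale"] * self.rng.normal()
        r = np.exp(log_r)
        g_new = self.gamma * r
        gb_new = self.gamma_bar * r
        sg_new = np.exp(self.log_sg) * r
        if (np.any(g_new <= lo) or np.any(g_new >= hi)
                or np.any(gb_new < lo) or np.any(gb_new > hi)):
            accepted = False
        else:
            mu_new = self.mu_beta - log_r
            beta, delta, gamma = self._pc_params(mu_beta=mu_new, gamma=g_new)
            p_new = self._forward(beta, delta, gamma)
            ll_new = self._vial_ll(p_new)
            m0, s0 = c.mu_beta_prior
            d_mu_prior = float(np.sum(
                -0.5 * ((mu_new - m0) / s0) ** 2 + 0.5 * ((self.mu_beta - m0) / s0) ** 2
            ))
            gp_old = _truncnorm_logpdf(self.gamma, self.gamma_bar[d.gamma_gbar],
                                       np.exp(self.log_sg), lo, hi).sum()
            gp_new = _truncnorm_logpdf(g_new, gb_new[d.gamma_gbar], sg_new, lo, hi).sum()
            d_sg_prior = (self._halfnormal_lp(sg_new, c.sigma_gamma_scale)
                          - self._halfnormal_lp(np.exp(self.log_sg), c.sigma_gamma_scale))
            # Jacobian: each gamma, gamma_bar and sigma_gamma scales by r
            jac = (d.n_gamma + d.n_gbar + 1) * log_r
            log_ratio = (float(ll_new.sum() - self.ll.sum()) + d_mu_prior
                         + gp_new - gp_old + d_sg_prior + jac)
            accepted = np.log(self.rng.uniform()) < log_ratio
            if accepted:
                self.mu_beta = mu_new
                self.gamma = g_new
                self.gamma_bar = gb_new
                self.log_sg = float(np.log(sg_new))
                self.p, self.ll = p_new, ll_new
        if adapt:
            self.step_scalar["gscale"] *= np.exp(
                (float(accepted) - c.target_accept) / (k + 1) ** 0.6 * 3
            )

    def update_ridge_pairs(self, adapt, k):
        """Pair-level beta-gamma ridge move (non-shared gamma only)."""
        d, c = self.d, self.c
        if c.fix_gamma is not None or c.gamma_shared_per_pair:
            return
        lo, hi = c.gamma_bounds
        sb = np.exp(self.log_sb)
        eps = self.step_ridge_p * self.rng.normal(size=d.n_pc)
        zb_new = self.z_beta + eps / max(sb, 1e-6)
        g_new = self.gamma * np.exp(-eps)
        ok = (g_new > lo) & (g_new < hi)
        beta, delta, gamma = self._pc_params(z_beta=zb_new, gamma=g_new)
        p_new = self._forward(beta, delta, gamma)
        ll_new = self._vial_ll(p_new)
        sg = np.exp(self.log_sg)
        gp_old = _truncnorm_logpdf(self.gamma, self.gamma_bar[d.gamma_gbar], sg, lo, hi)
        with np.errstate(invalid="ignore"):
            gp_new = _truncnorm_logpdf(
                np.where(ok, g_new, self.gamma), self.gamma_bar[d.gamma_gbar], sg, lo, hi)
        extra_old = -0.5 * self.z_beta**2 + gp_old
        extra_new = -0.5 * zb_new**2 + gp_new - eps
        acc = self._accept_groups(d.vial_pc, d.n_pc, ll_new, extra_old, extra_new)
        acc &= ok
        vial_acc = acc[d.vial_pc]
        self.z_beta = np.where(acc, zb_new, self.z_beta)
        self.gamma = np.where(acc, g_new, self.gamma)
        self.p = np.where(vial_acc, p_new, self.p)
        self.ll = np.where(vial_acc, ll_new, self.ll)
        if adapt:
            self.step_ridge_p *= np.exp((acc - c.target_accept) / (k + 1) ** 0.6 * 3)

    def update_asis(self, adapt, k):
        """Centered-parameterisation interweaving moves for mu and sigma.

        Holding the realised pair-level rates fixed (likelihood unchanged),
        shift each cell mean with a compensating shear of its z-scores, and
        rescale each spread with a compensating rescale of all z-scores.
        Cures the funnel-induced slow mixing of sigma_beta/sigma_delta and
        the cell means.
        """
        d, c = self.d, self.c
        for which in ("beta", "delta"):
            if which == "beta":
                mu, z, log_s = self.mu_beta, self.z_beta, self.log_sb
                prior, s_scale = c.mu_beta_prior, c.sigma_beta_scale
                step_mu = self.step_asis_mu_b
            else:
                mu, z, log_s = self.mu_delta, self.z_delta, self.log_sd
                prior, s_scale = c.mu_delta_prior, c.sigma_delta_scale
                step_mu = self.step_asis_mu_d
            sigma = max(np.exp(log_s), 1e-8)
            # per-cell mean shift with fixed pair-level rates (det = 1)
            eps = step_mu * self.rng.normal(size=d.n_cells)
            z_new = z - eps[d.pc_cell] / sigma
            pr_old = (-0.5 * ((mu - prior[0]) / prior[1]) ** 2
                      + np.bincount(d.pc_cell, -0.5 * z**2, minlength=d.n_cells))
            pr_new = (-0.5 * ((mu + eps - prior[0]) / prior[1]) ** 2
                      + np.bincount(d.pc_cell, -0.5 * z_new**2, minlength=d.n_cells))
            acc = np.log(self.rng.uniform(size=d.n_cells)) < pr_new - pr_old
            mu_out = np.where(acc, mu + eps, mu)
            z_out = np.where(acc[d.pc_cell], z_new, z)
            # global spread rescale with fixed pair-level rates
            eps_s = self.step_scalar[f"asis_{which}"] * self.rng.normal()
            sigma_new = max(np.exp(log_s + eps_s), 1e-8)
            z_scaled = z_out * (sigma / sigma_new)
            log_ratio = (
                float(np.sum(-0.5 * z_scaled**2 + 0.5 * z_out**2))
                + self._halfnormal_lp(sigma_new, s_scale)
                - self._halfnormal_lp(sigma, s_scale)
                + d.n_pc * (np.log(sigma) - np.log(sigma_new))
                + eps_s  # log-scale proposal Jacobian for sigma
            )
            acc_s = np.log(self.rng.uniform()) < log_ratio
            if acc_s:
                z_out = z_scaled
                log_s_out = float(np.log(sigma_new))
            else:
                log_s_out = log_s
            if which == "beta":
                self.mu_beta, self.z_beta, self.log_sb = mu_out, z_out, log_s_out
            else:
                self.mu_delta, self.z_delta, self.log_sd = mu_out, z_out, log_s_out
            if adapt:
                gain = 3 / (k + 1) ** 0.6
                step_mu *= np.exp((acc - c.target_accept) * gain)
                self.step_scalar[f"asis_{which}"] *= np.exp(
                    (float(acc_s) - c.target_accept) * gain
                )

    def _halfnormal_lp(self, x, scale):
        return -0.5 * (x / scale) ** 2

    def _update_scalar(self, name, adapt, k):
        """log-scale random-walk updates for sigma_beta/sigma_delta/sigma_gamma/lambda."""
        d, c = self.d, self.c
        lo, hi = c.gamma_bounds
        step = self.step_scalar[name]
        eps = step * self.rng.normal()
        if name == "sb":
            new = self.log_sb + eps
            beta, delta, gamma = self._pc_params(sb=np.exp(new))
            p_new = self._forward(beta, delta, gamma)
            ll_new = self._vial_ll(p_new)
            log_r = (ll_new.sum() - self.ll.sum()
                     + self._halfnormal_lp(np.exp(new), c.sigma_beta_scale)
                     - self._halfnormal_lp(np.exp(self.log_sb), c.sigma_beta_scale)
                     + new - self.log_sb)
            if np.log(self.rng.uniform()) < log_r:
                self.log_sb, self.p, self.ll = new, p_new, ll_new
                accepted = True
            else:
                accepted = False
        elif name == "sd":
            new = self.log_sd + eps
            beta, delta, gamma = self._pc_params(sd=np.exp(new))
            p_new = self._forward(beta, delta, gamma)
            ll_new = self._vial_ll(p_new)
            log_r = (ll_new.sum() - self.ll.sum()
                     + self._halfnormal_lp(np.exp(new), c.sigma_delta_scale)
                     - self._halfnormal_lp(np.exp(self.log_sd), c.sigma_delta_scale)
                     + new - self.log_sd)
            if np.log(self.rng.uniform()) < log_r:
                self.log_sd, self.p, self.ll = new, p_new, ll_new
                accepted = True
            else:
                accepted = False
        elif name == "sg":
            if c.fix_gamma is not None:
                return
            new = self.log_sg + eps
            gp_old = _truncnorm_logpdf(self.gamma, self.gamma_bar[d.gamma_gbar],
                                       np.exp(self.log_sg), lo, hi).sum()
            gp_new = _truncnorm_logpdf(self.gamma, self.gamma_bar[d.gamma_gbar],
                                       np.exp(new), lo, hi).sum()
            log_r = (gp_new - gp_old
                     + self._halfnormal_lp(np.exp(new), c.sigma_gamma_scale)
                     - self._halfnormal_lp(np.exp(self.log_sg), c.sigma_gamma_scale)
                     + new - self.log_sg)
            accepted = np.log(self.rng.uniform()) < log_r
            if accepted:
                self.log_sg = new
        else:  # lam
            new = self.log_lam + eps
            ll_new = self._vial_ll(self.p, lam=np.exp(new))
            log_r = (ll_new.sum() - self.ll.sum()
                     + self._halfnormal_lp(np.exp(new), c.lam_scale)
                     - self._halfnormal_lp(np.exp(self.log_lam), c.lam_scale)
                     + new - self.log_lam)
            if np.log(self.rng.uniform()) < log_r:
                self.log_lam, self.ll = new, ll_new
                accepted = True
            else:
                accepted = False
        if adapt:
            self.step_scalar[name] *= np.exp(
                (float(accepted) - c.target_accept) / (k + 1) ** 0.6 * 3
            )

    def sweep(self, adapt, k):
        self.update_paircells(adapt, k)
        self.update_gamma_pairs(adapt, k)
        self._update_mu("beta", adapt, k)
        self._update_mu("delta", adapt, k)
        self.update_gamma_bar(adapt, k)
        self.update_ridge_cells(adapt, k)
        self.update_ridge_jump()
        self.update_global_scale(adapt, k)
        self.update_ridge_pairs(adapt, k)
        self.update_asis(adapt, k)
        for name in ("sb", "sd", "sg", "lam"):
            self._update_scalar(name, adapt, k)


class HierarchicalKineticsModel:
    """Fit-style interface to the hierarchical Bayesian kinetics model.

    After ``fit``, ``summary_`` holds a :class:`PosteriorSummary` and
    ``draws_`` the raw posterior draws keyed by parameter name.
    """

    def __init__(self, config: HierModelConfig | None = None):
        self.config = config or HierModelConfig()

    def get_params(self) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "HierarchicalKineticsModel":
        if "config" in params:
            self.config = params["config"]
        return self

    def fit(self, records: Sequence[TrialRecord], seed: int = 0) -> "HierarchicalKineticsModel":
        c = self.config
        data = _ModelData(records, c)
        draws = {
            "mu_beta": np.empty((c.chains, c.draws, data.n_cells)),
            "mu_delta": np.empty((c.chains, c.draws, data.n_cells)),
            "gamma_bar": np.empty((c.chains, c.draws, data.n_gbar)),
            "sigma_beta": np.empty((c.chains, c.draws)),
            "sigma_delta": np.empty((c.chains, c.draws)),
            "sigma_gamma": np.empty((c.chains, c.draws)),
            "lam": np.empty((c.chains, c.draws)),
            "z_beta": np.empty((c.chains, c.draws, data.n_pc)),
            "z_delta": np.empty((c.chains, c.draws, data.n_pc)),
            "gamma": np.empty((c.chains, c.draws, data.n_gamma)),
        }
        ss = np.random.SeedSequence(entropy=seed)
        for chain, child in enumerate(ss.spawn(c.chains)):
            rng = np.random.default_rng(child)
            s = _Sampler(data, c, rng)
            for k in range(c.warmup):
                s.sweep(adapt=True, k=k)
            for i in range(c.draws):
                s.sweep(adapt=False, k=0)
                draws["mu_beta"][chain, i] = s.mu_beta
                draws["mu_delta"][chain, i] = s.mu_delta
                draws["gamma_bar"][chain, i] = s.gamma_bar
                draws["sigma_beta"][chain, i] = np.exp(s.log_sb)
                draws["sigma_delta"][chain, i] = np.exp(s.log_sd)
                draws["sigma_gamma"][chain, i] = np.exp(s.log_sg)
                draws["lam"][chain, i] = np.exp(s.log_lam)
                draws["z_beta"][chain, i] = s.z_beta
                draws["z_delta"][chain, i] = s.z_delta
                draws["gamma"][chain, i] = s.gamma
        self.data_ = data
        self.draws_ = draws
        self.summary_ = self._summarize(data, draws)
        return self

    def _summarize(self, data: _ModelData, draws: dict) -> PosteriorSummary:
        diag = convergence_check(
            {k: draws[k] for k in ("mu_beta", "mu_delta", "gamma_bar",
                                   "sigma_beta", "sigma_delta", "sigma_gamma",
                                   "lam")}
        )
        rows = []
        for name, key in (("beta", "mu_beta"), ("delta", "mu_delta")):
            vals = np.exp(draws[key])  # population medians of lognormal
            for ci, cell in enumerate(data.cells):
                v = vals[:, :, ci].ravel()
                rows.append({
                    "site": cell[0], "treatment": cell[1], "parameter": name,
                    "mean": v.mean(), "median": np.median(v),
                    "q2.5": np.quantile(v, 0.025), "q97.5": np.quantile(v, 0.975),
                    "rhat": diag["rhat"][f"{key}[{ci}]"],
                    "ess_bulk": diag["ess_bulk"][f"{key}[{ci}]"],
                    "ess_tail": diag["ess_tail"][f"{key}[{ci}]"],
                })
        for gi, label in enumerate(data.gbar_labels):
            v = draws["gamma_bar"][:, :, gi].ravel()
            rows.append({
                "site": label[0], "treatment": label[1], "parameter": "gamma",
                "mean": v.mean(), "median": np.median(v),
                "q2.5": np.quantile(v, 0.025), "q97.5": np.quantile(v, 0.975),
                "rhat": diag["rhat"][f"gamma_bar[{gi}]"],
                "ess_bulk": diag["ess_bulk"][f"gamma_bar[{gi}]"],
                "ess_tail": diag["ess_tail"][f"gamma_bar[{gi}]"],
            })
        population = pd.DataFrame(rows)

        sb = draws["sigma_beta"][..., None]
        sd = draws["sigma_delta"][..., None]
        beta_pc = np.exp(draws["mu_beta"][:, :, data.pc_cell] + sb * draws["z_beta"])
        delta_pc = np.exp(draws["mu_delta"][:, :, data.pc_cell] + sd * draws["z_delta"])
        gamma_pc = draws["gamma"][:, :, data.pc_gamma]
        pair_rows = []
        for j, (site, trt, pair) in enumerate(data.paircells):
            pair_rows.append({
                "site": site, "treatment": trt, "pair_id": pair,
                "beta": np.median(beta_pc[:, :, j]),
                "delta": np.median(delta_pc[:, :, j]),
                "gamma": np.median(gamma_pc[:, :, j]),
            })
        lam = draws["lam"].ravel()
        return PosteriorSummary(
            population=population,
            pairs=pd.DataFrame(pair_rows),
            lam={"mean": lam.mean(), "median": np.median(lam),
                 "q2.5": np.quantile(lam, 0.025), "q97.5": np.quantile(lam, 0.975)},
            draws=draws,
            cells=data.cells,
            converged=bool(diag["pass"]),
        )


def fit_hierarchical(
    records: Sequence[TrialRecord],
    config: HierModelConfig | None = None,
    seed: int = 0,
) -> PosteriorSummary:
    """Sample the hierarchical kinetics posterior from vial-level records."""
    model = HierarchicalKineticsModel(config)
    model.fit(records, seed=seed)
    return model.summary_


def decline_summary(
    posterior: PosteriorSummary,
    treatment: str,
    reference: str,
    site: str | None = None,
    parameter: str = "beta",
) -> DeclineSummary:
    """Percent decline of a population rate at ``treatment`` vs ``reference``.

    Computed per posterior draw as ``100 * (1 - rate_trt / rate_ref)``;
    reports the median, the equal-tailed 95% credible set, and the posterior
    probability of a decline (draws with ratio exactly 1 count half).
    """
    key = {"beta": "mu_beta", "delta": "mu_delta"}[parameter]
    cells = posterior.cells
    sites = sorted(set(c[0] for c in cells))
    if site is None:
        if len(sites) > 1:
            raise ValueError(f"multiple sites present {sites}; specify one")
        site = sites[0]
    try:
        i_trt = cells.index((site, treatment))
        i_ref = cells.index((site, reference))
    except ValueError as exc:
        raise ValueError(
            f"treatment cell not found in posterior: {exc}; have {cells}"
        ) from exc
    ratio = np.exp(posterior.draws[key][:, :, i_trt] - posterior.draws[key][:, :, i_ref]).ravel()
    decline = 100.0 * (1.0 - ratio)
    prob = float(np.mean(ratio < 1.0) + 0.5 * np.mean(ratio == 1.0))
    return DeclineSummary(
        site=site, parameter=parameter, treatment=treatment, reference=reference,
        decline_pct=float(np.median(decline)),
        ci_low=float(np.quantile(decline, 0.025)),
        ci_high=float(np.quantile(decline, 0.975)),
        prob_decline=prob,
    )


def convergence_check(draws: dict, rhat_max: float = 1.05, ess_min: float = 100.0) -> dict:
    """Split-Rhat, bulk/tail ESS and a boolean pass flag for posterior draws.

    ``draws`` maps names to arrays of shape (chain, draw) or
    (chain, draw, k).  Requires >= 2 chains.
    """
    first = next(iter(draws.values()))
    if first.ndim < 2 or first.shape[0] < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    rhat, ess_bulk, ess_tail = {}, {}, {}
    for name, arr in draws.items():
        arr = np.asarray(arr)
        cols = [("", arr)] if arr.ndim == 2 else [
            (f"[{i}]", arr[:, :, i]) for i in range(arr.shape[2])
        ]
        for suffix, a in cols:
            label = f"{name}{suffix}"
            rhat[label] = float(az.rhat(az.convert_to_dataset(a)).x)
            ess_bulk[label] = float(az.ess(az.convert_to_dataset(a), method="bulk").x)
            ess_tail[label] = float(az.ess(az.convert_to_dataset(a), method="tail").x)
    ok = (
        all(np.isnan(v) or v < rhat_max for v in rhat.values())
        and all(np.isnan(v) or v > ess_min for v in ess_bulk.values())
    )
    return {"rhat": rhat, "ess_bulk": ess_bulk, "ess_tail": ess_tail, "pass": bool(ok)}
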