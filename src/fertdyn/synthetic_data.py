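"""Synthetic fertilization-trial generator.

Emulates the study design the analyses assume: three sites (12/10/12
male-female pairs), three pH treatments per site, eight serial 1:10 sperm
dilutions per pair x treatment, 1,000 eggs per vial with 30 s sperm-egg
contact, and 200 embryos scored per vial.  Outcome probabilities come from
the mechanistic kinetics model with lognormal pair-level heterogeneity in
the sperm-egg interaction rate (beta) and polyspermy-block rate (delta),
truncated-normal heterogeneity in gamma, and beta-binomial (Dirichlet-
multinomial across categories) overdispersion in the scored counts.

Generator defaults are calibrated so total fertilization traverses 0 -> 1
across the eight-dilution range; they are generator choices, not estimates
from any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import (
    DEFAULT_EGG_CONC,
    DEFAULT_SPERM_DECAY,
    GAMMA_BOUNDS,
    KineticsParams,
    outcome_fractions_batch,
)
from .trial_model import (
    DilutionSeries,
    ExperimentDesign,
    TrialRecord,
    VialCounts,
    dilution_concentrations,
)

#: Default population truth shared by every site x treatment cell.
DEFAULT_TRUTH = {"beta": 3e-4, "gamma": 0.05, "delta": 0.2}
DEFAULT_SIGMAS = {"beta": 0.3, "delta": 0.3, "gamma": 0.01}


@dataclass(frozen=True)
class SimulationConfig:
    """Design + population truth + dispersion for one simulated experiment.

    ``truth`` maps (site, treatment) -> dict with keys beta/gamma/delta; a
    cell absent from ``truth`` falls back to ``default_truth``. ``sigmas``
    are the pair-level spreads (lognormal sd for beta/delta, truncated-
    normal sd for gamma). ``dispersion`` is the beta-binomial precision
    lambda. ``pending_as_normal`` scores eggs fertilized but not yet
    blocked at contact time as normal (the lab convention for any raised
    envelope without visible abnormality); ``abn_tight_ratio`` splits the
    polyspermic fraction between tight-membrane and abnormal-cleavage
    scoring categories.
    """

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    truth: dict = field(default_factory=dict)
    default_truth: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    sigmas: dict = field(default_factory=lambda: dict(DEFAULT_SIGMAS))
    dispersion: float = 100.0
    r: float = DEFAULT_SPERM_DECAY
    egg_conc: float = DEFAULT_EGG_CONC
    pending_as_normal: bool = True
    abn_tight_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion lambda must be > 0")
        if not (0.0 <= self.abn_tight_ratio <= 1.0):
            raise ValueError("abn_tight_ratio must be in [0, 1]")
        for name in ("beta", "delta", "gamma"):
            if self.sigmas[name] < 0:
                raise ValueError(f"sigma_{name} must be >= 0")

    def cell_truth(self, site: str, treatment: str) -> dict:
        return {**self.default_truth, **self.truth.get((site, treatment), {})}


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Complete site x pair x treatment x vial layout with concentrations."""
    design = config.design
    series = DilutionSeries(
        hemocytometer_count=design.stock_conc, n_steps=design.n_steps
    )
    concs = dilution_concentrations(series)
    rows = []
    for site, n_pairs, treatments in design.sites:
        for i in range(1, n_pairs + 1):
            pair = f"{site}{i:02d}"
            for trt in treatments:
                for k, conc in enumerate(concs, start=1):
                    rows.append(
                        {
                            "site": site,
                            "pair_id": pair,
                            "ph_treatment": trt,
                            "vial_index": k,
                            "sperm_conc": conc,
                        }
                    )
    return pd.DataFrame(rows)


def betabinomial_sample(n: int, p: float, lam: float, rng) -> int:
    """One beta-binomial draw with shapes (lam*p, lam*(1-p)).

    Mean n*p; variance n*p*(1-p)*(1 + (n-1)/(lam+1)).  ``rng`` is a
    numpy Generator or an integer seed.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if p == 0.0:
        return 0
    if p == 1.0:
        return int(n)
    q = rng.beta(lam * p, lam * (1.0 - p))
    return int(rng.binomial(n, q))


def _draw_pair_params(cell: dict, sigmas: dict, rng) -> tuple[float, float, float]:
    beta_i = cell["beta"] * np.exp(rng.normal(0.0, sigmas["beta"]))
    delta_i = cell["delta"] * np.exp(rng.normal(0.0, sigmas["delta"]))
    lo, hi = GAMMA_BOUNDS
    if sigmas["gamma"] == 0:
        gamma_i = float(np.clip(cell["gamma"], lo, hi))
    else:
        while True:
            gamma_i = rng.normal(cell["gamma"], sigmas["gamma"])
            if lo < gamma_i < hi:
                break
    return float(beta_i), float(delta_i), float(gamma_i)


def simulate_trials(
    config: SimulationConfig, seed: int
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Simulate a full experiment; returns (records, truth table).

    The truth table holds the population values and the realized pair-level
    (beta, gamma, delta) for every site x treatment cell, plus per-vial true
    outcome probabilities, for use in recovery tests.
    """
    ss = np.random.SeedSequence(entropy=seed)
    main_ss, split_ss = ss.spawn(2)
    rng = np.random.default_rng(main_ss)
    # the tight-membrane/abnormal-cleavage split is a nuisance draw; it gets
    # its own stream so the split ratio cannot perturb any other draw
    split_rng = np.random.default_rng(split_ss)
    layout = generate_design(config)
    design = config.design
    records: list[TrialRecord] = []
    truth_rows = []

    for site, n_pairs, treatments in design.sites:
        for i in range(1, n_pairs + 1):
            pair = f"{site}{i:02d}"
            for trt in treatments:
                cell = config.cell_truth(site, trt)
                beta_i, delta_i, gamma_i = _draw_pair_params(cell, config.sigmas, rng)
                params = KineticsParams(
                    beta=beta_i, gamma=gamma_i, delta=delta_i,
                    r=config.r, egg_conc=config.egg_conc, t=design.contact_time,
                )
                sub = layout[
                    (layout.site == site)
                    & (layout.pair_id == pair)
                    & (layout.ph_treatment == trt)
                ]
                outcomes = outcome_fractions_batch(
                    params, sub.sperm_conc.to_numpy(), rtol=1e-8, atol=1e-12
                )
                for (_, row), out in zip(sub.iterrows(), outcomes):
                    p_normal = out.frac_normal + (
                        out.frac_pending if config.pending_as_normal else 0.0
                    )
                    p_abn = out.frac_polyspermic + (
                        0.0 if config.pending_as_normal else out.frac_pending
                    )
                    p_unf = max(out.frac_unfert, 0.0)
                    probs = np.clip([p_unf, p_normal, p_abn], 0.0, None)
                    probs = probs / probs.sum()
                    n = design.n_scored
                    # Dirichlet-multinomial with concentration lam*p: each
                    # category count is marginally beta-binomial(lam*p_k).
                    alpha = np.maximum(config.dispersion * probs, 1e-9)
                    q = rng.dirichlet(alpha)
                    counts3 = rng.multinomial(n, q)
                    n_abn = int(counts3[2])
                    n_tight = int(split_rng.binomial(n_abn, config.abn_tight_ratio))
                    counts = VialCounts(
                        n_scored=n,
                        n_unfert=int(counts3[0]),
                        n_tight=n_tight,
                        n_abn_dev=n_abn - n_tight,
                    )
                    records.append(
                        TrialRecord(
                            site=site, pair_id=pair, ph_treatment=trt,
                            ph_measured=float(trt), vial_index=int(row.vial_index),
                            sperm_conc=float(row.sperm_conc), counts=counts,
                        )
                    )
                    truth_rows.append(
                        {
                            "site": site, "pair_id": pair, "ph_treatment": trt,
                            "vial_index": int(row.vial_index),
                            "sperm_conc": float(row.sperm_conc),
                            "beta": beta_i, "gamma": gamma_i, "delta": delta_i,
                            "beta_pop": cell["beta"], "gamma_pop": cell["gamma"],
                            "delta_pop": cell["delta"],
                            "p_unfert": probs[0], "p_normal": probs[1],
                            "p_abnormal": probs[2],
                        }
                    )
    return records, pd.DataFrame(truth_rows)
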