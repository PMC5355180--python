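"""Pipeline orchestration: configuration, staging, manifests, reports.

A single structured config (YAML/dict) drives a full reproducible run:
simulate or load trials -> score -> seawater chemistry table -> TF/AbnF
dose-response fits with bootstrap metrics -> optional hierarchical kinetics
fit -> report figures.  Every output file is recorded in a manifest with a
SHA-256 checksum; identical config + seeds give identical non-MCMC outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .carbonate import solve_carbonate
from .curve_metrics import GLMMSpec, bootstrap_contrasts, fit_glmm
from .hier_bayes import HierModelConfig, fit_hierarchical
from .synthetic_data import SimulationConfig, simulate_trials
from .trial_model import ExperimentDesign, load_trials, records_to_frame, write_trials


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RegimeStats:
    """Summary statistics of a pH_T time series against a low-pH threshold."""

    mean_ph: float
    cv: float
    frac_below: float  # fraction of observations <= threshold (inclusive)
    threshold: float
    n_obs: int


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    started: str
    finished: str = ""
    outputs: dict = field(default_factory=dict)  # path -> sha256
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def regime_stats(ph_values, threshold: float = 7.80) -> RegimeStats:
    """Mean, CV and fraction of observations at or below ``threshold``.

    ``ph_values`` is any sequence of pH_T observations (a DataFrame column
    of a `timestamp,ph_T` series works directly).  The threshold comparison
    is inclusive.
    """
    v = np.asarray(ph_values, float)
    if v.size == 0:
        raise ValueError("empty pH series")
    if np.any((v < 6.0) | (v > 9.0)):
        raise ValueError("pH values outside [6, 9]; input looks corrupted")
    mean = float(v.mean())
    return RegimeStats(
        mean_ph=mean,
        cv=float(v.std(ddof=0) / mean),
        frac_below=float(np.mean(v <= threshold)),
        threshold=threshold,
        n_obs=int(v.size),
    )


def load_regime_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if "ph_T" not in df.columns:
        raise ConfigError("pH series CSV requires columns timestamp,ph_T")
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _design_from_config(block: dict) -> ExperimentDesign:
    kwargs = {}
    if "sites" in block:
        kwargs["sites"] = tuple(
            (s[0], int(s[1]), tuple(str(t) for t in s[2])) for s in block["sites"]
        )
    for key in ("stock_conc", "n_steps", "eggs_per_vial", "n_scored"):
        if key in block:
            kwargs[key] = block[key]
    return ExperimentDesign(**kwargs)


def _sim_config(block: dict) -> SimulationConfig:
    design = _design_from_config(block.get("design", {}))
    truth = {}
    for row in block.get("truth", []):
        key = (row["site"], str(row["treatment"]))
        truth[key] = {k: row[k] for k in ("beta", "gamma", "delta") if k in row}
    kwargs = {}
    for key in ("dispersion", "pending_as_normal", "abn_tight_ratio"):
        if key in block:
            kwargs[key] = block[key]
    if "sigmas" in block:
        kwargs["sigmas"] = dict(block["sigmas"])
    return SimulationConfig(design=design, truth=truth, **kwargs)


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Execute the configured stages; returns the run manifest.

    Required: a ``simulate`` block or a ``trials`` path.  Optional blocks:
    ``carbonate`` (list of chemistry inputs), ``glmm`` (dose-response fits,
    metrics, bootstrap), ``bayes`` (hierarchical kinetics fit), ``regime``
    (pH time-series summary), ``report`` (figures).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        config=config, seed=seed, version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def record(path: Path):
        manifest.outputs[str(path.relative_to(out))] = _sha256(path)

    # --- stage: trials ---------------------------------------------------
    if "simulate" in config:
        sim = _sim_config(config["simulate"])
        records, truth_table = simulate_trials(sim, seed=seed)
        trials_path = out / "trials.csv"
        write_trials(records, trials_path)
        truth_path = out / "truth.csv"
        truth_table.to_csv(truth_path, index=False)
        record(trials_path)
        record(truth_path)
    elif "trials" in config:
        records = load_trials(config["trials"])
    else:
        raise ConfigError("config needs a 'simulate' block or a 'trials' path")

    scored_path = out / "scored.csv"
    records_to_frame(records, scored=True).to_csv(scored_path, index=False)
    record(scored_path)

    # --- stage: carbonate chemistry --------------------------------------
    if "carbonate" in config:
        rows = []
        for inp in config["carbonate"]:
            st = solve_carbonate(inp["ph_T"], inp["alk"], inp["sal"], inp["temp"])
            rows.append({
                "ph_T": st.ph_T, "alk": st.A_T, "sal": st.S, "temp": st.T,
                "dic": st.DIC, "pco2": st.pCO2, "omega_a": st.omega_a,
                "co3": st.co3,
            })
        chem_path = out / "carbonate.csv"
        pd.DataFrame(rows).to_csv(chem_path, index=False)
        record(chem_path)

    # --- stage: pH regime -------------------------------------------------
    if "regime" in config:
        block = config["regime"]
        series = load_regime_csv(block["path"])
        stats = regime_stats(series["ph_T"], threshold=block.get("threshold", 7.80))
        regime_path = out / "regime.json"
        regime_path.write_text(json.dumps(dataclasses.asdict(stats), indent=2))
        record(regime_path)

    # --- stage: dose-response fits + metrics ------------------------------
    metrics_df = contrasts_df = None
    curves = {}
    if config.get("glmm", {}).get("enabled", True):
        block = config.get("glmm", {})
        degree = int(block.get("degree", 3))
        for response in ("TF", "AbnF"):
            curve = fit_glmm(records, GLMMSpec(response=response, degree=degree))
            curves[response] = curve
            if not curve.converged:
                manifest.warnings.append(
                    f"{response} dose-response fit flagged: {curve.message}"
                )
            fit_path = out / f"fit_{response.lower()}.json"
            fit_path.write_text(json.dumps({
                "response": response,
                "coef": dict(zip(curve.coef_names, curve.coef.tolist())),
                "varcomps": curve.varcomps,
                "loglik": curve.loglik,
                "n_obs": curve.n_obs,
                "converged": curve.converged,
            }, indent=2))
            record(fit_path)
        metrics_df, contrasts_df = bootstrap_contrasts(
            curves["TF"], curves["AbnF"],
            n_boot=int(block.get("n_boot", 1000)), seed=seed + 1,
        )
        metrics_path = out / "metrics.csv"
        metrics_df.to_csv(metrics_path, index=False)
        record(metrics_path)
        contrasts_path = out / "contrasts.csv"
        contrasts_df.to_csv(contrasts_path, index=False)
        record(contrasts_path)

    # --- stage: hierarchical kinetics fit ---------------------------------
    posterior = None
    if config.get("bayes", {}).get("enabled", False):
        block = config["bayes"]
        hconf = HierModelConfig(
            chains=int(block.get("chains", 2)),
            warmup=int(block.get("warmup", 800)),
            draws=int(block.get("draws", 800)),
        )
        posterior = fit_hierarchical(records, hconf, seed=seed + 2)
        if not posterior.converged:
            manifest.warnings.append("hierarchical kinetics fit flagged non-converged")
        post_path = out / "posterior.csv"
        posterior.population.to_csv(post_path, index=False)
        record(post_path)

    # --- stage: report -----------------------------------------------------
    if config.get("report", {}).get("enabled", True) and metrics_df is not None:
        for fig_path in report(out, curves, metrics_df, contrasts_df, posterior):
            record(fig_path)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    return manifest


def report(out_dir, curves: dict, metrics_df: pd.DataFrame,
           contrasts_df: pd.DataFrame | None = None, posterior=None) -> list:
    """Write summary figures; returns the list of files created.

    Panels: per-site fertilization functions with 95% CI bands, metric
    dot-plots with bootstrap CIs and homogeneous-group letters, and (when a
    posterior is supplied) interval plots for the population rates.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.special import expit

    out = Path(out_dir)
    created = []

    tf = curves.get("TF")
    if tf is not None:
        sites = sorted(set(s for s, _ in tf.cells))
        fig, axes = plt.subplots(1, len(sites), figsize=(4 * len(sites), 3.2),
                                 squeeze=False, sharey=True)
        for ax, site in zip(axes[0], sites):
            for _, trt in [c for c in tf.cells if c[0] == site]:
                lo, hi = tf.x_range[(site, trt)]
                x = np.linspace(lo, hi, 200)
                prefix = f"{site}|{trt}|"
                idx = [i for i, nm in enumerate(tf.coef_names) if nm.startswith(prefix)]
                V = x[:, None] ** np.arange(len(idx))
                eta = V @ tf.coef[idx]
                se = np.sqrt(np.einsum("ij,jk,ik->i", V, tf.cov[np.ix_(idx, idx)], V))
                ax.plot(x, expit(eta), label=f"pH {trt}")
                ax.fill_between(x, expit(eta - 1.96 * se), expit(eta + 1.96 * se), alpha=0.2)
            ax.set_title(site)
            ax.set_xlabel("log10 sperm/ul")
        axes[0][0].set_ylabel("total fertilization")
        axes[0][-1].legend(fontsize=7)
        p = out / "fertilization_curves.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        created.append(p)

    if metrics_df is not None and len(metrics_df):
        sites = sorted(metrics_df.site.unique())
        metrics = sorted(metrics_df.metric.unique())
        fig, axes = plt.subplots(len(metrics), len(sites),
                                 figsize=(3.2 * len(sites), 2.2 * len(metrics)),
                                 squeeze=False, sharex="col")
        for i, metric in enumerate(metrics):
            for j, site in enumerate(sites):
                ax = axes[i][j]
                sub = metrics_df[(metrics_df.site == site)
                                 & (metrics_df.metric == metric)
                                 & metrics_df.attainable
                                 & metrics_df.estimate.notna()]
                if not len(sub):
                    ax.text(0.5, 0.5, "no estimable metrics", ha="center",
                            transform=ax.transAxes, fontsize=8)
                    continue
                ys = np.arange(len(sub))
                xerr = [np.clip(sub.estimate - sub.lo95, 0, None),
                        np.clip(sub.hi95 - sub.estimate, 0, None)]
                ax.errorbar(sub.estimate, ys, xerr=xerr, fmt="o", capsize=3)
                ax.set_yticks(ys, [str(t) for t in sub.treatment])
                ax.set_xscale("log")
                if i == 0:
                    ax.set_title(site)
                if j == 0:
                    ax.set_ylabel(metric)
        p = out / "metric_estimates.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        created.append(p)

    if posterior is not None:
        pop = posterior.population
        params = [p_ for p_ in ("beta", "delta") if (pop.parameter == p_).any()]
        fig, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 3),
                                 squeeze=False)
        for ax, param in zip(axes[0], params):
            sub = pop[pop.parameter == param]
            ys = np.arange(len(sub))
            ax.errorbar(sub["median"], ys,
                        xerr=[sub["median"] - sub["q2.5"], sub["q97.5"] - sub["median"]],
                        fmt="o", capsize=3)
            ax.set_yticks(ys, [f"{s} {t}" for s, t in zip(sub.site, sub.treatment)])
            ax.set_xscale("log")
            ax.set_title(param)
        p = out / "posterior_intervals.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        created.append(p)
    return created
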