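# fertdyn

Analysis pipeline for sea-urchin fertilization trials under experimental
seawater-pH treatments: trial scoring, seawater CO₂-system chemistry, a
mechanistic fertilization-kinetics model with hierarchical Bayesian
inference, and a flexible dose-response analysis with numerically solved
sperm-requirement metrics and parametric-bootstrap contrasts. A synthetic-
data generator reproduces the statistical structure of the experimental
design so every stage is testable without raw data.

## Who this is for

Researchers analysing gamete-exposure experiments in broadcast spawners
(urchins and other echinoderms) who need to separate two mechanistic
explanations for a pH effect on fertilization — a change in the sperm–egg
interaction rate versus a change in the polyspermy-block rate — and to
quantify how far pH shifts the fertilization function along the sperm-
concentration axis.

## The models

**Scoring.** Per vial, TF = (scored − unfertilized)/scored; among
fertilized eggs AbnF = (tight membrane + abnormal cleavage)/fertilized;
NF = TF·(1 − AbnF).

**Kinetics.** Eggs at concentration E_T meet sperm S(τ) = S₀e^(−(βE_T+r)τ)
for t = 30 s. Unfertilized eggs are fertilized at rate βγS; singly
fertilized eggs either complete a polyspermy block (rate δ → normal) or are
hit again first (rate βγS → polyspermic). The expected normal fraction

E_N(t)/E_T = δ∫₀ᵗ βγS₀ e^(−B(τ)) (e^(−(βE_T+r)τ) − e^(−δτ))/(δ − βE_T − r) dτ,
  B(τ) = βγS₀(1 − e^(−(βE_T+r)τ))/(βE_T + r)

is evaluated by composite Gauss–Legendre quadrature, with an adaptive ODE
integration as independent oracle. Site × treatment means of (β, δ, γ) with
pair-level heterogeneity are estimated in a hierarchical Bayesian model
with a beta-binomial likelihood; treatment effects are reported as percent
declines in β̄ with 95% credible sets and posterior decline probabilities.

**Dose-response.** logit TF and logit AbnF are cubic polynomials of
log₁₀(sperm/µl) per site × treatment cell, with pair and treatment-within-
pair random intercepts plus an observation-level Gaussian logit term
(overdispersion), fitted by Laplace ML. From the NF curve the package
solves S_NF50, S_OptNF and S_AbnF25 (sperm/µl to reach 50% NF, the NF
peak, and 25% AbnF) and bootstraps CIs and within-site treatment contrasts
(Bonferroni α = 0.05/3).

**Chemistry.** pH_T + total alkalinity (+ S, T) → DIC, pCO₂, CO₃²⁻ and
aragonite saturation, with Mehrbach-refit carbonic-acid constants and
CO2SYS-default ancillary constants.

## Worked example

Simulate the single-site design (12 pairs × 3 pH treatments × 8 serial
dilutions × 200 scored embryos) with a true 46% decline in the sperm–egg
interaction rate at pH 7.76, fit both dose-response curves, and solve the
sperm-requirement metrics:

```python
from fertdyn import (SimulationConfig, ExperimentDesign, simulate_trials,
                     fit_glmm, GLMMSpec, bootstrap_contrasts)

design = ExperimentDesign(sites=(("SB", 12, ("8.03", "7.87", "7.76")),))
truth = {("SB", "7.76"): {"beta": 3e-4 * 0.54}}   # 46% lower interaction rate
records, _ = simulate_trials(SimulationConfig(design=design, truth=truth), seed=11)

tf = fit_glmm(records, GLMMSpec(response="TF"))
ab = fit_glmm(records, GLMMSpec(response="AbnF"))
metrics, contrasts = bootstrap_contrasts(tf, ab, n_boot=1000, seed=1)
print(metrics[metrics.metric == "S_OptNF"]
      [["treatment", "estimate", "lo95", "hi95"]].round(0).to_string(index=False))
print(contrasts[contrasts.metric == "S_OptNF"]
      [["treatment_a", "treatment_b", "p_value", "significant"]].round(4)
      .to_string(index=False))
```

```
treatment  estimate     lo95      hi95
     7.76   45111.0  16345.0  197142.0
     7.87    3653.0   3080.0    4288.0
     8.03    3864.0   3216.0    4610.0
treatment_a treatment_b  p_value  significant
       7.76        7.87   0.0020         True
       7.76        8.03   0.0020         True
       7.87        8.03   0.6813        False
```

The optimal-fertilization sperm concentration at the reduced-β treatment
is right-shifted by roughly an order of magnitude (more sperm needed for
the same outcome), and only the contrasts against that treatment are
significant at the Bonferroni-adjusted α = 0.017 — the qualitative
signature of a sperm-side pH effect. The hierarchical model quantifies it
mechanistically:

```python
from fertdyn import fit_hierarchical, HierModelConfig, decline_summary
post = fit_hierarchical(records, HierModelConfig(), seed=5)
ds = decline_summary(post, "7.76", "8.03")
```

On a replicate of this design this yields a posterior median decline in β̄
of ~45% with a wide 95% credible set and a decline probability of ~0.8–0.95
(the exact numbers vary by simulation seed; coverage of the true 46% is
verified in the test suite over ten replicates).

Seawater chemistry for a low-pH treatment condition:

```python
from fertdyn import solve_carbonate
state = solve_carbonate(7.61, 2245, 33.0, 14.8)
print(f"pCO2 = {state.pCO2:.0f} uatm, omega_a = {state.omega_a:.2f}")
# pCO2 = 1202 uatm, omega_a = 0.93
```

At pH_T 7.61 the treatment water is ~1,200 µatm pCO₂ and undersaturated
with respect to aragonite (Ω_a < 1).

## Command line

```bash
fertdyn simulate --seed 42 --out trials.csv --truth truth.csv
fertdyn score --trials trials.csv --out scored.csv
fertdyn carbonate --ph 8.01 --alk 2227 --sal 33 --temp 15
fertdyn metrics --trials trials.csv --boot 1000 --seed 7 --out metrics.csv
fertdyn fit-kinetics --trials trials.csv --seed 7 --out posterior/
fertdyn regime --series ph_series.csv --threshold 7.80
fertdyn run --config pipeline.yaml --out results/
```

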