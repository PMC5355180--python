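# Methods

`fertdyn` analyses sea-urchin fertilization-trial data collected under
controlled seawater-pH treatments. This note describes the models, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Trial scoring

Each vial exposes ~1,000 eggs to one step of a serial 1:10 sperm dilution
for a 30-s contact window; 200 embryos are scored into four categories
(unfertilized; tight fertilization membrane; normal envelope with unequal
cleavage; normal). Three per-vial proportions follow:

- TF = (scored − unfertilized) / scored,
- AbnF = (tight + abnormal cleavage) / (scored − unfertilized),
- NF = TF · (1 − AbnF).

AbnF is undefined when nothing fertilized; such vials carry an explicit
flag and never enter abnormal-fertilization fits. Sperm concentration is
defined at the moment of egg addition (post-serial-dilution, before the
egg-suspension and stop-solution volumes), a constant convention that
cancels in every comparison. Dose-response fits are restricted to the open
windows 1 < sperm/µl < 2×10⁵ (TF) and 10² < sperm/µl < 2×10⁷ (AbnF),
outside of which the response is uniformly 0 or 100% and induces
underdispersion.

## Seawater CO₂-system solver

From pH on the total scale, total alkalinity, salinity and temperature the
solver computes DIC from the alkalinity balance (carbonate, borate, water,
free H⁺, bisulfate, fluoride; no nutrient terms, 0 dbar), then pCO₂,
carbonate ion and aragonite saturation. Carbonic-acid constants are the
Mehrbach measurements refit by Dickson & Millero (seawater scale, converted
to total); ancillary constants follow the de-facto CO2SYS defaults (Weiss
K₀; Dickson KB, KS; Millero KW; Perez & Fraga KF; Mucci aragonite Ksp;
Uppström borate; calcium proportional to salinity). pH from (DIC, A_T) is a
bracketed monotone root solve on pH ∈ [2, 12] at machine-precision relative
tolerance; the 25 °C-to-in-situ conversion conserves DIC. The solver
reproduces the ten published treatment-chemistry means for this experiment
within 1.5% (tested at 5%, which also covers the means-of-nonlinear-
function caveat).

## Fertilization kinetics

The mechanistic model tracks egg classes during the contact window: with
sperm depleted as S(τ) = S₀·e^(−aτ), a = βE_T + r, an unfertilized egg is
fertilized at rate βγS(τ); a singly fertilized egg either completes its
polyspermy block (rate δ, becoming a normal fertilization) or receives a
second sperm first (rate βγS(τ), becoming polyspermic). Parameters: β
(sperm–egg interaction rate, µl·sperm⁻¹·s⁻¹), γ (dimensionless
acceptability × fertilizable-surface product, truncated to (0.0001, 0.15)),
δ (block rate, s⁻¹), r (sperm viability decay, 0.0003 s⁻¹, fixed), E_T
(egg concentration, default 1,000 eggs / 23 ml = 0.0435 eggs/µl), t
(contact time, default 30 s).

The expected normal fraction has a single-integral form,

E_N(t)/E_T = δ ∫₀ᵗ βγS₀ e^(−B(τ)) (e^(−aτ) − e^(−δτ))/(δ − a) dτ,
B(τ) = βγS₀(1 − e^(−aτ))/a,

evaluated by composite Gauss–Legendre quadrature on geometrically graded
panels of [0, t] (ratio 4, 14 panels by default), which resolves the
fertilization transient at any sperm density; the per-panel order doubles
until successive estimates agree within 10⁻⁸. An adaptive stiff ODE
integration of the full kinetic system is the independent oracle; the two
agree to better than 10⁻⁵ relative over a wide parameter grid (typically
10⁻¹²). The same rate βγS governs first and second fertilizations (the
model has a single acceptability product). Eggs fertilized but not yet
blocked at time t ("pending") are not counted in E_N; the generator can
score them either way (below). The δ→∞ limit is the classic monospermy
expression 1 − e^(−B(t)). Setting r = 0 changes predicted proportions by
less than 10⁻³ in absolute terms at t = 30 s; the relative change is ≈ rt/2
≈ 4.5×10⁻³ by the model's own algebra, which is why the decay is treated
as negligible and fixed rather than estimated. δ = 0 is allowed as the
meaningful degenerate case in which no outcome is ever scored normal.

## Hierarchical Bayesian estimation

For every site × treatment cell the model estimates population log-means of
β and δ and a mean γ, with pair-level heterogeneity: log β_i and log δ_i
are normal around the cell means (shared spreads σ_β, σ_δ), γ_i is
truncated-normal on (0.0001, 0.15) around the cell mean γ̄ (spread σ_γ);
an option shares one γ per pair around a site-level mean instead. Vial
counts of normal outcomes are beta-binomial with mean given by the forward
model and precision λ (shape parameters λp, λ(1−p)), so λ → ∞ recovers the
binomial. Default priors are vague on the design's scales: log β̄ ~
N(log 10⁻⁴, 3), log δ̄ ~ N(log 0.1, 3), γ̄ ~ U(0.0001, 0.15), σ_β, σ_δ ~
Half-N(1), σ_γ ~ Half-N(0.05), λ ~ Half-N(500); all overridable.

The posterior is sampled by adaptive Metropolis-within-Gibbs with a
non-centered parameterisation for β and δ. Because a 30-s trial identifies
β and γ essentially only through their product, plain coordinate updates
mix along the β–γ ridge diffusively; the sampler therefore adds
(a) cell-level ridge moves (shift log β̄, rescale the cell's γs oppositely),
(b) a γ̄ independence jump across its whole uniform support with the same
compensation, (c) a global scale move rescaling every γ, γ̄ and σ_γ against
all log β̄ (preserving every z-score and every βγ product), and
(d) ASIS/interweaving moves that re-express the hierarchy in centered form
to update the cell means and spreads with the realised pair rates held
fixed (curing the funnel). Step sizes adapt during warmup only (Robbins–
Monro, target acceptance 0.35); defaults are 2 chains × 800 warmup + 800
draws. Split-R̂ and bulk/tail ESS (ArviZ) are reported for all population
parameters; a fit with R̂ > 1.05 or ESS < 100 is flagged, not silently
returned.

All β and δ estimates are marginal over the wide γ posterior. One known
mixing limitation remains: the pair-level spread of the identified product
βγ divides non-identifiably between σ_β and σ_γ, so σ_β retains long
autocorrelation times and short chains are flagged by the diagnostics even
when the scientifically relevant cell means and treatment contrasts have
adequate ESS. Recovery behaviour is verified by simulation: at the study's
design size, 95% credible intervals for the percent decline in β̄ cover a
true 46% decline in ≥ 8/10 replicates. Under the population null the
per-dataset decline probability honestly tracks the dataset's realised
pair-mean contrast (sd ≈ 0.12 on the log scale at 12 pairs), so it is its
average over replicate null datasets that sits at 0.5; every null
dataset's 95% credible set contains zero decline. Decline summaries are computed per draw as
100·(1 − β̄_trt/β̄_ref), with ties counted half toward the decline
probability.

## Dose-response curves and sperm-requirement metrics

TF and AbnF are modelled on the logit scale as cubic polynomials of
log₁₀ sperm concentration (raw powers; the closed-form identities below
depend on this basis), with fixed effects either per site × treatment cell
(cell-means coding, used for metrics — the incomplete factorial never
forces extrapolated cells) or factorial coding (used for term tests).
Random intercepts enter by pair and by treatment-within-pair, plus an
observation-level Gaussian logit term for overdispersion. Fitting is
maximum likelihood under the Laplace approximation (joint damped Newton
over fixed + random effects inside a Nelder–Mead search over the log
standard deviations), matching lme4's default objective; coefficients, SEs
and variance components agree with `glmer` to ~1% on shared test data.
AbnF fits weight by the fertilized count (the proportion's own
denominator) and use only vials with defined AbnF. Random polynomial
coefficients by pair are not implemented; at 10–12 pairs per site random
intercepts are what the data can identify.

Likelihood-ratio tests follow a fixed nesting scheme: each main effect is
tested in a model containing no interaction involving it; each two-way
interaction in the model with all two-ways but no three-way; the three-way
against the full model. Degrees of freedom are rank differences of the
pivoted-QR-reduced design matrices, which handles the incomplete site ×
treatment factorial (each site saw only three of the four nominal pH
levels) automatically.

From a TF/AbnF curve pair, NF(x) = TF(x)·(1 − AbnF(x)) and three metrics
are solved numerically: S_NF50 (smallest ascending crossing of NF = 0.5),
S_OptNF (argmax of NF, with the attained peak NF), and S_AbnF25 (smallest
ascending crossing of AbnF = 0.25). Searches are confined to each curve's
fitted concentration range (cubics produce spurious distal roots; metrics a
curve never attains are flagged, not extrapolated); crossings are refined
by Brent's method to |Δlog₁₀| < 10⁻⁴ and the peak by bounded scalar
minimisation. NF metrics use the TF curve's range, within which the AbnF
curve is evaluated as fitted.

Uncertainty comes from a fully parametric bootstrap: 1,000 fixed-effect
vectors drawn from the fitted multivariate normal (eigenvalue-clipped
covariance), independently for TF and AbnF; metrics recomputed per draw on
a dense grid with linear interpolation at crossings (grid error far below
Monte-Carlo error); 95% percentile intervals; pairwise within-site contrast
p-values as twice the smaller tail proportion of the bootstrap difference
with an add-one correction, Bonferroni-grouped at α = 0.05/3 with compact
letter displays. A zero-variance difference distribution returns p = 1 by
convention. Draws in which a metric is unattainable are recorded as
missing; intervals with > 20% missing draws are flagged unstable. Under a
null with identical treatment coefficients and covariance at the magnitude
real fits produce, contrast p-values are uniform (KS-tested); heavily
inflated covariances add the percentile bootstrap's known curvature-induced
conservatism.

Variance explained is partitioned on the logit scale: marginal R² is the
fixed-effect linear-predictor variance over the data against the total of
fixed + grouping-random + observation-level + distribution-specific (π²/3)
variance; conditional R² adds the grouping random effects, with the
observation-level term counted as residual. Per-term fixed shares use the
variance of the term's partial linear predictor; because terms can be
correlated, shares are not constrained to sum to the marginal R².

## Synthetic-data generator

The generator emulates the study design: sites FC (12 pairs), BMR (10) and
SB (12), three pH treatments per site (FC/BMR: 8.03, 7.76, 7.61; SB: 8.03,
7.87, 7.76), eight serial 1:10 dilutions from a 2×10⁶ sperm/µl stock
(first vial 2×10⁵ sperm/µl), 1,000 eggs per vial, 30 s contact, 200
scored. Pair-level rates are drawn from the hierarchical truth (lognormal
β, δ; truncated-normal γ), per-vial outcome probabilities come from the
ODE solution of the kinetics system, and the three scoring categories are
sampled Dirichlet-multinomially with concentration λ·p (marginally
beta-binomial per category, matching the fitting likelihood). Default
truth β = 3×10⁻⁴ µl·sperm⁻¹·s⁻¹, γ = 0.05, δ = 0.2 s⁻¹, σ = 0.3 on the
log rates, σ_γ = 0.01, λ = 100 — chosen so TF traverses 0→1 across the
dilution range, as in the experiment; these are generator defaults, not
estimates of any real dataset. Eggs still unblocked at 30 s are scored
normal by default (a raised envelope without visible abnormality is scored
normal at the bench); a toggle scores them abnormal instead, which is also
the configuration that makes the generator exactly match the fitting
likelihood's definition of a normal outcome. The tight-membrane vs
abnormal-cleavage split of the polyspermic fraction is a nuisance
parameter (default 0.5) drawn from a dedicated RNG stream so it cannot
perturb any pooled statistic.

What the generator does not emulate: day/run structure and technical
replication, egg-size variation, non-polyspermic abnormality mechanisms,
delayed-cleavage misclassification, and any pH dependence of scoring
quality. Passing recovery tests on these data therefore demonstrates
internal consistency of the pipeline under the model's own assumptions,
not robustness to the full messiness of bench data.

## Pipeline, configuration, reproducibility

A single structured config drives simulate/load → score → carbonate table →
dose-response fits + bootstrap metrics → optional hierarchical fit →
figures; every output lands in a manifest with SHA-256 checksums. All
randomness flows from explicit seeds (the MCMC is bit-reproducible given
seed and settings; the posterior is invariant to vial ordering). pH-regime
statistics (mean, CV, fraction of observations at or below a threshold,
default pH_T 7.80, inclusive) summarise sensor time series.

## Problem sizes used in the shipped checks

The shipped test suite runs the quadrature/ODE comparison on a 135-point
parameter grid; hierarchical recovery as 10 replicates of the single-site
design (12 pairs × 3 treatments × 8 dilutions × 200 eggs) at 2 chains ×
800/800; bootstrap calibration as 200 replicates × 400 draws; and the
metric solver against 10⁵-point brute-force grids. These sizes were chosen
to give stable pass/fail behaviour at interactive runtimes; all are
configurable upward.
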