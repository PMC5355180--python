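import math

import numpy as np
import pytest
from scipy.special import expit

from fertdyn.curve_metrics import (
    BONFERRONI_ALPHA,
    CurveError,
    FittedCurve,
    GLMMSpec,
    bootstrap_contrasts,
    fit_glmm,
    lrt_table,
    solve_metrics,
    variance_partition,
)
from fertdyn.synthetic_data import SimulationConfig, simulate_trials
from fertdyn.trial_model import ExperimentDesign


def _curve(cells_coefs, x_range=(0.5, 5.0), response="TF", cov=None, degree=3):
    """Hand-built cell-means FittedCurve for solver tests."""
    names, coef = [], []
    for (site, trt), c in cells_coefs.items():
        for k, v in enumerate(c):
            names.append(f"{site}|{trt}|x{k}")
            coef.append(v)
    coef = np.array(coef, float)
    p = len(coef)
    return FittedCurve(
        response=response, coding="cells", degree=degree, coef=coef,
        coef_names=names, cov=np.zeros((p, p)) if cov is None else cov,
        varcomps={}, loglik=0.0, n_obs=0,
        cells=sorted(cells_coefs), x_range={c: x_range for c in cells_coefs},
    )


class TestSolveMetrics:
    def test_linear_logit_closed_form(self):
        """For TF logit a + b*x with no abnormal fertilization,
        S_NF50 = 10^(-a/b) exactly."""
        a, b = -4.0, 1.6
        tf = _curve({("SB", "8.03"): [a, b, 0.0, 0.0]})
        ests = solve_metrics(tf, None, "SB", "8.03")
        assert math.log10(ests["S_NF50"].sperm_conc) == pytest.approx(-a / b, abs=1e-6)

    def test_peak_matches_dense_grid(self, rng):
        """Solver argmax agrees with brute force on unimodal cubics."""
        for _ in range(20):
            c_tf = [rng.uniform(-8, -4), rng.uniform(2, 5),
                    rng.uniform(-0.5, 0.2), rng.uniform(-0.3, -0.05)]
            c_ab = [rng.uniform(-9, -6), rng.uniform(0.5, 2.0), 0.0, 0.0]
            tf = _curve({("SB", "8.03"): c_tf})
            ab = _curve({("SB", "8.03"): c_ab}, response="AbnF")
            est = solve_metrics(tf, ab, "SB", "8.03")["S_OptNF"]
            x = np.linspace(0.5, 5.0, 100_001)
            nf = expit(np.polyval(c_tf[::-1], x)) * (1 - expit(np.polyval(c_ab[::-1], x)))
            x_brute = x[np.argmax(nf)]
            assert math.log10(est.sperm_conc) == pytest.approx(x_brute, abs=4.5e-5)

    def test_unattainable_metrics_flagged(self):
        """Flat 10% abnormal fertilization never reaches 25%; a TF curve
        stuck below 50% NF has no S_NF50."""
        low = _curve({("SB", "8.03"): [math.log(0.1 / 0.9), 0.0, 0.0, 0.0]},
                     response="AbnF")
        tf = _curve({("SB", "8.03"): [-4.0, 1.6, 0.0, 0.0]})
        ests = solve_metrics(tf, low, "SB", "8.03")
        assert not ests["S_AbnF25"].attainable
        assert math.isnan(ests["S_AbnF25"].sperm_conc)
        flat_tf = _curve({("SB", "8.03"): [-2.0, 0.1, 0.0, 0.0]})
        ests2 = solve_metrics(flat_tf, None, "SB", "8.03")
        assert not ests2["S_NF50"].attainable

    def test_unit_equivariance(self):
        """Re-expressing sperm per ml instead of per ul shifts every log10
        metric by exactly 3."""
        c = [-5.0, 3.0, 0.1, -0.15]
        tf = _curve({("SB", "8.03"): c})
        est = solve_metrics(tf, None, "SB", "8.03")
        # per-ml scale: u = x + 3, so q(u) = p(u - 3), Taylor shift at -3
        p = np.poly1d(c[::-1])
        shift = [np.polyder(p, k)(-3.0) / math.factorial(k) for k in range(4)]
        tf_ml = _curve({("SB", "8.03"): shift}, x_range=(0.5 + 3, 5.0 + 3))
        est_ml = solve_metrics(tf_ml, None, "SB", "8.03")
        for m in ("S_NF50", "S_OptNF"):
            assert math.log10(est_ml[m].sperm_conc) == pytest.approx(
                math.log10(est[m].sperm_conc) + 3.0, abs=1e-4)

    def test_nf_bounded_by_tf(self):
        c_tf = [-5.0, 3.0, 0.0, -0.2]
        c_ab = [-6.0, 1.5, 0.0, 0.0]
        tf = _curve({("SB", "8.03"): c_tf})
        ab = _curve({("SB", "8.03"): c_ab}, response="AbnF")
        x = np.linspace(0.5, 5.0, 100)
        nf = expit(np.polyval(c_tf[::-1], x)) * (1 - expit(np.polyval(c_ab[::-1], x)))
        assert np.all(nf <= expit(np.polyval(c_tf[::-1], x)) + 1e-12)


class TestBootstrap:
    def test_bonferroni_alpha(self):
        assert BONFERRONI_ALPHA == pytest.approx(0.05 / 3, abs=1e-6)

    def test_zero_covariance_degenerate(self):
        """All draws identical: zero-width CIs, contrast p-values 1."""
        cells = {("SB", "8.03"): [-4.0, 1.6, 0.0, 0.0],
                 ("SB", "7.76"): [-4.5, 1.6, 0.0, 0.0]}
        tf = _curve(cells)
        mdf, cdf = bootstrap_contrasts(tf, None, n_boot=200, seed=0)
        nf50 = mdf[mdf.metric == "S_NF50"]
        assert np.allclose(nf50.lo95, nf50.estimate, rtol=1e-3)
        assert np.allclose(nf50.hi95, nf50.estimate, rtol=1e-3)
        assert (cdf[cdf.metric == "S_NF50"].p_value == 1.0).all()

    def test_ci_shrinks_with_covariance(self):
        cells = {("SB", "8.03"): [-4.0, 1.6, 0.0, 0.0]}
        wide = _curve(cells, cov=np.diag([0.04, 0.0, 0.0, 0.0]))
        narrow = _curve(cells, cov=np.diag([0.0004, 0.0, 0.0, 0.0]))
        w_m, _ = bootstrap_contrasts(wide, None, n_boot=400, seed=1)
        n_m, _ = bootstrap_contrasts(narrow, None, n_boot=400, seed=1)
        w = w_m[w_m.metric == "S_NF50"]
        n = n_m[n_m.metric == "S_NF50"]
        assert (w.hi95.iloc[0] - w.lo95.iloc[0]) > 3 * (n.hi95.iloc[0] - n.lo95.iloc[0])

    def test_contrast_symmetry(self):
        """p-values do not depend on the order of the treatment pair."""
        cells = {("SB", "8.03"): [-4.0, 1.6, 0.0, 0.0],
                 ("SB", "7.76"): [-4.6, 1.6, 0.0, 0.0]}
        cov = np.kron(np.eye(2), np.diag([0.02, 0.005, 0.0, 0.0]))
        tf = _curve(cells, cov=cov)
        _, cdf = bootstrap_contrasts(tf, None, n_boot=500, seed=3)
        row = cdf[(cdf.metric == "S_NF50")].iloc[0]
        assert {row.treatment_a, row.treatment_b} == {"8.03", "7.76"}
        assert 0.0 < row.p_value <= 1.0


class TestFitAndPartition:
    def test_fit_recovers_simulated_dose_response(self, one_site_records):
        records, _ = one_site_records
        curve = fit_glmm(records, GLMMSpec(response="TF"))
        assert curve.converged
        # TF rises through 50% within the analysis window in every cell
        for site, trt in curve.cells:
            lo, hi = curve.x_range[(site, trt)]
            x = np.linspace(lo, hi, 200)
            tf = expit(curve.logit_curve(site, trt, x))
            assert tf.min() < 0.5 < tf.max()

    def test_degenerate_response_errors(self, one_site_records):
        records, _ = one_site_records
        from dataclasses import replace
        from fertdyn.trial_model import VialCounts
        saturated = [
            replace(r, counts=VialCounts(r.counts.n_scored, 0, 0, 0))
            for r in records
        ]
        with pytest.raises(Exception, match="separation|constant"):
            fit_glmm(saturated, GLMMSpec(response="TF"))

    def test_marginal_r2_closed_form(self, one_site_records):
        """With fixed-effect variance v and no random terms, marginal R2 is
        v / (v + pi^2/3)."""
        records, _ = one_site_records
        curve = fit_glmm(records, GLMMSpec(response="TF", random_pair=False,
                                           random_pair_treatment=False, olre=False))
        part = variance_partition(curve, records)
        v = part.fixed_total
        assert part.marginal_r2 == pytest.approx(v / (v + math.pi**2 / 3), rel=1e-10)
        assert part.marginal_r2 <= part.conditional_r2

    def test_random_component_halves_explained_share(self, one_site_records):
        """A random variance equal to the fixed variance makes the fixed
        share exactly half of the explained (conditional) variance."""
        records, _ = one_site_records
        curve = fit_glmm(records, GLMMSpec(response="TF", random_pair=False,
                                           random_pair_treatment=False, olre=False))
        curve.varcomps = {"pair": curve.coef @ np.zeros_like(curve.coef)}
        part0 = variance_partition(curve, records)
        curve.varcomps = {"pair": part0.fixed_total}
        part1 = variance_partition(curve, records)
        assert part1.marginal_r2 / part1.conditional_r2 == pytest.approx(0.5, rel=1e-10)

    def test_subset_not_found_errors(self, one_site_records):
        records, _ = one_site_records
        curve = fit_glmm(records, GLMMSpec(response="TF", random_pair=False,
                                           random_pair_treatment=False, olre=False))
        with pytest.raises(CurveError, match="matches no coefficients"):
            variance_partition(curve, records, {"bogus": ["nothere"]})


@pytest.fixture(scope="module")
def small_records():
    design = ExperimentDesign(
        sites=(("FC", 3, ("8.03", "7.76", "7.61")),
               ("SB", 3, ("8.03", "7.87", "7.76")))
    )
    records, _ = simulate_trials(SimulationConfig(design=design), seed=5)
    return records


class TestLrtScheme:
    def test_nesting_scheme_and_sperm_dominance(self, small_records):
        """Sperm concentration dominates; the nesting scheme matches the
        stated contrasts (mains tested without containing interactions,
        two-ways without the three-way)."""
        results = lrt_table(small_records, "TF", degree=2)
        by_term = {r.term: r for r in results}
        assert by_term["sperm"].p_value < 1e-6
        assert all(r.chisq >= 0 and r.df >= 1 for r in results)
        site_test = by_term["site"]
        assert "site:sperm" not in site_test.full_terms
        assert "site:ph" not in site_test.full_terms
        assert "ph:sperm" in site_test.full_terms
        two_way = by_term["site:sperm"]
        assert "site:ph:sperm" not in two_way.full_terms
        three_way = by_term["site:ph:sperm"]
        assert set(three_way.null_terms) == set(three_way.full_terms) - {"site:ph:sperm"}
        # incomplete factorial: site x ph has fewer estimable df than a
        # complete cross would give
        assert by_term["site:ph"].df < 6

    def test_null_threeway_not_rejected_wildly(self, small_records):
        """With no true three-way effect the three-way test should not
        produce an extreme statistic."""
        results = lrt_table(small_records, "TF", degree=2)
        three = [r for r in results if r.term == "site:ph:sperm"][0]
        assert three.p_value > 1e-4

    def test_threeway_type1_calibration(self):
        """Under a correctly specified binomial null (every cell shares one
        cubic dose-response, no random effects) the three-way interaction
        p-values are uniform across simulation replicates (KS at 1%)."""
        from scipy.special import expit
        from scipy.stats import kstest
        from fertdyn.trial_model import TrialRecord, VialCounts

        rng = np.random.default_rng(606)
        coefs = np.array([-6.0, 3.5, 0.2, -0.12])
        x = np.linspace(0.5, 4.2, 6)
        p_true = expit(np.polyval(coefs[::-1], x))
        cells = [("FC", "8.03"), ("FC", "7.76"), ("SB", "8.03"), ("SB", "7.76")]
        pvals = []
        for rep in range(100):
            records = []
            for site, trt in cells:
                for pair in (1, 2):
                    for i, (conc_x, p) in enumerate(zip(x, p_true)):
                        y = int(rng.binomial(200, p))
                        records.append(TrialRecord(
                            site=site, pair_id=f"{site}{pair}",
                            ph_treatment=trt, ph_measured=float(trt),
                            vial_index=i + 1, sperm_conc=10.0**conc_x,
                            counts=VialCounts(200, 200 - y, 0, 0),
                        ))
            results = lrt_table(records, "TF", degree=3, random_pair=False,
                                random_pair_treatment=False, olre=False)
            three = [r for r in results if r.term == "site:ph:sperm"][0]
            pvals.append(three.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01
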