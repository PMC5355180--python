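import io

import numpy as np
import pytest

from fertdyn.curve_metrics import GLMMSpec, fit_glmm, solve_metrics
from fertdyn.kinetics import KineticsParams, normal_fraction
from fertdyn.synthetic_data import (
    SimulationConfig,
    betabinomial_sample,
    generate_design,
    simulate_trials,
)
from fertdyn.trial_model import ExperimentDesign, records_to_frame, score_vial


class TestDesign:
    def test_default_design_size(self):
        layout = generate_design(SimulationConfig())
        assert len(layout) == (12 + 10 + 12) * 3 * 8 == 816

    def test_minimal_design(self):
        design = ExperimentDesign(sites=(("SB", 1, ("8.03",)),))
        layout = generate_design(SimulationConfig(design=design))
        assert len(layout) == 8

    def test_four_steps_span_three_decades(self):
        design = ExperimentDesign(sites=(("SB", 1, ("8.03",)),), n_steps=4)
        layout = generate_design(SimulationConfig(design=design))
        concs = sorted(layout.sperm_conc.unique())
        assert len(concs) == 4
        assert np.log10(concs[-1] / concs[0]) == pytest.approx(3.0, abs=1e-12)

    def test_concentrations_strictly_decreasing_with_vial_index(self):
        layout = generate_design(SimulationConfig())
        for _, sub in layout.groupby(["site", "pair_id", "ph_treatment"]):
            concs = sub.sort_values("vial_index").sperm_conc.to_numpy()
            assert np.all(np.diff(concs) < 0)


class TestSimulateTrials:
    def test_same_seed_byte_identical_csv(self):
        design = ExperimentDesign(sites=(("SB", 2, ("8.03", "7.76")),))
        cfg = SimulationConfig(design=design)
        outputs = []
        for _ in range(2):
            records, _ = simulate_trials(cfg, seed=99)
            buf = io.StringIO()
            records_to_frame(records).to_csv(buf, index=False)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_counts_sum_to_scored(self, one_site_records):
        records, _ = one_site_records
        for r in records:
            c = r.counts
            assert c.n_unfert + c.n_tight + c.n_abn_dev + c.n_normal == c.n_scored

    def test_truth_table_links_every_vial(self, one_site_records):
        records, truth = one_site_records
        assert len(truth) == len(records)
        assert {"beta", "gamma", "delta", "p_normal"} <= set(truth.columns)

    def test_mean_tf_tracks_forward_model_below_peak(self, one_site_records):
        """Sperm-limited regime: simulated mean TF is nondecreasing in S0
        and rises with the kinetics forward curve."""
        records, truth = one_site_records
        df = records_to_frame(records)
        df["tf"] = [score_vial(r.counts).tf for r in records]
        mean_tf = df.groupby("sperm_conc").tf.mean()
        limited = mean_tf[mean_tf.index <= 2e4]
        assert np.all(np.diff(limited.to_numpy()) >= -0.02)
        conc = mean_tf.index[np.argmin(np.abs(mean_tf.index - 2e3))]
        fwd = normal_fraction(KineticsParams(beta=3e-4, gamma=0.05, delta=0.2), conc)
        assert mean_tf.loc[conc] == pytest.approx(fwd, abs=0.15)

    def test_abnormal_split_never_affects_scored_statistics(self):
        """Eq.-style pooling: the tight-membrane vs abnormal-cleavage split
        is a nuisance; TF/AbnF/NF are identical for any split ratio."""
        design = ExperimentDesign(sites=(("SB", 2, ("8.03",)),))
        a, _ = simulate_trials(
            SimulationConfig(design=design, abn_tight_ratio=0.2), seed=5)
        b, _ = simulate_trials(
            SimulationConfig(design=design, abn_tight_ratio=0.9), seed=5)
        for ra, rb in zip(a, b):
            pa, pb = score_vial(ra.counts), score_vial(rb.counts)
            assert pa.tf == pb.tf and pa.nf == pb.nf
            assert (pa.abnf == pb.abnf) or (not pa.abnf_defined and not pb.abnf_defined)

    def test_missing_cell_truth_falls_back_to_default(self):
        cfg = SimulationConfig(truth={("SB", "7.76"): {"beta": 1e-4}})
        cell = cfg.cell_truth("SB", "7.76")
        assert cell["beta"] == 1e-4 and cell["gamma"] == 0.05
        assert cfg.cell_truth("FC", "8.03")["beta"] == 3e-4


class TestBetaBinomial:
    def test_boundary_probabilities(self, rng):
        assert betabinomial_sample(200, 0.0, 50.0, rng) == 0
        assert betabinomial_sample(200, 1.0, 50.0, rng) == 200

    def test_moments_match_closed_form(self, rng):
        n, p, lam = 200, 0.4, 50.0
        draws = np.array([betabinomial_sample(n, p, lam, rng) for _ in range(40_000)])
        assert draws.mean() == pytest.approx(n * p, rel=0.01)
        var = n * p * (1 - p) * (1 + (n - 1) / (lam + 1))
        assert draws.var() == pytest.approx(var, rel=0.05)

    def test_large_precision_recovers_binomial_variance(self, rng):
        """lambda = 1e6: empirical variance within 5% of binomial p(1-p)n."""
        n, p = 200, 0.4
        draws = np.array([betabinomial_sample(n, p, 1e6, rng) for _ in range(10_000)])
        assert draws.var() == pytest.approx(n * p * (1 - p), rel=0.05)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            betabinomial_sample(200, 1.5, 50.0, rng)
        with pytest.raises(ValueError):
            betabinomial_sample(200, 0.5, -1.0, rng)


class TestRightShiftSignature:
    def test_beta_decline_shifts_nf50_right(self):
        """Scaling true beta by 0.54 moves the estimated S_NF50 to higher
        sperm concentrations (the low-pH signature), replicate by replicate."""
        design = ExperimentDesign(sites=(("SB", 6, ("8.03",)),))
        spec = GLMMSpec(response="TF", random_pair=False,
                        random_pair_treatment=False, olre=False)
        shifted_right = 0
        n_rep = 6
        for rep in range(n_rep):
            base_cfg = SimulationConfig(design=design)
            low_cfg = SimulationConfig(
                design=design, truth={("SB", "8.03"): {"beta": 3e-4 * 0.54}})
            recs_base, _ = simulate_trials(base_cfg, seed=300 + rep)
            recs_low, _ = simulate_trials(low_cfg, seed=300 + rep)
            m_base = solve_metrics(fit_glmm(recs_base, spec), None, "SB", "8.03")
            m_low = solve_metrics(fit_glmm(recs_low, spec), None, "SB", "8.03")
            if m_low["S_NF50"].sperm_conc > m_base["S_NF50"].sperm_conc:
                shifted_right += 1
        assert shifted_right >= n_rep - 1
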