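import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fertdyn.trial_model import (
    ANALYSIS_WINDOWS,
    DilutionSeries,
    TrialRecord,
    TrialValidationError,
    VialCounts,
    dilution_concentrations,
    filter_analysis_window,
    frame_to_records,
    load_trials,
    score_vial,
    write_trials,
)


class TestScoreVial:
    @pytest.mark.parametrize(
        "counts,tf,abnf,nf",
        [
            ((200, 50, 10, 5), 0.75, 0.10, 0.675),
            ((100, 0, 0, 0), 1.0, 0.0, 1.0),
            ((200, 100, 100, 0), 0.5, 1.0, 0.0),
        ],
    )
    def test_proportions(self, counts, tf, abnf, nf):
        p = score_vial(VialCounts(*counts))
        assert p.tf == pytest.approx(tf)
        assert p.abnf == pytest.approx(abnf)
        assert p.nf == pytest.approx(nf)
        assert p.abnf_defined

    def test_all_unfertilized_flags_abnf_undefined(self):
        p = score_vial(VialCounts(200, 200, 0, 0))
        assert p.tf == 0.0
        assert not p.abnf_defined
        assert math.isnan(p.abnf)
        assert p.nf == 0.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(TrialValidationError, match="fertilized"):
            VialCounts(100, 90, 10, 5)
        with pytest.raises(TrialValidationError, match="n_unfert"):
            VialCounts(100, 150, 0, 0)
        with pytest.raises(TrialValidationError):
            VialCounts(100, -1, 0, 0)

    @given(
        n_unfert=st.integers(0, 50),
        n_tight=st.integers(0, 50),
        n_abn=st.integers(0, 50),
        n_normal=st.integers(1, 50),
        mult=st.integers(1, 5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_and_scale_invariance(self, n_unfert, n_tight, n_abn, n_normal, mult):
        """NF + TF*AbnF + (1-TF) = 1, and proportions ignore count scaling."""
        total = n_unfert + n_tight + n_abn + n_normal
        c = VialCounts(total, n_unfert, n_tight, n_abn)
        p = score_vial(c)
        if p.abnf_defined:
            assert p.nf + p.tf * p.abnf + (1 - p.tf) == pytest.approx(1.0)
        c2 = VialCounts(total * mult, n_unfert * mult, n_tight * mult, n_abn * mult)
        p2 = score_vial(c2)
        assert p2.tf == pytest.approx(p.tf)
        assert p2.nf == pytest.approx(p.nf)


class TestDilutionSeries:
    def test_geometric_series(self):
        series = DilutionSeries(hemocytometer_count=2e6, n_steps=8)
        concs = dilution_concentrations(series)
        expected = [2e6 * 0.1**k for k in range(1, 9)]
        assert concs == pytest.approx(expected, rel=1e-12)
        assert concs[0] == pytest.approx(2e5, rel=1e-12)
        assert concs[-1] == pytest.approx(2e-2, rel=1e-12)

    def test_single_step(self):
        series = DilutionSeries(hemocytometer_count=1e6, n_steps=1)
        assert dilution_concentrations(series) == pytest.approx([1e5], rel=1e-12)

    def test_volume_ratio_matches_nominal_factor(self):
        """2.3 ml into 23 ml total is exactly one 1:10 step."""
        by_volume = dilution_concentrations(
            DilutionSeries(hemocytometer_count=5e5, step_volume_ratio=2.3 / 23.0)
        )
        by_factor = [5e5 * 0.1**k for k in range(1, 9)]
        assert by_volume == pytest.approx(by_factor, rel=1e-14)

    def test_invalid_series(self):
        with pytest.raises(TrialValidationError):
            DilutionSeries(hemocytometer_count=-1.0)
        with pytest.raises(TrialValidationError):
            DilutionSeries(hemocytometer_count=1e6, n_steps=0)


def _record(conc, site="SB", trt="8.03", pair="SB01", vial=1):
    return TrialRecord(
        site=site, pair_id=pair, ph_treatment=trt, ph_measured=8.01,
        vial_index=vial, sperm_conc=conc,
        counts=VialCounts(200, 100, 5, 5),
    )


class TestAnalysisWindow:
    def test_response_specific_windows(self):
        records = [_record(c, vial=i + 1) for i, c in enumerate([0.5, 10, 1e5, 3e5])]
        tf_kept = filter_analysis_window(records, "TF")
        assert [r.sperm_conc for r in tf_kept] == [10, 1e5]
        ab_kept = filter_analysis_window(records, "AbnF")
        assert [r.sperm_conc for r in ab_kept] == [1e5, 3e5]

    def test_open_interval_bounds_excluded(self):
        lo, hi = ANALYSIS_WINDOWS["TF"]
        records = [_record(lo, vial=1), _record(hi, vial=2)]
        assert filter_analysis_window(records, "TF") == []

    def test_empty_and_idempotent(self):
        assert filter_analysis_window([], "TF") == []
        records = [_record(c, vial=i + 1) for i, c in enumerate([10, 1e4])]
        once = filter_analysis_window(records, "TF")
        assert filter_analysis_window(once, "TF") == once
        assert set(once) <= set(records)

    def test_unknown_response(self):
        with pytest.raises(ValueError, match="unknown response"):
            filter_analysis_window([], "NF50")


class TestCsvRoundTrip:
    def test_round_trip_identity(self, two_site_records, tmp_path):
        records, _ = two_site_records
        path = tmp_path / "trials.csv"
        write_trials(records, path)
        loaded = load_trials(path)
        assert loaded == list(records)

    def test_missing_column_named(self, two_site_records, tmp_path):
        records, _ = two_site_records
        path = tmp_path / "trials.csv"
        write_trials(records, path)
        df = pd.read_csv(path).drop(columns=["n_unfert"])
        with pytest.raises(TrialValidationError, match="n_unfert"):
            frame_to_records(df)

    def test_row_level_validation_reports_row(self, two_site_records, tmp_path):
        records, _ = two_site_records
        path = tmp_path / "trials.csv"
        write_trials(records, path)
        df = pd.read_csv(path, dtype={"site": str, "pair_id": str, "ph_treatment": str})
        df.loc[3, ["n_unfert", "n_tight", "n_abn_dev"]] = [150, 40, 40]
        with pytest.raises(TrialValidationError, match="row 3"):
            frame_to_records(df)

    def test_unknown_site_rejected(self):
        with pytest.raises(TrialValidationError, match="unknown site"):
            _record(10.0, site="XX")
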