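import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prepost_ma.data_model import Arm, MetaDataset, TrialArmSummary
from prepost_ma.fillin import (
    FillinError,
    InconsistentSummariesError,
    correlation_from_sds,
    fill_means,
    fill_sds_from_ses,
    impute_missing_correlations,
    impute_sdF_equals_sdB,
    run_fillin,
    sd_change_from_correlation,
    sd_from_se,
)
from prepost_ma.synthetic import aggregate_ipd, mask_summaries, simulate_ipd


class TestSdFromSe:
    def test_examples(self):
        assert sd_from_se(0.5, 16) == pytest.approx(2.0)
        assert sd_from_se(1.7, 1) == pytest.approx(1.7)
        assert sd_from_se(1.0, 2) == pytest.approx(math.sqrt(2))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(FillinError):
            sd_from_se(0.0, 10)
        with pytest.raises(FillinError):
            sd_from_se(-1.0, 10)


class TestCorrelationFromSds:
    def test_zero_change_variance_forces_r_one(self):
        assert correlation_from_sds(1.0, 1.0, 0.0) == pytest.approx(1.0)

    def test_symmetric_zero(self):
        assert correlation_from_sds(1.0, 1.0, math.sqrt(2)) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        assert correlation_from_sds(2.0, 3.0, 2.0) == pytest.approx(0.75)

    def test_clamp_just_above_one(self):
        # sd_B=2, sd_F=1: r = (5 - sd_CS^2)/4; choose sd_CS so r = 1 + 5e-9
        sd_cs = math.sqrt(5 - 4 * (1 + 5e-9))
        with pytest.warns(UserWarning, match="clamped"):
            r = correlation_from_sds(2.0, 1.0, sd_cs)
        assert r == 1.0

    def test_far_outside_is_error(self):
        with pytest.raises(InconsistentSummariesError):
            correlation_from_sds(1.0, 1.0, 10.0)


class TestSdChange:
    def test_perfect_correlation_zero_sd(self):
        assert sd_change_from_correlation(1.3, 1.3, 1.0) == pytest.approx(0.0)

    def test_independent(self):
        assert sd_change_from_correlation(1.0, 1.0, 0.0) == pytest.approx(math.sqrt(2))

    def test_round_trip_example(self):
        assert sd_change_from_correlation(2.0, 3.0, 0.75) == pytest.approx(2.0)

    @given(
        sd_b=st.floats(0.01, 100),
        sd_f=st.floats(0.01, 100),
        r=st.floats(-1.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, sd_b, sd_f, r):
        import warnings

        sd_cs = sd_change_from_correlation(sd_b, sd_f, r)
        if sd_cs > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # boundary |r|=1 may clamp
                back = correlation_from_sds(sd_b, sd_f, sd_cs)
            assert back == pytest.approx(r, abs=1e-12 * max(1.0, abs(r)) + 1e-9)


class TestStepOperations:
    def test_impute_sdF(self):
        rows = [
            TrialArmSummary("a", Arm.control, n=5, sd_B=2.0),
            TrialArmSummary("a", Arm.treatment, n=5, sd_B=3.0, sd_F=1.0),
        ]
        out = impute_sdF_equals_sdB(MetaDataset(rows))
        assert out.rows[0].sd_F == 2.0
        assert out.rows[1].sd_F == 1.0  # untouched

    def test_impute_sdF_both_missing_left_alone(self):
        rows = [
            TrialArmSummary("a", Arm.control, n=5),
            TrialArmSummary("a", Arm.treatment, n=5),
        ]
        out = impute_sdF_equals_sdB(MetaDataset(rows))
        assert out.rows[0].sd_F is None

    def test_fill_sds_from_ses(self):
        rows = [
            TrialArmSummary("a", Arm.control, n=16, se_B=0.5, se_F=0.25, se_CS=1.0),
            TrialArmSummary("a", Arm.treatment, n=4, se_B=1.0),
        ]
        out = fill_sds_from_ses(MetaDataset(rows))
        assert out.rows[0].sd_B == pytest.approx(2.0)
        assert out.rows[0].sd_F == pytest.approx(1.0)
        assert out.rows[0].sd_CS == pytest.approx(4.0)
        assert out.rows[1].sd_B == pytest.approx(2.0)

    def test_fill_means(self):
        rows = [
            TrialArmSummary("a", Arm.control, n=5, mean_B=10.0, mean_F=12.0),
            TrialArmSummary("a", Arm.treatment, n=5, mean_B=10.0, mean_CS=-1.0),
        ]
        out = fill_means(MetaDataset(rows))
        assert out.rows[0].mean_CS == pytest.approx(2.0)
        assert out.rows[1].mean_F == pytest.approx(9.0)

    def test_fill_means_consistent_row_unchanged(self):
        row = TrialArmSummary("a", Arm.control, n=5, mean_B=1.0, mean_F=3.0, mean_CS=2.0)
        out = fill_means(MetaDataset([row, row.replace(arm=Arm.treatment)]))
        assert out.rows[0] == row

    def test_weighted_mean_imputation(self):
        rows = [
            TrialArmSummary("a", Arm.control, n=3, r=0.5),
            TrialArmSummary("a", Arm.treatment, n=5, r=1.0),
            TrialArmSummary("b", Arm.control, n=9),
            TrialArmSummary("b", Arm.treatment, n=9),
        ]
        out = impute_missing_correlations(MetaDataset(rows), "weighted_mean")
        # (2*0.5 + 4*1.0) / 6 = 5/6
        assert out.rows[2].r == pytest.approx(5 / 6)
        assert out.rows[3].r == pytest.approx(5 / 6)

    def test_weighted_mean_constant(self):
        rows = [
            TrialArmSummary("a", Arm.control, n=11, r=0.6),
            TrialArmSummary("a", Arm.treatment, n=21, r=0.6),
            TrialArmSummary("b", Arm.control, n=5),
            TrialArmSummary("b", Arm.treatment, n=5, r=0.6),
        ]
        out = impute_missing_correlations(MetaDataset(rows), "weighted_mean")
        assert out.rows[2].r == pytest.approx(0.6)

    def test_fixed_imputation(self):
        rows = [
            TrialArmSummary("a", Arm.control, n=5),
            TrialArmSummary("a", Arm.treatment, n=5),
        ]
        out = impute_missing_correlations(MetaDataset(rows), "fixed", fixed_value=0.5)
        assert all(r.r == 0.5 for r in out.rows)

    def test_no_observed_correlations_error(self):
        rows = [
            TrialArmSummary("a", Arm.control, n=5),
            TrialArmSummary("a", Arm.treatment, n=5),
        ]
        with pytest.raises(FillinError, match="fixed"):
            impute_missing_correlations(MetaDataset(rows), "weighted_mean")


@pytest.fixture
def complete(complete_ds):
    return complete_ds


class TestRunFillin:
    def test_idempotent_on_complete_data(self, complete):
        out, report = run_fillin(complete)
        assert report.n_filled() == 0  # everything observed
        for a, b in zip(complete.rows, out.rows):
            assert a == b
        out2, report2 = run_fillin(out)
        assert report2.n_filled() == 0
        for a, b in zip(out.rows, out2.rows):
            assert a == b

    def test_ses_only_completes(self, complete):
        rows = []
        for row in complete.rows:
            rows.append(
                row.replace(
                    se_B=row.sd_B / math.sqrt(row.n), sd_B=None,
                    se_F=row.sd_F / math.sqrt(row.n), sd_F=None,
                    se_CS=row.sd_CS / math.sqrt(row.n), sd_CS=None,
                    r=None,
                )
            )
        out, report = run_fillin(MetaDataset(rows))
        for a, b in zip(complete.rows, out.rows):
            assert b.sd_B == pytest.approx(a.sd_B, abs=1e-10)
            assert b.sd_CS == pytest.approx(a.sd_CS, abs=1e-10)
            assert b.r == pytest.approx(a.r, abs=1e-10)
        assert report.n_filled("calculated") == 4 * len(complete.rows)

    def test_missing_n_error(self, complete):
        rows = list(complete.rows)
        rows[2] = rows[2].replace(n=None)
        with pytest.raises(FillinError, match=rows[2].trial_id):
            run_fillin(MetaDataset(rows))

    def test_irrecoverable_row_error(self, complete):
        rows = list(complete.rows)
        rows[0] = rows[0].replace(mean_B=None, mean_F=None)  # only mean_CS left
        with pytest.raises(FillinError, match="could not be completed"):
            run_fillin(MetaDataset(rows))

    def test_masking_recovery_exact(self, complete):
        masked = mask_summaries(complete, pattern="sd_to_se", fraction=1.0, seed=5)
        out, report = run_fillin(masked.dataset)
        for cell in masked.masked:
            assert getattr(out.rows[cell.row], cell.field) == pytest.approx(
                cell.true_value, abs=1e-10
            )
        assert report.n_filled("imputed") == 0

    def test_drop_r_recovery(self, complete):
        masked = mask_summaries(complete, pattern="drop_r", fraction=1.0, seed=5)
        out, _ = run_fillin(masked.dataset)
        for cell in masked.masked:
            assert getattr(out.rows[cell.row], cell.field) == pytest.approx(
                cell.true_value, abs=1e-10
            )

    def test_provenance_statuses(self, complete):
        masked = mask_summaries(complete, pattern="drop_sdF", fraction=0.5, seed=5)
        out, report = run_fillin(masked.dataset)
        frame = report.to_frame()
        assert set(frame["status"]) <= {"calculated", "imputed"}
        assert (frame.loc[frame["rule"] == "sdF_equals_sdB", "status"] == "imputed").all()
        status = report.cell_status(out)
        assert (status.loc[:, "mean_B"] == "observed").all()
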