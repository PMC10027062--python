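import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from panelqc import (
    ControlSpec,
    ExpressionMatrix,
    Flag,
    PanelQC,
    PanelQCError,
    QCThresholds,
    combine_flags,
    compute_cpm,
    control_fraction,
    flag_negative,
    flag_positive,
    negative_deviance,
    negative_mean_cpm,
    run_qc,
)

from conftest import random_panel_matrix
from oracle import oracle_qc

THR = QCThresholds()


class TestCpm:
    def test_definition(self):
        m = ExpressionMatrix(("P1", "P2"), ("A",), np.array([[100], [999_900]]))
        cpm = compute_cpm(m)
        assert cpm[0, 0] == pytest.approx(100.0)

    def test_small_library(self):
        m = ExpressionMatrix(("P1", "P2"), ("A",), np.array([[5], [995]]))
        assert compute_cpm(m)[0, 0] == pytest.approx(5000.0)

    def test_columns_sum_to_one_million(self, panel_matrix):
        sums = compute_cpm(panel_matrix).sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-6)

    def test_zero_library_names_sample(self):
        m = ExpressionMatrix(("P1",), ("A", "B"), np.array([[5, 0]]))
        with pytest.raises(PanelQCError, match="B"):
            compute_cpm(m)


class TestControlFraction:
    @pytest.mark.parametrize(
        "control_counts,rest,expected",
        [([450], 550, 45.0), ([0], 1000, 0.0), ([1000], 0, 100.0)],
    )
    def test_percent_of_total_library(self, control_counts, rest, expected):
        m = ExpressionMatrix(
            ("POS1", "GENE1"), ("A",), np.array([control_counts, [rest]])
        )
        assert control_fraction(m, ["POS1"], "A") == pytest.approx(expected)

    def test_unknown_sample_rejected(self, panel_matrix):
        with pytest.raises(PanelQCError, match="unknown sample"):
            control_fraction(panel_matrix, ["POS1"], "NOPE")


class TestNegativeMeanCpm:
    @pytest.mark.parametrize(
        "neg_cpms,expected",
        [([0.0, 0.0, 0.0, 0.0], 0.0), ([10.0, 20.0, 30.0, 40.0], 25.0), ([7.0], 7.0)],
    )
    def test_mean_over_negative_probes(self, neg_cpms, expected):
        probes = tuple(f"ANT{i}" for i in range(len(neg_cpms))) + ("GENE1",)
        cpm = np.array([[v] for v in neg_cpms] + [[123.0]])
        m = ExpressionMatrix(probes, ("A",), np.ones((len(probes), 1), dtype=int))
        got = negative_mean_cpm(cpm, m, [p for p in probes if p.startswith("ANT")], "A")
        assert got == pytest.approx(expected)

    def test_empty_negative_set_rejected(self, panel_matrix):
        with pytest.raises(PanelQCError, match="empty"):
            negative_mean_cpm(np.zeros((18, 4)), panel_matrix, [], "S1")


class TestNegativeDeviance:
    @pytest.mark.parametrize(
        "cpms,expected",
        [
            ([25.0, 75.0], [-25.0, 25.0]),
            ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
            ([0.0, 10.0, 20.0], [-10.0, 0.0, 10.0]),
        ],
    )
    def test_centering(self, cpms, expected):
        np.testing.assert_allclose(negative_deviance(cpms), expected)

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=50))
    def test_deviances_sum_to_zero(self, cpms):
        delta = negative_deviance(cpms)
        assert abs(delta.sum()) <= 1e-9 * max(1.0, np.abs(delta).sum())


class TestFlagPositive:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (45.0, Flag.FAIL),
            (15.0, Flag.ALERT),
            (4.0, Flag.PASS),
            (40.0, Flag.ALERT),  # strict "exceeds": exactly 40 is not a FAIL
            (10.0, Flag.PASS),
            (0.0, Flag.PASS),
            (100.0, Flag.FAIL),
        ],
    )
    def test_strict_exceeds_boundaries(self, pct, expected):
        assert flag_positive(pct, THR) is expected

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_monotone_in_percentage(self, a, b):
        lo, hi = sorted([a, b])
        assert flag_positive(lo, THR).severity <= flag_positive(hi, THR).severity


class TestFlagNegative:
    def test_fraction_rule_dominates(self):
        assert flag_negative(12.0, 0.0, 5.0, THR) is Flag.FAIL

    def test_deviance_outlier_is_alert(self):
        assert flag_negative(3.0, 15.0, 5.0, THR) is Flag.ALERT

    def test_inside_band_passes(self):
        assert flag_negative(3.0, 0.0, 5.0, THR) is Flag.PASS

    def test_band_is_two_sided_by_default(self):
        assert flag_negative(3.0, -15.0, 5.0, THR) is Flag.ALERT

    def test_one_sided_band_ignores_low_outliers(self):
        assert flag_negative(3.0, -15.0, 5.0, THR, one_sided_band=True) is Flag.PASS
        assert flag_negative(3.0, 15.0, 5.0, THR, one_sided_band=True) is Flag.ALERT

    def test_skipped_deviance_filter(self):
        assert flag_negative(3.0, 99.0, 0.0, THR, deviance_filter_applied=False) is Flag.PASS

    def test_degenerate_zero_sd_band(self):
        # strict inequality: delta 0 inside a zero-width band
        assert flag_negative(3.0, 0.0, 0.0, THR) is Flag.PASS


class TestCombineFlags:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [
            (Flag.PASS, Flag.PASS, Flag.PASS),
            (Flag.ALERT, Flag.PASS, Flag.ALERT),
            (Flag.PASS, Flag.ALERT, Flag.ALERT),
            (Flag.ALERT, Flag.ALERT, Flag.ALERT),
            (Flag.FAIL, Flag.PASS, Flag.FAIL),
            (Flag.PASS, Flag.FAIL, Flag.FAIL),
            (Flag.ALERT, Flag.FAIL, Flag.FAIL),
            (Flag.FAIL, Flag.ALERT, Flag.FAIL),
            (Flag.FAIL, Flag.FAIL, Flag.FAIL),
        ],
    )
    def test_worst_flag_wins(self, pos, neg, expected):
        assert combine_flags(pos, neg) is expected


class TestRunQC:
    def test_matches_brute_force_oracle_on_random_matrices(self):
        """Vectorised run_qc equals a pure-Python recomputation from definitions."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            matrix, controls = random_panel_matrix(
                rng, n_probes=int(rng.integers(5, 11)), n_samples=int(rng.integers(1, 7))
            )
            result = run_qc(matrix, controls, THR)
            expected, sd = oracle_qc(matrix, controls, THR)
            assert result.delta_sd == pytest.approx(sd, abs=1e-9)
            for rec, exp in zip(result.records, expected):
                assert rec.sample_id == exp["sample_id"]
                assert rec.library_size == exp["library_size"]
                assert rec.pos_pct == pytest.approx(exp["pos_pct"])
                assert rec.neg_pct == pytest.approx(exp["neg_pct"])
                assert rec.neg_mean_cpm == pytest.approx(exp["neg_mean_cpm"])
                assert rec.delta == pytest.approx(exp["delta"], abs=1e-9)
                assert rec.pos_flag.value == exp["pos_flag"]
                assert rec.neg_flag.value == exp["neg_flag"]
                assert rec.overall_flag.value == exp["overall_flag"]

    def test_deviances_sum_to_zero(self, panel_matrix, panel_controls):
        result = run_qc(panel_matrix, panel_controls)
        deltas = [r.delta for r in result.records]
        assert abs(sum(deltas)) <= 1e-6 * max(1.0, sum(abs(d) for d in deltas))

    def test_identical_columns_degenerate(self):
        col = np.array([50, 60, 10, 20, 500])
        m = ExpressionMatrix(
            ("POS1", "POS2", "ANT1", "ANT2", "GENE1"),
            ("A", "B", "C", "D"),
            np.tile(col[:, None], (1, 4)),
        )
        spec = ControlSpec(frozenset({"POS1", "POS2"}), frozenset({"ANT1", "ANT2"}))
        result = run_qc(m, spec)
        assert result.delta_sd == 0.0
        assert all(r.delta == 0.0 for r in result.records)
        # flags determined solely by the fraction filters
        for r in result.records:
            assert r.pos_flag is Flag.ALERT  # 110/640 = 17.2%
            assert r.neg_flag is Flag.PASS  # 30/640 = 4.7%

    def test_two_samples_skip_deviance_band(self):
        rng = np.random.default_rng(5)
        matrix, controls = random_panel_matrix(rng, n_samples=2)
        result = run_qc(matrix, controls)
        assert not result.deviance_filter_applied
        assert all(r.neg_flag in (Flag.PASS, Flag.FAIL) for r in result.records)

    def test_permutation_invariance(self, panel_matrix, panel_controls):
        result = run_qc(panel_matrix, panel_controls)
        order = ["S3", "S1", "S4", "S2"]
        permuted = run_qc(panel_matrix.select_samples(order), panel_controls)
        by_id = {r.sample_id: r for r in result.records}
        assert [r.sample_id for r in permuted.records] == order
        for rec in permuted.records:
            assert rec == by_id[rec.sample_id]

    def test_pass_and_fail_tables_partition_samples(self, panel_matrix, panel_controls):
        result = run_qc(panel_matrix, panel_controls)
        n = len(result.pass_table()) + len(result.fail_table())
        assert n == panel_matrix.n_samples

    def test_unbound_controls_rejected(self, panel_matrix):
        spec = ControlSpec(frozenset({"POS1"}), frozenset({"MISSING"}))
        with pytest.raises(PanelQCError, match="MISSING"):
            run_qc(panel_matrix, spec)


class TestQCThresholds:
    def test_defaults_are_the_published_constants(self):
        thr = QCThresholds()
        assert (thr.pos_fail_pct, thr.pos_alert_pct, thr.neg_fail_pct, thr.sd_multiplier) == (
            40.0,
            10.0,
            10.0,
            2.0,
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pos_alert_pct": 50.0},  # alert above fail
            {"pos_fail_pct": 120.0},
            {"neg_fail_pct": 0.0},
            {"sd_multiplier": -1.0},
        ],
    )
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(PanelQCError):
            QCThresholds(**kwargs)


class TestPanelQCEstimator:
    def test_fit_on_samples_by_probes_frame(self, panel_matrix, panel_controls):
        X = panel_matrix.to_frame().T  # sklearn orientation
        est = PanelQC().fit(X)
        reference = run_qc(panel_matrix, panel_controls)
        assert list(est.flags_) == [r.overall_flag.value for r in reference.records]
        assert est.delta_sd_ == reference.delta_sd
        assert est.band_high_ == -est.band_low_

    def test_fit_predict_on_expression_matrix(self, panel_matrix):
        flags = PanelQC().fit_predict(panel_matrix)
        assert set(flags) <= {"PASS", "ALERT", "FAIL"}
        assert len(flags) == panel_matrix.n_samples

    def test_sklearn_param_protocol(self):
        est = PanelQC(pos_fail_pct=50.0)
        assert clone(est).get_params()["pos_fail_pct"] == 50.0
        est.set_params(sd_multiplier=3.0)
        assert est.get_params()["sd_multiplier"] == 3.0

    def test_threshold_overrides_change_flags(self, panel_matrix):
        strict = PanelQC(pos_alert_pct=0.5, pos_fail_pct=1.0).fit(panel_matrix)
        # every sample's spike-in share is far above a 1% FAIL threshold
        assert set(strict.flags_) == {"FAIL"}
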