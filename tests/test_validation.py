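"""QC statistics, recovery/matrix effect, carryover, acceptance logic."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from microstab import (
    AcceptanceThresholds,
    carryover_check,
    evaluate_acceptance,
    extraction_recovery,
    is_normalized_me,
    matrix_effect,
    qc_statistics,
)
from microstab.errors import IncompleteRunError, InsufficientDataError
from microstab.validation import MatrixEffectResult, QcStatistics


def _qc(level, scope, nominal, mean, rsd=1.0):
    return QcStatistics(
        level_name=level, scope=scope, nominal=nominal, n=6, mean=mean,
        sd=rsd * mean / 100, precision_rsd_pct=rsd,
        accuracy_pct=100 * (mean - nominal) / nominal,
        recovery_pct=100 * mean / nominal,
    )


class TestQcStatistics:
    def test_interbatch_mid_level_accuracy(self):
        vals = np.array([912.08 - 9, 912.08 + 9, 912.08 - 3, 912.08 + 3, 912.08, 912.08])
        s = qc_statistics(vals, 900.0, "inter_batch", "MQC")
        assert round(s.accuracy_pct, 2) == 1.34
        assert s.scope == "inter_batch"

    def test_interbatch_high_level_recovery(self):
        vals = np.full(6, 2375.59) + np.array([-20, 20, -10, 10, 0, 0.0])
        s = qc_statistics(vals, 2400.0, "inter_batch", "HQC")
        assert round(s.recovery_pct, 2) == 98.98

    def test_exact_replicates(self):
        s = qc_statistics([900.0] * 6, 900.0, "intra_batch", "MQC")
        assert s.accuracy_pct == 0 and s.precision_rsd_pct == 0

    def test_bad_scope_and_small_n(self):
        with pytest.raises(ValueError):
            qc_statistics([1, 2], 1.0, "weekly")
        with pytest.raises(InsufficientDataError):
            qc_statistics([1.0], 1.0)


class TestRecoveryAndMatrixEffect:
    def test_identity_and_arithmetic(self):
        assert extraction_recovery([5.0, 5.0], [5.0, 5.0]) == 100.0
        assert extraction_recovery([10.0], [5.0]) == 200.0
        assert matrix_effect([0.9967], [1.0]) == pytest.approx(99.67)
        assert matrix_effect([1.0224], [1.0]) == pytest.approx(102.24)

    def test_published_recovery_ratio(self):
        neat = np.array([100.0, 102.0, 98.0])
        assert extraction_recovery(neat * 0.9955, neat) == pytest.approx(99.55)

    @given(
        set1=st.lists(st.floats(0.1, 1e3), min_size=1, max_size=6),
        set2=st.lists(st.floats(0.1, 1e3), min_size=1, max_size=6),
        c=st.floats(1e-3, 1e3),
    )
    def test_rescaling_invariance(self, set1, set2, c):
        base = matrix_effect(set1, set2)
        scaled = matrix_effect([v * c for v in set1], [v * c for v in set2])
        assert scaled == pytest.approx(base, rel=1e-9)


class TestIsNormalizedMe:
    def test_published_values(self):
        assert round(is_normalized_me(99.67, 102.24), 3) == 0.975

    @given(x=st.floats(1e-3, 1e3))
    def test_self_ratio_is_one(self, x):
        assert is_normalized_me(x, x) == 1.0

    def test_arithmetic_and_zero(self):
        assert is_normalized_me(85.0, 100.0) == 0.85
        with pytest.raises(ZeroDivisionError):
            is_normalized_me(1.0, 0.0)


class TestCarryover:
    @pytest.mark.parametrize(
        "blank,expect_pass", [(0.0, True), (0.19, True), (0.21, False)]
    )
    def test_fraction_boundaries(self, blank, expect_pass):
        res = carryover_check(blank, 1.0, AcceptanceThresholds())
        assert res.fraction_of_lloq == pytest.approx(blank)
        assert res.passed is expect_pass


class TestEvaluateAcceptance:
    def _baseline(self):
        return [
            _qc("LLQC", "intra_batch", 1.0, 0.95),
            _qc("LQC", "intra_batch", 3.0, 3.09),
            _qc("MQC", "intra_batch", 900.0, 898.67),
            _qc("HQC", "intra_batch", 2400.0, 2387.68),
            _qc("LLQC", "inter_batch", 1.0, 0.93, rsd=2.01),
            _qc("LQC", "inter_batch", 3.0, 3.16, rsd=3.08),
            _qc("MQC", "inter_batch", 900.0, 912.08, rsd=1.71),
            _qc("HQC", "inter_batch", 2400.0, 2375.59, rsd=1.04),
        ]

    def test_published_statistics_pass_default_thresholds(self):
        rep = evaluate_acceptance(
            self._baseline(),
            calibration_r2=0.9949,
            matrix_result=MatrixEffectResult(99.67, 102.24, 0.975),
            carryover=carryover_check(0.0, 1.0),
        )
        assert rep.overall_pass
        assert not rep.failures

    def test_injected_bias_flips_verdict_and_is_listed(self):
        stats = self._baseline()
        stats[2] = _qc("MQC", "intra_batch", 900.0, 900.0 * 1.30)  # +30% bias
        rep = evaluate_acceptance(stats)
        assert not rep.overall_pass
        assert any("MQC" in c.name and "accuracy" in c.name for c in rep.failures)

    def test_missing_level_raises_with_name(self):
        with pytest.raises(IncompleteRunError, match="HQC"):
            evaluate_acceptance(self._baseline()[:3])

    @given(
        bias=st.floats(-60, 60),
        rsd=st.floats(0, 40),
        improve=st.floats(0, 5),
    )
    def test_monotone_worsening_never_unfails(self, bias, rsd, improve):
        """Degrading one statistic past threshold fails overall; improving
        the others never un-fails it."""
        assume(abs(abs(bias) - 15) > 1e-6 and abs(rsd - 15) > 1e-6)
        stats = self._baseline()
        stats[3] = _qc("HQC", "intra_batch", 2400.0, 2400.0 * (1 + bias / 100), rsd=rsd)
        rep = evaluate_acceptance(stats)
        should_fail = abs(bias) > 15 or rsd > 15
        assert rep.overall_pass == (not should_fail)
        if should_fail:
            # make every other level perfect: still fails
            perfect = [
                _qc(s.level_name, s.scope, s.nominal, s.nominal, rsd=improve)
                for s in stats[:3] + stats[4:]
            ]
            rep2 = evaluate_acceptance(perfect + [stats[3]])
            assert not rep2.overall_pass
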