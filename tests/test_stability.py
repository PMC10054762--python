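"""Depletion kinetics: normalization, phase selection, t1/2, CLint, class."""

import numpy as np
import pandas as pd
import pytest

from microstab import (
    ClearanceBands,
    DepletionKinetics,
    DepletionSimParams,
    StudyDesign,
    classify_clearance,
    fit_depletion,
    half_life,
    intrinsic_clearance,
    ols_line,
    percent_remaining,
    select_linear_phase,
    simulate_depletion,
)
from microstab.errors import (
    ConfigError,
    NoDepletionError,
    NoLinearPhaseError,
    NormalizationError,
)


class TestPercentRemaining:
    def test_published_normalization(self, depletion_means):
        tc = percent_remaining(depletion_means)
        by_t = dict(zip(tc.times_min, tc.pct_remaining))
        assert round(by_t[7.5], 2) == 84.19
        assert round(by_t[20.0], 2) == 56.39
        ln_by_t = dict(zip(tc.times_min, tc.ln_pct_remaining))
        assert round(ln_by_t[20.0], 2) == 4.03
        assert tc.pct_remaining[tc.times_min == 0][0] == 100.0

    def test_replicates_averaged_before_normalization(self):
        df = pd.DataFrame(
            {"time_min": [0, 0, 10, 10], "conc_ng_ml": [90.0, 110.0, 40.0, 60.0]}
        )
        tc = percent_remaining(df)
        assert tc.mean_conc.tolist() == [100.0, 50.0]
        assert tc.pct_remaining.tolist() == [100.0, 50.0]

    def test_no_depletion_flat_curve(self):
        df = pd.DataFrame({"time_min": [0, 10, 20], "conc_ng_ml": [5.0, 5.0, 5.0]})
        tc = percent_remaining(df)
        assert np.allclose(tc.pct_remaining, 100.0)
        assert np.allclose(tc.ln_pct_remaining, np.log(100.0))

    def test_missing_t0_raises(self):
        with pytest.raises(NormalizationError):
            percent_remaining(pd.DataFrame({"time_min": [5, 10], "conc_ng_ml": [1, 2.0]}))


class TestSelectLinearPhase:
    def test_manual_window_published_points(self, depletion_means):
        tc = percent_remaining(depletion_means)
        sub = select_linear_phase(tc, "manual", (0, 30))
        assert sub.times_min.tolist() == [0, 2.5, 7.5, 15, 20, 30]

    def test_manual_is_idempotent(self, depletion_means):
        tc = percent_remaining(depletion_means)
        once = select_linear_phase(tc, "manual", (0, 30))
        twice = select_linear_phase(once, "manual", (0, 30))
        assert np.array_equal(once.times_min, twice.times_min)

    def test_auto_selects_all_points_for_pure_monoexponential(self):
        df = simulate_depletion(DepletionSimParams(plateau_fraction=0, replicate_cv=0))
        tc = percent_remaining(df)
        sub = select_linear_phase(tc, "auto", r2_floor=0.99)
        assert sub.times_min.size == tc.times_min.size

    def test_auto_matches_prefix_enumeration_oracle(self, depletion_means):
        tc = percent_remaining(depletion_means)
        r2_floor, min_points = 0.995, 4
        # independent oracle: enumerate every prefix, keep longest passing
        best_n = None
        for end in range(min_points, tc.times_min.size + 1):
            f = ols_line(tc.times_min[:end], tc.ln_pct_remaining[:end])
            if f.r2 >= r2_floor:
                best_n = end
        sub = select_linear_phase(tc, "auto", r2_floor=r2_floor, min_points=min_points)
        assert best_n is not None
        assert sub.times_min.size == best_n
        assert sub.times_min.max() <= 30.0

    def test_auto_no_qualifying_prefix(self, rng):
        df = pd.DataFrame(
            {"time_min": [0, 5, 10, 15, 20], "conc_ng_ml": [100, 10, 90, 5, 80.0]}
        )
        with pytest.raises(NoLinearPhaseError):
            select_linear_phase(percent_remaining(df), "auto", r2_floor=0.999)


class TestFitAndDerivedKinetics:
    def test_published_regression(self, depletion_means):
        tc = percent_remaining(depletion_means)
        sub = select_linear_phase(tc, "manual", (0, 30))
        slope, intercept, r2 = fit_depletion(sub)
        assert round(slope, 4) == -0.0291
        assert round(intercept, 4) == 4.6221
        assert round(r2, 4) == 0.9971

    def test_noise_free_monoexponential_exact(self):
        p = DepletionSimParams(c0=500, k_dep=0.05, plateau_fraction=0, replicate_cv=0)
        tc = percent_remaining(simulate_depletion(p))
        slope, _, r2 = fit_depletion(select_linear_phase(tc, "manual", (0, 70)))
        assert slope == pytest.approx(-0.05, rel=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "slope,decimals,expected",
        [(-0.0291, None, np.log(2) / 0.0291), (-np.log(2), None, 1.0)],
    )
    def test_half_life_values(self, slope, decimals, expected):
        assert half_life(slope, decimals) == pytest.approx(expected, rel=1e-12)

    def test_half_life_published_chain(self):
        assert round(half_life(-0.0291), 2) == 23.82

    def test_half_life_times_k_is_ln2(self):
        for k in (0.01, 0.0291, 0.5):
            assert half_life(-k) * k == pytest.approx(np.log(2), rel=1e-12)

    def test_no_depletion_raises(self):
        with pytest.raises(NoDepletionError):
            half_life(0.0)

    def test_intrinsic_clearance_published_and_algebra(self, design):
        cl_kg, cl_mg = intrinsic_clearance(23.82, design)
        assert round(cl_kg) == 34
        # unit inversion: t1/2 = 0.693*45*26 gives exactly 1 mL/min/kg
        cl1, _ = intrinsic_clearance(0.693 * 45 * 26, design)
        assert cl1 == pytest.approx(1.0, rel=1e-12)
        # linear in liver mass scaling
        doubled = StudyDesign(g_liver_per_kg_bw=52.0)
        assert intrinsic_clearance(23.82, doubled)[0] == pytest.approx(2 * cl_kg)
        # fixed unit ratio under default scaling
        assert cl_kg / cl_mg == pytest.approx(45 * 26 / 1000, rel=1e-12)

    @pytest.mark.parametrize(
        "clint,expected",
        [(34.0, "intermediate"), (10.0, "low"), (60.0, "high")],
    )
    def test_classify_clearance(self, clint, expected):
        assert classify_clearance(clint) == expected

    def test_malformed_bands(self):
        with pytest.raises(ConfigError):
            classify_clearance(10.0, {"low_max": 50.0, "high_min": 20.0})


class TestDepletionKineticsEstimator:
    def test_full_chain_on_published_timecourse(self, depletion_means):
        model = DepletionKinetics(slope_decimals=4, thalf_decimals=2).fit(depletion_means)
        r = model.result_
        assert round(r.slope, 4) == -0.0291
        assert round(r.t_half_min, 2) == 23.82
        assert round(r.clint_ml_min_kg) == 34
        assert r.clearance_class == "intermediate"

    def test_pipeline_identity_noise_free(self):
        p = DepletionSimParams(k_dep=0.02, plateau_fraction=0, replicate_cv=0)
        model = DepletionKinetics(window=(0, 70)).fit(simulate_depletion(p))
        assert model.k_dep_ == pytest.approx(0.02, rel=1e-10)
        assert model.t_half_min_ == pytest.approx(np.log(2) / 0.02, rel=1e-10)
        expected_cl = (0.693 / model.t_half_min_) * 45 * 26
        assert model.clint_ml_min_kg_ == pytest.approx(expected_cl, rel=1e-12)

    def test_recovery_under_replicate_noise(self):
        # monoexponential truth (no plateau) isolates estimator precision
        errs = []
        for seed in range(100):
            p = DepletionSimParams(plateau_fraction=0, replicate_cv=0.05, seed=seed)
            model = DepletionKinetics().fit(simulate_depletion(p))
            errs.append(abs(model.k_dep_ - 0.0291) / 0.0291)
        assert np.median(errs) <= 0.10

    def test_plateau_biases_window_fit_downward(self):
        # with a non-depleting floor the 0-30 min ln-linear slope understates
        # the fast-phase rate; the estimate must fall between 0 and k_dep
        p = DepletionSimParams(replicate_cv=0)  # plateau 0.30
        model = DepletionKinetics().fit(simulate_depletion(p))
        assert 0 < model.k_dep_ < p.k_dep

    def test_get_params_roundtrip(self):
        m = DepletionKinetics(mode="auto", r2_floor=0.99)
        params = m.get_params()
        assert params["mode"] == "auto" and params["r2_floor"] == 0.99
        m2 = DepletionKinetics(**params)
        assert m2.get_params() == params
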