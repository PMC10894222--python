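import numpy as np
import pandas as pd
import pytest

from tactime.psychometrics import (
    PsychometricCurve,
    bias_measure,
    bootstrap_fit_cloud,
    congruence_accuracy,
    exclude_easy,
    fit_psychometric,
    logistic4,
    permutation_bias_test,
    read_choice_table,
    svm_separation,
)
from tactime.recovery import recover_psychometric
from tactime.stimuli import delta_t, duration_levels, intensity_levels


def make_table(rng, u=0.0, nu=0.1, gamma=0.02, lam=0.02, n=400, coupling=0.0):
    """Choice table over the 7 x 7 design from a logistic observer whose
    decision variable is delta_t + coupling * delta_i."""
    rows = []
    for t2 in duration_levels():
        dt = delta_t(334.0, float(t2))
        for i2 in intensity_levels():
            di = (i2 - 64.0) / (i2 + 64.0)
            p = logistic4(dt + coupling * di, gamma, lam, u, nu)
            rows.append(
                dict(
                    delta_t=dt,
                    delta_i=di,
                    light="none",
                    n_trials=n,
                    n_chose2=rng.binomial(n, p),
                )
            )
    return pd.DataFrame(rows)


class TestPsychometricFit:
    def test_known_parameters_recovered_within_bootstrap_cis(self):
        report = recover_psychometric(seed=0, n_boot=300)
        assert report["passed"], report

    def test_symmetric_data_has_zero_pse(self):
        rng = np.random.default_rng(1)
        fit = fit_psychometric(make_table(rng, u=0.0, n=2000))
        assert fit.pse_ == pytest.approx(0.0, abs=0.01)

    def test_pse_equivariant_and_slope_invariant_under_shift(self):
        delta = np.linspace(-0.35, 0.35, 9)
        p = logistic4(delta, 0.03, 0.03, 0.0, 0.1)
        base = PsychometricCurve().fit(delta, p)
        shifted = PsychometricCurve().fit(delta + 0.08, p)
        assert shifted.pse_ - base.pse_ == pytest.approx(0.08, abs=1e-3)
        assert shifted.slope_ == pytest.approx(base.slope_, rel=1e-2)

    def test_fitted_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        fit = fit_psychometric(make_table(rng))
        grid = np.linspace(-1, 1, 201)
        curve = fit.predict_proba(grid)
        assert np.all(np.diff(curve) >= 0)
        assert np.all(curve >= fit.gamma_ - 1e-12)
        assert np.all(curve <= 1 - fit.lambda_ + 1e-12)

    def test_degenerate_data_flagged(self):
        delta = np.linspace(-0.3, 0.3, 7)
        fit = PsychometricCurve().fit(delta, np.ones(7))
        assert fit.degenerate_

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            PsychometricCurve().fit([0.0, 0.1, 0.2], [0.4, 0.5, 0.6])

    def test_long_format_session_reader(self, tmp_path):
        frame = pd.DataFrame(
            dict(
                delta_t=[0.1] * 4 + [-0.1] * 4,
                delta_i=0.0,
                light="none",
                chose2=[1, 1, 0, 1, 0, 0, 1, 0],
            )
        )
        path = tmp_path / "session.csv"
        frame.to_csv(path, index=False)
        table = read_choice_table(path)  # cells sorted by delta_t
        assert table.n_trials.tolist() == [4, 4]
        assert table.n_chose2.tolist() == [1, 3]


class TestBiasMeasure:
    def test_zero_bias_without_coupling(self):
        rng = np.random.default_rng(3)
        bias = bias_measure(make_table(rng, n=4000, coupling=0.0))
        assert np.all(np.abs(bias.to_numpy()) < 2.5)  # percent, binomial noise

    def test_bias_monotone_with_positive_coupling(self):
        rng = np.random.default_rng(4)
        bias = bias_measure(make_table(rng, n=4000, coupling=0.3))
        assert bias.is_monotonic_increasing
        assert bias.iloc[-1] > 5.0

    def test_zero_level_is_exactly_zero_after_normalization(self):
        rng = np.random.default_rng(5)
        bias = bias_measure(make_table(rng, coupling=0.2))
        zero_idx = [i for i in bias.index if abs(i) < 0.02]
        assert bias.loc[zero_idx[0]] == 0.0

    def test_missing_zero_level_warns(self):
        rng = np.random.default_rng(6)
        table = make_table(rng)
        table = table[np.abs(table.delta_i) > 0.01]
        with pytest.warns(UserWarning, match="not normalized"):
            bias_measure(table)

    def test_easy_trials_are_excluded(self):
        rng = np.random.default_rng(7)
        table = make_table(rng)
        kept = exclude_easy(table, "duration")
        assert np.abs(kept.delta_t).max() < 0.34
        assert len(kept) == 5 * 7


class TestPermutationBiasTest:
    def test_null_calibration_type_i_error(self):
        """Two tables from the same generator: the one-sided test should
        reject at close to the nominal rate."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = make_table(rng, n=60)
            b = make_table(rng, n=60)
            p, _ = permutation_bias_test(a, b, n_iter=400, rng=rng)
            rejections += p <= 0.05
        assert rejections / n_rep <= 0.07

    def test_large_shift_detected(self):
        rng = np.random.default_rng(9)
        a = make_table(rng, u=0.15, n=800)  # rightward shift: fewer "2" choices
        b = make_table(rng, u=-0.15, n=800)
        p, bias = permutation_bias_test(a, b, n_iter=1000, rng=0)
        assert p <= 0.001
        assert bias.mean() < 0

    def test_default_iteration_count(self):
        rng = np.random.default_rng(10)
        p, bias = permutation_bias_test(make_table(rng), make_table(rng), rng=0)
        assert bias.size == 1000


class TestSvmSeparation:
    def test_identical_clouds_at_chance(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, size=(200, 2))
        b = rng.normal(0, 1, size=(200, 2))
        assert svm_separation(a, b) == pytest.approx(0.5, abs=0.1)

    def test_separated_clouds_near_zero_error(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, size=(200, 2))
        b = rng.normal(10, 1, size=(200, 2))
        assert svm_separation(a, b) <= 0.01

    def test_error_decreases_with_separation(self):
        rng = np.random.default_rng(13)
        errors = []
        for gap in (0.0, 1.0, 2.0, 4.0):
            a = rng.normal(0, 1, size=(150, 2))
            b = rng.normal(gap, 1, size=(150, 2))
            errors.append(svm_separation(a, b))
        assert errors[0] > errors[-1]
        assert np.all(np.diff(errors) <= 0.05)  # monotone up to noise

    def test_bootstrap_cloud_feeds_svm(self):
        rng = np.random.default_rng(14)
        cloud_a = bootstrap_fit_cloud(make_table(rng, u=0.0, n=150), n_boot=60, rng=0)
        cloud_b = bootstrap_fit_cloud(make_table(rng, u=-0.1, n=150), n_boot=60, rng=1)
        err = svm_separation(cloud_a, cloud_b)
        assert 0.0 <= err <= 0.2  # shifted curves separate well

    def test_minimum_cloud_size_enforced(self):
        with pytest.raises(ValueError, match="20 points"):
            svm_separation(np.zeros((5, 2)), np.zeros((30, 2)))


class TestCongruenceAccuracy:
    def test_duration_only_observer_shows_no_congruence_gap(self):
        rng = np.random.default_rng(15)
        table = make_table(rng, n=3000, coupling=0.0)
        result = congruence_accuracy(table, rng=0, n_boot=300)
        gap = result["congruent_pct"] - result["incongruent_pct"]
        assert abs(gap) < 2.0

    def test_coupled_observer_better_on_congruent_trials(self, behavior_table):
        """Behavior generated by the drive-coupled percept model: intensity
        pushes perceived duration, so congruent trials are judged better."""
        no_light = behavior_table[behavior_table.light == "none"]
        result = congruence_accuracy(no_light, rng=0)
        assert result["congruent_pct"] > result["incongruent_pct"] + 3.0
        assert result["p_value"] < 0.05
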