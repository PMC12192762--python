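import numpy as np
import pytest

from maxsdm.evaluation import (
    auc,
    evaluate_replicates,
    jackknife_gains,
    or10_threshold,
    percent_contribution,
    permutation_importance,
    response_curve,
    tss_and_omission,
)
from maxsdm.maxent_core import build_features, fit_maxent, predict
from maxsdm.preprocess import extract_samples
from maxsdm.synthetic_data import LandscapeSpec, sample_presences, simulate_landscape

from test_maxent_core import make_samples


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_identical_lists(self):
        assert auc([0.3, 0.5], [0.3, 0.5]) == 0.5

    def test_enumerated_pairs(self):
        # pairs: (0.9 vs 0.5, win) (0.9 vs 0.1, win) (0.4 vs 0.5, lose) (0.4 vs 0.1, win)
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        p, b = rng.normal(1, 1, 50), rng.normal(0, 1, 80)
        assert auc(p, b) == pytest.approx(auc(np.exp(p), np.exp(b)), abs=1e-12)
        assert auc(p, b) == pytest.approx(auc(3 * p - 7, 3 * b - 7), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestTssOmission:
    def test_perfect_separation_tss_one(self):
        tss, _, _ = tss_and_omission([0.9, 0.8], [0.2, 0.1])
        assert tss == 1.0

    def test_null_scores_tss_near_zero(self):
        rng = np.random.default_rng(1)
        tss, _, _ = tss_and_omission(rng.uniform(size=1000), rng.uniform(size=1000))
        assert tss <= 0.1

    def test_omission_counting(self):
        _, _, om = tss_and_omission([0.1, 0.6, 0.7], [0.5, 0.2], omission_threshold=0.5)
        assert om == pytest.approx(1 / 3)

    def test_or10_threshold(self):
        scores = np.linspace(0, 1, 101)
        assert or10_threshold(scores) == pytest.approx(0.1)


class TestReplicates:
    def test_no_test_fraction_flags_absent(self, samples):
        fs = build_features(samples, classes=("L",))
        rep = evaluate_replicates(samples, fs, n_replicates=1, test_fraction=0.0, seed=0)
        assert np.isnan(rep.records["test_auc"]).all()
        assert np.isfinite(rep.records["train_auc"]).all()

    def test_seed_determinism(self, samples):
        fs = build_features(samples, classes=("L",))
        a = evaluate_replicates(samples, fs, n_replicates=2, seed=3)
        b = evaluate_replicates(samples, fs, n_replicates=2, seed=3)
        assert a.records.equals(b.records)

    def test_averaged_map_is_cellwise_mean(self, landscape, samples):
        _, stack, _ = landscape
        fs = build_features(samples, classes=("L",))
        rep = evaluate_replicates(
            samples, fs, n_replicates=2, seed=4, stack=stack, keep_models=True
        )
        m1 = predict(rep.models[0], stack).values
        m2 = predict(rep.models[1], stack).values
        vm = stack.valid_mask
        assert np.allclose(rep.averaged_map.values[vm], (m1[vm] + m2[vm]) / 2)
        assert ((rep.averaged_map.values[vm] >= 0) & (rep.averaged_map.values[vm] <= 1)).all()

    def test_too_few_presences(self, samples):
        fs = build_features(samples, classes=("L",))
        few = samples.take_presences(np.arange(2))
        with pytest.raises(ValueError):
            evaluate_replicates(few, fs, n_replicates=2, test_fraction=0.1)


class TestContribution:
    def test_single_variable_is_100(self, samples):
        sub = samples.select(["bio12"])
        fs = build_features(sub, classes=("L", "Q"))
        m = fit_maxent(sub, fs, rm=1.0, track_contributions=True)
        pct = percent_contribution(m)
        assert pct["bio12"] == pytest.approx(100.0)

    def test_untracked_fit_rejected(self, samples):
        fs = build_features(samples, classes=("L",))
        m = fit_maxent(samples, fs, rm=1.0)
        with pytest.raises(ValueError, match="tracking"):
            percent_contribution(m)

    def test_sums_to_100(self, samples):
        fs = build_features(samples, classes=("L", "Q"))
        m = fit_maxent(samples, fs, rm=1.0, track_contributions=True)
        assert sum(percent_contribution(m).values()) == pytest.approx(100.0, abs=0.1)

    def test_constant_variable_gets_zero(self):
        rng = np.random.default_rng(0)
        bg = np.column_stack([rng.normal(size=60), np.full(60, 3.0)])
        pres = np.column_stack([rng.normal(1, 1, 25), np.full(25, 3.0)])
        sm = make_samples(pres, bg, names=["x", "flat"])
        fs = build_features(sm, classes=("L", "Q"))
        m = fit_maxent(sm, fs, rm=1.0, track_contributions=True)
        pct = percent_contribution(m)
        assert pct["flat"] == 0.0
        assert pct["x"] == pytest.approx(100.0)


class TestPermutation:
    def test_single_variable_is_100(self, samples):
        sub = samples.select(["bio12"])
        fs = build_features(sub, classes=("L", "Q"))
        m = fit_maxent(sub, fs, rm=1.0)
        imp = permutation_importance(m, sub, seed=0)
        assert imp["bio12"] == pytest.approx(100.0)

    def test_ignored_variable_is_zero(self):
        # 'flat' is constant on training, so it carries no features at all
        rng = np.random.default_rng(1)
        bg = np.column_stack([rng.normal(size=60), np.full(60, 3.0)])
        pres = np.column_stack([rng.normal(1, 1, 25), np.full(25, 3.0)])
        sm = make_samples(pres, bg, names=["x", "flat"])
        fs = build_features(sm, classes=("L",))
        m = fit_maxent(sm, fs, rm=1.0)
        imp = permutation_importance(m, sm, seed=0)
        assert imp["flat"] == 0.0

    def test_zeroed_lambda_variable_is_zero(self, samples):
        sub = samples.select(["bio12", "bio3"])
        fs = build_features(sub, classes=("L",))
        m = fit_maxent(sub, fs, rm=1.0)
        m.lam[1] = 0.0  # force bio3 out of the model
        imp = permutation_importance(m, sub, seed=0)
        assert imp["bio3"] == 0.0

    def test_seed_stability_at_5000_rows(self):
        spec = LandscapeSpec(seed=21)
        stack, truth = simulate_landscape(spec)
        occ = sample_presences(truth, stack, n=2500, seed=22)
        sm = extract_samples(stack, occ, n_background=2500, seed=23)
        fs = build_features(sm, classes=("L", "Q"))
        m = fit_maxent(sm, fs, rm=1.0)
        a = permutation_importance(m, sm, seed=1)
        b = permutation_importance(m, sm, seed=2)
        for v in sm.variable_names:
            assert abs(a[v] - b[v]) < 2.0

    def test_sums_to_100(self, samples):
        fs = build_features(samples, classes=("L", "Q"))
        m = fit_maxent(samples, fs, rm=1.0)
        assert sum(permutation_importance(m, samples, seed=0).values()) == pytest.approx(
            100.0, abs=0.1
        )


class TestJackknife:
    def test_without_leq_full(self, samples):
        sub = samples.select(["bio12", "bio6", "bio3"])
        fs = build_features(sub, classes=("L", "Q"))
        gains = jackknife_gains(sub, fs, rm=1.0)
        for v, (g_only, g_without, g_full) in gains.items():
            assert g_without <= g_full + 1e-6
            assert g_only >= 0 and g_without >= 0

    def test_uninformative_alone_near_zero(self, samples):
        sub = samples.select(["bio12", "bio3"])
        fs = build_features(sub, classes=("L", "Q"))
        gains = jackknife_gains(sub, fs, rm=1.0)
        assert gains["bio3"][0] <= 0.05

    def test_duplicated_variable_removal_harmless(self, samples):
        sub = samples.select(["bio12", "bio6"])
        dup = sub.values[:, [0]]
        from maxsdm.preprocess import SampleMatrix

        sm = SampleMatrix(
            variable_names=["bio12", "bio6", "bio12copy"],
            values=np.column_stack([sub.values, dup]),
            is_presence=sub.is_presence,
            coords=sub.coords,
        )
        fs = build_features(sm, classes=("L", "Q"))
        gains = jackknife_gains(sm, fs, rm=1.0, variables=["bio12copy"])
        g_only, g_without, g_full = gains["bio12copy"]
        assert g_full - g_without < 0.05 * max(g_full, 1e-9)

    def test_needs_two_variables(self, samples):
        sub = samples.select(["bio12"])
        fs = build_features(sub, classes=("L",))
        with pytest.raises(ValueError):
            jackknife_gains(sub, fs)


class TestResponseCurve:
    def test_point_count(self, samples):
        fs = build_features(samples, classes=("L",))
        m = fit_maxent(samples, fs, rm=1.0)
        curve = response_curve(m, samples, "bio12", n_points=11)
        assert len(curve) == 11
        assert ((curve["logistic"] >= 0) & (curve["logistic"] <= 1)).all()

    def test_positive_linear_curve_monotone(self):
        rng = np.random.default_rng(5)
        bg = rng.uniform(size=(100, 1))
        pres = rng.uniform(0.5, 1.0, size=(40, 1))  # presences at high values
        sm = make_samples(pres, bg, names=["v"])
        fs = build_features(sm, classes=("L",))
        m = fit_maxent(sm, fs, rm=1.0)
        assert m.lam[0] > 0
        curve = response_curve(m, sm, "v", n_points=21)
        assert (np.diff(curve["logistic"]) >= -1e-12).all()

    def test_quadratic_truth_argmax_recovered(self, landscape, samples):
        spec, _, _ = landscape
        fs = build_features(samples, classes=("L", "Q"))
        m = fit_maxent(samples, fs, rm=1.0)
        curve = response_curve(m, samples, "bio12", n_points=201)
        a, b = spec.truth_coefficients["bio12"]
        true_opt = -a / (2 * b)
        fitted_opt = curve["value"][np.argmax(curve["logistic"].to_numpy())]
        value_range = curve["value"].max() - curve["value"].min()
        assert abs(fitted_opt - true_opt) <= 0.15 * value_range

    def test_unknown_variable(self, samples):
        fs = build_features(samples, classes=("L",))
        m = fit_maxent(samples, fs, rm=1.0)
        with pytest.raises(KeyError):
            response_curve(m, samples, "nope")
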