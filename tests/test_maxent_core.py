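import numpy as np
import pytest
from scipy.special import logsumexp

from maxsdm.grid_io import stack_layers
from maxsdm.maxent_core import (
    MaxEntModel,
    build_features,
    default_beta,
    fit_maxent,
    predict,
)
from maxsdm.preprocess import SampleMatrix
from maxsdm.evaluation import auc


def make_samples(pres, bg, names=None):
    pres = np.atleast_2d(np.asarray(pres, dtype=float))
    bg = np.atleast_2d(np.asarray(bg, dtype=float))
    d = pres.shape[1]
    names = names or [f"v{i}" for i in range(d)]
    values = np.vstack([pres, bg])
    return SampleMatrix(
        variable_names=names,
        values=values,
        is_presence=np.concatenate(
            [np.ones(len(pres), dtype=bool), np.zeros(len(bg), dtype=bool)]
        ),
        coords=np.zeros((len(values), 2)),
    )


class TestBuildFeatures:
    def test_linear_count(self):
        sm = make_samples(np.random.default_rng(0).normal(size=(5, 3)),
                          np.random.default_rng(1).normal(size=(20, 3)))
        assert build_features(sm, classes=("L",)).n_features == 3

    def test_lqp_count(self):
        sm = make_samples(np.random.default_rng(0).normal(size=(5, 3)),
                          np.random.default_rng(1).normal(size=(20, 3)))
        assert build_features(sm, classes=("L", "Q", "P")).n_features == 9

    def test_hinge_count(self):
        rng = np.random.default_rng(2)
        sm = make_samples(rng.normal(size=(5, 2)), rng.normal(size=(100, 2)))
        fs = build_features(sm, classes=("H",), knots_per_variable=10)
        assert fs.n_features == 2 * 2 * 10

    def test_product_single_variable_warns(self):
        rng = np.random.default_rng(3)
        sm = make_samples(rng.normal(size=(5, 1)), rng.normal(size=(20, 1)))
        with pytest.warns(UserWarning, match="product"):
            fs = build_features(sm, classes=("L", "P"))
        assert fs.n_features == 1

    def test_features_normalized_to_unit_interval(self):
        rng = np.random.default_rng(4)
        sm = make_samples(rng.normal(size=(10, 2)) * 7, rng.normal(size=(50, 2)) * 7)
        fs = build_features(sm, classes=("L", "Q", "H", "T"), knots_per_variable=5)
        F = fs.design(sm.values)
        assert F.min() >= -1e-12 and F.max() <= 1 + 1e-12

    def test_empty_classes_rejected(self):
        rng = np.random.default_rng(5)
        sm = make_samples(rng.normal(size=(3, 2)), rng.normal(size=(9, 2)))
        with pytest.raises(ValueError):
            build_features(sm, classes=())


class TestDefaultBeta:
    def test_table_knot_exact(self):
        assert default_beta("linear", 10) == 1.0
        assert default_beta("linear", 17) == 0.2
        assert default_beta("threshold", 100) == 1.0

    def test_clamped_above_largest_knot(self):
        assert default_beta("linear", 100000) == 0.05
        assert default_beta("threshold", 5000) == 1.0

    @pytest.mark.parametrize(
        "cls", ["linear", "quadratic", "product", "hinge_fwd", "hinge_rev", "threshold"]
    )
    def test_monotone_non_increasing(self, cls):
        vals = [default_beta(cls, n) for n in range(1, 301)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            default_beta("linear", 0)
        with pytest.raises(ValueError):
            default_beta("nope", 10)


class TestFit:
    def test_matched_means_give_zero_lambda(self):
        rng = np.random.default_rng(0)
        bg = rng.normal(size=(40, 2))
        sm = make_samples(bg.copy(), bg)  # presence empirical means == background means
        fs = build_features(sm, classes=("L",))
        m = fit_maxent(sm, fs, beta_override=0.05)
        assert np.allclose(m.lam, 0.0)
        assert m.training_gain == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_analytic_optimum(self):
        # f(A)=1, f(B)=0, all presences at A, beta=0.1:
        # stationarity gives q(A) = 1 - beta = 0.9, lambda = ln 9
        sm = make_samples([[1.0]] * 10, [[1.0], [0.0]])
        fs = build_features(sm, classes=("L",))
        m = fit_maxent(sm, fs, beta_override=0.1, tolerance=1e-12)
        assert m.lam[0] == pytest.approx(np.log(9), abs=1e-4)
        qA = np.exp(m.lam[0] - m.log_z)
        assert qA == pytest.approx(0.9, abs=1e-4)

    def test_objective_trace_monotone(self, samples):
        fs = build_features(samples, classes=("L", "Q", "H"), knots_per_variable=5)
        m = fit_maxent(samples, fs, rm=1.0)
        assert all(b <= a + 1e-12 for a, b in zip(m.objective_trace, m.objective_trace[1:]))

    def test_gain_non_increasing_in_rm(self, samples):
        fs = build_features(samples, classes=("L", "Q"))
        gains = [fit_maxent(samples, fs, rm=rm).training_gain for rm in (0.1, 1.0, 4.0)]
        assert gains[0] >= gains[1] - 1e-9 >= gains[2] - 2e-9

    def test_huge_rm_gives_null_model(self, samples):
        fs = build_features(samples, classes=("L", "Q"))
        m = fit_maxent(samples, fs, rm=1e6)
        assert np.allclose(m.lam, 0.0)
        sc = m.logistic(samples.values)
        a = auc(sc[samples.is_presence], sc[~samples.is_presence])
        assert a == pytest.approx(0.5, abs=0.02)

    def test_background_raw_sums_to_one(self, samples):
        fs = build_features(samples, classes=("L", "Q"))
        m = fit_maxent(samples, fs, rm=1.0)
        assert m.raw(samples.background_values).sum() == pytest.approx(1.0, abs=1e-8)
        assert m.entropy >= 0
        assert m.training_gain >= 0

    def test_requires_presences(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(10, 2))
        sm = make_samples(np.empty((0, 2)), bg)
        fs_src = make_samples(bg[:2], bg)
        fs = build_features(fs_src, classes=("L",))
        with pytest.raises(ValueError, match="presence"):
            fit_maxent(sm, fs)

    @pytest.mark.parametrize("seed", range(10))
    def test_grid_search_oracle_equivalence(self, seed):
        # independent oracle: refine a dense grid over lambda in [-5,5]^2
        # on the identical objective; fitted lambda must match to 1e-3
        rng = np.random.default_rng(seed)
        bg = rng.uniform(size=(30, 2))
        pres = bg[rng.choice(30, size=12, replace=True)]
        sm = make_samples(pres, bg)
        fs = build_features(sm, classes=("L",))
        beta = 0.05
        m = fit_maxent(sm, fs, beta_override=beta, tolerance=1e-12, max_iterations=20000)

        Fb = fs.design(sm.background_values)
        b = fs.design(sm.presence_values).mean(axis=0)

        def objective(l1, l2):
            lam = np.stack(np.broadcast_arrays(l1, l2), axis=-1)
            s = lam @ Fb.T
            return -(lam @ b) + logsumexp(s, axis=-1) + beta * np.abs(lam).sum(axis=-1)

        center, span = np.zeros(2), 5.0
        for _ in range(5):
            g1 = np.linspace(center[0] - span, center[0] + span, 41)
            g2 = np.linspace(center[1] - span, center[1] + span, 41)
            G1, G2 = np.meshgrid(g1, g2, indexing="ij")
            obj = objective(G1, G2)
            k = np.unravel_index(np.argmin(obj), obj.shape)
            center = np.array([g1[k[0]], g2[k[1]]])
            span = span * 2 / 40 * 1.5
        assert np.max(np.abs(m.lam - center)) < 1e-3


class TestPredict:
    def test_uniform_model_closed_form(self, landscape, samples):
        _, stack, _ = landscape
        fs = build_features(samples, classes=("L",))
        m = fit_maxent(samples, fs, rm=1e9)
        assert np.allclose(m.lam, 0.0)
        assert m.entropy == pytest.approx(np.log(samples.n_background), abs=1e-9)
        raw = predict(m, stack, transform="raw")
        vm = raw.valid_mask
        assert np.allclose(raw.values[vm], 1.0 / samples.n_background)
        logi = predict(m, stack, transform="logistic")
        assert np.allclose(logi.values[vm], 0.5)

    def test_clamping_clips_to_training_range(self, samples):
        fs = build_features(samples, classes=("L", "Q"))
        m = fit_maxent(samples, fs, rm=1.0)
        lo = m.feature_set.var_min.copy()
        below = lo - 10.0
        assert np.allclose(
            m.logistic(below[None, :], clamp=True), m.logistic(lo[None, :], clamp=True)
        )

    def test_logistic_monotone_in_raw(self, samples):
        fs = build_features(samples, classes=("L", "Q"))
        m = fit_maxent(samples, fs, rm=1.0)
        raw = m.raw(samples.values)
        logi = m.logistic(samples.values)
        order = np.argsort(raw)
        assert (np.diff(logi[order]) >= -1e-15).all()

    def test_missing_layer_named(self, landscape, samples):
        _, stack, _ = landscape
        sub = samples.select(["bio12", "bio6"])
        fs = build_features(sub, classes=("L",))
        m = fit_maxent(sub, fs, rm=1.0)
        partial = stack_layers([("bio12", stack.layers["bio12"])])
        with pytest.raises(KeyError, match="bio6"):
            predict(m, partial)

    def test_nodata_mask_preserved(self, samples, grid_factory):
        sub = samples.select(["bio12"])
        fs = build_features(sub, classes=("L",))
        m = fit_maxent(sub, fs, rm=1.0)
        vals = np.random.default_rng(0).normal(size=(4, 4))
        vals[2, 2] = -9999.0
        stack = stack_layers([("bio12", grid_factory(vals))])
        smap = predict(m, stack)
        assert not smap.valid_mask[2, 2]
        assert smap.grid.values[2, 2] == -9999.0


def test_serialization_round_trip(tmp_path, landscape, samples):
    _, stack, _ = landscape
    fs = build_features(samples, classes=("L", "Q", "H"), knots_per_variable=5)
    m = fit_maxent(samples, fs, rm=0.5)
    path = tmp_path / "model.json"
    m.save(path)
    m2 = MaxEntModel.load(path)
    p1 = predict(m, stack).values
    p2 = predict(m2, stack).values
    assert np.array_equal(p1, p2)
    assert m2.rm == m.rm and m2.n_nonzero == m.n_nonzero
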