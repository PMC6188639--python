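"""Objective gradients (quadratic, inverse-consistency, Pearson) and the
gradient-based fit drivers."""

import numpy as np
import pytest

from lnlcascade.core import (
    Cascade,
    Identity,
    Layer,
    LinearStage,
    pack_params,
    unpack_params,
)
from lnlcascade.calculus import fd_oracle
from lnlcascade.divisive import DivisiveNorm, DivNormParams
from lnlcascade.fitting import (
    FitSchedule,
    QualityDataset,
    fit,
    inverse_consistency_cost,
    inverse_consistency_gradient,
    pearson_gradient,
    pearson_objective,
    quadratic_cost,
    quadratic_cost_gradient,
)
from lnlcascade.toys import build_cartoon_model
from lnlcascade.synth import SyntheticMOSSpec, generate_mos_dataset


def scalar_dn_cascade(gamma=1.0, b=1.0, H=0.5):
    p = DivNormParams(gamma, np.atleast_1d(float(b)), np.array([[H]]))
    return Cascade([Layer(LinearStage(np.eye(1), pinv_ridge=0.0), DivisiveNorm(p))])


@pytest.fixture(scope="module")
def mos_data():
    truth = build_cartoon_model(gamma1=0.65, b=4.0)
    ds, _ = generate_mos_dataset(SyntheticMOSSpec(cascade=truth, n_items=80, seed=11))
    return ds


class TestQuadraticCost:
    def test_perfect_fit_zero_gradient(self, rng):
        c = scalar_dn_cascade()
        X = rng.uniform(0.5, 2, (10, 1))
        Y = np.array([c.response(x) for x in X])
        _, layout = pack_params(c, trainable={0: ["gamma", "b", "H"]})
        np.testing.assert_allclose(quadratic_cost_gradient(c, X, Y, layout), 0, atol=1e-12)
        assert quadratic_cost(c, X, Y) == 0

    def test_gradient_matches_fd(self, rng):
        c = scalar_dn_cascade(gamma=0.8, b=1.3, H=0.4)
        X = rng.uniform(0.5, 2, (6, 1))
        truth = scalar_dn_cascade(gamma=1.1, b=0.9, H=0.6)
        Y = np.array([truth.response(x) for x in X])
        theta, layout = pack_params(c, trainable={0: ["gamma", "b", "H"]})
        g = quadratic_cost_gradient(c, X, Y, layout)

        def cost_of(th):
            c2 = scalar_dn_cascade(gamma=0.8, b=1.3, H=0.4)
            unpack_params(th, layout, c2)
            return np.array([quadratic_cost(c2, X, Y)])

        gfd = fd_oracle(cost_of, theta).ravel()
        assert np.max(np.abs(g - gfd)) / np.max(np.abs(gfd)) < 1e-5

    def test_recovery_of_scalar_dn_parameters(self, rng):
        truth = scalar_dn_cascade(gamma=0.9, b=1.4, H=0.3)
        X = (rng.uniform(0.3, 2, (60, 1)) * rng.choice([-1, 1], (60, 1)))
        Y = np.array([truth.response(x) for x in X])
        model = scalar_dn_cascade(gamma=0.7, b=1.0, H=0.45)
        _, layout = pack_params(model, trainable={0: ["gamma", "b", "H"]})
        fit(model, (X, Y), layout, objective="quadratic",
            schedule=FitSchedule(method="lbfgs", n_iter=200))
        p = model.layers[0].nonlin.params
        assert abs(p.gamma - 0.9) / 0.9 < 0.01
        assert abs(p.b[0] - 1.4) / 1.4 < 0.01


class TestInverseConsistency:
    def test_zero_at_generating_parameters(self, rng):
        c = scalar_dn_cascade(gamma=0.8, b=1.2, H=0.4)
        X = rng.uniform(0.5, 2, (5, 1))
        R = np.array([c.response(x) for x in X])
        _, layout = pack_params(c, trainable={0: ["b"]})
        assert inverse_consistency_cost(c, X, R) < 1e-12
        np.testing.assert_allclose(
            inverse_consistency_gradient(c, X, R, layout), 0, atol=1e-9
        )

    def test_gradient_matches_fd(self, rng):
        gen = scalar_dn_cascade(gamma=1.0, b=1.5, H=0.3)
        X = rng.uniform(0.5, 2, (5, 1))
        R = np.array([gen.response(x) for x in X])
        c = scalar_dn_cascade(gamma=1.0, b=1.0, H=0.3)
        theta, layout = pack_params(c, trainable={0: ["b"]})
        g = inverse_consistency_gradient(c, X, R, layout)

        def cost_of(th):
            c2 = scalar_dn_cascade(gamma=1.0, b=1.0, H=0.3)
            unpack_params(th, layout, c2)
            return np.array([inverse_consistency_cost(c2, X, R)])

        gfd = fd_oracle(cost_of, theta).ravel()
        assert np.max(np.abs(g - gfd)) / np.max(np.abs(gfd)) < 1e-5

    def test_joint_objective_recovers_truth_on_noisy_targets(self, rng):
        truth = scalar_dn_cascade(gamma=1.0, b=1.4, H=0.3)
        X = rng.uniform(0.5, 2, (40, 1))
        R = np.array([truth.response(x) for x in X]) + 0.01 * rng.standard_normal((40, 1))
        errs = {}
        for obj in ("quadratic", "joint"):
            model = scalar_dn_cascade(gamma=1.0, b=0.9, H=0.3)
            _, layout = pack_params(model, trainable={0: ["b"]})
            fit(model, (X, R), layout, objective=obj,
                schedule=FitSchedule(method="lbfgs", n_iter=100))
            errs[obj] = abs(model.layers[0].nonlin.params.b[0] - 1.4)
        # the extra inverse constraint must not hurt the estimate materially
        assert errs["joint"] < 2 * errs["quadratic"] + 0.02


class TestPearson:
    def test_affine_of_mos_gives_correlation_one(self, rng):
        c = Cascade([Layer(LinearStage(np.eye(2)), Identity())])
        X = rng.standard_normal((6, 2))
        Z = X + rng.standard_normal((6, 2))
        D = np.array([np.linalg.norm(z - x) for x, z in zip(X, Z)])
        ds = QualityDataset(X, Z, mos=2.0 * D + 1.0)
        assert pearson_objective(c, ds) == pytest.approx(1.0)
        ds_neg = QualityDataset(X, Z, mos=-D)
        assert pearson_objective(c, ds_neg) == pytest.approx(-1.0)

    def test_matches_independent_formula(self, rng, mos_data):
        model = build_cartoon_model(gamma1=0.5, b=7.0)
        from scipy import stats

        D = np.array(
            [
                np.linalg.norm(model.response(z) - model.response(x))
                for x, z in zip(mos_data.originals, mos_data.distorted)
            ]
        )
        expected = stats.pearsonr(mos_data.mos, D).statistic
        assert pearson_objective(model, mos_data) == pytest.approx(expected, abs=1e-12)

    def test_gradient_matches_fd(self, mos_data):
        model = build_cartoon_model(gamma1=0.5, b=7.0)
        theta, layout = pack_params(model, trainable={1: ["gamma", "b"]})
        g = pearson_gradient(model, mos_data, layout)

        def obj(th):
            m2 = build_cartoon_model(gamma1=0.5, b=7.0)
            unpack_params(th, layout, m2)
            return np.array([pearson_objective(m2, mos_data)])

        gfd = fd_oracle(obj, theta).ravel()
        assert np.max(np.abs(g - gfd)) / np.max(np.abs(gfd)) < 1e-5

    def test_identity_cascade_has_zero_gradient(self, rng):
        # no parameters influence the distances of a parameter-free cascade,
        # but a cascade whose L is packed still has a gradient; use a 3-item
        # set where distances are invariant to uniform rescaling instead
        c = Cascade([Layer(LinearStage(np.eye(2)), Identity())])
        X = rng.standard_normal((3, 2))
        Z = X + rng.standard_normal((3, 2))
        D = np.array([np.linalg.norm(z - x) for x, z in zip(X, Z)])
        ds = QualityDataset(X, Z, mos=D.copy())
        _, layout = pack_params(c, trainable={0: ["L"]})
        g = pearson_gradient(c, ds, layout)
        # at ϱ=1, rescaling L uniformly rescales all D: ϱ is invariant, so
        # the gradient has no component along that direction
        direction = np.eye(2).ravel()
        assert abs(g @ direction) < 1e-9

    def test_zero_variance_rejected(self, rng):
        c = Cascade([Layer(LinearStage(np.eye(2)), Identity())])
        X = rng.standard_normal((4, 2))
        ds = QualityDataset(X, X + 1.0, mos=np.ones(4))
        with pytest.raises(ValueError, match="variance"):
            pearson_objective(c, ds)


class TestFitDriver:
    def test_same_seed_identical_traces(self, mos_data):
        traces = []
        for _ in range(2):
            model = build_cartoon_model(gamma1=0.5, b=7.0)
            _, layout = pack_params(model, trainable={1: ["b"]})
            tr = fit(model, mos_data, layout, objective="pearson",
                     schedule=FitSchedule(method="gd", n_iter=10, step=0.3,
                                          batch_size=30, seed=42))
            traces.append(np.asarray(tr.objectives))
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_full_batch_ascent_reaches_grid_optimum(self, mos_data):
        # 1-parameter problem: compare against a brute-force grid search
        def rho_of_b(b):
            return pearson_objective(build_cartoon_model(gamma1=0.65, b=b), mos_data)

        grid = np.linspace(0.5, 20, 300)
        best = grid[np.argmax([rho_of_b(b) for b in grid])]
        model = build_cartoon_model(gamma1=0.65, b=9.0)
        _, layout = pack_params(model, trainable={1: ["b"]})
        # b is per-sensor; tie the comparison to the scalar grid by fitting
        # all three and checking the achieved objective instead
        tr = fit(model, mos_data, layout, objective="pearson",
                 schedule=FitSchedule(method="gd", n_iter=120, step=0.5))
        assert tr.objectives[-1] >= rho_of_b(best) - 1e-3

    def test_held_out_improvement_and_early_stopping(self, mos_data):
        train = mos_data.subset(np.arange(40))
        test = mos_data.subset(np.arange(40, 80))
        model = build_cartoon_model(gamma1=0.5, b=7.0)
        _, layout = pack_params(model, trainable={1: ["gamma", "b"]})
        r0 = pearson_objective(model, test)
        fit(model, train, layout, objective="pearson",
            schedule=FitSchedule(method="gd", n_iter=60, step=0.5), test_data=test)
        assert pearson_objective(model, test) > r0
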