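"""Single-head sequential learning: interpolation, minimality, fits."""

import numpy as np
import pytest

from clforget import (
    FeatureMapSpec,
    ForgettingCurve,
    GramSet,
    delta_F21,
    fit_exponential,
    forgetting_curve,
    forgetting_curve_kernel,
    make_gaussian_pool,
    min_norm_readout,
    normalize_inputs,
    normalized_loss,
    order_params_from_grams,
    permutation_sequence,
    predict_F21,
    predict_fmax,
    sample_features,
    sequential_min_change,
)
from clforget.taskgen import TaskDataset, TaskSequence
from conftest import td_pair


def _features(P, N, N0=20, seed=0, xseed=1):
    rng = np.random.default_rng(xseed)
    X = normalize_inputs(rng.standard_normal((P, N0)))
    spec = FeatureMapSpec(depth=1, width=N, input_dim=N0, seed=seed)
    return sample_features(spec, X)


class TestMinNormReadout:
    def test_interpolates_and_matches_rule_vector(self):
        phi = _features(6, 30)
        rng = np.random.default_rng(2)
        Y = rng.choice([-1.0, 1.0], 6)
        state = min_norm_readout(phi, Y)
        assert normalized_loss(state, phi, Y) < 1e-10
        # a1/||Y|| equals the normalized rule vector of the order parameters
        G = phi.matrix @ phi.matrix.T
        V = np.sqrt(30) * phi.matrix.T @ np.linalg.solve(G, Y / np.linalg.norm(Y))
        assert np.allclose(state.a / np.linalg.norm(Y), V, atol=1e-10)

    def test_sparse_label_reproduced_and_linearity(self):
        phi = _features(5, 25)
        Y = np.zeros(5)
        Y[2] = 1.0
        state = min_norm_readout(phi, Y)
        pred = phi.matrix @ state.a / np.sqrt(25)
        assert np.allclose(pred, Y, atol=1e-10)
        state3 = min_norm_readout(phi, 3.0 * Y)
        assert np.allclose(state3.a, 3.0 * state.a, atol=1e-10)


class TestSequentialMinChange:
    def test_already_interpolated_is_fixed_point(self):
        phi = _features(6, 30)
        Y = np.random.default_rng(0).choice([-1.0, 1.0], 6)
        state = min_norm_readout(phi, Y)
        state2 = sequential_min_change(state, phi, Y)
        assert np.allclose(state2.a, state.a, atol=1e-12)
        assert state2.t == 2

    def test_matches_kkt_oracle(self):
        """Equality-constrained least-change solve via the KKT system."""
        rng = np.random.default_rng(4)
        for trial in range(5):
            P, N = 3, 6
            phi_prev = _features(P, N, N0=8, seed=trial, xseed=trial)
            phi_new = _features(P, N, N0=8, seed=trial + 50, xseed=trial + 50)
            Y0 = rng.choice([-1.0, 1.0], P)
            Y1 = rng.choice([-1.0, 1.0], P)
            a0 = min_norm_readout(phi_prev, Y0).a
            a1 = sequential_min_change(
                min_norm_readout(phi_prev, Y0), phi_new, Y1
            ).a
            # KKT: min ||a - a0||^2 s.t. Phi a / sqrt(N) = Y1
            A = phi_new.matrix / np.sqrt(N)
            kkt = np.block([
                [np.eye(N), A.T],
                [A, np.zeros((P, P))],
            ])
            sol = np.linalg.solve(kkt, np.concatenate([a0, Y1]))
            assert np.allclose(a1, sol[:N], atol=1e-10)

    def test_interpolation_invariant_along_sequence(self):
        seq, _ = td_pair(0.5, 0.8, 0.2, P=20, N0=30, seed=5, T=4)
        spec = FeatureMapSpec(depth=1, width=200, input_dim=30, seed=0)
        feats = [sample_features(spec, t.X) for t in seq.tasks]
        state = min_norm_readout(feats[0], seq[0].Y)
        for t in range(1, 4):
            state = sequential_min_change(state, feats[t], seq[t].Y)
            assert normalized_loss(state, feats[t], seq[t].Y) < 1e-10


class TestNormalizedLoss:
    def test_reference_values(self):
        phi = _features(4, 10)
        Y = np.array([1.0, -1.0, 1.0, 1.0])
        state = min_norm_readout(phi, Y)
        assert normalized_loss(state, phi, Y) == pytest.approx(0.0, abs=1e-12)
        assert normalized_loss(np.zeros(10), phi, Y) == pytest.approx(1.0)
        # flipped readout predicts -Y: ||(-2Y)||^2 / ||Y||^2 = 4
        assert normalized_loss(-state.a, phi, Y) == pytest.approx(4.0)


class TestForgettingCurve:
    def test_identical_tasks_zero_curve(self):
        pool = make_gaussian_pool(15, 25, seed=0)
        Y = np.random.default_rng(1).choice([-1.0, 1.0], 15)
        tasks = [TaskDataset(X=pool.X.copy(), Y=Y.copy(), task_id=t) for t in range(4)]
        seq = TaskSequence(tasks=tasks, protocol="manual")
        spec = FeatureMapSpec(depth=1, width=120, input_dim=25, seed=0)
        assert np.all(forgetting_curve(seq, spec).values < 1e-10)
        assert np.all(forgetting_curve_kernel(seq).values < 1e-8)

    def test_opposite_rule_pair_forgets_fully(self):
        pool = make_gaussian_pool(12, 40, seed=2)
        Y = np.random.default_rng(3).choice([-1.0, 1.0], 12)
        tasks = [TaskDataset(X=pool.X.copy(), Y=Y), TaskDataset(X=pool.X.copy(), Y=-Y)]
        seq = TaskSequence(tasks=tasks, protocol="manual")
        assert forgetting_curve_kernel(seq).F21 == pytest.approx(4.0, abs=1e-6)
        spec = FeatureMapSpec(depth=1, width=300, input_dim=40, seed=1)
        assert forgetting_curve(seq, spec).F21 == pytest.approx(4.0, abs=1e-6)

    def test_two_task_consistency(self):
        """F_{2,1} from a T=4 run equals the standalone two-task value."""
        seq, _ = td_pair(0.4, 0.8, 0.3, P=25, N0=40, seed=9, T=4)
        short = TaskSequence(tasks=seq.tasks[:2], protocol=seq.protocol)
        full = forgetting_curve_kernel(seq)
        two = forgetting_curve_kernel(short)
        assert full.values[1] == pytest.approx(two.values[1], abs=1e-10)

    def test_finite_width_approaches_kernel(self):
        seq, _ = td_pair(0.5, 1.0, 0.2, P=20, N0=30, seed=3)
        kf = forgetting_curve_kernel(seq).F21
        vals = [
            forgetting_curve(
                seq, FeatureMapSpec(depth=1, width=8000, input_dim=30, seed=s)
            ).F21
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(kf, abs=0.05)


class TestPredictF21:
    def test_agreement_with_simulation_on_pairs(self):
        """Forgetting equals twice the conflict across a small grid."""
        sims, preds = [], []
        for rs in (0.3, 0.6):
            for rf in (0.0, 0.2, 0.5):
                f_s, f_p = [], []
                for seed in range(6):
                    seq, grams = td_pair(rs, 0.8, rf, P=60, N0=80, seed=seed)
                    op = order_params_from_grams(grams, seq[0].Y, seq[1].Y)
                    f_s.append(forgetting_curve_kernel(seq).F21)
                    f_p.append(predict_F21(op))
                sims.append(np.mean(f_s))
                preds.append(np.mean(f_p))
        sims, preds = np.array(sims), np.array(preds)
        assert np.linalg.norm(sims - preds) / np.linalg.norm(sims) < 0.10


class TestDeltaF21:
    def test_identical_tasks_nonpositive(self):
        pool = make_gaussian_pool(15, 25, seed=0)
        Y = np.random.default_rng(1).choice([-1.0, 1.0], 15)
        tasks = [TaskDataset(X=pool.X.copy(), Y=Y.copy()) for _ in range(2)]
        seq = TaskSequence(tasks=tasks, protocol="manual")
        spec = FeatureMapSpec(depth=1, width=150, input_dim=25, seed=0)
        assert delta_F21(seq, spec, n_ref_seeds=10) <= 0.0

    def test_unrelated_tasks_reference_near_one(self):
        """The lambda=0 baseline on orthogonal-ish tasks is uninformative."""
        rng = np.random.default_rng(7)
        X1 = normalize_inputs(rng.standard_normal((20, 60)))
        X2 = normalize_inputs(rng.standard_normal((20, 60)))
        seq = TaskSequence(
            tasks=[
                TaskDataset(X=X1, Y=rng.choice([-1.0, 1.0], 20)),
                TaskDataset(X=X2, Y=rng.choice([-1.0, 1.0], 20)),
            ],
            protocol="manual",
        )
        spec = FeatureMapSpec(depth=1, width=400, input_dim=60, seed=0)
        f21 = forgetting_curve(seq, spec).F21
        d = delta_F21(seq, spec, n_ref_seeds=10)
        assert d == pytest.approx(f21 - 1.0, abs=0.25)


class TestExponentialFit:
    def test_noiseless_recovery(self):
        t = np.arange(1, 31)
        values = 0.3 * (1.0 - np.exp(-(t - 1) / 4.0))
        fit = fit_exponential(ForgettingCurve(values=values))
        assert fit.fmax == pytest.approx(0.3, rel=0.01)
        assert fit.tau == pytest.approx(4.0, rel=0.01)

    def test_noisy_recovery_median_within_10pct(self):
        t = np.arange(1, 31)
        base = 0.3 * (1.0 - np.exp(-(t - 1) / 4.0))
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = np.clip(base + 0.01 * rng.standard_normal(len(t)), 0, None)
            noisy[0] = 0.0
            fit = fit_exponential(ForgettingCurve(values=noisy))
            errs.append(abs(fit.tau - 4.0) / 4.0)
        assert np.median(errs) < 0.10

    def test_degenerate_and_constant_curves(self):
        fit = fit_exponential(ForgettingCurve(values=np.zeros(10)))
        assert fit.degenerate and fit.fmax == 0.0
        const = np.full(12, 0.25)
        const[0] = 0.0
        with pytest.warns(UserWarning, match="lower bound"):
            fit = fit_exponential(ForgettingCurve(values=const))
        assert fit.fmax == pytest.approx(0.25, rel=0.01)
        assert fit.tau == pytest.approx(0.1, abs=1e-3)


class TestPredictFmax:
    def test_closed_form_and_limits(self):
        assert predict_fmax(0.2, 1.0) == pytest.approx(0.2 / (1 - np.exp(-1)))
        assert predict_fmax(0.2, 1e-9) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            predict_fmax(-0.1, 1.0)

    def test_roundtrip_through_fit(self):
        t = np.arange(1, 41)
        values = 0.5 * (1.0 - np.exp(-(t - 1) / 6.0))
        fit = fit_exponential(ForgettingCurve(values=values))
        f21 = values[1]
        assert predict_fmax(f21, fit.tau) == pytest.approx(0.5, rel=0.01)
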