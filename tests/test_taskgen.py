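"""Task-sequence generators: counts, determinism, and label statistics."""

import numpy as np
import pytest

from clforget import (
    ParameterInfeasibleError,
    TargetDistractorParams,
    binarize_labels,
    load_sequence,
    make_gaussian_pool,
    permutation_sequence,
    perturbed_test,
    save_sequence,
    split_ratio_pair,
    split_sequence,
    target_distractor_sequence,
    validate_sequence,
)


def _pool_for(params, N0=50):
    need = params.n_shared + params.T * (params.P - params.n_shared)
    return make_gaussian_pool(need, N0, seed=params.seed)


class TestGaussianPool:
    def test_row_norms_and_shape(self):
        pool = make_gaussian_pool(10, 4, seed=0)
        assert pool.X.shape == (10, 4)
        assert np.allclose(np.linalg.norm(pool.X, axis=1), 2.0)

    def test_seed_determinism(self):
        a = make_gaussian_pool(5, 3, seed=9).X
        b = make_gaussian_pool(5, 3, seed=9).X
        c = make_gaussian_pool(5, 3, seed=10).X
        assert np.array_equal(a, b)
        assert np.any(a != c)


class TestTargetDistractor:
    def test_fully_shared_unflipped_tasks_identical(self):
        params = TargetDistractorParams(
            rho_shared=1.0, rho_target=1.0, rho_flip=0.0, P=20, T=3, seed=1
        )
        seq = target_distractor_sequence(_pool_for(params), params)
        for t in (1, 2):
            assert np.array_equal(seq[0].X, seq[t].X)
            assert np.array_equal(seq[0].Y, seq[t].Y)

    def test_zero_flip_keeps_shared_labels(self):
        params = TargetDistractorParams(
            rho_shared=0.5, rho_target=1.0, rho_flip=0.0, P=40, T=3, seed=2
        )
        seq = target_distractor_sequence(_pool_for(params), params)
        shared = range(params.n_shared)
        for t in (1, 2):
            assert np.array_equal(seq[0].Y[shared], seq[t].Y[shared])

    def test_shared_and_target_counts(self):
        """rho_shared=0.6, rho_target=1: 60 shared rows, all 50 targets shared."""
        params = TargetDistractorParams(
            rho_shared=0.6, rho_target=1.0, rho_flip=0.0, P=100, T=2, seed=3
        )
        seq = target_distractor_sequence(_pool_for(params), params)
        x1, x2 = seq[0].X, seq[1].X
        shared_rows = sum(
            any(np.array_equal(r1, r2) for r2 in x2) for r1 in x1
        )
        assert shared_rows == 60
        for task in seq.tasks:
            nz = np.flatnonzero(task.Y)
            assert len(nz) == 50
            assert set(nz) <= set(range(60))  # all targets on shared block

    def test_flip_fraction_matches_rho_flip(self):
        """Measured flip rate across seeds within 3 binomial SEs of rho_flip."""
        rho_flip, n_tg, n_seeds = 0.3, 20, 200
        flips = []
        for seed in range(n_seeds):
            params = TargetDistractorParams(
                rho_shared=1.0, rho_target=1.0, rho_flip=rho_flip,
                P=40, T=2, seed=seed,
            )
            seq = target_distractor_sequence(_pool_for(params), params)
            tg = np.flatnonzero(seq[0].Y)
            flips.append(np.mean(seq[0].Y[tg] != seq[1].Y[tg]))
        se = np.sqrt(rho_flip * (1 - rho_flip) / (n_tg * n_seeds))
        assert abs(np.mean(flips) - rho_flip) < 3 * se

    def test_determinism_and_validators(self):
        params = TargetDistractorParams(
            rho_shared=0.4, rho_target=0.7, rho_flip=0.2, P=30, T=4, seed=11
        )
        s1 = target_distractor_sequence(_pool_for(params), params)
        s2 = target_distractor_sequence(_pool_for(params), params)
        for a, b in zip(s1.tasks, s2.tasks):
            assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)
        validate_sequence(s1)

    def test_infeasible_counts_raise_in_strict_mode(self):
        params = TargetDistractorParams(
            rho_shared=0.1, rho_target=1.0, rho_flip=0.0, P=100, T=2, seed=0,
            cap_shared_targets=False,
        )
        with pytest.raises(ParameterInfeasibleError, match="shared count"):
            target_distractor_sequence(_pool_for(params), params)

    def test_pool_too_small_raises(self):
        params = TargetDistractorParams(
            rho_shared=0.0, rho_target=0.0, rho_flip=0.0, P=50, T=4, seed=0
        )
        with pytest.raises(ParameterInfeasibleError, match="pool"):
            target_distractor_sequence(make_gaussian_pool(60, 10, 0), params)


class TestPermutation:
    def test_zero_ratio_identical_and_norms_preserved(self, rng):
        X = rng.standard_normal((12, 10))
        Y = np.where(rng.random(12) < 0.5, -1.0, 1.0)
        seq = permutation_sequence(X, Y, 3, 0.0, seed=0)
        assert np.array_equal(seq[0].X, seq[2].X)
        seq2 = permutation_sequence(X, Y, 3, 0.8, seed=0)
        for task in seq2.tasks:
            assert np.allclose(
                np.linalg.norm(task.X, axis=1), np.linalg.norm(X, axis=1)
            )

    def test_each_task_is_column_permutation_recorded_in_metadata(self, rng):
        X = rng.standard_normal((5, 3))
        Y = np.ones(5)
        seq = permutation_sequence(X, Y, 2, 1.0, seed=4)
        perm = np.array(seq[1].meta["permutation"])
        assert sorted(perm.tolist()) == [0, 1, 2]
        assert np.allclose(seq[1].X, X[:, perm])

    def test_tiny_ratio_warns_and_permutes_two(self, rng):
        X = rng.standard_normal((4, 40))
        with pytest.warns(UserWarning, match="fewer than 2"):
            seq = permutation_sequence(X, np.ones(4), 2, 0.01, seed=0)
        perm = np.array(seq[1].meta["permutation"])
        assert np.sum(perm != np.arange(40)) <= 2


class TestSplit:
    @staticmethod
    def _source(n_classes=8, per_class=30, N0=12, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(n_classes), per_class)
        X = rng.standard_normal((len(labels), N0)) + labels[:, None]
        return X, labels

    def test_too_many_tasks_raises(self):
        X, labels = self._source()
        with pytest.raises(ValueError, match="classes"):
            split_sequence(X, labels, T=5, classes_per_task=2, P=10, seed=0)

    def test_tasks_use_disjoint_classes(self):
        X, labels = self._source()
        seq = split_sequence(X, labels, T=3, classes_per_task=2, P=20, seed=1)
        class_sets = [set(t.meta["classes"]) for t in seq.tasks]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not class_sets[i] & class_sets[j]

    def test_balanced_dichotomy_labels_sum_to_zero(self):
        X, labels = self._source()
        seq = split_sequence(X, labels, T=2, classes_per_task=2, P=20, seed=2)
        for task in seq.tasks:
            assert task.Y.sum() == 0

    def test_split_ratio_pair_shared_rows(self):
        X, labels = self._source(per_class=80)
        for ratio, expected in ((0.0, 100), (0.25, 75), (1.0, 0)):
            seq = split_ratio_pair(X, labels, ratio, P=100, seed=3)
            shared = sum(
                np.array_equal(a, b) for a, b in zip(seq[0].X, seq[1].X)
            )
            assert shared == expected
        assert np.array_equal(
            split_ratio_pair(X, labels, 0.0, P=100, seed=3)[1].Y,
            split_ratio_pair(X, labels, 0.0, P=100, seed=3)[0].Y,
        )


class TestPerturbedTest:
    def test_eta_zero_is_identity_and_labels_kept(self, rng):
        pool = make_gaussian_pool(10, 20, seed=0)
        from clforget import TaskDataset

        task = TaskDataset(X=pool.X, Y=np.where(rng.random(10) < 0.5, -1.0, 1.0))
        t0 = perturbed_test(task, 0.0, seed=1)
        assert np.allclose(t0.X, task.X)
        t1 = perturbed_test(task, 0.5, seed=1)
        assert np.array_equal(t1.Y, task.Y)
        assert not np.allclose(t1.X, task.X)

    def test_displacement_scale(self):
        """Mean pre-normalization displacement ~ eta * sqrt(N0)."""
        from clforget import TaskDataset

        eta, N0 = 0.1, 100
        pool = make_gaussian_pool(5, N0, seed=2)
        task = TaskDataset(X=pool.X, Y=np.ones(5))
        disps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            Z = rng.standard_normal(task.X.shape)
            disps.append(np.mean(np.linalg.norm(eta * Z, axis=1)))
        assert np.mean(disps) == pytest.approx(eta * np.sqrt(N0), rel=0.05)


class TestBinarize:
    def test_explicit_dichotomy_and_determinism(self):
        labels = np.array([0, 1, 2, 3, 3, 0])
        dich = {0: 1.0, 1: -1.0, 2: 1.0, 3: -1.0}
        out = binarize_labels(labels, dich)
        assert np.array_equal(out, [1, -1, 1, -1, -1, 1])
        a = binarize_labels(np.arange(10), seed=3)
        b = binarize_labels(np.arange(10), seed=3)
        assert np.array_equal(a, b)
        assert np.sum(a == 1.0) == 5  # balanced on 10 classes

    def test_unassigned_class_raises(self):
        with pytest.raises(ValueError, match="not assigned"):
            binarize_labels(np.array([0, 1, 2]), {0: 1.0, 1: -1.0})


def test_sequence_roundtrip(tmp_path):
    params = TargetDistractorParams(
        rho_shared=0.5, rho_target=0.5, rho_flip=0.1, P=16, T=3, seed=6
    )
    seq = target_distractor_sequence(_pool_for(params), params)
    save_sequence(seq, tmp_path / "seq")
    back = load_sequence(tmp_path / "seq")
    assert back.protocol == seq.protocol and len(back) == len(seq)
    for a, b in zip(seq.tasks, back.tasks):
        assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)
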