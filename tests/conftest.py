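import numpy as np
import pytest

from clforget import (
    FeatureMapSpec,
    GramSet,
    TargetDistractorParams,
    make_gaussian_pool,
    normalize_inputs,
    sample_features,
    target_distractor_sequence,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_task_pair(rng):
    """Two small random tasks with explicit finite-width features."""
    P, N0, N = 10, 20, 40
    X1 = normalize_inputs(rng.standard_normal((P, N0)))
    X2 = normalize_inputs(rng.standard_normal((P, N0)))
    Y1 = np.where(rng.random(P) < 0.5, -1.0, 1.0)
    Y2 = np.where(rng.random(P) < 0.5, -1.0, 1.0)
    spec = FeatureMapSpec(depth=2, width=N, input_dim=N0, seed=7)
    F1 = sample_features(spec, X1)
    F2 = sample_features(spec, X2)
    return F1, F2, Y1, Y2


def td_pair(rho_shared, rho_target, rho_flip, P=100, N0=100, seed=0, T=2,
            target_fraction=0.5):
    """Target-distractor sequence plus its depth-1 kernel Gram blocks."""
    params = TargetDistractorParams(
        rho_shared=rho_shared, rho_target=rho_target, rho_flip=rho_flip,
        target_fraction=target_fraction, P=P, T=T, seed=seed,
    )
    pool = make_gaussian_pool(
        params.n_shared + T * (P - params.n_shared), N0, seed=seed
    )
    seq = target_distractor_sequence(pool, params)
    grams = GramSet.from_kernel(seq[0].X, seq[1].X, depth=1)
    return seq, grams
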