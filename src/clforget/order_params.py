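"""Task-relation order parameters from features or Gram matrices.

For a pair of tasks with last-layer features ``X_i`` (``P x N``) and labels
``Y_i``, define the row-space projector ``P_i = X_iᵀ (X_i X_iᵀ)⁻¹ X_i`` and the
normalized rule vector ``V_i = sqrt(N) X_iᵀ (X_i X_iᵀ)⁻¹ Y_i / ||Y_i||`` — the
minimum-norm readout that interpolates task ``i`` alone.  The order parameters
are

* ``gamma_feature = Tr(P1 P2) / P`` — overlap of the two feature subspaces,
* ``gamma_RF = V2ᵀ P12 V2`` — projection of the rule vectors onto the shared
  feature subspace ("relevant-feature" similarity),
* ``gamma_rule = V2ᵀ P12 V1`` — similarity of the rules on the shared subspace,
* ``conflict = gamma_RF - gamma_rule`` — which is directly proportional to
  short-term forgetting in the single-head fixed-feature theory,
* ``gamma_sim = gamma_feature + cos(V1, V2) - V1ᵀ P2 V1 / ||V1||²`` — the
  overall similarity that controls the multihead phase transition,

with ``P12 = (P2 X1ᵀ X1 P2 + P1 X2ᵀ X2 P1) / (2N)``.

Two computation paths are provided.  The *Gram path* (default) reduces every
bilinear form to products of the ``P x P`` blocks ``G_ij = X_i X_jᵀ / N`` using
the dual coefficients ``u_i = G_ii⁻¹ Y_i / ||Y_i||`` (so ``V_i = X_iᵀ u_i /
sqrt(N)``); it never materializes an ``N x N`` matrix and is exact in the
infinite-width limit when the blocks come from the NNGP kernel.  The *explicit
path* builds the ``N x N`` projectors directly from finite-width features; it
is quadratic in ``N`` and serves as the brute-force reference.

All order parameters are invariant under rescaling of the features (hence
under the weight scale ``sigma``), under relabelling of hidden units, and —
for ``gamma_feature`` and ``gamma_rule`` — under exchanging the two tasks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import scipy.linalg

from .features import FeatureEnsemble, FeatureMapSpec, GramSet, sample_features

__all__ = [
    "ConditioningError",
    "OrderParams",
    "SimOP",
    "gamma_feature",
    "gamma_RF",
    "gamma_rule",
    "gamma_sim",
    "conflict",
    "order_params_from_grams",
    "order_params_explicit",
    "order_params_finite_width",
    "pve_decomposition",
]


class ConditioningError(np.linalg.LinAlgError):
    """A Gram block is rank deficient beyond what the jitter can absorb."""


@dataclass
class OrderParams:
    """Single-head order parameters of one task pair."""

    gamma_feature: float
    gamma_RF: float
    gamma_rule: float
    spread: dict | None = None  # per-OP SD across feature seeds, if averaged

    @property
    def conflict(self) -> float:
        return self.gamma_RF - self.gamma_rule


@dataclass
class SimOP:
    """Multihead similarity order parameter and its three addends."""

    gamma_sim: float
    feature_term: float
    cosine_term: float
    projection_term: float


def conflict(op: OrderParams) -> float:
    """``gamma_RF - gamma_rule``; proportional to short-term forgetting."""
    return op.conflict


# ---------------------------------------------------------------------------
# linear algebra helpers
# ---------------------------------------------------------------------------


def _solve(G: np.ndarray, B: np.ndarray, jitter: float) -> np.ndarray:
    """Solve ``(G + eps I) x = B`` with relative jitter ``eps = jitter*Tr(G)/P``."""
    P = G.shape[0]
    eps = jitter * np.trace(G) / P
    try:
        c, low = scipy.linalg.cho_factor(G + eps * np.eye(P))
        return scipy.linalg.cho_solve((c, low), B)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(G)
        raise ConditioningError(
            f"Gram block of size {P} is not positive definite after jitter "
            f"{eps:.3e} (condition number {cond:.3e})"
        ) from exc


def _normalize_labels(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float).ravel()
    norm = np.linalg.norm(Y)
    if norm == 0:
        raise ValueError("label vector has zero norm")
    return Y / norm


# ---------------------------------------------------------------------------
# Gram path
# ---------------------------------------------------------------------------


def gamma_feature(grams: GramSet, P: int | None = None) -> float:
    """Feature-subspace overlap ``Tr(P1 P2)/P = Tr(G11⁻¹ G12 G22⁻¹ G21)/P``."""
    P = grams.g11.shape[0] if P is None else P
    A = _solve(grams.g11, grams.g12, grams.jitter)      # G11^-1 G12
    B = _solve(grams.g22, grams.g21, grams.jitter)      # G22^-1 G21
    return float(np.einsum("ij,ji->", A, B) / P)


def _dual_coeffs(grams: GramSet, Y1: np.ndarray, Y2: np.ndarray):
    y1 = _normalize_labels(Y1)
    y2 = _normalize_labels(Y2)
    u1 = _solve(grams.g11, y1, grams.jitter)
    u2 = _solve(grams.g22, y2, grams.jitter)
    return y1, y2, u1, u2


def gamma_RF(grams: GramSet, Y1: np.ndarray, Y2: np.ndarray) -> float:
    """Relevant-feature similarity ``V2ᵀ P12 V2`` via Gram algebra.

    Reduction: with ``u2 = G22⁻¹ Y2/||Y2||`` and ``M = G21 G11⁻¹ G12``,
    ``gamma_RF = (u2ᵀ G21 G12 u2 + u2ᵀ M² u2) / 2``.
    """
    _, _, _, u2 = _dual_coeffs(grams, Y1, Y2)
    g12_u2 = grams.g12 @ u2                              # P1
    term1 = float(g12_u2 @ g12_u2)
    m_u2 = grams.g21 @ _solve(grams.g11, g12_u2, grams.jitter)  # M u2, P2
    term2 = float(m_u2 @ m_u2)
    return 0.5 * (term1 + term2)


def gamma_rule(grams: GramSet, Y1: np.ndarray, Y2: np.ndarray) -> float:
    """Rule similarity ``V2ᵀ P12 V1`` via Gram algebra.

    Reduction: ``gamma_rule = u2ᵀ G21 [G12 G22⁻¹ + G11⁻¹ G12] G21 u1 / 2``
    with the inverses applied as solves (first term: ``G12 (G22⁻¹ G21 u1)``;
    second: ``G11⁻¹ (G12 G21 u1)``).
    """
    _, _, u1, u2 = _dual_coeffs(grams, Y1, Y2)
    g12_u2 = grams.g12 @ u2                              # (u2ᵀ G21)ᵀ, P1
    w = grams.g21 @ u1                                   # P2
    term1 = float(g12_u2 @ (grams.g12 @ _solve(grams.g22, w, grams.jitter)))
    term2 = float(g12_u2 @ _solve(grams.g11, grams.g12 @ w, grams.jitter))
    return 0.5 * (term1 + term2)


def gamma_sim(grams: GramSet, Y1: np.ndarray, Y2: np.ndarray) -> SimOP:
    """Multihead similarity ``gamma_feature + cos(V1,V2) - V1ᵀP2V1/||V1||²``."""
    y1, y2, u1, u2 = _dual_coeffs(grams, Y1, Y2)
    feature_term = gamma_feature(grams)
    v1_sq = float(y1 @ u1)        # ||V1||^2 = u1ᵀ G11 u1
    v2_sq = float(y2 @ u2)
    if v1_sq <= 0 or v2_sq <= 0:
        raise ValueError("zero-norm rule vector")
    cosine_term = float(u1 @ grams.g12 @ u2) / np.sqrt(v1_sq * v2_sq)
    g21_u1 = grams.g21 @ u1
    projection_term = float(g21_u1 @ _solve(grams.g22, g21_u1, grams.jitter)) / v1_sq
    return SimOP(
        gamma_sim=feature_term + cosine_term - projection_term,
        feature_term=feature_term,
        cosine_term=cosine_term,
        projection_term=projection_term,
    )


def order_params_from_grams(
    grams: GramSet, Y1: np.ndarray, Y2: np.ndarray
) -> OrderParams:
    """All single-head order parameters of a task pair from its Gram blocks."""
    return OrderParams(
        gamma_feature=gamma_feature(grams),
        gamma_RF=gamma_RF(grams, Y1, Y2),
        gamma_rule=gamma_rule(grams, Y1, Y2),
    )


# ---------------------------------------------------------------------------
# explicit-feature path (brute-force reference)
# ---------------------------------------------------------------------------


def order_params_explicit(
    F1: FeatureEnsemble | np.ndarray,
    F2: FeatureEnsemble | np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    jitter: float = 1e-12,
) -> tuple[OrderParams, SimOP]:
    """Order parameters via explicit ``N x N`` projectors and rule vectors.

    Materializes ``P_i``, ``P12`` and ``V_i`` directly from the feature
    matrices; O(N²) memory, intended for validation at small width.
    """
    X1 = F1.matrix if isinstance(F1, FeatureEnsemble) else np.asarray(F1, float)
    X2 = F2.matrix if isinstance(F2, FeatureEnsemble) else np.asarray(F2, float)
    N = X1.shape[1]
    y1, y2 = _normalize_labels(Y1), _normalize_labels(Y2)

    def projector_and_rule(X, y):
        G = X @ X.T
        eps = jitter * np.trace(G) / G.shape[0]
        Ginv = np.linalg.inv(G + eps * np.eye(G.shape[0]))
        proj = X.T @ Ginv @ X
        V = np.sqrt(N) * X.T @ Ginv @ y
        return proj, V

    P1, V1 = projector_and_rule(X1, y1)
    P2, V2 = projector_and_rule(X2, y2)
    P12 = (P2 @ X1.T @ X1 @ P2 + P1 @ X2.T @ X2 @ P1) / (2.0 * N)
    gf = float(np.trace(P1 @ P2)) / X1.shape[0]
    grf = float(V2 @ P12 @ V2)
    gr = float(V2 @ P12 @ V1)
    cos = float(V1 @ V2) / (np.linalg.norm(V1) * np.linalg.norm(V2))
    proj = float(V1 @ P2 @ V1) / float(V1 @ V1)
    op = OrderParams(gamma_feature=gf, gamma_RF=grf, gamma_rule=gr)
    sim = SimOP(gamma_sim=gf + cos - proj, feature_term=gf,
                cosine_term=cos, projection_term=proj)
    return op, sim


# ---------------------------------------------------------------------------
# finite-width seed averaging
# ---------------------------------------------------------------------------


def order_params_finite_width(
    X1: np.ndarray,
    Y1: np.ndarray,
    X2: np.ndarray,
    Y2: np.ndarray,
    spec: FeatureMapSpec,
    n_seeds: int = 40,
    jitter: float = 1e-10,
) -> tuple[OrderParams, SimOP]:
    """Order parameters on random finite-width features, averaged over seeds.

    Each seed draws a fresh feature map from ``spec`` (offsetting ``spec.seed``)
    and featurizes both tasks with the same weights.  Means are returned with
    the across-seed SD stored in ``OrderParams.spread``.
    """
    rows, sims = [], []
    for k in range(n_seeds):
        sk = FeatureMapSpec(
            depth=spec.depth, width=spec.width, input_dim=spec.input_dim,
            weight_scale=spec.weight_scale, seed=spec.seed + k,
        )
        f1 = sample_features(sk, X1)
        f2 = sample_features(sk, X2)
        grams = GramSet.from_features(f1, f2, jitter=jitter)
        op = order_params_from_grams(grams, Y1, Y2)
        sims.append(gamma_sim(grams, Y1, Y2))
        rows.append([op.gamma_feature, op.gamma_RF, op.gamma_rule])
    arr = np.asarray(rows)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if n_seeds > 1 else np.zeros(3)
    op = OrderParams(
        gamma_feature=float(mean[0]), gamma_RF=float(mean[1]),
        gamma_rule=float(mean[2]),
        spread={"gamma_feature": float(sd[0]), "gamma_RF": float(sd[1]),
                "gamma_rule": float(sd[2])},
    )
    sim_vals = np.array([s.gamma_sim for s in sims])
    sim = SimOP(
        gamma_sim=float(sim_vals.mean()),
        feature_term=float(np.mean([s.feature_term for s in sims])),
        cosine_term=float(np.mean([s.cosine_term for s in sims])),
        projection_term=float(np.mean([s.projection_term for s in sims])),
    )
    return op, sim


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------


def pve_decomposition(op_table: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Share of response variance attributable to each order parameter.

    LMG decomposition: the incremental R² of each predictor is averaged over
    all orderings in which it can enter an OLS model, and the three averages
    are normalized to sum to one.  Predictors are standardized internally, so
    the result is invariant to their units; it is also invariant to permuting
    the rows.
    """
    X = np.asarray(op_table, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("op_table must be (n, 3): gamma_feature, gamma_RF, gamma_rule")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 rows for a variance decomposition")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; PVE is undefined")
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    yc = y - y.mean()
    tss = float(yc @ yc)

    def r2(cols: tuple[int, ...]) -> float:
        if not cols:
            return 0.0
        beta, *_ = np.linalg.lstsq(Xs[:, cols], yc, rcond=None)
        resid = yc - Xs[:, cols] @ beta
        return 1.0 - float(resid @ resid) / tss

    shares = np.zeros(3)
    orderings = list(permutations(range(3)))
    for order in orderings:
        seen: tuple[int, ...] = ()
        for j in order:
            shares[j] += r2(tuple(sorted(seen + (j,)))) - r2(seen)
            seen = tuple(sorted(seen + (j,)))
    shares /= len(orderings)
    total = shares.sum()
    if total <= 0:
        raise ValueError("predictors explain no variance; PVE is undefined")
    return shares / total
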