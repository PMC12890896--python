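"""Multihead continual learning at finite load: trainer, metrics, phases.

With a readout per task and shared hidden weights, continual learning at
finite load ``alpha = P/N`` exhibits three regimes as a function of the load
and the task-similarity order parameter ``gamma_sim``:

* **FR** (fixed representations, ``alpha < 1``): the new head alone can
  interpolate the new task, the hidden weights do not move, and forgetting is
  exactly zero — but the new-task generalization error diverges as
  ``alpha -> 1`` (the linear-regression interpolation threshold).
* **OF** (overfitting, ``1 < alpha < alpha_c``): hidden weights move, but only
  within the null space of the task-1 readout, so forgetting stays zero while
  the new head's norm and test error blow up ("catastrophic anterograde
  interference").
* **G** (generalization, ``alpha > alpha_c``): forgetting becomes finite and
  the network generalizes on the new task.

The OF/G boundary is ``alpha_c = gamma_sim**-2`` (infinite for
``gamma_sim <= 0``).  The trainer below realizes the zero-temperature point
solution of the Gibbs cost for one hidden layer and two tasks: task 1 is
learned from a random initialization with a vanishing ridge, task 2 with a
perturbation penalty ``lambda ||W - W1||^2`` on the hidden weights only.
``lambda = inf`` is solved exactly by the head-only least-squares solution
when that is feasible, and otherwise by penalty continuation (the data-misfit
weight grows relative to the penalty until the fit interpolates and the
weight change stabilizes).  Optimization is full-batch quasi-Newton (L-BFGS)
on the exact gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .features import normalize_inputs
from .taskgen import TaskDataset, TargetDistractorParams, make_gaussian_pool, \
    perturbed_test, target_distractor_sequence

__all__ = [
    "TrainConfig",
    "MultiheadNet",
    "PhaseDiagnosis",
    "MultiheadMetrics",
    "RepSimilarity",
    "critical_load",
    "classify_regime",
    "train_task1",
    "continue_task2",
    "baseline_task2",
    "multihead_metrics",
    "empirical_alpha_c",
    "lambda_sweep",
    "representation_similarity",
    "head_interpolation_boundary",
    "gaussian_overlap_pair",
    "phase_scan",
]


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters of the two-task multihead point solver.

    ``lam`` is the perturbation-penalty scale on the hidden-weight change
    (``math.inf`` selects the constrained minimum-perturbation solver);
    ``ridge`` is the small L2 weight standing in for ``sigma**-2`` at zero
    temperature; ``head_ridge_ratio`` is the relative weight of the head norm
    inside the vanishing regularizer of the continuation; ``tol`` is the
    normalized training-loss tolerance that defines interpolation.  Only the
    zero-temperature limit is implemented — the inverse temperature ``beta``
    of the underlying Gibbs formulation is conceptual here.
    """

    lam: float = math.inf
    sigma: float = 1.0
    ridge: float = 1e-3
    head_ridge_ratio: float = 1e-6
    tol: float = 1e-8
    max_iter: int = 150
    n_stages: int = 7
    stage_factor: float = 10.0
    seed: int = 0


@dataclass
class MultiheadNet:
    """One-hidden-layer network with task-dedicated readouts.

    ``W`` is the current hidden-weight matrix (``N x N0``); ``heads[tau]`` is
    the readout learned for task ``tau+1`` and is never modified after its
    task concludes.  ``W0`` and ``W1`` snapshot the initialization and the
    post-task-1 weights.
    """

    W: np.ndarray
    heads: list[np.ndarray]
    W0: np.ndarray
    W1: np.ndarray | None = None
    sigma: float = 1.0
    converged: bool = True
    train_loss: float = 0.0

    @property
    def width(self) -> int:
        return self.W.shape[0]

    def features(self, X: np.ndarray, W: np.ndarray | None = None) -> np.ndarray:
        W = self.W if W is None else W
        return np.maximum(np.asarray(X, float) @ W.T / np.sqrt(W.shape[1]), 0.0)

    def predict(self, X: np.ndarray, head: int) -> np.ndarray:
        phi = self.features(X)
        return phi @ self.heads[head] / np.sqrt(self.width)


@dataclass
class PhaseDiagnosis:
    """Regime classification of one (load, similarity) point."""

    alpha: float
    gamma_sim: float
    alpha_c: float
    regime: str  # "FR", "OF", or "G"
    on_boundary: bool = False


@dataclass
class MultiheadMetrics:
    """Performance summary after sequentially learning two tasks."""

    F21: float          # head-1 training loss on task 1
    G21: float          # normalized test loss on task 1 (ratio to solo if given)
    G22: float          # test loss on task 2 divided by the solo baseline G20
    G20: float          # solo-learning baseline on task 2
    a2_norm: float      # ||a2||^2 / N
    dW_norm: float      # ||W2 - W1||^2


@dataclass
class RepSimilarity:
    """Hidden-layer similarity matrices before/after learning."""

    K_before: np.ndarray
    K_after: np.ndarray
    block_score: float | None = None

    @property
    def learned_component(self) -> np.ndarray:
        return self.K_after - self.K_before


# ---------------------------------------------------------------------------
# phase theory
# ---------------------------------------------------------------------------


def critical_load(gamma_sim: float) -> float:
    """OF/G phase boundary ``alpha_c = gamma_sim**-2`` (inf for gamma_sim<=0)."""
    if not -1.0 - 1e-6 <= gamma_sim <= 1.0 + 1e-6:
        raise ValueError(f"gamma_sim={gamma_sim} outside [-1, 1]")
    if gamma_sim <= 0.0:
        return math.inf
    return 1.0 / gamma_sim**2


def classify_regime(alpha: float, gamma_sim: float) -> PhaseDiagnosis:
    """Place a (load, similarity) point in the FR / OF / G phase diagram."""
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    ac = critical_load(gamma_sim)
    boundary = abs(alpha - 1.0) <= 1e-9 or (
        math.isfinite(ac) and abs(alpha - ac) <= 1e-9
    )
    if alpha < 1.0:
        regime = "FR"
    elif alpha < ac:
        regime = "OF"
    else:
        regime = "G"
    return PhaseDiagnosis(
        alpha=alpha, gamma_sim=gamma_sim, alpha_c=ac,
        regime=regime, on_boundary=boundary,
    )


# ---------------------------------------------------------------------------
# optimizer core
# ---------------------------------------------------------------------------


def _min_norm_head(phi: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-norm least-squares head; returns (a, normalized residual)."""
    n = phi.shape[1]
    a, *_ = np.linalg.lstsq(phi / np.sqrt(n), Y, rcond=None)
    resid = phi @ a / np.sqrt(n) - Y
    return a, float(resid @ resid) / float(Y @ Y)


def _ridge_head(phi: np.ndarray, Y: np.ndarray, a_pen: float) -> np.ndarray:
    """Exact head for fixed features: argmin ||phi a/sqrt(N) - Y||^2 + a_pen ||a||^2."""
    n = phi.shape[1]
    A = phi.T @ phi / n + a_pen * np.eye(n)
    c, low = scipy.linalg.cho_factor(A)
    return scipy.linalg.cho_solve((c, low), phi.T @ Y / np.sqrt(n))


def _reduced_loss_and_grad(w_flat, X, Y, n, n0, Wref, w_pen, a_pen):
    """Objective in W alone, with the head eliminated by its exact ridge
    solution; the gradient through the head vanishes at the inner optimum
    (envelope theorem), leaving only the explicit W dependence."""
    W = w_flat.reshape(n, n0)
    Z = X @ W.T / np.sqrt(n0)
    mask = Z > 0
    phi = np.where(mask, Z, 0.0)
    a = _ridge_head(phi, Y, a_pen)
    r = phi @ a / np.sqrt(n) - Y
    dW_r = W - Wref
    loss = 0.5 * (r @ r) + 0.5 * w_pen * np.sum(dW_r**2) + 0.5 * a_pen * (a @ a)
    dZ = (r[:, None] * a[None, :] / np.sqrt(n)) * mask
    gW = dZ.T @ X / np.sqrt(n0) + w_pen * dW_r
    return loss, gW.ravel()


def _lbfgs_W(W0_flat, args, max_iter):
    res = scipy.optimize.minimize(
        _reduced_loss_and_grad, W0_flat, args=args, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 3 * max_iter,
                 "ftol": 1e-15, "gtol": 1e-11},
    )
    return res.x


def _train_loss(W, a, X, Y, n0):
    phi = np.maximum(X @ W.T / np.sqrt(n0), 0.0)
    r = phi @ a / np.sqrt(W.shape[0]) - Y
    return float(r @ r) / float(Y @ Y)


def _continuation(X, Y, Wref, a0, cfg: TrainConfig, a_pen_ratio: float,
                  require_dw_stable: bool = True):
    """Vanishing-regularizer continuation toward the minimum-perturbation
    interpolator: minimize ``0.5 ||r||^2 + 0.5 eps (||W-Wref||^2 +
    kappa ||a||^2)`` for a geometric ladder of ``eps`` with warm starts,
    stopping once the fit interpolates and ``||dW||`` stabilizes."""
    n, n0 = Wref.shape
    w = Wref.ravel().copy()
    eps = 1e-3
    prev_dw = None
    for _ in range(cfg.n_stages):
        w = _lbfgs_W(w, (X, Y, n, n0, Wref, eps, eps * a_pen_ratio), cfg.max_iter)
        W = w.reshape(n, n0)
        phi = np.maximum(X @ W.T / np.sqrt(n0), 0.0)
        a = _ridge_head(phi, Y, eps * a_pen_ratio)
        loss = _train_loss(W, a, X, Y, n0)
        dw = float(np.sum((W - Wref) ** 2))
        stable = prev_dw is not None and (
            abs(dw - prev_dw) <= 0.01 * max(prev_dw, 1e-30)
        )
        if loss <= cfg.tol and (stable or not require_dw_stable):
            return W, a, loss, True
        prev_dw = dw
        eps /= cfg.stage_factor
    return W, a, loss, loss <= cfg.tol


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------


def train_task1(task: TaskDataset, width: int, cfg: TrainConfig) -> MultiheadNet:
    """Learn the first task from a random initialization.

    The cost is the training MSE plus a vanishing ridge on the head and on the
    weight change from the initialization ``W0 ~ N(0, sigma^2)``.  When the
    head alone can interpolate (load below 1), the exact limit is taken:
    ``W = W0`` with the minimum-norm head.  Otherwise the continuation solver
    trains both.  Deterministic given ``cfg.seed``.
    """
    X = np.asarray(task.X, float)
    Y = np.asarray(task.Y, float).ravel()
    n0 = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    W0 = rng.normal(0.0, cfg.sigma, size=(width, n0))
    phi0 = np.maximum(X @ W0.T / np.sqrt(n0), 0.0)
    a, resid = _min_norm_head(phi0, Y)
    if resid <= cfg.tol:
        return MultiheadNet(W=W0.copy(), heads=[a], W0=W0, W1=W0.copy(),
                            sigma=cfg.sigma, train_loss=resid)
    W, a, loss, ok = _continuation(X, Y, W0, a, cfg, a_pen_ratio=1.0,
                                   require_dw_stable=False)
    if not ok:
        raise RuntimeError(
            f"task-1 training did not reach tolerance {cfg.tol:.1e}; "
            f"final normalized loss {loss:.3e}"
        )
    return MultiheadNet(W=W, heads=[a], W0=W0, W1=W.copy(), sigma=cfg.sigma,
                        train_loss=loss)


def continue_task2(net: MultiheadNet, task2: TaskDataset, cfg: TrainConfig) -> MultiheadNet:
    """Learn a second task with a fresh head and penalized hidden weights.

    ``cfg.lam = inf``: if the new head alone interpolates on the frozen
    post-task-1 features, that exact solution is returned (zero weight
    change); otherwise penalty continuation finds the minimum-perturbation
    interpolator.  Finite ``cfg.lam``: a single penalized solve of
    ``0.5||r||^2 + 0.5 lam ||W - W1||^2 + 0.5 ridge ||a2||^2``.
    ``cfg.lam = 0``: task 2 is learned exactly as a first task from the
    original initialization ``W0`` (no memory of task 1 in the weights).
    The task-1 head is never touched.
    """
    if net.W1 is None:
        raise ValueError("net has not completed task 1")
    X = np.asarray(task2.X, float)
    Y = np.asarray(task2.Y, float).ravel()
    n0 = X.shape[1]
    W1 = net.W1

    if cfg.lam == 0.0:
        fresh = train_task1(task2, net.width, cfg)
        return MultiheadNet(W=fresh.W, heads=[net.heads[0].copy(), fresh.heads[0]],
                            W0=net.W0, W1=W1, sigma=net.sigma,
                            converged=fresh.converged, train_loss=fresh.train_loss)

    phi1 = np.maximum(X @ W1.T / np.sqrt(n0), 0.0)
    a2, resid = _min_norm_head(phi1, Y)
    if math.isinf(cfg.lam):
        if resid <= cfg.tol:
            return MultiheadNet(W=W1.copy(), heads=[net.heads[0].copy(), a2],
                                W0=net.W0, W1=W1, sigma=net.sigma,
                                train_loss=resid)
        W, a2, loss, ok = _continuation(
            X, Y, W1, a2, cfg, a_pen_ratio=cfg.head_ridge_ratio
        )
        if not ok:
            raise RuntimeError(
                f"task-2 interpolation stuck above tolerance: loss {loss:.3e}; "
                "the width may be too small for this load"
            )
    else:
        w = _lbfgs_W(
            W1.ravel().copy(),
            (X, Y, net.width, n0, W1, cfg.lam, cfg.ridge),
            cfg.max_iter,
        )
        W = w.reshape(net.width, n0)
        phi = np.maximum(X @ W.T / np.sqrt(n0), 0.0)
        a2 = _ridge_head(phi, Y, cfg.ridge)
        loss = _train_loss(W, a2, X, Y, n0)
    return MultiheadNet(W=W, heads=[net.heads[0].copy(), a2], W0=net.W0, W1=W1,
                        sigma=net.sigma, train_loss=loss)


def baseline_task2(
    task2: TaskDataset, width: int, cfg: TrainConfig,
    n_seeds: int = 5, eta: float = 0.1,
) -> tuple[float, float]:
    """Solo-learning generalization baseline ``G20`` on a perturbed test set.

    Trains the task from fresh initializations and evaluates the raw
    normalized test loss on ``eta``-perturbed training inputs; returns
    (mean, SD) over seeds.
    """
    losses = []
    for k in range(n_seeds):
        cfg_k = replace(cfg, seed=cfg.seed + 1000 + k)
        net = train_task1(task2, width, cfg_k)
        test = perturbed_test(task2, eta, seed=cfg_k.seed)
        pred = net.predict(test.X, head=0)
        losses.append(float(np.sum((pred - test.Y) ** 2) / (test.Y @ test.Y)))
    return float(np.mean(losses)), float(np.std(losses))


def multihead_metrics(
    net: MultiheadNet,
    task1: TaskDataset,
    task2: TaskDataset,
    test1: TaskDataset,
    test2: TaskDataset,
    G20: float,
    G10: float | None = None,
) -> MultiheadMetrics:
    """Forgetting, anterograde, and norm diagnostics after two tasks.

    ``G22`` is the task-2 test loss divided by the solo baseline ``G20``;
    ``G21`` is divided by ``G10`` when given (else reported as the raw
    normalized test loss).
    """
    if not G20 > 0:
        raise ValueError("G20 must be positive")
    pred1 = net.predict(task1.X, head=0)
    F21 = float(np.sum((pred1 - task1.Y) ** 2) / (task1.Y @ task1.Y))
    t1 = net.predict(test1.X, head=0)
    g21_raw = float(np.sum((t1 - test1.Y) ** 2) / (test1.Y @ test1.Y))
    t2 = net.predict(test2.X, head=1)
    g22_raw = float(np.sum((t2 - test2.Y) ** 2) / (test2.Y @ test2.Y))
    return MultiheadMetrics(
        F21=F21,
        G21=g21_raw / G10 if G10 else g21_raw,
        G22=g22_raw / G20,
        G20=G20,
        a2_norm=float(net.heads[1] @ net.heads[1]) / net.width,
        dW_norm=float(np.sum((net.W - net.W1) ** 2)),
    )


# ---------------------------------------------------------------------------
# empirical phase boundary
# ---------------------------------------------------------------------------


def empirical_alpha_c(
    alphas: np.ndarray, F21_values: np.ndarray, threshold: float = 0.01
) -> float:
    """Load at which seed-averaged forgetting first exceeds ``threshold``.

    Linearly interpolates between the bracketing grid points; returns ``inf``
    if the curve never crosses.
    """
    alphas = np.asarray(alphas, float)
    F = np.asarray(F21_values, float)
    if len(alphas) < 5:
        raise ValueError("need a grid of at least 5 loads")
    if np.any(np.diff(alphas) <= 0):
        raise ValueError("alpha grid must be strictly increasing")
    above = F > threshold
    if not above.any():
        return math.inf
    i = int(np.argmax(above))
    if i == 0:
        return float(alphas[0])
    a_lo, a_hi = alphas[i - 1], alphas[i]
    f_lo, f_hi = F[i - 1], F[i]
    return float(a_lo + (threshold - f_lo) / (f_hi - f_lo) * (a_hi - a_lo))


def head_interpolation_boundary(
    width: int,
    alphas: np.ndarray,
    input_dim: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    resolution: float = 0.05,
) -> float:
    """Load at which head-only interpolation of a generic task becomes
    infeasible with frozen random hidden weights.

    For each load, a Gaussian task of ``P = round(alpha * width)`` examples is
    fit by least squares on frozen random ReLU features; feasible means the
    normalized residual falls below ``tol``.  The feasible/infeasible boundary
    is bisected to ``+- resolution`` and its midpoint returned.
    """
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 1.0, size=(width, input_dim))

    def feasible(alpha: float) -> bool:
        P = int(round(alpha * width))
        X = normalize_inputs(rng.standard_normal((P, input_dim)))
        Y = np.where(rng.random(P) < 0.5, -1.0, 1.0)
        phi = np.maximum(X @ W.T / np.sqrt(input_dim), 0.0)
        _, resid = _min_norm_head(phi, Y)
        return resid <= tol

    alphas = np.sort(np.asarray(alphas, float))
    flags = [feasible(a) for a in alphas]
    if all(flags) or not any(flags):
        raise ValueError("grid does not bracket the feasibility boundary")
    i = int(np.argmin(flags))  # first infeasible
    lo, hi = alphas[i - 1], alphas[i]
    while hi - lo > 2.0 * resolution:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# experiment helpers
# ---------------------------------------------------------------------------


def gaussian_overlap_pair(
    P: int, input_dim: int, overlap: float, seed: int = 0
) -> tuple[TaskDataset, TaskDataset]:
    """Two Gaussian tasks sharing a fraction ``overlap`` of (input, label)
    pairs; the remainder is fresh inputs with fresh balanced ±1 labels.

    A convenient one-knob family for dialing ``gamma_sim`` between ~0
    (disjoint) and 1 (identical)."""
    params = TargetDistractorParams(
        rho_shared=overlap, rho_target=overlap, rho_flip=0.0,
        target_fraction=1.0, P=P, T=2, seed=seed,
    )
    pool = make_gaussian_pool(2 * P + P, input_dim, seed=seed + 7919)
    seq = target_distractor_sequence(pool, params)
    return seq[0], seq[1]


def phase_scan(
    pair_factory,
    width: int,
    alphas: np.ndarray,
    cfg: TrainConfig,
    n_seeds: int = 3,
    eta: float = 0.1,
) -> pd.DataFrame:
    """Sweep the load grid with the lambda->inf trainer.

    ``pair_factory(P, seed)`` must return a two-task tuple.  Returns one row
    per (alpha, seed) with forgetting, generalization, and norm metrics.
    """
    rows = []
    for alpha in alphas:
        P = int(round(alpha * width))
        for s in range(n_seeds):
            task1, task2 = pair_factory(P, cfg.seed + 17 * s)
            cfg_s = replace(cfg, seed=cfg.seed + 17 * s)
            net = train_task1(task1, width, cfg_s)
            net = continue_task2(net, task2, cfg_s)
            G20, _ = baseline_task2(task2, width, cfg_s, n_seeds=3, eta=eta)
            test1 = perturbed_test(task1, eta, seed=cfg_s.seed + 1)
            test2 = perturbed_test(task2, eta, seed=cfg_s.seed + 2)
            m = multihead_metrics(net, task1, task2, test1, test2, G20)
            rows.append({
                "alpha": float(alpha), "seed": s, "F21": m.F21, "G21": m.G21,
                "G22": m.G22, "a2_norm": m.a2_norm, "dW_norm": m.dW_norm,
            })
    return pd.DataFrame(rows)


def lambda_sweep(
    task1: TaskDataset,
    task2: TaskDataset,
    width: int,
    cfg: TrainConfig,
    lambdas: np.ndarray,
    n_seeds: int = 2,
    eta: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """Trade-off scan over the perturbation-penalty scale.

    Returns the per-lambda seed-averaged metric table and the grid lambda
    minimizing ``max(G21, G22)`` (both normalized by their solo baselines).
    """
    lambdas = np.asarray(lambdas, float)
    if len(lambdas) < 8:
        raise ValueError("lambda grid should have at least 8 points")
    rows = []
    for s in range(n_seeds):
        cfg_s = replace(cfg, seed=cfg.seed + 31 * s)
        net1 = train_task1(task1, width, cfg_s)
        G20, _ = baseline_task2(task2, width, cfg_s, n_seeds=3, eta=eta)
        G10, _ = baseline_task2(task1, width, cfg_s, n_seeds=3, eta=eta)
        test1 = perturbed_test(task1, eta, seed=cfg_s.seed + 1)
        test2 = perturbed_test(task2, eta, seed=cfg_s.seed + 2)
        for lam in lambdas:
            net = continue_task2(net1, task2, replace(cfg_s, lam=float(lam)))
            m = multihead_metrics(net, task1, task2, test1, test2, G20, G10=G10)
            rows.append({
                "lam": float(lam), "seed": s, "F21": m.F21, "G21": m.G21,
                "G22": m.G22, "max_G": max(m.G21, m.G22),
                "a2_norm": m.a2_norm, "dW_norm": m.dW_norm,
            })
    table = pd.DataFrame(rows)
    mean = table.groupby("lam", sort=True)["max_G"].mean()
    return table, float(mean.idxmin())


# ---------------------------------------------------------------------------
# representation similarity
# ---------------------------------------------------------------------------


def representation_similarity(
    net: MultiheadNet,
    X: np.ndarray,
    reference_W: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> RepSimilarity:
    """Hidden-layer similarity matrix and its learned component.

    ``K(X) = Phi Phiᵀ / N`` under the current weights, minus the same kernel
    under ``reference_W`` (default: the random initialization ``W0``).  When
    ±1 ``labels`` are given, the block score is the mean within-class minus
    mean between-class entry of the learned component — positive when the
    representation has clustered by task label.
    """
    X = np.asarray(X, float)
    if X.size == 0:
        raise ValueError("X is empty")
    ref = net.W0 if reference_W is None else reference_W
    phi_after = net.features(X)
    phi_before = net.features(X, W=ref)
    K_after = phi_after @ phi_after.T / net.width
    K_before = phi_before @ phi_before.T / net.width
    score = None
    if labels is not None:
        y = np.asarray(labels, float).ravel()
        learned = K_after - K_before
        same = np.outer(y, y) > 0
        off = ~np.eye(len(y), dtype=bool)
        score = float(learned[same & off].mean() - learned[~same & off].mean())
    return RepSimilarity(K_before=K_before, K_after=K_after, block_score=score)
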