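"""Parametric task-sequence generators for continual-learning experiments.

A *task* is a dataset ``(X, Y)`` of ``P`` labelled inputs; a *sequence* is an
ordered list of tasks of identical size produced by one generation protocol.
Three protocols with controllable between-task relations are implemented:

* **target-distractor** — tasks draw ``P`` stimuli from a common pool; a
  fraction ``rho_shared`` of stimuli is reused in every task, a fraction
  ``rho_target`` of the ±1-labelled ("target") stimuli sits on the shared set,
  and shared target labels are flipped between tasks with probability
  ``rho_flip``.  The three knobs independently steer the feature-overlap,
  relevant-feature, and rule-similarity order parameters.
* **permutation** — every task applies a fresh random permutation of a subset
  of input coordinates (a fraction ``perm_ratio`` of them); labels unchanged.
* **split** — each task draws its examples from its own disjoint set of source
  classes, binarized by a per-task random balanced dichotomy.

All generators are pure functions of their arguments and a seed.  Fractional
counts round half away from zero and every derived count is recorded in the
task metadata for auditability.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import normalize_inputs

__all__ = [
    "ParameterInfeasibleError",
    "StimulusPool",
    "TaskDataset",
    "TaskSequence",
    "TargetDistractorParams",
    "make_gaussian_pool",
    "target_distractor_sequence",
    "permutation_sequence",
    "split_sequence",
    "split_ratio_pair",
    "perturbed_test",
    "binarize_labels",
    "validate_sequence",
    "save_sequence",
    "load_sequence",
]


class ParameterInfeasibleError(ValueError):
    """Raised when protocol parameters imply inconsistent index-set sizes."""


def _round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1), unlike banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class StimulusPool:
    """A pool of candidate stimuli tasks draw from (rows normalized)."""

    X: np.ndarray
    labels: np.ndarray | None = None
    seed: int | None = None

    @property
    def size(self) -> int:
        return self.X.shape[0]

    @property
    def input_dim(self) -> int:
        return self.X.shape[1]


@dataclass
class TaskDataset:
    """One task's inputs ``X`` (P x N0) and labels ``Y`` (P,)."""

    X: np.ndarray
    Y: np.ndarray
    task_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")

    def validate(self) -> None:
        if np.linalg.norm(self.Y) == 0:
            raise ValueError(f"task {self.task_id} has an all-zero label vector")
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"task {self.task_id} has non-finite inputs")

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]


@dataclass
class TaskSequence:
    """An ordered sequence of same-size tasks sharing one protocol."""

    tasks: list[TaskDataset]
    protocol: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.tasks) < 2:
            raise ValueError("a task sequence needs at least 2 tasks")
        shapes = {t.X.shape for t in self.tasks}
        if len(shapes) != 1:
            raise ValueError("all tasks must share P and N0")

    def __len__(self) -> int:
        return len(self.tasks)

    def __getitem__(self, i: int) -> TaskDataset:
        return self.tasks[i]


def validate_sequence(seq: TaskSequence) -> None:
    """Check every task's invariants; raises on the first violation."""
    for task in seq.tasks:
        task.validate()


# ---------------------------------------------------------------------------
# gaussian pool
# ---------------------------------------------------------------------------


def make_gaussian_pool(M: int, N0: int, seed: int = 0) -> StimulusPool:
    """``M`` i.i.d. standard-normal stimuli in ``N0`` dimensions, normalized."""
    if M < 1 or N0 < 1:
        raise ValueError("M and N0 must be >= 1")
    rng = np.random.default_rng(seed)
    X = normalize_inputs(rng.standard_normal((M, N0)))
    return StimulusPool(X=X, seed=seed)


# ---------------------------------------------------------------------------
# target-distractor protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetDistractorParams:
    """Knobs of the target-distractor protocol.

    ``rho_shared`` — fraction of each task's ``P`` stimuli reused across all
    tasks; ``rho_target`` — fraction of the ±1-labelled stimuli that lie on the
    shared set; ``rho_flip`` — per-stimulus probability that a shared target
    label is flipped in task t>1 relative to task 1; ``target_fraction`` —
    fraction of stimuli carrying ±1 (vs. 0) labels.
    """

    rho_shared: float
    rho_target: float
    rho_flip: float
    target_fraction: float = 0.5
    P: int = 100
    T: int = 2
    seed: int = 0
    cap_shared_targets: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_shared <= 1.0:
            raise ValueError("rho_shared must be in [0, 1]")
        if not 0.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must be in [0, 1]")
        if not 0.0 <= self.rho_flip <= 0.5:
            raise ValueError("rho_flip must be in [0, 0.5]")
        if not 0.0 < self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in (0, 1]")
        if self.P < 1 or self.T < 2:
            raise ValueError("need P >= 1 and T >= 2")

    @property
    def n_shared(self) -> int:
        return _round_half_away(self.rho_shared * self.P)

    @property
    def n_target(self) -> int:
        return _round_half_away(self.target_fraction * self.P)

    @property
    def n_shared_target(self) -> int:
        n = _round_half_away(self.rho_target * self.n_target)
        if not self.cap_shared_targets:
            return n
        # clamp to the feasible interval: at most every shared stimulus is a
        # target, and targets that cannot fit on unique stimuli must be shared
        lo = max(0, self.n_target - (self.P - self.n_shared))
        return min(max(n, lo), self.n_shared, self.n_target)


def _balanced_signs(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random ±1 vector balanced up to one element."""
    signs = np.ones(n)
    signs[: n // 2] = -1.0
    rng.shuffle(signs)
    return signs


def target_distractor_sequence(
    pool: StimulusPool, params: TargetDistractorParams
) -> TaskSequence:
    """Build a target-distractor sequence from a stimulus pool.

    Task 1 fixes the shared stimuli, the shared target subset, and the task-1
    labels; every later task reuses the shared stimuli, draws its own unique
    stimuli, and independently flips each shared target label with probability
    ``rho_flip`` *relative to task 1*, so all pairs (1, t) have identical
    statistics.  Shared non-target stimuli keep label 0 in every task.

    By default the shared-target count is capped at the shared count (the
    effective ``rho_target`` saturates once every shared stimulus is a
    target); with ``cap_shared_targets=False`` inconsistent counts raise
    :class:`ParameterInfeasibleError` instead.
    """
    P, T = params.P, params.T
    n_sh, n_tg, n_tg_sh = params.n_shared, params.n_target, params.n_shared_target
    if n_tg_sh > n_sh:
        raise ParameterInfeasibleError(
            f"round(rho_target * n_target) = {n_tg_sh} exceeds the shared count "
            f"{n_sh}; lower rho_target or raise rho_shared"
        )
    n_unique = P - n_sh
    if n_tg - n_tg_sh > n_unique:
        raise ParameterInfeasibleError(
            f"{n_tg - n_tg_sh} unique targets required but only {n_unique} "
            "unique stimuli per task are available"
        )
    needed = n_sh + T * n_unique
    if pool.size < needed:
        raise ParameterInfeasibleError(
            f"pool of {pool.size} stimuli cannot supply {needed} distinct rows"
        )

    rng = np.random.default_rng(params.seed)
    order = rng.permutation(pool.size)
    shared_idx = order[:n_sh]
    # among shared stimuli, which ones carry +-1 labels (same across tasks)
    shared_target_pos = rng.choice(n_sh, size=n_tg_sh, replace=False) if n_sh else np.array([], int)
    base_shared_signs = _balanced_signs(n_tg_sh, rng)

    tasks: list[TaskDataset] = []
    cursor = n_sh
    for t in range(T):
        unique_idx = order[cursor : cursor + n_unique]
        cursor += n_unique
        idx = np.concatenate([shared_idx, unique_idx]).astype(int)
        Y = np.zeros(P)
        if t == 0:
            shared_signs = base_shared_signs
        else:
            flips = rng.random(n_tg_sh) < params.rho_flip
            shared_signs = np.where(flips, -base_shared_signs, base_shared_signs)
        Y[shared_target_pos] = shared_signs
        n_tg_unique = n_tg - n_tg_sh
        unique_target_pos = (
            n_sh + rng.choice(n_unique, size=n_tg_unique, replace=False)
            if n_tg_unique
            else np.array([], int)
        )
        Y[unique_target_pos.astype(int)] = _balanced_signs(n_tg_unique, rng)
        tasks.append(
            TaskDataset(
                X=pool.X[idx],
                Y=Y,
                task_id=t,
                meta={
                    "pool_indices": idx.tolist(),
                    "shared_positions": list(range(n_sh)),
                    "shared_target_positions": shared_target_pos.tolist(),
                    "n_shared": n_sh,
                    "n_target": n_tg,
                    "n_shared_target": n_tg_sh,
                },
            )
        )
    return TaskSequence(
        tasks=tasks,
        protocol="target_distractor",
        params={
            "rho_shared": params.rho_shared,
            "rho_target": params.rho_target,
            "rho_flip": params.rho_flip,
            "target_fraction": params.target_fraction,
            "P": P,
            "T": T,
        },
        seed=params.seed,
    )


# ---------------------------------------------------------------------------
# permutation protocol
# ---------------------------------------------------------------------------


def permutation_sequence(
    X: np.ndarray,
    Y: np.ndarray,
    T: int,
    perm_ratio: float,
    seed: int = 0,
) -> TaskSequence:
    """Tasks that permute a random subset of input coordinates.

    Task 1 is ``(X, Y)`` unchanged; each later task shuffles a freshly chosen
    subset of ``round(perm_ratio * N0)`` coordinates (the same permutation for
    every row), leaving labels untouched.  Per-example input norms are exactly
    preserved.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not 0.0 <= perm_ratio <= 1.0:
        raise ValueError("perm_ratio must be in [0, 1]")
    n0 = X.shape[1]
    k = _round_half_away(perm_ratio * n0)
    if perm_ratio > 0 and k < 2:
        warnings.warn(
            "perm_ratio rounds to fewer than 2 coordinates; permuting 2",
            stacklevel=2,
        )
        k = 2
    rng = np.random.default_rng(seed)
    tasks = [TaskDataset(X=X.copy(), Y=Y.copy(), task_id=0,
                         meta={"permutation": list(range(n0))})]
    for t in range(1, T):
        perm = np.arange(n0)
        if k:
            subset = rng.choice(n0, size=k, replace=False)
            perm[subset] = subset[rng.permutation(k)]
        tasks.append(
            TaskDataset(
                X=X[:, perm], Y=Y.copy(), task_id=t,
                meta={"permutation": perm.tolist()},
            )
        )
    return TaskSequence(
        tasks=tasks, protocol="permutation",
        params={"perm_ratio": perm_ratio, "T": T, "n_permuted": k}, seed=seed,
    )


# ---------------------------------------------------------------------------
# split protocols
# ---------------------------------------------------------------------------


def binarize_labels(
    labels: np.ndarray,
    dichotomy: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Map multiway class labels to ±1 via a (possibly random) dichotomy.

    ``dichotomy`` maps each class to +1 or -1; if absent, a random balanced
    partition of the present classes is drawn from ``seed``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if dichotomy is None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(classes))
        dichotomy = {
            classes[i]: (1.0 if rank < len(classes) // 2 + len(classes) % 2 else -1.0)
            for rank, i in enumerate(order)
        }
    missing = [c for c in classes if c not in dichotomy]
    if missing:
        raise ValueError(f"classes {missing} are not assigned by the dichotomy")
    return np.array([dichotomy[c] for c in labels], dtype=float)


def _draw_stratified(
    X: np.ndarray, labels: np.ndarray, classes: np.ndarray, P: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ~P/len(classes) examples of each class; returns (indices, classes)."""
    base, extra = divmod(P, len(classes))
    counts = np.full(len(classes), base)
    counts[rng.permutation(len(classes))[:extra]] += 1
    idx_parts = []
    for c, cnt in zip(classes, counts):
        pool_idx = np.flatnonzero(labels == c)
        if pool_idx.size < cnt:
            raise ValueError(
                f"class {c} has only {pool_idx.size} examples, {cnt} needed"
            )
        idx_parts.append(rng.choice(pool_idx, size=cnt, replace=False))
    idx = np.concatenate(idx_parts)
    rng.shuffle(idx)
    return idx, labels[idx]


def split_sequence(
    X: np.ndarray,
    labels: np.ndarray,
    T: int,
    classes_per_task: int,
    P: int,
    seed: int = 0,
) -> TaskSequence:
    """Class-split sequence: each task owns a disjoint set of source classes.

    Examples are drawn stratified (as evenly as possible across the task's
    classes) and binarized by a per-task random balanced dichotomy.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if T * classes_per_task > len(classes):
        raise ValueError(
            f"{T} tasks x {classes_per_task} classes need "
            f"{T * classes_per_task} classes, only {len(classes)} available"
        )
    rng = np.random.default_rng(seed)
    class_order = rng.permutation(classes)
    tasks = []
    for t in range(T):
        task_classes = class_order[t * classes_per_task : (t + 1) * classes_per_task]
        idx, cls = _draw_stratified(X, labels, task_classes, P, rng)
        dichotomy = {
            c: s
            for c, s in zip(task_classes, _balanced_signs(classes_per_task, rng))
        }
        tasks.append(
            TaskDataset(
                X=X[idx],
                Y=binarize_labels(cls, dichotomy),
                task_id=t,
                meta={
                    "classes": [c.item() if hasattr(c, "item") else c for c in task_classes],
                    "source_indices": idx.tolist(),
                    "dichotomy": {str(k): v for k, v in dichotomy.items()},
                },
            )
        )
    return TaskSequence(
        tasks=tasks, protocol="split",
        params={"classes_per_task": classes_per_task, "P": P, "T": T}, seed=seed,
    )


def split_ratio_pair(
    X: np.ndarray,
    labels: np.ndarray,
    split_ratio: float,
    P: int,
    seed: int = 0,
    classes_per_task: int = 2,
) -> TaskSequence:
    """Two-task sequence whose similarity is tuned by a split ratio.

    Task 2 copies task 1 but replaces ``round(split_ratio * P)`` of its
    examples with examples from classes unused by task 1, labelled by a fresh
    dichotomy over the replacement classes.  ``split_ratio=0`` gives identical
    tasks, ``split_ratio=1`` fully disjoint ones.
    """
    if not 0.0 <= split_ratio <= 1.0:
        raise ValueError("split_ratio must be in [0, 1]")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if 2 * classes_per_task > len(classes):
        raise ValueError("need at least 2 * classes_per_task distinct classes")
    rng = np.random.default_rng(seed)
    class_order = rng.permutation(classes)
    cls1 = class_order[:classes_per_task]
    cls2 = class_order[classes_per_task : 2 * classes_per_task]
    idx1, src1 = _draw_stratified(X, labels, cls1, P, rng)
    dich1 = {c: s for c, s in zip(cls1, _balanced_signs(classes_per_task, rng))}
    Y1 = binarize_labels(src1, dich1)

    n_replace = _round_half_away(split_ratio * P)
    replace_pos = rng.choice(P, size=n_replace, replace=False) if n_replace else np.array([], int)
    X2 = X[idx1].copy()
    Y2 = Y1.copy()
    if n_replace:
        ridx, rsrc = _draw_stratified(X, labels, cls2, n_replace, rng)
        dich2 = {c: s for c, s in zip(cls2, _balanced_signs(classes_per_task, rng))}
        X2[replace_pos] = X[ridx]
        Y2[replace_pos] = binarize_labels(rsrc, dich2)
    tasks = [
        TaskDataset(X=X[idx1], Y=Y1, task_id=0,
                    meta={"classes": [str(c) for c in cls1],
                          "source_indices": idx1.tolist()}),
        TaskDataset(X=X2, Y=Y2, task_id=1,
                    meta={"replaced_positions": replace_pos.tolist(),
                          "classes_new": [str(c) for c in cls2]}),
    ]
    return TaskSequence(
        tasks=tasks, protocol="split_ratio",
        params={"split_ratio": split_ratio, "P": P, "n_replaced": n_replace},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# perturbed test sets
# ---------------------------------------------------------------------------


def perturbed_test(task: TaskDataset, eta: float, seed: int = 0) -> TaskDataset:
    """Training inputs plus Gaussian noise of relative scale ``eta``.

    ``X' = normalize(X + eta * Z)`` with ``Z`` i.i.d. standard normal, so the
    expected perturbation norm per row is ``eta * sqrt(N0)`` — a fraction
    ``eta`` of the input norm.  Labels are unchanged.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal(task.X.shape)
    Xp = normalize_inputs(task.X + eta * Z) if eta > 0 else normalize_inputs(task.X)
    return TaskDataset(
        X=Xp, Y=task.Y.copy(), task_id=task.task_id,
        meta={**task.meta, "perturbation_eta": eta, "perturbation_seed": seed},
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_sequence(seq: TaskSequence, directory: str | Path) -> Path:
    """Write a sequence as ``X_t.npy``/``Y_t.npy`` pairs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t, task in enumerate(seq.tasks):
        np.save(directory / f"X_{t}.npy", task.X)
        np.save(directory / f"Y_{t}.npy", task.Y)
    manifest = {
        "protocol": seq.protocol,
        "params": seq.params,
        "seed": seq.seed,
        "T": len(seq),
        "task_meta": [task.meta for task in seq.tasks],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_sequence(directory: str | Path) -> TaskSequence:
    """Load a sequence saved by :func:`save_sequence`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    tasks = [
        TaskDataset(
            X=np.load(directory / f"X_{t}.npy"),
            Y=np.load(directory / f"Y_{t}.npy"),
            task_id=t,
            meta=manifest["task_meta"][t],
        )
        for t in range(manifest["T"])
    ]
    return TaskSequence(
        tasks=tasks, protocol=manifest["protocol"],
        params=manifest["params"], seed=manifest["seed"],
    )
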