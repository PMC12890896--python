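"""Hidden-layer representations of wide random ReLU networks.

Two interchangeable routes to the geometry of a task's last-hidden-layer
features are provided:

* an explicit *finite-width* route — :func:`sample_features` draws the random
  hidden weights and returns the ``P x N`` activation matrix of the ``P``
  inputs at the last hidden layer;
* an exact *infinite-width* route — :func:`nngp_gram` evaluates the depth-``L``
  arc-cosine (NNGP) ReLU kernel, which is the almost-sure limit of
  ``Phi(X) Phi(X')ᵀ / N`` as the layer width ``N`` grows.

Everything downstream (order parameters, forgetting simulators) consumes a
:class:`GramSet`, the pair/cross Gram blocks of two tasks, so the finite and
infinite routes are drop-in replacements for each other.

Conventions: every hidden layer has the same width ``N``; pre-activations are
divided by the square root of the fan-in; weights are i.i.d. Gaussian with
mean zero and variance ``sigma**2``.  Inputs are normalized to Euclidean norm
``sqrt(N0)`` so that the kernel diagonal is O(1) and angles between inputs are
well defined.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DegenerateInputError",
    "FeatureMapSpec",
    "FeatureEnsemble",
    "GramSet",
    "normalize_inputs",
    "sample_features",
    "nngp_gram",
    "load_inputs",
]


class DegenerateInputError(ValueError):
    """Raised when an input matrix cannot be normalized or featurized."""


# ---------------------------------------------------------------------------
# specs and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureMapSpec:
    """Architecture of a random ReLU feature map.

    Parameters
    ----------
    depth
        Number of hidden layers ``L`` (>= 1).
    width
        Neurons per hidden layer ``N`` (>= 1); all layers share it.
    input_dim
        Input dimensionality ``N0``.
    weight_scale
        Standard deviation ``sigma`` of the i.i.d. Gaussian weights.
    activation
        Only ``"relu"`` is supported.
    seed
        Seed of the weight draw; equal specs produce bit-identical features.
    """

    depth: int
    width: int
    input_dim: int
    weight_scale: float = 1.0
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.width < 1:
            raise ValueError(f"width must be >= 1, got {self.width}")
        if self.input_dim < 1:
            raise ValueError(f"input_dim must be >= 1, got {self.input_dim}")
        if not self.weight_scale > 0:
            raise ValueError(f"weight_scale must be > 0, got {self.weight_scale}")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")


@dataclass
class FeatureEnsemble:
    """Last-hidden-layer activations ``P x N`` of one task's inputs."""

    matrix: np.ndarray
    spec: FeatureMapSpec

    @property
    def n_examples(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# input handling
# ---------------------------------------------------------------------------


def normalize_inputs(X: np.ndarray) -> np.ndarray:
    """Rescale each row of ``X`` to Euclidean norm ``sqrt(N0)``.

    Idempotent; preserves row order and sign.  Raises
    :class:`DegenerateInputError` naming the first all-zero row, since such a
    row has no direction to preserve.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D input matrix, got shape {X.shape}")
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise DegenerateInputError(f"input row {zero[0]} is all zeros")
    return X * (np.sqrt(X.shape[1]) / norms)[:, None]


def sample_features(spec: FeatureMapSpec, X: np.ndarray) -> FeatureEnsemble:
    """Propagate ``X`` through a freshly drawn random ReLU network.

    ``h^0 = x`` and ``h^l = relu(W^l h^{l-1} / sqrt(fan_in))`` with entries of
    ``W^l`` i.i.d. ``N(0, sigma^2)``.  Deterministic given ``spec.seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ValueError(
            f"input has shape {X.shape}, expected (P, {spec.input_dim})"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite values")
    rng = np.random.default_rng(spec.seed)
    h = X
    fan_in = spec.input_dim
    for _ in range(spec.depth):
        W = rng.normal(0.0, spec.weight_scale, size=(spec.width, fan_in))
        h = np.maximum(h @ W.T / np.sqrt(fan_in), 0.0)
        fan_in = spec.width
    return FeatureEnsemble(h, spec)


# ---------------------------------------------------------------------------
# infinite-width kernel
# ---------------------------------------------------------------------------


def _arccos_step(cov: np.ndarray, var1: np.ndarray, var2: np.ndarray) -> np.ndarray:
    """One ReLU layer of the kernel recursion: ``E[relu(u) relu(v)]``.

    ``(u, v)`` is zero-mean Gaussian with variances ``var1``/``var2`` and
    covariance ``cov`` (broadcast elementwise).  Closed form:
    ``sqrt(var1*var2)/(2 pi) * (sin t + (pi - t) cos t)`` with ``t`` the angle.
    """
    scale = np.sqrt(var1 * var2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.clip(np.where(scale > 0, cov / scale, 0.0), -1.0, 1.0)
    theta = np.arccos(cos)
    return scale / (2.0 * np.pi) * (np.sin(theta) + (np.pi - theta) * cos)


def nngp_gram(
    depth: int,
    sigma: float,
    X: np.ndarray,
    X2: np.ndarray | None = None,
) -> np.ndarray:
    """Depth-``L`` arc-cosine (NNGP) ReLU kernel matrix ``K^L(X, X2)``.

    The recursion starts from the linear kernel ``K^0 = X X2ᵀ / N0`` and
    applies ``K^l = sigma^2 E[relu(u) relu(v)]`` per layer, where the Gaussian
    pair ``(u, v)`` has second moments given by ``K^{l-1}``.  The self-variance
    recursion for ReLU is simply ``d^l = sigma^2 d^{l-1} / 2``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    X = np.asarray(X, dtype=float)
    Xb = X if X2 is None else np.asarray(X2, dtype=float)
    if X.shape[1] != Xb.shape[1]:
        raise ValueError(
            f"input dimensions differ: {X.shape[1]} vs {Xb.shape[1]}"
        )
    n0 = X.shape[1]
    var1 = np.einsum("ij,ij->i", X, X) / n0
    var2 = np.einsum("ij,ij->i", Xb, Xb) / n0
    cov = X @ Xb.T / n0
    for _ in range(depth):
        if np.any(var1 < 0) or np.any(var2 < 0):
            raise DegenerateInputError(
                "negative self-kernel encountered; input normalization is broken"
            )
        cov = sigma**2 * _arccos_step(cov, var1[:, None], var2[None, :])
        var1 = sigma**2 * var1 / 2.0
        var2 = sigma**2 * var2 / 2.0
    return cov


# ---------------------------------------------------------------------------
# Gram blocks
# ---------------------------------------------------------------------------


@dataclass
class GramSet:
    """Pairwise Gram blocks of two tasks' hidden-layer features.

    ``g11``/``g22`` are the within-task Grams, ``g12`` the cross block, with
    the convention ``G_ij = X_i^L (X_j^L)ᵀ / N`` on the finite-width path or
    the depth-``L`` kernel matrix on the infinite-width path (where no width
    appears at all).  ``jitter`` is the relative diagonal regularizer used
    when blocks are inverted downstream.
    """

    g11: np.ndarray
    g22: np.ndarray
    g12: np.ndarray
    jitter: float = 1e-10

    def __post_init__(self) -> None:
        p1, p2 = self.g12.shape
        if self.g11.shape != (p1, p1) or self.g22.shape != (p2, p2):
            raise ValueError("inconsistent Gram block shapes")

    @property
    def g21(self) -> np.ndarray:
        return self.g12.T

    @classmethod
    def from_features(
        cls, f1: FeatureEnsemble | np.ndarray, f2: FeatureEnsemble | np.ndarray,
        jitter: float = 1e-10,
    ) -> "GramSet":
        """Finite-width blocks ``X_i X_jᵀ / N`` from explicit features."""
        m1 = f1.matrix if isinstance(f1, FeatureEnsemble) else np.asarray(f1, float)
        m2 = f2.matrix if isinstance(f2, FeatureEnsemble) else np.asarray(f2, float)
        if m1.shape[1] != m2.shape[1]:
            raise ValueError("feature widths differ between tasks")
        n = m1.shape[1]
        return cls(m1 @ m1.T / n, m2 @ m2.T / n, m1 @ m2.T / n, jitter=jitter)

    @classmethod
    def from_kernel(
        cls, X1: np.ndarray, X2: np.ndarray, depth: int = 1,
        sigma: float = 1.0, jitter: float = 1e-10,
    ) -> "GramSet":
        """Infinite-width blocks from the depth-``L`` NNGP kernel."""
        return cls(
            nngp_gram(depth, sigma, X1),
            nngp_gram(depth, sigma, X2),
            nngp_gram(depth, sigma, X1, X2),
            jitter=jitter,
        )

    def joint(self) -> np.ndarray:
        """The stacked ``(P1+P2) x (P1+P2)`` joint Gram matrix."""
        top = np.hstack([self.g11, self.g12])
        bottom = np.hstack([self.g21, self.g22])
        return np.vstack([top, bottom])


# ---------------------------------------------------------------------------
# file loaders
# ---------------------------------------------------------------------------


def _load_idx(path: Path) -> np.ndarray:
    """Read an IDX (MNIST-style) file into a float array scaled to [0, 1]."""
    raw = path.read_bytes()
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", raw[:4])
    if zero1 != 0 or zero2 != 0:
        raise ValueError(f"{path} is not an IDX file")
    dtypes = {
        0x08: np.uint8, 0x09: np.int8, 0x0B: np.int16,
        0x0C: np.int32, 0x0D: np.float32, 0x0E: np.float64,
    }
    if dtype_code not in dtypes:
        raise ValueError(f"unsupported IDX dtype code {dtype_code:#x}")
    dims = struct.unpack(f">{ndim}I", raw[4 : 4 + 4 * ndim])
    data = np.frombuffer(raw, dtype=np.dtype(dtypes[dtype_code]).newbyteorder(">"),
                         offset=4 + 4 * ndim)
    arr = data.reshape(dims).astype(float)
    if dtype_code == 0x08:
        arr = arr / 255.0
    return arr.reshape(dims[0], -1) if ndim > 1 else arr


def load_inputs(path: str | Path, normalize: bool = True) -> np.ndarray:
    """Load an input matrix from NPY, headerless CSV, or IDX.

    IDX images are flattened row-major and scaled to ``[0, 1]`` before the
    optional row normalization.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        X = np.load(path)
    elif suffix in (".csv", ".txt"):
        X = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        X = _load_idx(path)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{path} did not contain a 2-D matrix")
    return normalize_inputs(X) if normalize else X
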