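"""Affine-invariant geometry of symmetric positive-definite (SPD) matrices.

Covariance matrices of log-expression are points on the SPD manifold. The
affine-invariant metric assigns the pair (C, A) the geodesic distance

    d(C, A) = || log(C^{-1/2} A C^{-1/2}) ||_F = sqrt( sum_n log^2 lambda_n ),

where lambda_n are the (real, strictly positive) eigenvalues of C^{-1}A.
The logarithmic map sends a point A to the tangent space at C; the
exponential map inverts it. A minimal vectorization of the whitened tangent
element — upper triangle with off-diagonal entries scaled by sqrt(2) —
makes the Euclidean norm of the tangent vector equal the geodesic distance,
so downstream code can work with ordinary vectors.

All matrix functions (sqrt, log, exp) go through symmetric
eigendecomposition of whitened matrices, never through the nonsymmetric
product C^{-1}A, which is mathematically equivalent but numerically
asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPDPoint",
    "TangentVector",
    "ManifoldError",
    "validate_spd",
    "riemannian_distance",
    "log_map",
    "exp_map",
    "tangent_vectorize",
    "tangent_distance",
]

# A matrix is accepted as symmetric if max|M - M^T| <= SYM_RTOL * max|M|,
# and as positive definite if lambda_min > EIG_RTOL * lambda_max.
SYM_RTOL = 1e-10
EIG_RTOL = 1e-12


class ManifoldError(ValueError):
    """Raised for non-SPD input, dimension mismatch, or asymmetric tangents."""


def _check_symmetric(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ManifoldError(f"{name} must be a square matrix, got shape {mat.shape}")
    scale = np.abs(mat).max()
    tol = SYM_RTOL * max(scale, 1.0)
    if np.abs(mat - mat.T).max() > tol:
        raise ManifoldError(f"{name} is not symmetric within tolerance {tol:g}")
    return 0.5 * (mat + mat.T)


def validate_spd(mat: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate that *mat* is SPD; return its exactly-symmetrized copy.

    Raises :class:`ManifoldError` if the matrix is not square, not symmetric
    within ``SYM_RTOL`` (relative to its largest entry), or has an eigenvalue
    at or below ``EIG_RTOL`` times the largest eigenvalue.
    """
    sym = _check_symmetric(mat, name)
    w = np.linalg.eigvalsh(sym)
    if w[-1] <= 0 or w[0] <= EIG_RTOL * w[-1]:
        raise ManifoldError(
            f"{name} is not positive definite: eigenvalue range [{w[0]:.3e}, {w[-1]:.3e}]"
        )
    return sym


@dataclass(frozen=True)
class SPDPoint:
    """A point on the SPD manifold: a symmetric positive-definite matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", validate_spd(self.matrix, "SPDPoint.matrix"))

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class TangentVector:
    """Minimal N(N+1)/2 vectorization of a tangent-space element at some base point."""

    values: np.ndarray
    base_dim: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        expected = self.base_dim * (self.base_dim + 1) // 2
        if vals.size != expected:
            raise ManifoldError(
                f"tangent vector has length {vals.size}, expected "
                f"{expected} = {self.base_dim}({self.base_dim}+1)/2"
            )
        object.__setattr__(self, "values", vals)


def _as_spd(x, name: str) -> np.ndarray:
    if isinstance(x, SPDPoint):
        return x.matrix
    return validate_spd(x, name)


def _check_same_dim(C: np.ndarray, A: np.ndarray) -> None:
    if C.shape != A.shape:
        raise ManifoldError(f"dimension mismatch: {C.shape} vs {A.shape}")


def _spectral_apply(mat: np.ndarray, fun) -> np.ndarray:
    """f(M) for symmetric M via eigendecomposition; result symmetrized."""
    w, V = np.linalg.eigh(mat)
    out = (V * fun(w)) @ V.T
    return 0.5 * (out + out.T)


def _whitened(C: np.ndarray, A: np.ndarray) -> np.ndarray:
    """C^{-1/2} A C^{-1/2}, symmetrized."""
    Cinv_half = _spectral_apply(C, lambda w: 1.0 / np.sqrt(w))
    W = Cinv_half @ A @ Cinv_half
    return 0.5 * (W + W.T)


def riemannian_distance(C, A) -> float:
    """Affine-invariant geodesic distance between two SPD points.

    Equal to ``sqrt(sum(log^2 lambda))`` over the eigenvalues lambda of
    C^{-1}A, computed through the symmetric form C^{-1/2} A C^{-1/2}.
    Symmetric in its arguments and zero iff C == A.
    """
    C = _as_spd(C, "C")
    A = _as_spd(A, "A")
    _check_same_dim(C, A)
    lam = np.linalg.eigvalsh(_whitened(C, A))
    if lam[0] <= 0:
        raise ManifoldError("whitened matrix lost positive definiteness")
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def log_map(C, A) -> np.ndarray:
    """Logarithmic map Log_C(A) = C^{1/2} log(C^{-1/2} A C^{-1/2}) C^{1/2}.

    Projects the manifold point A into the tangent space at C; the result
    is a symmetric matrix (the zero matrix iff A == C).
    """
    C = _as_spd(C, "C")
    A = _as_spd(A, "A")
    _check_same_dim(C, A)
    C_half = _spectral_apply(C, np.sqrt)
    M = _spectral_apply(_whitened(C, A), np.log)
    out = C_half @ M @ C_half
    return 0.5 * (out + out.T)


def exp_map(C, S) -> SPDPoint:
    """Exponential map Exp_C(S) = C^{1/2} exp(C^{-1/2} S C^{-1/2}) C^{1/2}.

    Inverse of :func:`log_map`; maps a symmetric tangent element S at C back
    onto the manifold. Always returns an SPD point.
    """
    C = _as_spd(C, "C")
    S = _check_symmetric(S, "S")
    _check_same_dim(C, S)
    C_half = _spectral_apply(C, np.sqrt)
    Cinv_half = _spectral_apply(C, lambda w: 1.0 / np.sqrt(w))
    inner = Cinv_half @ S @ Cinv_half
    E = _spectral_apply(0.5 * (inner + inner.T), np.exp)
    out = C_half @ E @ C_half
    return SPDPoint(0.5 * (out + out.T))


def tangent_vectorize(C, A) -> TangentVector:
    """Minimal vectorization of the whitened tangent element of A at C.

    Forms ``M = log(C^{-1/2} A C^{-1/2})`` and stacks its upper triangle in
    row-major order, multiplying off-diagonal entries by sqrt(2) so that the
    Euclidean norm of the vector equals :func:`riemannian_distance`(C, A).
    """
    C = _as_spd(C, "C")
    A = _as_spd(A, "A")
    _check_same_dim(C, A)
    M = _spectral_apply(_whitened(C, A), np.log)
    n = M.shape[0]
    iu = np.triu_indices(n)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return TangentVector(values=M[iu] * weights, base_dim=n)


def tangent_distance(v: TangentVector) -> float:
    """Euclidean distance of a tangent vector from the tangent-space origin.

    The origin is the image of the base point C itself, so this is the
    pathway dysregulation score for the sample that produced ``v``.
    """
    if not isinstance(v, TangentVector):
        v = TangentVector(values=np.asarray(v, float), base_dim=_infer_dim(np.asarray(v).size))
    return float(np.linalg.norm(v.values))


def _infer_dim(length: int) -> int:
    # length = n(n+1)/2  =>  n = (-1 + sqrt(1+8L)) / 2
    n = int(round((-1 + np.sqrt(1 + 8 * length)) / 2))
    if n * (n + 1) // 2 != length:
        raise ManifoldError(f"length {length} is not a triangular number")
    return n
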