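"""SPD-covariance features and affine-invariant Riemannian geometry.

Each filtered epoch X_i (2C x N) is concatenated with the class evoked
templates P1 (2C x N) into a super-trial [P1; X_i] (4C x N) whose sample
covariance carries both the temporal-template correlation and the
single-trial spatial structure.  Covariances live on the SPD manifold
with the affine-invariant metric

    delta_R(S1, S2) = || log eigvals(S1^-1 S2) ||_2,

under which class geometry is summarized by the Fréchet (Karcher) mean and
epochs are either classified by minimum distance to mean (MDM) or mapped
into the Euclidean tangent space at the mean for a conventional linear
classifier.

Sample covariances follow the plain uncentered estimator X X'/(N-1); the
super-trial rows are near zero-mean after bandpass filtering, and centering
is exposed as an option rather than the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg


class MeanConvergenceError(RuntimeError):
    """Fréchet-mean iteration failed to reach tolerance."""

    def __init__(self, msg: str, iterate: np.ndarray, residual: float):
        super().__init__(msg)
        self.iterate = iterate
        self.residual = residual


# ---------------------------------------------------------------------------
# super-trials and covariance estimation
# ---------------------------------------------------------------------------


def make_supertrial(p1: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """Stack the class templates over a filtered epoch: [P1; X_i], 4C x N."""
    p1 = np.asarray(p1, float)
    xi = np.asarray(xi, float)
    if p1.ndim != 2 or xi.ndim != 2 or p1.shape[1] != xi.shape[1]:
        raise ValueError(
            f"P1 {p1.shape} and X_i {xi.shape} must be 2-D with equal columns"
        )
    return np.vstack([p1, xi])


def scm(x: np.ndarray, center: bool = False, ridge_rel: float = 1e-10) -> np.ndarray:
    """Sample covariance X X'/(N-1) of a (d x N) array, symmetrized.

    Not mean-centered by default.  If the smallest eigenvalue falls below
    ``ridge_rel`` x trace, a ridge is added (with a warning) so the output
    is usable under the affine-invariant metric.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D array with at least 2 columns")
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    n = x.shape[1]
    sigma = x @ x.T / (n - 1)
    sigma = 0.5 * (sigma + sigma.T)
    tr = np.trace(sigma)
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig < ridge_rel * tr:
        eps = max(ridge_rel * tr, 1e-12 * tr) - min(min_eig, 0.0)
        warnings.warn(
            f"rank-deficient covariance (min eig {min_eig:.3g}); adding ridge"
        )
        sigma = sigma + eps * np.eye(sigma.shape[0])
    return sigma


def _check_spd(sigma: np.ndarray, name: str = "matrix") -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-8 * max(1.0, np.abs(sigma).max())):
        raise ValueError(f"{name} is not symmetric")
    if np.linalg.eigvalsh(sigma)[0] <= 0:
        raise ValueError(f"{name} is not positive definite")
    return 0.5 * (sigma + sigma.T)


def _eigh_fun(sigma: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to a symmetric matrix's eigenvalues.

    Eigenvalues are clipped at 1e-12 x trace from below before the function
    is applied, guarding log/inverse-sqrt against roundoff-negative values.
    """
    vals, vecs = np.linalg.eigh(sigma)
    floor = 1e-12 * max(np.trace(sigma), np.finfo(float).tiny)
    vals = np.maximum(vals, floor)
    return (vecs * fun(vals)) @ vecs.T


def spd_logm(sigma: np.ndarray) -> np.ndarray:
    return _eigh_fun(sigma, np.log)


def spd_expm(sym: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (sym + sym.T))
    return (vecs * np.exp(vals)) @ vecs.T


def spd_invsqrtm(sigma: np.ndarray) -> np.ndarray:
    return _eigh_fun(sigma, lambda v: 1.0 / np.sqrt(v))


def spd_sqrtm(sigma: np.ndarray) -> np.ndarray:
    return _eigh_fun(sigma, np.sqrt)


# ---------------------------------------------------------------------------
# metric, mean, tangent space
# ---------------------------------------------------------------------------


def riemannian_distance(sigma1: np.ndarray, sigma2: np.ndarray) -> float:
    """Affine-invariant distance: sqrt(sum log^2 eigvals(S1^-1 S2))."""
    s1 = _check_spd(sigma1, "sigma1")
    s2 = _check_spd(sigma2, "sigma2")
    # generalized symmetric eigenproblem S2 v = lambda S1 v gives the
    # eigenvalues of S1^-1 S2, guaranteed real and positive
    lam = linalg.eigh(s2, s1, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def riemannian_mean(
    sigmas,
    tol: float = 1e-9,
    max_iter: int = 100,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Fréchet (Karcher) mean: argmin_S sum_i delta_R^2(S, S_i).

    Standard fixed-point iteration with unit step: map all matrices to the
    tangent space at the current estimate, average, exponentiate back.
    Initialized at the arithmetic mean.  Raises
    :class:`MeanConvergenceError` (carrying the last iterate and residual)
    if the tangent-mean gradient norm does not fall below ``tol``.
    """
    mats = [np.asarray(s, dtype=float) for s in sigmas]
    if not mats:
        raise ValueError("need at least one matrix")
    if len(mats) == 1:
        return _check_spd(mats[0])
    if weights is None:
        weights = np.full(len(mats), 1.0 / len(mats))
    else:
        weights = np.asarray(weights, float)
        weights = weights / weights.sum()

    stack = np.stack(mats)
    mean = np.einsum("i,ijk->jk", weights, stack)
    for _ in range(max_iter):
        w_inv = spd_invsqrtm(mean)
        w = spd_sqrtm(mean)
        whitened = w_inv @ stack @ w_inv
        # batch matrix log of the whitened set
        vals, vecs = np.linalg.eigh(0.5 * (whitened + whitened.transpose(0, 2, 1)))
        vals = np.maximum(vals, 1e-300)
        logs = (vecs * np.log(vals)[:, None, :]) @ vecs.transpose(0, 2, 1)
        tangent_mean = np.einsum("i,ijk->jk", weights, logs)
        residual = float(np.linalg.norm(tangent_mean, "fro"))
        mean = w @ spd_expm(tangent_mean) @ w
        if residual <= tol:
            return mean
    raise MeanConvergenceError(
        f"Fréchet mean did not converge in {max_iter} iterations "
        f"(residual {residual:.3g} > tol {tol:.3g})",
        iterate=mean,
        residual=residual,
    )


def log_map(sigma: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Riemannian logarithm of ``sigma`` at ``base`` (a symmetric matrix)."""
    w = spd_sqrtm(base)
    w_inv = spd_invsqrtm(base)
    return w @ spd_logm(w_inv @ sigma @ w_inv) @ w


def upper(sym: np.ndarray, sqrt2_offdiag: bool = True) -> np.ndarray:
    """Vectorize a symmetric matrix by its upper triangle.

    Off-diagonal entries are weighted by sqrt(2) (default) so the Euclidean
    norm of the vector equals the Frobenius norm of the matrix — and hence
    the tangent vector's norm equals the Riemannian distance to the base
    point.
    """
    sym = np.asarray(sym, float)
    d = sym.shape[0]
    iu, ju = np.triu_indices(d)
    v = sym[iu, ju].copy()
    if sqrt2_offdiag:
        v[iu != ju] *= np.sqrt(2.0)
    return v


def tangent_dim(d: int) -> int:
    return d * (d + 1) // 2


def tangent_project(
    sigma: np.ndarray, base: np.ndarray, sqrt2_offdiag: bool = True
) -> np.ndarray:
    """Tangent-space coordinates of ``sigma`` at the reference ``base``.

    v = upper(base^-1/2 Log_base(sigma) base^-1/2), which simplifies to the
    matrix log of the whitened covariance; with the sqrt(2) off-diagonal
    weighting ||v|| = delta_R(sigma, base).
    """
    s = _check_spd(sigma, "sigma")
    b = _check_spd(base, "base")
    w_inv = spd_invsqrtm(b)
    return upper(spd_logm(w_inv @ s @ w_inv), sqrt2_offdiag=sqrt2_offdiag)


def tangent_vectors(
    sigmas, base: np.ndarray, sqrt2_offdiag: bool = True
) -> np.ndarray:
    """Batch tangent projection: (n, d(d+1)/2) feature matrix."""
    b = _check_spd(base, "base")
    w_inv = spd_invsqrtm(b)
    stack = np.stack([np.asarray(s, float) for s in sigmas])
    whitened = w_inv @ stack @ w_inv
    vals, vecs = np.linalg.eigh(0.5 * (whitened + whitened.transpose(0, 2, 1)))
    vals = np.maximum(vals, 1e-300)
    logs = (vecs * np.log(vals)[:, None, :]) @ vecs.transpose(0, 2, 1)
    d = logs.shape[1]
    iu, ju = np.triu_indices(d)
    out = logs[:, iu, ju].copy()
    if sqrt2_offdiag:
        out[:, iu != ju] *= np.sqrt(2.0)
    return out


@dataclass
class TangentVector:
    """Tangent-space image of one covariance with its reference point."""

    v: np.ndarray
    reference: np.ndarray


# ---------------------------------------------------------------------------
# minimum distance to mean
# ---------------------------------------------------------------------------


class MDM:
    """Minimum-distance-to-mean classifier on the SPD manifold.

    Fits one Fréchet mean per class; predicts the class whose mean is
    nearest under the affine-invariant distance.  Exact ties resolve to the
    negative ("nonattended") class deterministically.
    """

    def __init__(self, tol: float = 1e-9, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter
        self.means_: dict | None = None

    def fit(self, sigmas, labels) -> "MDM":
        labels = np.asarray(labels)
        self.classes_ = np.unique(labels)
        stack = np.stack([np.asarray(s, float) for s in sigmas])
        self.means_ = {
            c: riemannian_mean(stack[labels == c], tol=self.tol,
                               max_iter=self.max_iter)
            for c in self.classes_
        }
        return self

    def distances(self, sigmas) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("MDM is not fitted")
        return np.array(
            [[riemannian_distance(s, self.means_[c]) for c in self.classes_]
             for s in sigmas]
        )

    def predict(self, sigmas) -> np.ndarray:
        d = self.distances(sigmas)
        # argmin with ties resolved toward the first (sorted, i.e. negative/
        # "nonattended" under {False, True} or {0, 1} labelling) class
        return self.classes_[np.argmin(d, axis=1)]
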