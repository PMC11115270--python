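"""xDAWN spatial filtering: SSNR-maximizing evoked-subspace estimation.

For each class (attended / nonattended deviants) the evoked response P1 is
estimated by least squares from the continuous data X (time x channels)
and a zero/one Toeplitz stimulus-design matrix D1, correctly handling
overlapping response windows.  A spatial filter u maximizes the
signal-to-signal-plus-noise ratio

    rho(u) = (u' S1 u) / (u' Sx u),   S1 = P1' D1' D1 P1,  Sx = X' X,

solved as a generalized symmetric eigenproblem via Cholesky whitening of
Sx; the top ``n_components`` eigenvectors per class (default 3) form the
filter bank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, sparse


@dataclass
class ToeplitzDesign:
    """Sparse stimulus-design matrix D1 (n_samples x epoch_len)."""

    matrix: sparse.csr_matrix
    onsets: np.ndarray  # kept onsets (window-start samples)
    epoch_len: int
    n_dropped: int = 0

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


def build_toeplitz(onsets, n_samples: int, epoch_len: int) -> ToeplitzDesign:
    """Build D1 with D1[i, k] = 1 iff i = onset + k for some kept onset.

    Onsets whose window would leave [0, n_samples) are dropped with a
    warning.  Overlapping windows are allowed; each (onset, k) pair
    contributes its own unit entry.
    """
    onsets = np.asarray(onsets, dtype=int)
    keep = (onsets >= 0) & (onsets <= n_samples - epoch_len)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} onset(s) out of range; dropped")
    onsets = onsets[keep]
    rows = (onsets[:, None] + np.arange(epoch_len)[None, :]).ravel()
    cols = np.tile(np.arange(epoch_len), onsets.size)
    mat = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_samples, epoch_len)
    )
    return ToeplitzDesign(matrix=mat, onsets=onsets, epoch_len=epoch_len,
                          n_dropped=n_dropped)


def _gram_from_onsets(onsets: np.ndarray, epoch_len: int) -> np.ndarray:
    """G = D1' D1 without materializing D1.

    G[j, k] equals the number of ordered onset pairs (o1, o2) with
    o2 - o1 = j - k, so G is Toeplitz in the pairwise onset differences.
    """
    onsets = np.asarray(onsets, dtype=np.int64)
    diffs = (onsets[:, None] - onsets[None, :]).ravel()
    diffs = diffs[np.abs(diffs) < epoch_len]
    vals, counts = np.unique(diffs, return_counts=True)
    G = np.zeros((epoch_len, epoch_len))
    for d, c in zip(vals, counts):
        if d >= 0:
            j = np.arange(d, epoch_len)
        else:
            j = np.arange(0, epoch_len + d)
        G[j, j - d] = c
    return G


def _window_sum(X: np.ndarray, onsets: np.ndarray, epoch_len: int) -> np.ndarray:
    """B = D1' X: sum of the response windows (epoch_len x n_channels)."""
    B = np.zeros((epoch_len, X.shape[1]))
    for o in onsets:
        B += X[o : o + epoch_len]
    return B


def ssnr(u: np.ndarray, sigma1: np.ndarray, sigma_x: np.ndarray) -> float:
    """Rayleigh quotient rho(u) = (u' S1 u)/(u' Sx u); scale-invariant."""
    u = np.asarray(u, dtype=float)
    return float(u @ sigma1 @ u) / float(u @ sigma_x @ u)


@dataclass
class XdawnModel:
    """Per-class SSNR-optimal spatial filters and evoked estimates.

    filters[c] is (n_channels, C), unit-norm columns with the sign fixed so
    each filtered evoked estimate has a positive maximum; ssnr[c] is the
    non-increasing generalized-eigenvalue spectrum of the kept components.
    """

    classes: tuple[str, ...]
    filters: dict[str, np.ndarray]
    evoked: dict[str, np.ndarray]  # (C, epoch_len), filtered templates
    p1_channel: dict[str, np.ndarray]  # (epoch_len, n_channels) LS estimates
    ssnr: dict[str, np.ndarray]
    sigma1: dict[str, np.ndarray]
    sigma_x: np.ndarray
    n_components: int
    epoch_len: int

    @property
    def n_channels(self) -> int:
        return self.sigma_x.shape[0]

    def stacked_templates(self) -> np.ndarray:
        """P1 of the super-trial construction: (2C, epoch_len), attended on top."""
        return np.vstack([self.evoked[c] for c in self.classes])


def _fit_from_stats(
    stats_by_class: dict[str, tuple[np.ndarray, np.ndarray]],
    sigma_x: np.ndarray,
    n_t: float,
    n_components: int,
    epoch_len: int,
    ridge: float = 1e-8,
) -> XdawnModel:
    """Core solver from per-class (G, B) sufficient statistics."""
    n_ch = sigma_x.shape[0]
    sigma_x = 0.5 * (sigma_x + sigma_x.T)
    sigma_x = sigma_x + (ridge * np.trace(sigma_x) / n_ch) * np.eye(n_ch)
    try:
        L = np.linalg.cholesky(sigma_x)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge should prevent
        raise np.linalg.LinAlgError(f"signal covariance not SPD: {exc}") from exc

    classes, filters, evoked, p1s, rhos, sigma1s = [], {}, {}, {}, {}, {}
    for cls, (G, B) in stats_by_class.items():
        classes.append(cls)
        try:
            P1 = np.linalg.solve(G, B)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular design Gram for class {cls!r}; "
                "falling back to onset averaging"
            )
            counts = np.maximum(np.diag(G), 1.0)
            P1 = B / counts[:, None]
        sigma1 = P1.T @ G @ P1 / n_t
        sigma1 = 0.5 * (sigma1 + sigma1.T)

        # whiten and solve the symmetric eigenproblem
        M = linalg.solve_triangular(L, sigma1, lower=True)
        M = linalg.solve_triangular(L, M.T, lower=True).T
        M = 0.5 * (M + M.T)
        evals, evecs = np.linalg.eigh(M)
        order = np.argsort(evals)[::-1][:n_components]
        lam = np.maximum(evals[order], 0.0)
        U = linalg.solve_triangular(L.T, evecs[:, order], lower=False)

        # sign/scale convention: unit norm, positive evoked maximum
        for j in range(U.shape[1]):
            u = U[:, j]
            template = P1 @ u
            if np.max(template) < -np.min(template):
                u = -u
            U[:, j] = u / np.linalg.norm(u)

        filters[cls] = U
        evoked[cls] = (P1 @ U).T
        p1s[cls] = P1
        rhos[cls] = lam
        sigma1s[cls] = sigma1

    return XdawnModel(
        classes=tuple(classes),
        filters=filters,
        evoked=evoked,
        p1_channel=p1s,
        ssnr=rhos,
        sigma1=sigma1s,
        sigma_x=sigma_x,
        n_components=n_components,
        epoch_len=epoch_len,
    )


def fit_xdawn(
    X: np.ndarray,
    onsets_by_class: dict[str, np.ndarray],
    epoch_len: int,
    n_components: int = 3,
    ridge: float = 1e-8,
) -> XdawnModel:
    """Fit xDAWN filters from continuous data X (n_samples x n_channels).

    ``onsets_by_class`` maps class name to window-start samples (use
    onset + tmin*rate if templates should include a pre-stimulus segment).
    Out-of-range onsets are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    n_t = X.shape[0]
    sigma_x = X.T @ X / n_t
    stats = {}
    for cls, onsets in onsets_by_class.items():
        onsets = np.asarray(onsets, dtype=int)
        keep = (onsets >= 0) & (onsets <= n_t - epoch_len)
        if (~keep).any():
            warnings.warn(f"{int((~keep).sum())} onset(s) out of range "
                          f"for class {cls!r}; dropped")
        onsets = onsets[keep]
        if onsets.size < n_components:
            raise ValueError(f"class {cls!r} needs >= {n_components} onsets")
        G = _gram_from_onsets(onsets, epoch_len)
        B = _window_sum(X, onsets, epoch_len)
        stats[cls] = (G, B)
    return _fit_from_stats(stats, sigma_x, n_t, n_components, epoch_len, ridge)


def fit_xdawn_from_windows(
    windows_by_class: dict[str, np.ndarray],
    onsets_by_class: dict[str, np.ndarray],
    sigma_x: np.ndarray,
    n_t: float,
    n_components: int = 3,
    ridge: float = 1e-8,
) -> XdawnModel:
    """Fit from pre-cut raw windows plus a precomputed signal covariance.

    ``windows_by_class[c]`` is (n_events, n_channels, epoch_len) containing
    the *uncorrected* data windows whose global start samples are
    ``onsets_by_class[c]`` (used only through their pairwise differences,
    which encode window overlap).  ``sigma_x`` is X'X/n_t from the
    continuous data.  This is the cross-validation entry point: only
    training-fold windows/onsets enter the class statistics.
    """
    stats = {}
    epoch_len = None
    for cls, win in windows_by_class.items():
        win = np.asarray(win)
        if win.ndim != 3:
            raise ValueError("windows must be (n_events, n_channels, epoch_len)")
        epoch_len = win.shape[2]
        onsets = np.asarray(onsets_by_class[cls], dtype=int)
        if onsets.size != win.shape[0]:
            raise ValueError("onsets and windows disagree in length")
        G = _gram_from_onsets(onsets, epoch_len)
        B = win.sum(axis=0).T  # (epoch_len, n_channels)
        stats[cls] = (G, B)
    return _fit_from_stats(stats, np.asarray(sigma_x, float), n_t,
                           n_components, epoch_len, ridge)


def apply_filters(epoch_data: np.ndarray, model: XdawnModel) -> np.ndarray:
    """Project an epoch (n_channels x n_times) to the 2C evoked subspace.

    Rows are the attended-class components stacked over the
    nonattended-class components.
    """
    epoch_data = np.asarray(epoch_data, dtype=float)
    if epoch_data.shape[0] != model.n_channels:
        raise ValueError(
            f"epoch has {epoch_data.shape[0]} channels, model expects "
            f"{model.n_channels}"
        )
    return np.vstack([model.filters[c].T @ epoch_data for c in model.classes])
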