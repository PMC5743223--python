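"""Diffusion-style affinities and low-dimensional embeddings of clones.

The similarity between clones i and j in log-yield space is a Gaussian
conditional probability

    P(j|i) = exp(-||x_i - x_j||^2 / (2 sigma_i^2)) / sum_{k != i} exp(-||x_i - x_k||^2 / (2 sigma_i^2))

with each bandwidth sigma_i calibrated so that the perplexity
2^H(P(.|i)) of row i equals a user-set value (default 20).  Rows are
symmetrized into joint probabilities

    P(i, j) = (P(j|i) + P(i|j)) / (2N),

which sum to one and can be read as single-step transition probabilities
of a diffusion over clones.  The 2-D map minimizes the Kullback-Leibler
divergence KL(P || Q) against a Student-t kernel Q by exact gradient
descent (no tree approximation: the data sets here are a few thousand
clones at most).

Also provided: PCA on centered/scaled columns, the 1 - Spearman-rho
co-ancestry distance between lineages, and classical (Torgerson) MDS.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .clone_io import CloneTable
from .errors import InsufficientDataError, ValidationError

MACHINE_EPS = 1e-12


# ---------------------------------------------------------------------------
# affinities

def conditional_affinities(
    X: np.ndarray, perplexity: float = 20.0, tol: float = 1e-5, max_iter: int = 200
):
    """Per-row Gaussian conditional probabilities at a fixed perplexity.

    For every clone i a binary search adjusts sigma_i until
    |log2 perplexity(P(.|i)) - log2 u| < tol (at most *max_iter*
    halvings).  Returns ``(P, sigma)`` with zero diagonal and unit row
    sums.

    Raises when a row cannot be calibrated (e.g. all neighbors coincide
    with the point), naming the offending rows.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise InsufficientDataError("need at least 3 points")
    if not 1.0 <= perplexity < n:
        raise ValidationError(f"perplexity must be in [1, n); got {perplexity} with n={n}")
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    P = np.zeros((n, n))
    sigma = np.empty(n)
    target = np.log2(perplexity)
    failed = []
    for i in range(n):
        d = np.delete(D2[i], i)
        lo, hi = 0.0, np.inf
        beta = 1.0  # precision 1 / (2 sigma_i^2)
        row = None
        for _ in range(max_iter):
            w = np.exp(-d * beta)
            s = w.sum()
            if s <= 0:
                hi = beta
                beta = beta / 2.0
                continue
            row = w / s
            # Shannon entropy in bits
            h = -np.sum(row * np.log2(row + MACHINE_EPS))
            diff = h - target
            if abs(diff) < tol:
                break
            if diff > 0:  # distribution too flat -> sharpen
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else (lo + hi) / 2.0
            else:
                hi = beta
                beta = (lo + hi) / 2.0
        else:
            if row is None or abs(-np.sum(row * np.log2(row + MACHINE_EPS)) - target) > 1e-2:
                failed.append(i)
        if row is None:
            failed.append(i)
            row = np.full(n - 1, 1.0 / (n - 1))
            beta = 1.0
        P[i, np.arange(n) != i] = row
        sigma[i] = np.sqrt(1.0 / (2.0 * beta))
    if failed:
        raise ValidationError(f"sigma search failed for row(s) {sorted(set(failed))}")
    return P, sigma


@dataclasses.dataclass
class AffinityMatrix:
    """Symmetric joint probabilities over clones, with calibration record."""

    P: np.ndarray
    sigma: np.ndarray
    perplexity: float

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        n = P.shape[0]
        if P.shape != (n, n):
            raise ValidationError("P must be square")
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValidationError("P must be symmetric")
        if np.abs(np.diag(P)).max() > 1e-12 or (P < 0).any():
            raise ValidationError("P must be non-negative with zero diagonal")
        if abs(P.sum() - 1.0) > 1e-10:
            raise ValidationError(f"P must sum to 1; got {P.sum():.12f}")
        self.P = P

    @property
    def n(self) -> int:
        return self.P.shape[0]


def joint_affinities(conditional: np.ndarray, sigma: np.ndarray | None = None,
                     perplexity: float = float("nan")) -> AffinityMatrix:
    """Symmetrize conditionals: P(i,j) = (P(j|i) + P(i|j)) / (2N)."""
    C = np.asarray(conditional, dtype=float)
    n = C.shape[0]
    if not np.allclose(C.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("conditional rows must sum to 1")
    P = (C + C.T) / (2.0 * n)
    np.fill_diagonal(P, 0.0)
    return AffinityMatrix(P=P, sigma=np.ones(n) if sigma is None else np.asarray(sigma),
                          perplexity=perplexity)


# ---------------------------------------------------------------------------
# t-SNE

@dataclasses.dataclass
class Embedding:
    """2-D coordinates with the optimization trace that produced them."""

    coords: np.ndarray
    kl_initial: float
    kl_final: float
    kl_trace: list
    seed: int

    def __post_init__(self):
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite embedding coordinates")


def _kl(P: np.ndarray, Q: np.ndarray) -> float:
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], MACHINE_EPS))))


def _q_matrix(Y: np.ndarray):
    num = 1.0 / (1.0 + squareform(pdist(Y, metric="sqeuclidean")))
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    return np.maximum(Q, MACHINE_EPS), num


def embed_tsne(
    affinities: AffinityMatrix,
    seed: int = 0,
    n_iter: int = 1000,
    learning_rate: float | None = None,
    early_exaggeration: float = 12.0,
    exaggeration_iter: int = 250,
    momentum: tuple[float, float] = (0.5, 0.8),
    trace_every: int = 50,
) -> Embedding:
    """Minimize KL(P || Q) over 2-D coordinates with a Student-t kernel.

    Standard schedule: early exaggeration of P for the first
    ``exaggeration_iter`` iterations, momentum switching from 0.5 to 0.8
    afterwards, per-coordinate adaptive gains.  The default learning rate
    is max(N / early_exaggeration, 50), which keeps the descent stable
    across problem sizes.  Fully reproducible for a given seed.  The
    reported KL trace always uses the un-exaggerated P.
    """
    P = affinities.P
    n = P.shape[0]
    if learning_rate is None:
        learning_rate = max(n / early_exaggeration, 50.0)
    exaggeration_iter = min(exaggeration_iter, n_iter // 2)
    rng = np.random.default_rng(seed)
    Y = rng.normal(scale=1e-4, size=(n, 2))
    update = np.zeros_like(Y)
    gains = np.ones_like(Y)
    Q, _ = _q_matrix(Y)
    kl0 = _kl(P, Q)
    trace = [(0, kl0)]
    for it in range(1, n_iter + 1):
        exag = early_exaggeration if it <= exaggeration_iter else 1.0
        mom = momentum[0] if it <= exaggeration_iter else momentum[1]
        Q, num = _q_matrix(Y)
        W = (exag * P - Q) * num
        np.fill_diagonal(W, 0.0)
        # gradient: 4 * sum_j W_ij (y_i - y_j) = 4 * (diag(W 1) - W) Y
        grad = 4.0 * ((W.sum(axis=1)[:, None]) * Y - W @ Y)
        if not np.isfinite(grad).all():
            raise ValidationError(f"non-finite t-SNE gradient at iteration {it}")
        # adaptive per-coordinate gains (reference-implementation schedule)
        same_sign = np.sign(grad) == np.sign(update)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.clip(gains, 0.01, None, out=gains)
        update = mom * update - learning_rate * gains * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
        if it % trace_every == 0 or it == n_iter:
            Q, _ = _q_matrix(Y)
            trace.append((it, _kl(P, Q)))
    Q, _ = _q_matrix(Y)
    return Embedding(coords=Y, kl_initial=kl0, kl_final=_kl(P, Q), kl_trace=trace, seed=seed)


# ---------------------------------------------------------------------------
# PCA

@dataclasses.dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    dropped_columns: list


def pca_scores(X: np.ndarray) -> PCAResult:
    """PCA of centered, unit-scaled columns (correlation-matrix PCA).

    Constant columns cannot be scaled; they are dropped with a warning.
    Variance fractions over all retained components sum to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InsufficientDataError("need >= 2 rows and >= 2 columns")
    sd = X.std(axis=0, ddof=1)
    dropped = list(np.flatnonzero(sd == 0))
    if dropped:
        warnings.warn(f"dropping constant column(s) {dropped}", stacklevel=2)
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U * S
    var = S**2
    return PCAResult(scores=scores, loadings=Vt.T, variance_fraction=var / var.sum(),
                     dropped_columns=dropped)


# ---------------------------------------------------------------------------
# co-ancestry distance and MDS

def spearman_distance(M: np.ndarray) -> np.ndarray:
    """1 - Spearman-rho distance between the columns of M (average ranks)."""
    M = np.asarray(M, dtype=float)
    rho = stats.spearmanr(M).statistic
    if np.ndim(rho) == 0:  # two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    if np.isnan(rho).any():
        const = [j for j in range(M.shape[1]) if np.ptp(M[:, j]) == 0]
        warnings.warn(f"constant column(s) {const}: rho undefined for their pairs", stacklevel=2)
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    return D


def lineage_ancestry_distance(table: CloneTable, productive_only: bool = True) -> np.ndarray:
    """6x6 co-ancestry distance between lineages: d = 1 - Spearman rho of
    their yield columns across clones.

    Lineages whose yields co-vary across clones (frequently produced by
    the same clones) are close: they are likely to share ancestry.
    """
    Y = table.yields()
    if productive_only:
        Y = Y[Y.sum(axis=1) > 0]
    if Y.shape[0] < 3:
        raise InsufficientDataError("need >= 3 productive clones")
    return spearman_distance(Y)


def classical_mds(D: np.ndarray, k: int = 2):
    """Torgerson MDS: double-center -(1/2) J D^2 J and eigendecompose.

    Returns ``(coords, eigenvalues)`` with coordinates scaled by the
    square root of the top-k eigenvalues.  1 - rho distances need not be
    Euclidean, so negative eigenvalues are possible and are returned for
    inspection; axes beyond the positive spectrum are zero-filled with a
    warning.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("D must be a symmetric square matrix")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValidationError("D must have zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, k))
    n_pos = int((vals > 1e-12).sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalue(s); remaining axes zero-filled",
                      stacklevel=2)
    for j in range(min(k, n_pos)):
        coords[:, j] = vecs[:, j] * np.sqrt(vals[j])
    return coords, vals
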