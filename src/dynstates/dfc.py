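"""Tapered sliding-window connectivity.

The pipeline per subject is:

1. build a tapered window (rectangle convolved with a Gaussian) and slide
   it along the time courses in steps of ``step`` TR;
2. estimate a taper-weighted sample covariance per window;
3. regularize each window with the graphical LASSO, with the L1 penalty
   ``lambda`` chosen per subject by k-fold cross-validation over windows
   (held-out Gaussian log-likelihood);
4. convert to correlations, Fisher r-to-z transform;
5. residualize the z values with respect to subject covariates (age,
   gender, study membership) across subjects, per connection and window;
6. summarize temporal variability as the SD of each connection over
   windows.

Connectivity matrices are handled in vectorized upper-triangle form
(row-major order, diagonal excluded) wherever a flat feature vector is
more convenient; :func:`triu_vector` / :func:`triu_to_matrix` convert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.covariance import log_likelihood as _sk_log_likelihood
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "TaperSpec",
    "LambdaSelection",
    "VariabilityResult",
    "make_taper",
    "window_count",
    "window_starts",
    "windowed_covariance",
    "graphical_lasso",
    "glasso_objective",
    "select_lambda",
    "to_correlation",
    "to_fisher_z",
    "residualize",
    "connectivity_variability",
    "triu_vector",
    "triu_to_matrix",
    "default_lambda_grid",
]


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaperSpec:
    """Tapered sliding window: rectangle of ``width_tr`` samples convolved
    with a unit-area Gaussian of ``gaussian_sigma_tr``, truncated to the
    central ``width_tr`` samples and renormalized to sum 1."""

    width_tr: int
    gaussian_sigma_tr: float
    step_tr: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.size != self.width_tr:
            raise ValueError("weights length must equal width_tr")
        if np.any(w < 0):
            raise ValueError("taper weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("taper weights must sum to 1")
        if np.max(np.abs(w - w[::-1])) > 1e-12:
            raise ValueError("taper weights must be symmetric")


def make_taper(w: int = 22, sigma: float = 3.0, step: int = 1) -> TaperSpec:
    """Convolve a length-``w`` rectangle with a Gaussian kernel of SD
    ``sigma`` (in TR units), keep the central ``w`` samples, normalize."""
    if w < 2:
        raise ValueError("window width must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = max(1, int(np.ceil(4 * sigma)))
    k = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (k / sigma) ** 2)
    kernel /= kernel.sum()
    rect = np.ones(w)
    full = np.convolve(rect, kernel)  # length w + 2*half
    weights = full[half:half + w]
    weights = weights / weights.sum()
    # enforce exact symmetry against floating-point drift
    weights = 0.5 * (weights + weights[::-1])
    weights = weights / weights.sum()
    return TaperSpec(width_tr=w, gaussian_sigma_tr=sigma, step_tr=step, weights=weights)


def window_count(T: int, w: int, step: int = 1) -> int:
    """Number of windows: floor((T - w)/step) + 1."""
    if T < w:
        raise ValueError(f"T={T} shorter than window w={w}")
    if step < 1:
        raise ValueError("step must be >= 1")
    return (T - w) // step + 1


def window_starts(T: int, w: int, step: int = 1) -> np.ndarray:
    return np.arange(window_count(T, w, step)) * step


def windowed_covariance(data: np.ndarray, taper: TaperSpec) -> np.ndarray:
    """Taper-weighted sample covariance per window.

    Returns an array (W, N, N).  Within each window the taper-weighted mean
    is removed and the covariance normalized by 1 - sum(weights^2), which
    reduces to the usual unbiased 1/(w-1) estimator for a uniform taper.
    """
    data = np.asarray(data, dtype=float)
    T, N = data.shape
    w = taper.width_tr
    starts = window_starts(T, w, taper.step_tr)
    wt = taper.weights
    denom = 1.0 - float(wt @ wt)
    covs = np.empty((starts.size, N, N))
    for i, s in enumerate(starts):
        X = data[s:s + w]
        mu = wt @ X
        Xc = X - mu
        covs[i] = (Xc * wt[:, None]).T @ Xc / denom
    return covs


# ---------------------------------------------------------------------------
# Graphical LASSO and lambda selection
# ---------------------------------------------------------------------------


class GlassoConvergenceError(RuntimeError):
    def __init__(self, lam: float, max_iter: int, cause: Exception):
        super().__init__(
            f"graphical LASSO did not converge at lambda={lam} within {max_iter} iterations: {cause}"
        )
        self.lam = lam
        self.max_iter = max_iter


def graphical_lasso(
    S: np.ndarray, lam: float, max_iter: int = 200, tol: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """L1-penalized precision estimation.

    Maximizes ``log det(Theta) - tr(S Theta) - lam * ||Theta||_1(offdiag)``.
    Returns (precision, covariance) with covariance the exact inverse of the
    returned precision.  ``lam = 0`` inverts ``S`` directly (requires a
    non-singular input).

    Raises :class:`GlassoConvergenceError` (carrying lambda and the
    iteration budget) when the solver breaks down or produces a
    non-positive-definite precision.  A merely slow final dual gap on an
    otherwise valid SPD solution is accepted; tighten ``tol`` for
    high-precision uses.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        prec = np.linalg.inv(S)
        return 0.5 * (prec + prec.T), S.copy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            cov, prec = _sk_graphical_lasso(S, alpha=lam, max_iter=max_iter, tol=tol)
    except FloatingPointError as exc:  # sklearn's breakdown signal
        raise GlassoConvergenceError(lam, max_iter, exc) from exc
    prec = 0.5 * (prec + prec.T)
    if not np.all(np.isfinite(prec)) or np.linalg.eigvalsh(prec)[0] <= 0:
        raise GlassoConvergenceError(
            lam, max_iter, ValueError("non-SPD precision returned")
        )
    return prec, np.linalg.inv(prec)


def glasso_objective(S: np.ndarray, precision: np.ndarray, lam: float) -> float:
    """Penalized negative log-likelihood (the quantity the solver minimizes):
    -log det(Theta) + tr(S Theta) + lam * sum off-diagonal |Theta_ij|."""
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    off = np.abs(precision).sum() - np.abs(np.diag(precision)).sum()
    return float(-logdet + np.trace(S @ precision) + lam * off)


def default_lambda_grid(n: int = 30, lo: float = 1e-3, hi: float = 1.0) -> np.ndarray:
    return np.geomspace(lo, hi, n)


@dataclass
class LambdaSelection:
    grid: np.ndarray
    mean_loglik: np.ndarray        # per grid value, mean over folds
    fold_loglik: np.ndarray        # (n_grid, n_folds)
    chosen: float

    def __post_init__(self) -> None:
        if self.chosen not in np.asarray(self.grid):
            raise ValueError("chosen lambda must belong to the grid")


def select_lambda(
    window_covs: np.ndarray,
    grid: np.ndarray | None = None,
    n_folds: int = 20,
    max_iter: int = 200,
) -> LambdaSelection:
    """Choose the graphical-LASSO penalty for one subject by k-fold CV.

    Windows are partitioned into ``n_folds`` contiguous blocks (contiguous
    rather than interleaved, to reduce sample sharing between train and test
    windows).  For each candidate lambda and fold, one model is fitted to the
    pooled (averaged) covariance of the training windows and scored by the
    mean Gaussian log-likelihood of the held-out windows' sample covariances.
    The lambda maximizing the mean held-out log-likelihood is returned.
    """
    covs = np.asarray(window_covs, dtype=float)
    W = covs.shape[0]
    if W < n_folds:
        raise ValueError(
            f"{W} windows < {n_folds} folds; use a smaller n_folds"
        )
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    bounds = np.linspace(0, W, n_folds + 1).astype(int)
    fold_ll = np.full((grid.size, n_folds), -np.inf)
    for f in range(n_folds):
        test = np.arange(bounds[f], bounds[f + 1])
        train = np.setdiff1d(np.arange(W), test)
        S_train = covs[train].mean(axis=0)
        for gi, lam in enumerate(grid):
            try:
                prec, _ = graphical_lasso(S_train, lam, max_iter=max_iter)
            except (GlassoConvergenceError, np.linalg.LinAlgError):
                continue
            lls = [_sk_log_likelihood(covs[t], prec) for t in test]
            fold_ll[gi, f] = float(np.mean(lls))
    mean_ll = fold_ll.mean(axis=1)
    if not np.any(np.isfinite(mean_ll)):
        raise RuntimeError("graphical LASSO failed on every fold/lambda combination")
    chosen = float(grid[int(np.nanargmax(np.where(np.isfinite(mean_ll), mean_ll, -np.inf)))])
    return LambdaSelection(grid=grid, mean_loglik=mean_ll, fold_loglik=fold_ll, chosen=chosen)


def regularized_windows(
    window_covs: np.ndarray, lam: float, max_iter: int = 200
) -> np.ndarray:
    """Apply the graphical LASSO at a fixed lambda to every window covariance;
    returns the regularized covariance estimates (W, N, N).

    Window covariances from short tapered windows are rank-deficient
    (fewer effective samples than networks) and occasionally break the
    coordinate-descent solver; such windows are retried with a small
    diagonal loading (1e-6, then 1e-4, of the mean variance) before the
    convergence error is propagated.
    """
    out = np.empty_like(window_covs)
    for i, S in enumerate(window_covs):
        try:
            _, out[i] = graphical_lasso(S, lam, max_iter=max_iter)
        except GlassoConvergenceError:
            mean_var = float(np.trace(S)) / S.shape[0]
            for eps in (1e-6, 1e-4):
                try:
                    loaded = S + eps * mean_var * np.eye(S.shape[0])
                    _, out[i] = graphical_lasso(loaded, lam, max_iter=max_iter)
                    break
                except GlassoConvergenceError:
                    continue
            else:
                raise
    return out


# ---------------------------------------------------------------------------
# Correlation / Fisher z / residualization
# ---------------------------------------------------------------------------


def to_correlation(covs: np.ndarray) -> np.ndarray:
    """Covariance -> correlation per window; unit diagonal."""
    covs = np.asarray(covs, dtype=float)
    single = covs.ndim == 2
    if single:
        covs = covs[None]
    d = np.sqrt(np.einsum("wii->wi", covs))
    if np.any(d <= 0):
        raise ValueError("non-positive diagonal in covariance")
    corr = covs / (d[:, :, None] * d[:, None, :])
    return corr[0] if single else corr


def to_fisher_z(covs: np.ndarray) -> np.ndarray:
    """Covariance (or correlation) windows -> Fisher z matrices with zero
    diagonal.  An off-diagonal |r| = 1 is an error (infinite z)."""
    corr = to_correlation(covs)
    single = corr.ndim == 2
    if single:
        corr = corr[None]
    W, N, _ = corr.shape
    off = ~np.eye(N, dtype=bool)
    bad = np.abs(corr[:, off]) >= 1.0
    if np.any(bad):
        wi = int(np.argwhere(bad)[0][0])
        pair = np.argwhere(off)[np.argwhere(bad)[0][1]]
        raise ValueError(
            f"|r| = 1 in window {wi}, pair ({pair[0]}, {pair[1]}): Fisher z undefined"
        )
    z = np.zeros_like(corr)
    z[:, off] = np.arctanh(corr[:, off])
    return z[0] if single else z


def triu_vector(mat: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (diagonal excluded) of one matrix or a stack."""
    mat = np.asarray(mat)
    N = mat.shape[-1]
    iu = np.triu_indices(N, k=1)
    return mat[..., iu[0], iu[1]]


def triu_to_matrix(vec: np.ndarray, N: int) -> np.ndarray:
    """Inverse of :func:`triu_vector` (symmetric, zero diagonal)."""
    iu = np.triu_indices(N, k=1)
    mat = np.zeros(vec.shape[:-1] + (N, N))
    mat[..., iu[0], iu[1]] = vec
    mat[..., iu[1], iu[0]] = vec
    return mat


def residualize(
    z: np.ndarray, covariates: pd.DataFrame, add_intercept_back: bool = True
) -> np.ndarray:
    """Residualize connectivity values with respect to subject covariates.

    ``z`` has shape (n_subjects, ...) — typically (subjects, windows, pairs).
    For every trailing cell, a least-squares fit of the value on the centered
    covariates plus intercept is computed across subjects; the value is
    replaced by residual + intercept, so the grand level is retained for the
    downstream clustering.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    C = covariates.to_numpy(dtype=float)
    if C.shape[0] != n:
        raise ValueError("covariate rows must match number of subjects")
    if n < C.shape[1] + 3:
        raise ValueError("need at least 2 more subjects than covariates (plus intercept)")
    Xc = C - C.mean(axis=0)
    X = np.column_stack([np.ones(n), Xc])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR diagonal
        _, R = np.linalg.qr(X)
        bad = [covariates.columns[i - 1] for i in range(1, X.shape[1])
               if abs(R[i, i]) < 1e-10 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    Y = z.reshape(n, -1)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    if add_intercept_back:
        resid = resid + beta[0]
    return resid.reshape(z.shape)


# ---------------------------------------------------------------------------
# Temporal variability
# ---------------------------------------------------------------------------


@dataclass
class VariabilityResult:
    """SD of connectivity over windows: full N x N matrix (upper triangle
    meaningful), per-network mean over its N-1 connections, and the overall
    mean over all N(N-1)/2 connections."""

    sd_matrix: np.ndarray
    network_mean: np.ndarray
    overall_mean: float
    network_names: list[str] = field(default_factory=list)


def connectivity_variability(
    z_windows: np.ndarray, network_names: list[str] | None = None
) -> VariabilityResult:
    """Per-connection SD over windows (W-1 denominator) for one subject.

    ``z_windows`` is (W, N, N) or a (W, n_pairs) upper-triangle stack; at
    least two windows are required.
    """
    z = np.asarray(z_windows, dtype=float)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 windows to compute an SD over time")
    if z.ndim == 2:  # (W, n_pairs)
        n_pairs = z.shape[1]
        N = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
        if N * (N - 1) // 2 != n_pairs:
            raise ValueError("pair count is not N(N-1)/2 for any integer N")
        sd_vec = z.std(axis=0, ddof=1)
        sd_mat = triu_to_matrix(sd_vec, N)
    elif z.ndim == 3:
        N = z.shape[1]
        sd_mat = z.std(axis=0, ddof=1)
        np.fill_diagonal(sd_mat, 0.0)
        sd_vec = triu_vector(sd_mat)
    else:
        raise ValueError("z_windows must be 2-D or 3-D")
    network_mean = (sd_mat.sum(axis=0)) / (N - 1)
    return VariabilityResult(
        sd_matrix=sd_mat,
        network_mean=network_mean,
        overall_mean=float(sd_vec.mean()),
        network_names=list(network_names) if network_names else [],
    )
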