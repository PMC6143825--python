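"""Sparse inverse covariance networks and the partial-correlation baseline.

The estimator at the core of this module solves, for a sample covariance S
of an expanded region subset,

    theta_hat = argmin_{theta > 0}  -log det(theta) + tr(S theta) + lam * ||theta||_1

where ``||theta||_1`` sums the absolute values of ALL entries, the diagonal
included.  Zeros in theta_hat encode conditional independence between
regions; the first column of theta_hat for the expanded subset
[target, E_p] is the weight vector of the target's sub-network.

The solver is block coordinate descent over columns: with the diagonal
penalized, the working covariance W starts at S + lam*I on the diagonal and
each column update is a lasso subproblem solved by coordinate descent
(JIT-compiled).  The outer iteration stops when the sum of absolute
entrywise changes of theta between sweeps falls below ``tol``.

The non-sparse comparison network is the partial-correlation matrix

    Pi_ij = -(S^-1)_ij / sqrt((S^-1)_ii (S^-1)_jj),   i != j,

computed from the dense inverse of the full (or subset) covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np

from .panel import TimeSeriesPanel
from .topology import TopologySelection

__all__ = [
    "NearSingularCovarianceError",
    "SiceConvergenceError",
    "CovarianceMatrix",
    "PrecisionEstimate",
    "SubnetworkWeights",
    "ConnectivityMatrix",
    "PartialCorrelationMatrix",
    "sample_covariance",
    "partial_correlation",
    "graphical_lasso",
    "sice_objective",
    "build_subnetworks",
    "assemble_connectivity",
    "full_partial_network",
]

#: condition-number threshold beyond which a covariance is treated as singular
COND_THRESHOLD = 1e12


class NearSingularCovarianceError(np.linalg.LinAlgError):
    """Covariance matrix too ill-conditioned to invert reliably."""


class SiceConvergenceError(RuntimeError):
    """Sparse inverse covariance estimation failed to reach the tolerance."""

    def __init__(self, message: str, final_delta: float):
        super().__init__(message)
        self.final_delta = final_delta


@dataclass
class CovarianceMatrix:
    """Sample covariance S (R x R, symmetric) with its sample count."""

    S: np.ndarray
    n_samples: int


@dataclass
class PrecisionEstimate:
    """Estimated sparse precision matrix at penalty ``lam``.

    ``delta_theta_trace`` records, per outer sweep, the sum of absolute
    entrywise differences between successive iterates.  At ``lam = 0`` the
    estimate is the plain inverse of S (no iteration, empty trace).
    """

    theta: np.ndarray
    lam: float
    delta_theta_trace: np.ndarray = field(
        default_factory=lambda: np.zeros(0)
    )
    n_iter: int = 0


@dataclass
class SubnetworkWeights:
    """First column of the sub-network precision for one (target, subject).

    ``weights[k]`` is the estimated conditional dependence between the target
    region and ``member_indices[k]``; the target's own diagonal entry is
    dropped.
    """

    target_index: int
    subject_index: int
    weights: np.ndarray
    member_indices: np.ndarray


@dataclass
class ConnectivityMatrix:
    """Per-subject P x P connectivity matrix assembled column-wise."""

    theta_full: np.ndarray
    symmetric_flag: bool = False


@dataclass
class PartialCorrelationMatrix:
    """Partial-correlation matrix Pi: symmetric, unit diagonal."""

    pi: np.ndarray


def _as_cov_array(S) -> np.ndarray:
    arr = S.S if isinstance(S, CovarianceMatrix) else np.asarray(S, dtype=float)
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("covariance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    return 0.5 * (arr + arr.T)


def sample_covariance(X: np.ndarray) -> CovarianceMatrix:
    """Unbiased sample covariance of an (n_t x R) matrix (divisor n_t - 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_t = X.shape[0]
    if n_t < 2:
        raise ValueError(f"need at least 2 time points, got {n_t}")
    centered = X - X.mean(axis=0, keepdims=True)
    S = centered.T @ centered / (n_t - 1)
    return CovarianceMatrix(S=0.5 * (S + S.T), n_samples=n_t)


def partial_correlation(S) -> PartialCorrelationMatrix:
    """Partial correlations from the dense inverse covariance.

    Raises :class:`NearSingularCovarianceError` when the condition number of
    S exceeds 1e12 (or is not finite).
    """
    arr = _as_cov_array(S)
    cond = np.linalg.cond(arr)
    if not np.isfinite(cond) or cond > COND_THRESHOLD:
        raise NearSingularCovarianceError(
            f"covariance matrix is near-singular (condition number {cond:.3g}); "
            "partial correlations undefined"
        )
    K = np.linalg.inv(arr)
    d = np.sqrt(np.diag(K))
    pi = -K / np.outer(d, d)
    np.fill_diagonal(pi, 1.0)
    return PartialCorrelationMatrix(pi=0.5 * (pi + pi.T))


@numba.njit(cache=True)
def _glasso_bcd(S, lam, tol, max_iter, inner_tol, inner_max):  # pragma: no cover
    R = S.shape[0]
    W = S.copy()
    for i in range(R):
        W[i, i] = S[i, i] + lam
    B = np.zeros((R, R))
    theta = np.zeros((R, R))
    theta_prev = np.zeros((R, R))
    for i in range(R):
        theta_prev[i, i] = 1.0 / W[i, i]
    deltas = np.zeros(max_iter)
    n_iter = 0
    converged = False
    for it in range(max_iter):
        for j in range(R):
            # lasso subproblem for column j: coordinate descent on B[:, j]
            for _ in range(inner_max):
                max_change = 0.0
                for k in range(R):
                    if k == j:
                        continue
                    g = S[k, j]
                    for l in range(R):
                        if l == j or l == k:
                            continue
                        g -= W[k, l] * B[l, j]
                    if g > lam:
                        b_new = (g - lam) / W[k, k]
                    elif g < -lam:
                        b_new = (g + lam) / W[k, k]
                    else:
                        b_new = 0.0
                    change = abs(b_new - B[k, j])
                    if change > max_change:
                        max_change = change
                    B[k, j] = b_new
                if max_change < inner_tol:
                    break
            for k in range(R):
                if k == j:
                    continue
                acc = 0.0
                for l in range(R):
                    if l == j:
                        continue
                    acc += W[k, l] * B[l, j]
                W[k, j] = acc
                W[j, k] = acc
        for j in range(R):
            acc = 0.0
            for k in range(R):
                if k != j:
                    acc += W[k, j] * B[k, j]
            dj = W[j, j] - acc
            theta[j, j] = 1.0 / dj
            for k in range(R):
                if k != j:
                    theta[k, j] = -B[k, j] / dj
        for i in range(R):
            for j2 in range(i + 1, R):
                v = 0.5 * (theta[i, j2] + theta[j2, i])
                theta[i, j2] = v
                theta[j2, i] = v
        delta = 0.0
        for i in range(R):
            for j2 in range(R):
                delta += abs(theta[i, j2] - theta_prev[i, j2])
                theta_prev[i, j2] = theta[i, j2]
        deltas[it] = delta
        n_iter = it + 1
        if delta < tol:
            converged = True
            break
    return theta, deltas[:n_iter], n_iter, converged


def sice_objective(theta: np.ndarray, S, lam: float) -> float:
    """-log det(theta) + tr(S theta) + lam * sum |theta| (all entries)."""
    arr = S.S if isinstance(S, CovarianceMatrix) else np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    return float(-logdet + np.trace(arr @ theta) + lam * np.abs(theta).sum())


def graphical_lasso(
    S, lam: float, tol: float = 1e-6, max_iter: int = 200
) -> PrecisionEstimate:
    """L1-penalized maximum-likelihood precision estimate (diagonal penalized).

    At ``lam = 0`` this is the plain maximum-likelihood inverse of S (S must
    then be positive definite).  For ``lam > 0`` the block coordinate descent
    runs until the sum of absolute entrywise changes of theta falls below
    ``tol``; exceeding ``max_iter`` sweeps raises
    :class:`SiceConvergenceError` carrying the final change.
    """
    arr = _as_cov_array(S)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    R = arr.shape[0]
    if R == 1:
        denom = arr[0, 0] + lam
        if denom <= 0:
            raise ValueError("S + lam*I not positive on the diagonal")
        return PrecisionEstimate(theta=np.array([[1.0 / denom]]), lam=float(lam))
    if lam == 0.0:
        try:
            np.linalg.cholesky(arr)
        except np.linalg.LinAlgError as exc:
            raise NearSingularCovarianceError(
                "S must be positive definite for the unpenalized estimate"
            ) from exc
        theta = np.linalg.inv(arr)
        return PrecisionEstimate(theta=0.5 * (theta + theta.T), lam=0.0)
    inner_tol = max(tol * 1e-2, 1e-13)
    theta, deltas, n_iter, converged = _glasso_bcd(
        arr, float(lam), float(tol), int(max_iter), inner_tol, 10_000
    )
    if not converged:
        raise SiceConvergenceError(
            f"no convergence within {max_iter} sweeps "
            f"(final delta-theta {deltas[-1]:.3e} >= tol {tol:.3e})",
            final_delta=float(deltas[-1]),
        )
    if np.linalg.eigvalsh(theta)[0] <= 0:  # pragma: no cover - BCD preserves PD
        raise SiceConvergenceError(
            "estimate lost positive definiteness", final_delta=float(deltas[-1])
        )
    return PrecisionEstimate(
        theta=theta, lam=float(lam), delta_theta_trace=deltas, n_iter=n_iter
    )


def build_subnetworks(
    panel: TimeSeriesPanel,
    selection: TopologySelection,
    p: int,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 200,
    trace_collector: list | None = None,
) -> list[SubnetworkWeights]:
    """Per-subject sub-network weight vectors for target region ``p``.

    For each subject the expanded subset [p, E_p] is covaried, the sparse
    precision estimated at ``lam``, and the first column (diagonal dropped)
    returned aligned to E_p.  An empty E_p yields all-zero weights with a
    warning.  ``trace_collector``, when given, receives each estimate's
    ``(n_iter, delta_theta_trace)``.
    """
    E_p = np.asarray(selection.subsets[p], dtype=int)
    if E_p.size == 0:
        warnings.warn(
            f"target region {p}: empty predictor subset, zero weights returned",
            RuntimeWarning,
        )
        return [
            SubnetworkWeights(p, m, np.zeros(0), E_p.copy())
            for m in range(panel.M)
        ]
    cols = np.concatenate(([p], E_p))
    out = []
    for m, x in enumerate(panel.subjects):
        est = graphical_lasso(
            sample_covariance(x[:, cols]), lam, tol=tol, max_iter=max_iter
        )
        if trace_collector is not None:
            trace_collector.append((est.n_iter, est.delta_theta_trace))
        out.append(
            SubnetworkWeights(
                target_index=p,
                subject_index=m,
                weights=est.theta[1:, 0].copy(),
                member_indices=E_p.copy(),
            )
        )
    return out


def assemble_connectivity(
    subnetworks, P: int, symmetrize: bool = False
) -> ConnectivityMatrix:
    """Scatter one subject's P weight vectors into the P x P matrix.

    Column p of the result holds the target-p weight vector at the rows of
    its member regions, zeros elsewhere; the diagonal is zero.  No
    symmetrization by default (the column-wise scatter is asymmetric);
    ``symmetrize=True`` applies (theta + theta^T) / 2.
    """
    subnets = list(subnetworks)
    if len(subnets) != P:
        raise ValueError(f"expected {P} sub-networks (one per target), got {len(subnets)}")
    targets = sorted(sw.target_index for sw in subnets)
    if targets != list(range(P)):
        raise ValueError("sub-networks must cover each target region exactly once")
    theta = np.zeros((P, P))
    for sw in subnets:
        p = sw.target_index
        idx = np.asarray(sw.member_indices, dtype=int)
        if idx.size != len(sw.weights):
            raise ValueError(f"target {p}: weights/member_indices length mismatch")
        if idx.size == 0:
            continue
        if np.any((idx < 0) | (idx >= P)):
            raise ValueError(f"target {p}: member index out of range")
        if np.any(idx == p):
            raise ValueError(f"target {p}: member set contains the target itself")
        if len(np.unique(idx)) != idx.size:
            raise ValueError(f"target {p}: duplicate member indices")
        theta[idx, p] = sw.weights
    if symmetrize:
        return ConnectivityMatrix(0.5 * (theta + theta.T), symmetric_flag=True)
    return ConnectivityMatrix(theta, symmetric_flag=False)


def full_partial_network(
    panel: TimeSeriesPanel,
    selection: TopologySelection | None,
    m: int,
) -> ConnectivityMatrix:
    """Non-sparse comparison network for subject ``m``.

    Without a topology selection, the whole-brain P x P partial-correlation
    matrix (symmetric, unit diagonal).  With one, each target's partial
    correlations are computed on its expanded subset [p, E_p] and the first
    column scattered as in :func:`assemble_connectivity` (asymmetric, zero
    diagonal).
    """
    x = panel.subjects[m]
    if selection is None:
        pi = partial_correlation(sample_covariance(x))
        return ConnectivityMatrix(pi.pi.copy(), symmetric_flag=True)
    P = panel.P
    theta = np.zeros((P, P))
    for p in range(P):
        E_p = np.asarray(selection.subsets[p], dtype=int)
        if E_p.size == 0:
            continue
        cols = np.concatenate(([p], E_p))
        pi = partial_correlation(sample_covariance(x[:, cols]))
        theta[E_p, p] = pi.pi[1:, 0]
    return ConnectivityMatrix(theta, symmetric_flag=False)
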