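"""Group-constrained topology detection: shared predictor subsets per region.

For each target region p, an l2,1-penalized multi-subject regression selects
one subset of predictor regions shared by all M subjects:

    min_beta  sum_m ||x_p^m - X_p^m beta_p^m||_2^2  +  phi * ||beta_p||_{2,1}

where ``beta_p`` is the (P-1) x M coefficient matrix (one column per subject)
and the l2,1 norm sums the Euclidean norms of its rows.  Because the penalty
acts on whole rows, a predictor is either kept for every subject or dropped
for every subject — the topology is identical across subjects while the
coefficient values remain individual.

The regularization parameter phi is chosen per target by the Bayesian
information criterion

    BIC = sum_m ln ESS(m) + d * ln(n_t) / n_t

with ESS(m) the residual sum of squares of subject m and d the number of
nonzero coefficients.

The solver is block coordinate descent over rows with the group
soft-thresholding proximal update; it requires the standardized inputs
produced by :func:`standardize_target_and_design` (mean-centered, unit-norm
columns), under which each row update is an exact minimization and the
objective descends monotonically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import TimeSeriesPanel

__all__ = [
    "ZeroVarianceTargetError",
    "TopologyFitError",
    "StandardizedRegression",
    "GroupCoefficients",
    "TopologySelection",
    "standardize_target_and_design",
    "solve_group_lasso",
    "phi_max",
    "row_support",
    "bic_from_ess",
    "bic_score",
    "select_topology",
    "default_phi_grid",
]

#: relative row-norm threshold below which a coefficient row counts as zero
ROW_ZERO_RTOL = 1e-6
#: floor applied to ESS before the logarithm in the BIC
_ESS_FLOOR = 1e-12


class ZeroVarianceTargetError(ValueError):
    """The response (target region) time series has zero variance."""


class TopologyFitError(RuntimeError):
    """A group-lasso fit failed; message carries the (target, phi) cell."""


@dataclass
class StandardizedRegression:
    """Standardized per-subject (response, design) pairs for one target.

    ``responses`` is (n_t, M); ``designs`` is (M, n_t, K) with K = P - 1.
    Every response and every non-degenerate design column is mean-centered
    and scaled to unit Euclidean norm.  ``zero_variance`` flags predictor
    rows degenerate (constant) in at least one subject; their columns are
    zero vectors and their coefficients stay pinned at zero.
    """

    target_index: int
    responses: np.ndarray
    designs: np.ndarray
    predictor_rois: np.ndarray
    zero_variance: np.ndarray
    _gram: np.ndarray | None = field(default=None, repr=False)
    _xty: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_t(self) -> int:
        return self.responses.shape[0]

    @property
    def M(self) -> int:
        return self.responses.shape[1]

    @property
    def K(self) -> int:
        return self.designs.shape[2]

    @property
    def pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-subject (response vector, design matrix) views."""
        return [
            (self.responses[:, m], self.designs[m]) for m in range(self.M)
        ]

    def gram(self) -> np.ndarray:
        """Per-subject Gram matrices X_m^T X_m, shape (M, K, K); cached."""
        if self._gram is None:
            self._gram = np.einsum("mti,mtj->mij", self.designs, self.designs)
        return self._gram

    def xty(self) -> np.ndarray:
        """Per-subject X_m^T y_m stacked as columns, shape (K, M); cached."""
        if self._xty is None:
            self._xty = np.einsum("mti,tm->im", self.designs, self.responses)
        return self._xty


def _standardize_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center columns and scale to unit l2 norm; zero-variance -> zero column."""
    centered = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    degenerate = norms < 1e-12
    safe = np.where(degenerate, 1.0, norms)
    out = centered / safe
    out[:, degenerate] = 0.0
    return out, degenerate


def standardize_target_and_design(
    panel: TimeSeriesPanel, p: int
) -> StandardizedRegression:
    """Split region ``p`` out as the response and standardize everything.

    Raises :class:`ZeroVarianceTargetError` if any subject's target series is
    constant.  Degenerate predictor columns are flagged and zeroed.
    """
    if not 0 <= p < panel.P:
        raise ValueError(f"target index {p} out of range [0, {panel.P})")
    others = np.array([q for q in range(panel.P) if q != p])
    responses = np.empty((panel.n_t, panel.M))
    designs = np.empty((panel.M, panel.n_t, panel.P - 1))
    degenerate = np.zeros(panel.P - 1, dtype=bool)
    for m, x in enumerate(panel.subjects):
        y, y_bad = _standardize_columns(x[:, [p]])
        if y_bad[0]:
            raise ZeroVarianceTargetError(
                f"target region {p} has zero variance for subject "
                f"{panel.subject_ids[m]!r}"
            )
        responses[:, m] = y[:, 0]
        cols, bad = _standardize_columns(x[:, others])
        designs[m] = cols
        degenerate |= bad
    designs[:, :, degenerate] = 0.0
    return StandardizedRegression(
        target_index=p,
        responses=responses,
        designs=designs,
        predictor_rois=others,
        zero_variance=degenerate,
    )


@dataclass
class GroupCoefficients:
    """Fitted coefficient matrix for one target region at one phi.

    ``beta`` is (P-1) x M; row support is shared across subject columns by
    construction of the group soft-threshold update.  ``objective_trace`` and
    ``delta_beta_trace`` record, per iteration, the penalized objective and
    the Frobenius norm of the change in beta.
    """

    target_index: int
    beta: np.ndarray
    phi: float
    objective_trace: np.ndarray
    delta_beta_trace: np.ndarray
    n_iter: int
    predictor_rois: np.ndarray
    zero_variance: np.ndarray


def phi_max(std: StandardizedRegression) -> float:
    """Smallest phi at which the all-zero solution is optimal.

    From the subgradient condition at beta = 0: row j stays zero iff
    ``2 * ||X_j^T y||_2 <= phi``, so phi_max is twice the largest row-wise
    l2 norm of the stacked per-subject correlations.
    """
    b = std.xty()
    norms = np.linalg.norm(b, axis=1)
    norms[std.zero_variance] = 0.0
    return float(2.0 * norms.max()) if norms.size else 0.0


def solve_group_lasso(
    std: StandardizedRegression,
    phi: float,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> GroupCoefficients:
    """Block coordinate descent on the l2,1-penalized multi-subject regression.

    Each sweep minimizes the objective exactly over one coefficient row at a
    time (group soft-threshold); iteration stops when the Frobenius norm of
    the update falls below ``tol`` or after ``max_iter`` sweeps, whichever
    comes first.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    K, M = std.K, std.M
    G = std.gram()  # (M, K, K)
    b = std.xty()  # (K, M)
    yty = np.einsum("tm,tm->m", std.responses, std.responses)
    active = ~std.zero_variance
    beta = np.zeros((K, M))
    R = b.copy()  # residual correlations X^T (y - X beta), per subject column

    def objective_from_residual(bt: np.ndarray, Rt: np.ndarray) -> float:
        # beta^T G beta = beta . (b - R) with R = b - G beta, so the
        # objective costs O(KM) instead of O(MK^2)
        fid = float(yty.sum() - np.sum(bt * b) - np.sum(bt * Rt))
        return fid + float(phi * np.linalg.norm(bt, axis=1).sum())

    obj_trace = [objective_from_residual(beta, R)]
    delta_trace: list[float] = []
    n_iter = 0
    half_phi = 0.5 * phi
    for it in range(max_iter):
        beta_prev = beta.copy()
        for j in range(K):
            if not active[j]:
                continue
            # c_j = correlation of column j with the residual excluding row j
            c = R[j, :] + beta[j, :]  # G_m[j, j] == 1 on standardized inputs
            nc = np.linalg.norm(c)
            if nc <= half_phi:
                new_row = np.zeros(M)
            else:
                new_row = c * (1.0 - half_phi / nc)
            d = new_row - beta[j, :]
            if np.any(d != 0.0):
                beta[j, :] = new_row
                R -= G[:, :, j].T * d[None, :]
        # majorize-minimize refinement of the active rows, iterated to its
        # own fixed point: solving (2G + phi*diag(1/||beta_j||)) beta_m =
        # 2 b_m minimizes the standard quadratic upper bound of the group
        # penalty, tangent at the current iterate.  Cyclic descent alone
        # crawls on strongly correlated designs and near-boundary rows; this
        # step keeps exact zeros (inactive rows untouched) and monotone
        # descent while reaching the tolerance within the sweep cap.
        norms = np.linalg.norm(beta, axis=1)
        act = np.where(norms > 0)[0]
        if act.size:
            # the refinement never zeroes a row, so the active set is fixed
            # for the whole inner loop and its Gram can be extracted once;
            # large active sets (far from the sparse optimum, where the slow
            # tail never bites) get a light touch since solves cost |A|^3
            G_act = G[:, act[:, None], act[None, :]]
            b_act = b[act, :]
            beta_act = beta[act, :]

            def act_objective(bt_act: np.ndarray) -> float:
                # rows off the active set are exactly zero, so this is the
                # full objective evaluated in the active subspace
                quad = float(np.einsum("im,mij,jm->", bt_act, G_act, bt_act))
                return float(
                    yty.sum() - 2.0 * np.sum(bt_act * b_act) + quad
                    + phi * np.linalg.norm(bt_act, axis=1).sum()
                )

            cur_obj = act_objective(beta_act)
            max_rounds = 30 if act.size <= 32 else 2
            for _ in range(max_rounds):
                inv_r = 1.0 / np.linalg.norm(beta_act, axis=1)
                cand = np.empty_like(beta_act)
                ok = True
                for m in range(M):
                    lhs = 2.0 * G_act[m] + phi * np.diag(inv_r)
                    try:
                        cand[:, m] = np.linalg.solve(lhs, 2.0 * b_act[:, m])
                    except np.linalg.LinAlgError:
                        ok = False
                        break
                if not ok:
                    break
                cand_obj = act_objective(cand)
                if cand_obj > cur_obj:
                    break
                step = float(np.linalg.norm(cand - beta_act))
                beta_act, cur_obj = cand, cand_obj
                if step < 1e-10:
                    break
            beta[act, :] = beta_act
            R = b - np.einsum("mij,jm->im", G[:, :, act], beta_act)
        delta = float(np.linalg.norm(beta - beta_prev))
        obj = objective_from_residual(beta, R)
        if not np.isfinite(obj):
            raise TopologyFitError(
                f"non-finite objective at iteration {it + 1} (phi={phi})"
            )
        obj_trace.append(obj)
        delta_trace.append(delta)
        n_iter = it + 1
        if delta < tol:
            break
    return GroupCoefficients(
        target_index=std.target_index,
        beta=beta,
        phi=float(phi),
        objective_trace=np.asarray(obj_trace),
        delta_beta_trace=np.asarray(delta_trace),
        n_iter=n_iter,
        predictor_rois=std.predictor_rois,
        zero_variance=std.zero_variance,
    )


def row_support(coeffs: GroupCoefficients, rtol: float = ROW_ZERO_RTOL) -> np.ndarray:
    """Boolean mask of nonzero coefficient rows (relative-norm threshold).

    A row is zero when its l2 norm is below ``rtol`` times the largest row
    norm (or below ``rtol`` itself when every row is zero).
    """
    norms = np.linalg.norm(coeffs.beta, axis=1)
    scale = norms.max() if norms.size and norms.max() > 0 else 1.0
    return norms > rtol * scale


def bic_from_ess(ess: np.ndarray, d: int, n_t: int) -> float:
    """BIC score from per-subject residual sums of squares.

    ``sum_m ln ESS(m) + d * ln(n_t) / n_t``; ESS values at or below zero are
    floored at 1e-12 with a warning (interpolating fits would otherwise give
    a log of zero).
    """
    ess = np.asarray(ess, dtype=float)
    if np.any(ess <= _ESS_FLOOR):
        warnings.warn(
            "ESS at or below 1e-12 floored before the logarithm", RuntimeWarning
        )
        ess = np.maximum(ess, _ESS_FLOOR)
    return float(np.sum(np.log(ess)) + d * np.log(n_t) / n_t)


def bic_score(coeffs: GroupCoefficients, std: StandardizedRegression) -> float:
    """BIC of a fitted coefficient matrix on its standardized inputs.

    ``d`` counts the nonzero entries within the rows passing the numeric-zero
    row threshold.
    """
    if coeffs.beta.shape != (std.K, std.M):
        raise ValueError("coefficients inconsistent with standardized inputs")
    ess = np.empty(std.M)
    for m, (y, X) in enumerate(std.pairs):
        r = y - X @ coeffs.beta[:, m]
        ess[m] = float(r @ r)
    kept = row_support(coeffs)
    d = int(np.count_nonzero(np.abs(coeffs.beta[kept, :]) > 0.0))
    return bic_from_ess(ess, d, std.n_t)


def default_phi_grid() -> np.ndarray:
    """19 grid points 0.05, 0.10, ..., 0.95."""
    return np.round(np.arange(1, 20) * 0.05, 10)


@dataclass
class TopologySelection:
    """Selected predictor subsets E_p and the BIC table behind them.

    ``subsets[p]`` holds the ROI indices whose coefficient rows are nonzero at
    the BIC-minimizing phi for target p (never containing p itself);
    ``chosen_phi[p]`` attains the minimum of the BIC row, ties resolved toward
    the smallest phi (denser, more conservative topology).
    """

    subsets: list[np.ndarray]
    chosen_phi: np.ndarray
    bic_table: pd.DataFrame
    phi_grid: np.ndarray
    roi_names: list[str]
    delta_traces: dict = field(default_factory=dict)
    n_iters: dict = field(default_factory=dict)

    @property
    def P(self) -> int:
        return len(self.subsets)

    def to_json_dict(self) -> dict:
        return {
            "roi_names": list(self.roi_names),
            "phi_grid": [float(v) for v in self.phi_grid],
            "chosen_phi": [float(v) for v in self.chosen_phi],
            "subsets": [[int(i) for i in s] for s in self.subsets],
            "subsets_1based": [[int(i) + 1 for i in s] for s in self.subsets],
            "subset_names": [
                [self.roi_names[i] for i in s] for s in self.subsets
            ],
            "bic_table": {
                str(col): [float(v) for v in self.bic_table[col]]
                for col in self.bic_table.columns
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TopologySelection":
        phi_grid = np.asarray(d["phi_grid"], dtype=float)
        bic = pd.DataFrame({float(k): v for k, v in d["bic_table"].items()})
        return cls(
            subsets=[np.asarray(s, dtype=int) for s in d["subsets"]],
            chosen_phi=np.asarray(d["chosen_phi"], dtype=float),
            bic_table=bic,
            phi_grid=phi_grid,
            roi_names=list(d["roi_names"]),
        )


def _fit_one_target(panel, p, grid, tol, max_iter):
    std = standardize_target_and_design(panel, p)
    fits, bics = [], []
    for phi in grid:
        try:
            fit = solve_group_lasso(std, phi, max_iter=max_iter, tol=tol)
            bics.append(bic_score(fit, std))
        except Exception as exc:
            raise TopologyFitError(
                f"group-lasso fit failed at target {p}, phi {phi}: {exc}"
            ) from exc
        fits.append(fit)
    bics = np.asarray(bics)
    i_best = int(np.argmin(bics))  # first minimum = smallest phi on sorted grid
    best = fits[i_best]
    mask = row_support(best)
    return (
        best.predictor_rois[mask],
        float(grid[i_best]),
        bics,
        best.delta_beta_trace,
        best.n_iter,
    )


def select_topology(
    panel: TimeSeriesPanel,
    phi_grid=None,
    tol: float = 1e-6,
    max_iter: int = 100,
    n_jobs: int = 1,
) -> TopologySelection:
    """Fit every (target, phi) cell, score by BIC, and keep the minimizers.

    For each target region p the group lasso is fitted at every phi in the
    grid; the phi with the smallest BIC wins (ties: smallest phi) and E_p is
    the set of predictor regions with nonzero coefficient rows at that phi.
    Targets are independent; ``n_jobs`` > 1 fits them in parallel.
    """
    grid = default_phi_grid() if phi_grid is None else np.sort(
        np.asarray(phi_grid, dtype=float)
    )
    if grid.size == 0:
        raise ValueError("phi_grid must be nonempty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("phi grid values must lie in (0, 1)")
    if n_jobs == 1:
        results = [
            _fit_one_target(panel, p, grid, tol, max_iter) for p in range(panel.P)
        ]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_fit_one_target)(panel, p, grid, tol, max_iter)
            for p in range(panel.P)
        )
    subsets, chosen, rows = [], [], []
    delta_traces, n_iters = {}, {}
    for p, (subset, phi_best, bics, trace, n_it) in enumerate(results):
        subsets.append(subset)
        chosen.append(phi_best)
        rows.append(bics)
        delta_traces[p] = trace
        n_iters[p] = n_it
    bic_table = pd.DataFrame(
        np.vstack(rows), columns=[float(v) for v in grid]
    )
    bic_table.index.name = "target"
    return TopologySelection(
        subsets=subsets,
        chosen_phi=np.asarray(chosen),
        bic_table=bic_table,
        phi_grid=grid,
        roi_names=list(panel.roi_names),
        delta_traces=delta_traces,
        n_iters=n_iters,
    )
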