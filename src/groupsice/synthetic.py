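"""Synthetic two-group cohorts drawn from known sparse precision matrices.

The generator emulates the data the estimators target: zero-mean multivariate
Gaussian time series whose inverse covariance (precision) matrix is sparse,
with one support topology shared by every subject in a group and a small set
of edges differing between the two groups.  A Gaussian graphical model is
used because the sparse inverse covariance estimator's likelihood is exactly
the Gaussian one, so the generating precision matrix is the ground truth for
the quantity being estimated.

Per-subject individuality enters only through the *values* of the nonzero
precision entries (multiplicative jitter), never through the support — the
premise of the group-constrained approach is that topology is shared across
subjects while connectivity strengths differ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .panel import TimeSeriesPanel

__all__ = [
    "PrecisionSpec",
    "CohortConfig",
    "generate_precision_spec",
    "perturb_for_group",
    "simulate_panel",
    "make_two_group_cohort",
]

#: diagonal loading target: smallest eigenvalue after loading
_MIN_EIG = 1e-3


def _as_pair(edge) -> tuple[int, int]:
    i, j = int(edge[0]), int(edge[1])
    if i == j:
        raise ValueError(f"edge ({i},{j}) is a self-loop")
    return (i, j) if i < j else (j, i)


def _load_pd(theta: np.ndarray) -> np.ndarray:
    """Diagonally load until the smallest eigenvalue is at least ``_MIN_EIG``."""
    theta = 0.5 * (theta + theta.T)
    # slack keeps the bump representable when added to O(1) diagonal entries
    slack = 1e-9
    for _ in range(8):
        w = np.linalg.eigvalsh(theta)[0]
        if w >= _MIN_EIG - slack:
            return theta
        theta = theta + (_MIN_EIG - w + slack) * np.eye(theta.shape[0])
    raise RuntimeError("diagonal loading failed to reach positive definiteness")


@dataclass(frozen=True)
class PrecisionSpec:
    """A ground-truth sparse precision matrix for one group.

    ``theta`` is symmetric positive definite with zeros exactly off
    ``support`` (a frozenset of unordered index pairs ``(i, j)``, ``i < j``).
    """

    P: int
    support: frozenset
    theta: np.ndarray
    group_label: int = 0

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (self.P, self.P):
            raise ValueError("theta shape inconsistent with P")
        if not np.allclose(theta, theta.T, atol=1e-12):
            raise ValueError("theta must be symmetric")
        if np.linalg.eigvalsh(theta)[0] <= 0:
            raise ValueError("theta must be positive definite")
        support = frozenset(_as_pair(e) for e in self.support)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "theta", theta)
        for i in range(self.P):
            for j in range(i + 1, self.P):
                on = (i, j) in support
                if on and theta[i, j] == 0.0:
                    raise ValueError(f"support pair ({i},{j}) has zero entry")
                if not on and theta[i, j] != 0.0:
                    raise ValueError(f"nonzero entry ({i},{j}) off support")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort dimensions and per-subject variability.

    ``subject_jitter`` scales the multiplicative perturbation of nonzero
    precision entries: each off-diagonal nonzero is multiplied by ``(1 + u)``
    with ``u ~ U[-jitter, +jitter]``, identical for the two symmetric entries,
    so the support is preserved for any jitter below 1.
    """

    M_per_group: int
    n_t: int = 229
    subject_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M_per_group < 1:
            raise ValueError("M_per_group must be >= 1")
        if self.n_t < 2:
            raise ValueError("n_t must be >= 2")
        if not 0.0 <= self.subject_jitter < 1.0:
            raise ValueError("subject_jitter must be in [0, 1)")


def generate_precision_spec(
    P: int, n_edges: int, strength: float, seed: int, group_label: int = 0
) -> PrecisionSpec:
    """Draw a sparse precision matrix with exactly ``n_edges`` nonzero pairs.

    Off-diagonal magnitudes are ``strength`` times a U[0.8, 1.2] factor with a
    random sign; the diagonal starts at 1 and is loaded until the smallest
    eigenvalue reaches 1e-3.  Identical seeds give identical specs.
    """
    if strength <= 0:
        raise ValueError("strength must be positive")
    pairs = list(itertools.combinations(range(P), 2))
    if not 0 <= n_edges <= len(pairs):
        raise ValueError(
            f"n_edges={n_edges} outside [0, {len(pairs)}] for P={P} regions"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_edges, replace=False) if n_edges else []
    theta = np.eye(P)
    support = set()
    for k in chosen:
        i, j = pairs[int(k)]
        val = strength * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
        theta[i, j] = theta[j, i] = val
        support.add((i, j))
    return PrecisionSpec(
        P=P, support=frozenset(support), theta=_load_pd(theta), group_label=group_label
    )


def perturb_for_group(
    base: PrecisionSpec,
    edges_to_flip,
    strength: float,
    seed: int,
    group_label: int = 1,
) -> PrecisionSpec:
    """Flip edge membership on ``edges_to_flip`` to create the second group.

    Edges present in ``base`` are removed; absent ones are added with random
    sign and magnitude ``strength * U[0.8, 1.2]``.  The supports of the two
    specs differ exactly on the flip set.  The diagonal is reset to 1 and
    re-loaded to positive definiteness, so diagonals may differ from ``base``.
    """
    flips = {_as_pair(e) for e in edges_to_flip}
    for i, j in flips:
        if not (0 <= i < base.P and 0 <= j < base.P):
            raise ValueError(f"edge ({i},{j}) out of range for P={base.P}")
    rng = np.random.default_rng(seed)
    theta = base.theta.copy()
    np.fill_diagonal(theta, 1.0)
    support = set(base.support)
    for i, j in sorted(flips):
        if (i, j) in support:
            theta[i, j] = theta[j, i] = 0.0
            support.remove((i, j))
        else:
            val = strength * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
            theta[i, j] = theta[j, i] = val
            support.add((i, j))
    return PrecisionSpec(
        P=base.P,
        support=frozenset(support),
        theta=_load_pd(theta),
        group_label=group_label,
    )


def _jittered_precision(
    spec: PrecisionSpec, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    pairs = sorted(spec.support)
    u = rng.uniform(-jitter, jitter, size=len(pairs))
    theta = spec.theta.copy()
    for (i, j), uk in zip(pairs, u):
        theta[i, j] = theta[j, i] = spec.theta[i, j] * (1.0 + uk)
    theta = _load_pd(theta)
    if np.linalg.eigvalsh(theta)[0] <= 0:  # pragma: no cover - loading guarantees
        raise RuntimeError("jittered precision lost positive definiteness")
    return theta


def simulate_panel(
    spec_A: PrecisionSpec, spec_B: PrecisionSpec, cfg: CohortConfig
) -> TimeSeriesPanel:
    """Draw the two-group cohort: i.i.d. Gaussian rows per subject.

    Each subject's ``(n_t, P)`` matrix is drawn from ``N(0, theta_m^{-1})``
    where ``theta_m`` is the subject's jittered group precision.  Draws are
    i.i.d. across time (no temporal autocorrelation; the estimators treat
    time points as exchangeable samples).  A fixed config seed gives a
    bit-identical panel.  The generating precisions and supports are recorded
    in ``panel.extras`` as ground truth for recovery tests.
    """
    if spec_A.P != spec_B.P:
        raise ValueError("both groups must share the region count P")
    P = spec_A.P
    if cfg.n_t < P + 1:
        raise ValueError(f"n_t={cfg.n_t} must be >= P+1={P + 1}")
    rng = np.random.default_rng(cfg.seed)
    subjects, labels, ids, precisions = [], [], [], []
    for spec in (spec_A, spec_B):
        for s in range(cfg.M_per_group):
            theta_m = _jittered_precision(spec, cfg.subject_jitter, rng)
            cov = np.linalg.inv(theta_m)
            cov = 0.5 * (cov + cov.T)
            x = rng.multivariate_normal(
                np.zeros(P), cov, size=cfg.n_t, method="cholesky"
            )
            subjects.append(x)
            labels.append(spec.group_label)
            ids.append(f"g{spec.group_label}_s{s:02d}")
            precisions.append(theta_m)
    ground_truth = {
        "seed": cfg.seed,
        "support_A": sorted(list(e) for e in spec_A.support),
        "support_B": sorted(list(e) for e in spec_B.support),
        "flipped_edges": sorted(list(e) for e in spec_A.support ^ spec_B.support),
        "subject_jitter": cfg.subject_jitter,
    }
    return TimeSeriesPanel(
        subjects=subjects,
        labels=np.array(labels),
        subject_ids=ids,
        roi_names=[f"ROI{i + 1:03d}" for i in range(P)],
        extras={"ground_truth": ground_truth, "subject_precisions": precisions},
    )


#: study conditions for end-to-end method comparisons: region count as in the
#: 90-region atlas parcellation, sparse base support (mean degree 4), six
#: planted edge differences, 10+10 subjects, 300 time points
COMPARISON_COHORT = dict(
    P=90, n_edges=180, n_flip=6, strength=0.3, M_per_group=10, n_t=300,
    subject_jitter=0.1,
)


def make_two_group_cohort(
    seed: int,
    P: int = 20,
    n_edges: int = 30,
    n_flip: int = 6,
    strength: float = 0.3,
    M_per_group: int = 10,
    n_t: int = 300,
    subject_jitter: float = 0.1,
) -> TimeSeriesPanel:
    """Convenience builder for the planted-difference study cohort.

    Base support of ``n_edges`` random pairs; ``n_flip`` pairs drawn uniformly
    from all pairs have their membership flipped to create the patient group.
    All randomness is forked from ``seed`` via named substreams so the cohort
    is fully reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    spec_a = generate_precision_spec(P, n_edges, strength, seeds[0], group_label=0)
    pairs = list(itertools.combinations(range(P), 2))
    rng = np.random.default_rng(seeds[1])
    flip_idx = rng.choice(len(pairs), size=n_flip, replace=False)
    flips = {pairs[int(k)] for k in flip_idx}
    spec_b = perturb_for_group(spec_a, flips, strength, seeds[2], group_label=1)
    cfg = CohortConfig(
        M_per_group=M_per_group, n_t=n_t, subject_jitter=subject_jitter, seed=seeds[3]
    )
    return simulate_panel(spec_a, spec_b, cfg)
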