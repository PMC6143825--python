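"""Feature extraction, nested leave-one-out CV, and classification metrics.

Each subject's P x P connectivity matrix is flattened row-major into a
P^2-length feature vector (8,100 features at P = 90); a binary decision tree
is trained on these features.  Generalization is estimated by nested
leave-one-out cross-validation: the outer loop holds out one subject at a
time; for each outer fold an inner leave-one-out loop over the remaining
M - 1 subjects evaluates every candidate penalty ``lam`` end-to-end (network
construction plus tree) and hands the inner-accuracy maximizer to the outer
fold.  Accuracy, sensitivity, specificity, the ROC curve and its area are
computed from the accumulated outer predictions and decision scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .network import (
    assemble_connectivity,
    build_subnetworks,
    full_partial_network,
    graphical_lasso,
    sample_covariance,
    ConnectivityMatrix,
)
from .panel import TimeSeriesPanel
from .topology import TopologySelection, select_topology

__all__ = [
    "MODES",
    "FeatureMatrix",
    "FittedTree",
    "CVResult",
    "MetricsReport",
    "vectorize",
    "unvectorize",
    "train_classifier",
    "nested_loocv",
    "compute_metrics",
    "connection_frequency",
]

#: network construction variants: the sparse estimator and the
#: partial-correlation baseline, each with or without the group constraint
MODES = ("partial", "group-partial", "sice", "group-sice")
_LAMBDA_MODES = ("sice", "group-sice")
_TOPOLOGY_MODES = ("group-partial", "group-sice")


@dataclass
class FeatureMatrix:
    """Subjects x edges feature matrix with the edge bookkeeping.

    ``X[m, k]`` is entry ``(q, p)`` of subject m's connectivity matrix where
    ``edge_index[k] = (q, p)`` (row-major flattening, all P^2 entries kept,
    zeros included).
    """

    X: np.ndarray
    edge_index: np.ndarray
    labels: np.ndarray
    P: int
    subject_ids: list[str] = field(default_factory=list)


def vectorize(matrices, labels=None, subject_ids=None) -> FeatureMatrix:
    """Flatten connectivity matrices row-major into the feature matrix."""
    mats = [
        m.theta_full if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
        for m in matrices
    ]
    if not mats:
        raise ValueError("no connectivity matrices given")
    P = mats[0].shape[0]
    for m in mats:
        if m.shape != (P, P):
            raise ValueError(f"expected {P}x{P} matrices, got {m.shape}")
    X = np.vstack([m.reshape(1, -1) for m in mats])
    rows, cols = np.divmod(np.arange(P * P), P)
    edge_index = np.column_stack([rows, cols])
    labels = np.zeros(len(mats), int) if labels is None else np.asarray(labels, int)
    return FeatureMatrix(
        X=X,
        edge_index=edge_index,
        labels=labels,
        P=P,
        subject_ids=list(subject_ids) if subject_ids else [],
    )


def unvectorize(row: np.ndarray, P: int) -> np.ndarray:
    """Inverse of the row-major flattening."""
    row = np.asarray(row, dtype=float)
    if row.size != P * P:
        raise ValueError(f"expected {P * P} features, got {row.size}")
    return row.reshape(P, P)


@dataclass
class FittedTree:
    """A fitted binary decision tree plus the feature columns it splits on."""

    model: DecisionTreeClassifier
    used_features: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def score_positive(self, X: np.ndarray) -> np.ndarray:
        """Positive-class proportion at the reached leaf."""
        proba = self.model.predict_proba(X)
        pos_col = int(np.where(self.model.classes_ == 1)[0][0])
        return proba[:, pos_col]


def train_classifier(X_train, y_train, seed: int = 0) -> FittedTree:
    """Fit a Gini decision tree (no depth limit, min leaf 1, fixed seed)."""
    y_train = np.asarray(y_train, int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    model = DecisionTreeClassifier(criterion="gini", random_state=seed)
    model.fit(np.asarray(X_train, float), y_train)
    feats = model.tree_.feature
    used = np.unique(feats[feats >= 0])
    return FittedTree(model=model, used_features=used)


def _predict_one(X_train, y_train, x_test, seed) -> tuple[int, float]:
    """Fit on a training block and score one held-out subject.

    An inner training block can be single-class (e.g. M = 3 cohorts); it then
    predicts that class with a degenerate score, rather than erroring.
    """
    classes = np.unique(y_train)
    if len(classes) < 2:
        c = int(classes[0])
        return c, float(c)
    tree = train_classifier(X_train, y_train, seed)
    x = np.asarray(x_test, float).reshape(1, -1)
    return int(tree.predict(x)[0]), float(tree.score_positive(x)[0])


def _build_features(
    panel: TimeSeriesPanel,
    mode: str,
    selection: TopologySelection | None,
    lam: float | None,
    sice_tol: float,
    sice_max_iter: int,
    trace_collector: list | None = None,
) -> np.ndarray:
    """(M, P^2) feature matrix for one network variant at one penalty."""
    P = panel.P
    mats: list[np.ndarray] = []
    if mode == "partial":
        mats = [full_partial_network(panel, None, m).theta_full for m in range(panel.M)]
    elif mode == "group-partial":
        mats = [full_partial_network(panel, selection, m).theta_full for m in range(panel.M)]
    elif mode == "sice":
        for m in range(panel.M):
            est = graphical_lasso(
                sample_covariance(panel.subjects[m]),
                lam,
                tol=sice_tol,
                max_iter=sice_max_iter,
            )
            if trace_collector is not None:
                trace_collector.append((est.n_iter, est.delta_theta_trace))
            mats.append(est.theta)
    elif mode == "group-sice":
        per_subject = [[None] * P for _ in range(panel.M)]
        for p in range(P):
            subnets = build_subnetworks(
                panel,
                selection,
                p,
                lam,
                tol=sice_tol,
                max_iter=sice_max_iter,
                trace_collector=trace_collector,
            )
            for m, sw in enumerate(subnets):
                per_subject[m][p] = sw
        mats = [
            assemble_connectivity(per_subject[m], P).theta_full
            for m in range(panel.M)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    return np.vstack([m.reshape(1, -1) for m in mats])


@dataclass
class CVResult:
    """Nested leave-one-out cross-validation output.

    One outer prediction and decision score per subject; ``chosen_lambda``
    and ``selected_connections`` (feature columns split on by the outer
    fold's tree) are recorded per fold; ``confusion`` holds TP/FN/TN/FP with
    the patient group (label 1) positive.
    """

    subject_ids: list[str]
    labels: np.ndarray
    outer_predictions: np.ndarray
    outer_scores: np.ndarray
    chosen_lambda: list
    selected_connections: list
    inner_fold_counts: list
    edge_index: np.ndarray
    confusion: dict
    seed: int
    mode: str
    P: int

    @property
    def M(self) -> int:
        return len(self.labels)


def _inner_select_lambda(
    features_by_lam: dict,
    labels: np.ndarray,
    train_idx: np.ndarray,
    lambda_pool,
    seed: int,
) -> tuple[float | None, int]:
    """Inner leave-one-out sweep over the penalty pool.

    Only rows in ``train_idx`` are ever touched; returns the accuracy-
    maximizing penalty (ties: smallest) and the number of inner folds run
    per candidate.
    """
    best_lam, best_acc = None, -1.0
    n_inner = len(train_idx)
    for lam in lambda_pool:
        F = features_by_lam[lam]
        correct = 0
        for j in train_idx:
            block = np.array([i for i in train_idx if i != j])
            pred, _ = _predict_one(F[block], labels[block], F[j], seed)
            correct += int(pred == labels[j])
        acc = correct / n_inner
        if acc > best_acc:  # strict: first (smallest) lambda wins ties
            best_acc, best_lam = acc, lam
    return best_lam, n_inner


def nested_loocv(
    panel: TimeSeriesPanel,
    mode: str = "group-sice",
    lambda_pool=None,
    selection: TopologySelection | None = None,
    topology_scope: str = "all_subjects",
    phi_grid=None,
    classifier_seed: int = 0,
    sice_tol: float = 1e-6,
    sice_max_iter: int = 200,
    topology_tol: float = 1e-6,
    topology_max_iter: int = 100,
    trace_collector: list | None = None,
) -> CVResult:
    """Nested leave-one-out cross-validation of one network variant.

    ``topology_scope='all_subjects'`` detects the shared topology once on the
    full cohort before cross-validation (the sequencing described for the
    original framework; note this leaks test information into the selected
    structure).  ``'train_only'`` refits the topology inside each outer fold
    for a leakage-free estimate.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if topology_scope not in ("all_subjects", "train_only"):
        raise ValueError("topology_scope must be 'all_subjects' or 'train_only'")
    M = panel.M
    if M < 3:
        raise ValueError("nested LOOCV needs at least 3 subjects")
    labels = panel.labels
    if mode in _LAMBDA_MODES:
        pool = (
            list(np.round(np.arange(1, 20) * 0.05, 10))
            if lambda_pool is None
            else sorted(float(v) for v in lambda_pool)
        )
        if not pool:
            raise ValueError("lambda_pool must be nonempty")
    else:
        pool = [None]

    needs_topology = mode in _TOPOLOGY_MODES
    refit = needs_topology and topology_scope == "train_only"
    if needs_topology and not refit and selection is None:
        selection = select_topology(
            panel, phi_grid=phi_grid, tol=topology_tol, max_iter=topology_max_iter
        )

    # features cache: key (fold or 'all', lam) -> (M, P^2) matrix
    cache: dict = {}

    def features(lam, fold_key, fold_selection):
        key = (fold_key, lam)
        if key not in cache:
            try:
                cache[key] = _build_features(
                    panel,
                    mode,
                    fold_selection,
                    lam,
                    sice_tol,
                    sice_max_iter,
                    trace_collector,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"network construction failed (fold {fold_key}, lam {lam}): {exc}"
                ) from exc
        return cache[key]

    predictions = np.zeros(M, int)
    scores = np.zeros(M)
    chosen: list = []
    selected: list = []
    inner_counts: list = []
    for i in range(M):
        train_idx = np.array([t for t in range(M) if t != i])
        if refit:
            fold_key = i
            fold_sel = select_topology(
                panel.subset(train_idx),
                phi_grid=phi_grid,
                tol=topology_tol,
                max_iter=topology_max_iter,
            )
        else:
            fold_key = "all"
            fold_sel = selection
        if len(pool) > 1:
            feats_by_lam = {
                lam: features(lam, fold_key, fold_sel) for lam in pool
            }
            lam_star, n_inner = _inner_select_lambda(
                feats_by_lam, labels, train_idx, pool, classifier_seed
            )
        else:
            lam_star, n_inner = pool[0], 0
        chosen.append(lam_star)
        inner_counts.append(n_inner)
        F = features(lam_star, fold_key, fold_sel)
        if len(np.unique(labels[train_idx])) < 2:
            # degenerate outer training block (tiny cohorts): constant class
            predictions[i], scores[i] = _predict_one(
                F[train_idx], labels[train_idx], F[i], classifier_seed
            )
            selected.append(np.zeros(0, dtype=int))
        else:
            tree = train_classifier(F[train_idx], labels[train_idx], classifier_seed)
            x = F[i].reshape(1, -1)
            predictions[i] = int(tree.predict(x)[0])
            scores[i] = float(tree.score_positive(x)[0])
            selected.append(tree.used_features.copy())

    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    rows, cols = np.divmod(np.arange(panel.P * panel.P), panel.P)
    return CVResult(
        subject_ids=list(panel.subject_ids),
        labels=labels.copy(),
        outer_predictions=predictions,
        outer_scores=scores,
        chosen_lambda=chosen,
        selected_connections=selected,
        inner_fold_counts=inner_counts,
        edge_index=np.column_stack([rows, cols]),
        confusion={"TP": tp, "FN": fn, "TN": tn, "FP": fp},
        seed=classifier_seed,
        mode=mode,
        P=panel.P,
    )


@dataclass
class MetricsReport:
    """ACC/SEN/SPE as percentages, AUC in [0, 1], and the ROC staircase.

    Metrics whose denominator is zero (no positives or no negatives) are NaN
    and named in ``flags`` rather than raising.
    """

    acc: float
    sen: float
    spe: float
    auc: float
    roc_points: np.ndarray
    confusion: dict
    flags: list

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "auc": self.auc,
            "confusion": dict(self.confusion),
            "flags": list(self.flags),
        }


def _roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC staircase from a descending threshold sweep; ties grouped."""
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    k = 0
    s, y = scores[order], labels[order]
    while k < len(s):
        thr = s[k]
        while k < len(s) and s[k] == thr:
            if y[k] == 1:
                tp += 1
            else:
                fp += 1
            k += 1
        points.append(
            (fp / n_neg if n_neg else 0.0, tp / n_pos if n_pos else 0.0)
        )
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return np.asarray(points)


def compute_metrics(cv: CVResult) -> MetricsReport:
    """ACC/SEN/SPE from confusion counts; ROC/AUC from the decision scores."""
    c = cv.confusion
    tp, fn, tn, fp = c["TP"], c["FN"], c["TN"], c["FP"]
    M = tp + fn + tn + fp
    if M != cv.M:
        raise ValueError("confusion counts inconsistent with the subject count")
    flags = []
    acc = 100.0 * (tp + tn) / M
    if tp + fn > 0:
        sen = 100.0 * tp / (tp + fn)
    else:
        sen, flags = np.nan, flags + ["sen undefined: no positive subjects"]
    if tn + fp > 0:
        spe = 100.0 * tn / (tn + fp)
    else:
        spe, flags = np.nan, flags + ["spe undefined: no negative subjects"]
    if (tp + fn > 0) and (tn + fp > 0):
        roc = _roc_curve(cv.outer_scores, cv.labels)
        auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    else:
        roc = np.asarray([(0.0, 0.0), (1.0, 1.0)])
        auc = np.nan
        flags.append("auc undefined: single-class cohort")
    return MetricsReport(
        acc=float(acc),
        sen=float(sen),
        spe=float(spe),
        auc=auc,
        roc_points=roc,
        confusion=dict(c),
        flags=flags,
    )


def connection_frequency(cv: CVResult, roi_names=None) -> pd.DataFrame:
    """How often each connection is split on across the outer folds.

    Counts, per ordered ROI pair (row region, target region), the number of
    outer folds whose trained tree splits on that feature column; sorted by
    count descending, ties broken by feature column index.  Human-facing ROI
    indices are 1-based.
    """
    counts: dict[int, int] = {}
    for cols in cv.selected_connections:
        for k in cols:
            counts[int(k)] = counts.get(int(k), 0) + 1
    if not counts:
        return pd.DataFrame(
            columns=["feature", "roi_row", "roi_col", "name_row", "name_col", "count"]
        )
    names = roi_names or [f"ROI{i + 1:03d}" for i in range(cv.P)]
    rows = []
    for k, n in counts.items():
        q, p = cv.edge_index[k]
        rows.append(
            {
                "feature": k,
                "roi_row": int(q) + 1,
                "roi_col": int(p) + 1,
                "name_row": names[int(q)],
                "name_col": names[int(p)],
                "count": n,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["count", "feature"], ascending=[False, True], kind="stable"
    )
    return df.reset_index(drop=True)
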