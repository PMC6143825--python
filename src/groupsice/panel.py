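"""Multi-subject ROI time-series container and delimited-text I/O.

A cohort is a set of M subjects, each contributing an (n_t x P) matrix of
regional mean time series (n_t time points, P atlas regions), plus a binary
group label per subject (1 = patient, 0 = control).  All downstream stages
(topology detection, sparse network construction, classification) consume
this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesPanel", "write_panel", "read_panel"]

_LABELS_FILE = "labels.tsv"
_GROUND_TRUTH_FILE = "ground_truth.json"


@dataclass
class TimeSeriesPanel:
    """M subjects' (n_t x P) time-series matrices plus binary labels.

    Parameters
    ----------
    subjects
        One float array of shape ``(n_t, P)`` per subject; column ``p`` is the
        mean time series of region ``p``.
    labels
        Binary vector of length ``M`` (1 = patient group, 0 = control group).
    subject_ids
        Unique string identifier per subject.
    roi_names
        ``P`` region names, carried through to all human-facing outputs.
    extras
        Optional provenance, e.g. the ground-truth record attached by the
        synthetic generator.  Never required by any computation.
    """

    subjects: list[np.ndarray]
    labels: np.ndarray
    subject_ids: list[str]
    roi_names: list[str]
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subjects = [np.asarray(x, dtype=float) for x in self.subjects]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.subjects) != len(self.labels) or len(self.subjects) != len(
            self.subject_ids
        ):
            raise ValueError("subjects, labels and subject_ids must have equal length")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
        if self.subjects:
            shape = self.subjects[0].shape
            for sid, x in zip(self.subject_ids, self.subjects):
                if x.ndim != 2 or x.shape != shape:
                    raise ValueError(
                        f"subject {sid!r}: expected shape {shape}, got {x.shape}"
                    )
                if not np.isfinite(x).all():
                    raise ValueError(f"subject {sid!r}: non-finite entries")
            if shape[1] != len(self.roi_names):
                raise ValueError("roi_names length must equal the region count")

    @property
    def M(self) -> int:
        return len(self.subjects)

    @property
    def n_t(self) -> int:
        return self.subjects[0].shape[0] if self.subjects else 0

    @property
    def P(self) -> int:
        return self.subjects[0].shape[1] if self.subjects else len(self.roi_names)

    def subset(self, indices) -> "TimeSeriesPanel":
        """Panel restricted to the given subject indices (used by CV folds)."""
        idx = list(indices)
        return TimeSeriesPanel(
            subjects=[self.subjects[i] for i in idx],
            labels=self.labels[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            roi_names=list(self.roi_names),
            extras=dict(self.extras),
        )


def write_panel(panel: TimeSeriesPanel, directory) -> list[Path]:
    """Write one tab-separated time-series file per subject plus a labels table.

    Each subject file ``<subject_id>.tsv`` has a header row of ROI names and
    ``n_t`` data rows; floats are printed with %.17g so the round trip through
    :func:`read_panel` is bit exact.  If ``panel.extras`` carries a JSON-able
    ``"ground_truth"`` record it is written alongside as ``ground_truth.json``.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for sid, x in zip(panel.subject_ids, panel.subjects):
            path = directory / f"{sid}.tsv"
            df = pd.DataFrame(x, columns=panel.roi_names)
            df.to_csv(path, sep="\t", index=False, float_format="%.17g")
            written.append(path)
        labels_path = directory / _LABELS_FILE
        pd.DataFrame(
            {"subject_id": panel.subject_ids, "label": panel.labels}
        ).to_csv(labels_path, sep="\t", index=False)
        written.append(labels_path)
        gt = panel.extras.get("ground_truth")
        if gt is not None:
            import json

            gt_path = directory / _GROUND_TRUTH_FILE
            gt_path.write_text(json.dumps(gt, indent=2, sort_keys=True) + "\n")
            written.append(gt_path)
        return written
    except OSError as exc:
        raise OSError(f"failed writing panel under {directory}: {exc}") from exc


def read_panel(directory) -> TimeSeriesPanel:
    """Read a panel previously written by :func:`write_panel`."""
    directory = Path(directory)
    labels_path = directory / _LABELS_FILE
    if not labels_path.exists():
        raise FileNotFoundError(f"no labels table at {labels_path}")
    table = pd.read_csv(labels_path, sep="\t")
    subjects: list[np.ndarray] = []
    roi_names: list[str] = []
    for sid in table["subject_id"].astype(str):
        path = directory / f"{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing time-series file {path}")
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        roi_names = list(df.columns)
        subjects.append(df.to_numpy(dtype=float))
    extras: dict = {}
    gt_path = directory / _GROUND_TRUTH_FILE
    if gt_path.exists():
        import json

        extras["ground_truth"] = json.loads(gt_path.read_text())
    return TimeSeriesPanel(
        subjects=subjects,
        labels=table["label"].to_numpy(dtype=int) if len(table) else np.zeros(0, int),
        subject_ids=list(table["subject_id"].astype(str)),
        roi_names=roi_names,
        extras=extras,
    )
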