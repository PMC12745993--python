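"""Hypnogram scoring and optimal cluster-to-stage alignment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from aisleep.signal_io import UNKNOWN, Hypnogram

N_STAGES = 5


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (5, 5), rows = reference stage, columns = predicted
    n_excluded: int = 0  # Unknown-coded reference epochs dropped before tallying

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Row-normalized view: entry [i, j] is the proportion of reference
        stage i predicted as stage j (zero rows stay zero)."""
        row = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / row
        return np.where(row > 0, out, 0.0)


@dataclass
class StagingScores:
    accuracy: float
    macro_f1: float
    kappa: float
    per_class_f1: np.ndarray  # (5,)


def confusion(ref: Hypnogram, pred: Hypnogram) -> ConfusionMatrix:
    """Tally a 5x5 confusion matrix, excluding Unknown-coded reference epochs."""
    r = ref.stages
    p = pred.stages
    if r.shape != p.shape:
        raise ValueError(f"length mismatch: ref {r.size} vs pred {p.size}")
    keep = r != UNKNOWN
    n_excluded = int((~keep).sum())
    r, p = r[keep], p[keep]
    if np.any((p < 0) | (p > 4)):
        raise ValueError("predicted codes must lie in {0..4}")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (r, p), 1)
    return ConfusionMatrix(counts, n_excluded)


def score(cm: ConfusionMatrix, mf1_present_only: bool = True) -> StagingScores:
    """Accuracy, per-class F1, macro F1 and Cohen's kappa from a confusion matrix.

    Per-class precision/recall use the 0/0 -> 0 convention. By default MF1
    averages over classes present in the reference; set
    ``mf1_present_only=False`` to include absent classes as zero.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    present = counts.sum(axis=1) > 0
    if mf1_present_only:
        macro_f1 = float(f1[present].mean()) if present.any() else 0.0
    else:
        macro_f1 = float(f1.mean())
    accuracy = float(tp.sum() / total)
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / total**2)
    kappa = 1.0 if p_e == 1.0 else (accuracy - p_e) / (1.0 - p_e)
    return StagingScores(accuracy, macro_f1, float(kappa), f1)


def align_clusters(ref: Hypnogram, clusters: np.ndarray) -> Hypnogram:
    """Relabel arbitrary cluster ids with the one-to-one cluster-to-stage
    mapping that maximizes agreement with the reference (linear assignment on
    the contingency table)."""
    r = np.asarray(ref.stages)
    c = np.asarray(clusters)
    if r.shape != c.shape:
        raise ValueError("length mismatch between reference and cluster labels")
    labels = np.unique(c)
    if labels.size > N_STAGES:
        raise ValueError(f"more than {N_STAGES} distinct cluster labels: {labels.size}")
    contingency = np.zeros((labels.size, N_STAGES), dtype=np.int64)
    for i, lab in enumerate(labels):
        mask = c == lab
        for s in range(N_STAGES):
            contingency[i, s] = int(np.sum(r[mask] == s))
    rows, cols = linear_sum_assignment(contingency, maximize=True)
    mapping = dict(zip(labels[rows].tolist(), cols.tolist()))
    relabeled = np.array([mapping[x] for x in c], dtype=np.int64)
    return Hypnogram(relabeled)
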