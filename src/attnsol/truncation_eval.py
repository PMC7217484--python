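"""Sequence-ablation experiments and the classification-metric suite.

Two ablations probe where the predictive signal lives: removing the
first and last fraction of every sequence (termini truncation) and
removing the central span between two relative-position percentiles
(central truncation).  If the signal sits in the termini, the first
ablation should push the AUC towards chance while the second should
barely move it.

Metrics: sensitivity, specificity, precision, accuracy, balanced
accuracy (the arithmetic mean of Sen and Spe), Matthews correlation
coefficient, ROC AUC and area under the precision-recall curve.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import ModelParams, predict
from .sequence_io import ProteinRecord

__all__ = [
    "MetricsReport",
    "truncate_termini",
    "truncate_central",
    "compute_metrics",
    "ablation_experiment",
]


@dataclass
class MetricsReport:
    """Threshold metrics plus ranking metrics for one scored set.

    All rates are stored as fractions in [0, 1] (MCC in [-1, 1]);
    multiply by 100 for the percentage convention used in reports.
    """

    sen: float
    spe: float
    pre: float
    acc: float
    bac: float
    mcc: float
    auc: float
    auprc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return asdict(self)


def truncate_termini(sequence: str, fraction: float = 0.2) -> str:
    """Remove the first and last ``floor(fraction * L)`` residues."""
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    L = len(sequence)
    k = int(np.floor(fraction * L))
    out = sequence[k : L - k]
    if not out:
        raise ValueError(f"sequence of length {L} does not survive fraction {fraction}")
    return out


def truncate_central(sequence: str, lo: float = 0.2, hi: float = 0.8) -> str:
    """Remove residues at relative positions in (lo, hi].

    A 1-based position i is removed when lo*L < i <= hi*L; the two
    flanks are concatenated in order.
    """
    if not (0.0 <= lo < hi <= 1.0) and not (lo == hi):
        raise ValueError("need 0 <= lo < hi <= 1")
    L = len(sequence)
    if lo == hi:
        return sequence
    keep = [i for i in range(1, L + 1) if not (lo * L < i <= hi * L)]
    out = "".join(sequence[i - 1] for i in keep)
    if not out:
        raise ValueError("central truncation removed the whole sequence")
    return out


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Full metric suite; AUC/AUPRC by rank statistics with tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class; AUC/MCC undefined")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    pre = tp / (tp + fp) if (tp + fp) else 0.0
    acc = (tp + tn) / labels.size
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return MetricsReport(
        sen=sen,
        spe=spe,
        pre=pre,
        acc=acc,
        bac=(sen + spe) / 2.0,
        mcc=float(mcc),
        auc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        threshold=threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def ablation_experiment(
    params: ModelParams,
    records: list[ProteinRecord],
    mode: str = "termini",
    fraction: float = 0.2,
    central_lo: float = 0.2,
    central_hi: float = 0.8,
    threshold: float = 0.5,
) -> tuple[MetricsReport, MetricsReport]:
    """Score full vs ablated sequences; returns (full, ablated) metric reports.

    ``mode`` is "termini" (drop both terminal fractions) or "central"
    (drop the span between the two relative percentiles).
    """
    if mode not in ("termini", "central"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.array([r.label for r in records])
    if any(r.label is None for r in records):
        raise ValueError("all records must be labelled")

    def ablate(seq: str) -> str:
        if mode == "termini":
            return truncate_termini(seq, fraction)
        return truncate_central(seq, central_lo, central_hi)

    ablated = [ProteinRecord(r.id, ablate(r.sequence), r.label) for r in records]
    full_scores = np.array([o.score for o in predict(params, records)])
    abl_scores = np.array([o.score for o in predict(params, ablated)])
    for name, s in (("full", full_scores), ("ablated", abl_scores)):
        if np.ptp(s) == 0:
            raise ValueError(f"{name} scores are constant; ranking metrics degenerate")
    return (
        compute_metrics(full_scores, labels, threshold),
        compute_metrics(abl_scores, labels, threshold),
    )
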