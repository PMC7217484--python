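"""Per-residue interpretability: attention/prediction/solubility profiles.

The solubility profile of a protein is the elementwise product
a_i * p_i of the attention and prediction vectors; sigmoid of its sum
is exactly the sequence score, so each entry is the residue's signed
vote for the soluble class.  This module aggregates profiles by
relative position, correlates them against residue propensity scales,
and evaluates them against per-residue binary annotations (e.g.
amyloid-aggregation regions) with a ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .model import ModelParams, predict
from .sequence_io import ProteinRecord

__all__ = [
    "ResidueProfile",
    "PositionalSummary",
    "extract_profiles",
    "positional_summary",
    "profile_annotation_auc",
    "profile_scale_correlation",
    "PROPENSITY_SCALES",
]

# Residue propensity scales (per-residue physicochemical scores).
# kd: Kyte & Doolittle hydropathy; hw: Hopp-Woods hydrophilicity;
# charge: net side-chain charge at pH 7; volume: side-chain volume (A^3, Zamyatnin).
PROPENSITY_SCALES: dict[str, dict[str, float]] = {
    "hydrophobicity_kd": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
        "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
        "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
    "hydrophilicity_hw": {
        "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
        "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
        "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
    },
    "charge": {
        "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0, "E": -1.0,
        "G": 0.0, "H": 0.1, "I": 0.0, "L": 0.0, "K": 1.0, "M": 0.0, "F": 0.0,
        "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0, "Y": 0.0, "V": 0.0,
    },
    "volume": {
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
        "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
        "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
        "Y": 193.6, "V": 140.0,
    },
}


@dataclass
class ResidueProfile:
    """Attention, prediction and solubility-profile vectors for one sequence."""

    id: str
    sequence: str
    attention: np.ndarray
    prediction: np.ndarray

    @property
    def solubility_profile(self) -> np.ndarray:
        return self.attention * self.prediction

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PositionalSummary:
    """Per-bin statistics of attention and prediction over relative position."""

    bin_edges: np.ndarray  # (n_bins + 1,) over [0, 1]
    attention_mean: np.ndarray
    attention_median: np.ndarray
    prediction_mean: np.ndarray
    prediction_median: np.ndarray
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.counts.size


def extract_profiles(
    params: ModelParams, records: list[ProteinRecord], batch_size: int = 256
) -> list[ResidueProfile]:
    """Run the model and return one :class:`ResidueProfile` per record."""
    if not records:
        raise ValueError("no records")
    outputs = predict(params, records, batch_size=batch_size)
    return [
        ResidueProfile(id=r.id, sequence=r.sequence, attention=o.attention, prediction=o.prediction)
        for r, o in zip(records, outputs)
    ]


def positional_summary(profiles: list[ResidueProfile], n_bins: int = 100) -> PositionalSummary:
    """Aggregate attention and prediction by relative sequence position.

    Residue i (1-based) of a length-L sequence lands in bin
    floor(n_bins * (i-1) / L); bins partition [0, 1).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not profiles:
        raise ValueError("no profiles")
    bins: list[list[list[float]]] = [[[], []] for _ in range(n_bins)]
    for prof in profiles:
        L = len(prof)
        idx = (n_bins * np.arange(L)) // L
        for b, a, p in zip(idx, prof.attention, prof.prediction):
            bins[b][0].append(a)
            bins[b][1].append(p)
    att_mean = np.array([np.mean(b[0]) if b[0] else np.nan for b in bins])
    att_med = np.array([np.median(b[0]) if b[0] else np.nan for b in bins])
    pred_mean = np.array([np.mean(b[1]) if b[1] else np.nan for b in bins])
    pred_med = np.array([np.median(b[1]) if b[1] else np.nan for b in bins])
    counts = np.array([len(b[0]) for b in bins])
    return PositionalSummary(
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        attention_mean=att_mean,
        attention_median=att_med,
        prediction_mean=pred_mean,
        prediction_median=pred_med,
        counts=counts,
    )


def profile_annotation_auc(
    profiles: list[ResidueProfile],
    annotations: dict[str, dict[int, int]],
    lower_means_positive: bool = True,
) -> float:
    """ROC AUC of solubility-profile values against per-residue binary labels.

    ``annotations`` maps sequence id -> {1-based position: label}.  By
    default a *lower* profile value counts as evidence for the positive
    (aggregation-prone) class; pass ``lower_means_positive=False`` to
    score the profile directly.
    """
    scores, labels = [], []
    for prof in profiles:
        ann = annotations.get(prof.id)
        if not ann:
            continue
        sp = prof.solubility_profile
        for pos, lab in ann.items():
            if not 1 <= pos <= len(prof):
                raise ValueError(f"{prof.id}: annotated position {pos} outside sequence")
            scores.append(sp[pos - 1])
            labels.append(lab)
    if not scores:
        raise ValueError("no annotated residues matched the profiles")
    labels_arr = np.asarray(labels)
    if labels_arr.min() == labels_arr.max():
        raise ValueError("annotations contain a single class; AUC undefined")
    vals = np.asarray(scores)
    return float(roc_auc_score(labels_arr, -vals if lower_means_positive else vals))


def profile_scale_correlation(
    profiles: list[ResidueProfile],
    scale: dict[str, float],
    which: str = "profile",
) -> tuple[float, float]:
    """Pearson correlation of per-residue values against a propensity scale.

    ``which`` selects the vector: "profile" (a_i * p_i), "attention" or
    "prediction".  Residues absent from the scale (the unknown token)
    are skipped.  Returns (r, two-sided p-value).
    """
    if len(scale) < 20:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(scale)
        raise ValueError(f"scale incomplete; missing {sorted(missing)}")
    xs, ys = [], []
    for prof in profiles:
        vec = {
            "profile": prof.solubility_profile,
            "attention": prof.attention,
            "prediction": prof.prediction,
        }[which]
        for aa, v in zip(prof.sequence, vec):
            if aa in scale:
                xs.append(v)
                ys.append(scale[aa])
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.size < 3:
        raise ValueError("need at least 3 residues")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
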