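"""Overlap metrics (DSC, IoU), report aggregation, and the stratified
patient-level k-fold harness.

For a predicted region R and ground truth G (one structure, one volume):

    DSC(R, G) = 2 TP / (2 TP + FP + FN)
    IoU(R, G) =   TP / (TP + FP + FN)

with the identity DSC = 2 IoU / (1 + IoU). When both R and G are empty the
score is 1 by convention; when exactly one is empty it is 0. Per-structure
scores are pooled over the voxels of a volume, then macro-averaged across
volumes (micro-averaging pools counts across volumes instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io_acdc import LabelMap

STRUCTURES = {"RV": 1, "Myo": 2, "LV": 3}
PHASES = ("ED", "ES")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest voxel counts for a single structure."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, LabelMap) else np.asarray(x)


def confusion_counts(pred, gt, cls: int) -> ConfusionCounts:
    """Binarize both maps at class ``cls`` and count voxels."""
    p, g = _as_array(pred), _as_array(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs ground truth {g.shape}")
    pb, gb = p == cls, g == cls
    tp = int(np.count_nonzero(pb & gb))
    fp = int(np.count_nonzero(pb & ~gb))
    fn = int(np.count_nonzero(~pb & gb))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(counts: ConfusionCounts) -> float:
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        return 1.0  # both regions empty
    return 2 * counts.TP / denom


def iou(counts: ConfusionCounts) -> float:
    denom = counts.TP + counts.FP + counts.FN
    if denom == 0:
        return 1.0  # both regions empty
    return counts.TP / denom


@dataclass
class MetricsReport:
    """Per-structure, per-phase DSC/IoU with phase-level means and the
    per-volume table the aggregates derive from."""

    dsc: dict[tuple[str, str], float]       # (structure, phase) -> score
    iou: dict[tuple[str, str], float]
    mean_dsc: dict[str, float]              # phase -> mean over structures
    miou: dict[str, float]
    per_volume: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [{"structure": s, "phase": ph, "DSC": self.dsc[(s, ph)],
                 "IoU": self.iou[(s, ph)]}
                for ph in sorted({k[1] for k in self.dsc})
                for s in STRUCTURES]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "dsc": {f"{s}_{ph}": v for (s, ph), v in self.dsc.items()},
            "iou": {f"{s}_{ph}": v for (s, ph), v in self.iou.items()},
            "mean_dsc": dict(self.mean_dsc),
            "miou": dict(self.miou),
        }


def evaluate(preds, gts, micro: bool = False) -> MetricsReport:
    """Score paired predictions against ground truth.

    ``preds`` and ``gts`` are sequences of ``(patient_id, phase, labels)``
    triples; pairing is by (patient_id, phase) and must be one-to-one.
    """
    pred_map = {(pid, ph): _as_array(lab) for pid, ph, lab in preds}
    gt_map = {(pid, ph): _as_array(lab) for pid, ph, lab in gts}
    if len(pred_map) != len(preds) or len(gt_map) != len(gts):
        raise ValueError("duplicate (patient_id, phase) keys")
    if pred_map.keys() != gt_map.keys():
        missing = sorted(pred_map.keys() ^ gt_map.keys())
        raise ValueError(f"unpaired prediction/ground-truth keys: {missing}")
    rows = []
    for (pid, ph), p in sorted(pred_map.items()):
        g = gt_map[(pid, ph)]
        for sname, cls in STRUCTURES.items():
            c = confusion_counts(p, g, cls)
            rows.append({"patient_id": pid, "phase": ph, "structure": sname,
                         "TP": c.TP, "FP": c.FP, "FN": c.FN,
                         "DSC": dsc(c), "IoU": iou(c)})
    table = pd.DataFrame(rows)
    d_scores: dict[tuple[str, str], float] = {}
    i_scores: dict[tuple[str, str], float] = {}
    phases = sorted(table["phase"].unique())
    for ph in phases:
        for sname in STRUCTURES:
            sub = table[(table.phase == ph) & (table.structure == sname)]
            if micro:
                pooled = ConfusionCounts(int(sub.TP.sum()), int(sub.FP.sum()),
                                         int(sub.FN.sum()), 0)
                d_scores[(sname, ph)] = dsc(pooled)
                i_scores[(sname, ph)] = iou(pooled)
            else:
                d_scores[(sname, ph)] = float(sub.DSC.mean())
                i_scores[(sname, ph)] = float(sub.IoU.mean())
    mean_dsc = {ph: float(np.mean([d_scores[(s, ph)] for s in STRUCTURES])) for ph in phases}
    miou = {ph: float(np.mean([i_scores[(s, ph)] for s in STRUCTURES])) for ph in phases}
    return MetricsReport(d_scores, i_scores, mean_dsc, miou, table)


def aggregate_folds(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean +/- SD of per-structure, per-phase scores across folds."""
    rows = []
    for k, rep in enumerate(reports):
        for (s, ph), v in rep.dsc.items():
            rows.append({"fold": k, "structure": s, "phase": ph,
                         "DSC": v, "IoU": rep.iou[(s, ph)]})
    df = pd.DataFrame(rows)
    return df.groupby(["structure", "phase"])[["DSC", "IoU"]].agg(["mean", "std"])


def stratified_kfold(roster, k: int, seed: int = 0) -> list[list[str]]:
    """Partition a (patient_id, pathology) roster into ``k`` folds with
    per-class counts differing by at most one across folds. Patient-level:
    both cardiac phases of a patient travel together.
    """
    roster = list(roster)
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = np.array([pid for pid, _ in roster])
    classes = np.array([str(c) for _, c in roster])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in roster")
    _, counts = np.unique(classes, return_counts=True)
    if counts.min() < k:
        small = np.unique(classes)[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [sorted(ids[test]) for _, test in skf.split(ids, classes)]
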