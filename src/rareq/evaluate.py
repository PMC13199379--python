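"""Scoring predicted partitions against ground-truth cell types.

Each predicted cluster is first annotated with the majority ground-truth
type of its members; for a given rare type, the union of clusters
annotated to it forms the positive prediction set, from which TP/FP/FN,
precision, recall, F1 and the Jaccard index follow.  Global agreement is
summarized by normalized mutual information (arithmetic-mean
normalization).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import mutual_info_score
from scipy.stats import entropy

__all__ = ["LabeledPartition", "EvaluationReport", "annotate_clusters",
           "rare_prf", "jaccard_index", "nmi", "evaluate_partition"]


@dataclass(frozen=True)
class LabeledPartition:
    """A predicted clustering and the true typing of the same cells.

    ``rare_types``: the types evaluated as rare; by default every type
    whose frequency is below ``rare_frac`` (1%).
    """

    predicted: np.ndarray
    truth: np.ndarray
    rare_types: tuple = ()
    rare_frac: float = 0.01

    def __post_init__(self) -> None:
        pred = np.asarray(self.predicted)
        truth = np.asarray(self.truth)
        if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
            raise ValueError("inconsistent inputs: label vectors must match")
        object.__setattr__(self, "predicted", pred)
        object.__setattr__(self, "truth", truth)
        if not self.rare_types:
            types, counts = np.unique(truth, return_counts=True)
            rare = tuple(t for t, c in zip(types, counts)
                         if c / truth.size < self.rare_frac)
            object.__setattr__(self, "rare_types", rare)
        else:
            object.__setattr__(self, "rare_types", tuple(self.rare_types))


@dataclass(frozen=True)
class EvaluationReport:
    per_type: dict
    nmi: float
    annotation: dict = field(default_factory=dict)


def annotate_clusters(part: LabeledPartition) -> dict:
    """Map each predicted cluster to the modal true type of its members;
    modal ties go to the alphabetically (or numerically) first type."""
    mapping = {}
    for cid in np.unique(part.predicted):
        members = part.truth[part.predicted == cid]
        counts = Counter(members.tolist())
        top = max(counts.values())
        mapping[cid if not isinstance(cid, np.generic) else cid.item()] = \
            sorted(t for t, c in counts.items() if c == top)[0]
    return mapping


def _positive_set(part: LabeledPartition, rare_type) -> np.ndarray:
    mapping = annotate_clusters(part)
    positive = np.zeros(part.predicted.size, dtype=bool)
    for cid, t in mapping.items():
        if t == rare_type:
            positive |= part.predicted == cid
    return positive


def rare_prf(part: LabeledPartition, rare_type) -> tuple[float, float, float]:
    """Precision, recall and F1 for one rare type.

    With no cluster annotated to the type, all three are 0 by convention.
    """
    truth_set = part.truth == rare_type
    if not truth_set.any():
        raise ValueError("type not in truth")
    positive = _positive_set(part, rare_type)
    tp = int(np.count_nonzero(positive & truth_set))
    fp = int(np.count_nonzero(positive & ~truth_set))
    fn = int(np.count_nonzero(~positive & truth_set))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def jaccard_index(part: LabeledPartition, rare_type) -> float:
    """|S n T| / |S u T| between the positive prediction set S and the
    true rare-type set T."""
    truth_set = part.truth == rare_type
    if not truth_set.any():
        raise ValueError("type not in truth")
    positive = _positive_set(part, rare_type)
    union = int(np.count_nonzero(positive | truth_set))
    inter = int(np.count_nonzero(positive & truth_set))
    return inter / union if union else 0.0


def nmi(part: LabeledPartition, average_method: str = "arithmetic") -> float:
    """Normalized mutual information between prediction and truth.

    Normalized by the arithmetic mean of the two entropies by default
    (``"min"``, ``"max"`` and ``"geometric"`` also accepted).  If either
    labeling has zero entropy the score is 1 when the two are identical
    as set partitions and 0 otherwise.
    """
    _, pred = np.unique(part.predicted, return_inverse=True)
    _, true = np.unique(part.truth, return_inverse=True)
    h_pred = entropy(np.bincount(pred))
    h_true = entropy(np.bincount(true))
    if h_pred == 0.0 or h_true == 0.0:
        same = len(set(zip(pred.tolist(), true.tolist()))) == \
            max(pred.max(), true.max()) + 1 and h_pred == h_true
        return 1.0 if same else 0.0
    mi = mutual_info_score(true, pred)
    norm = {"arithmetic": (h_pred + h_true) / 2,
            "geometric": float(np.sqrt(h_pred * h_true)),
            "min": min(h_pred, h_true),
            "max": max(h_pred, h_true)}[average_method]
    return float(mi / norm)


def evaluate_partition(part: LabeledPartition) -> EvaluationReport:
    """Full report: per-rare-type counts/metrics plus global NMI."""
    mapping = annotate_clusters(part)
    per_type = {}
    for t in part.rare_types:
        truth_set = part.truth == t
        positive = _positive_set(part, t)
        tp = int(np.count_nonzero(positive & truth_set))
        fp = int(np.count_nonzero(positive & ~truth_set))
        fn = int(np.count_nonzero(~positive & truth_set))
        p, r, f1 = rare_prf(part, t)
        per_type[t if not isinstance(t, np.generic) else t.item()] = {
            "TP": tp, "FP": fp, "FN": fn,
            "precision": p, "recall": r, "f1": f1,
            "jaccard": jaccard_index(part, t),
        }
    return EvaluationReport(per_type=per_type, nmi=nmi(part),
                            annotation=mapping)
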