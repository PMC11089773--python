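"""Anchor points and tie groups of a precision-recall curve.

A classifier assigns each entity a real-valued score; thresholding at ``t``
predicts positive every entity with score >= t (inclusive).  Each unique
observed score, used as a threshold, yields one *anchor point* with
cumulative true/false positive counts and hence one (recall, precision)
pair.  Entities sharing a score form a *tie group*: the (dTP, dFP)
increment between adjacent anchors.  Every downstream connection method
consumes this anchor/tie-group decomposition.

The virtual origin (TP = FP = 0, recall 0, precision undefined) is *not*
an anchor point; tie groups whose left flank is the origin carry
``from_anchor = None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScoredLabels",
    "AnchorPoint",
    "TieGroup",
    "compute_anchor_points",
    "confusion_at_threshold",
]


@dataclass(frozen=True)
class ScoredLabels:
    """Scores and binary labels for a set of entities.

    Parameters
    ----------
    scores
        Finite real classification scores, one per entity.  Ties allowed.
    labels
        Binary actual-class labels: 1/True = actual positive.
    ids
        Optional entity identifiers, kept in input order.

    Row order is preserved: some surveyed tools are sensitive to the input
    order of tied entities, and emulating that requires the original order.
    """

    scores: np.ndarray
    labels: np.ndarray
    ids: tuple | None = None

    def __init__(self, scores, labels, ids=None):
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite score")
        raw = np.asarray(labels)
        if raw.dtype == bool:
            lab = raw.astype(np.int64)
        else:
            lab = np.asarray(raw, dtype=np.int64)
            if not np.array_equal(lab, np.asarray(raw)):  # reject 0.5 etc.
                raise ValueError("labels must be 0/1 or boolean")
        if lab.shape != scores.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.all((lab == 0) | (lab == 1)):
            bad = np.where((lab != 0) & (lab != 1))[0][0]
            raise ValueError(f"labels must be 0/1 or boolean (row {bad}: {raw[bad]!r})")
        scores.setflags(write=False)
        lab.setflags(write=False)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "ids", tuple(ids) if ids is not None else None)

    @property
    def n(self) -> int:
        return self.scores.size

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.n - self.labels.sum())

    @property
    def prevalence(self) -> float:
        """P/(P+N): the AUPRC of a no-skill classifier (baseline)."""
        return self.n_pos / self.n

    def require_positives(self) -> None:
        if self.n_pos == 0:
            raise ValueError("no positive entities")


@dataclass(frozen=True)
class AnchorPoint:
    """Cumulative confusion counts at one unique-score threshold."""

    threshold: float
    tp: int
    fp: int
    n_pos: int
    n_neg: int

    @property
    def recall(self) -> float:
        return self.tp / self.n_pos

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)


@dataclass(frozen=True)
class TieGroup:
    """The (dTP, dFP) increment between two adjacent anchor points.

    ``from_anchor is None`` means the left flank is the virtual origin.
    ``size == 1`` for every group exactly when the scores have no ties.
    """

    dtp: int
    dfp: int
    from_anchor: AnchorPoint | None
    to_anchor: AnchorPoint

    @property
    def size(self) -> int:
        return self.dtp + self.dfp

    @property
    def tp_before(self) -> int:
        return 0 if self.from_anchor is None else self.from_anchor.tp

    @property
    def fp_before(self) -> int:
        return 0 if self.from_anchor is None else self.from_anchor.fp

    @property
    def n_pos(self) -> int:
        return self.to_anchor.n_pos

    @property
    def from_recall(self) -> float:
        return self.tp_before / self.n_pos

    @property
    def to_recall(self) -> float:
        return self.to_anchor.recall

    @property
    def delta_recall(self) -> float:
        return self.dtp / self.n_pos


def compute_anchor_points(
    data: ScoredLabels,
) -> tuple[list[AnchorPoint], list[TieGroup]]:
    """Decompose scored entities into ordered anchors and tie groups.

    One anchor per unique score, in descending score order; the final
    anchor has TP = P and FP = N (recall 1, precision = prevalence).  The
    result depends only on the multiset of (score, label) pairs, never on
    input order: tied entities are grouped by score value.

    Raises
    ------
    ValueError
        If there are no positive entities or scores are non-finite.
    """
    data.require_positives()
    order = np.argsort(-data.scores, kind="stable")
    s = data.scores[order]
    lab = data.labels[order]
    # right edge (inclusive) of each tie group in the sorted array
    boundaries = np.nonzero(np.diff(s))[0]
    ends = np.append(boundaries, s.size - 1)
    tp_cum = np.cumsum(lab)
    fp_cum = np.cumsum(1 - lab)
    P, N = data.n_pos, data.n_neg
    anchors: list[AnchorPoint] = []
    groups: list[TieGroup] = []
    prev: AnchorPoint | None = None
    for e in ends:
        a = AnchorPoint(
            threshold=float(s[e]), tp=int(tp_cum[e]), fp=int(fp_cum[e]),
            n_pos=P, n_neg=N,
        )
        groups.append(
            TieGroup(
                dtp=a.tp - (0 if prev is None else prev.tp),
                dfp=a.fp - (0 if prev is None else prev.fp),
                from_anchor=prev,
                to_anchor=a,
            )
        )
        anchors.append(a)
        prev = a
    return anchors, groups


def compute_anchor_points_order_sensitive(
    data: ScoredLabels,
) -> tuple[list[AnchorPoint], list[TieGroup]]:
    """Anchors computed as if no two entities were tied.

    Entities sharing a score are sequenced by their input order and every
    entity becomes its own (singleton) anchor.  This reproduces the
    input-order-dependent behaviour of tools that break ties positionally
    instead of grouping them; it is deliberately *not* permutation
    invariant and exists only for emulation.
    """
    data.require_positives()
    order = np.argsort(-data.scores, kind="stable")
    lab = data.labels[order]
    s = data.scores[order]
    P, N = data.n_pos, data.n_neg
    anchors: list[AnchorPoint] = []
    groups: list[TieGroup] = []
    prev: AnchorPoint | None = None
    tp = fp = 0
    for i in range(lab.size):
        tp += int(lab[i])
        fp += 1 - int(lab[i])
        a = AnchorPoint(threshold=float(s[i]), tp=tp, fp=fp, n_pos=P, n_neg=N)
        groups.append(
            TieGroup(dtp=int(lab[i]), dfp=1 - int(lab[i]), from_anchor=prev, to_anchor=a)
        )
        anchors.append(a)
        prev = a
    return anchors, groups


def confusion_at_threshold(
    data: ScoredLabels, t: float
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) when predicting positive every score >= t."""
    if not np.isfinite(t):
        raise ValueError("non-finite threshold")
    pred = data.scores >= t
    tp = int(np.sum(pred & (data.labels == 1)))
    fp = int(np.sum(pred & (data.labels == 0)))
    return tp, fp, data.n_pos - tp, data.n_neg - fp


def anchors_table(anchors: Sequence[AnchorPoint]):
    """Structured rows (threshold, tp, fp, recall, precision) for export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "threshold": [a.threshold for a in anchors],
            "tp": [a.tp for a in anchors],
            "fp": [a.fp for a in anchors],
            "recall": [a.recall for a in anchors],
            "precision": [a.precision for a in anchors],
        }
    )
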