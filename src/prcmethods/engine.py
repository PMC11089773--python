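"""Full PR curves, AUPRC/AUROC, and tool emulation profiles.

A :class:`PRCurve` is the ordered anchor sequence plus one
:class:`~prcmethods.interpolation.Segment` per tie group (including the
segment from the virtual origin), under a chosen connection method and
start convention.  AUPRC is the sum of exact segment areas.

A :class:`MethodProfile` bundles the documented behaviour of one surveyed
software tool: which connection method it uses without and with tied
scores, how it starts the curve at recall 0, and which known defects it
embodies.  Profiles emulate *documented* method combinations and
convention flags, not third-party source code; bit-exact agreement with
the real packages is not promised.

The five defect flags:

``tie_linear_optimism``
    Linear interpolation across tie groups, which inflates AUPRC.
``fixed_start_point``
    The curve always starts at (0, 1) even when the method's own limit at
    recall 0 is below 1.
``incomplete_recall_range``
    The drawn curve does not span the full recall range 0 to 1 (the
    virtual-origin segment is left off the plotted points; the area a
    real truncating tool would lose is not emulated).
``input_order_ties``
    Tied entities are sequenced by input order and treated as if their
    scores were distinct, making the result input-order dependent.
``missing_anchors_on_prc``
    Some anchor points are left off the drawn curve (a visualization
    defect; AUPRC is unaffected).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .anchors import (
    AnchorPoint,
    ScoredLabels,
    TieGroup,
    compute_anchor_points,
    compute_anchor_points_order_sensitive,
)
from .interpolation import METHODS, Segment, connect

__all__ = [
    "PRCurve",
    "MethodProfile",
    "EvaluationReport",
    "REFERENCE_PROFILE",
    "PROFILES",
    "build_prc",
    "auprc",
    "auroc",
    "evaluate_with_profile",
    "get_profile",
]

START_CONVENTIONS = ("derived", "fixed_0_1")

ISSUE_DESCRIPTIONS = {
    "tie_linear_optimism": "linear interpolation across tied scores (overly-optimistic AUPRC)",
    "fixed_start_point": "curve forced to start at (0, 1)",
    "incomplete_recall_range": "curve does not cover the full recall range 0-1",
    "input_order_ties": "tied entities ordered by input position (input-order-dependent AUPRC)",
    "missing_anchors_on_prc": "not all anchor points drawn on the PRC",
}


@dataclass(frozen=True)
class PRCurve:
    """An assembled precision-recall curve with its exact area."""

    anchors: tuple[AnchorPoint, ...]
    groups: tuple[TieGroup, ...]
    segments: tuple[Segment, ...]
    method: str
    no_tie_method: str
    start_convention: str
    step: float
    n_pos: int
    n_neg: int
    drop_anchors: bool = False
    full_coverage: bool = True

    @property
    def auprc(self) -> float:
        return math.fsum(seg.area for seg in self.segments)

    @property
    def prevalence(self) -> float:
        return self.n_pos / (self.n_pos + self.n_neg)

    def curve_points(self) -> np.ndarray:
        """Ordered (recall, precision) vertices of the drawn curve.

        With ``drop_anchors`` only each segment's right-anchor point is
        retained, mimicking tools that omit interior anchor points from
        the plot; with ``full_coverage`` unset the origin segment is left
        off, so the drawn curve fails to span recall 0 to 1.  Both are
        defects of the *drawn curve*: the area is unaffected because
        integration uses the exact per-segment areas, not these vertices.
        """
        segments = self.segments
        if not self.full_coverage and len(segments) > 1:
            segments = segments[1:]
        rows: list[np.ndarray] = []
        for seg in segments:
            pts = seg.points
            if self.drop_anchors:
                pts = pts[-1:]
            rows.append(pts)
        all_pts = np.vstack(rows)
        keep = np.ones(len(all_pts), dtype=bool)
        keep[1:] = np.any(np.diff(all_pts, axis=0) != 0.0, axis=1)
        return all_pts[keep]


@dataclass(frozen=True)
class MethodProfile:
    """Documented anchor-connection behaviour of one software tool."""

    name: str
    no_tie_method: str
    tie_method: str
    start_convention: str = "derived"
    full_coverage: bool = True
    tie_order_sensitive: bool = False
    drop_anchors: bool = False
    step: float = 1.0
    notes: str = ""

    @property
    def issues(self) -> tuple[str, ...]:
        out = []
        if self.tie_method == "linear" and not self.tie_order_sensitive:
            out.append("tie_linear_optimism")
        if self.start_convention == "fixed_0_1":
            out.append("fixed_start_point")
        if not self.full_coverage:
            out.append("incomplete_recall_range")
        if self.tie_order_sensitive:
            out.append("input_order_ties")
        if self.drop_anchors:
            out.append("missing_anchors_on_prc")
        return tuple(out)


REFERENCE_PROFILE = MethodProfile(
    name="reference",
    no_tie_method="continuous_expectation",
    tie_method="continuous_expectation",
    notes="defect-free continuous-expectation reference configuration",
)

# One row per surveyed tool/method combination; tools offering several
# anchor-connection modes appear once per mode.
PROFILES: dict[str, MethodProfile] = {
    p.name: p
    for p in [
        REFERENCE_PROFILE,
        MethodProfile("ROCR", "linear", "discrete_expectation",
                      start_convention="fixed_0_1", drop_anchors=True),
        MethodProfile("Weka", "ap", "ap"),
        MethodProfile("scikit-learn-curve", "linear", "linear",
                      start_convention="fixed_0_1"),
        MethodProfile("scikit-learn-ap", "ap", "ap"),
        MethodProfile("PerfMeas", "linear", "linear",
                      tie_order_sensitive=True, full_coverage=False,
                      notes="ties broken by input position, then treated as distinct scores"),
        MethodProfile("PRROC-discrete", "linear", "discrete_expectation"),
        MethodProfile("PRROC-continuous", "continuous_expectation",
                      "continuous_expectation"),
        MethodProfile("TensorFlow", "continuous_expectation",
                      "continuous_expectation",
                      notes="expects classification scores in [0, 1]"),
        MethodProfile("precrec", "discrete_expectation", "discrete_expectation"),
        MethodProfile("TorchEval", "ap", "ap",
                      notes="Riemann-integral AUPRC, equivalent to AP"),
        MethodProfile("MLeval", "linear", "linear", full_coverage=False),
        MethodProfile("yardstick-curve", "linear", "linear",
                      start_convention="fixed_0_1"),
        MethodProfile("yardstick-ap", "ap", "ap"),
    ]
}


def get_profile(name: str) -> MethodProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {', '.join(sorted(PROFILES))}"
        ) from None


def _apply_fixed01(seg: Segment) -> Segment:
    """Force the origin segment's recall-0 point up to precision 1.

    For chord-integrated methods (linear, discrete expectation) this
    changes the area: the first chord now runs from (0, 1).  For the
    continuous-expectation curve and the AP step it only prepends a
    drawn point of measure zero, leaving the area unchanged.
    """
    if seg.method in ("linear", "discrete_expectation"):
        pts = seg.points.copy()
        pts[0, 1] = 1.0
        area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
        return replace(seg, points=pts, area=area)
    pts = np.vstack([[0.0, 1.0], seg.points])
    return replace(seg, points=pts)


def build_prc(
    data: ScoredLabels,
    method: str = "continuous_expectation",
    step: float = 1.0,
    start_convention: str = "derived",
    no_tie_method: str | None = None,
    full_coverage: bool = True,
    tie_order_sensitive: bool = False,
    drop_anchors: bool = False,
) -> PRCurve:
    """Assemble the PR curve for ``data`` under one method configuration.

    Parameters
    ----------
    method
        Connection method for tie groups (size > 1).
    no_tie_method
        Connection method for singleton groups; defaults to ``method``.
        Surveyed tools often pair different methods for the two cases.
    step
        Interpolation increment for the discrete-expectation method, in
        true positives per interpolated point.
    start_convention
        ``"derived"`` starts the curve at the method's own recall->0
        limit; ``"fixed_0_1"`` forces the start point (0, 1).
    full_coverage
        When False, the drawn curve begins at the first observed anchor
        (recall range [r1, 1]) instead of extending to recall 0; a
        plot-level defect, AUPRC unaffected.
    tie_order_sensitive
        When True, tied entities are sequenced by input order and every
        entity becomes its own anchor ("as if there are no ties").
    drop_anchors
        Plot-level flag: only right-anchor vertices appear in
        ``curve_points``; AUPRC is unaffected.
    """
    if method not in METHODS:
        raise ValueError(f"unknown connection method: {method!r}")
    no_tie = method if no_tie_method is None else no_tie_method
    if no_tie not in METHODS:
        raise ValueError(f"unknown connection method: {no_tie!r}")
    if start_convention not in START_CONVENTIONS:
        raise ValueError(f"unknown start convention: {start_convention!r}")
    if data.n_neg == 0:
        warnings.warn(
            "no negative entities: precision is identically 1 and AUPRC = 1",
            stacklevel=2,
        )
    if tie_order_sensitive:
        anchors, groups = compute_anchor_points_order_sensitive(data)
    else:
        anchors, groups = compute_anchor_points(data)
    segments = [
        connect(g, no_tie if g.size == 1 else method, step=step) for g in groups
    ]
    if start_convention == "fixed_0_1":
        segments[0] = _apply_fixed01(segments[0])
    return PRCurve(
        anchors=tuple(anchors),
        groups=tuple(groups),
        segments=tuple(segments),
        method=method,
        no_tie_method=no_tie,
        start_convention=start_convention,
        step=step,
        n_pos=data.n_pos,
        n_neg=data.n_neg,
        drop_anchors=drop_anchors,
        full_coverage=full_coverage,
    )


def auprc(curve: PRCurve) -> float:
    """Area under the PR curve: the sum of exact segment areas."""
    return curve.auprc


def auroc(data: ScoredLabels) -> float:
    """Trapezoidal area under the ROC curve.

    Tie groups are crossed by a single diagonal chord, so the value
    equals the Mann-Whitney U statistic (half credit for tied score
    pairs) divided by P*N.  Unlike AUPRC, this is insensitive to which
    tie-interpolation method is configured.
    """
    data.require_positives()
    if data.n_neg == 0:
        raise ValueError("AUROC undefined without negative entities")
    anchors, _ = compute_anchor_points(data)
    fpr = np.concatenate([[0.0], [a.fp / data.n_neg for a in anchors]])
    tpr = np.concatenate([[0.0], [a.tp / data.n_pos for a in anchors]])
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class EvaluationReport:
    """One profile's evaluation of one dataset, with full provenance."""

    profile: str
    method: str
    no_tie_method: str
    start_convention: str
    step: float
    auprc: float
    auroc: float | None
    baseline: float
    issues: tuple[str, ...]
    n_pos: int
    n_neg: int
    n_anchors: int

    def as_dict(self) -> dict:
        from . import __version__

        return {
            "profile": self.profile,
            "method": self.method,
            "no_tie_method": self.no_tie_method,
            "start_convention": self.start_convention,
            "step": self.step,
            "auprc": self.auprc,
            "auroc": self.auroc,
            "baseline": self.baseline,
            "issues": list(self.issues),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n_anchors": self.n_anchors,
            "version": __version__,
        }


def evaluate_with_profile(
    data: ScoredLabels, profile: MethodProfile | str
) -> EvaluationReport:
    """Evaluate ``data`` exactly as the profiled tool would.

    Applies the profile's method pair and convention flags; the report
    names every defect the profile embodies so downstream consumers can
    tell a reference value from an emulated one.  The prevalence
    baseline P/(P+N) accompanies every AUPRC.
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    curve = build_prc(
        data,
        method=profile.tie_method,
        step=profile.step,
        start_convention=profile.start_convention,
        no_tie_method=profile.no_tie_method,
        full_coverage=profile.full_coverage,
        tie_order_sensitive=profile.tie_order_sensitive,
        drop_anchors=profile.drop_anchors,
    )
    return EvaluationReport(
        profile=profile.name,
        method=profile.tie_method,
        no_tie_method=profile.no_tie_method,
        start_convention=profile.start_convention,
        step=profile.step,
        auprc=curve.auprc,
        auroc=auroc(data) if data.n_neg > 0 else None,
        baseline=curve.prevalence,
        issues=profile.issues,
        n_pos=data.n_pos,
        n_neg=data.n_neg,
        n_anchors=len(curve.anchors),
    )
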