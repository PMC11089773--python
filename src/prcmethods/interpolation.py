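"""The four methods for connecting adjacent anchor points.

Between two adjacent anchors separated by a tie group of dTP positives and
dFP negatives, precision as a function of recall is not observed; each
method commits to a different completion:

``linear``
    A straight chord in (recall, precision) space; the segment area is the
    trapezoid.  Known to be optimistic across wide tie groups.
``discrete_expectation``
    Interpolated points at fractional true-positive increments
    x = 0, step, 2*step, ..., dTP on the expectation curve, connected by
    straight lines.
``continuous_expectation``
    The expectation curve itself; the segment area is its exact integral
    (closed form, log antiderivative).
``ap``
    Average precision: a right-continuous step, i.e. a rectangle of width
    delta-recall and height the *right* anchor's precision.

The expectation curve gives each interpolated point its expected
coordinates under the assumption that all orderings of the tied entities
are equally likely: after covering x of the dTP tied positives, the
expected number of accompanying false positives is s*x with
s = dFP/dTP, so

    precision(x) = (TP_A + x) / (TP_A + FP_A + (1 + s) * x),   x in [0, dTP]

where (TP_A, FP_A) are the left anchor's cumulative counts.  From the
virtual origin (TP_A = FP_A = 0) the curve is constant at dTP/(dTP+dFP).

Singleton (no-tie) groups go through the same four code paths; with
dTP <= 1 the expectation forms reduce to the no-tie pictures, so tied and
untied data share one implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anchors import TieGroup

__all__ = [
    "Segment",
    "expectation_precision",
    "connect_linear",
    "connect_discrete_expectation",
    "connect_continuous_expectation",
    "connect_ap",
    "connect",
    "METHODS",
]

METHODS = ("linear", "discrete_expectation", "continuous_expectation", "ap")


@dataclass(frozen=True)
class Segment:
    """One tie group realized on the curve under one connection method.

    ``points`` are ordered (recall, precision) vertices: the polyline
    actually drawn for linear/discrete methods, a dense sampling for the
    continuous method, and the step vertices for AP.  ``area`` is the
    exact integral of precision over recall across the segment (not a
    quadrature of ``points``).
    """

    group: TieGroup
    method: str
    area: float
    points: np.ndarray  # shape (k, 2): (recall, precision)
    step: float | None = None

    @property
    def delta_recall(self) -> float:
        return self.group.delta_recall


def expectation_precision(group: TieGroup, x) -> np.ndarray:
    """Expected precision after covering ``x`` of the group's positives.

    ``x`` may be scalar or array, in [0, dTP].  Requires dTP >= 1.
    """
    if group.dtp < 1:
        raise ValueError("expectation curve undefined for dTP = 0")
    x = np.asarray(x, dtype=float)
    tp_a, fp_a = group.tp_before, group.fp_before
    s = group.dfp / group.dtp
    denom = tp_a + fp_a + (1.0 + s) * x
    out = np.empty_like(denom)
    zero = denom == 0.0  # only at x=0 from the virtual origin
    out[~zero] = (tp_a + x[~zero]) / denom[~zero]
    out[zero] = group.dtp / group.size
    return out


def _zero_width(group: TieGroup, method: str, step: float | None = None) -> Segment:
    r = group.to_recall
    pts = np.array([[r, _left_precision(group)], [r, group.to_anchor.precision]])
    return Segment(group=group, method=method, area=0.0, points=pts, step=step)


def _left_precision(group: TieGroup) -> float:
    """Precision at the segment's left end.

    At the virtual origin precision is undefined; each method's own
    recall->0 limit is used instead, which for every method here is the
    expectation value dTP/(dTP+dFP) when dTP >= 1 (constant first
    expectation segment), or the right anchor's precision when dTP = 0.
    """
    if group.from_anchor is not None:
        return group.from_anchor.precision
    if group.dtp >= 1:
        return group.dtp / group.size
    return group.to_anchor.precision


def connect_linear(group: TieGroup) -> Segment:
    """Straight chord between the flanking anchors; trapezoid area."""
    p0 = _left_precision(group)
    p1 = group.to_anchor.precision
    dr = group.delta_recall
    pts = np.array([[group.from_recall, p0], [group.to_recall, p1]])
    return Segment(group=group, method="linear", area=dr * (p0 + p1) / 2.0, points=pts)


def connect_discrete_expectation(group: TieGroup, step: float = 1.0) -> Segment:
    """Piecewise-linear interpolation through expectation-curve points.

    Points sit at x = 0, step, 2*step, ... and x = dTP (clamped); with
    step >= dTP the segment degenerates to a single chord whose endpoints
    lie on the expectation curve.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if group.dtp == 0:
        return _zero_width(group, "discrete_expectation", step)
    xs = np.arange(0.0, group.dtp, step)
    xs = np.append(xs, float(group.dtp))
    prec = expectation_precision(group, xs)
    rec = (group.tp_before + xs) / group.n_pos
    area = float(np.trapezoid(prec, rec))
    pts = np.column_stack([rec, prec])
    return Segment(group=group, method="discrete_expectation", area=area,
                   points=pts, step=step)


def _continuous_area_x(tp_a: float, fp_a: float, dtp: float, dfp: float) -> float:
    """Exact integral of the expectation precision over x in [0, dTP].

    With a = TP_A, c = TP_A + FP_A, b = 1 + dFP/dTP:

        int_0^dTP (a+x)/(c+bx) dx = dTP/b + (a - c/b)/b * log((c+b*dTP)/c)

    and for c = 0 (virtual origin) the integrand is constant 1/b.
    The result is in x-units; divide by P for recall-units.
    """
    a = float(tp_a)
    c = float(tp_a + fp_a)
    b = 1.0 + dfp / dtp
    if c == 0.0:
        return dtp / b
    return dtp / b + (a - c / b) / b * math.log1p(b * dtp / c)


def connect_continuous_expectation(group: TieGroup, n_samples: int = 64) -> Segment:
    """The expectation curve itself, with closed-form area.

    ``points`` samples the curve densely (for plotting and for the
    polyline-vs-area consistency check); ``area`` is the exact integral.
    """
    if group.dtp == 0:
        return _zero_width(group, "continuous_expectation")
    area = _continuous_area_x(group.tp_before, group.fp_before,
                              group.dtp, group.dfp) / group.n_pos
    xs = np.linspace(0.0, group.dtp, max(2, n_samples))
    prec = expectation_precision(group, xs)
    rec = (group.tp_before + xs) / group.n_pos
    return Segment(group=group, method="continuous_expectation", area=area,
                   points=np.column_stack([rec, prec]))


def connect_ap(group: TieGroup) -> Segment:
    """Average-precision step: rectangle at the right anchor's precision.

    The step is right-continuous, so the curve passes through the right
    anchor but only through the *recall* of the left one (vertical jump);
    the contribution is (R_k - R_{k-1}) * P_k.
    """
    p1 = group.to_anchor.precision
    dr = group.delta_recall
    pts = np.array([
        [group.from_recall, _left_precision(group)],
        [group.from_recall, p1],
        [group.to_recall, p1],
    ])
    return Segment(group=group, method="ap", area=dr * p1, points=pts)


def connect(group: TieGroup, method: str, step: float = 1.0) -> Segment:
    """Dispatch to one of the four connection methods by name."""
    if method == "linear":
        return connect_linear(group)
    if method == "discrete_expectation":
        return connect_discrete_expectation(group, step=step)
    if method == "continuous_expectation":
        return connect_continuous_expectation(group)
    if method == "ap":
        return connect_ap(group)
    raise ValueError(f"unknown connection method: {method!r}")
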