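"""Readers and writers for the score-table, report, and curve formats.

The score table is TSV or CSV with a header row and columns ``score``
(float) and ``label`` (0/1 or true/false), plus an optional ``id``;
lines starting with ``#`` are ignored.  The delimiter is sniffed from
the header.  Row order is preserved on read because order-sensitive tie
emulation depends on it.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anchors import ScoredLabels
from .engine import EvaluationReport, PRCurve

__all__ = [
    "read_scores",
    "write_scores",
    "write_report",
    "write_curve",
    "rescale_unit_interval",
    "round_scores",
]

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


def read_scores(path: str | Path) -> ScoredLabels:
    """Parse a score table, reporting malformed rows by file line number."""
    path = Path(path)
    kept: list[tuple[int, str]] = []  # (1-based file line, content)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            kept.append((lineno, line.rstrip("\n")))
    if not kept:
        raise ValueError(f"{path}: empty file")
    header = kept[0][1]
    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(
        _io.StringIO("\n".join(line for _, line in kept)), sep=sep, dtype=str
    )
    frame.columns = [c.strip() for c in frame.columns]
    for col in ("score", "label"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")

    def line_of(pos: int) -> int:
        return kept[pos + 1][0]  # +1 skips the header row

    scores = pd.to_numeric(frame["score"], errors="coerce").to_numpy()
    bad = np.nonzero(~np.isfinite(scores))[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-numeric or non-finite score on line {line_of(bad[0])}"
        )
    labels = np.empty(len(frame), dtype=int)
    for i, raw in enumerate(frame["label"].astype(str).str.strip()):
        if raw in _TRUE:
            labels[i] = 1
        elif raw in _FALSE:
            labels[i] = 0
        else:
            raise ValueError(
                f"{path}: label must be 0/1 or true/false, got {raw!r} "
                f"on line {line_of(i)}"
            )
    ids = frame["id"].tolist() if "id" in frame.columns else None
    return ScoredLabels(scores, labels, ids=ids)


def write_scores(data: ScoredLabels, path: str | Path, sep: str = "\t") -> None:
    """Write the standard score-table dialect (deterministic formatting)."""
    cols: dict = {}
    if data.ids is not None:
        cols["id"] = list(data.ids)
    cols["score"] = [repr(float(s)) for s in data.scores]
    cols["label"] = data.labels
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """JSON report: full-precision values plus 3-decimal display strings."""
    doc = report.as_dict()
    doc["display"] = {
        "auprc": f"{report.auprc:.3f}",
        "auroc": None if report.auroc is None else f"{report.auroc:.3f}",
        "baseline": f"{report.baseline:.3f}",
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_curve(curve: PRCurve, path: str | Path) -> None:
    """TSV of the drawn curve's (recall, precision) vertices."""
    pts = curve.curve_points()
    pd.DataFrame(
        {
            "recall": [repr(float(r)) for r in pts[:, 0]],
            "precision": [repr(float(p)) for p in pts[:, 1]],
        }
    ).to_csv(path, sep="\t", index=False)


def rescale_unit_interval(data: ScoredLabels) -> ScoredLabels:
    """Order-preserving rescale of scores to [0, 1].

    Convenience for tools that require scores in the unit interval; a
    strictly increasing affine map, so anchors and every AUPRC are
    unchanged.  Constant score vectors map to 0.5.
    """
    lo, hi = data.scores.min(), data.scores.max()
    if hi == lo:
        scaled = np.full_like(data.scores, 0.5)
    else:
        scaled = (data.scores - lo) / (hi - lo)
    return ScoredLabels(scaled, data.labels, ids=data.ids)


def round_scores(data: ScoredLabels, decimals: int) -> ScoredLabels:
    """Round scores to ``decimals`` places (merges near-ties explicitly).

    Tie grouping uses exact float equality; this is the supported way to
    coarsen nearly-equal scores into shared tie groups.
    """
    return ScoredLabels(np.round(data.scores, decimals), data.labels, ids=data.ids)
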