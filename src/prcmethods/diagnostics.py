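"""Cross-profile disagreement diagnostics for sets of classifiers.

Given several classifier score vectors ("submissions") over the same
entities and ground truth, score every submission under every emulation
profile, rank the submissions within each profile, and enumerate *rank
flips*: pairs of submissions whose relative order by AUPRC reverses
between two profiles.  Value- and rank-level correlations between profile
columns summarize how far the profiles agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anchors import ScoredLabels
from .engine import MethodProfile, evaluate_with_profile, get_profile

__all__ = [
    "SubmissionSet",
    "RankMatrix",
    "score_all",
    "rank_flips",
    "profile_correlations",
]


@dataclass(frozen=True)
class SubmissionSet:
    """Named score vectors sharing one entity universe and ground truth."""

    submissions: dict[str, ScoredLabels]

    def __post_init__(self) -> None:
        items = list(self.submissions.values())
        if len(items) < 1:
            raise ValueError("empty submission set")
        ref = items[0].labels
        for name, sub in self.submissions.items():
            if sub.n != items[0].n or not np.array_equal(sub.labels, ref):
                raise ValueError(f"submission {name!r} has a mismatched label vector")

    @property
    def names(self) -> list[str]:
        return list(self.submissions)


@dataclass(frozen=True)
class RankMatrix:
    """AUPRC values and per-profile dense ranks, submissions x profiles."""

    values: pd.DataFrame  # rows: submissions, columns: profiles
    ranks: pd.DataFrame   # dense ranks, 1 = best, ties share the rank

    @property
    def n_submissions(self) -> int:
        return len(self.values)


def _dense_ranks(col: np.ndarray) -> np.ndarray:
    # descending dense rank: best AUPRC -> 1, exact ties share a rank
    return stats.rankdata(-col, method="dense").astype(int)


def score_all(
    subs: SubmissionSet, profiles: list[MethodProfile | str]
) -> RankMatrix:
    """AUPRC of every submission under every profile, with dense ranks."""
    if len(subs.submissions) < 2:
        raise ValueError("need at least 2 submissions")
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    profiles = [get_profile(p) if isinstance(p, str) else p for p in profiles]
    values = pd.DataFrame(
        {
            p.name: [
                evaluate_with_profile(sub, p).auprc
                for sub in subs.submissions.values()
            ]
            for p in profiles
        },
        index=subs.names,
    )
    ranks = values.apply(lambda c: _dense_ranks(c.to_numpy()), axis=0)
    return RankMatrix(values=values, ranks=ranks)


def rank_flips(
    matrix: RankMatrix,
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """All (submission pair, profile pair) whose relative order reverses.

    A flip is strict: submission a beats b under one profile and loses to
    it under another.  The list is empty exactly when all profile columns
    induce the same weak ordering of the submissions.
    """
    vals = matrix.values
    subs = list(vals.index)
    profs = list(vals.columns)
    flips = []
    arr = vals.to_numpy()
    for i in range(len(subs)):
        for j in range(i + 1, len(subs)):
            diffs = arr[i] - arr[j]
            for a in range(len(profs)):
                for b in range(a + 1, len(profs)):
                    if diffs[a] * diffs[b] < 0:
                        flips.append(((subs[i], subs[j]), (profs[a], profs[b])))
    return flips


def profile_correlations(
    matrix: RankMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(Pearson on AUPRC values, Spearman on values) between profile columns.

    Zero-variance columns yield NaN (undefined), never 0: a constant
    column carries no ordering information and must not masquerade as
    uncorrelated.
    """
    if matrix.n_submissions < 3:
        raise ValueError("need at least 3 submissions for correlations")
    vals = matrix.values
    pearson = vals.corr(method="pearson")
    spearman = vals.corr(method="spearman")
    # pandas yields NaN for zero-variance columns already; keep diagonal exact
    np.fill_diagonal(pearson.values, 1.0)
    np.fill_diagonal(spearman.values, 1.0)
    return pearson, spearman
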