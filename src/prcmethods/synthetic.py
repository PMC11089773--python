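"""Synthetic score/label generators and canned degenerate fixtures.

Real evaluations hit three score regimes: continuous scorers (no ties),
coarsely discretized scorers (large tie groups), and hard cluster
assignments (a single predicted-positive group, two tie groups in total —
the cell-type-cluster-as-classifier situation).  The generators here
produce all three with controlled prevalence and separability, so every
connection method, emulation profile, and diagnostic can be exercised
without external data.

Fixtures reproduce the *structure* of the illustrative datasets used
throughout (tie-group sizes, degenerate configurations); the underlying
score values are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchors import ScoredLabels

__all__ = ["GeneratorConfig", "generate", "fixture", "FIXTURES", "flip_pair"]

MODELS = ("gaussian2", "discretized", "cluster_binary", "random")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for one synthetic dataset draw.

    Parameters
    ----------
    n_pos, n_neg
        Actual-class counts.
    model
        ``gaussian2``: negatives ~ N(0,1), positives ~ N(separation, 1);
        continuous scores, ties almost surely absent.
        ``discretized``: gaussian2 scores quantized to ``n_levels``
        equal-width bins; guarantees tie groups when n_levels < n.
        ``cluster_binary``: scores in {1, 0} — a hard single-cluster
        prediction with exactly two tie groups; ``separation`` in [0, 1]
        sets the fraction of positives inside the predicted cluster.
        ``random``: uniform scores independent of the labels (no-skill).
    separation
        Location shift (gaussian2/discretized) or within-cluster recall
        (cluster_binary).
    n_levels
        Number of distinct score values for ``discretized``.
    seed
        Same seed, same config => byte-identical output.
    """

    n_pos: int
    n_neg: int
    model: str = "gaussian2"
    separation: float = 1.0
    n_levels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1:
            raise ValueError("n_pos must be >= 1")
        if self.n_neg < 0:
            raise ValueError("n_neg must be >= 0")
        if self.model not in MODELS:
            raise ValueError(f"unknown model: {self.model!r}")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")


def generate(config: GeneratorConfig) -> ScoredLabels:
    """Draw one synthetic dataset according to ``config``."""
    rng = np.random.default_rng(config.seed)
    P, N = config.n_pos, config.n_neg
    labels = np.concatenate([np.ones(P, dtype=int), np.zeros(N, dtype=int)])
    if config.model == "gaussian2":
        scores = rng.standard_normal(P + N)
        scores[:P] += config.separation
    elif config.model == "discretized":
        raw = rng.standard_normal(P + N)
        raw[:P] += config.separation
        lo, hi = raw.min(), raw.max()
        width = (hi - lo) or 1.0
        levels = np.minimum(
            ((raw - lo) / width * config.n_levels).astype(int),
            config.n_levels - 1,
        )
        scores = levels.astype(float)
    elif config.model == "cluster_binary":
        if not 0.0 <= config.separation <= 1.0:
            raise ValueError("cluster_binary separation must be in [0, 1]")
        in_cluster_pos = int(round(config.separation * P))
        scores = np.zeros(P + N)
        scores[:in_cluster_pos] = 1.0
        # the predicted cluster also sweeps in some negatives
        n_fp = min(N, max(1, in_cluster_pos // 2)) if N else 0
        scores[P : P + n_fp] = 1.0
    else:  # random
        scores = rng.uniform(size=P + N)
    perm = rng.permutation(P + N)
    return ScoredLabels(scores[perm], labels[perm])


def _fixture_no_ties_small() -> ScoredLabels:
    # distinct scores, mixed labels: the generic no-tie illustration
    return ScoredLabels(
        scores=[0.95, 0.9, 0.85, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2],
        labels=[1, 1, 0, 1, 0, 1, 0, 0, 1, 0],
    )


def _fixture_four_tie_groups() -> ScoredLabels:
    # four anchor points from tie groups of 3, 7, 2 and 1 entities
    sizes = [3, 7, 2, 1]
    group_pos = [2, 3, 1, 1]  # positives inside each group
    scores, labels = [], []
    for g, (sz, np_) in enumerate(zip(sizes, group_pos)):
        scores += [1.0 - 0.2 * g] * sz
        labels += [1] * np_ + [0] * (sz - np_)
    return ScoredLabels(scores, labels)


def _fixture_all_tied(n_pos: int = 32, n_neg: int = 42) -> ScoredLabels:
    return ScoredLabels([0.5] * (n_pos + n_neg), [1] * n_pos + [0] * n_neg)


def _fixture_perfect() -> ScoredLabels:
    return ScoredLabels(
        scores=[0.9, 0.8, 0.7, 0.3, 0.2, 0.1],
        labels=[1, 1, 1, 0, 0, 0],
    )


def _fixture_one_pos_last() -> ScoredLabels:
    # the single positive scores below every negative: worst case
    return ScoredLabels(
        scores=[0.9, 0.8, 0.7, 0.6, 0.1],
        labels=[0, 0, 0, 0, 1],
    )


FIXTURES = {
    "no_ties_small": _fixture_no_ties_small,
    "four_tie_groups": _fixture_four_tie_groups,
    "all_tied": _fixture_all_tied,
    "perfect": _fixture_perfect,
    "one_pos_last": _fixture_one_pos_last,
}


def fixture(name: str) -> ScoredLabels:
    """Deterministic canned dataset from the catalogue.

    Catalogue: ``no_ties_small`` (distinct scores), ``four_tie_groups``
    (tie groups of 3, 7, 2, 1 entities), ``all_tied`` (one tie group,
    P=32/N=42), ``perfect`` (complete separation), ``one_pos_last``.
    """
    try:
        make = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None
    return make()


def flip_pair() -> tuple[ScoredLabels, ScoredLabels]:
    """A tied and a tie-free submission that different methods rank oppositely.

    Both score the same 6 entities (3 positives, 3 negatives, labels
    fixed).  The first submission ties every score, so its
    continuous-expectation AUPRC is exactly the prevalence 0.5; the
    second is tie-free with continuous-expectation AUPRC ~0.485 —
    near-equal classifiers by the expectation criterion.  Yet AP ranks
    the tie-free one higher while linear interpolation with a (0, 1)
    start ranks the tied one higher: a guaranteed rank flip.  Found by
    exhaustive search over 6-entity tie-free label orderings.
    """
    labels = [0, 1, 1, 0, 1, 0]
    tied = ScoredLabels([0.5] * 6, labels)
    tie_free = ScoredLabels([1.0, 0.9, 0.8, 0.7, 0.6, 0.5], labels)
    return tied, tie_free
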