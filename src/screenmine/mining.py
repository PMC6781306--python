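"""Graph-mining score and candidate selection.

A candidate earns one point for every scoring feature it carries (most
central ring, selected plain rings, high-activity atom groups) plus one
point for similarity to a known active above the configured threshold.
Candidates with a total score of at least ``min_score`` (default 3)
survive to the next screening stage; the two published phrasings of the
rule — "similarity and two or more features" or "no similarity and three
or more features" — are both exactly a total-score threshold of three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .scaffolds import FeatureVector

DEFAULT_SCORING_FEATURES = (
    "MCR-1", "PR-1", "PR-3", "PR-6", "PR-7", "PR-8",
    "AG-4", "AG-5", "AG-7", "AG-8", "AG-10", "AG-12",
)


@dataclass
class MiningConfig:
    scoring_features: list[str] = field(default_factory=lambda: list(DEFAULT_SCORING_FEATURES))
    similarity_point: bool = True
    min_score: int = 3

    def __post_init__(self) -> None:
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")
        if not self.scoring_features:
            raise ValueError("scoring_features must be non-empty")


def mining_score(
    feature_vector: FeatureVector,
    has_similarity: bool = False,
    config: MiningConfig | None = None,
) -> int:
    """Count of true scoring features, plus the similarity point."""
    config = config or MiningConfig()
    score = sum(
        1 for name in config.scoring_features if feature_vector.flags.get(name, False)
    )
    if has_similarity and config.similarity_point:
        score += 1
    return score


def select_candidates(
    scored_library: Sequence[tuple[str, int]], config: MiningConfig | None = None
) -> list[tuple[str, int]]:
    """Entries with score >= min_score, input order preserved."""
    config = config or MiningConfig()
    return [(ident, s) for ident, s in scored_library if s >= config.min_score]


def score_distribution(scores: Sequence[int]) -> tuple[int, int, float, float]:
    """(min, max, mean, sample SD) summary for reporting."""
    if not scores:
        raise ValueError("no scores")
    n = len(scores)
    mean = sum(scores) / n
    sd = math.sqrt(sum((s - mean) ** 2 for s in scores) / (n - 1)) if n > 1 else 0.0
    return (min(scores), max(scores), mean, sd)
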