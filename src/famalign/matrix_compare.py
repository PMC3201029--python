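"""Analytics over collections of derived matrices versus a fallback matrix.

D1 is the element-wise average difference between the family matrices and
the fallback. The better-vs-similar contrast averages the matrices that
significantly outperform the fallback (BP) and those that perform similarly
to it (SP); D2 = BP - SP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import DataError, SimilarityMatrix
from .evaluation import GroupComparison, P_SIGNIFICANT, P_SIMILAR_FLOOR

__all__ = [
    "MatrixDelta",
    "PerformanceContrast",
    "average_delta",
    "performance_contrast",
    "classify_matrices",
]


@dataclass
class MatrixDelta:
    d1: np.ndarray  # 20x20 average element difference
    n_matrices: int


@dataclass
class PerformanceContrast:
    bp: np.ndarray  # mean over better-performing matrices
    sp: np.ndarray  # mean over similar-performing matrices
    d2: np.ndarray  # bp - sp
    nb: int
    ns: int


def _check_alphabets(matrices: Sequence[SimilarityMatrix]):
    alphabets = {m.alphabet.letters for m in matrices}
    if len(alphabets) > 1:
        raise DataError("matrices are indexed by different alphabets")


def average_delta(
    family_matrices: Sequence[SimilarityMatrix], fallback: SimilarityMatrix
) -> MatrixDelta:
    """D1(i,j) = mean_k [ s_k(i,j) - v(i,j) ]."""
    if not family_matrices:
        raise DataError("need at least one family matrix")
    _check_alphabets(list(family_matrices) + [fallback])
    stack = np.stack([m.scores for m in family_matrices]).astype(float)
    d1 = stack.mean(axis=0) - fallback.scores
    return MatrixDelta(d1=d1, n_matrices=len(family_matrices))


def performance_contrast(
    better: Sequence[SimilarityMatrix], similar: Sequence[SimilarityMatrix]
) -> PerformanceContrast:
    """Element-wise means of the two performance classes and their difference."""
    if not better:
        raise DataError("the better-performing class is empty")
    if not similar:
        raise DataError("the similar-performing class is empty")
    _check_alphabets(list(better) + list(similar))
    bp = np.stack([m.scores for m in better]).astype(float).mean(axis=0)
    sp = np.stack([m.scores for m in similar]).astype(float).mean(axis=0)
    return PerformanceContrast(bp=bp, sp=sp, d2=bp - sp, nb=len(better), ns=len(similar))


def classify_matrices(
    comparisons: Sequence[GroupComparison],
    p_better: float = P_SIGNIFICANT,
    p_similar_floor: float = P_SIMILAR_FLOOR,
) -> tuple[list[str], list[str], list[str], list[str]]:
    """Partition group names into performance classes vs the fallback.

    ``scores_a`` is taken as the family-specific side of each comparison.
    Returns (better, similar, worse, excluded); the excluded band
    p_better <= p <= p_similar_floor holds the trend-toward-significance
    cases.
    """
    better: list[str] = []
    similar: list[str] = []
    worse: list[str] = []
    excluded: list[str] = []
    for c in comparisons:
        if c.p_value < p_better:
            (better if c.mean_difference > 0 else worse).append(c.group_name)
        elif c.p_value > p_similar_floor:
            similar.append(c.group_name)
        else:
            excluded.append(c.group_name)
    return better, similar, worse, excluded
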