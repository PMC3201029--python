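"""Derivation of group-specific log-odds similarity matrices.

A group's reference alignments are reduced to unordered residue-pair counts;
observed pair frequencies are converted to half-bit log-odds scores against
the expected frequencies under residue independence, and blended with a
general-purpose fallback matrix by a weight that grows with the amount of
data:

    s(i,j) = round( w * 2*log2(q(i,j)/e(i,j)) + (1-w) * v(i,j) )
    w      = 1 - 10^(-n / blend_constant)           (blend_constant = 8000)

with e(i,i) = p(i)^2 and e(i,j) = 2*p(i)*p(j) for i != j, and
p(i) = q(i,i) + sum_{j != i} q(i,j)/2.

Zero observed counts are smoothed with background-proportional pseudocounts
so the logarithm stays finite: q~(i,j) = (f(i,j) + m*e(i,j)) / (n + m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    ALPHABET,
    GAP,
    DEFAULT_ALPHABET,
    DataError,
    ReferenceGroup,
    SimilarityMatrix,
)

__all__ = [
    "PairCounts",
    "FrequencyModel",
    "count_pairs",
    "estimate_frequencies",
    "blend_weight",
    "derive_matrix",
    "log_odds_from_counts",
]

#: Minimum number of reference alignments for a group to be derivation-eligible.
MIN_ALIGNMENTS = 10

#: Constant of the blend weight w = 1 - 10^(-n/BLEND_CONSTANT).
BLEND_CONSTANT = 8000.0

_IDX = {c: i for i, c in enumerate(ALPHABET)}


@dataclass
class PairCounts:
    """Symmetric table of observed unordered aligned residue-pair counts."""

    f: np.ndarray  # 20x20 symmetric, f[i,j] == f[j,i]
    n: int  # total unordered pairs == sum_{i<=j} f[i,j]
    skipped_columns: int = 0  # gap or non-standard-residue columns

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=np.int64)
        if self.f.shape != (20, 20) or not np.array_equal(self.f, self.f.T):
            raise DataError("pair counts must be a symmetric 20x20 table")
        if np.any(self.f < 0):
            raise DataError("pair counts must be non-negative")
        total = int(np.triu(self.f).sum())
        if total != self.n:
            raise DataError(f"pair count total {total} != declared n {self.n}")


@dataclass
class FrequencyModel:
    """Observed/expected pair frequencies and the data-driven blend weight.

    ``q`` and ``e`` are unordered-pair distributions: summing the upper
    triangle (diagonal included) of either table gives 1.
    """

    q: np.ndarray
    p: np.ndarray
    e: np.ndarray
    w: float
    n: int


def count_pairs(group: ReferenceGroup) -> PairCounts:
    """Count unordered residue pairs over all residue-residue columns.

    Columns containing a gap or a non-standard residue contribute nothing
    and are tallied in ``skipped_columns``.
    """
    if not group.alignments:
        raise DataError(f"group {group.name} has no alignments")
    f = np.zeros((20, 20), dtype=np.int64)
    skipped = 0
    for aln in group.alignments:
        for x, y in aln.columns():
            if x == GAP or y == GAP or x not in _IDX or y not in _IDX:
                skipped += 1
                continue
            i, j = _IDX[x], _IDX[y]
            f[i, j] += 1
            if i != j:
                f[j, i] += 1
    n = int(np.triu(f).sum())
    if n == 0:
        raise DataError(f"group {group.name} has no residue-residue columns")
    return PairCounts(f=f, n=n, skipped_columns=skipped)


def blend_weight(n: int | float, blend_constant: float = BLEND_CONSTANT) -> float:
    """Weight of the group-specific score: w = 1 - 10^(-n/blend_constant)."""
    return 1.0 - 10.0 ** (-float(n) / blend_constant)


def estimate_frequencies(
    counts: PairCounts, blend_constant: float = BLEND_CONSTANT
) -> FrequencyModel:
    """Observed pair frequencies q, residue frequencies p, expected pair
    frequencies e, and blend weight w, from raw pair counts."""
    if counts.n < 1:
        raise DataError("cannot estimate frequencies from zero pairs")
    n = counts.n
    q = counts.f / n  # symmetric; unordered mass: sum over i<=j is 1
    # p(i) = q(i,i) + sum_{j!=i} q(i,j)/2
    p = np.diag(q) + (q.sum(axis=1) - np.diag(q)) / 2.0
    e = 2.0 * np.outer(p, p)
    np.fill_diagonal(e, p * p)
    return FrequencyModel(q=q, p=p, e=e, w=blend_weight(n, blend_constant), n=n)


def _smoothed_q(counts: PairCounts, e: np.ndarray, pseudocount_mass: float) -> np.ndarray:
    """Background-proportional pseudocount smoothing of observed frequencies."""
    return (counts.f + pseudocount_mass * e) / (counts.n + pseudocount_mass)


def log_odds_from_counts(
    counts: PairCounts, pseudocount_mass: float = 1.0
) -> np.ndarray:
    """Half-bit log-odds table 2*log2(q~/e) without fallback blending."""
    model = estimate_frequencies(counts)
    qs = _smoothed_q(counts, model.e, pseudocount_mass)
    return 2.0 * np.log2(qs / model.e)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def derive_matrix(
    group: ReferenceGroup,
    fallback: SimilarityMatrix,
    pseudocount_mass: float = 1.0,
    min_alignments: int = MIN_ALIGNMENTS,
    blend_constant: float = BLEND_CONSTANT,
    blend_mode: str = "score",
    source: str = "family-specific",
) -> SimilarityMatrix:
    """Derive the group-specific similarity matrix, blended with ``fallback``.

    ``blend_mode="score"`` (default) forms the convex combination of the two
    scores. ``blend_mode="odds"`` instead blends the odds ratios inside the
    logarithm: s = round(2*log2(w*q~/e + (1-w)*2^(v/2))) — provided for
    sensitivity checks only.
    """
    if fallback is None:
        raise DataError("a fallback similarity matrix is required")
    if len(group.alignments) < min_alignments:
        raise DataError(
            f"group {group.name} has {len(group.alignments)} alignments; "
            f"{min_alignments} required for derivation"
        )
    counts = count_pairs(group)
    model = estimate_frequencies(counts, blend_constant)
    qs = _smoothed_q(counts, model.e, pseudocount_mass)
    v = fallback.scores.astype(float)
    w = model.w
    observable = model.e > 0
    if np.any((qs == 0) & observable):
        raise DataError(
            "zero observed frequency with zero pseudocount mass; "
            "use pseudocount_mass > 0"
        )
    # residues absent from the group make e(i,j)=0; the group term carries no
    # information there, so those entries take the fallback score outright
    ratio = np.divide(qs, model.e, out=np.ones_like(qs), where=observable)
    group_score = np.where(observable, 2.0 * np.log2(ratio), v)
    if blend_mode == "score":
        s = w * group_score + (1.0 - w) * v
    elif blend_mode == "odds":
        odds = np.where(observable, ratio, np.exp2(v / 2.0))
        s = 2.0 * np.log2(w * odds + (1.0 - w) * np.exp2(v / 2.0))
    else:
        raise ValueError(f"unknown blend_mode {blend_mode!r}")
    scores = _round_half_away(s).astype(np.int64)
    return SimilarityMatrix(
        name=f"{group.name}", scores=scores, source=source, alphabet=DEFAULT_ALPHABET
    )
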