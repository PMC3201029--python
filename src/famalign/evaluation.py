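"""Alignment-quality benchmarking: Q scores, gap-penalty grid search,
3-fold cross-validation, and paired-t-test comparison of scoring functions.

The quality of a test alignment against a reference is

    f_D = n_I / l_R * 100      f_M = n_I / l_T * 100      Q = (f_D + f_M) / 2

where n_I counts residue pairs aligned identically in both alignments and
l_R / l_T count the aligned residue pairs (residue-residue columns) of the
reference / test alignment, so identical alignments always score 100%.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .aligner import EXTENDED_LETTERS, _global_align_idx, encode
from .core_io import (
    DataError,
    GapPenalties,
    PairwiseAlignment,
    ReferenceGroup,
    SimilarityMatrix,
)
from .matrix_derive import derive_matrix

__all__ = [
    "QualityScore",
    "GroupComparison",
    "CrossValidationPlan",
    "ScoringSpec",
    "quality",
    "grid_search_penalties",
    "make_cv_plan",
    "run_cross_validation",
    "paired_t_test",
    "compare_matrices_on_groups",
    "overlap_analysis",
    "DEFAULT_ALPHA_RANGE",
    "DEFAULT_BETA_RANGE",
]

#: Grid-search ranges for the affine penalties.
DEFAULT_ALPHA_RANGE = range(1, 51)
DEFAULT_BETA_RANGE = range(1, 31)

#: Two-sided significance threshold for better/worse verdicts.
P_SIGNIFICANT = 0.05
#: Floor above which two scoring functions are called similar-performing.
P_SIMILAR_FLOOR = 0.1


@dataclass(frozen=True)
class QualityScore:
    """Developer score f_D, modeler score f_M, and their average Q (percent)."""

    f_d: float
    f_m: float

    @property
    def q(self) -> float:
        return (self.f_d + self.f_m) / 2.0


@dataclass
class GroupComparison:
    """Paired comparison of two scoring functions on one group."""

    group_name: str
    scores_a: list[float]
    scores_b: list[float]
    t_statistic: float
    p_value: float
    verdict: str  # A-better | B-better | no-significant-difference

    @property
    def mean_difference(self) -> float:
        return float(np.mean(np.asarray(self.scores_a) - np.asarray(self.scores_b)))


@dataclass
class CrossValidationPlan:
    """Seeded partition of a group's pair indices into disjoint folds."""

    group_name: str
    folds: list[list[int]]
    seed: int

    def __post_init__(self):
        flat = sorted(i for fold in self.folds for i in fold)
        if flat != list(range(len(flat))):
            raise DataError("cross-validation folds must partition the pair indices")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise DataError(f"fold sizes {sizes} differ by more than 1")


@dataclass
class ScoringSpec:
    """A scoring function under evaluation.

    Either a fixed matrix (training = penalty optimization only) or a
    group-specific derivation (training = derive matrix on the training
    folds, then optimize penalties).
    """

    name: str
    matrix: SimilarityMatrix | None = None
    group_specific: bool = False
    fallback: SimilarityMatrix | None = None
    pseudocount_mass: float = 1.0
    blend_constant: float = 8000.0

    def __post_init__(self):
        if self.group_specific and self.fallback is None:
            raise DataError(f"spec {self.name}: group-specific scoring needs a fallback matrix")
        if not self.group_specific and self.matrix is None:
            raise DataError(f"spec {self.name}: fixed scoring needs a matrix")


def quality(test: PairwiseAlignment, ref: PairwiseAlignment) -> QualityScore:
    """Q score of a test alignment against the reference for the same pair."""
    if test.seq_a != ref.seq_a or test.seq_b != ref.seq_b:
        raise DataError(
            f"test alignment {test.id_a}/{test.id_b} does not align the same "
            f"sequences as reference {ref.id_a}/{ref.id_b}"
        )
    ref_pairs = ref.aligned_pairs()
    test_pairs = test.aligned_pairs()
    n_i = len(test_pairs & ref_pairs)
    return QualityScore(
        f_d=n_i / len(ref_pairs) * 100.0 if ref_pairs else 0.0,
        f_m=n_i / len(test_pairs) * 100.0 if test_pairs else 0.0,
    )


def _ref_map(ref: PairwiseAlignment) -> np.ndarray:
    """For each residue index in seq_a, its aligned index in seq_b (or -1)."""
    m = np.full(len(ref.seq_a), -1, dtype=np.int64)
    for ia, ib in ref.aligned_pairs():
        m[ia] = ib
    return m


def _q_of_columns(acol: np.ndarray, bcol: np.ndarray, ref_map: np.ndarray, l_ref: int) -> float:
    mask = (acol >= 0) & (bcol >= 0)
    l_t = int(np.count_nonzero(mask))  # residue-residue columns of the test
    if l_t == 0 or l_ref == 0:
        return 0.0
    n_i = int(np.count_nonzero(ref_map[acol[mask]] == bcol[mask]))
    return (n_i / l_ref * 100.0 + n_i / l_t * 100.0) / 2.0


def grid_search_penalties(
    train_pairs: Sequence[PairwiseAlignment],
    matrix: SimilarityMatrix,
    alpha_range: Iterable[int] = DEFAULT_ALPHA_RANGE,
    beta_range: Iterable[int] = DEFAULT_BETA_RANGE,
) -> GapPenalties:
    """Exhaustive search for the (alpha, beta) maximizing mean training Q.

    Ties resolve to the smallest alpha, then the smallest beta.
    """
    train_pairs = list(train_pairs)
    if not train_pairs:
        raise DataError("grid search needs a non-empty training set")
    table = matrix.extended_table(EXTENDED_LETTERS)
    enc = [
        (encode(p.seq_a), encode(p.seq_b), _ref_map(p), len(p.aligned_pairs()))
        for p in train_pairs
    ]
    alphas = sorted(set(alpha_range))
    betas = sorted(set(beta_range))
    best: tuple[float, int, int] | None = None
    for alpha in alphas:
        for beta in betas:
            total = 0.0
            for a, b, rmap, l_ref in enc:
                _, acol, bcol = _global_align_idx(a, b, table, alpha, beta)
                total += _q_of_columns(acol, bcol, rmap, l_ref)
            mean_q = total / len(enc)
            if best is None or mean_q > best[0]:
                best = (mean_q, alpha, beta)
    return GapPenalties(best[1], best[2])


def make_cv_plan(group: ReferenceGroup, seed: int, n_folds: int = 3) -> CrossValidationPlan:
    """Seeded uniform shuffle followed by a round-robin split into folds."""
    n = len(group.alignments)
    if n < n_folds:
        raise DataError(f"group {group.name} has {n} pairs; need at least {n_folds}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [sorted(int(i) for i in perm[k::n_folds]) for k in range(n_folds)]
    return CrossValidationPlan(group_name=group.name, folds=folds, seed=seed)


def run_cross_validation(
    group: ReferenceGroup,
    specs: Sequence[ScoringSpec],
    seed: int,
    alpha_range: Iterable[int] = DEFAULT_ALPHA_RANGE,
    beta_range: Iterable[int] = DEFAULT_BETA_RANGE,
    n_folds: int = 3,
    train_observer: Callable[..., None] | None = None,
) -> dict[str, list[float]]:
    """Cross-validated per-pair Q scores for each scoring function.

    Training on each fold never sees the fold's test alignments: a
    group-specific spec derives its matrix from the training alignments only,
    and penalty optimization uses training alignments only.
    ``train_observer(spec_name, fold_index, train_indices, test_indices)``
    is invoked once per (spec, fold) for leakage instrumentation.
    """
    plan = make_cv_plan(group, seed, n_folds)
    results: dict[str, list[float]] = {spec.name: [0.0] * len(group.alignments) for spec in specs}
    for k, test_idx in enumerate(plan.folds):
        train_idx = [i for kk, fold in enumerate(plan.folds) if kk != k for i in fold]
        train = [group.alignments[i] for i in train_idx]
        for spec in specs:
            if train_observer is not None:
                train_observer(spec.name, k, list(train_idx), list(test_idx))
            if spec.group_specific:
                train_group = ReferenceGroup(name=f"{group.name}/fold{k}", alignments=train)
                matrix = derive_matrix(
                    train_group,
                    spec.fallback,
                    pseudocount_mass=spec.pseudocount_mass,
                    blend_constant=spec.blend_constant,
                    min_alignments=1,  # eligibility is enforced at group level
                )
            else:
                matrix = spec.matrix
            penalties = grid_search_penalties(train, matrix, alpha_range, beta_range)
            table = matrix.extended_table(EXTENDED_LETTERS)
            for i in test_idx:
                ref = group.alignments[i]
                _, acol, bcol = _global_align_idx(
                    encode(ref.seq_a), encode(ref.seq_b), table, penalties.alpha, penalties.beta
                )
                results[spec.name][i] = _q_of_columns(
                    acol, bcol, _ref_map(ref), len(ref.aligned_pairs())
                )
    return results


def paired_t_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on Q-score lists.

    Returns (t, p) with t = mean(d) / (sd(d)/sqrt(n)) on the paired
    differences and p from Student's t with n-1 degrees of freedom.
    All-zero differences give (0.0, 1.0).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"paired score lists differ in length ({a.size} vs {b.size})")
    if a.size < 2:
        raise DataError("paired t-test needs at least 2 paired scores")
    d = a - b
    sd = float(np.std(d, ddof=1))
    n = d.size
    if sd == 0.0:
        if np.all(d == 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p


def _verdict(t: float, p: float, mean_diff: float, p_threshold: float) -> str:
    if p < p_threshold and mean_diff > 0:
        return "A-better"
    if p < p_threshold and mean_diff < 0:
        return "B-better"
    return "no-significant-difference"


def _group_seed(seed: int, name: str) -> int:
    return (seed * 2654435761 + zlib.crc32(name.encode())) % (2**32)


def compare_matrices_on_groups(
    groups: Sequence[ReferenceGroup],
    spec_a: ScoringSpec,
    spec_b: ScoringSpec,
    seed: int,
    alpha_range: Iterable[int] = DEFAULT_ALPHA_RANGE,
    beta_range: Iterable[int] = DEFAULT_BETA_RANGE,
    p_threshold: float = P_SIGNIFICANT,
) -> tuple[dict[str, int], list[GroupComparison]]:
    """Tournament comparison of two scoring functions over many groups.

    Returns aggregate counts {"a_better", "b_better", "no_difference"} and
    the per-group comparisons.
    """
    if not groups:
        raise DataError("need at least one group to compare on")
    counts = {"a_better": 0, "b_better": 0, "no_difference": 0}
    comparisons: list[GroupComparison] = []
    for group in groups:
        gseed = _group_seed(seed, group.name)
        scores = run_cross_validation(
            group, [spec_a, spec_b], gseed, alpha_range, beta_range
        )
        qa, qb = scores[spec_a.name], scores[spec_b.name]
        t, p = paired_t_test(qa, qb)
        verdict = _verdict(t, p, float(np.mean(np.asarray(qa) - np.asarray(qb))), p_threshold)
        comparisons.append(
            GroupComparison(group.name, qa, qb, t, p, verdict)
        )
        if verdict == "A-better":
            counts["a_better"] += 1
        elif verdict == "B-better":
            counts["b_better"] += 1
        else:
            counts["no_difference"] += 1
    return counts, comparisons


def overlap_analysis(significant_sets: Sequence[set]) -> dict[frozenset[int], int]:
    """Sizes of all Venn-partition regions of the given significant-group sets.

    Keys are frozensets of set indices; the value is the number of elements
    belonging to exactly those sets.
    """
    if len(significant_sets) < 2:
        raise DataError("overlap analysis needs at least 2 sets")
    universe = set().union(*significant_sets)
    partition: dict[frozenset[int], int] = {}
    for element in universe:
        signature = frozenset(
            i for i, s in enumerate(significant_sets) if element in s
        )
        partition[signature] = partition.get(signature, 0) + 1
    return partition
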