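"""Generators for benchmark fixtures with known ground truth.

Each family is a joint residue-pair emission distribution plus an indel
process (per-column Bernoulli opening, geometric run lengths). A sampled
pair of sequences carries its emitted alignment as the reference, so
derivation, evaluation and adaptive selection can be tested against
closed-form answers without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adaptive_select import FamilyDatabase
from .core_io import ALPHABET, DataError, PairwiseAlignment, ReferenceGroup

__all__ = [
    "FamilyModel",
    "closed_form_log_odds",
    "random_family_model",
    "sample_reference_group",
    "make_benchmark",
]


@dataclass
class FamilyModel:
    """Generative model of one family's reference alignments."""

    name: str
    joint_sub_probs: np.ndarray  # symmetric 20x20, sums to 1 over all cells
    indel_open_prob: float = 0.0
    indel_extend_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        P = np.asarray(self.joint_sub_probs, dtype=float)
        if P.shape != (20, 20):
            raise DataError("joint_sub_probs must be 20x20")
        if np.any(P < 0) or not np.allclose(P.sum(), 1.0):
            raise DataError("joint_sub_probs must be non-negative and sum to 1")
        if not np.allclose(P, P.T):
            raise DataError("joint_sub_probs must be symmetric")
        if P.max() == 0:
            raise DataError("degenerate model: all-zero probabilities")
        if not (0 <= self.indel_open_prob < 1 and 0 <= self.indel_extend_prob < 1):
            raise DataError("indel probabilities must lie in [0, 1)")
        self.joint_sub_probs = P

    @property
    def residue_probs(self) -> np.ndarray:
        """Marginal single-residue distribution."""
        return self.joint_sub_probs.sum(axis=1)


def closed_form_log_odds(joint_sub_probs: np.ndarray) -> np.ndarray:
    """Half-bit log-odds 2*log2(q/e) of a generating joint distribution.

    ``q`` is the unordered-pair distribution implied by the (ordered,
    symmetric) joint table and ``e`` the expectation under residue
    independence; for both on- and off-diagonal entries the ratio reduces to
    P(i,j) / (p_i * p_j).
    """
    P = np.asarray(joint_sub_probs, dtype=float)
    p = P.sum(axis=1)
    with np.errstate(divide="ignore"):
        return 2.0 * np.log2(P / np.outer(p, p))


def random_family_model(
    name: str,
    seed: int,
    identity: float = 0.65,
    n_preferred: int = 7,
    indel_open_prob: float = 0.03,
    indel_extend_prob: float = 0.3,
    preferred: "list[int] | None" = None,
) -> FamilyModel:
    """A family with a distinctive residue composition and tunable identity.

    A Dirichlet background concentrated on ``n_preferred`` randomly chosen
    residues (or the explicit ``preferred`` index list) gives families
    distinguishable compositions; the joint table puts ``identity`` mass on
    exact conservation and emits independent substitutions otherwise, so
    expected within-pair identity is ``identity + (1-identity)*sum(p^2)``.
    """
    rng = np.random.default_rng(seed)
    concentration = np.full(20, 0.08)
    if preferred is None:
        preferred = rng.choice(20, size=n_preferred, replace=False)
    concentration[np.asarray(preferred, dtype=int)] = 4.0
    p = rng.dirichlet(concentration)
    P = identity * np.diag(p) + (1.0 - identity) * np.outer(p, p)
    P = (P + P.T) / 2.0
    P /= P.sum()
    return FamilyModel(
        name=name,
        joint_sub_probs=P,
        indel_open_prob=indel_open_prob,
        indel_extend_prob=indel_extend_prob,
        seed=seed,
    )


def distinct_family_models(
    n_families: int,
    seed: int,
    identity: float = 0.65,
    indel_open_prob: float = 0.03,
    indel_extend_prob: float = 0.3,
    name_prefix: str = "fam",
) -> list[FamilyModel]:
    """Family models with pairwise-disjoint preferred residue sets.

    A seeded permutation of the 20 residues is sliced evenly across the
    families, guaranteeing distinguishable compositions for up to 6 families.
    """
    if not 2 <= n_families <= 6:
        raise DataError("distinct families require 2 <= n_families <= 6")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(20)
    width = 20 // n_families
    return [
        random_family_model(
            f"{name_prefix}{k}",
            seed=int(rng.integers(0, 2**31)),
            identity=identity,
            indel_open_prob=indel_open_prob,
            indel_extend_prob=indel_extend_prob,
            preferred=list(perm[k * width : (k + 1) * width]),
        )
        for k in range(n_families)
    ]


def _sample_pair(
    model: FamilyModel, rng: np.random.Generator, n_match: int, id_a: str, id_b: str
) -> PairwiseAlignment:
    flat = model.joint_sub_probs.ravel()
    draws = rng.choice(400, size=n_match, p=flat)
    ia, ib = draws // 20, draws % 20
    if model.indel_open_prob == 0.0:
        row_a = "".join(ALPHABET[i] for i in ia)
        row_b = "".join(ALPHABET[j] for j in ib)
        return PairwiseAlignment(id_a, id_b, row_a, row_b)

    p_marginal = model.residue_probs
    opens = rng.random(n_match) < model.indel_open_prob
    cols_a: list[str] = []
    cols_b: list[str] = []
    for k in range(n_match):
        cols_a.append(ALPHABET[ia[k]])
        cols_b.append(ALPHABET[ib[k]])
        # a gap run may open only after a substitution column, so opposing
        # runs are never adjacent and no column is all-gap
        if opens[k] and k != n_match - 1:
            run = int(rng.geometric(1.0 - model.indel_extend_prob))
            residues = rng.choice(20, size=run, p=p_marginal)
            if rng.random() < 0.5:
                cols_a.extend(ALPHABET[r] for r in residues)
                cols_b.extend("-" * run)
            else:
                cols_a.extend("-" * run)
                cols_b.extend(ALPHABET[r] for r in residues)
    return PairwiseAlignment(id_a, id_b, "".join(cols_a), "".join(cols_b))


def sample_reference_group(
    model: FamilyModel,
    n_pairs: int,
    mean_len: int,
    subset_tag: str = "SUP",
) -> ReferenceGroup:
    """Sample a reference group of ``n_pairs`` alignments from the model.

    The emitted alignment of each pair is stored as its reference; the
    ungapped rows are the member sequences. Pair lengths are Poisson around
    ``mean_len`` substitution columns (floored at 10).
    """
    if n_pairs < 1:
        raise DataError("n_pairs must be >= 1")
    if mean_len < 10:
        raise DataError("mean_len must be >= 10")
    rng = np.random.default_rng(model.seed)
    alignments = []
    for k in range(n_pairs):
        n_match = max(10, int(rng.poisson(mean_len)))
        alignments.append(
            _sample_pair(model, rng, n_match, f"{model.name}_p{k}_a", f"{model.name}_p{k}_b")
        )
    return ReferenceGroup(name=model.name, alignments=alignments, subset_tag=subset_tag)


@dataclass
class BenchmarkTruth:
    """Ground truth of a generated benchmark, keyed by family name."""

    joint_probs: dict[str, np.ndarray]
    log_odds: dict[str, np.ndarray]
    family_of: dict[str, str]  # sequence id -> family


def make_benchmark(
    models: list[FamilyModel],
    pairs_per_family: int,
    seed: int,
    mean_len: int = 80,
) -> tuple[list[ReferenceGroup], FamilyDatabase, BenchmarkTruth]:
    """Groups, a family database, and truth tables for a set of family models.

    Every model is reseeded deterministically from ``seed`` so the whole
    benchmark is a pure function of its arguments.
    """
    names = [m.name for m in models]
    if len(names) != len(set(names)):
        raise DataError("duplicate family names in benchmark models")
    if len(models) < 2:
        raise DataError("a benchmark needs at least 2 family models")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(models))
    groups: list[ReferenceGroup] = []
    records: list[tuple[str, str, str]] = []
    truth = BenchmarkTruth(joint_probs={}, log_odds={}, family_of={})
    for model, child in zip(models, child_seeds):
        reseeded = FamilyModel(
            name=model.name,
            joint_sub_probs=model.joint_sub_probs,
            indel_open_prob=model.indel_open_prob,
            indel_extend_prob=model.indel_extend_prob,
            seed=int(child),
        )
        group = sample_reference_group(reseeded, pairs_per_family, mean_len)
        groups.append(group)
        for sid, seq in sorted(group.sequences.items()):
            records.append((sid, model.name, seq))
            truth.family_of[sid] = model.name
        truth.joint_probs[model.name] = model.joint_sub_probs
        truth.log_odds[model.name] = closed_form_log_odds(model.joint_sub_probs)
    return groups, FamilyDatabase(records=records), truth
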