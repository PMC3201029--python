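"""Domain types and readers/writers for sequences, alignments and score matrices.

The on-disk formats are deliberately plain: FASTA for sequences, aligned
FASTA (two gapped records, ``-`` gaps) for pairwise alignments, NCBI/EMBOSS
square-matrix text for similarity matrices, and TSV for per-group gap-penalty
tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "AMBIGUOUS_RESIDUES",
    "AminoAlphabet",
    "SimilarityMatrix",
    "GapPenalties",
    "PairwiseAlignment",
    "ReferenceGroup",
    "ParseError",
    "DataError",
    "read_fasta",
    "write_fasta",
    "read_matrix",
    "write_matrix",
    "load_builtin_matrix",
    "read_reference_group",
    "write_reference_group",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_penalty_table",
    "write_penalty_table",
]

GAP = "-"

#: Canonical residue ordering used by every 20x20 table in the package.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Non-standard residue codes accepted in input sequences but excluded from
#: the 20x20 counting model.
AMBIGUOUS_RESIDUES = frozenset("BZXUOJ*")


class ParseError(ValueError):
    """Raised when an input file violates its expected syntax."""


class DataError(ValueError):
    """Raised when parsed data violates a domain invariant."""


class AminoAlphabet:
    """Ordered alphabet of the 20 standard one-letter residue codes."""

    def __init__(self, letters: str = ALPHABET):
        letters = letters.upper()
        if len(letters) != 20 or len(set(letters)) != 20:
            raise DataError("alphabet must contain exactly 20 unique letters")
        self.letters: str = letters
        self._index = {c: i for i, c in enumerate(letters)}

    def index(self, letter: str) -> int:
        try:
            return self._index[letter]
        except KeyError:
            raise KeyError(f"residue {letter!r} is not in the standard alphabet") from None

    def __contains__(self, letter: str) -> bool:
        return letter in self._index

    def __len__(self) -> int:
        return 20

    def __iter__(self):
        return iter(self.letters)

    def __eq__(self, other) -> bool:
        return isinstance(other, AminoAlphabet) and other.letters == self.letters


#: Module-wide default alphabet instance.
DEFAULT_ALPHABET = AminoAlphabet()


@dataclass(frozen=True)
class GapPenalties:
    """Positive magnitudes of the affine gap cost G(m) = alpha + (m-1)*beta."""

    alpha: int
    beta: int

    def __post_init__(self):
        if self.alpha < 1 or self.beta < 1:
            raise DataError(f"gap penalties must be positive magnitudes, got {self}")

    def cost(self, run_length: int) -> int:
        """Total cost of one gap run of ``run_length`` positions."""
        if run_length < 1:
            raise ValueError("gap run length must be >= 1")
        return self.alpha + (run_length - 1) * self.beta


class SimilarityMatrix:
    """Symmetric 20x20 integer score table over the standard alphabet.

    Scores for pairs involving ambiguity codes (B, Z, X, ``*`` ...) present in
    the source file are kept in ``ambiguity`` and consulted by
    :meth:`score`; pairs with no defined score fall back to 0.
    """

    def __init__(
        self,
        name: str,
        scores: np.ndarray,
        source: str = "general-purpose",
        ambiguity: dict[tuple[str, str], int] | None = None,
        alphabet: AminoAlphabet = DEFAULT_ALPHABET,
    ):
        scores = np.asarray(scores)
        if scores.shape != (20, 20):
            raise DataError(f"similarity matrix must be 20x20, got {scores.shape}")
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(scores == np.round(scores)):
                raise DataError("similarity matrix entries must be integers")
            scores = scores.astype(np.int64)
        if not np.array_equal(scores, scores.T):
            bad = [
                (alphabet.letters[i], alphabet.letters[j])
                for i, j in zip(*np.nonzero(scores != scores.T))
                if i < j
            ]
            raise DataError(f"similarity matrix is not symmetric at pairs {bad}")
        self.name = name
        self.scores = scores.astype(np.int64)
        self.source = source
        self.ambiguity = dict(ambiguity or {})
        self.alphabet = alphabet

    def score(self, a: str, b: str) -> int:
        """Score for residues ``a``/``b``; ambiguity pairs default to 0."""
        if a in self.alphabet and b in self.alphabet:
            return int(self.scores[self.alphabet.index(a), self.alphabet.index(b)])
        val = self.ambiguity.get((a, b), self.ambiguity.get((b, a)))
        return 0 if val is None else int(val)

    def extended_table(self, letters: str) -> np.ndarray:
        """Dense integer score table over an extended residue ordering."""
        n = len(letters)
        table = np.zeros((n, n), dtype=np.int64)
        for i, a in enumerate(letters):
            for j, b in enumerate(letters):
                table[i, j] = self.score(a, b)
        return table

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SimilarityMatrix)
            and self.name == other.name
            and np.array_equal(self.scores, other.scores)
            and self.ambiguity == other.ambiguity
        )

    def __repr__(self) -> str:
        return f"SimilarityMatrix({self.name!r}, source={self.source!r})"


def _strip_gaps(row: str) -> str:
    return row.replace(GAP, "")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped residue strings plus identifiers."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise DataError(
                f"alignment rows of {self.id_a}/{self.id_b} differ in length "
                f"({len(self.row_a)} vs {len(self.row_b)})"
            )
        if len(self.row_a) == 0:
            raise DataError(f"alignment {self.id_a}/{self.id_b} is empty")
        for col, (x, y) in enumerate(zip(self.row_a, self.row_b)):
            if x == GAP and y == GAP:
                raise DataError(
                    f"alignment {self.id_a}/{self.id_b} has an all-gap column at {col}"
                )

    @property
    def seq_a(self) -> str:
        return _strip_gaps(self.row_a)

    @property
    def seq_b(self) -> str:
        return _strip_gaps(self.row_b)

    def __len__(self) -> int:
        return len(self.row_a)

    def aligned_pairs(self) -> frozenset[tuple[int, int]]:
        """Set of (index-in-a, index-in-b) residue-residue correspondences."""
        pairs = []
        ia = ib = 0
        for x, y in zip(self.row_a, self.row_b):
            if x != GAP and y != GAP:
                pairs.append((ia, ib))
            if x != GAP:
                ia += 1
            if y != GAP:
                ib += 1
        return frozenset(pairs)

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.row_a, self.row_b)


@dataclass
class ReferenceGroup:
    """Named set of reference pairwise alignments (one family or fold)."""

    name: str
    alignments: list[PairwiseAlignment]
    subset_tag: str = "other"
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequences:
            seqs: dict[str, str] = {}
            for aln in self.alignments:
                seqs.setdefault(aln.id_a, aln.seq_a)
                seqs.setdefault(aln.id_b, aln.seq_b)
            self.sequences = seqs
        for aln in self.alignments:
            for sid, seq in ((aln.id_a, aln.seq_a), (aln.id_b, aln.seq_b)):
                if self.sequences.get(sid) != seq:
                    raise DataError(
                        f"group {self.name}: sequence {sid} in alignment "
                        f"{aln.id_a}/{aln.id_b} disagrees with the group sequence set"
                    )

    def __len__(self) -> int:
        return len(self.alignments)

    def eligible(self, min_alignments: int = 10) -> bool:
        """Whether the group is large enough for matrix derivation."""
        return len(self.alignments) >= min_alignments


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_VALID_RESIDUES = frozenset(ALPHABET) | AMBIGUOUS_RESIDUES | {GAP}


def read_fasta(path: str | os.PathLike, allow_gaps: bool = False) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercased sequence)`` in file order.

    A strict reader: it reports the offending line for malformed headers,
    empty sequences, and characters outside the accepted residue alphabet.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int):
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {header!r} (line {header_line})")
        records.append((header, seq))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {line_no}")
                header_line = line_no
            else:
                if header is None:
                    raise ParseError(f"{path}: sequence data before any header at line {line_no}")
                seq = line.upper()
                bad = set(seq) - _VALID_RESIDUES
                if not allow_gaps and GAP in seq:
                    bad = bad | {GAP}
                if bad:
                    raise ParseError(
                        f"{path}: invalid residue(s) {sorted(bad)} at line {line_no}"
                    )
                chunks.append(seq)
        flush(line_no=0)
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Similarity-matrix files (NCBI/EMBOSS square text format)
# ---------------------------------------------------------------------------


def read_matrix(
    path: str | os.PathLike,
    name: str | None = None,
    source: str = "general-purpose",
) -> SimilarityMatrix:
    """Parse an NCBI/EMBOSS-style square matrix file.

    The 20 standard residues populate the 20x20 core table; any extra
    columns/rows (B, Z, X, ``*``) are stored as ambiguity scores.
    """
    path = Path(path)
    header: list[str] | None = None
    rows: dict[str, list[int]] = {}
    mat_name = name
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comment = line.lstrip("# ").strip()
                if mat_name is None and comment.lower().startswith("name:"):
                    mat_name = comment.split(":", 1)[1].strip()
                continue
            fields = line.split()
            if header is None:
                if any(len(f) != 1 for f in fields):
                    raise ParseError(f"{path}: malformed matrix header at line {line_no}")
                header = [f.upper() for f in fields]
                continue
            label = fields[0].upper()
            if len(fields) != len(header) + 1:
                raise ParseError(
                    f"{path}: row {label!r} at line {line_no} has {len(fields) - 1} "
                    f"entries, expected {len(header)}"
                )
            try:
                rows[label] = [int(v) for v in fields[1:]]
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer score in row {label!r} at line {line_no}"
                ) from None
    if header is None:
        raise ParseError(f"{path}: no matrix header found")
    missing = [c for c in ALPHABET if c not in header or c not in rows]
    if missing:
        raise ParseError(f"{path}: matrix is missing standard residue(s) {missing}")

    col = {c: i for i, c in enumerate(header)}
    core = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            core[i, j] = rows[a][col[b]]
    asym = [
        (ALPHABET[i], ALPHABET[j])
        for i, j in zip(*np.nonzero(core != core.T))
        if i < j
    ]
    if asym:
        raise ParseError(f"{path}: asymmetric entries for pairs {asym}")

    ambiguity: dict[tuple[str, str], int] = {}
    extra = [c for c in header if c not in ALPHABET]
    for a in rows:
        for b in extra:
            ambiguity[(a, b)] = rows[a][col[b]]
    for a in extra:
        if a in rows:
            for b in header:
                ambiguity.setdefault((a, b), rows[a][col[b]])

    if mat_name is None:
        mat_name = path.stem if path.stem else path.name
    return SimilarityMatrix(mat_name, core, source=source, ambiguity=ambiguity)


def write_matrix(matrix: SimilarityMatrix, path: str | os.PathLike) -> None:
    """Write a matrix in the NCBI square format; round-trips with read_matrix."""
    letters = matrix.alphabet.letters
    width = max(3, max(len(str(int(v))) for v in matrix.scores.ravel()) + 1)
    with open(path, "w") as fh:
        fh.write(f"# name: {matrix.name}\n")
        fh.write(f"# source: {matrix.source}\n")
        fh.write("  " + "".join(f"{c:>{width}}" for c in letters) + "\n")
        for i, a in enumerate(letters):
            vals = "".join(f"{int(v):>{width}d}" for v in matrix.scores[i])
            fh.write(f"{a} {vals}\n")


def load_builtin_matrix(name: str) -> SimilarityMatrix:
    """Load a matrix bundled with the package (``vtml200`` or ``blosum50``)."""
    fname = {"vtml200": "VTML200", "blosum50": "BLOSUM50"}.get(name.lower(), name)
    ref = resources.files("famalign.data").joinpath(fname)
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled matrix named {name!r}")
    with resources.as_file(ref) as p:
        return read_matrix(p, name=fname)


# ---------------------------------------------------------------------------
# Aligned-FASTA pairs and reference groups
# ---------------------------------------------------------------------------


def read_alignment_fasta(path: str | os.PathLike) -> PairwiseAlignment:
    """Read one aligned-FASTA file holding exactly two gapped records."""
    records = read_fasta(path, allow_gaps=True)
    if len(records) != 2:
        raise ParseError(f"{path}: expected exactly 2 aligned records, found {len(records)}")
    (id_a, row_a), (id_b, row_b) = records
    try:
        return PairwiseAlignment(id_a, id_b, row_a, row_b)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from None


def write_alignment_fasta(aln: PairwiseAlignment, path: str | os.PathLike) -> None:
    write_fasta([(aln.id_a, aln.row_a), (aln.id_b, aln.row_b)], path)


def read_reference_group(
    directory: str | os.PathLike,
    name: str | None = None,
    subset_tag: str = "other",
) -> ReferenceGroup:
    """Load a group from a directory of aligned-FASTA pair files."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".fa", ".fasta", ".afa"}
    )
    if not files:
        raise ParseError(f"{directory}: no aligned-FASTA pair files found")
    alignments = [read_alignment_fasta(p) for p in files]
    return ReferenceGroup(
        name=name or directory.name, alignments=alignments, subset_tag=subset_tag
    )


def write_reference_group(group: ReferenceGroup, directory: str | os.PathLike) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, aln in enumerate(group.alignments):
        write_alignment_fasta(aln, directory / f"pair_{k:04d}.fasta")


# ---------------------------------------------------------------------------
# Penalty tables
# ---------------------------------------------------------------------------


def read_penalty_table(path: str | os.PathLike) -> dict[str, GapPenalties]:
    """TSV with columns group_name, alpha, beta."""
    table: dict[str, GapPenalties] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:3] == ["group_name", "alpha", "beta"]:
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}: expected 3 tab-separated columns at line {line_no}")
            table[fields[0]] = GapPenalties(int(fields[1]), int(fields[2]))
    return table


def write_penalty_table(table: dict[str, GapPenalties], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("group_name\talpha\tbeta\n")
        for name in sorted(table):
            g = table[name]
            fh.write(f"{name}\t{g.alpha}\t{g.beta}\n")
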