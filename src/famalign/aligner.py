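"""Global (Needleman-Wunsch) and local (Smith-Waterman) pairwise alignment
with the affine gap cost G(m) = alpha + (m-1)*beta.

The dynamic programming uses the three-state Gotoh recurrence over integer
scores. Traceback tie-break is fixed — diagonal, then gap-in-b (up), then
gap-in-a (left), decided from the terminal cell — so output is deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core_io import (
    ALPHABET,
    GAP,
    DataError,
    GapPenalties,
    PairwiseAlignment,
    SimilarityMatrix,
)

__all__ = ["AlignmentScore", "global_align", "local_align", "score_alignment", "encode"]

#: Alignment scores are plain integers.
AlignmentScore = int

#: Residue codes the aligner accepts, in table order.
EXTENDED_LETTERS = ALPHABET + "BZXUOJ*"
_CODE = {c: i for i, c in enumerate(EXTENDED_LETTERS)}

_NEG = np.int64(-(10**15))

# DP states: 0 = match/mismatch (diagonal), 1 = gap in b (up, consumes a),
# 2 = gap in a (left, consumes b). Order encodes the tie-break preference.


def encode(seq: str) -> np.ndarray:
    """Map a residue string to integer codes over EXTENDED_LETTERS."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError:
        bad = sorted(set(seq.upper()) - set(EXTENDED_LETTERS))
        raise DataError(f"residue(s) {bad} have no defined score") from None


@njit(cache=True)
def _gotoh_global(a, b, table, alpha, beta, free_ends):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in b
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in a
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = 0 if free_ends else -(alpha + (i - 1) * beta)
    for j in range(1, m + 1):
        Y[0, j] = 0 if free_ends else -(alpha + (j - 1) * beta)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = table[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s

            vm = M[i - 1, j] - alpha
            vx = X[i - 1, j] - beta
            vy = Y[i - 1, j] - alpha
            best = vm
            if vx > best:
                best = vx
            if vy > best:
                best = vy
            X[i, j] = best

            vm = M[i, j - 1] - alpha
            vx = X[i, j - 1] - alpha
            vy = Y[i, j - 1] - beta
            best = vm
            if vx > best:
                best = vx
            if vy > best:
                best = vy
            Y[i, j] = best
    return M, X, Y


@njit(cache=True)
def _trace_global(M, X, Y, a, b, table, alpha, beta):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    # terminal state: prefer diagonal, then gap-in-b, then gap-in-a
    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2
    acol = np.empty(n + m, dtype=np.int64)
    bcol = np.empty(n + m, dtype=np.int64)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            acol[k] = i - 1
            bcol[k] = j - 1
            target = M[i, j] - table[a[i - 1], b[j - 1]]
            i -= 1
            j -= 1
            if M[i, j] == target:
                state = 0
            elif X[i, j] == target:
                state = 1
            else:
                state = 2
        elif state == 1:
            acol[k] = i - 1
            bcol[k] = -1
            target = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - alpha == target:
                state = 0
            elif X[i, j] - beta == target:
                state = 1
            elif Y[i, j] - alpha == target:
                state = 2
            # else: boundary column, stay in state 1
        else:
            acol[k] = -1
            bcol[k] = j - 1
            target = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - alpha == target:
                state = 0
            elif X[i, j] - alpha == target:
                state = 1
            elif Y[i, j] - beta == target:
                state = 2
    return score, acol[k:], bcol[k:]


@njit(cache=True)
def _global_align_idx(a, b, table, alpha, beta):  # pragma: no cover - jitted
    M, X, Y = _gotoh_global(a, b, table, alpha, beta, False)
    return _trace_global(M, X, Y, a, b, table, alpha, beta)


@njit(cache=True)
def _local_align_idx(a, b, table, alpha, beta):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    M = np.zeros((n + 1, m + 1), dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    best_score = np.int64(0)
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = table[a[i - 1], b[j - 1]]
            prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            v = prev + s
            M[i, j] = v if v > 0 else 0

            vm = M[i - 1, j] - alpha
            vx = X[i - 1, j] - beta
            vy = Y[i - 1, j] - alpha
            best = vm
            if vx > best:
                best = vx
            if vy > best:
                best = vy
            X[i, j] = best

            vm = M[i, j - 1] - alpha
            vx = X[i, j - 1] - alpha
            vy = Y[i, j - 1] - beta
            best = vm
            if vx > best:
                best = vx
            if vy > best:
                best = vy
            Y[i, j] = best

            if M[i, j] > best_score:
                best_score = M[i, j]
                bi, bj = i, j
    acol = np.empty(n + m, dtype=np.int64)
    bcol = np.empty(n + m, dtype=np.int64)
    k = n + m
    if best_score <= 0:
        return np.int64(0), acol[k:], bcol[k:]
    i, j = bi, bj
    state = 0
    while True:
        if state == 0:
            if M[i, j] == 0:
                break
            k -= 1
            acol[k] = i - 1
            bcol[k] = j - 1
            target = M[i, j] - table[a[i - 1], b[j - 1]]
            i -= 1
            j -= 1
            if target == 0 and M[i, j] == 0:
                break
            if M[i, j] == target:
                state = 0
            elif X[i, j] == target:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            acol[k] = i - 1
            bcol[k] = -1
            target = X[i, j]
            i -= 1
            if M[i, j] - alpha == target:
                state = 0
            elif X[i, j] - beta == target:
                state = 1
            else:
                state = 2
        else:
            k -= 1
            acol[k] = -1
            bcol[k] = j - 1
            target = Y[i, j]
            j -= 1
            if M[i, j] - alpha == target:
                state = 0
            elif X[i, j] - alpha == target:
                state = 1
            else:
                state = 2
    return best_score, acol[k:], bcol[k:]


def _rows_from_columns(seq_a: str, seq_b: str, acol: np.ndarray, bcol: np.ndarray) -> tuple[str, str]:
    row_a = "".join(seq_a[p] if p >= 0 else GAP for p in acol)
    row_b = "".join(seq_b[p] if p >= 0 else GAP for p in bcol)
    return row_a, row_b


def _check_inputs(seq_a: str, seq_b: str):
    if not seq_a or not seq_b:
        raise DataError("cannot align empty sequences")


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: SimilarityMatrix,
    penalties: GapPenalties,
    id_a: str = "a",
    id_b: str = "b",
    free_end_gaps: bool = False,
) -> tuple[PairwiseAlignment, AlignmentScore]:
    """Optimal global alignment of two residue strings.

    End gaps are penalized like internal gaps unless ``free_end_gaps`` is set.
    """
    _check_inputs(seq_a, seq_b)
    a, b = encode(seq_a), encode(seq_b)
    table = matrix.extended_table(EXTENDED_LETTERS)
    if free_end_gaps:
        M, X, Y = _gotoh_global(a, b, table, penalties.alpha, penalties.beta, True)
        score, acol, bcol = _trace_semiglobal(M, X, Y, a, b, table, penalties.alpha, penalties.beta)
    else:
        score, acol, bcol = _global_align_idx(a, b, table, penalties.alpha, penalties.beta)
    row_a, row_b = _rows_from_columns(seq_a.upper(), seq_b.upper(), acol, bcol)
    return PairwiseAlignment(id_a, id_b, row_a, row_b), int(score)


@njit(cache=True)
def _trace_semiglobal(M, X, Y, a, b, table, alpha, beta):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    # free trailing gaps: best cell on the last row/column, any state
    best = M[n, m]
    state = 0
    bi, bj = n, m
    for i in range(n + 1):
        if M[i, m] > best:
            best, state, bi, bj = M[i, m], 0, i, m
        if X[i, m] > best:
            best, state, bi, bj = X[i, m], 1, i, m
        if Y[i, m] > best:
            best, state, bi, bj = Y[i, m], 2, i, m
    for j in range(m + 1):
        if M[n, j] > best:
            best, state, bi, bj = M[n, j], 0, n, j
        if X[n, j] > best:
            best, state, bi, bj = X[n, j], 1, n, j
        if Y[n, j] > best:
            best, state, bi, bj = Y[n, j], 2, n, j
    acol = np.empty(2 * (n + m), dtype=np.int64)
    bcol = np.empty(2 * (n + m), dtype=np.int64)
    k = 2 * (n + m)
    for i in range(n, bi, -1):  # trailing unpenalized gap in b
        k -= 1
        acol[k] = i - 1
        bcol[k] = -1
    for j in range(m, bj, -1):  # trailing unpenalized gap in a
        k -= 1
        acol[k] = -1
        bcol[k] = j - 1
    i, j = bi, bj
    while i > 0 or j > 0:
        if state == 0:
            k -= 1
            acol[k] = i - 1
            bcol[k] = j - 1
            target = M[i, j] - table[a[i - 1], b[j - 1]]
            i -= 1
            j -= 1
            if M[i, j] == target:
                state = 0
            elif X[i, j] == target:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            acol[k] = i - 1
            bcol[k] = -1
            target = X[i, j]
            i -= 1
            if j == 0:
                continue  # free leading gap column
            if M[i, j] - alpha == target:
                state = 0
            elif X[i, j] - beta == target:
                state = 1
            elif Y[i, j] - alpha == target:
                state = 2
        else:
            k -= 1
            acol[k] = -1
            bcol[k] = j - 1
            target = Y[i, j]
            j -= 1
            if i == 0:
                continue
            if M[i, j] - alpha == target:
                state = 0
            elif X[i, j] - alpha == target:
                state = 1
            elif Y[i, j] - beta == target:
                state = 2
    return best, acol[k:], bcol[k:]


def local_align(
    seq_a: str,
    seq_b: str,
    matrix: SimilarityMatrix,
    penalties: GapPenalties,
    id_a: str = "a",
    id_b: str = "b",
) -> tuple[PairwiseAlignment | None, AlignmentScore]:
    """Optimal local alignment; returns (None, 0) when no cell scores > 0."""
    _check_inputs(seq_a, seq_b)
    a, b = encode(seq_a), encode(seq_b)
    table = matrix.extended_table(EXTENDED_LETTERS)
    score, acol, bcol = _local_align_idx(a, b, table, penalties.alpha, penalties.beta)
    if len(acol) == 0:
        return None, 0
    row_a, row_b = _rows_from_columns(seq_a.upper(), seq_b.upper(), acol, bcol)
    return PairwiseAlignment(id_a, id_b, row_a, row_b), int(score)


def local_score(seq_a: str, seq_b: str, table: np.ndarray, penalties: GapPenalties) -> int:
    """Score-only Smith-Waterman over pre-encoded score table (fast path)."""
    a, b = encode(seq_a), encode(seq_b)
    score, _, _ = _local_align_idx(a, b, table, penalties.alpha, penalties.beta)
    return int(score)


def score_alignment(
    aln: PairwiseAlignment, matrix: SimilarityMatrix, penalties: GapPenalties
) -> AlignmentScore:
    """Apply the global-alignment objective to a fixed alignment.

    Residue-residue columns add the matrix score; every maximal gap run of
    length m subtracts alpha + (m-1)*beta. End gaps are charged.
    """
    total = 0
    run_a = run_b = 0  # current gap-run lengths in row_a / row_b
    for x, y in aln.columns():
        if x == GAP:
            run_a += 1
            total -= penalties.alpha if run_a == 1 else penalties.beta
        else:
            run_a = 0
        if y == GAP:
            run_b += 1
            total -= penalties.alpha if run_b == 1 else penalties.beta
        else:
            run_b = 0
        if x != GAP and y != GAP:
            if x not in EXTENDED_LETTERS or y not in EXTENDED_LETTERS:
                raise DataError(f"no score defined for residue pair ({x}, {y})")
            total += matrix.score(x, y)
    return total
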