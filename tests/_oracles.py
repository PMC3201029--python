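"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately share no code with the package's dynamic programming:
alignments are enumerated exhaustively and scored by a standalone affine
cost routine, so agreement with the DP is a genuine cross-check.
"""

from __future__ import annotations

from functools import lru_cache


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as a list of columns.

    A column is (x, y) where x is a residue of ``a`` or None (gap), likewise
    y; (None, None) never occurs.
    """
    if not a and not b:
        yield []
        return
    if a and b:
        for rest in enumerate_global_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest
    if a:
        for rest in enumerate_global_alignments(a[1:], b):
            yield [(a[0], None)] + rest
    if b:
        for rest in enumerate_global_alignments(a, b[1:]):
            yield [(None, b[0])] + rest


def affine_alignment_score(columns, score_of, alpha: int, beta: int) -> int:
    """Score a column list: matrix scores minus alpha + (m-1)*beta per gap run."""
    total = 0
    run_a = run_b = 0
    for x, y in columns:
        if x is None:
            run_a += 1
            total -= alpha if run_a == 1 else beta
        else:
            run_a = 0
        if y is None:
            run_b += 1
            total -= alpha if run_b == 1 else beta
        else:
            run_b = 0
        if x is not None and y is not None:
            total += score_of(x, y)
    return total


def brute_force_global_score(a: str, b: str, score_of, alpha: int, beta: int) -> int:
    """Maximum affine-gap score over every global alignment of a and b."""
    return max(
        affine_alignment_score(cols, score_of, alpha, beta)
        for cols in enumerate_global_alignments(a, b)
    )


def brute_force_local_score(a: str, b: str, score_of, alpha: int, beta: int) -> int:
    """Maximum over all substring pairs of their best global score; >= 0."""
    best = 0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for m in range(j + 1, len(b) + 1):
                    s = brute_force_global_score(a[i:k], b[j:m], score_of, alpha, beta)
                    if s > best:
                        best = s
    return best


@lru_cache(maxsize=None)
def _t_cdf_integral(t: float, df: int) -> float:
    """Student-t upper-tail probability by numerical integration of the pdf.

    Independent of scipy: Simpson's rule on a transformed domain.
    """
    import math

    # pdf normalisation via log-gamma
    logc = (
        math.lgamma((df + 1) / 2.0)
        - math.lgamma(df / 2.0)
        - 0.5 * math.log(df * math.pi)
    )

    def pdf(x: float) -> float:
        return math.exp(logc - ((df + 1) / 2.0) * math.log1p(x * x / df))

    # integrate pdf from t to a far cutoff with Simpson's rule
    hi = max(abs(t) + 60.0, 100.0)
    n = 200001
    h = (hi - t) / (n - 1)
    s = pdf(t) + pdf(hi)
    for i in range(1, n - 1):
        s += pdf(t + i * h) * (4 if i % 2 else 2)
    return s * h / 3.0


def two_sided_t_pvalue(t: float, df: int) -> float:
    return 2.0 * _t_cdf_integral(abs(t), df)
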