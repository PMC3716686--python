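"""Brute-force affine-gap local alignment (Gotoh), used as a test oracle.

This is deliberately a separate, straightforward per-cell implementation,
independent of the seeded engine in :mod:`numtscape.align`, so the two can
be compared against each other.  Tie-breaking during traceback is fixed:
match > substitution > gap in ``a`` > gap in ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass

MAX_CELLS = 10_000_000

_NEG = -(10**9)


@dataclass
class LocalAlignment:
    """One optimal local alignment between two sequences."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x in "ACGT"
        )

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def smith_waterman(a: str, b: str, params) -> LocalAlignment:
    """Exact affine-gap Smith-Waterman optimum via the Gotoh recurrences.

    ``params`` provides match/mismatch/gap_open/gap_extend (e.g. a
    :class:`numtscape.align.ScoringParams`).  N never matches anything.
    Refuses instances above ``MAX_CELLS`` dynamic-programming cells.
    """
    n, m = len(a), len(b)
    if n * m > MAX_CELLS:
        raise ValueError(f"instance too large: {n}x{m} > {MAX_CELLS} cells")
    match, mismatch = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    au = a.upper()
    bu = b.upper()
    best = 0
    bi = bj_idx = 0
    acgt = frozenset("ACGT")
    for i in range(1, n + 1):
        ai = au[i - 1]
        ai_ok = ai in acgt
        Hi, Hp, Ei, Fi, Fp = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == bu[j - 1] and ai_ok) else mismatch
            e = Ei[j - 1] - ge
            eo = Hi[j - 1] - go - ge
            if eo > e:
                e = eo
            Ei[j] = e
            f = Fp[j] - ge
            fo = Hp[j] - go - ge
            if fo > f:
                f = fo
            Fi[j] = f
            h = Hp[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hi[j] = h
            if h > best:
                best = h
                bi, bj_idx = i, j
    score = best
    if score == 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")
    i, j = bi, bj_idx
    a_end, b_end = i, j
    col_a: list[str] = []
    col_b: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            s = match if (au[i - 1] == bu[j - 1] and au[i - 1] in "ACGT") else mismatch
            # tie-break: (mis)match > gap in a > gap in b
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + s:
                col_a.append(a[i - 1])
                col_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in a
            col_a.append("-")
            col_b.append(b[j - 1])
            if H[i][j - 1] - go - ge >= E[i][j - 1] - ge:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # F: gap in b
            col_a.append(a[i - 1])
            col_b.append("-")
            if H[i - 1][j] - go - ge >= F[i - 1][j] - ge:
                i -= 1
                state = "H"
            else:
                i -= 1
    return LocalAlignment(
        score=score,
        a_start=i,
        a_end=a_end,
        b_start=j,
        b_end=b_end,
        aligned_a="".join(reversed(col_a)),
        aligned_b="".join(reversed(col_b)),
    )
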