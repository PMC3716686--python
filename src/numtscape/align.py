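"""Seed-and-extend nucleotide local alignment with Karlin-Altschul statistics.

A small BLASTN-style engine: exact word seeding (one-hit), ungapped X-drop
extension into HSPs, greedy collinear chaining, and affine-gap local
(Smith-Waterman/Gotoh) alignment over the chain's padded rectangle,
vectorized row-wise with numpy.  Raw scores are converted to bit scores and
E-values using the Karlin-Altschul parameters (lambda, K) computed from the
scoring scheme and background composition.

Coordinates are 0-based half-open internally; the tabular writer emits
BLAST outfmt-6 conventions (1-based closed, minus strand as sstart > send).
Query intervals are always reported on the plus strand of the query; the
``strand`` field records whether the reverse complement matched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

UNIFORM_FREQS = (0.25, 0.25, 0.25, 0.25)

_NEG_INF = np.int32(-(10**9) // 2)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def _pair_score_distribution(
    match: int, mismatch: int, freqs: Sequence[float]
) -> tuple[int, np.ndarray]:
    """Distribution of the score of one aligned residue pair under background.

    Returns (lowest score, probability vector p[s - lowest]).
    """
    f = np.asarray(freqs, dtype=float)
    if f.size != 4 or abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
        raise ValueError("background_freqs must be four non-negative values summing to 1")
    p_match = float(np.sum(f * f))
    lo = min(mismatch, 0)
    p = np.zeros(match - lo + 1)
    p[match - lo] += p_match
    p[mismatch - lo] += 1.0 - p_match
    return lo, p


def solve_lambda(
    match: int, mismatch: int, background_freqs: Sequence[float] = UNIFORM_FREQS
) -> float:
    """Solve the Karlin-Altschul transcendental equation for lambda.

    Finds the unique positive root of ``sum_ij p_i p_j exp(lambda * s_ij) = 1``
    for a match/mismatch scoring scheme under the given background
    composition.  Local alignment statistics require a negative expected
    pair score; otherwise a ValueError is raised.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("require match > 0 and mismatch < 0")
    lo, p = _pair_score_distribution(match, mismatch, background_freqs)
    scores = np.arange(lo, lo + p.size)
    if float(np.sum(scores * p)) >= 0:
        raise ValueError(
            "expected pair score is non-negative; local alignment statistics undefined"
        )

    def f(lam: float) -> float:
        return float(np.sum(p * np.exp(lam * scores))) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-12, hi, xtol=1e-14, rtol=8.9e-16))
    assert abs(f(lam)) < 1e-9
    return lam


def karlin_k(
    match: int,
    mismatch: int,
    background_freqs: Sequence[float] = UNIFORM_FREQS,
    lam: float | None = None,
    iterations: int = 120,
) -> float:
    """Karlin-Altschul K for an ungapped match/mismatch scheme (lattice case).

    Uses the classical renewal-theoretic formula
    ``K = d * lambda * exp(-2 sigma) / (H * (1 - exp(-lambda d)))`` with
    sigma accumulated over convolutions of the pair-score distribution and
    d the lattice span of achievable scores.  Reproduces the standard
    tabulated ungapped values (e.g. +1/-2 -> K = 0.621).
    """
    if lam is None:
        lam = solve_lambda(match, mismatch, background_freqs)
    lo, p = _pair_score_distribution(match, mismatch, background_freqs)
    scores = np.arange(lo, lo + p.size)
    d = 0
    for s, ps in zip(scores, p):
        if ps > 0 and s != 0:
            d = math.gcd(d, abs(int(s)))
    entropy_h = lam * float(np.sum(scores * p * np.exp(lam * scores)))
    sigma = 0.0
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(1, iterations + 1):
        cur = np.convolve(cur, p)
        cur_lo += lo
        s = np.arange(cur_lo, cur_lo + cur.size)
        neg = s < 0
        sigma += (
            float(np.sum(cur[neg] * np.exp(lam * s[neg])) + np.sum(cur[~neg])) / j
        )
    return d * lam * math.exp(-2.0 * sigma) / (entropy_h * (1.0 - math.exp(-lam * d)))


# ---------------------------------------------------------------------------
# Parameters and hit record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringParams:
    """Scoring scheme, seeding/extension controls and alignment statistics.

    Defaults mirror classic blastn-style nucleotide scoring: match +1,
    mismatch -2, affine gaps 5/2, word size 11.  ``lambda_`` and ``k``
    are derived from the scheme and background composition unless
    overridden.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11
    xdrop_ungapped: int = 20
    xdrop_gapped: int = 30
    evalue_max: float = 1e-4
    min_hit_length: int = 50
    background_freqs: tuple[float, float, float, float] = UNIFORM_FREQS
    lambda_: float = field(default=0.0)
    k: float = field(default=0.0)
    # engine internals
    gapped_trigger_score: int = 18
    chain_max_gap: int = 100
    chain_diag_band: int = 50
    chain_pad: int = 100
    max_dp_cells: int = 20_000_000
    full_dp_cells: int = 300_000
    containment_frac: float = 0.9
    mask_low_complexity: bool = False

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0:
            raise ValueError("require match > 0 and mismatch <= 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.lambda_ <= 0.0:
            object.__setattr__(
                self, "lambda_", solve_lambda(self.match, self.mismatch, self.background_freqs)
            )
        if self.k <= 0.0:
            object.__setattr__(
                self,
                "k",
                karlin_k(self.match, self.mismatch, self.background_freqs, self.lambda_),
            )

    def evalue(self, score: int, m: int, n: int) -> float:
        """Expected chance hits of at least this score in an m x n search space."""
        return self.k * m * n * math.exp(-self.lambda_ * score)

    def bitscore(self, score: int) -> float:
        return (self.lambda_ * score - math.log(self.k)) / math.log(2.0)

    def score_pair(self, a: str, b: str) -> int:
        # N scores as mismatch
        return self.match if (a == b and a in "ACGT") else self.mismatch


@dataclass
class AlignmentHit:
    """One local alignment (HSP) between a query and a subject sequence."""

    query_id: str
    subject_id: str
    query_start: int  # 0-based half-open, plus strand of the query
    query_end: int
    subject_start: int  # 0-based half-open, plus strand of the subject
    subject_end: int
    strand: str  # '+' or '-'
    aligned_length: int  # alignment columns including gaps
    identity: float  # percent of columns that match
    score: int
    bitscore: float
    evalue: float
    n_mismatch: int = 0
    n_gap_opens: int = 0
    wraps_origin: bool = False

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def subject_span(self) -> int:
        return self.subject_end - self.subject_start


# ---------------------------------------------------------------------------
# Seeding and ungapped extension
# ---------------------------------------------------------------------------

def _kmer_codes(codes: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling base-4 codes of all w-mers; windows containing N are dropped.

    Returns (positions, codes) arrays of equal length.
    """
    n = codes.size
    if n < w:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = n - w + 1
    vals = np.zeros(m, dtype=np.int64)
    for k in range(w):
        vals = vals * 4 + codes[k : k + m]
    bad = (codes == 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    has_n = (cs[w:] - cs[:-w]) > 0
    pos = np.nonzero(~has_n)[0]
    return pos, vals[pos]


def _extend_ungapped(
    q: np.ndarray, s: np.ndarray, qi: int, sj: int, w: int, p: ScoringParams
) -> tuple[int, int, int, int, int]:
    """X-drop ungapped extension of an exact word seed; returns best segment.

    Returns (qstart, qend, sstart, send, score), 0-based half-open.
    """
    match, mismatch, xdrop = p.match, p.mismatch, p.xdrop_ungapped
    score = w * match
    best = score
    best_right = qi + w
    i, j = qi + w, sj + w
    nq, ns = q.size, s.size
    while i < nq and j < ns:
        score += match if (q[i] == s[j] and q[i] != 4) else mismatch
        i += 1
        j += 1
        if score > best:
            best = score
            best_right = i
        elif best - score > xdrop:
            break
    right_score = best
    score = right_score
    best_left = qi
    i, j = qi - 1, sj - 1
    while i >= 0 and j >= 0:
        score += match if (q[i] == s[j] and q[i] != 4) else mismatch
        if score > best:
            best = score
            best_left = i
        elif best - score > xdrop:
            break
        i -= 1
        j -= 1
    diag = sj - qi
    return best_left, best_right, best_left + diag, best_right + diag, best


def _find_hsps(
    q: np.ndarray, s: np.ndarray, p: ScoringParams
) -> list[tuple[int, int, int, int, int]]:
    """One-hit seeded ungapped HSPs, with per-diagonal seed skipping."""
    w = p.word_size
    qpos, qcodes = _kmer_codes(q, w)
    if qpos.size == 0:
        return []
    index: dict[int, list[int]] = {}
    for pos, code in zip(qpos.tolist(), qcodes.tolist()):
        index.setdefault(code, []).append(pos)
    spos, scodes = _kmer_codes(s, w)
    if spos.size == 0:
        return []
    known = np.isin(scodes, np.fromiter(index.keys(), dtype=np.int64))
    hsps: list[tuple[int, int, int, int, int]] = []
    diag_end: dict[int, int] = {}
    for sj, code in zip(spos[known].tolist(), scodes[known].tolist()):
        for qi in index[code]:
            d = sj - qi
            if diag_end.get(d, -1) >= sj + w:
                continue
            qs, qe, ss, se, score = _extend_ungapped(q, s, qi, sj, w, p)
            diag_end[d] = se
            if qe - qs >= w:
                hsps.append((qs, qe, ss, se, score))
    return hsps


def _chain_hsps(
    hsps: list[tuple[int, int, int, int, int]], p: ScoringParams
) -> list[list[tuple[int, int, int, int, int]]]:
    """Greedy single-linkage chaining of near-collinear HSPs.

    Chains are indexed by diagonal bucket so chaining stays near-linear in
    the number of HSPs even on genome-scale subjects.
    """
    if not hsps:
        return []
    band = max(1, p.chain_diag_band)
    hsps = sorted(hsps, key=lambda h: (h[2], h[0]))
    chains: list[dict] = []
    buckets: dict[int, list[int]] = {}
    for h in hsps:
        qs, qe, ss, se, score = h
        d = ss - qs
        # among all joinable chains prefer the strongest (then nearest
        # diagonal), so stray micro-HSPs cannot hijack a real alignment
        target = None
        for bb in (d // band - 1, d // band, d // band + 1):
            for ci in buckets.get(bb, ()):
                c = chains[ci]
                if (
                    abs(d - c["diag"]) <= band
                    and ss - c["se"] <= p.chain_max_gap
                    and qs - c["qe"] <= p.chain_max_gap
                    and qe > c["qs"]
                ):
                    if target is None or (c["score"], -abs(d - c["diag"])) > (
                        target["score"],
                        -abs(d - target["diag"]),
                    ):
                        target = c
        if target is not None:
            target["members"].append(h)
            target["qs"] = min(target["qs"], qs)
            target["qe"] = max(target["qe"], qe)
            target["se"] = max(target["se"], se)
            old_bucket = target["diag"] // band
            target["diag"] = d
            target["score"] = max(target["score"], score)
            if d // band != old_bucket:
                buckets.setdefault(d // band, []).append(target["index"])
        else:
            ci = len(chains)
            chains.append(
                {
                    "members": [h],
                    "qs": qs,
                    "qe": qe,
                    "ss": ss,
                    "se": se,
                    "diag": d,
                    "score": score,
                    "index": ci,
                }
            )
            buckets.setdefault(d // band, []).append(ci)
    return [c["members"] for c in chains if c["score"] >= p.gapped_trigger_score]


# ---------------------------------------------------------------------------
# Gapped alignment (vectorized Gotoh, local)
# ---------------------------------------------------------------------------

def _gotoh_local(
    a: np.ndarray, b: np.ndarray, p: ScoringParams
) -> tuple[int, int, int, int, int, int, int, int, int] | None:
    """Affine-gap Smith-Waterman over the full a x b matrix (numpy row-wise).

    The horizontal gap state is computed with the running-maximum trick
    (E[j] = max_k H[k] - open - (j-k)*extend), which is exact for affine
    costs.  Returns (score, qs, qe, ss, se, matches, mismatches, gap_opens,
    columns) of one optimal local alignment, or None if the optimum is 0.
    """
    n, m = a.size, b.size
    if n == 0 or m == 0:
        return None
    match, mismatch = np.int32(p.match), np.int32(p.mismatch)
    go, ge = np.int32(p.gap_open), np.int32(p.gap_extend)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    idx = np.arange(m + 1, dtype=np.int32)
    valid_b = b != 4
    for i in range(1, n + 1):
        ai = a[i - 1]
        sub = np.where((b == ai) & valid_b & (ai != 4), match, mismatch)
        diag = H[i - 1, :-1] + sub
        F[i, 1:] = np.maximum(F[i - 1, 1:] - ge, H[i - 1, 1:] - go - ge)
        h0 = np.maximum(0, np.maximum(np.concatenate(([np.int32(0)], diag)), F[i]))
        h0[0] = 0
        run = np.maximum.accumulate(h0 + idx * ge)
        E[i, 1:] = run[:-1] - go - ge * idx[1:]
        H[i] = np.maximum(h0, E[i])
        H[i, 0] = 0
    best = int(H.max())
    if best <= 0:
        return None
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(i), int(j)
    qe, se = i, j
    matches = mismatches = gap_opens = cols = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4 and b[j - 1] != 4) else mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
                if sub == match:
                    matches += 1
                else:
                    mismatches += 1
                cols += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failure in H state")
        elif state == "E":
            cols += 1
            if j > 0 and H[i, j - 1] - go - ge == E[i, j]:
                j -= 1
                gap_opens += 1
                state = "H"
            elif j > 0 and E[i, j - 1] - ge == E[i, j]:
                j -= 1
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failure in E state")
        else:  # F
            cols += 1
            if i > 0 and H[i - 1, j] - go - ge == F[i, j]:
                i -= 1
                gap_opens += 1
                state = "H"
            elif i > 0 and F[i - 1, j] - ge == F[i, j]:
                i -= 1
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failure in F state")
    return best, i, qe, j, se, matches, mismatches, gap_opens, cols


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def _hits_from_chain(
    chain: list[tuple[int, int, int, int, int]],
    q: np.ndarray,
    s: np.ndarray,
    p: ScoringParams,
) -> list[tuple[int, int, int, int, int, int, int, int, int]]:
    """Gapped alignment over a chain's padded rectangle.

    Falls back to reporting the chain's HSPs as ungapped alignments when
    the rectangle would exceed the DP cell cap (e.g. a full-length
    self-alignment, which needs no gaps anyway).
    """
    qs = min(h[0] for h in chain)
    qe = max(h[1] for h in chain)
    ss = min(h[2] for h in chain)
    se = max(h[3] for h in chain)
    pad = p.chain_pad
    q0, q1 = max(0, qs - pad), min(q.size, qe + pad)
    s0, s1 = max(0, ss - pad), min(s.size, se + pad)
    out = []
    cells = (q1 - q0) * (s1 - s0)
    # Single exact-diagonal HSPs need no gapped pass unless the matrix is
    # small enough for an exact polish; multi-HSP chains imply indels.
    do_dp = (len(chain) > 1 and cells <= p.max_dp_cells) or (
        len(chain) == 1 and cells <= p.full_dp_cells
    )
    if do_dp:
        res = _gotoh_local(q[q0:q1], s[s0:s1], p)
        if res is not None:
            score, aqs, aqe, ass_, ase, mt, mm, gaps, cols = res
            out.append((score, q0 + aqs, q0 + aqe, s0 + ass_, s0 + ase, mt, mm, gaps, cols))
            return out
    for qs, qe, ss, se, score in chain:
        seg_q = q[qs:qe]
        seg_s = s[ss:se]
        mt = int(np.sum((seg_q == seg_s) & (seg_q != 4)))
        out.append((score, qs, qe, ss, se, mt, (qe - qs) - mt, 0, qe - qs))
    return out


def search(
    query: str,
    subject: str,
    params: ScoringParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    search_space: tuple[int, int] | None = None,
) -> list[AlignmentHit]:
    """Local alignment search of query against subject on both strands.

    Returns hits sorted by E-value (ties broken by score and coordinates);
    contained lower-scoring hits are suppressed.  ``search_space`` overrides
    the (m, n) effective lengths used for E-values, e.g. when the query was
    extended for circular topology or the subject is one scaffold of a
    larger genome.
    """
    if params is None:
        params = ScoringParams()
    if not query or not subject or params.word_size > len(query):
        return []
    s_codes = encode(subject)
    m_eff, n_eff = search_space if search_space else (len(query), len(subject))
    raw: list[tuple[str, tuple[int, int, int, int, int, int, int, int, int]]] = []
    small = len(query) * len(subject) <= params.full_dp_cells
    for strand in ("+", "-"):
        q_str = query if strand == "+" else revcomp(query)
        q_codes = encode(q_str)
        hsps = _find_hsps(q_codes, s_codes, params)
        if small:
            # desk-scale: one exact gapped pass whenever any word seed exists
            if hsps:
                res = _gotoh_local(q_codes, s_codes, params)
                if res is not None:
                    raw.append((strand, res))
            continue
        for chain in _chain_hsps(hsps, params):
            for rec in _hits_from_chain(chain, q_codes, s_codes, params):
                raw.append((strand, rec))
    hits: list[AlignmentHit] = []
    qlen = len(query)
    for strand, (score, qs, qe, ss, se, mt, mm, gaps, cols) in raw:
        if strand == "-":
            qs, qe = qlen - qe, qlen - qs
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                query_start=qs,
                query_end=qe,
                subject_start=ss,
                subject_end=se,
                strand=strand,
                aligned_length=cols,
                identity=100.0 * mt / cols if cols else 0.0,
                score=score,
                bitscore=params.bitscore(score),
                evalue=params.evalue(score, m_eff, n_eff),
                n_mismatch=mm,
                n_gap_opens=gaps,
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_start, h.query_start))
    return _dedup_contained(hits, params.containment_frac)


def _interval_overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _dedup_contained(hits: list[AlignmentHit], frac: float) -> list[AlignmentHit]:
    """Drop hits whose query and subject intervals are near-contained in a
    kept higher-scoring hit on the same strand."""
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if k.strand != h.strand:
                continue
            qo = _interval_overlap(h.query_start, h.query_end, k.query_start, k.query_end)
            so = _interval_overlap(
                h.subject_start, h.subject_end, k.subject_start, k.subject_end
            )
            if (
                h.query_span > 0
                and h.subject_span > 0
                and qo >= frac * h.query_span
                and so >= frac * h.subject_span
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Circular topology support
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularMap:
    """Coordinate fold for a circular molecule searched via linear extension."""

    length: int

    def fold_interval(self, start: int, end: int) -> tuple[int, int, bool]:
        """Map an interval on the extended sequence back onto the circle.

        Returns (start, end, wraps_origin); a wrapping interval keeps
        ``end`` > ``length`` so that ``end - start`` stays the true span,
        with both endpoints taken mod length when wraps_origin is False.
        """
        wraps = start < self.length <= end
        if wraps:
            return start, end, True
        return start % self.length, ((end - 1) % self.length) + 1, False


def circularize(seq: str, max_hit_span: int, topology: str = "circular") -> tuple[str, CircularMap]:
    """Extend a circular sequence past its origin so hits can cross it.

    Appends a prefix of length ``max_hit_span - 1``; downstream dedup must
    remove cyclic duplicates (see :func:`dedup_circular_hits`).
    """
    if topology != "circular":
        raise ValueError("circularize applies only to circular topology")
    if max_hit_span > len(seq):
        raise ValueError("max_hit_span exceeds molecule length")
    return seq + seq[: max_hit_span - 1], CircularMap(len(seq))


def dedup_circular_hits(hits: Iterable[AlignmentHit], cmap: CircularMap) -> list[AlignmentHit]:
    """Fold query intervals of hits found on a circular-extended query and
    drop cyclic duplicates of already-reported hits."""
    out: list[AlignmentHit] = []
    seen: set[tuple[int, int, int, int, str]] = set()
    for h in sorted(hits, key=lambda h: (h.evalue, -h.score, h.subject_start)):
        qs, qe, wraps = cmap.fold_interval(h.query_start, h.query_end)
        key = (qs % cmap.length, (qe - 1) % cmap.length + 1, h.subject_start, h.subject_end, h.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(replace(h, query_start=qs, query_end=qe, wraps_origin=wraps))
    return out


# ---------------------------------------------------------------------------
# Tabular (BLAST outfmt 6) I/O
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def hits_to_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits as BLAST outfmt-6 (1-based closed; minus strand: sstart > send)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.subject_start + 1, h.subject_end
            else:
                ss, se = h.subject_end, h.subject_start + 1
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity:.2f}\t{h.aligned_length}\t"
                f"{h.n_mismatch}\t{h.n_gap_opens}\t{h.query_start + 1}\t{h.query_end}\t"
                f"{ss}\t{se}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def hits_from_tsv(path) -> list[AlignmentHit]:
    """Read BLAST outfmt-6 rows back into AlignmentHit records."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qs, qe = int(f[6]) - 1, int(f[7])
            ss_raw, se_raw = int(f[8]), int(f[9])
            if ss_raw <= se_raw:
                strand, ss, se = "+", ss_raw - 1, se_raw
            else:
                strand, ss, se = "-", se_raw - 1, ss_raw
            length = int(f[3])
            identity = float(f[2])
            hits.append(
                AlignmentHit(
                    query_id=f[0],
                    subject_id=f[1],
                    query_start=qs,
                    query_end=qe,
                    subject_start=ss,
                    subject_end=se,
                    strand=strand,
                    aligned_length=length,
                    identity=identity,
                    score=0,
                    bitscore=float(f[11]),
                    evalue=float(f[10]),
                    n_mismatch=int(f[4]),
                    n_gap_opens=int(f[5]),
                )
            )
    return hits
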