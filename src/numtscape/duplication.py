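"""Duplication families, split NUMT pairs, and interruption classification.

Two NUMTs that originate from the same mitochondrial location (reciprocal
origin overlap above a threshold) but sit at distinct nuclear loci are
interpreted as one insertion followed by nuclear duplication; families are
connected components of that relation.  Conversely, two NUMTs with nearly
contiguous mitochondrial origins separated by a large nuclear gap point at
one insertion interrupted by an interposed element; the gap sequence is
extracted and classified as low-complexity (windowed trinucleotide
entropy) or transposable-element-derived (alignment against a repeat
library).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from numtscape.align import ScoringParams, search
from numtscape.calling import Numt


@dataclass
class NumtFamily:
    family_id: str
    member_numt_ids: list[str]
    mito_chromosome: str
    representative_interval: tuple[int, int]

    @property
    def family_size(self) -> int:
        return len(self.member_numt_ids)


@dataclass
class SplitPair:
    """Two NUMTs that look like one interrupted insertion."""

    numt_id_a: str
    numt_id_b: str
    scaffold: str
    gap_start: int  # nuclear gap interval (0-based half-open)
    gap_end: int
    mito_gap: int
    strand: str


@dataclass
class InterruptionCall:
    pair: tuple[str, str]
    gap_start: int
    gap_end: int
    mito_gap: int
    classification: str  # low_complexity / transposable_element / other
    evidence: str = ""
    low_entropy_fraction: float = 0.0


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|); 0 for empty intervals."""
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    return min(ov / la, ov / lb)


def _nuclear_distinct(a: Numt, b: Numt) -> bool:
    if a.nuclear_scaffold != b.nuclear_scaffold:
        return True
    return a.nuclear_end <= b.nuclear_start or b.nuclear_end <= a.nuclear_start


def group_duplicates(
    numts: Sequence[Numt], min_reciprocal_overlap: float = 0.8
) -> list[NumtFamily]:
    """Group NUMTs into duplication families by shared mitochondrial origin.

    Two NUMTs match when their origin intervals on the same mitochondrial
    chromosome reciprocally overlap at least ``min_reciprocal_overlap`` and
    their nuclear loci are distinct.  Families are the connected components
    of the match relation; singletons are not reported.
    """
    n = len(numts)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    by_chrom: dict[str, list[int]] = {}
    for i, nu in enumerate(numts):
        by_chrom.setdefault(nu.mito_chromosome, []).append(i)
    for idxs in by_chrom.values():
        idxs = sorted(idxs, key=lambda i: numts[i].mito_start)
        for ai in range(len(idxs)):
            a = numts[idxs[ai]]
            for bi in range(ai + 1, len(idxs)):
                b = numts[idxs[bi]]
                if b.mito_start >= a.mito_end:
                    break
                if (
                    reciprocal_overlap(a.mito_interval, b.mito_interval)
                    >= min_reciprocal_overlap
                    and _nuclear_distinct(a, b)
                ):
                    union(idxs[ai], idxs[bi])

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    families = []
    rank = 0
    for root in sorted(comps):
        members = comps[root]
        if len(members) < 2:
            continue
        rank += 1
        rep = numts[members[0]]
        families.append(
            NumtFamily(
                family_id=f"family_{rank:03d}",
                member_numt_ids=[numts[i].id for i in members],
                mito_chromosome=rep.mito_chromosome,
                representative_interval=rep.mito_interval,
            )
        )
    return families


def family_size_histogram(families: Sequence[NumtFamily]) -> dict[int, int]:
    return dict(Counter(f.family_size for f in families))


def find_split_pairs(
    numts: Sequence[Numt],
    max_mito_gap: int = 100,
    min_nuclear_separation: int = 50,
    max_extraction: int = 50_000,
    min_mito_gap: int = -20,
) -> list[SplitPair]:
    """Find NUMT pairs from neighbouring mtDNA origins at separated nuclear loci.

    Pairs must lie on the same scaffold and strand and be collinear: the
    nuclear-downstream member continues the mitochondrial origin (for the
    minus strand, in reversed mitochondrial order).  The mitochondrial gap
    must be within [min_mito_gap, max_mito_gap] (a small negative overlap
    tolerates alignment end slop) and the nuclear gap within
    [min_nuclear_separation, max_extraction].
    """
    ordered = sorted(numts, key=lambda n: (n.nuclear_scaffold, n.nuclear_start))
    pairs: list[SplitPair] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if b.nuclear_scaffold != a.nuclear_scaffold:
                break
            gap = b.nuclear_start - a.nuclear_end
            if gap > max_extraction:
                break
            if gap < min_nuclear_separation:
                continue
            if a.strand != b.strand or a.mito_chromosome != b.mito_chromosome:
                continue
            if a.strand == "+":
                mito_gap = b.mito_start - a.mito_end
            else:
                mito_gap = a.mito_start - b.mito_end
            if not (min_mito_gap <= mito_gap <= max_mito_gap):
                continue
            pairs.append(
                SplitPair(
                    numt_id_a=a.id,
                    numt_id_b=b.id,
                    scaffold=a.nuclear_scaffold,
                    gap_start=a.nuclear_end,
                    gap_end=b.nuclear_start,
                    mito_gap=mito_gap,
                    strand=a.strand,
                )
            )
    return pairs


def extract_gap_sequence(pair: SplitPair, scaffolds: Mapping[str, str]) -> str:
    seq = scaffolds[pair.scaffold]
    if pair.gap_end > len(seq):
        raise ValueError(
            f"gap extraction beyond scaffold bounds: {pair.scaffold}:{pair.gap_end}"
        )
    return seq[pair.gap_start : pair.gap_end]


def trinucleotide_entropy(window: str) -> float:
    """Shannon entropy (bits) of overlapping trinucleotides in a window."""
    counts = Counter(window[i : i + 3] for i in range(len(window) - 2))
    counts = {k: v for k, v in counts.items() if "N" not in k}
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def classify_interruption(
    pair: SplitPair,
    gap_sequence: str,
    repeat_library: Mapping[str, str] | None = None,
    params: ScoringParams | None = None,
    entropy_threshold: float = 1.2,
    low_fraction: float = 0.5,
    window: int = 64,
    step: int = 32,
) -> InterruptionCall:
    """Classify an interposed sequence as TE-derived, low-complexity, or other.

    A repeat-library alignment (E <= evalue_max, >= min_hit_length) takes
    precedence; otherwise the gap is low-complexity when at least
    ``low_fraction`` of its sliding windows fall below the trinucleotide
    entropy threshold.
    """
    if not gap_sequence:
        raise ValueError("empty gap sequence")
    if params is None:
        params = ScoringParams()
    evidence = ""
    classification = None
    if repeat_library:
        best = None
        for name, lib_seq in repeat_library.items():
            for h in search(gap_sequence, lib_seq, params, query_id="gap", subject_id=name):
                if h.evalue <= params.evalue_max and h.subject_span >= params.min_hit_length:
                    if best is None or h.evalue < best[1]:
                        best = (name, h.evalue)
        if best is not None:
            classification = "transposable_element"
            evidence = best[0]

    windows = [
        gap_sequence[i : i + window]
        for i in range(0, max(1, len(gap_sequence) - window + 1), step)
    ] or [gap_sequence]
    low = sum(1 for w in windows if trinucleotide_entropy(w) < entropy_threshold)
    frac = low / len(windows)
    if classification is None:
        if frac >= low_fraction:
            classification = "low_complexity"
            evidence = f"entropy<{entropy_threshold} in {low}/{len(windows)} windows"
        else:
            classification = "other"
    return InterruptionCall(
        pair=(pair.numt_id_a, pair.numt_id_b),
        gap_start=pair.gap_start,
        gap_end=pair.gap_end,
        mito_gap=pair.mito_gap,
        classification=classification,
        evidence=evidence,
        low_entropy_fraction=frac,
    )
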