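"""Genic context of NUMTs: gene density around each insertion and precise
localization within gene models.

Density uses a fixed window centred on the NUMT (default 10 kbp added in
total, i.e. 5 kbp of padding per side) and an interval-tree gene index:
no genes -> non-genic, 1-2 genes -> low density, more than two -> high
density.  Localization reports the intron (numbered in transcription
order), UTR, or exon overlap, together with the insertion's orientation
relative to the host gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from numtscape.calling import Numt
from numtscape.gffio import GeneModel

DENSITY_NON_GENIC = "non_genic"
DENSITY_LOW = "low_density"
DENSITY_HIGH = "high_density"


@dataclass
class ContextCall:
    numt_id: str
    density: str
    genes_in_window: int
    host_gene: str | None = None
    feature: str = "intergenic"  # intron_<i> / exon / utr5 / utr3 / intergenic
    same_orientation_as_host: bool | None = None


class GeneIndex:
    """Per-scaffold interval trees over gene spans."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.trees: dict[str, IntervalTree] = {}
        self.genes = list(genes)
        for g in genes:
            self.trees.setdefault(g.scaffold, IntervalTree()).addi(g.start, g.end, g)

    def overlapping(self, scaffold: str, start: int, end: int) -> list[GeneModel]:
        tree = self.trees.get(scaffold)
        if tree is None or start >= end:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)), key=lambda g: g.id)


def classify_density(
    numt: Numt,
    index: GeneIndex,
    window_bp: int = 10_000,
    scaffold_length: int | None = None,
) -> tuple[str, int]:
    """Count genes intersecting the padded window and map to a category.

    The window is the NUMT span padded by ``window_bp/2`` on each side,
    clipped to the scaffold; intersection is half-open, so a gene ending
    exactly at the window start does not count.
    """
    pad = window_bp // 2
    lo = max(0, numt.nuclear_start - pad)
    hi = numt.nuclear_end + pad
    if scaffold_length is not None:
        hi = min(hi, scaffold_length)
    count = len(index.overlapping(numt.nuclear_scaffold, lo, hi))
    if count == 0:
        return DENSITY_NON_GENIC, 0
    if count <= 2:
        return DENSITY_LOW, count
    return DENSITY_HIGH, count


def locate_in_gene(numt: Numt, gene: GeneModel) -> tuple[str, bool]:
    """Locate a NUMT within one gene model.

    Precedence: wholly inside an intron (numbered in transcription order)
    -> wholly inside an annotated UTR -> any exon overlap -> intergenic
    (partial overlap with the gene's edge).  Returns (feature,
    same_orientation_as_host).
    """
    s, e = numt.nuclear_start, numt.nuclear_end
    same = numt.strand == gene.strand
    for idx, (is_, ie) in enumerate(gene.introns):
        if is_ <= s and e <= ie:
            return f"intron_{gene.intron_number(idx)}", same
    for utr, name in ((gene.utr5, "utr5"), (gene.utr3, "utr3")):
        if utr is not None and utr[0] <= s and e <= utr[1]:
            return name, same
    for es, ee in gene.exons:
        if max(s, es) < min(e, ee):
            return "exon", same
    return "intergenic", same


def classify_context(
    numt: Numt,
    index: GeneIndex,
    window_bp: int = 10_000,
    scaffold_length: int | None = None,
) -> ContextCall:
    """Full context call: density category plus host-gene localization.

    A NUMT overlapping several genes is assigned to the gene with the
    largest overlap (ties broken by gene id) so each NUMT has one host.
    """
    density, count = classify_density(numt, index, window_bp, scaffold_length)
    hosts = index.overlapping(numt.nuclear_scaffold, numt.nuclear_start, numt.nuclear_end)
    call = ContextCall(numt_id=numt.id, density=density, genes_in_window=count)
    if hosts:
        def overlap(g: GeneModel) -> int:
            return min(numt.nuclear_end, g.end) - max(numt.nuclear_start, g.start)

        host = max(hosts, key=lambda g: (overlap(g), [-ord(c) for c in g.id]))
        feature, same = locate_in_gene(numt, host)
        if feature != "intergenic":
            call.host_gene = host.id
            call.feature = feature
            call.same_orientation_as_host = same
    return call


def classify_contexts(
    numts: Sequence[Numt],
    genes: Sequence[GeneModel],
    window_bp: int = 10_000,
    scaffold_lengths: dict[str, int] | None = None,
) -> list[ContextCall]:
    index = GeneIndex(genes)
    return [
        classify_context(
            n,
            index,
            window_bp,
            scaffold_lengths.get(n.nuclear_scaffold) if scaffold_lengths else None,
        )
        for n in numts
    ]


def density_counts(calls: Sequence[ContextCall]) -> dict[str, int]:
    out = {DENSITY_NON_GENIC: 0, DENSITY_LOW: 0, DENSITY_HIGH: 0}
    for c in calls:
        out[c.density] += 1
    return out
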