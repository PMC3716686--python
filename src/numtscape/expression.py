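"""Expressed-NUMT detection from EST sets.

Pure mitochondrial transcripts (contaminants) are filtered out; ESTs in
which an mtDNA-homologous block is joined to nuclear sequence are kept as
chimeric candidates, placed back onto the nuclear genome, linked to called
NUMTs, and classified as 5'UTR or internal insertions.  Reading frames are
screened for internal stop codons under the universal genetic code and the
mold/protozoan/coelenterate mitochondrial code (NCBI translation table 4,
where TGA encodes tryptophan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Data import CodonTable

from numtscape.align import AlignmentHit, ScoringParams, revcomp, search
from numtscape.calling import Numt
from numtscape.gffio import GeneModel

GENETIC_CODES = {"universal": 1, "mold_mito": 4}


@dataclass
class EstBlocks:
    """Decomposition of one EST into mt-homologous and other blocks."""

    est_id: str
    category: str  # pure_mito / chimeric / no_mt
    mt_blocks: list[tuple[int, int]] = field(default_factory=list)
    non_mt_blocks: list[tuple[int, int]] = field(default_factory=list)
    mt_coverage: float = 0.0
    mt_identity: float = 0.0
    hits: list[AlignmentHit] = field(default_factory=list)


@dataclass
class Placement:
    scaffold: str
    start: int
    end: int
    coverage: float
    ambiguous: bool = False
    alternatives: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class ExpressedNumt:
    est_id: str
    mt_chromosome: str
    mt_block: tuple[int, int]
    mt_identity: float
    non_mt_blocks: list[tuple[int, int]]
    placement: Placement | None = None
    linked_numt_id: str | None = None
    insertion_class: str = "unplaced"  # utr5 / internal / unplaced
    stop_codon_report: dict = field(default_factory=dict)


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def screen_ests(
    ests: Mapping[str, str],
    mito_chromosomes: Mapping[str, str],
    params: ScoringParams | None = None,
    pure_coverage: float = 0.95,
    pure_identity: float = 98.0,
    min_flank: int = 50,
) -> dict[str, EstBlocks]:
    """Partition ESTs into pure-mito, chimeric, and no-mt classes.

    An EST is pure mitochondrial when accepted mtDNA alignments cover at
    least ``pure_coverage`` of its length at a length-weighted identity of
    at least ``pure_identity`` percent; chimeric when at least one accepted
    alignment remains and a contiguous non-mt block of >= ``min_flank`` bp
    is left over; otherwise it carries no usable mt homology.
    """
    if params is None:
        params = ScoringParams()
    out: dict[str, EstBlocks] = {}
    for est_id, seq in ests.items():
        hits: list[AlignmentHit] = []
        for chrom, cseq in mito_chromosomes.items():
            hs = search(seq, cseq, params, query_id=est_id, subject_id=chrom)
            hits.extend(
                h
                for h in hs
                if h.evalue <= params.evalue_max and h.query_span >= params.min_hit_length
            )
        blocks = _merge([(h.query_start, h.query_end) for h in hits])
        covered = sum(e - s for s, e in blocks)
        coverage = covered / len(seq) if seq else 0.0
        identity = (
            sum(h.identity * h.query_span for h in hits) / sum(h.query_span for h in hits)
            if hits
            else 0.0
        )
        non_mt: list[tuple[int, int]] = []
        prev = 0
        for s, e in blocks + [(len(seq), len(seq))]:
            if s - prev >= min_flank:
                non_mt.append((prev, s))
            prev = max(prev, e)
        if hits and coverage >= pure_coverage and identity >= pure_identity:
            category = "pure_mito"
        elif hits and non_mt:
            category = "chimeric"
        else:
            category = "no_mt"
        out[est_id] = EstBlocks(
            est_id=est_id,
            category=category,
            mt_blocks=blocks,
            non_mt_blocks=non_mt,
            mt_coverage=coverage,
            mt_identity=identity,
            hits=hits,
        )
    return out


def place_in_genome(
    est_id: str,
    est_seq: str,
    blocks: EstBlocks,
    scaffolds: Mapping[str, str],
    numts: Sequence[Numt],
    genes: Sequence[GeneModel] = (),
    params: ScoringParams | None = None,
    min_locus_coverage: float = 0.9,
    locus_join: int = 5_000,
) -> ExpressedNumt:
    """Place a chimeric EST on the nuclear genome and classify the insertion.

    Hits to one scaffold within ``locus_join`` bp are grouped into a
    candidate locus; a locus is accepted when it covers at least
    ``min_locus_coverage`` of the EST.  The placed mt block is linked to an
    overlapping called NUMT if one exists, and classified ``utr5`` when it
    falls inside the 5'UTR of an annotated host gene, else ``internal``.
    """
    if params is None:
        params = ScoringParams()
    best_hit = max(blocks.hits, key=lambda h: h.bitscore, default=None)
    result = ExpressedNumt(
        est_id=est_id,
        mt_chromosome=best_hit.subject_id if best_hit else "",
        mt_block=blocks.mt_blocks[0] if blocks.mt_blocks else (0, 0),
        mt_identity=blocks.mt_identity,
        non_mt_blocks=blocks.non_mt_blocks,
    )
    # collect loci across scaffolds
    loci: list[tuple[float, str, int, int, list[AlignmentHit]]] = []
    for name, sseq in scaffolds.items():
        hs = [
            h
            for h in search(est_seq, sseq, params, query_id=est_id, subject_id=name)
            if h.evalue <= params.evalue_max
        ]
        hs.sort(key=lambda h: h.subject_start)
        group: list[AlignmentHit] = []
        for h in hs + [None]:
            if group and (
                h is None or h.subject_start - group[-1].subject_end > locus_join
            ):
                cov = sum(e - s for s, e in _merge([(x.query_start, x.query_end) for x in group]))
                loci.append(
                    (
                        cov / len(est_seq),
                        name,
                        min(x.subject_start for x in group),
                        max(x.subject_end for x in group),
                        group,
                    )
                )
                group = []
            if h is not None:
                group.append(h)
    loci = [l for l in loci if l[0] >= min_locus_coverage]
    if not loci:
        return result
    loci.sort(key=lambda l: (-l[0], l[1], l[2]))
    top = loci[0]
    ambiguous = len(loci) > 1 and abs(loci[1][0] - top[0]) < 1e-9
    result.placement = Placement(
        scaffold=top[1],
        start=top[2],
        end=top[3],
        coverage=top[0],
        ambiguous=ambiguous,
        alternatives=[(l[1], l[2], l[3]) for l in loci[1:]] if ambiguous else [],
    )
    # project the EST's mt block through the overlapping locus hit onto the
    # genome (linear interpolation; indels shift this by at most a few bp)
    mt_genomic: tuple[int, int] | None = None
    for h in top[4]:
        for s, e in blocks.mt_blocks:
            qs, qe = max(h.query_start, s), min(h.query_end, e)
            if qs < qe:
                if h.strand == "+":
                    mt_genomic = (
                        h.subject_start + (qs - h.query_start),
                        h.subject_start + (qe - h.query_start),
                    )
                else:
                    mt_genomic = (
                        h.subject_end - (qe - h.query_start),
                        h.subject_end - (qs - h.query_start),
                    )
                break
        if mt_genomic:
            break
    if mt_genomic:
        for n in numts:
            if n.nuclear_scaffold == top[1] and max(n.nuclear_start, mt_genomic[0]) < min(
                n.nuclear_end, mt_genomic[1]
            ):
                result.linked_numt_id = n.id
                break
        result.insertion_class = "internal"
        for g in genes:
            if g.scaffold != top[1] or not g.cds or g.utr5 is None:
                continue
            if g.utr5[0] <= mt_genomic[0] and mt_genomic[1] <= g.utr5[1]:
                result.insertion_class = "utr5"
                break
    else:
        result.insertion_class = "internal"
    return result


def check_translation(sequence: str, code_table: str = "universal") -> dict[str, dict]:
    """Per-frame internal-stop report under a named genetic code.

    Frames are +1/+2/+3 on the given strand and -1/-2/-3 on the reverse
    complement.  A stop is internal when it is not the last complete codon
    of the frame.
    """
    if code_table not in GENETIC_CODES:
        raise ValueError(
            f"unknown code table {code_table!r}; choose from {sorted(GENETIC_CODES)}"
        )
    table = CodonTable.unambiguous_dna_by_id[GENETIC_CODES[code_table]]
    stops = set(table.stop_codons)
    report: dict[str, dict] = {}
    for strand, seq in (("+", sequence.upper()), ("-", revcomp(sequence.upper()))):
        for off in range(3):
            frame = f"{strand}{off + 1}"
            codons = [seq[i : i + 3] for i in range(off, len(seq) - 2, 3)]
            stop_idx = [i for i, c in enumerate(codons) if c in stops]
            internal = [i for i in stop_idx if i < len(codons) - 1]
            report[frame] = {
                "n_codons": len(codons),
                "stop_positions": stop_idx,
                "has_internal_stop": bool(internal),
                "terminal_stop": bool(codons) and codons[-1] in stops,
            }
    return report
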