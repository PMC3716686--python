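"""Gene models and GFF3 reading/writing.

Internally everything is 0-based half-open; GFF3 on disk is 1-based
closed.  Reading goes through :mod:`gffutils` (in-memory sqlite DB);
writing emits gene/mRNA/exon/CDS and UTR features directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils


@dataclass
class GeneModel:
    """A protein-coding gene with one transcript's exon/CDS structure."""

    id: str
    scaffold: str
    start: int  # 0-based half-open span
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # coordinate-sorted
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.id}: overlapping exons {e1}>{s2}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in coordinate order."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def intron_number(self, index_in_coordinate_order: int) -> int:
        """Intron number in transcription order (1-based).

        On the minus strand the last intron in coordinate order is
        intron 1.
        """
        n = len(self.introns)
        if self.strand == "+":
            return index_in_coordinate_order + 1
        return n - index_in_coordinate_order

    @property
    def cds_start(self) -> int | None:
        """First coding base in transcription order (genomic coordinate)."""
        if not self.cds:
            return None
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1] - 1


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            a = f"ID={g.id}"
            fh.write(
                f"{g.scaffold}\tnumtscape\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{a}\n"
            )
            mrna = f"{g.id}.t1"
            fh.write(
                f"{g.scaffold}\tnumtscape\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tnumtscape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.scaffold}\tnumtscape\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )
            if g.utr5 is not None:
                s, e = g.utr5
                fh.write(
                    f"{g.scaffold}\tnumtscape\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.utr5;Parent={mrna}\n"
                )
            if g.utr3 is not None:
                s, e = g.utr3
                fh.write(
                    f"{g.scaffold}\tnumtscape\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.utr3;Parent={mrna}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/exon/CDS, optional UTR features)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        utr5 = utr3 = None
        for child in db.children(g, order_by="start"):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype in ("five_prime_UTR", "5UTR"):
                utr5 = iv
            elif child.featuretype in ("three_prime_UTR", "3UTR"):
                utr3 = iv
        genes.append(
            GeneModel(
                id=g.id,
                scaffold=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


def transcript_sequence(gene: GeneModel, scaffold_seq: str) -> str:
    """Spliced transcript sequence in transcription orientation."""
    from numtscape.align import revcomp

    parts = [scaffold_seq[s:e] for s, e in gene.exons]
    seq = "".join(parts)
    return seq if gene.strand == "+" else revcomp(seq)
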