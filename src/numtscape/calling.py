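"""NUMT calling from filtered alignment hits, and genome-level summaries.

A NUMT call is the nuclear footprint of one accepted mtDNA alignment (or,
in ``merged`` mode, the union of overlapping footprints).  The summary
reproduces the standard per-genome accounting: count, summed bp, union bp,
cumulative percentage of the nuclear genome, fraction of the mitochondrial
genome covered by the union of origin intervals, length-distribution
moments, and the ratio of total NUMT bp to mtDNA length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from numtscape.align import AlignmentHit


@dataclass
class Numt:
    """A called nuclear mitochondrial insertion."""

    id: str
    nuclear_scaffold: str
    nuclear_start: int  # 0-based half-open
    nuclear_end: int
    mito_chromosome: str
    mito_start: int
    mito_end: int
    strand: str
    identity: float
    evalue: float
    bitscore: float = 0.0
    wraps_origin: bool = False
    source_hit_ids: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        """Nuclear span of the insertion in bp."""
        return self.nuclear_end - self.nuclear_start

    @property
    def mito_interval(self) -> tuple[int, int]:
        return (self.mito_start, self.mito_end)

    @property
    def nuclear_interval(self) -> tuple[int, int]:
        return (self.nuclear_start, self.nuclear_end)


@dataclass
class NumtSummary:
    """Per-genome NUMT statistics."""

    n_numts: int
    total_bp: int
    union_bp: int
    genome_size: int
    cumulative_percent: float
    union_percent: float
    mt_fraction_transferred: float
    mean_length: float
    median_length: float
    length_variance: float  # population (denominator n)
    length_variance_sample: float  # denominator n-1
    min_length: int
    max_length: int
    identity_min: float | None
    identity_max: float | None
    ratio_to_mtdna: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_hits(
    hits: Iterable[AlignmentHit],
    evalue_max: float = 1e-4,
    min_hit_length: int = 50,
) -> list[AlignmentHit]:
    """Apply the acceptance filter: E <= evalue_max and nuclear span >= floor.

    Both boundaries are inclusive ("maximum expectation value" keeps
    E == evalue_max; spans of exactly ``min_hit_length`` are kept, only
    shorter ones are ignored).  Input order is preserved.
    """
    return [
        h
        for h in hits
        if h.evalue <= evalue_max and h.subject_span >= min_hit_length
    ]


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
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


def _union_length(ivs: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge_intervals(ivs))


def call_numts(
    hits: Sequence[AlignmentHit],
    mode: str = "per_hit",
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[Numt]:
    """Turn filtered hits into NUMT calls.

    ``per_hit`` (default): one call per hit, mirroring per-alignment
    accounting.  ``merged``: hits whose nuclear intervals overlap on the
    same scaffold are unioned into one call that keeps the best E-value and
    lists all source hits.  Ids are deterministic, assigned in
    (scaffold, start) order.
    """
    if mode not in ("per_hit", "merged"):
        raise ValueError(f"unknown mode {mode!r}")
    if scaffold_lengths is not None:
        for h in hits:
            if h.subject_id not in scaffold_lengths:
                raise ValueError(f"hit references unknown scaffold {h.subject_id!r}")

    indexed = sorted(
        enumerate(hits), key=lambda ih: (ih[1].subject_id, ih[1].subject_start, ih[1].subject_end)
    )
    numts: list[Numt] = []
    if mode == "per_hit":
        for rank, (hid, h) in enumerate(indexed):
            numts.append(
                Numt(
                    id=f"numt_{rank + 1:05d}",
                    nuclear_scaffold=h.subject_id,
                    nuclear_start=h.subject_start,
                    nuclear_end=h.subject_end,
                    mito_chromosome=h.query_id,
                    mito_start=h.query_start,
                    mito_end=h.query_end,
                    strand=h.strand,
                    identity=h.identity,
                    evalue=h.evalue,
                    bitscore=h.bitscore,
                    wraps_origin=h.wraps_origin,
                    source_hit_ids=[hid],
                )
            )
        return numts

    # merged: union overlapping nuclear intervals per scaffold
    cluster: list[tuple[int, AlignmentHit]] = []
    clusters: list[list[tuple[int, AlignmentHit]]] = []
    for hid, h in indexed:
        if (
            cluster
            and h.subject_id == cluster[-1][1].subject_id
            and h.subject_start < max(x[1].subject_end for x in cluster)
        ):
            cluster.append((hid, h))
        else:
            if cluster:
                clusters.append(cluster)
            cluster = [(hid, h)]
    if cluster:
        clusters.append(cluster)
    for rank, cl in enumerate(clusters):
        best = min(cl, key=lambda x: (x[1].evalue, -x[1].score))[1]
        numts.append(
            Numt(
                id=f"numt_{rank + 1:05d}",
                nuclear_scaffold=best.subject_id,
                nuclear_start=min(x[1].subject_start for x in cl),
                nuclear_end=max(x[1].subject_end for x in cl),
                mito_chromosome=best.query_id,
                mito_start=min(x[1].query_start for x in cl),
                mito_end=max(x[1].query_end for x in cl),
                strand=best.strand,
                identity=best.identity,
                evalue=best.evalue,
                bitscore=best.bitscore,
                wraps_origin=any(x[1].wraps_origin for x in cl),
                source_hit_ids=[x[0] for x in cl],
            )
        )
    return numts


def summarize(
    numts: Sequence[Numt],
    genome_size: int,
    mito_lengths: Mapping[str, int],
) -> NumtSummary:
    """Compute the per-genome summary statistics.

    ``cumulative_percent`` uses the sum of call lengths (the conventional
    accounting, which can double-count overlapping calls); the union-based
    percentage is reported alongside.  The mtDNA fraction transferred is
    the union of origin intervals over the total mtDNA length; intervals of
    origin-wrapping calls on circular molecules are split at the origin
    before the union.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    mito_total = sum(mito_lengths.values())
    if not numts:
        return NumtSummary(
            n_numts=0,
            total_bp=0,
            union_bp=0,
            genome_size=genome_size,
            cumulative_percent=0.0,
            union_percent=0.0,
            mt_fraction_transferred=0.0,
            mean_length=0.0,
            median_length=0.0,
            length_variance=0.0,
            length_variance_sample=0.0,
            min_length=0,
            max_length=0,
            identity_min=None,
            identity_max=None,
            ratio_to_mtdna=0.0,
        )
    lengths = np.array([n.length for n in numts], dtype=float)
    total_bp = int(lengths.sum())
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for n in numts:
        by_scaffold.setdefault(n.nuclear_scaffold, []).append(n.nuclear_interval)
    union_bp = sum(_union_length(ivs) for ivs in by_scaffold.values())
    mito_ivs: dict[str, list[tuple[int, int]]] = {}
    for n in numts:
        L = mito_lengths.get(n.mito_chromosome)
        s, e = n.mito_start, n.mito_end
        if L is not None and e > L:  # wraps the origin of a circular molecule
            mito_ivs.setdefault(n.mito_chromosome, []).extend([(s, L), (0, e - L)])
        else:
            mito_ivs.setdefault(n.mito_chromosome, []).append((s, e))
    covered = 0
    for chrom, ivs in mito_ivs.items():
        L = mito_lengths.get(chrom, max(e for _, e in ivs))
        covered += sum(
            min(e, L) - min(s, L) for s, e in _merge_intervals(ivs)
        )
    identities = [n.identity for n in numts]
    return NumtSummary(
        n_numts=len(numts),
        total_bp=total_bp,
        union_bp=union_bp,
        genome_size=genome_size,
        cumulative_percent=100.0 * total_bp / genome_size,
        union_percent=100.0 * union_bp / genome_size,
        mt_fraction_transferred=100.0 * covered / mito_total if mito_total else 0.0,
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        length_variance=float(lengths.var(ddof=0)),
        length_variance_sample=float(lengths.var(ddof=1)) if len(lengths) > 1 else 0.0,
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        identity_min=min(identities),
        identity_max=max(identities),
        ratio_to_mtdna=total_bp / mito_total if mito_total else 0.0,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

NUMT_TSV_COLUMNS = (
    "numt_id scaffold nuc_start nuc_end mito_chromosome mito_start mito_end "
    "strand length identity evalue"
).split()


def numts_to_tsv(numts: Iterable[Numt], path) -> None:
    """Write calls as TSV (1-based closed coordinates, per-alignment rows)."""
    with open(path, "w") as fh:
        fh.write("\t".join(NUMT_TSV_COLUMNS) + "\n")
        for n in numts:
            fh.write(
                f"{n.id}\t{n.nuclear_scaffold}\t{n.nuclear_start + 1}\t{n.nuclear_end}\t"
                f"{n.mito_chromosome}\t{n.mito_start + 1}\t{n.mito_end}\t{n.strand}\t"
                f"{n.length}\t{n.identity:.2f}\t{n.evalue:.3g}\n"
            )


def numts_from_tsv(path) -> list[Numt]:
    numts = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            numts.append(
                Numt(
                    id=f[col["numt_id"]],
                    nuclear_scaffold=f[col["scaffold"]],
                    nuclear_start=int(f[col["nuc_start"]]) - 1,
                    nuclear_end=int(f[col["nuc_end"]]),
                    mito_chromosome=f[col["mito_chromosome"]],
                    mito_start=int(f[col["mito_start"]]) - 1,
                    mito_end=int(f[col["mito_end"]]),
                    strand=f[col["strand"]],
                    identity=float(f[col["identity"]]),
                    evalue=float(f[col["evalue"]]),
                )
            )
    return numts


def numts_to_bed(numts: Iterable[Numt], path) -> None:
    """BED6: 0-based half-open, score = bitscore, name = numt id."""
    with open(path, "w") as fh:
        for n in numts:
            fh.write(
                f"{n.nuclear_scaffold}\t{n.nuclear_start}\t{n.nuclear_end}\t"
                f"{n.id}\t{n.bitscore:.0f}\t{n.strand}\n"
            )


def summary_to_json(summary: NumtSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
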