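"""Synthetic genomes with planted NUMTs and a machine-readable truth ledger.

The simulator emulates the study system end to end: a mitochondrial genome
(one circular molecule, or two linear molecules sharing identical inverted
terminal repeats), a multi-scaffold nuclear genome with annotated
multi-exon genes, planted mtDNA insertions with configurable divergence
and indels, post-insertion duplication families, insertions interrupted by
low-complexity or transposable-element sequence, intronic and 5'UTR
insertions, and an EST set containing pure mitochondrial contaminants and
chimeric NUMT-carrying transcripts.  Every planted feature is recorded in
a :class:`TruthLedger` so downstream stages can be scored for recovery.

Nuclear scaffolds are assembled from a shuffled layout of blocks (genes,
insertions, interrupted-insertion cassettes) separated by i.i.d.
background, so planted intervals never overlap and all coordinates are
exact by construction.  All randomness derives from one master seed via
numpy's SeedSequence spawning, so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from numtscape.align import revcomp
from numtscape.gffio import GeneModel, transcript_sequence


class SimulationError(ValueError):
    """Invalid simulation configuration or infeasible placement."""


_BASES = np.array(list("ACGT"))

# 13 protein-coding + 2 rRNA + 2 tRNA placeholders for the mito annotation
_MITO_GENES = [
    ("ND1", "CDS"), ("ND2", "CDS"), ("ND3", "CDS"), ("ND4", "CDS"),
    ("ND4L", "CDS"), ("ND5", "CDS"), ("ND6", "CDS"),
    ("COX1", "CDS"), ("COX2", "CDS"), ("COX3", "CDS"),
    ("CYTB", "CDS"), ("ATP6", "CDS"), ("ATP8", "CDS"),
    ("s-rRNA", "rRNA"), ("l-rRNA", "rRNA"),
    ("tRNA-Met", "tRNA"), ("tRNA-Trp", "tRNA"),
]


@dataclass(frozen=True)
class EstSpec:
    """Counts of simulated EST classes."""

    pure_mito: int = 5
    chimeric_utr5: int = 2
    chimeric_internal: int = 3
    plain_nuclear: int = 3

    @property
    def total(self) -> int:
        return self.pure_mito + self.chimeric_utr5 + self.chimeric_internal + self.plain_nuclear


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults describe the study conditions.

    The default mitochondrial genome mirrors the hydrozoan arrangement
    (two linear chromosomes of 8,194 and 7,686 bp with identical ITRs);
    set ``mito_topology='circular'``/``n_mito_chromosomes=1`` for the
    anthozoan arrangement.  Insertion lengths are log-uniform on
    [100, 2000] bp so that short insertions dominate while the mean stays
    several hundred bp; per-insertion substitution rates are uniform on
    ``divergence_range`` with indels at one tenth the substitution rate.
    """

    seed: int = 0
    nuclear_length: int = 2_000_000
    n_scaffolds: int = 4
    gc_content: float = 0.35
    n_genes: int = 80
    mito_topology: str = "linear"
    n_mito_chromosomes: int = 2
    mito_lengths: tuple[int, ...] = (8194, 7686)
    itr_length: int = 150
    intron_in_nd5: bool = False
    n_insertions: int = 100
    insertion_length_dist: tuple[int, int, str] = (100, 2000, "loguniform")
    divergence_range: tuple[float, float] = (0.0, 0.10)
    indel_fraction: float = 0.1  # indel rate = substitution rate * this
    duplication_spec: tuple[tuple[int, int], ...] = ((2, 34), (3, 4), (6, 1))
    n_interrupted: int = 6
    interruption_kind_probs: tuple[float, float] = (0.5, 0.5)  # (low_complexity, te)
    n_intronic: int = 5
    n_origin_spanning: int = 0  # circular topology only
    est_spec: EstSpec = EstSpec()

    def __post_init__(self) -> None:
        if self.mito_topology not in ("linear", "circular"):
            raise SimulationError(f"unknown topology {self.mito_topology!r}")
        if self.mito_topology == "circular" and self.n_mito_chromosomes != 1:
            raise SimulationError("circular topology requires exactly one mito chromosome")
        if self.n_mito_chromosomes not in (1, 2):
            raise SimulationError("n_mito_chromosomes must be 1 or 2")
        if len(self.mito_lengths) != self.n_mito_chromosomes:
            raise SimulationError("mito_lengths must match n_mito_chromosomes")
        if sum(self.mito_lengths) < 1000:
            raise SimulationError("total mitochondrial length must be >= 1000 bp")
        if self.mito_topology == "linear" and not (
            0 <= self.itr_length < min(self.mito_lengths) / 2
        ):
            raise SimulationError("itr_length must be < min(mito_lengths)/2")
        if not 0.0 <= self.gc_content <= 1.0:
            raise SimulationError("gc_content must be in [0,1]")
        lo, hi = self.divergence_range
        if not (0.0 <= lo <= hi <= 0.3):
            raise SimulationError("divergence_range must be within [0, 0.3]")
        if self.n_intronic > self.n_insertions:
            raise SimulationError("n_intronic exceeds n_insertions")
        fam = sum(size * count for size, count in self.duplication_spec)
        reserved = fam + self.n_interrupted + self.n_intronic + self.est_spec.chimeric_utr5
        if reserved > self.n_insertions:
            raise SimulationError(
                f"insertion budget exceeded: families({fam}) + interrupted"
                f"({self.n_interrupted}) + intronic({self.n_intronic}) + "
                f"utr5({self.est_spec.chimeric_utr5}) > n_insertions({self.n_insertions})"
            )
        if self.n_origin_spanning and self.mito_topology != "circular":
            raise SimulationError("origin-spanning insertions require circular topology")


@dataclass
class MitoFeature:
    chromosome: str
    start: int
    end: int
    strand: str
    ftype: str  # CDS / rRNA / tRNA / intron
    name: str


@dataclass
class MitoGenome:
    """Mitochondrial chromosomes with topology, optional ITRs, annotation."""

    chromosomes: dict[str, str]
    topology: str
    itr_length: int = 0
    itr_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    features: list[MitoFeature] = field(default_factory=list)
    nd5_intron: tuple[str, int, int] | None = None

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in self.features:
                fh.write(
                    f"{f.chromosome}\tnumtscape\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\tID={f.name}\n"
                )


@dataclass
class PlantedInsertion:
    """Ledger record of one planted NUMT."""

    id: str
    nuclear_scaffold: str
    nuclear_start: int
    nuclear_end: int
    mito_chromosome: str
    mito_start: int
    mito_end: int  # > chromosome length when the origin is wrapped
    strand: str
    divergence: float
    indel_rate: float
    role: str  # single / family / interrupted / intronic / utr5
    family_id: str | None = None
    interrupted_by: dict | None = None  # {kind, start, end} nuclear coords
    pieces: list[tuple[int, int]] | None = None  # mito-derived sub-intervals
    host_gene: str | None = None
    host_feature: str | None = None  # e.g. intron_2, utr5
    est_ids: list[str] = field(default_factory=list)
    sequence: str = ""  # planted nuclear-strand sequence (gap excluded)

    @property
    def nuclear_interval(self) -> tuple[int, int]:
        return (self.nuclear_start, self.nuclear_end)

    @property
    def mito_derived_intervals(self) -> list[tuple[int, int]]:
        """Nuclear intervals actually made of mitochondrial sequence."""
        return self.pieces if self.pieces else [self.nuclear_interval]


@dataclass
class TruthLedger:
    """Ground truth of every planted feature, keyed for recovery scoring."""

    insertions: list[PlantedInsertion] = field(default_factory=list)

    def by_id(self) -> dict[str, PlantedInsertion]:
        return {ins.id: ins for ins in self.insertions}

    def families(self) -> dict[str, list[PlantedInsertion]]:
        fams: dict[str, list[PlantedInsertion]] = {}
        for ins in self.insertions:
            if ins.family_id:
                fams.setdefault(ins.family_id, []).append(ins)
        return fams

    def family_size_histogram(self) -> dict[int, int]:
        """{family size: number of families} over families with >= 2 members."""
        hist: dict[int, int] = {}
        for members in self.families().values():
            if len(members) >= 2:
                hist[len(members)] = hist.get(len(members), 0) + 1
        return hist

    def to_json(self, path) -> None:
        payload = [asdict(ins) for ins in self.insertions]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        insertions = []
        for rec in payload:
            if rec.get("pieces"):
                rec["pieces"] = [tuple(p) for p in rec["pieces"]]
            insertions.append(PlantedInsertion(**rec))
        return cls(insertions)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for ins in self.insertions:
                fh.write(
                    f"{ins.nuclear_scaffold}\t{ins.nuclear_start}\t{ins.nuclear_end}\t"
                    f"{ins.id}\t0\t{ins.strand}\n"
                )


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def mutate_sequence(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Apply i.i.d. substitutions and geometric-length indels (p=0.5, <=10 bp)."""
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        r = rng.random()
        if indel_rate > 0 and r < indel_rate / 2:  # deletion
            dlen = min(int(rng.geometric(0.5)), 10)
            i += dlen
            continue
        if indel_rate > 0 and r < indel_rate:  # insertion before this base
            ilen = min(int(rng.geometric(0.5)), 10)
            out.append("".join(rng.choice(_BASES, size=ilen)))
        base = seq[i]
        if sub_rate > 0 and rng.random() < sub_rate and base in "ACGT":
            choices = [b for b in "ACGT" if b != base]
            base = choices[int(rng.integers(0, 3))]
        out.append(base)
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# Mitochondrial genome
# ---------------------------------------------------------------------------

def generate_mito_genome(config: SimConfig) -> MitoGenome:
    """Generate mitochondrial chromosome(s) with annotation.

    Linear two-chromosome genomes carry one identical ITR at each end of
    both molecules (the right-hand copy reverse-complemented, as an
    inverted repeat).  The annotation tiles 13 protein-coding genes,
    2 rRNAs and 2 tRNA placeholders over the molecules; with
    ``intron_in_nd5`` the ND5 gene is split by a recorded group-I-style
    intron.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    gc = config.gc_content
    chroms: dict[str, str] = {}
    itr_intervals: dict[str, list[tuple[int, int]]] = {}
    names = (
        ["mt-Chr1", "mt-Chr2"] if config.n_mito_chromosomes == 2 else ["mtDNA"]
    )
    itr = ""
    if config.mito_topology == "linear" and config.itr_length > 0:
        itr = _random_seq(rng, config.itr_length, gc)
    for name, length in zip(names, config.mito_lengths):
        if itr:
            core = _random_seq(rng, length - 2 * len(itr), gc)
            seq = itr + core + revcomp(itr)
            itr_intervals[name] = [(0, len(itr)), (length - len(itr), length)]
        else:
            seq = _random_seq(rng, length, gc)
        chroms[name] = seq

    # annotation: tile genes across the molecules, proportional to length
    features: list[MitoFeature] = []
    nd5_intron = None
    n_chrom = len(names)
    per_chrom = (
        [_MITO_GENES] if n_chrom == 1 else [_MITO_GENES[:9], _MITO_GENES[9:]]
    )
    for name, genes in zip(names, per_chrom):
        length = len(chroms[name])
        lo = config.itr_length if itr else 0
        hi = length - (config.itr_length if itr else 0)
        span = hi - lo
        slot = span // len(genes)
        pos = lo
        for gname, ftype in genes:
            if ftype == "tRNA":
                glen = 70
            elif ftype == "rRNA":
                glen = min(max(slot - 40, 200), 1600)
            else:
                glen = min(max(slot - 40, 150), 1800)
            if gname == "ND5" and config.intron_in_nd5:
                exon1 = glen // 3
                intron_len = min(900, slot - glen - 20) if slot - glen - 20 > 200 else 400
                total = glen + intron_len
                features.append(
                    MitoFeature(name, pos, pos + exon1, "+", "CDS", "ND5.exon1")
                )
                features.append(
                    MitoFeature(name, pos + exon1, pos + exon1 + intron_len, "+", "intron", "ND5.intron1")
                )
                features.append(
                    MitoFeature(name, pos + exon1 + intron_len, pos + total, "+", "CDS", "ND5.exon2")
                )
                nd5_intron = (name, pos + exon1, pos + exon1 + intron_len)
                pos += slot
                continue
            features.append(MitoFeature(name, pos, pos + glen, "+", ftype, gname))
            pos += slot
    return MitoGenome(
        chromosomes=chroms,
        topology=config.mito_topology,
        itr_length=config.itr_length if itr else 0,
        itr_intervals=itr_intervals,
        features=features,
        nd5_intron=nd5_intron,
    )


# ---------------------------------------------------------------------------
# Nuclear genome with planted insertions
# ---------------------------------------------------------------------------

def _sample_length(rng: np.random.Generator, dist: tuple[int, int, str], lo_floor: int = 0) -> int:
    lo, hi, shape = dist
    lo = max(lo, lo_floor)
    if lo >= hi:
        return hi
    if shape == "uniform":
        return int(rng.integers(lo, hi + 1))
    if shape == "loguniform":
        return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    raise SimulationError(f"unknown length distribution shape {shape!r}")


def _sample_origin(
    rng: np.random.Generator,
    mito: MitoGenome,
    length: int,
    wrap: bool = False,
) -> tuple[str, int, int, str]:
    """Pick a mitochondrial chromosome and interval; returns (chrom, s, e, seg)."""
    names = list(mito.chromosomes)
    lens = np.array([len(mito.chromosomes[n]) for n in names], dtype=float)
    chrom = names[int(rng.choice(len(names), p=lens / lens.sum()))]
    seq = mito.chromosomes[chrom]
    L = len(seq)
    length = min(length, L - 1 if wrap else L)
    if wrap:
        start = int(rng.integers(L - length + 1, L))
        end = start + length
        seg = seq[start:] + seq[: end - L]
    else:
        start = int(rng.integers(0, L - length + 1))
        end = start + length
        seg = seq[start:end]
    return chrom, start, end, seg


def generate_nuclear_genome(
    config: SimConfig, mito: MitoGenome
) -> tuple[dict[str, str], list[GeneModel], TruthLedger, dict[str, str]]:
    """Build the nuclear genome, gene models, truth ledger and repeat library.

    Returns (scaffolds, genes, ledger, repeat_library).  Scaffolds are
    assembled from a shuffled layout of gene blocks, intergenic
    insertions, and interrupted-insertion cassettes separated by i.i.d.
    background at the configured GC content.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gc = config.gc_content
    div_lo, div_hi = config.divergence_range
    min_gap = 200

    # repeat ("TE") library used for interruptions
    repeat_library = {
        f"TE_{i + 1}": _random_seq(rng, int(rng.integers(600, 2500)), gc)
        for i in range(3)
    }

    # --- plan insertions -------------------------------------------------
    plans: list[dict] = []
    used_origins: list[tuple[str, int, int]] = []

    def _clashes(chrom: str, s: int, e: int) -> bool:
        # two intervals clash when they could be confused under the
        # duplication rule (reciprocal overlap kept safely below 0.8)
        for uc, us, ue in used_origins:
            if uc != chrom:
                continue
            ov = max(0, min(e, ue) - max(s, us))
            if ov and min(ov / (e - s), ov / (ue - us)) >= 0.7:
                return True
        return False

    def _distinct_origin(length: int, wrap: bool) -> tuple[str, int, int, str]:
        # independent transfer events get distinct origins
        for _ in range(60):
            chrom, s, e, seg = _sample_origin(rng, mito, length, wrap=wrap)
            if not _clashes(chrom, s, e):
                used_origins.append((chrom, s, e))
                return chrom, s, e, seg
        raise SimulationError(
            "could not sample a distinct mitochondrial origin; too many "
            "insertions for the mitochondrial genome size"
        )

    def _new_insertion(role: str, length_floor: int = 0, length_cap: int | None = None,
                       wrap: bool = False) -> dict:
        length = _sample_length(rng, config.insertion_length_dist, length_floor)
        if length_cap:
            length = min(length, length_cap)
        chrom, s, e, seg = _distinct_origin(length, wrap)
        div = float(rng.uniform(div_lo, div_hi))
        indel = div * config.indel_fraction
        mutated = mutate_sequence(seg, div, indel, rng)
        return {
            "role": role,
            "mito_chromosome": chrom,
            "mito_start": s,
            "mito_end": e,
            "divergence": div,
            "indel_rate": indel,
            "mutated": mutated,
            "strand": "+" if rng.random() < 0.5 else "-",
            "family_id": None,
        }

    def _plan_interrupted() -> dict:
        # the two mito-derived pieces are planned (and mutated) separately so
        # their exact origin sub-intervals can be kept distinct from every
        # other planted origin, not just the full interval
        for _ in range(60):
            length = _sample_length(rng, config.insertion_length_dist, 300)
            chrom, s, e, seg = _sample_origin(rng, mito, length)
            split_rel = int(rng.integers(120, len(seg) - 120))
            mito_gap = int(rng.integers(0, 21))
            left_iv = (s, s + split_rel)
            right_iv = (s + split_rel + mito_gap, e)
            if right_iv[1] - right_iv[0] < 100:
                continue
            if (
                _clashes(chrom, s, e)
                or _clashes(chrom, *left_iv)
                or _clashes(chrom, *right_iv)
            ):
                continue
            used_origins.extend([(chrom, s, e), (chrom, *left_iv), (chrom, *right_iv)])
            div = float(rng.uniform(div_lo, div_hi))
            indel = div * config.indel_fraction
            return {
                "role": "interrupted",
                "mito_chromosome": chrom,
                "mito_start": s,
                "mito_end": e,
                "divergence": div,
                "indel_rate": indel,
                "mutated_left": mutate_sequence(seg[:split_rel], div, indel, rng),
                "mutated_right": mutate_sequence(
                    seg[split_rel + mito_gap :], div, indel, rng
                ),
                "mito_gap": mito_gap,
                "strand": "+" if rng.random() < 0.5 else "-",
                "family_id": None,
            }
        raise SimulationError(
            "could not sample a distinct origin for an interrupted insertion"
        )

    fam_id = 0
    for size, count in config.duplication_spec:
        for _ in range(count):
            fam_id += 1
            src = _new_insertion("family")
            src["family_id"] = f"fam_{fam_id:03d}"
            plans.append(src)
            for _ in range(size - 1):
                copy = dict(src)
                copy["strand"] = "+" if rng.random() < 0.5 else "-"
                plans.append(copy)

    for _ in range(config.n_interrupted):
        p = _plan_interrupted()
        kinds = ["low_complexity", "te"]
        p["interruption_kind"] = kinds[
            int(rng.choice(2, p=np.asarray(config.interruption_kind_probs)))
        ]
        plans.append(p)

    intronic_plans = [
        _new_insertion("intronic", length_cap=1500) for _ in range(config.n_intronic)
    ]
    utr5_plans = []
    for _ in range(config.est_spec.chimeric_utr5):
        length = int(rng.integers(80, 301))
        chrom, s, e, seg = _distinct_origin(length, wrap=False)
        div = float(rng.uniform(div_lo, div_hi))
        utr5_plans.append(
            {
                "role": "utr5",
                "mito_chromosome": chrom,
                "mito_start": s,
                "mito_end": e,
                "divergence": div,
                "indel_rate": div * config.indel_fraction,
                "mutated": mutate_sequence(seg, div, div * config.indel_fraction, rng),
                "strand": "+",
                "family_id": None,
            }
        )

    fam_members = sum(size * count for size, count in config.duplication_spec)
    n_singles = (
        config.n_insertions
        - fam_members
        - config.n_interrupted
        - config.n_intronic
        - config.est_spec.chimeric_utr5
    )
    for k in range(n_singles):
        plans.append(_new_insertion("single", wrap=k < config.n_origin_spanning))

    # --- gene structures --------------------------------------------------
    gene_specs: list[dict] = []
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(2, 9))
        exon_lens = [int(rng.integers(100, 401)) for _ in range(n_ex)]
        intron_lens = [int(rng.integers(200, 2001)) for _ in range(n_ex - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        utr5_len = int(rng.integers(50, min(150, exon_lens[0] - 30)))
        utr3_len = int(rng.integers(50, min(150, exon_lens[-1] - 30)))
        gene_specs.append(
            {
                "id": f"gene_{gi + 1:04d}",
                "exon_lens": exon_lens,
                "intron_lens": intron_lens,
                "strand": strand,
                "utr5_len": utr5_len,
                "utr3_len": utr3_len,
                "intronic": {},  # intron index -> list of plans
                "utr5_numt": None,
                "numt_strand": "+" if rng.random() < 0.5 else "-",
            }
        )

    # assign intronic insertions to host genes/introns
    for p in intronic_plans:
        g = gene_specs[int(rng.integers(0, len(gene_specs)))]
        intron_idx = int(rng.integers(0, len(g["intron_lens"])))
        g["intronic"].setdefault(intron_idx, []).append(p)
        plans.append(p)
    # assign utr5 insertions to distinct plus-strand hosts without intronic load
    free = [g for g in gene_specs if not g["intronic"] and g["utr5_numt"] is None]
    if len(free) < len(utr5_plans):
        raise SimulationError("not enough genes available to host 5'UTR insertions")
    for p, g in zip(utr5_plans, free):
        g["utr5_numt"] = p
        g["strand"] = "+"
        plans.append(p)

    # --- build blocks -----------------------------------------------------
    blocks: list[dict] = []  # {seq, kind, payload}
    for g in gene_specs:
        blocks.append(_build_gene_block(g, gc, rng))
    for p in plans:
        if p["role"] in ("intronic", "utr5"):
            continue  # already inside a gene block
        if p["role"] == "interrupted":
            blocks.append(_build_interrupted_block(p, repeat_library, gc, rng))
        else:
            planted = p["mutated"] if p["strand"] == "+" else revcomp(p["mutated"])
            blocks.append({"kind": "numt", "seq": planted, "plan": p, "planted": planted})

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # --- distribute blocks over scaffolds --------------------------------
    n_scaf = config.n_scaffolds
    scaffold_len = config.nuclear_length // n_scaf
    scaf_blocks: list[list[dict]] = [[] for _ in range(n_scaf)]
    loads = [0] * n_scaf
    for b in blocks:
        i = int(np.argmin(loads))
        scaf_blocks[i].append(b)
        loads[i] += len(b["seq"]) + min_gap
    for i, load in enumerate(loads):
        if load + min_gap > scaffold_len:
            raise SimulationError(
                f"cannot place blocks: scaffold {i + 1} needs {load + min_gap} bp "
                f"but has {scaffold_len} (raise nuclear_length or lower feature counts)"
            )

    scaffolds: dict[str, str] = {}
    genes: list[GeneModel] = []
    ledger = TruthLedger()
    numt_counter = 0
    for si in range(n_scaf):
        name = f"scaffold_{si + 1}"
        bl = scaf_blocks[si]
        content = sum(len(b["seq"]) for b in bl)
        spare = scaffold_len - content - (len(bl) + 1) * min_gap
        gaps = rng.multinomial(spare, np.ones(len(bl) + 1) / (len(bl) + 1)) + min_gap
        parts: list[str] = []
        pos = 0
        for b, gap in zip(bl, gaps[:-1]):
            parts.append(_random_seq(rng, int(gap), gc))
            pos += int(gap)
            offset = pos
            parts.append(b["seq"])
            pos += len(b["seq"])
            numt_counter = _register_block(
                b, name, offset, genes, ledger, numt_counter
            )
        parts.append(_random_seq(rng, int(gaps[-1]), gc))
        scaffolds[name] = "".join(parts)

    ledger.insertions.sort(key=lambda r: (r.nuclear_scaffold, r.nuclear_start))
    for i, rec in enumerate(ledger.insertions, 1):
        rec.id = f"ins_{i:04d}"
    return scaffolds, genes, ledger, repeat_library


def _build_gene_block(g: dict, gc: float, rng: np.random.Generator) -> dict:
    """Assemble a gene's sequence with any hosted NUMTs; relative features."""
    exon_seqs: list[str] = []
    for i, elen in enumerate(g["exon_lens"]):
        seq = _random_seq(rng, elen, gc)
        exon_seqs.append(seq)
    # 5'UTR-hosted NUMT goes inside the UTR portion of the transcription-first exon
    utr5_numt_rel = None
    if g["utr5_numt"] is not None:
        p = g["utr5_numt"]
        planted = p["mutated"] if g["numt_strand"] == "+" else revcomp(p["mutated"])
        p["strand"] = g["numt_strand"]
        pad_left = int(rng.integers(20, 60))
        pad_right = int(rng.integers(20, 60))
        utr5_seq = (
            _random_seq(rng, pad_left, gc) + planted + _random_seq(rng, pad_right, gc)
        )
        g["utr5_len"] = len(utr5_seq)
        exon_seqs[0] = utr5_seq + exon_seqs[0]
        utr5_numt_rel = (pad_left, pad_left + len(planted), planted)

    intron_seqs: list[str] = []
    intron_numts_rel: list[list[tuple[int, int, dict, str]]] = []
    for i, ilen in enumerate(g["intron_lens"]):
        hosted = g["intronic"].get(i, [])
        rel: list[tuple[int, int, dict, str]] = []
        if hosted:
            parts = []
            pos = 0
            for p in hosted:
                planted = (
                    p["mutated"] if g["numt_strand"] == "+" else revcomp(p["mutated"])
                )
                p["strand"] = g["numt_strand"]
                spacer = int(rng.integers(100, 400))
                parts.append(_random_seq(rng, spacer, gc))
                pos += spacer
                rel.append((pos, pos + len(planted), p, planted))
                parts.append(planted)
                pos += len(planted)
            parts.append(_random_seq(rng, int(rng.integers(100, 400)), gc))
            intron_seqs.append("".join(parts))
        else:
            intron_seqs.append(_random_seq(rng, ilen, gc))
        intron_numts_rel.append(rel)

    seq_parts: list[str] = []
    exons_rel: list[tuple[int, int]] = []
    introns_rel: list[tuple[int, int]] = []
    pos = 0
    for i, es in enumerate(exon_seqs):
        exons_rel.append((pos, pos + len(es)))
        seq_parts.append(es)
        pos += len(es)
        if i < len(intron_seqs):
            introns_rel.append((pos, pos + len(intron_seqs[i])))
            seq_parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    return {
        "kind": "gene",
        "seq": "".join(seq_parts),
        "gene": g,
        "exons_rel": exons_rel,
        "introns_rel": introns_rel,
        "intron_numts_rel": intron_numts_rel,
        "utr5_numt_rel": utr5_numt_rel,
    }


def _build_interrupted_block(
    p: dict, repeat_library: dict[str, str], gc: float, rng: np.random.Generator
) -> dict:
    """Assemble a split insertion: piece + interposed element + piece.

    On the minus strand the mitochondrially-later piece comes first in
    nuclear coordinates, so the pieces are swapped and each
    reverse-complemented.
    """
    if p["strand"] == "+":
        left, right = p["mutated_left"], p["mutated_right"]
    else:
        left, right = revcomp(p["mutated_right"]), revcomp(p["mutated_left"])
    if p["interruption_kind"] == "te":
        te_name = list(repeat_library)[int(rng.integers(0, len(repeat_library)))]
        te = repeat_library[te_name]
        elen = int(rng.integers(300, len(te) + 1))
        element = mutate_sequence(te[:elen], 0.02, 0.002, rng)
        evidence = te_name
    else:
        # AT-rich microsatellites of period <= 2 (trinucleotide entropy <= 1 bit)
        motif = ["AT", "A", "TA", "T"][int(rng.integers(0, 4))]
        elen = int(rng.integers(300, 1500))
        element = (motif * (elen // len(motif) + 1))[:elen]
        evidence = f"motif:{motif}"
    seq = left + element + right
    return {
        "kind": "interrupted",
        "seq": seq,
        "plan": p,
        "left_len": len(left),
        "element_len": len(element),
        "right_len": len(right),
        "element_kind": p["interruption_kind"],
        "element_evidence": evidence,
        "mito_gap": p["mito_gap"],
    }


def _register_block(
    b: dict,
    scaffold: str,
    offset: int,
    genes: list[GeneModel],
    ledger: TruthLedger,
    counter: int,
) -> int:
    """Record a placed block's features at absolute coordinates."""
    if b["kind"] == "numt":
        p = b["plan"]
        counter += 1
        ledger.insertions.append(
            PlantedInsertion(
                id=f"tmp_{counter}",
                nuclear_scaffold=scaffold,
                nuclear_start=offset,
                nuclear_end=offset + len(b["seq"]),
                mito_chromosome=p["mito_chromosome"],
                mito_start=p["mito_start"],
                mito_end=p["mito_end"],
                strand=p["strand"],
                divergence=p["divergence"],
                indel_rate=p["indel_rate"],
                role=p["role"],
                family_id=p["family_id"],
                sequence=b["planted"],
            )
        )
        return counter
    if b["kind"] == "interrupted":
        p = b["plan"]
        counter += 1
        lstart = offset
        lend = offset + b["left_len"]
        estart, eend = lend, lend + b["element_len"]
        rstart, rend = eend, eend + b["right_len"]
        ledger.insertions.append(
            PlantedInsertion(
                id=f"tmp_{counter}",
                nuclear_scaffold=scaffold,
                nuclear_start=lstart,
                nuclear_end=rend,
                mito_chromosome=p["mito_chromosome"],
                mito_start=p["mito_start"],
                mito_end=p["mito_end"],
                strand=p["strand"],
                divergence=p["divergence"],
                indel_rate=p["indel_rate"],
                role="interrupted",
                interrupted_by={
                    "kind": b["element_kind"],
                    "start": estart,
                    "end": eend,
                    "evidence": b["element_evidence"],
                    "mito_gap": b["mito_gap"],
                },
                pieces=[(lstart, lend), (rstart, rend)],
                sequence=b["seq"][: b["left_len"]] + b["seq"][eend - offset :],
            )
        )
        return counter
    # gene block
    g = b["gene"]
    exons = [(offset + s, offset + e) for s, e in b["exons_rel"]]
    start, end = exons[0][0], exons[-1][1]
    if g["strand"] == "+":
        utr5 = (start, start + g["utr5_len"])
        utr3 = (end - g["utr3_len"], end)
    else:
        utr5 = (end - g["utr5_len"], end)
        utr3 = (start, start + g["utr3_len"])
    # CDS = exon sequence between the two UTRs (which sit at the gene tips)
    left_utr, right_utr = sorted([utr5, utr3])
    coding_lo, coding_hi = left_utr[1], right_utr[0]
    cds = [
        (max(s, coding_lo), min(e, coding_hi))
        for s, e in exons
        if max(s, coding_lo) < min(e, coding_hi)
    ]
    model = GeneModel(
        id=g["id"],
        scaffold=scaffold,
        start=start,
        end=end,
        strand=g["strand"],
        exons=exons,
        cds=cds,
        utr5=utr5,
        utr3=utr3,
    )
    genes.append(model)
    n_introns = len(b["introns_rel"])
    for intron_idx, rel in enumerate(b["intron_numts_rel"]):
        intron_abs = (
            offset + b["introns_rel"][intron_idx][0],
            offset + b["introns_rel"][intron_idx][1],
        )
        tx_index = intron_idx + 1 if g["strand"] == "+" else n_introns - intron_idx
        for rs, re, p, planted in rel:
            counter += 1
            ledger.insertions.append(
                PlantedInsertion(
                    id=f"tmp_{counter}",
                    nuclear_scaffold=scaffold,
                    nuclear_start=intron_abs[0] + rs,
                    nuclear_end=intron_abs[0] + re,
                    mito_chromosome=p["mito_chromosome"],
                    mito_start=p["mito_start"],
                    mito_end=p["mito_end"],
                    strand=p["strand"],
                    divergence=p["divergence"],
                    indel_rate=p["indel_rate"],
                    role="intronic",
                    host_gene=g["id"],
                    host_feature=f"intron_{tx_index}",
                    sequence=planted,
                )
            )
            rec = ledger.insertions[-1]
            assert intron_abs[0] <= rec.nuclear_start < rec.nuclear_end <= intron_abs[1]
    if b["utr5_numt_rel"] is not None:
        rs, re, planted = b["utr5_numt_rel"]
        p = g["utr5_numt"]
        counter += 1
        # the UTR sits at the start of the transcription-first exon; hosts are
        # forced to the plus strand so relative == absolute offsets
        ledger.insertions.append(
            PlantedInsertion(
                id=f"tmp_{counter}",
                nuclear_scaffold=scaffold,
                nuclear_start=offset + rs,
                nuclear_end=offset + re,
                mito_chromosome=p["mito_chromosome"],
                mito_start=p["mito_start"],
                mito_end=p["mito_end"],
                strand=p["strand"],
                divergence=p["divergence"],
                indel_rate=p["indel_rate"],
                role="utr5",
                host_gene=g["id"],
                host_feature="utr5",
                sequence=planted,
            )
        )
    return counter


# ---------------------------------------------------------------------------
# ESTs
# ---------------------------------------------------------------------------

def generate_ests(
    config: SimConfig,
    mito: MitoGenome,
    scaffolds: dict[str, str],
    genes: Sequence[GeneModel],
    ledger: TruthLedger,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate the EST set; returns (sequences, truth table).

    Classes: ``pure_mito`` (mutated mitochondrial substrings, the
    contaminants), ``chimeric_utr5`` (spliced transcript prefixes of genes
    whose 5'UTR hosts a planted NUMT), ``chimeric_internal`` (a planted
    NUMT with its genomic flanks), and ``plain_nuclear`` (genomic slices
    free of planted insertions).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    spec = config.est_spec
    ests: dict[str, str] = {}
    rows: list[dict] = []
    gene_by_id = {g.id: g for g in genes}

    for i in range(spec.pure_mito):
        chrom = list(mito.chromosomes)[int(rng.integers(0, len(mito.chromosomes)))]
        seq = mito.chromosomes[chrom]
        length = int(rng.integers(300, min(801, len(seq))))
        start = int(rng.integers(0, len(seq) - length + 1))
        est = mutate_sequence(seq[start : start + length], 0.005, 0.0005, rng)
        if rng.random() < 0.5:
            est = revcomp(est)
        eid = f"est_mito_{i + 1:02d}"
        ests[eid] = est
        rows.append({"est_id": eid, "category": "pure_mito", "insertion_id": ""})

    utr5_hosts = [ins for ins in ledger.insertions if ins.role == "utr5"]
    if spec.chimeric_utr5 > len(utr5_hosts):
        raise SimulationError(
            "chimeric 5'UTR ESTs requested but no 5'UTR insertions were planted"
        )
    for i, ins in enumerate(utr5_hosts[: spec.chimeric_utr5]):
        gene = gene_by_id[ins.host_gene]
        tseq = transcript_sequence(gene, scaffolds[gene.scaffold])
        utr_len = gene.utr5[1] - gene.utr5[0]
        take = utr_len + int(rng.integers(150, 300))
        eid = f"est_utr5_{i + 1:02d}"
        ests[eid] = tseq[: min(take, len(tseq))]
        ins.est_ids.append(eid)
        rows.append({"est_id": eid, "category": "chimeric_utr5", "insertion_id": ins.id})

    internal_pool = [
        ins
        for ins in ledger.insertions
        if ins.role in ("single", "family") and ins.nuclear_end - ins.nuclear_start >= 100
    ]
    if spec.chimeric_internal > len(internal_pool):
        raise SimulationError("not enough planted insertions for chimeric_internal ESTs")
    chosen = [internal_pool[int(k)] for k in rng.choice(len(internal_pool), spec.chimeric_internal, replace=False)]
    for i, ins in enumerate(chosen):
        seq = scaffolds[ins.nuclear_scaffold]
        fl = int(rng.integers(100, 301))
        fr = int(rng.integers(100, 301))
        s = max(0, ins.nuclear_start - fl)
        e = min(len(seq), ins.nuclear_end + fr)
        est = seq[s:e]
        if rng.random() < 0.5:
            est = revcomp(est)
        eid = f"est_chimeric_{i + 1:02d}"
        ests[eid] = est
        ins.est_ids.append(eid)
        rows.append({"est_id": eid, "category": "chimeric_internal", "insertion_id": ins.id})

    planted_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for ins in ledger.insertions:
        planted_by_scaffold.setdefault(ins.nuclear_scaffold, []).append(
            ins.nuclear_interval
        )
    names = list(scaffolds)
    for i in range(spec.plain_nuclear):
        for _ in range(100):
            name = names[int(rng.integers(0, len(names)))]
            seq = scaffolds[name]
            length = int(rng.integers(300, 801))
            start = int(rng.integers(0, len(seq) - length))
            iv = (start, start + length)
            if all(
                iv[1] <= s or iv[0] >= e
                for s, e in planted_by_scaffold.get(name, [])
            ):
                break
        else:
            raise SimulationError("could not place a NUMT-free nuclear EST")
        eid = f"est_nuclear_{i + 1:02d}"
        ests[eid] = seq[iv[0] : iv[1]]
        rows.append({"est_id": eid, "category": "plain_nuclear", "insertion_id": ""})

    table = pd.DataFrame(rows, columns=["est_id", "category", "insertion_id"])
    return ests, table
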