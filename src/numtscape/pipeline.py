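"""End-to-end orchestration: simulate -> search -> call -> characterize ->
context -> express -> report.

Each stage is a thin wrapper over the library modules so the pipeline can
run on simulated inputs (in memory or from a config) or on user-supplied
FASTA/GFF3 files via the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from numtscape.align import (
    AlignmentHit,
    ScoringParams,
    circularize,
    dedup_circular_hits,
    search,
)
from numtscape.calling import (
    Numt,
    call_numts,
    filter_hits,
    numts_to_bed,
    numts_to_tsv,
    summarize,
)
from numtscape.context import classify_contexts
from numtscape.duplication import (
    classify_interruption,
    extract_gap_sequence,
    find_split_pairs,
    group_duplicates,
)
from numtscape.expression import check_translation, place_in_genome, screen_ests
from numtscape.gffio import write_gff3
from numtscape.ioutils import write_fasta
from numtscape.report import build_report
from numtscape.simulate import (
    MitoGenome,
    SimConfig,
    generate_ests,
    generate_mito_genome,
    generate_nuclear_genome,
)


@dataclass
class PipelineConfig:
    """Thresholds and mode flags for a full run."""

    params: ScoringParams = field(default_factory=ScoringParams)
    evalue_max: float = 1e-4
    min_hit_length: int = 50
    call_mode: str = "per_hit"  # or "merged"
    nonredundant: bool = False  # collapse ITR double counts
    min_reciprocal_overlap: float = 0.8
    max_mito_gap: int = 100
    min_nuclear_separation: int = 50
    window_bp: int = 10_000
    pure_mito_coverage: float = 0.95
    pure_mito_identity: float = 98.0
    circular_max_hit_span: int = 10_000


def search_genome(
    mito: MitoGenome,
    scaffolds: Mapping[str, str],
    params: ScoringParams | None = None,
    nonredundant: bool = False,
    circular_max_hit_span: int = 10_000,
) -> list[AlignmentHit]:
    """Search every mitochondrial chromosome against every nuclear scaffold.

    Each chromosome is searched independently and hits are labelled by
    chromosome; with identical ITRs on two linear chromosomes this
    double-reports ITR-derived hits, mirroring per-chromosome accounting.
    ``nonredundant`` collapses hits whose nuclear interval is already
    claimed by another chromosome's hit.  Circular molecules are extended
    past the origin and origin-crossing hits folded back and flagged.
    """
    if params is None:
        params = ScoringParams()
    genome_size = sum(len(s) for s in scaffolds.values())
    hits: list[AlignmentHit] = []
    for chrom, cseq in mito.chromosomes.items():
        cmap = None
        qseq = cseq
        if mito.topology == "circular":
            span = min(circular_max_hit_span, len(cseq))
            qseq, cmap = circularize(cseq, span, mito.topology)
        chrom_hits: list[AlignmentHit] = []
        for name, sseq in scaffolds.items():
            chrom_hits.extend(
                search(
                    qseq,
                    sseq,
                    params,
                    query_id=chrom,
                    subject_id=name,
                    search_space=(len(cseq), genome_size),
                )
            )
        if cmap is not None:
            chrom_hits = dedup_circular_hits(chrom_hits, cmap)
        hits.extend(chrom_hits)
    if nonredundant:
        hits = _collapse_cross_chromosome(hits)
    hits.sort(key=lambda h: (h.subject_id, h.subject_start, h.query_id))
    return hits


def _collapse_cross_chromosome(
    hits: list[AlignmentHit], frac: float = 0.9
) -> list[AlignmentHit]:
    """Keep one hit when different mito chromosomes claim the same nuclear
    interval (identical-ITR double counts)."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: (h.evalue, -h.score)):
        dup = False
        for k in kept:
            if k.subject_id != h.subject_id or k.query_id == h.query_id:
                continue
            ov = max(
                0, min(h.subject_end, k.subject_end) - max(h.subject_start, k.subject_start)
            )
            if h.subject_span and ov >= frac * h.subject_span:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def run_synthetic(
    sim_config: SimConfig,
    pipeline_config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Simulate a genome and run every downstream stage on it.

    Returns a dict of all in-memory stage outputs (mito, scaffolds, genes,
    ledger, hits, numts, summary, families, split pairs, interruption
    calls, contexts, expression records, report bundle).  When ``outdir``
    is given, writes the simulated inputs and all reports there.
    """
    pc = pipeline_config or PipelineConfig()
    params = replace(
        pc.params, evalue_max=pc.evalue_max, min_hit_length=pc.min_hit_length
    )

    mito = generate_mito_genome(sim_config)
    scaffolds, genes, ledger, repeat_library = generate_nuclear_genome(sim_config, mito)
    ests, est_truth = generate_ests(sim_config, mito, scaffolds, genes, ledger)

    hits = search_genome(
        mito,
        scaffolds,
        params,
        nonredundant=pc.nonredundant,
        circular_max_hit_span=pc.circular_max_hit_span,
    )
    accepted = filter_hits(hits, pc.evalue_max, pc.min_hit_length)
    scaffold_lengths = {k: len(v) for k, v in scaffolds.items()}
    numts = call_numts(accepted, mode=pc.call_mode, scaffold_lengths=scaffold_lengths)
    summary = summarize(numts, sum(scaffold_lengths.values()), mito.lengths)

    families = group_duplicates(numts, pc.min_reciprocal_overlap)
    pairs = find_split_pairs(
        numts, pc.max_mito_gap, pc.min_nuclear_separation
    )
    interruptions = [
        classify_interruption(
            p, extract_gap_sequence(p, scaffolds), repeat_library, params
        )
        for p in pairs
    ]
    contexts = classify_contexts(numts, genes, pc.window_bp, scaffold_lengths)

    screened = screen_ests(
        ests,
        mito.chromosomes,
        params,
        pc.pure_mito_coverage,
        pc.pure_mito_identity,
    )
    expressed = []
    for est_id, blocks in screened.items():
        if blocks.category != "chimeric":
            continue
        rec = place_in_genome(
            est_id, ests[est_id], blocks, scaffolds, numts, genes, params
        )
        rec.stop_codon_report = {
            code: check_translation(ests[est_id], code)
            for code in ("universal", "mold_mito")
        }
        expressed.append(rec)

    result = {
        "mito": mito,
        "scaffolds": scaffolds,
        "genes": genes,
        "ledger": ledger,
        "repeat_library": repeat_library,
        "ests": ests,
        "est_truth": est_truth,
        "hits": hits,
        "accepted_hits": accepted,
        "numts": numts,
        "summary": summary,
        "families": families,
        "split_pairs": pairs,
        "interruptions": interruptions,
        "contexts": contexts,
        "screened_ests": screened,
        "expressed": expressed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_simulation(outdir, result)
        from numtscape.align import hits_to_tsv

        hits_to_tsv(accepted, outdir / "hits.tsv")
        numts_to_tsv(numts, outdir / "numts.tsv")
        numts_to_bed(numts, outdir / "numts.bed")
        result["report"] = build_report(
            outdir / "report",
            summary,
            numts,
            contexts,
            families,
            interruptions,
            expressed,
            mito.lengths,
            mode=pc.call_mode,
        )
    else:
        result["report"] = build_report_dict(result, pc)
    return result


def build_report_dict(result: dict, pc: PipelineConfig) -> dict:
    """Report bundle without touching the filesystem."""
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        return build_report(
            tmp,
            result["summary"],
            result["numts"],
            result["contexts"],
            result["families"],
            result["interruptions"],
            result["expressed"],
            result["mito"].lengths,
            mode=pc.call_mode,
        )


def write_simulation(outdir: str | Path, result: dict) -> None:
    """Write the simulated inputs (FASTA/GFF3/BED/JSON) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mito: MitoGenome = result["mito"]
    write_fasta(mito.chromosomes, outdir / "mito.fa")
    mito.to_gff3(outdir / "mito.gff3")
    write_fasta(result["scaffolds"], outdir / "nuclear.fa")
    write_gff3(result["genes"], outdir / "genes.gff3")
    write_fasta(result["repeat_library"], outdir / "repeats.fa")
    if result["ests"]:
        write_fasta(result["ests"], outdir / "ests.fa")
    result["est_truth"].to_csv(outdir / "est_truth.tsv", sep="\t", index=False)
    result["ledger"].to_json(outdir / "truth_ledger.json")
    result["ledger"].to_bed(outdir / "truth_ledger.bed")
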