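"""Statistical utilities and the aggregated report bundle.

Implements the two tests used for NUMT summaries — the classical
equal-variance two-sample t-test on length sets, and Pearson correlation
on log-log genome size vs cumulative NUMT percentage — and renders all
stage outputs into summary tables (per-chromosome counts, genic-context
table, 100-bp length histogram, duplication and expression sections).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from numtscape.calling import Numt, NumtSummary
from numtscape.context import ContextCall, density_counts
from numtscape.duplication import InterruptionCall, NumtFamily, family_size_histogram


def students_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, int, float]:
    """Two-sample Student's t-test (pooled variance), two-sided.

    Returns (t, df, p) with df = n_a + n_b - 2.  Degenerate inputs with
    zero pooled variance give p = 1 for equal means and p = 0 otherwise
    (Welch's variant is available via scipy directly if unequal variances
    are a concern).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), df, 0.0
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1 / a.size + 1 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def pearson_loglog(
    genome_sizes: Sequence[float], cumulative_percents: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson correlation of log10(genome size) vs log10(cumulative %).

    Pairs with a non-positive value on either axis are excluded (log
    undefined); returns (r, p, n_excluded).  Raises if fewer than three
    pairs remain.
    """
    x = np.asarray(genome_sizes, dtype=float)
    y = np.asarray(cumulative_percents, dtype=float)
    if x.size != y.size:
        raise ValueError("paired inputs required")
    keep = (x > 0) & (y > 0)
    n_excluded = int((~keep).sum())
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("fewer than 3 usable pairs after excluding non-positive values")
    r, p = sps.pearsonr(np.log10(x), np.log10(y))
    return float(r), float(p), n_excluded


def length_histogram(lengths: Sequence[int], bin_width: int = 100) -> pd.DataFrame:
    """Counts of NUMT lengths in [0,100), [100,200), ... bins."""
    lengths = np.asarray(lengths, dtype=int)
    if lengths.size == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    top = (int(lengths.max()) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


@dataclass
class ComparativeRecord:
    """One species' genome size and NUMT content, for cross-genome plots."""

    label: str
    genome_size: int
    numt_total_bp: int

    @property
    def cumulative_percent(self) -> float:
        return 100.0 * self.numt_total_bp / self.genome_size


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def per_chromosome_counts(numts: Sequence[Numt]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for n in numts:
        counts[n.mito_chromosome] = counts.get(n.mito_chromosome, 0) + 1
    return counts


def build_report(
    outdir,
    summary: NumtSummary,
    numts: Sequence[Numt],
    contexts: Sequence[ContextCall] = (),
    families: Sequence[NumtFamily] = (),
    interruptions: Sequence[InterruptionCall] = (),
    expression: Sequence = (),
    mito_lengths: Mapping[str, int] | None = None,
    mode: str = "per_hit",
    input_hashes: Mapping[str, str] | None = None,
) -> dict:
    """Aggregate all stage outputs into a report bundle under ``outdir``.

    Writes summary.json, genome_table.tsv (per-chromosome and total
    accounting), context_table.tsv (host genes with intronic/UTR NUMTs),
    length_histogram.tsv, duplication.tsv, interruptions.tsv and
    expression.tsv, plus a manifest with provenance metadata.  Returns the
    summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    per_chrom = per_chromosome_counts(numts)
    dens = density_counts(contexts) if contexts else {}
    intronic = [c for c in contexts if c.feature.startswith("intron")]
    utr = [c for c in contexts if c.feature in ("utr5", "utr3")]
    fam_hist = family_size_histogram(families)
    bundle = {
        "mode": mode,
        "summary": summary.to_dict(),
        "per_chromosome_counts": per_chrom,
        "density_counts": dens,
        "n_intronic": len(intronic),
        "n_utr": len(utr),
        "n_duplication_families": len(families),
        "family_size_histogram": {str(k): v for k, v in sorted(fam_hist.items())},
        "n_interruptions": len(interruptions),
        "interruption_classes": {
            cls: sum(1 for ic in interruptions if ic.classification == cls)
            for cls in ("low_complexity", "transposable_element", "other")
        },
        "n_expressed_numts": sum(
            1 for e in expression if getattr(e, "placement", None) is not None
        ),
        "input_hashes": dict(input_hashes or {}),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # genome accounting table (per mito chromosome + total)
    rows = []
    for chrom, count in sorted(per_chrom.items()):
        sub = [n for n in numts if n.mito_chromosome == chrom]
        bp = sum(n.length for n in sub)
        rows.append(
            {
                "mito_chromosome": chrom,
                "n_numts": count,
                "total_bp": bp,
                "mean_length": round(bp / count) if count else 0,
            }
        )
    rows.append(
        {
            "mito_chromosome": "total",
            "n_numts": summary.n_numts,
            "total_bp": summary.total_bp,
            "mean_length": round(summary.mean_length),
        }
    )
    pd.DataFrame(rows).to_csv(outdir / "genome_table.tsv", sep="\t", index=False)

    # genic-context table: one row per host gene carrying NUMTs
    ctx_rows: dict[str, dict] = {}
    numt_by_id = {n.id: n for n in numts}
    for c in contexts:
        if c.host_gene is None:
            continue
        row = ctx_rows.setdefault(
            c.host_gene,
            {"host_gene": c.host_gene, "n_numts": 0, "total_bp": 0, "features": set()},
        )
        row["n_numts"] += 1
        row["total_bp"] += numt_by_id[c.numt_id].length
        row["features"].add(c.feature)
    ctx_df = pd.DataFrame(
        [
            {**r, "features": ",".join(sorted(r["features"]))}
            for r in ctx_rows.values()
        ]
    )
    ctx_df.to_csv(outdir / "context_table.tsv", sep="\t", index=False)

    length_histogram([n.length for n in numts]).to_csv(
        outdir / "length_histogram.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "size": f.family_size,
                "members": ",".join(f.member_numt_ids),
            }
            for f in families
        ]
    ).to_csv(outdir / "duplication.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "numt_a": ic.pair[0],
                "numt_b": ic.pair[1],
                "gap_start": ic.gap_start,
                "gap_end": ic.gap_end,
                "mito_gap": ic.mito_gap,
                "classification": ic.classification,
                "evidence": ic.evidence,
            }
            for ic in interruptions
        ]
    ).to_csv(outdir / "interruptions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "est_id": e.est_id,
                "class": e.insertion_class,
                "scaffold": e.placement.scaffold if e.placement else "",
                "start": e.placement.start if e.placement else "",
                "end": e.placement.end if e.placement else "",
                "linked_numt": e.linked_numt_id or "",
                "internal_stops_universal": sum(
                    1
                    for fr in e.stop_codon_report.get("universal", {}).values()
                    if fr["has_internal_stop"]
                ),
                "internal_stops_mold_mito": sum(
                    1
                    for fr in e.stop_codon_report.get("mold_mito", {}).values()
                    if fr["has_internal_stop"]
                ),
            }
            for e in expression
        ]
    ).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    return bundle
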