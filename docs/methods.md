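# Methods

## Local alignment engine

The search stage is a self-contained nucleotide local aligner in the
BLASTN tradition, chosen so the whole pipeline's filtering contract
(E ≤ 10⁻⁴, hit length ≥ 50 nt) rests on owned, testable computation.

**Seeding.** Every exact word match of length `word_size` (default 11)
between query and subject triggers extension (one-hit seeding; at desk
scale sensitivity matters more than the two-hit speed trick). Words are
computed as rolling base-4 codes with numpy; any window containing N is
excluded — N never seeds, and scores as a mismatch during extension.
Seeds falling inside a region already extended on the same diagonal are
skipped.

**Extension.** Ungapped X-drop extension (default drop 20) produces
HSPs. Near-collinear HSPs (diagonal band ±50, gaps ≤ 100 bp) are chained
greedily; each HSP joins the *highest-scoring* chain it is compatible
with — joining the first match allowed stray 11-bp micro-HSPs on nearby
diagonals to capture the continuation of a real alignment and fragment
one insertion into two calls. Each chain with a member HSP scoring at
least `gapped_trigger_score` (default 18) is then polished by a full
affine-gap Smith–Waterman (Gotoh) pass over the chain's rectangle padded
by 100 bp, vectorized row-wise; the horizontal gap state is computed
with the running-maximum identity
`E[j] = max_k (H[k] + ge·k) − go − ge·j`, which is exact for affine
costs. Two shortcuts bound the work: single-HSP chains whose rectangle
exceeds `full_dp_cells` (3·10⁵) are reported as ungapped alignments
(they contain no indel evidence; this also covers the full-length mtDNA
self-hit, whose matrix would otherwise be 2.5·10⁸ cells), and
multi-HSP chains are capped at `max_dp_cells` (2·10⁷). When the whole
problem is small (|q|·|s| ≤ `full_dp_cells`) and any seed exists, one
exact DP over the full matrix is run instead — at that scale the seeded
engine and the exact optimum coincide whenever a shared word exists.

**Statistics.** λ is the positive root of Σ pᵢpⱼ e^{λs(i,j)} = 1
(Brent's method, residual < 10⁻⁹). K uses the classical lattice-case
renewal formula — convolutions of the pair-score distribution
accumulated into σ, then K = dλe^{−2σ}/(H(1−e^{−λd})) — which reproduces
the standard tabulated ungapped values (+1/−2 → λ = 1.3327, K = 0.6210);
the ungapped K is reused for gapped scores, with a config override.
Search space is raw m·n without edge correction: at E ≤ 10⁻⁴ and these
sequence lengths the correction is immaterial. Default scoring is
+1/−2 with affine gaps 5/2, the classic blastn-style scheme.

**Topology.** Circular molecules are searched after appending a prefix
of length `max_hit_span − 1`; hits are folded back modulo the molecule
length, cyclic duplicates dropped, and origin-crossing hits flagged
`wraps_origin` (their origin interval keeps `end > length` so the span
stays meaningful). For a two-chromosome linear genome each chromosome is
searched independently and hits labelled by chromosome, so insertions
originating inside the shared ITR are deliberately claimed by both
molecules; a `nonredundant` mode collapses those double counts.

**Oracle.** `numtscape.swalign` is a deliberately separate per-cell
Gotoh implementation with fixed tie-breaking (match > substitution >
gap-in-first-sequence > gap-in-second), used only as a test oracle.
Because the engine searches both strands, oracle comparisons take the
maximum of the plus-strand and reverse-complement optima.

## Calling and summaries

Filtering is inclusive on both boundaries: spans of exactly 50 bp and
E-values of exactly 10⁻⁴ are kept. The default `per_hit` mode calls one
NUMT per accepted alignment (per-alignment accounting, which is what
per-chromosome counts and summed-bp totals are built on); `merged` mode
unions overlapping nuclear intervals. The cumulative percentage uses
summed call lengths — overlapping calls double-count, so the union-based
percentage is reported alongside. The mtDNA fraction transferred is
computed on the union of origin intervals (origin-wrapping intervals are
split at the origin first). Length variance is reported with both
denominators (population n, and n−1).

## Duplication families and interruptions

"Same origin" is operationalized as reciprocal overlap ≥ 0.8 of the
mitochondrial origin intervals on the same chromosome, with distinct
(non-overlapping) nuclear loci; families are connected components of
that relation, and nothing in the component construction assumes
transitive consistency of the threshold. "Closely spaced in the
mitochondrion but apart in the nucleus" is quantified as: same scaffold,
same strand, collinear (reversed mitochondrial order on the minus
strand), mitochondrial gap in [−20, 100] bp (small negative tolerates
alignment end slop), nuclear gap in [50 bp, 50 kb]. The extracted gap is
classified by precedence: a repeat-library alignment passing the hit
filter → transposable element; otherwise ≥ 50% of 64-bp windows (step
32) below 1.2 bits of overlapping-trinucleotide Shannon entropy → low
complexity; otherwise other. The entropy detector stands in for a
simple-repeat track: 1.2 bits admits mono- and dinucleotide repeats
(entropy ≤ 1 bit) while a uniform-random window sits near 5.9 bits;
note that a *pure* period-3 repeat (1.585 bits) is deliberately outside
this definition.

## Genic context

Density pads the NUMT span by 5 kb per side (10 kb of window added in
total — the alternative ±10 kb reading is configurable), counts `gene`
features intersecting the half-open window, and maps 0 / 1–2 / >2 to
non-genic / low / high density. Localization precedence is wholly-inside
an intron (numbered in transcription order) → wholly inside an annotated
UTR → any exon overlap → intergenic. The UTR check must precede the exon
check because UTRs are sub-intervals of exons; putting the exon rule
first would make the UTR classes unreachable while still letting a
boundary-straddling NUMT be called exonic. A NUMT overlapping several
genes is assigned to the gene with the larger overlap (ties by gene id),
so each NUMT has exactly one host.

## Expression screen

An EST is *pure mitochondrial* when accepted mtDNA alignments cover
≥ 95% of it at ≥ 98% length-weighted identity (the filtering rule for
transcripts of the organelle itself, tolerant of sequencing error);
*chimeric* when at least one accepted alignment remains and a contiguous
non-mt block ≥ 50 bp survives; otherwise it carries no usable homology.
Chimeric ESTs are aligned to the nuclear genome; hits within 5 kb on one
scaffold form a candidate locus (5 kb exceeds the largest simulated
intron; transcripts spanning much larger introns would fragment into
separate loci — a known limitation), and a locus covering ≥ 90% of the
EST places it. The mt block is projected through the overlapping hit
onto the genome by linear interpolation (exact up to indel shift),
linked to an overlapping NUMT call if any, and classified `utr5` when it
falls inside an annotated 5′UTR of a gene with a CDS, else `internal`.
Copies of a duplication family are sequence-identical, so an EST derived
from one may link to any family member. Frame checks report internal
stop codons in all six frames under the universal code and NCBI
translation table 4 (mold/protozoan/coelenterate mitochondrial; TGA →
Trp), the cnidarian-appropriate choice.

## Synthetic data

The generator emulates the study system: by default two linear
mitochondrial chromosomes of 8,194 and 7,686 bp sharing an identical
150-bp ITR at both ends (right-hand copies reverse-complemented), a
2-Mb nuclear genome in 4 scaffolds at GC 0.35 (AT-rich, hydrozoan-like),
80 multi-exon genes (2–8 exons of 100–400 bp, introns 0.2–2 kb), and 100
planted insertions: lengths log-uniform on [100, 2000] bp (short
insertions dominate, mean several hundred bp), per-insertion
substitution rates uniform on [0, 0.10] with indels at one tenth the
substitution rate (geometric lengths, p = 0.5, ≤ 10 bp), random strand.
Thirty-nine duplication families (34 pairs, 4 triples, one six-member
family) copy one mutated insertion to additional loci; 6 insertions are
split by an interposed element (AT-rich microsatellite of period ≤ 2, or
a 2%-diverged copy of a generated repeat-library element); 5 are placed
wholly inside introns (all insertions within one host gene share an
orientation); 2 sit in 5′UTRs and feed the chimeric-EST classes. ESTs
comprise pure mitochondrial contaminants, 5′UTR-chimeric transcript
prefixes (spliced), internal chimeras (a planted NUMT with genomic
flanks), and insertion-free nuclear slices.

Scaffolds are assembled from a shuffled layout of blocks separated by
i.i.d. background, so planted intervals never overlap and every
coordinate in the truth ledger is exact by construction; all randomness
derives from one master seed through spawned sub-streams, giving
byte-identical outputs for identical configs. Independent insertions are
given *distinct* mitochondrial origins (resampled until reciprocal
overlap with every registered origin — including the piece sub-intervals
of interrupted insertions — stays below 0.7): duplication families are
the explicit model of shared origin, and coincidental origin collisions
would otherwise be indistinguishable from duplications under the 0.8
rule.

What the simulator does *not* model: realistic repeat landscapes beyond
the small generated library, codon structure in gene sequences, higher-
order background composition, splice-variant diversity, and NUMT decay
by large deletions. Passing recovery tests therefore demonstrates the
pipeline's correctness under the stated noise model, not performance on
repeat-dense real assemblies.

## Benchmarks and problem sizes

The recovery benchmark plants 100 insertions in a 2-Mb genome
(divergence ≤ 10%) and scores calls against the ledger at 50% reciprocal
overlap, matching interrupted insertions piecewise; the duplication
benchmark repeats it at divergence ≤ 5% and requires the family-size
histogram exactly. Both benchmark configs set `itr_length = 0`: ITR
double-reports are per-chromosome bookkeeping, not detection, and would
confound reciprocal-overlap scoring (the study-condition default keeps
the ITR). Oracle agreement uses 100 random 200-mer pairs sharing a
planted 11-mer. These sizes keep the full test suite and the acceptance
script each within a couple of minutes on one CPU while exercising every
stage at genome scale.

## Statistical utilities

The two-sample test is Student's pooled-variance t (df = n₁+n₂−2),
two-sided; degenerate zero-variance inputs return p = 1 (equal means) or
p = 0. Welch's variant is a scipy call away but the classical test is
the default by construction. The cross-genome correlation is Pearson's r
on (log₁₀ genome size, log₁₀ cumulative %) with non-positive pairs
excluded and counted, p via the t-transform with n−2 df. Length
histograms use fixed [0,100), [100,200), … bins.
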