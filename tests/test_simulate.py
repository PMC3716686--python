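"""Synthetic-genome generator: determinism, ledger truth, calibration."""

import numpy as np
import pytest

from numtscape.align import revcomp
from numtscape.simulate import (
    EstSpec,
    SimConfig,
    SimulationError,
    generate_ests,
    generate_mito_genome,
    generate_nuclear_genome,
    mutate_sequence,
)


class TestMitoGenome:
    def test_two_linear_chromosomes_sum_to_configured_total(self):
        cfg = SimConfig(seed=1)
        mito = generate_mito_genome(cfg)
        assert mito.lengths == {"mt-Chr1": 8194, "mt-Chr2": 7686}
        assert mito.total_length == 15_880

    def test_identical_inverted_terminal_repeats_on_both_chromosomes(self):
        mito = generate_mito_genome(SimConfig(seed=2, itr_length=150))
        c1, c2 = mito.chromosomes["mt-Chr1"], mito.chromosomes["mt-Chr2"]
        assert c1[:150] == c2[:150]  # identical left ITR copy
        assert c1[-150:] == revcomp(c1[:150])  # inverted right copy
        assert c2[-150:] == revcomp(c2[:150])

    def test_circular_single_molecule_without_itr(self):
        cfg = SimConfig(
            seed=3,
            mito_topology="circular",
            n_mito_chromosomes=1,
            mito_lengths=(16_389,),
            itr_length=0,
            intron_in_nd5=True,
        )
        mito = generate_mito_genome(cfg)
        assert mito.lengths == {"mtDNA": 16_389}
        assert mito.itr_intervals == {}
        assert mito.nd5_intron is not None

    def test_zero_itr_leaves_chromosome_ends_unrelated(self):
        mito = generate_mito_genome(SimConfig(seed=4, itr_length=0))
        c1, c2 = mito.chromosomes["mt-Chr1"], mito.chromosomes["mt-Chr2"]
        assert c1[:150] != c2[:150]

    def test_annotation_covers_required_gene_classes(self):
        mito = generate_mito_genome(SimConfig(seed=5))
        kinds = {}
        for f in mito.features:
            kinds.setdefault(f.ftype, set()).add(f.name)
        assert len(kinds["CDS"]) >= 13
        assert len(kinds["rRNA"]) == 2
        assert len(kinds["tRNA"]) >= 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mito_topology="circular", n_mito_chromosomes=2),
            dict(mito_lengths=(400, 300)),
            dict(itr_length=5_000),
            dict(divergence_range=(0.0, 0.5)),
            dict(n_intronic=200),
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            SimConfig(seed=1, **kwargs)


class TestNuclearGenome:
    def test_ledger_sequences_match_genome_slices(self, small_run):
        scaffolds, ledger = small_run["scaffolds"], small_run["ledger"]
        for ins in ledger.insertions:
            seq = scaffolds[ins.nuclear_scaffold]
            if ins.pieces:
                got = "".join(seq[s:e] for s, e in ins.pieces)
            else:
                got = seq[ins.nuclear_start : ins.nuclear_end]
            assert got == ins.sequence

    def test_planted_intervals_do_not_overlap(self, small_run):
        by_scaffold = {}
        for ins in small_run["ledger"].insertions:
            by_scaffold.setdefault(ins.nuclear_scaffold, []).append(ins.nuclear_interval)
        for ivs in by_scaffold.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_zero_divergence_plants_exact_substrings(self):
        cfg = SimConfig(
            seed=6,
            nuclear_length=400_000,
            n_scaffolds=1,
            n_genes=10,
            n_insertions=10,
            divergence_range=(0.0, 0.0),
            duplication_spec=(),
            n_interrupted=0,
            n_intronic=2,
            est_spec=EstSpec(0, 0, 0, 0),
        )
        mito = generate_mito_genome(cfg)
        scaffolds, _, ledger, _ = generate_nuclear_genome(cfg, mito)
        for ins in ledger.insertions:
            source = mito.chromosomes[ins.mito_chromosome][ins.mito_start : ins.mito_end]
            if ins.strand == "-":
                source = revcomp(source)
            assert scaffolds[ins.nuclear_scaffold].find(source) >= 0

    def test_duplication_spec_reproduced_in_ledger(self, recovery_run):
        # default spec: 34 families of 2, 4 of 3, 1 of 6 -> 39 families
        hist = recovery_run["ledger"].family_size_histogram()
        assert hist == {2: 34, 3: 4, 6: 1}
        assert sum(hist.values()) == 39

    def test_family_members_share_origin_at_distinct_loci(self, small_run):
        for members in small_run["ledger"].families().values():
            origins = {(m.mito_chromosome, m.mito_start, m.mito_end) for m in members}
            assert len(origins) == 1
            loci = {(m.nuclear_scaffold, m.nuclear_start) for m in members}
            assert len(loci) == len(members)

    def test_intronic_insertions_inside_introns_same_orientation_per_gene(self, small_run):
        genes = {g.id: g for g in small_run["genes"]}
        per_gene = {}
        for ins in small_run["ledger"].insertions:
            if ins.role != "intronic":
                continue
            gene = genes[ins.host_gene]
            assert any(
                s <= ins.nuclear_start and ins.nuclear_end <= e for s, e in gene.introns
            )
            per_gene.setdefault(ins.host_gene, set()).add(ins.strand)
        for strands in per_gene.values():
            assert len(strands) == 1

    def test_determinism_byte_identical_outputs(self):
        cfg = SimConfig(
            seed=7,
            nuclear_length=300_000,
            n_scaffolds=1,
            n_genes=8,
            n_insertions=12,
            duplication_spec=((2, 2),),
            n_interrupted=1,
            n_intronic=1,
            est_spec=EstSpec(1, 1, 1, 1),
        )
        runs = []
        for _ in range(2):
            mito = generate_mito_genome(cfg)
            scaffolds, genes, ledger, repeats = generate_nuclear_genome(cfg, mito)
            ests, table = generate_ests(cfg, mito, scaffolds, genes, ledger)
            runs.append((mito.chromosomes, scaffolds, repeats, ests, table))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]
        assert runs[0][2] == runs[1][2]
        assert runs[0][3] == runs[1][3]
        assert runs[0][4].equals(runs[1][4])

    def test_infeasible_placement_raises_with_constraint_named(self):
        cfg = SimConfig(
            seed=8,
            nuclear_length=40_000,
            n_scaffolds=1,
            n_genes=40,
            n_insertions=5,
            duplication_spec=(),
            n_interrupted=0,
            n_intronic=0,
            est_spec=EstSpec(0, 0, 0, 0),
        )
        mito = generate_mito_genome(cfg)
        with pytest.raises(SimulationError, match="cannot place"):
            generate_nuclear_genome(cfg, mito)

    def test_divergence_calibration_within_two_sd(self):
        # no indels: planted copies align positionally, so the empirical
        # mismatch rate is binomial around the configured substitution rate
        rate = 0.05
        cfg = SimConfig(
            seed=9,
            nuclear_length=900_000,
            n_scaffolds=1,
            n_genes=5,
            n_insertions=25,
            insertion_length_dist=(500, 2000, "uniform"),
            divergence_range=(rate, rate),
            indel_fraction=0.0,
            duplication_spec=(),
            n_interrupted=0,
            n_intronic=0,
            est_spec=EstSpec(0, 0, 0, 0),
        )
        mito = generate_mito_genome(cfg)
        scaffolds, _, ledger, _ = generate_nuclear_genome(cfg, mito)
        for ins in ledger.insertions:
            source = mito.chromosomes[ins.mito_chromosome][ins.mito_start : ins.mito_end]
            if ins.strand == "-":
                source = revcomp(source)
            planted = scaffolds[ins.nuclear_scaffold][ins.nuclear_start : ins.nuclear_end]
            assert len(planted) == len(source) >= 500
            mismatches = sum(1 for a, b in zip(source, planted) if a != b)
            n = len(source)
            sd = np.sqrt(rate * (1 - rate) / n)
            assert abs(mismatches / n - rate) <= 2 * sd + 1e-9


class TestMutator:
    def test_zero_rates_identity(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 100
        assert mutate_sequence(seq, 0.0, 0.0, rng) == seq

    def test_substitution_only_preserves_length(self):
        rng = np.random.default_rng(1)
        seq = "ACGT" * 250
        out = mutate_sequence(seq, 0.1, 0.0, rng)
        assert len(out) == len(seq)
        assert out != seq


class TestEsts:
    def test_pure_mito_ests_are_near_mitochondrial_substrings(self, small_run, params):
        from numtscape.align import search

        mito = small_run["mito"]
        truth = small_run["est_truth"]
        for est_id in truth[truth.category == "pure_mito"].est_id:
            est = small_run["ests"][est_id]
            best_cov = 0.0
            for chrom_seq in mito.chromosomes.values():
                for h in search(est, chrom_seq, params):
                    best_cov = max(best_cov, h.query_span / len(est))
            assert best_cov >= 0.95

    def test_chimeric_utr5_ests_contain_mt_and_coding_blocks(self, small_run, params):
        from numtscape.align import search

        mito = small_run["mito"]
        truth = small_run["est_truth"]
        ledger = small_run["ledger"].by_id()
        for row in truth[truth.category == "chimeric_utr5"].itertuples():
            est = small_run["ests"][row.est_id]
            ins = ledger[row.insertion_id]
            hits = [
                h
                for h in search(est, mito.chromosomes[ins.mito_chromosome], params)
                if h.evalue <= 1e-4
            ]
            assert hits, "no mt-homologous block found"
            covered = sum(h.query_span for h in hits)
            assert covered < 0.9 * len(est)  # a non-mt (coding) block remains

    def test_empty_est_spec_gives_empty_outputs(self):
        cfg = SimConfig(
            seed=10,
            nuclear_length=300_000,
            n_scaffolds=1,
            n_genes=6,
            n_insertions=6,
            duplication_spec=(),
            n_interrupted=0,
            n_intronic=0,
            est_spec=EstSpec(0, 0, 0, 0),
        )
        mito = generate_mito_genome(cfg)
        scaffolds, genes, ledger, _ = generate_nuclear_genome(cfg, mito)
        ests, table = generate_ests(cfg, mito, scaffolds, genes, ledger)
        assert ests == {}
        assert table.empty

    def test_ledger_round_trips_through_json(self, small_run, tmp_path):
        from numtscape.simulate import TruthLedger

        path = tmp_path / "ledger.json"
        small_run["ledger"].to_json(path)
        back = TruthLedger.from_json(path)
        assert len(back.insertions) == len(small_run["ledger"].insertions)
        for a, b in zip(back.insertions, small_run["ledger"].insertions):
            assert a == b
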