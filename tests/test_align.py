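"""Seeded local-alignment engine: statistics, search semantics, topology."""

import math

import numpy as np
import pytest

from numtscape.align import (
    CircularMap,
    ScoringParams,
    circularize,
    dedup_circular_hits,
    encode,
    hits_from_tsv,
    hits_to_tsv,
    karlin_k,
    revcomp,
    search,
    solve_lambda,
)

from conftest import random_seq


class TestKarlinAltschul:
    def test_lambda_closed_form_plus1_minus1(self):
        # 0.25 e^l + 0.75 e^-l = 1 has the closed-form root l = ln 3
        lam = solve_lambda(1, -1)
        assert lam == pytest.approx(math.log(3), abs=1e-9)

    def test_lambda_against_bisection_oracle(self):
        # independent bisection on the same transcendental equation
        def f(lam):
            return 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) - 1.0

        lo, hi = 1e-9, 4.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert solve_lambda(1, -2) == pytest.approx((lo + hi) / 2, abs=1e-8)

    @pytest.mark.parametrize("match,mismatch", [(1, -2), (1, -3), (2, -3), (1, -1)])
    def test_lambda_residual_below_1e9(self, match, mismatch):
        lam = solve_lambda(match, mismatch)
        p_match = 0.25
        residual = (
            p_match * math.exp(lam * match)
            + (1 - p_match) * math.exp(lam * mismatch)
            - 1.0
        )
        assert abs(residual) < 1e-9

    def test_non_negative_expected_score_rejected(self):
        with pytest.raises(ValueError):
            solve_lambda(1, 0)

    def test_k_matches_tabulated_ungapped_values(self):
        # classical tabulated ungapped (lambda, K) for blastn schemes
        assert karlin_k(1, -2) == pytest.approx(0.621, abs=0.005)
        assert karlin_k(1, -3) == pytest.approx(0.711, abs=0.005)

    def test_evalue_strictly_monotone_in_score(self, params):
        evs = [params.evalue(s, 15880, 2_000_000) for s in range(20, 200)]
        assert all(a > b for a, b in zip(evs, evs[1:]))


class TestSearch:
    def test_self_alignment_full_length_identity(self, params):
        rng = np.random.default_rng(42)
        q = random_seq(rng, 100)
        hits = search(q, q, params)
        top = hits[0]
        assert top.identity == 100.0
        assert top.score == 100 * params.match
        assert (top.query_start, top.query_end) == (0, 100)
        assert (top.subject_start, top.subject_end) == (0, 100)

    def test_empty_and_short_inputs_give_empty_results(self, params):
        assert search("", "ACGT" * 50, params) == []
        assert search("ACGT" * 50, "", params) == []
        assert search("ACGTACGT", "ACGT" * 50, params) == []  # < word_size

    def test_planted_diverged_segment_recovered(self, params):
        rng = np.random.default_rng(7)
        scaffold = list(random_seq(rng, 100_000))
        segment = random_seq(rng, 500)
        mutated = list(segment)
        for i in rng.choice(500, 25, replace=False):
            mutated[i] = rng.choice([c for c in "ACGT" if c != mutated[i]])
        scaffold[50_000:50_500] = mutated
        hits = [h for h in search(segment, "".join(scaffold), params) if h.evalue <= 1e-4]
        top = hits[0]
        overlap = min(top.subject_end, 50_500) - max(top.subject_start, 50_000)
        assert overlap >= 0.9 * 500
        assert 93.0 <= top.identity <= 97.0

    def test_strand_consistency_under_query_reversal(self, params):
        rng = np.random.default_rng(3)
        subject = random_seq(rng, 400)
        query = subject[100:250]
        fwd = search(query, subject, params)
        rev = search(revcomp(query), subject, params)
        flip = {"+": "-", "-": "+"}
        n = len(query)
        fwd_set = {
            (h.strand, h.query_start, h.query_end, h.subject_start, h.subject_end, h.score)
            for h in fwd
        }
        rev_set = {
            (flip[h.strand], n - h.query_end, n - h.query_start, h.subject_start, h.subject_end, h.score)
            for h in rev
        }
        assert fwd_set == rev_set

    def test_minus_strand_hit_found_and_labelled(self, params):
        rng = np.random.default_rng(11)
        segment = random_seq(rng, 300)
        scaffold = random_seq(rng, 5_000) + revcomp(segment) + random_seq(rng, 5_000)
        hits = search(segment, scaffold, params)
        top = hits[0]
        assert top.strand == "-"
        assert (top.subject_start, top.subject_end) == (5_000, 5_300)
        assert top.identity == 100.0

    def test_n_runs_never_seed(self, params):
        rng = np.random.default_rng(13)
        subject = random_seq(rng, 2_000)
        assert search("N" * 60, subject, params) == []

    def test_mito_self_search_reports_full_length_hit_first(self, small_run, params):
        mito = small_run["mito"]
        for chrom, seq in mito.chromosomes.items():
            top = search(seq, seq, params)[0]
            assert (top.query_start, top.query_end) == (0, len(seq))
            assert top.identity == 100.0


class TestCircular:
    def test_identity_extension_for_span_one(self):
        ext, cmap = circularize("ACGTACGTAC", 1)
        assert ext == "ACGTACGTAC"
        assert cmap.fold_interval(2, 7) == (2, 7, False)

    def test_span_larger_than_molecule_rejected(self):
        with pytest.raises(ValueError):
            circularize("ACGT", 5)

    def test_linear_topology_refused(self):
        with pytest.raises(ValueError):
            circularize("ACGTACGT", 4, topology="linear")

    def test_fold_flags_origin_wrap(self):
        cmap = CircularMap(100)
        s, e, wraps = cmap.fold_interval(90, 110)
        assert (s, e, wraps) == (90, 110, True)
        s, e, wraps = cmap.fold_interval(100, 130)
        assert (s, e, wraps) == (0, 30, False)

    def test_junction_spanning_numt_reported_folded(self):
        # plant a NUMT across the origin of a circular molecule and confirm
        # the engine reports one wrapped hit rather than a cyclic duplicate
        from numtscape.pipeline import search_genome
        from numtscape.simulate import (
            EstSpec,
            SimConfig,
            generate_mito_genome,
            generate_nuclear_genome,
        )

        cfg = SimConfig(
            seed=17,
            nuclear_length=200_000,
            n_scaffolds=1,
            n_genes=5,
            mito_topology="circular",
            n_mito_chromosomes=1,
            mito_lengths=(16_389,),
            itr_length=0,
            n_insertions=5,
            duplication_spec=(),
            n_interrupted=0,
            n_intronic=0,
            n_origin_spanning=2,
            divergence_range=(0.0, 0.02),
            est_spec=EstSpec(0, 0, 0, 0),
        )
        mito = generate_mito_genome(cfg)
        scaffolds, _, ledger, _ = generate_nuclear_genome(cfg, mito)
        wrapped_truth = [i for i in ledger.insertions if i.mito_end > 16_389]
        assert wrapped_truth
        hits = search_genome(mito, scaffolds)
        L = 16_389
        for ins in wrapped_truth:
            matches = [
                h
                for h in hits
                if h.wraps_origin
                and h.subject_start < ins.nuclear_end
                and ins.nuclear_start < h.subject_end
            ]
            assert matches, "origin-spanning insertion not reported as wrapped"
            h = matches[0]
            assert h.query_start < L < h.query_end


class TestTabularIO:
    def test_outfmt6_roundtrip_preserves_coordinates(self, params, tmp_path):
        rng = np.random.default_rng(23)
        segment = random_seq(rng, 200)
        scaffold = (
            random_seq(rng, 3_000) + segment + random_seq(rng, 1_000)
            + revcomp(segment) + random_seq(rng, 3_000)
        )
        hits = search(segment, scaffold, params, query_id="mt", subject_id="scaf")
        path = tmp_path / "hits.tsv"
        hits_to_tsv(hits, path)
        back = hits_from_tsv(path)
        assert len(back) == len(hits)
        for a, b in zip(hits, back):
            assert (a.query_start, a.query_end) == (b.query_start, b.query_end)
            assert (a.subject_start, a.subject_end) == (b.subject_start, b.subject_end)
            assert a.strand == b.strand
            assert a.identity == pytest.approx(b.identity, abs=0.01)

    def test_minus_strand_encoded_by_swapped_subject_coords(self, params, tmp_path):
        rng = np.random.default_rng(29)
        segment = random_seq(rng, 150)
        scaffold = random_seq(rng, 1_000) + revcomp(segment) + random_seq(rng, 1_000)
        hits = [h for h in search(segment, scaffold, params) if h.strand == "-"]
        path = tmp_path / "hits.tsv"
        hits_to_tsv(hits, path)
        line = path.read_text().strip().split("\n")[0].split("\t")
        sstart, send = int(line[8]), int(line[9])
        assert sstart > send


def test_encode_maps_acgt_and_n():
    codes = encode("ACGTNacgtn")
    assert codes.tolist() == [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]
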