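"""Duplication families, split pairs, and interruption classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from numtscape.duplication import (
    SplitPair,
    classify_interruption,
    family_size_histogram,
    find_split_pairs,
    group_duplicates,
    reciprocal_overlap,
    trinucleotide_entropy,
)

from conftest import random_seq
from test_calling import make_numt


class TestGrouping:
    def test_identical_origins_on_different_scaffolds_form_family(self):
        numts = [
            make_numt("a", 100, 600, scaffold="s1", mito=("mt", 0, 500)),
            make_numt("b", 100, 600, scaffold="s2", mito=("mt", 0, 500)),
        ]
        fams = group_duplicates(numts)
        assert len(fams) == 1
        assert fams[0].family_size == 2

    def test_small_origin_overlap_below_threshold_ignored(self):
        numts = [
            make_numt("a", 100, 1_100, scaffold="s1", mito=("mt", 0, 1_000)),
            make_numt("b", 5_000, 6_000, scaffold="s1", mito=("mt", 900, 1_900)),
        ]
        assert group_duplicates(numts) == []

    def test_same_nuclear_locus_not_a_duplication(self):
        # overlapping nuclear intervals are one locus, not a duplication
        numts = [
            make_numt("a", 100, 600, mito=("mt", 0, 500)),
            make_numt("b", 300, 800, mito=("mt", 0, 500)),
        ]
        assert group_duplicates(numts) == []

    def test_different_mito_chromosomes_never_grouped(self):
        numts = [
            make_numt("a", 100, 600, scaffold="s1", mito=("mt1", 0, 500)),
            make_numt("b", 100, 600, scaffold="s2", mito=("mt2", 0, 500)),
        ]
        assert group_duplicates(numts) == []

    def test_family_histogram_recovered_on_benchmark(self, duplication_run):
        assert duplication_run["family_histogram"] == duplication_run[
            "truth_family_histogram"
        ]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 40), st.integers(5, 30), st.integers(0, 3)),
            min_size=2,
            max_size=12,
        )
    )
    def test_components_match_brute_force_closure(self, raw):
        numts = [
            make_numt(f"n{i}", i * 10_000, i * 10_000 + 100, scaffold=f"s{scaf}",
                      mito=("mt", start * 25, start * 25 + length * 25))
            for i, (start, length, scaf) in enumerate(raw)
        ]
        fams = group_duplicates(numts, 0.8)
        # brute-force: pairwise matrix + transitive closure
        n = len(numts)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                a, b = numts[i], numts[j]
                distinct = a.nuclear_scaffold != b.nuclear_scaffold or (
                    a.nuclear_end <= b.nuclear_start or b.nuclear_end <= a.nuclear_start
                )
                if (
                    a.mito_chromosome == b.mito_chromosome
                    and reciprocal_overlap(a.mito_interval, b.mito_interval) >= 0.8
                    and distinct
                ):
                    adj[i, j] = True
        reach = adj | np.eye(n, dtype=bool)
        for _ in range(n):
            reach = reach | (reach @ reach)
        expected = set()
        seen = set()
        for i in range(n):
            if i in seen:
                continue
            comp = frozenset(np.nonzero(reach[i] | reach[:, i])[0].tolist())
            comp = frozenset(
                j for j in range(n) if reach[i, j] or reach[j, i] or j == i
            )
            seen |= comp
            if len(comp) >= 2 and any(adj[a, b] for a in comp for b in comp):
                expected.add(frozenset(numts[j].id for j in comp))
        got = {frozenset(f.member_numt_ids) for f in fams}
        assert got == expected

    def test_raising_threshold_never_grows_grouped_membership(self):
        rng = np.random.default_rng(0)
        numts = []
        for i in range(30):
            start = int(rng.integers(0, 2_000))
            length = int(rng.integers(100, 800))
            numts.append(
                make_numt(f"n{i}", i * 5_000, i * 5_000 + length,
                          mito=("mt", start, start + length))
            )
        sizes = []
        for thr in (0.5, 0.7, 0.9, 1.0):
            fams = group_duplicates(numts, thr)
            sizes.append(sum(f.family_size for f in fams))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestSplitPairs:
    def test_collinear_same_strand_pair_reported_with_gap(self):
        numts = [
            make_numt("a", 10_000, 10_500, mito=("mt", 0, 500)),
            make_numt("b", 14_000, 14_400, mito=("mt", 510, 900)),
        ]
        pairs = find_split_pairs(numts)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.gap_start, p.gap_end) == (10_500, 14_000)
        assert p.mito_gap == 10

    def test_opposite_strands_not_reported(self):
        numts = [
            make_numt("a", 10_000, 10_500, mito=("mt", 0, 500), strand="+"),
            make_numt("b", 14_000, 14_400, mito=("mt", 510, 900), strand="-"),
        ]
        assert find_split_pairs(numts) == []

    def test_minus_strand_pair_uses_reversed_mito_order(self):
        numts = [
            make_numt("a", 10_000, 10_400, mito=("mt", 510, 900), strand="-"),
            make_numt("b", 14_000, 14_500, mito=("mt", 0, 500), strand="-"),
        ]
        pairs = find_split_pairs(numts)
        assert len(pairs) == 1
        assert pairs[0].mito_gap == 10

    def test_adjacent_numts_below_separation_not_reported(self):
        numts = [
            make_numt("a", 10_000, 10_500, mito=("mt", 0, 500)),
            make_numt("b", 10_520, 10_900, mito=("mt", 510, 900)),
        ]
        assert find_split_pairs(numts, min_nuclear_separation=50) == []

    def test_planted_interruptions_recovered(self, recovery_run):
        assert recovery_run["split_planted"] >= 1
        assert recovery_run["split_recovered"] == recovery_run["split_planted"]


class TestInterruptionClassification:
    def pair(self):
        return SplitPair("a", "b", "s1", 0, 400, 5, "+")

    def test_dyad_repeat_is_low_complexity(self):
        # trinucleotide entropy of (AT)n is exactly 1 bit (ATA and TAT)
        gap = "AT" * 200
        assert trinucleotide_entropy(gap[:64]) == pytest.approx(1.0, abs=0.01)
        call = classify_interruption(self.pair(), gap)
        assert call.classification == "low_complexity"

    def test_planted_library_element_detected_as_te(self):
        rng = np.random.default_rng(1)
        te = random_seq(rng, 1_200)
        gap = list(te[:600])
        for i in rng.choice(600, 12, replace=False):  # 2% divergence
            gap[i] = rng.choice([c for c in "ACGT" if c != gap[i]])
        call = classify_interruption(self.pair(), "".join(gap), {"TE_x": te})
        assert call.classification == "transposable_element"
        assert call.evidence == "TE_x"

    def test_random_uniform_gap_is_other(self):
        # Monte-Carlo: random 400-mers essentially never look low-complexity
        rng = np.random.default_rng(2)
        others = sum(
            classify_interruption(self.pair(), random_seq(rng, 400)).classification
            == "other"
            for _ in range(200)
        )
        assert others >= 198

    def test_te_precedence_over_low_complexity(self):
        te = "AT" * 300  # a library element that is itself low-complexity
        call = classify_interruption(self.pair(), "AT" * 250, {"TE_at": te})
        assert call.classification == "transposable_element"

    def test_empty_gap_rejected(self):
        with pytest.raises(ValueError):
            classify_interruption(self.pair(), "")

    def test_classification_deterministic(self):
        rng = np.random.default_rng(3)
        gap = random_seq(rng, 500)
        a = classify_interruption(self.pair(), gap)
        b = classify_interruption(self.pair(), gap)
        assert a == b

    def test_pipeline_classifies_planted_elements_correctly(self, recovery_run):
        ledger = recovery_run["ledger"]
        planted = {
            (i.interrupted_by["start"], i.interrupted_by["end"]): i.interrupted_by["kind"]
            for i in ledger.insertions
            if i.interrupted_by
        }
        matched = 0
        for call in recovery_run["interruptions"]:
            for (es, ee), kind in planted.items():
                ov = max(0, min(call.gap_end, ee) - max(call.gap_start, es))
                if ov >= 0.8 * (ee - es):
                    expected = (
                        "transposable_element" if kind == "te" else "low_complexity"
                    )
                    assert call.classification == expected
                    matched += 1
        assert matched == len(planted)


def test_family_size_histogram_counts():
    from numtscape.duplication import NumtFamily

    fams = [
        NumtFamily("f1", ["a", "b"], "mt", (0, 100)),
        NumtFamily("f2", ["c", "d"], "mt", (0, 100)),
        NumtFamily("f3", ["e", "f", "g"], "mt", (0, 100)),
    ]
    assert family_size_histogram(fams) == {2: 2, 3: 1}
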