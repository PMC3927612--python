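"""Tests of DA construction, alignment, difference classification and the
aggregate statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paranet import architectures as arch


def _ann(rows, protein_id="P1"):
    return pd.DataFrame(
        [
            {"protein_id": protein_id, "family_id": f, "start": s, "end": e, "evalue": ev}
            for f, s, e, ev in rows
        ]
    )


class TestBuildArchitecture:
    def test_non_overlapping_hits_in_start_order(self):
        da = arch.build_architecture(
            _ann([("a", 1, 50, 1e-10), ("b", 60, 120, 1e-8)]), 1e-5
        )
        assert da.domains == ("a", "b")

    def test_overlapping_weaker_hit_eliminated(self):
        da = arch.build_architecture(
            _ann([("a", 1, 50, 1e-10), ("a2", 10, 55, 1e-6)]), 1e-5
        )
        assert da.domains == ("a",)

    def test_small_overlap_tolerated(self):
        # 10 residues shared out of a 50-residue hit: 20% < 30% tolerance
        da = arch.build_architecture(
            _ann([("a", 1, 50, 1e-10), ("b", 41, 90, 1e-8)]), 1e-5
        )
        assert da.domains == ("a", "b")

    def test_cutoff_threshold_semantics(self):
        rows = _ann([("a", 1, 50, 1e-4)])
        assert arch.build_architecture(rows, 1e-5).domains == ()
        assert arch.build_architecture(rows, 1e-2).domains == ("a",)

    def test_start_after_end_rejected(self):
        with pytest.raises(ValueError):
            arch.build_architecture(_ann([("a", 50, 10, 1e-10)]), 1e-5)

    def test_relaxing_cutoff_only_adds_domains(self, rng):
        """Architectures grow as supersets (as multisets of families) as the
        cutoff loosens."""
        for _ in range(30):
            n = int(rng.integers(1, 8))
            rows = []
            pos = 1
            for i in range(n):
                length = int(rng.integers(30, 90))
                rows.append(
                    (f"f{rng.integers(4)}", pos, pos + length, 10.0 ** -rng.uniform(1, 12))
                )
                pos += length + int(rng.integers(1, 20))
            frame = _ann(rows)
            previous = None
            for cutoff in (1e-5, 1e-4, 1e-3, 1e-2):
                domains = arch.build_architecture(frame, cutoff).domains
                if previous is not None:
                    counts_prev = {f: previous.count(f) for f in previous}
                    counts_now = {f: domains.count(f) for f in domains}
                    for fam, c in counts_prev.items():
                        assert counts_now.get(fam, 0) >= c
                previous = domains


def _brute_force_lcs_length(a, b):
    best = 0
    for r in range(len(a), 0, -1):
        for idx_a in itertools.combinations(range(len(a)), r):
            sub = tuple(a[i] for i in idx_a)
            for idx_b in itertools.combinations(range(len(b)), r):
                if tuple(b[j] for j in idx_b) == sub:
                    best = r
                    break
            if best == r:
                break
        if best:
            break
    return best


class TestAlignment:
    def test_identical_lists_fully_matched(self):
        al = arch.align_architectures(["a", "b"], ["a", "b"])
        assert al.matches == ((0, 0), (1, 1))
        assert al.unmatched_a == al.unmatched_b == ()

    def test_single_insertion_detected(self):
        al = arch.align_architectures(["a", "s", "b"], ["a", "b"])
        assert al.matches == ((0, 0), (2, 1))
        assert al.unmatched_a == (1,)

    def test_tandem_core_matches_confirmed_by_enumeration(self):
        a, b = ["x", "s", "s", "z"], ["a", "s", "s", "b"]
        al = arch.align_architectures(a, b)
        assert len(al.matches) == _brute_force_lcs_length(a, b) == 2
        assert al.matches == ((1, 1), (2, 2))

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(st.sampled_from("abcs"), max_size=7),
        st.lists(st.sampled_from("abcs"), max_size=7),
    )
    def test_lcs_length_matches_brute_force(self, a, b):
        al = arch.align_architectures(a, b)
        assert len(al.matches) == _brute_force_lcs_length(a, b)
        # matched pairs strictly increasing on both sides
        for (i1, j1), (i2, j2) in zip(al.matches, al.matches[1:]):
            assert i1 < i2 and j1 < j2


class TestClassifyDifference:
    CASES = [
        (["a", "b"], ["a", "b"], {arch.IDENTICAL}),
        (["s", "a", "b"], ["a", "b"], {arch.N_TERMINAL}),
        (["a", "b", "s"], ["a", "b"], {arch.C_TERMINAL}),
        (["a", "s", "b"], ["a", "b"], {arch.INTERNAL}),
        (["a", "s", "s", "b"], ["a", "s", "b"], {arch.DUPLICATION}),
        (["x", "s", "s", "z"], ["a", "s", "s", "b"], {arch.N_TERMINAL, arch.C_TERMINAL}),
        (["a", "b"], ["x", "z"], {arch.UNASSIGNED}),
    ]

    @pytest.mark.parametrize("a,b,expected", CASES)
    def test_category_assignment(self, a, b, expected):
        assert arch.compare_pair(a, b) == frozenset(expected)

    @pytest.mark.parametrize("a,b,expected", CASES)
    def test_classification_symmetric(self, a, b, expected):
        assert arch.compare_pair(a, b) == arch.compare_pair(b, a)

    def test_terminal_tandem_copy_counts_as_duplication(self):
        assert arch.compare_pair(["s", "s", "a"], ["s", "a"]) == frozenset(
            {arch.DUPLICATION}
        )

    def test_multiple_categories_union(self):
        assert arch.compare_pair(["n", "a", "q", "b"], ["a", "b"]) == frozenset(
            {arch.N_TERMINAL, arch.INTERNAL}
        )


class TestTransitionType:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (1, 2, arch.TYPE1),
            (2, 1, arch.TYPE1),
            (2, 3, arch.TYPE2),
            (5, 6, arch.TYPE3),
            (3, 3, arch.TYPE_NA),
            (2, 4, arch.TYPE_NA),
            (0, 1, arch.TYPE_NA),
        ],
    )
    def test_types(self, a, b, expected):
        assert arch.transition_type(a, b) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            arch.transition_type(-1, 0)


class TestMulticutoff:
    def test_identical_at_all_cutoffs(self):
        ann = _ann([("a", 1, 50, 1e-10)])
        record = arch.classify_pair_multicutoff(ann, ann.assign(protein_id="P2"))
        assert all(
            cats == frozenset({arch.IDENTICAL})
            for cats in record.categories.values()
        )
        assert record.n_domain_diff == 0
        assert record.transition_type == arch.TYPE_NA

    def test_weak_domain_appears_only_at_loose_cutoffs(self):
        # the cutoff is a strict upper bound, so 9e-4 qualifies at <1e-3
        ann_a = _ann([("a", 1, 50, 1e-10), ("w", 60, 100, 9e-4)])
        ann_b = _ann([("a", 1, 50, 1e-10)], protein_id="P2")
        record = arch.classify_pair_multicutoff(ann_a, ann_b)
        assert record.categories[1e-5] == frozenset({arch.IDENTICAL})
        assert record.categories[1e-4] == frozenset({arch.IDENTICAL})
        assert record.categories[1e-3] == frozenset({arch.C_TERMINAL})
        assert record.categories[1e-2] == frozenset({arch.C_TERMINAL})

    def test_domain_count_and_type_taken_at_primary_cutoff(self):
        ann_a = _ann([("a", 1, 50, 1e-10)])
        ann_b = _ann([("a", 1, 50, 1e-10), ("b", 60, 110, 1e-9)], protein_id="P2")
        record = arch.classify_pair_multicutoff(ann_a, ann_b)
        assert record.n_domain_diff == 1
        assert record.transition_type == arch.TYPE1

    def test_exactly_four_nonempty_assignments(self):
        ann_a = _ann([("a", 1, 50, 1e-10), ("s", 60, 100, 1e-4)])
        ann_b = _ann([("b", 1, 50, 1e-7)], protein_id="P2")
        record = arch.classify_pair_multicutoff(ann_a, ann_b)
        assert len(record.categories) == 4
        for cats in record.categories.values():
            assert cats
            if arch.IDENTICAL in cats:
                assert cats == frozenset({arch.IDENTICAL})


class TestAggregates:
    def test_homogeneous_pair_cluster(self):
        archs = {"p1": ("A", "B"), "p2": ("A", "B")}
        assert arch.aggregate_homogeneity([["p1", "p2"]], archs) == (100.0, 0.0)

    def test_mixed_cluster_counts_pairs(self):
        archs = {"p1": ("A", "B"), "p2": ("A", "B"), "p3": ("A",)}
        pct_hom, pct_diff = arch.aggregate_homogeneity([["p1", "p2", "p3"]], archs)
        assert pct_hom == 0.0
        assert pct_diff == pytest.approx(200.0 / 3, abs=0.05)

    def test_two_clusters_pooled(self):
        archs = {
            "p1": ("A", "B"), "p2": ("A", "B"), "p3": ("A",),
            "q1": ("C",), "q2": ("C",),
        }
        pct_hom, pct_diff = arch.aggregate_homogeneity(
            [["p1", "p2", "p3"], ["q1", "q2"]], archs
        )
        assert pct_hom == 50.0
        # enumeration: 4 within-cluster pairs in total, 2 differ
        assert pct_diff == pytest.approx(50.0)

    def test_undersized_cluster_skipped_with_warning(self):
        archs = {"p1": ("A",), "q1": ("C",), "q2": ("C",)}
        with pytest.warns(UserWarning):
            pct_hom, _ = arch.aggregate_homogeneity([["p1"], ["q1", "q2"]], archs)
        assert pct_hom == 100.0

    def _record(self, cats_by_cutoff, n_diff=1, ttype=arch.TYPE1):
        return arch.DADifferenceRecord(
            "a", "b", cats_by_cutoff, n_domain_diff=n_diff, transition_type=ttype
        )

    def test_positional_distribution_single_category(self):
        record = self._record(
            {c: frozenset({arch.N_TERMINAL}) for c in arch.DEFAULT_CUTOFFS}
        )
        frame = arch.positional_distribution([record])
        by_cat = frame.set_index("category")["proportion_pct"]
        assert by_cat[arch.N_TERMINAL] == 100.0

    def test_positional_distribution_splits_multi_category(self):
        record = self._record(
            {
                c: frozenset({arch.N_TERMINAL, arch.C_TERMINAL})
                for c in arch.DEFAULT_CUTOFFS
            }
        )
        frame = arch.positional_distribution([record])
        by_cat = frame.set_index("category")["proportion_pct"]
        assert by_cat[arch.N_TERMINAL] == by_cat[arch.C_TERMINAL] == 50.0

    def test_all_identical_records_flagged(self):
        record = self._record(
            {c: frozenset({arch.IDENTICAL}) for c in arch.DEFAULT_CUTOFFS},
            n_diff=0,
            ttype=arch.TYPE_NA,
        )
        with pytest.warns(UserWarning):
            frame = arch.positional_distribution([record])
        assert frame["count"].sum() == 0

    def test_count_diff_distribution_binning(self):
        records = [self._record({}, n_diff=d) for d in (1, 1, 2, 4)]
        frame = arch.domain_count_diff_distribution(records)
        by_bin = frame.set_index("n_domain_diff")["proportion_pct"]
        assert by_bin["1"] == 50.0
        assert by_bin["2"] == 25.0
        assert by_bin["3"] == 0.0
        assert by_bin[">=4"] == 25.0

    def test_count_diff_single_large_difference(self):
        frame = arch.domain_count_diff_distribution([self._record({}, n_diff=7)])
        assert frame.set_index("n_domain_diff")["proportion_pct"][">=4"] == 100.0

    def test_count_diff_all_zero_flagged(self):
        with pytest.warns(UserWarning):
            frame = arch.domain_count_diff_distribution(
                [self._record({}, n_diff=0)]
            )
        assert frame["count"].sum() == 0


class TestRate:
    def test_zero_percent_gives_zero_rate(self):
        assert arch.rate_per_my(0.0, 910.0).rate_lb == 0.0

    def test_non_positive_time_rejected(self):
        with pytest.raises(ValueError):
            arch.rate_per_my(28.0, 0.0)

    def test_percentage_bounds_enforced(self):
        with pytest.raises(ValueError):
            arch.rate_per_my(101.0, 910.0)
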