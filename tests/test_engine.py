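"""Frame engine: worked examples on the dystrophin fixture plus exhaustive
oracle-equivalence properties on random synthetic transcripts."""

import pytest
from hypothesis import given, settings, strategies as st

from skipscan import (
    EngineConfig,
    Mutation,
    annotate,
    deletion_frame_status,
    deletion_skips,
    duplication_double_copy_rescue,
    duplication_skips,
    multi_skip_applicable,
    small_lesion_skips,
    strategy_label,
)
from skipscan.engine import DOUBLE_COPY_RESCUE, NO_ASO_NEEDED

from conftest import (
    make_transcript,
    oracle_deletion_skips,
    oracle_double_copy_rescue,
    oracle_duplication_skips,
    oracle_intra_lesion_skips,
    oracle_splice_lesion_skips,
)

# transcripts for the property suite: 5-15 exons, coding lengths 1-300
transcripts = st.lists(st.integers(1, 300), min_size=5, max_size=15).map(make_transcript)


def target_sets(strategies):
    return {s.targets for s in strategies}


class TestDeletions:
    def test_frame_status_examples(self, dmd):
        assert deletion_frame_status(dmd, 52, 52) == "frameshift"
        assert deletion_frame_status(dmd, 45, 55) == "in_frame"
        assert deletion_frame_status(dmd, 3, 9) == "in_frame"
        # deleting a single symmetric exon never shifts the frame
        sym = next(e for e in range(1, 80) if dmd.is_symmetric(e))
        assert deletion_frame_status(dmd, sym, sym) == "in_frame"

    def test_exon52_deletion_rescued_by_51_or_53(self, dmd):
        skips = deletion_skips(dmd, 52, 52)
        singles = {s.targets for s in skips if s.category == "single"}
        assert singles == {frozenset([51]), frozenset([53])}

    def test_cross_flank_double_for_deletion_46_50(self, dmd):
        skips = deletion_skips(dmd, 46, 50)
        assert frozenset([45, 51]) in target_sets(skips)

    def test_in_frame_deletion_is_contract_error(self, dmd):
        with pytest.raises(ValueError, match="in-frame"):
            deletion_skips(dmd, 45, 55)

    def test_excluded_regions_are_contiguous_and_in_frame(self, dmd):
        for first, last in [(48, 50), (2, 2), (10, 43), (52, 52), (77, 78)]:
            if deletion_frame_status(dmd, first, last) != "frameshift":
                continue
            for s in deletion_skips(dmd, first, last):
                region = sorted(s.excluded_region)
                assert region == list(range(region[0], region[-1] + 1))
                assert sum(dmd.coding_length(e) for e in region) % 3 == 0

    @settings(max_examples=400, derandomize=True)
    @given(t=transcripts, data=st.data())
    def test_matches_exhaustive_oracle(self, t, data):
        first = data.draw(st.integers(1, t.n_exons))
        last = data.draw(st.integers(first, t.n_exons))
        if deletion_frame_status(t, first, last) == "in_frame":
            return
        assert target_sets(deletion_skips(t, first, last)) == oracle_deletion_skips(
            t, first, last
        )


class TestSmallLesions:
    def test_symmetric_exon_single_skip(self, dmd):
        # exon 35 (180 nt) is symmetric: the lesion-bearing exon itself is the target
        m = Mutation.small_lesion("x", 35, "intra")
        (s,) = small_lesion_skips(dmd, m)
        assert s.targets == frozenset([35]) and s.category == "single"

    def test_asymmetric_exon_70_pairs_with_69(self, dmd):
        m = Mutation.small_lesion("x", 70, "intra")
        skips = small_lesion_skips(dmd, m)
        assert frozenset([69, 70]) in target_sets(skips)
        for s in skips:
            assert sum(dmd.coding_length(e) for e in s.targets) % 3 == 0

    def test_donor_lesion_own_exon_convention(self, dmd):
        m = Mutation.small_lesion("x", 52, "donor")
        skips = small_lesion_skips(dmd, m)
        assert target_sets(skips) == target_sets(deletion_skips(dmd, 52, 52))
        assert all(52 not in s.targets or len(s.targets) > 1 for s in skips)

    def test_splice_on_symmetric_exon_needs_no_aso(self, dmd):
        m = Mutation.small_lesion("x", 35, "acceptor")
        (s,) = small_lesion_skips(dmd, m)
        assert s.targets == frozenset() and s.note == NO_ASO_NEEDED
        assert s.category == "none"

    def test_neighbor_convention_shifts_lost_exon(self, dmd):
        cfg = EngineConfig(splice_loss_convention="neighbor")
        m = Mutation.small_lesion("x", 51, "donor")
        # literal reading: the downstream exon (52) is lost
        skips = small_lesion_skips(dmd, m, cfg)
        assert target_sets(skips) == target_sets(deletion_skips(dmd, 52, 52))

    def test_terminal_exon_lesion_yields_empty_list(self):
        # 5-exon transcript, every exon asymmetric: no pair fits inside [2, n-1]
        t = make_transcript([4, 4, 4, 4, 4])
        assert small_lesion_skips(t, Mutation.small_lesion("x", 1, "intra")) == []

    @settings(max_examples=400, derandomize=True)
    @given(t=transcripts, data=st.data())
    def test_matches_exhaustive_oracle(self, t, data):
        e = data.draw(st.integers(1, t.n_exons))
        site = data.draw(st.sampled_from(["intra", "donor", "acceptor"]))
        if site == "donor" and e == t.n_exons:
            return
        if site == "acceptor" and e == 1:
            return
        m = Mutation.small_lesion("x", e, site)
        got = small_lesion_skips(t, m)
        if site == "intra":
            expected = oracle_intra_lesion_skips(t, e)
        elif t.is_symmetric(e):  # own-exon convention: lost exon is e
            assert [s.note for s in got] == [NO_ASO_NEEDED]
            return
        else:
            expected = oracle_splice_lesion_skips(t, e)
        assert target_sets(got) == expected


class TestDuplications:
    def test_single_exon_duplication_always_self_skippable(self, dmd):
        skips = duplication_skips(dmd, 2, 2)
        assert frozenset([2]) in target_sets(skips)

    def test_adjacent_pair_6_7(self, dmd):
        dup_len = dmd.segment_length(6, 7)
        assert dup_len % 3 != 0
        skips = duplication_skips(dmd, 6, 7)
        pair = frozenset([6, 7])
        assert (pair in target_sets(skips)) == ((dup_len - dup_len) % 3 == 0)

    def test_in_frame_duplication_is_contract_error(self, dmd):
        with pytest.raises(ValueError, match="in-frame"):
            duplication_skips(dmd, 45, 55)

    def test_double_copy_rescue_of_exon_52(self, dmd):
        rescues = duplication_double_copy_rescue(dmd, 52)
        assert target_sets(rescues) == {frozenset([51]), frozenset([53])}
        assert all(s.note == DOUBLE_COPY_RESCUE for s in rescues)

    def test_rescue_on_symmetric_exon_rejected(self, dmd):
        with pytest.raises(ValueError, match="symmetric"):
            duplication_double_copy_rescue(dmd, 35)

    def test_rescue_fraction_matches_brute_force(self, dmd):
        engine = sum(
            1 for e in range(2, 79)
            if not dmd.is_symmetric(e) and duplication_double_copy_rescue(dmd, e)
        )
        brute = sum(
            1 for e in range(2, 79)
            if not dmd.is_symmetric(e) and oracle_double_copy_rescue(dmd, e)
        )
        assert engine == brute

    @settings(max_examples=400, derandomize=True)
    @given(t=transcripts, data=st.data())
    def test_matches_exhaustive_oracle(self, t, data):
        first = data.draw(st.integers(1, t.n_exons))
        last = data.draw(st.integers(first, t.n_exons))
        if t.segment_length(first, last) % 3 == 0:
            return
        assert target_sets(duplication_skips(t, first, last)) == oracle_duplication_skips(
            t, first, last
        )
        if first == last:
            assert target_sets(duplication_double_copy_rescue(t, first)) == \
                oracle_double_copy_rescue(t, first)


class TestMultiSkip:
    def test_containment_rule(self, dmd):
        assert multi_skip_applicable(dmd, Mutation.deletion("x", 52, 52), 45, 55)
        assert not multi_skip_applicable(dmd, Mutation.deletion("x", 44, 50), 45, 55)
        assert multi_skip_applicable(dmd, Mutation.small_lesion("x", 6), 3, 9)
        assert not multi_skip_applicable(dmd, Mutation.duplication("x", 46, 47), 45, 55)

    def test_in_frame_deletion_not_applicable(self, dmd):
        assert not multi_skip_applicable(dmd, Mutation.deletion("x", 45, 55), 45, 55)

    def test_out_of_frame_cocktail_rejected(self, dmd):
        with pytest.raises(ValueError, match="in-frame"):
            multi_skip_applicable(dmd, Mutation.deletion("x", 52, 52), 45, 54)

    def test_splice_lesion_uses_lost_exon(self, dmd):
        m = Mutation.small_lesion("x", 45, "acceptor")
        assert multi_skip_applicable(dmd, m, 45, 55)
        cfg = EngineConfig(splice_loss_convention="neighbor")
        # literal reading: acceptor lesion on exon 45 removes exon 44 (outside)
        assert not multi_skip_applicable(dmd, m, 45, 55, cfg)


class TestAnnotate:
    def test_worked_example_deletion_52(self, dmd):
        a = annotate(dmd, Mutation.deletion("m", 52, 52))
        assert a.frame_status == "frameshift"
        labels = {s.label for s in a.strategies}
        assert {"51", "53", "45–55"} <= labels
        singles = {s.label for s in a.strategies if s.category == "single"}
        assert singles == {"51", "53"}

    def test_in_frame_deletion_has_no_strategies(self, dmd):
        a = annotate(dmd, Mutation.deletion("m", 45, 55))
        assert a.frame_status == "in_frame" and a.strategies == ()

    def test_duplication_2_with_rescues(self, dmd):
        a = annotate(dmd, Mutation.duplication("m", 2, 2))
        assert {s.label for s in a.by_category("single")} >= {"2"}
        rescue_labels = {s.label for s in a.strategies if s.note == DOUBLE_COPY_RESCUE}
        # exon 2 (62 nt) pairs with a neighbour iff their sum is a multiple of 3
        expected = {
            str(f) for f in (3,) if (dmd.coding_length(2) + dmd.coding_length(f)) % 3 == 0
        }
        assert rescue_labels == expected

    def test_annotation_deduplicated_and_deterministic(self, dmd):
        m = Mutation.duplication("m", 2, 2)
        a1, a2 = annotate(dmd, m), annotate(dmd, m)
        assert a1 == a2
        keys = [(s.targets, s.category) for s in a1.strategies]
        assert len(keys) == len(set(keys))

    def test_labels_follow_table_conventions(self, dmd):
        a = annotate(dmd, Mutation.small_lesion("m", 70, "intra"))
        for s in a.strategies:
            if s.category == "double":
                lo, hi = sorted(s.targets)
                assert strategy_label(s) == f"{lo} & {hi}"
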