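"""The segmentation algorithm: grouping, classification, block extension."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfrscan import (
    CallerParams,
    Probe,
    ProbeGroup,
    ProbeTrack,
    blocks_to_hfrs,
    call_blocks,
    call_hfrs,
    classify_group,
    cross_array_consistency,
    partition_groups,
)
from hfrscan.caller import HIGH, LOW, HFR, HFRCatalog

from conftest import make_track


def contiguous_probes(n, chrom="chrT", start=0, step=50, length=60, nlr=-1.0):
    return [
        Probe(chrom, start + i * step, start + i * step + length, nlr) for i in range(n)
    ]


class TestPartitionGroups:
    def test_exact_division_into_groups_of_five(self):
        groups = partition_groups(contiguous_probes(10))
        assert [len(g.probes) for g in groups] == [5, 5]
        assert {g.segment for g in groups} == {0}

    def test_gap_over_200bp_restarts_partition(self):
        # 12 probes with a 250-bp gap after the 7th
        left = contiguous_probes(7)
        gap_start = left[-1].end + 250
        right = contiguous_probes(5, start=gap_start)
        groups = partition_groups(left + right)
        assert [len(g.probes) for g in groups] == [5, 2, 5]
        assert [g.segment for g in groups] == [0, 0, 1]

    def test_overlapping_tiling_never_triggers_gap_rule(self):
        # 60-mers at 50-bp step: inter-probe gap = next.start - prev.end = -10
        probes = contiguous_probes(23)
        assert all(
            b.start - a.end == -10 for a, b in zip(probes, probes[1:])
        )
        groups = partition_groups(probes)
        assert {g.segment for g in groups} == {0}

    def test_trailing_partial_group_retained(self):
        groups = partition_groups(contiguous_probes(7))
        assert [len(g.probes) for g in groups] == [5, 2]

    def test_empty_track_gives_empty_list(self):
        assert partition_groups([]) == []

    def test_multi_chromosome_input_rejected(self):
        probes = contiguous_probes(2) + contiguous_probes(2, chrom="chrU")
        with pytest.raises(ValueError, match="one chromosome"):
            partition_groups(probes)


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "nlrs,expected",
        [
            ((-1, -1, -1, -1, -1), LOW),
            ((1, 1, 1, 1, 1), HIGH),
            # exactly three strict negatives; 0.0 counts as non-negative
            ((-0.2, -0.1, 0.0, 0.3, -0.4), LOW),
            ((-0.2, -0.1, 0.0, 0.0, 0.4), HIGH),
            ((-1, -1, 1, 1, 1), HIGH),
        ],
    )
    def test_low_iff_three_or_more_strict_negatives(self, nlrs, expected):
        probes = [Probe("c", i * 50, i * 50 + 60, v) for i, v in enumerate(nlrs)]
        assert classify_group(ProbeGroup(tuple(probes), 0)) == expected

    def test_partial_groups_use_absolute_rule(self):
        # a 2-probe group can never reach 3 negatives
        probes = [Probe("c", 0, 60, -1.0), Probe("c", 50, 110, -1.0)]
        assert classify_group(ProbeGroup(tuple(probes), 0)) == HIGH


def labelled_groups(labels, segments=None):
    """One-probe groups from a label string for block-level tests."""
    groups = []
    for i, lab in enumerate(labels):
        p = Probe("chrT", i * 10, i * 10 + 5, -1.0 if lab == "L" else 1.0)
        groups.append(
            ProbeGroup((p,), segments[i] if segments else 0, LOW if lab == "L" else HIGH)
        )
    return groups


def block_index_ranges(blocks):
    return [(b.groups[0].probes[0].start // 10, b.groups[-1].probes[-1].start // 10)
            for b in blocks]


def brute_force_segments(labels, stop_high_run=2):
    """Independent oracle: maximal segments that start and end low and
    contain no run of >= stop_high_run consecutive highs."""

    def valid(i, j):
        if labels[i] != "L" or labels[j] != "L":
            return False
        run = 0
        for k in range(i, j + 1):
            run = run + 1 if labels[k] == "H" else 0
            if run >= stop_high_run:
                return False
        return True

    candidates = [
        (i, j)
        for i in range(len(labels))
        for j in range(i, len(labels))
        if valid(i, j)
    ]
    return sorted(
        (i, j)
        for (i, j) in candidates
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in candidates)
    )


class TestCallBlocks:
    def test_double_high_run_terminates_block(self):
        blocks = call_blocks(labelled_groups("LLHLLHHL"))
        assert block_index_ranges(blocks) == [(0, 4), (7, 7)]

    def test_all_high_yields_no_blocks(self):
        assert call_blocks(labelled_groups("HHHH")) == []

    def test_interior_double_high_splits_into_single_group_blocks(self):
        assert block_index_ranges(call_blocks(labelled_groups("LHHL"))) == [(0, 0), (3, 3)]

    def test_single_interior_high_absorbed(self):
        assert block_index_ranges(call_blocks(labelled_groups("LHL"))) == [(0, 2)]

    def test_blocks_never_span_segment_breaks(self):
        groups = labelled_groups("LLLL", segments=[0, 0, 1, 1])
        assert block_index_ranges(call_blocks(groups)) == [(0, 1), (2, 3)]

    def test_unlabelled_groups_rejected(self):
        g = ProbeGroup((Probe("c", 0, 60, -1.0),), 0)
        with pytest.raises(ValueError, match="labelled"):
            call_blocks([g])

    def test_matches_bruteforce_oracle_up_to_length_10(self):
        for n in range(1, 11):
            for labels in map("".join, itertools.product("LH", repeat=n)):
                got = block_index_ranges(call_blocks(labelled_groups(labels)))
                assert got == brute_force_segments(labels), labels

    @pytest.mark.parametrize("stop_high_run", [1, 3])
    def test_oracle_agreement_for_other_stop_runs(self, stop_high_run):
        params = CallerParams(stop_high_run=stop_high_run)
        for n in range(1, 9):
            for labels in map("".join, itertools.product("LH", repeat=n)):
                got = block_index_ranges(call_blocks(labelled_groups(labels), params))
                assert got == brute_force_segments(labels, stop_high_run), labels

    def test_every_low_group_in_exactly_one_block(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            labels = "".join(rng.choice(["L", "H"], size=rng.integers(1, 30)))
            groups = labelled_groups(labels)
            blocks = call_blocks(groups)
            in_blocks = [g for b in blocks for g in b.groups if g.label == LOW]
            assert len(in_blocks) == labels.count("L")
            assert len({id(g) for g in in_blocks}) == len(in_blocks)


class TestBlocksToHfrs:
    def test_ten_probe_block_spans_510_bp(self):
        groups = partition_groups(contiguous_probes(10, nlr=-1.0))
        for g in groups:
            g.label = classify_group(g)
        hfrs = blocks_to_hfrs(call_blocks(groups))
        assert len(hfrs) == 1
        assert hfrs[0].size == 60 + 9 * 50 == 510

    def test_single_low_group_discarded_under_min_groups(self):
        groups = partition_groups(contiguous_probes(5, nlr=-1.0))
        for g in groups:
            g.label = classify_group(g)
        assert blocks_to_hfrs(call_blocks(groups)) == []

    def test_span_includes_interior_masked_stretch(self):
        # two 5-probe runs separated by a 150-bp hole (< max_gap): one block,
        # HFR size is the genomic span, not probe-covered bases
        left = contiguous_probes(5, nlr=-1.0)
        right = contiguous_probes(5, start=left[-1].end + 150, nlr=-1.0)
        groups = partition_groups(left + right)
        for g in groups:
            g.label = classify_group(g)
        hfrs = blocks_to_hfrs(call_blocks(groups))
        assert len(hfrs) == 1
        assert hfrs[0].size == right[-1].end - left[0].start
        assert hfrs[0].n_probes == 10


class TestCallHfrs:
    def test_recovers_single_planted_stretch(self):
        # 12 depleted probes planted in an enriched background
        nlrs = [1.0] * 30 + [-1.0] * 12 + [1.0] * 30
        catalog = call_hfrs(make_track(nlrs))
        assert len(catalog) == 1
        h = catalog[0]
        planted_start, planted_end = 30 * 50, 41 * 50 + 60
        # group phase can strand up to two trailing depleted probes in a
        # high group, so edges land within two probe steps of the truth
        assert abs(h.start - planted_start) <= 100
        assert abs(h.end - planted_end) <= 100

    def test_all_positive_track_gives_empty_catalog(self):
        assert len(call_hfrs(make_track([1.0] * 40))) == 0

    def test_deterministic_reruns_identical(self, sim_dataset):
        track = sim_dataset.tracks["panH3"]
        a = call_hfrs(track).to_dataframe()
        b = call_hfrs(track).to_dataframe()
        assert a.equals(b)

    def test_negating_all_nlrs_on_called_track_empties_catalog(self):
        nlrs = [-1.0] * 40
        assert len(call_hfrs(make_track(nlrs))) == 1
        flipped = make_track([-v for v in nlrs])
        assert len(call_hfrs(flipped)) == 0

    def test_catalog_sorted_and_non_overlapping(self, sim_dataset):
        catalog = call_hfrs(sim_dataset.tracks["panH3"])
        hfrs = list(catalog)
        assert all(a.end <= b.start for a, b in zip(hfrs, hfrs[1:]))


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.sampled_from([-1.0, 1.0]), min_size=10, max_size=120), st.integers(0, 3))
def test_raising_min_extent_never_adds_hfrs(nlrs, bump):
    """Monotonicity: stricter min_span / min_groups cannot add calls."""
    track = make_track(nlrs)
    base = len(call_hfrs(track, CallerParams()))
    stricter = CallerParams(min_span=500 + 300 * bump, min_groups=2 + bump)
    assert len(call_hfrs(track, stricter)) <= base


class TestCrossArrayConsistency:
    @staticmethod
    def _catalog():
        return HFRCatalog([HFR("chrT", 0, 600, 10, 2, -1.0, name="h1")])

    def test_all_negative_track_flags_everything(self):
        df, frac = cross_array_consistency(self._catalog(), [make_track([-1.0] * 12)])
        assert bool(df.iloc[0, 0]) is True
        assert frac == 1.0

    def test_all_positive_track_flags_nothing(self):
        df, frac = cross_array_consistency(self._catalog(), [make_track([1.0] * 12)])
        assert bool(df.iloc[0, 0]) is False
        assert frac == 0.0

    def test_decision_rule_mean_and_fraction(self):
        # overlapping NLRs (-1, -1, +0.5, +0.5): mean -0.25 < 0 and 50% negative
        track = make_track([-1.0, -1.0, 0.5, 0.5], step=150, length=150)
        catalog = HFRCatalog([HFR("chrT", 0, 600, 4, 2, -0.25, name="h1")])
        df, frac = cross_array_consistency(catalog, [track])
        assert bool(df.iloc[0, 0]) is True

    def test_no_overlapping_probes_excluded_from_denominator(self, caplog):
        import logging

        catalog = HFRCatalog(
            [
                HFR("chrT", 0, 600, 10, 2, -1.0, name="h1"),
                HFR("chrT", 10_000, 10_600, 10, 2, -1.0, name="h2"),
            ]
        )
        with caplog.at_level(logging.WARNING):
            df, frac = cross_array_consistency(catalog, [make_track([-1.0] * 12)])
        assert frac == 1.0  # h2 undetermined, excluded
        assert df.loc["h2"].isna().all()

    def test_synthetic_tracks_consistent_across_antibodies(self, sim_dataset):
        catalog = call_hfrs(sim_dataset.tracks["panH3"])
        others = [sim_dataset.tracks["H3K4me3"], sim_dataset.tracks["H3K27me3"]]
        _, frac = cross_array_consistency(catalog, others)
        # depletion is planted jointly, so consistency should be near-total
        assert frac >= 0.66
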