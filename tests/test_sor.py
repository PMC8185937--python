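"""SOR segmentation against a brute-force per-base oracle, plus the
conservation, idempotence and burden properties."""

import numpy as np
import pytest

from sorcna.cna_io import CaseSet, CnaCall
from sorcna.sor import (
    build_sor_profile,
    build_sors,
    per_case_region_burden,
    percent_genome_altered,
    pga_per_case,
    profile_matrix,
    relative_frequency,
)
from tests.conftest import make_clinical, random_case_set


def per_base_support(case_set, direction, chrom, max_pos):
    """Independent oracle: for every base, the set of cases covering it."""
    support = [set() for _ in range(max_pos + 1)]
    for call in case_set.calls:
        if call.direction != direction or call.chromosome != chrom:
            continue
        for pos in range(call.start, call.end + 1):
            support[pos].add(call.case_id)
    return support


def segments_to_per_base(segments, max_pos):
    support = [set() for _ in range(max_pos + 1)]
    for seg in segments:
        for pos in range(seg.start, seg.end + 1):
            assert not support[pos], "segments of one direction overlap"
            support[pos] = set(seg.supporting_cases)
    return support


def test_no_calls_gives_empty_profile():
    cs = CaseSet(calls=[], clinical=make_clinical(["A", "B"]))
    assert len(build_sors(cs, "gain")) == 0


def test_single_call_single_segment():
    cs = CaseSet(calls=[CnaCall("A", "chr1", 10, 50, "gain")],
                 clinical=make_clinical(["A", "B", "C", "D"]))
    (seg,) = build_sors(cs, "gain").segments
    assert (seg.start, seg.end) == (10, 50)
    assert seg.rf == 0.25


def test_two_overlapping_calls_partition(two_call_case_set):
    profile = build_sors(two_call_case_set, "gain")
    got = [(s.start, s.end, s.rf) for s in profile.segments]
    assert got == [(10, 29, 0.5), (30, 50, 1.0), (51, 80, 0.5)]
    # middle segment is supported by everyone
    assert profile.segments[1].supporting_cases == frozenset({"A", "B"})


def test_relative_frequency_direct():
    assert relative_frequency(frozenset({"a", "b", "c"}), 75) == pytest.approx(0.04)
    assert relative_frequency(frozenset({"a", "b"}), 2) == 1.0
    with pytest.raises(ValueError):
        relative_frequency(frozenset({"a"}), 0)


@pytest.mark.parametrize("direction", ["gain", "loss"])
def test_sweep_matches_per_base_oracle_random_instances(direction):
    rng = np.random.default_rng(20240)
    for _ in range(60):
        cs = random_case_set(rng, n_cases=int(rng.integers(2, 9)), chrom_len=400)
        for chrom in ("chr1", "chr2"):
            segs = [
                s for s in build_sors(cs, direction).segments
                if s.chromosome == chrom
            ]
            assert segments_to_per_base(segs, 400) == per_base_support(
                cs, direction, chrom, 400
            )


def test_maximality_adjacent_segments_differ():
    rng = np.random.default_rng(7)
    for _ in range(30):
        cs = random_case_set(rng, n_cases=5, chrom_len=300)
        for direction in ("gain", "loss"):
            segs = build_sors(cs, direction).segments
            by_chrom = {}
            for s in segs:
                by_chrom.setdefault(s.chromosome, []).append(s)
            for chrom_segs in by_chrom.values():
                for a, b in zip(chrom_segs, chrom_segs[1:]):
                    if a.end + 1 == b.start:
                        assert a.supporting_cases != b.supporting_cases


def test_conservation_of_covered_bases():
    """sum(length x support) over segments equals total covered bases over
    cases, per direction."""
    rng = np.random.default_rng(99)
    for _ in range(30):
        cs = random_case_set(rng, n_cases=6, chrom_len=500)
        for direction in ("gain", "loss"):
            segs = build_sors(cs, direction).segments
            lhs = sum(s.length * len(s.supporting_cases) for s in segs)
            rhs = sum(c.length for c in cs.calls if c.direction == direction)
            assert lhs == rhs


def test_idempotence_on_sor_shaped_calls():
    rng = np.random.default_rng(4242)
    cs = random_case_set(rng, n_cases=6, chrom_len=500)
    profile = build_sors(cs, "gain")
    # turn every (segment, supporting case) pair into a call and rebuild
    calls = [
        CnaCall(cid, s.chromosome, s.start, s.end, "gain")
        for s in profile.segments
        for cid in s.supporting_cases
    ]
    rebuilt = build_sors(
        CaseSet(calls=calls, clinical=make_clinical(cs.case_ids)), "gain"
    )
    assert [
        (s.chromosome, s.start, s.end, s.supporting_cases)
        for s in rebuilt.segments
    ] == [
        (s.chromosome, s.start, s.end, s.supporting_cases)
        for s in profile.segments
    ]


class TestPercentGenomeAltered:
    def test_no_calls_is_zero(self, toy_build):
        assert percent_genome_altered([], toy_build) == 0.0

    def test_whole_genome_is_100(self, toy_build):
        calls = [
            CnaCall("A", "chr1", 1, 100, "gain"),
            CnaCall("A", "chr2", 1, 50, "loss"),
        ]
        assert percent_genome_altered(calls, toy_build) == 100.0

    def test_two_small_calls(self, toy_build):
        calls = [
            CnaCall("A", "chr1", 1, 5, "gain"),
            CnaCall("A", "chr2", 11, 20, "loss"),
        ]
        assert percent_genome_altered(calls, toy_build) == pytest.approx(10.0)

    def test_invariant_to_call_fragmentation(self, toy_build):
        whole = [CnaCall("A", "chr1", 10, 49, "gain")]
        split = [
            CnaCall("A", "chr1", 10, 29, "gain"),
            CnaCall("A", "chr1", 30, 49, "gain"),
        ]
        assert percent_genome_altered(whole, toy_build) == percent_genome_altered(
            split, toy_build
        )

    def test_pga_per_case_includes_cna_free(self, toy_build):
        cs = CaseSet(calls=[CnaCall("A", "chr1", 1, 15, "gain")],
                     clinical=make_clinical(["A", "B"]))
        pga = pga_per_case(cs, toy_build)
        assert pga["A"] == pytest.approx(10.0)
        assert pga["B"] == 0.0


class TestRegionBurden:
    def test_exact_cover_is_one(self):
        cs = CaseSet(calls=[CnaCall("A", "chr1", 100, 199, "loss")],
                     clinical=make_clinical(["A", "B"]))
        burden = per_case_region_burden(cs, ("chr1", 100, 199), "loss")
        assert burden["A"] == 1.0
        assert burden["B"] == 0.0

    def test_half_cover(self):
        cs = CaseSet(calls=[CnaCall("A", "chr1", 100, 149, "loss")],
                     clinical=make_clinical(["A"]))
        burden = per_case_region_burden(cs, ("chr1", 100, 199), "loss")
        assert burden["A"] == 0.5

    def test_binary_indicator(self):
        cs = CaseSet(calls=[CnaCall("A", "chr1", 100, 101, "loss")],
                     clinical=make_clinical(["A", "B"]))
        burden = per_case_region_burden(cs, ("chr1", 100, 199), "loss", binary=True)
        assert burden.tolist() == [1.0, 0.0]

    def test_wrong_direction_does_not_count(self):
        cs = CaseSet(calls=[CnaCall("A", "chr1", 100, 199, "gain")],
                     clinical=make_clinical(["A"]))
        burden = per_case_region_burden(cs, ("chr1", 100, 199), "loss")
        assert burden["A"] == 0.0


class TestProfileMatrix:
    def test_two_call_fixture_rows(self, two_call_case_set):
        profile = build_sors(two_call_case_set, "gain")
        matrix = profile_matrix(two_call_case_set, profile.segments)
        assert matrix.loc["A"].tolist() == [1.0, 1.0, 0.0]
        assert matrix.loc["B"].tolist() == [0.0, 1.0, 1.0]

    def test_cna_free_case_row_is_zero(self):
        cs = CaseSet(calls=[CnaCall("A", "chr1", 10, 50, "gain")],
                     clinical=make_clinical(["A", "B"]))
        matrix = profile_matrix(cs, build_sors(cs, "gain").segments)
        assert (matrix.loc["B"] == 0).all()

    def test_loss_calls_give_negative_entries(self):
        cs = CaseSet(calls=[CnaCall("A", "chr1", 10, 50, "loss")],
                     clinical=make_clinical(["A"]))
        matrix = profile_matrix(cs, build_sors(cs, "loss").segments)
        assert matrix.loc["A"].tolist() == [-1.0]

    def test_matches_support_sets_on_random_instances(self):
        """Midpoint membership must agree with the segment's supporting
        cases (their calls cover the whole segment, hence its midpoint)."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            cs = random_case_set(rng, n_cases=5, chrom_len=300)
            profile = build_sor_profile(cs)
            matrix = profile_matrix(cs, profile.segments)
            for seg in profile.segments:
                col = matrix[seg.label()]
                sign = 1.0 if seg.direction == "gain" else -1.0
                for cid in cs.case_ids:
                    expected = sign if cid in seg.supporting_cases else 0.0
                    assert col[cid] == expected
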