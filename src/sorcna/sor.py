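"""Smallest overlap regions (SORs) and relative frequencies (RFs).

An SOR is a maximal genomic segment over which the set of cases carrying an
overlapping CNA of one direction is constant: sweeping over all call
breakpoints partitions the altered genome into atomic segments, each
supported by a fixed case set; adjacent segments with identical support are
merged back.  The relative frequency of an SOR is the number of supporting
cases divided by the number of *all* analysed cases — CNA-free cases count
in the denominator.

Gains and losses are segmented independently; a per-case signed profile
matrix over the combined segment list feeds the clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cna_io import DIRECTIONS, CaseSet, CnaCall
from .genome import GenomeBuild, chrom_sort_key
from .intervals import Interval, covered_length, covers, merge_intervals, overlap_length

__all__ = [
    "SorSegment",
    "SorProfile",
    "build_sors",
    "build_sor_profile",
    "relative_frequency",
    "percent_genome_altered",
    "pga_per_case",
    "per_case_region_burden",
    "profile_matrix",
    "arm_max_rf",
]

Region = tuple[str, int, int]


@dataclass(frozen=True)
class SorSegment:
    chromosome: str
    start: int
    end: int
    direction: str
    supporting_cases: frozenset
    rf: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def region(self) -> Region:
        return (self.chromosome, self.start, self.end)

    def label(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}:{self.direction}"


@dataclass
class SorProfile:
    """Sorted SOR segments for one or both directions of a case set."""

    segments: list[SorSegment]
    n_cases: int
    directions: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.segments = sorted(
            self.segments,
            key=lambda s: (chrom_sort_key(s.chromosome), s.start, s.direction),
        )
        if not self.directions:
            self.directions = frozenset(s.direction for s in self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def of_direction(self, direction: str) -> list[SorSegment]:
        return [s for s in self.segments if s.direction == direction]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chromosome": s.chromosome,
                    "start": s.start,
                    "end": s.end,
                    "direction": s.direction,
                    "n_cases": len(s.supporting_cases),
                    "rf": s.rf,
                }
                for s in self.segments
            ],
            columns=["chromosome", "start", "end", "direction", "n_cases", "rf"],
        )

    def to_bedgraph(self, direction: str) -> pd.DataFrame:
        """bedGraph rows (chrom, 0-based start, end, rf) for one direction."""
        return pd.DataFrame(
            [
                {"chrom": s.chromosome, "start": s.start - 1, "end": s.end, "rf": s.rf}
                for s in self.of_direction(direction)
            ],
            columns=["chrom", "start", "end", "rf"],
        )


def relative_frequency(segment_or_cases: Union[SorSegment, Sequence, frozenset],
                       n_cases: int) -> float:
    """|supporting cases| / n_cases, the RF of an SOR."""
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    cases = (
        segment_or_cases.supporting_cases
        if isinstance(segment_or_cases, SorSegment)
        else segment_or_cases
    )
    if len(cases) > n_cases:
        raise ValueError("more supporting cases than cases in the cohort")
    return len(cases) / n_cases


def build_sors(case_set: CaseSet, direction: str) -> SorProfile:
    """Sweep-line segmentation of all calls of one direction into SORs.

    Zero-support gaps are discarded; adjacent contiguous segments whose
    supporting case sets coincide are merged (maximality).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    by_chrom: dict[str, list[CnaCall]] = {}
    for call in case_set.calls:
        if call.direction == direction:
            by_chrom.setdefault(call.chromosome, []).append(call)

    segments: list[SorSegment] = []
    n = case_set.n_cases
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        calls = by_chrom[chrom]
        # event lists at breakpoints: a call covers [start, end]
        starts: dict[int, list[str]] = {}
        ends: dict[int, list[str]] = {}
        for c in calls:
            starts.setdefault(c.start, []).append(c.case_id)
            ends.setdefault(c.end + 1, []).append(c.case_id)
        breakpoints = sorted(set(starts) | set(ends))
        active: set[str] = set()
        atomic: list[tuple[int, int, frozenset]] = []
        for pos, nxt in zip(breakpoints, breakpoints[1:]):
            active -= set(ends.get(pos, ()))
            active |= set(starts.get(pos, ()))
            if active:
                atomic.append((pos, nxt - 1, frozenset(active)))
        # merge contiguous atomic segments with identical support
        merged: list[tuple[int, int, frozenset]] = []
        for seg in atomic:
            if merged and merged[-1][1] + 1 == seg[0] and merged[-1][2] == seg[2]:
                merged[-1] = (merged[-1][0], seg[1], seg[2])
            else:
                merged.append(seg)
        for start, end, support in merged:
            segments.append(
                SorSegment(chrom, start, end, direction, support,
                           relative_frequency(support, n))
            )
    return SorProfile(segments=segments, n_cases=n, directions=frozenset({direction}))


def build_sor_profile(case_set: CaseSet) -> SorProfile:
    """Both directions concatenated into one profile (for clustering)."""
    gain = build_sors(case_set, "gain")
    loss = build_sors(case_set, "loss")
    return SorProfile(
        segments=gain.segments + loss.segments,
        n_cases=case_set.n_cases,
        directions=frozenset(DIRECTIONS),
    )


def percent_genome_altered(calls: Iterable[CnaCall], build: GenomeBuild) -> float:
    """Per-case CNA burden: 100 x altered bases / genome size.

    Gains and losses both count; overlapping same-direction calls are merged
    before summing so the result is invariant to call fragmentation.
    """
    calls = list(calls)
    cases = {c.case_id for c in calls}
    if len(cases) > 1:
        raise ValueError(f"calls from more than one case: {sorted(cases)}")
    altered = 0
    for direction in DIRECTIONS:
        by_chrom: dict[str, list[Interval]] = {}
        for c in calls:
            if c.direction == direction:
                by_chrom.setdefault(c.chromosome, []).append(c.interval)
        altered += sum(covered_length(ivs) for ivs in by_chrom.values())
    return 100.0 * altered / build.genome_size


def pga_per_case(case_set: CaseSet, build: GenomeBuild) -> pd.Series:
    """Percent genome altered for every clinical case (0 for CNA-free)."""
    by_case: dict[str, list[CnaCall]] = {cid: [] for cid in case_set.case_ids}
    for call in case_set.calls:
        by_case[call.case_id].append(call)
    return pd.Series(
        {cid: percent_genome_altered(calls, build) for cid, calls in by_case.items()},
        name="pga",
    ).loc[case_set.case_ids]


def per_case_region_burden(case_set: CaseSet, region: Region, direction: str,
                           binary: bool = False) -> pd.Series:
    """Fraction of ``region`` covered by each case's calls of ``direction``.

    One value per clinical case, 0 for cases without overlap.  With
    ``binary=True`` the value is a 0/1 overlap indicator instead.
    """
    chrom, start, end = region
    if end < start:
        raise ValueError("region end < start")
    length = end - start + 1
    values = dict.fromkeys(case_set.case_ids, 0.0)
    for call in case_set.calls:
        if call.direction != direction or call.chromosome != chrom:
            continue
        values[call.case_id] += overlap_length(call.interval, (start, end))
    if binary:
        return pd.Series(
            {cid: float(v > 0) for cid, v in values.items()}, name="burden"
        ).loc[case_set.case_ids]
    return pd.Series(
        {cid: v / length for cid, v in values.items()}, name="burden"
    ).loc[case_set.case_ids]


def profile_matrix(case_set: CaseSet, segments: Sequence[SorSegment],
                   membership: str = "midpoint") -> pd.DataFrame:
    """Signed cases x segments matrix: +1 where a case's gain calls cover the
    segment (midpoint by default), -1 for loss, 0 otherwise.

    ``membership`` is ``'midpoint'`` (robust to 1 bp boundary ambiguity) or
    ``'overlap'`` (any shared base counts).
    """
    if membership not in ("midpoint", "overlap"):
        raise ValueError(f"unknown membership rule {membership!r}")
    segs = sorted(segments, key=lambda s: (chrom_sort_key(s.chromosome), s.start,
                                           s.direction))
    seg_cases = {s.label(): s.supporting_cases for s in segs}
    unknown = set().union(*seg_cases.values()) - set(case_set.case_ids) if segs else set()
    if unknown:
        raise ValueError(f"segments reference unknown case(s): {sorted(unknown)}")

    by_case: dict[str, dict[str, dict[str, list[Interval]]]] = {
        cid: {"gain": {}, "loss": {}} for cid in case_set.case_ids
    }
    for call in case_set.calls:
        by_case[call.case_id][call.direction].setdefault(call.chromosome, []).append(
            call.interval
        )

    matrix = np.zeros((case_set.n_cases, len(segs)), dtype=float)
    for j, seg in enumerate(segs):
        sign = 1.0 if seg.direction == "gain" else -1.0
        for i, cid in enumerate(case_set.case_ids):
            ivs = by_case[cid][seg.direction].get(seg.chromosome, [])
            if membership == "midpoint":
                hit = covers(ivs, seg.midpoint)
            else:
                hit = any(overlap_length(iv, (seg.start, seg.end)) > 0 for iv in ivs)
            if hit:
                matrix[i, j] = sign
    return pd.DataFrame(
        matrix, index=pd.Index(case_set.case_ids, name="case_id"),
        columns=[s.label() for s in segs],
    )


def arm_max_rf(profile: SorProfile, build: GenomeBuild) -> pd.DataFrame:
    """Maximum SOR relative frequency per (arm, direction).

    Summarises a profile at the chromosome-arm scale, e.g. to check that a
    cohort shows the recurrent hepatocellular-carcinoma landscape (1q/8q
    gains, 16q loss, ...).  The arm of a segment is taken at its midpoint.
    """
    records: dict[tuple[str, str], float] = {}
    for seg in profile.segments:
        arm = build.arm_of(seg.chromosome, seg.midpoint)
        key = (arm, seg.direction)
        records[key] = max(records.get(key, 0.0), seg.rf)
    return pd.DataFrame(
        [
            {"arm": arm, "direction": direction, "max_rf": rf}
            for (arm, direction), rf in sorted(records.items())
        ],
        columns=["arm", "direction", "max_rf"],
    )
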