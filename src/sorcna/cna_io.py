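"""Reading, validation and writing of per-case CNA calls and clinical tables.

The canonical call format is a headered TSV with columns ``case_id``,
``chromosome``, ``start``, ``end``, ``direction`` (gain/loss), coordinates
1-based inclusive.  A SEG-dialect reader (``sample``, ``chrom``,
``loc.start``, ``loc.end``, ``seg.mean``) thresholds log2 ratios into
gain/loss calls since segmentation output rarely carries discrete states.

Within one case, overlapping calls of the same direction are merged on load
(with a logged warning) so each case contributes at most once per base per
direction; overlapping calls of *opposite* direction are a hard input error,
because a per-case copy-number profile is single-valued.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .genome import GenomeBuild, chrom_sort_key, normalize_chrom
from .intervals import (
    Interval,
    covered_length,
    merge_intervals,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

DIRECTIONS = ("gain", "loss")
GRADES = ("II", "III")
STAGES = ("A", "B", "C")
RECURRENCE = ("yes", "no")
EVENTS = ("dead", "censored")

PathLike = Union[str, io.IOBase]

__all__ = [
    "CnaCall",
    "ClinicalRecord",
    "CaseSet",
    "read_cna_table",
    "read_seg_table",
    "read_clinical_table",
    "read_blacklist",
    "subtract_blacklist",
    "write_calls",
    "write_clinical",
    "write_bed",
    "merge_case_calls",
]


@dataclass(frozen=True, order=True)
class CnaCall:
    """One somatic copy-number call: a 1-based closed interval with a
    direction (gain or loss) attributed to a single case."""

    case_id: str
    chromosome: str
    start: int
    end: int
    direction: str

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"call end {self.end} < start {self.start} "
                f"({self.case_id} {self.chromosome})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinicopathologic annotation and survival outcome for one case.

    ``grade`` is the Edmondson-Steiner histologic grade (II or III),
    ``stage`` the Barcelona-Clinic Liver Cancer stage (A/B/C), ``time`` is
    follow-up in months from surgery, ``event`` is ``dead`` or ``censored``.
    """

    case_id: str
    grade: str
    stage: str
    recurrence: str
    time: float
    event: str

    def __post_init__(self):
        if self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}, got {self.grade!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.recurrence not in RECURRENCE:
            raise ValueError(f"recurrence must be yes/no, got {self.recurrence!r}")
        if self.event not in EVENTS:
            raise ValueError(f"event must be dead/censored, got {self.event!r}")
        if not self.time > 0:
            raise ValueError(f"survival time must be positive, got {self.time}")


def merge_case_calls(calls: Iterable[CnaCall], warn: bool = True) -> list[CnaCall]:
    """Merge overlapping same-direction calls within each case.

    Raises ValueError if calls of opposite direction overlap within a case.
    Output is sorted (case, chromosome, start, direction).
    """
    grouped: dict[tuple[str, str, str], list[Interval]] = {}
    for call in calls:
        key = (call.case_id, call.chromosome, call.direction)
        grouped.setdefault(key, []).append(call.interval)

    merged_calls: list[CnaCall] = []
    n_merged = 0
    for (case_id, chrom, direction), ivs in grouped.items():
        merged = merge_intervals(ivs)
        n_merged += len(ivs) - len(merged)
        for start, end in merged:
            merged_calls.append(CnaCall(case_id, chrom, start, end, direction))
    if n_merged and warn:
        logger.warning(
            "merged %d overlapping same-direction call(s) within cases", n_merged
        )

    # opposite-direction overlap check per (case, chromosome)
    by_case_chrom: dict[tuple[str, str], dict[str, list[Interval]]] = {}
    for call in merged_calls:
        by_case_chrom.setdefault((call.case_id, call.chromosome), {}).setdefault(
            call.direction, []
        ).append(call.interval)
    for (case_id, chrom), sides in by_case_chrom.items():
        gains = sides.get("gain", [])
        losses = sides.get("loss", [])
        for gs, ge in gains:
            for ls, le in losses:
                if gs <= le and ls <= ge:
                    raise ValueError(
                        f"case {case_id!r} has overlapping gain and loss on "
                        f"{chrom}: [{gs},{ge}] vs [{ls},{le}]"
                    )
    merged_calls.sort(
        key=lambda c: (c.case_id, chrom_sort_key(c.chromosome), c.start, c.direction)
    )
    return merged_calls


@dataclass
class CaseSet:
    """All calls plus clinical records for a cohort, keyed by case id.

    Cases present in the clinical table but without any call are retained as
    CNA-free cases — they count in every relative-frequency denominator.
    """

    calls: list[CnaCall]
    clinical: list[ClinicalRecord]

    def __post_init__(self):
        ids = [r.case_id for r in self.clinical]
        if len(ids) == 0:
            raise ValueError("clinical table is empty")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated case_id(s) in clinical table: {dupes}")
        known = set(ids)
        orphans = sorted({c.case_id for c in self.calls} - known)
        if orphans:
            raise ValueError(f"calls for case(s) missing from clinical: {orphans}")
        self.calls = merge_case_calls(self.calls, warn=False)
        self._ids = ids

    @property
    def case_ids(self) -> list[str]:
        return list(self._ids)

    @property
    def n_cases(self) -> int:
        return len(self._ids)

    def calls_of(self, case_id: str, direction: Optional[str] = None) -> list[CnaCall]:
        return [
            c
            for c in self.calls
            if c.case_id == case_id and (direction is None or c.direction == direction)
        ]

    def clinical_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.clinical]).set_index("case_id")
        return df.loc[self._ids]

    def grouping(self, factor: str) -> pd.Series:
        """Per-case labels for one clinical factor (grade/stage/recurrence)."""
        df = self.clinical_frame()
        if factor not in df.columns:
            raise ValueError(f"unknown clinical factor {factor!r}")
        return df[factor]

    def subset(self, case_ids: Sequence[str]) -> "CaseSet":
        keep = set(case_ids)
        return CaseSet(
            calls=[c for c in self.calls if c.case_id in keep],
            clinical=[r for r in self.clinical if r.case_id in keep],
        )


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s): {missing}")


def read_cna_table(source: PathLike, build: Optional[GenomeBuild] = None) -> list[CnaCall]:
    """Read the canonical headered call TSV.

    Exact duplicate rows are collapsed with a logged warning; overlapping
    same-direction calls within a case are merged.  When ``build`` is given,
    calls are checked against chromosome bounds.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    _require_columns(df, ["case_id", "chromosome", "start", "end", "direction"], "CNA table")
    if df.empty:
        return []
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        logger.warning("collapsed %d duplicate call row(s)", n_before - len(df))
    calls = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric coordinate in row {row!r}"
            ) from None
        calls.append(CnaCall(str(row.case_id), str(row.chromosome), start, end,
                             str(row.direction)))
    if build is not None:
        for call in calls:
            if call.end > build.chrom_length(call.chromosome):
                raise ValueError(
                    f"call {call.case_id} {call.chromosome}:{call.start}-{call.end} "
                    "extends past the chromosome end"
                )
    return merge_case_calls(calls)


def read_seg_table(source: PathLike, gain_threshold: float = 0.25,
                   loss_threshold: float = -0.25) -> list[CnaCall]:
    """Read a SEG dialect (sample, chrom, loc.start, loc.end, seg.mean) and
    threshold the log2 ratio into gain/loss calls; neutral segments dropped."""
    if gain_threshold <= loss_threshold:
        raise ValueError("gain_threshold must exceed loss_threshold")
    df = pd.read_csv(source, sep="\t")
    _require_columns(df, ["sample", "chrom", "loc.start", "loc.end", "seg.mean"], "SEG table")
    df = df[["sample", "chrom", "loc.start", "loc.end", "seg.mean"]]
    calls = []
    for row in df.itertuples(index=False):
        mean = float(getattr(row, "_4"))
        if mean > gain_threshold:
            direction = "gain"
        elif mean < loss_threshold:
            direction = "loss"
        else:
            continue
        calls.append(
            CnaCall(str(row.sample), str(row.chrom), int(getattr(row, "_2")),
                    int(getattr(row, "_3")), direction)
        )
    return merge_case_calls(calls)


def read_clinical_table(source: PathLike) -> list[ClinicalRecord]:
    df = pd.read_csv(source, sep="\t", dtype=str)
    _require_columns(
        df, ["case_id", "grade", "stage", "recurrence", "time", "event"], "clinical table"
    )
    ids = df["case_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated case_id(s): {dupes}")
    return [
        ClinicalRecord(
            case_id=str(r.case_id),
            grade=str(r.grade),
            stage=str(r.stage),
            recurrence=str(r.recurrence),
            time=float(r.time),
            event=str(r.event),
        )
        for r in df.itertuples(index=False)
    ]


def read_blacklist(source: PathLike) -> list[tuple[str, int, int]]:
    """Benign-variant blacklist as headerless TSV: chromosome, start, end
    (1-based inclusive)."""
    df = pd.read_csv(source, sep="\t", header=None,
                     names=["chromosome", "start", "end"], comment="#")
    return [
        (normalize_chrom(r.chromosome), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def subtract_blacklist(calls: Iterable[CnaCall],
                       blacklist: Sequence[tuple[str, int, int]]) -> list[CnaCall]:
    """Remove blacklisted spans from every call (interval set-difference).

    Calls fully covered by the blacklist are dropped; a call punctured in
    the middle yields two fragments.  An empty blacklist is the identity.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for chrom, start, end in blacklist:
        if end < start:
            raise ValueError(f"invalid blacklist interval {chrom}:{start}-{end}")
        by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))
    out: list[CnaCall] = []
    for call in calls:
        cutters = by_chrom.get(call.chromosome)
        if not cutters:
            out.append(call)
            continue
        for start, end in subtract_intervals(call.interval, cutters):
            out.append(CnaCall(call.case_id, call.chromosome, start, end, call.direction))
    return out


# ---------------------------------------------------------------------------
# writers


def _calls_frame(calls: Iterable[CnaCall]) -> pd.DataFrame:
    rows = sorted(
        calls,
        key=lambda c: (c.case_id, chrom_sort_key(c.chromosome), c.start, c.direction),
    )
    return pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "chromosome": c.chromosome,
                "start": c.start,
                "end": c.end,
                "direction": c.direction,
            }
            for c in rows
        ],
        columns=["case_id", "chromosome", "start", "end", "direction"],
    )


def write_calls(calls: Iterable[CnaCall], destination: PathLike) -> None:
    """Write the canonical TSV; round-trips with :func:`read_cna_table`.

    Rows are deterministically ordered by (case, chromosome, start)."""
    _calls_frame(calls).to_csv(destination, sep="\t", index=False)


def write_clinical(records: Iterable[ClinicalRecord], destination: PathLike) -> None:
    df = pd.DataFrame(
        [vars(r) for r in sorted(records, key=lambda r: r.case_id)],
        columns=["case_id", "grade", "stage", "recurrence", "time", "event"],
    )
    df.to_csv(destination, sep="\t", index=False)


def write_bed(calls: Iterable[CnaCall], destination: PathLike) -> None:
    """BED export (0-based half-open) with name ``case:direction`` for
    genome-browser viewing."""
    rows = sorted(calls, key=lambda c: (chrom_sort_key(c.chromosome), c.start))
    df = pd.DataFrame(
        [
            {
                "chrom": c.chromosome,
                "chromStart": c.start - 1,
                "chromEnd": c.end,
                "name": f"{c.case_id}:{c.direction}",
            }
            for c in rows
        ],
        columns=["chrom", "chromStart", "chromEnd", "name"],
    )
    df.to_csv(destination, sep="\t", index=False, header=False)
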