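"""Reference-genome model: chromosome sizes, cytobands and arm lookup.

All coordinates in this package are 1-based and fully closed, matching the
convention in which copy-number regions are reported cytogenetically (a
region ``chr1:100-200`` includes both base 100 and base 200, so its length
is ``200 - 100 + 1``).  UCSC-style inputs (0-based half-open starts) are
converted on load and round-trip losslessly.

The bundled hg18 (NCBI36) build carries the true chromosome lengths together
with a constructed arm-level banding table (one p and one q band per
chromosome, split at an approximate centromere position); it is sufficient
for arm assignment of arm-scale events but does not resolve sub-band labels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "Cytoband",
    "GenomeBuild",
    "load_genome",
    "load_hg18",
    "region_size_mb",
    "chrom_sort_key",
    "normalize_chrom",
]

_CANONICAL = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
_CANONICAL_RANK = {name: i for i, name in enumerate(_CANONICAL)}

PathLike = Union[str, io.IOBase]


def normalize_chrom(name: str) -> str:
    """Return the chromosome name with a ``chr`` prefix (``1`` -> ``chr1``)."""
    name = str(name).strip()
    if not name:
        raise ValueError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


def chrom_sort_key(name: str):
    """Sort key placing autosomes 1..22 first, then X and Y, then the rest."""
    name = normalize_chrom(name)
    return (_CANONICAL_RANK.get(name, len(_CANONICAL)), name)


@dataclass(frozen=True)
class Cytoband:
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    name: str
    arm: str

    def __post_init__(self):
        if self.arm not in ("p", "q"):
            raise ValueError(f"band arm must be 'p' or 'q', got {self.arm!r}")
        if not self.name.startswith(self.arm):
            raise ValueError(
                f"band name {self.name!r} inconsistent with arm {self.arm!r}"
            )
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid band span {self.start}-{self.end}")


@dataclass
class GenomeBuild:
    """Chromosome lengths plus a banding table tiling each chromosome."""

    build_name: str = "hg18"
    chromosomes: list[tuple[str, int]] = field(default_factory=list)
    cytobands: list[Cytoband] = field(default_factory=list)

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
        self._lengths = dict(self.chromosomes)
        self._bands: dict[str, list[Cytoband]] = {}
        for band in self.cytobands:
            if band.chromosome not in self._lengths:
                raise ValueError(f"band on unknown chromosome {band.chromosome!r}")
            if band.end > self._lengths[band.chromosome]:
                raise ValueError(
                    f"band {band.name} extends past the end of {band.chromosome}"
                )
            self._bands.setdefault(band.chromosome, []).append(band)
        for chrom, bands in self._bands.items():
            bands.sort(key=lambda b: b.start)
            if bands[0].start != 1:
                raise ValueError(f"{chrom} bands do not start at base 1")
            for prev, cur in zip(bands, bands[1:]):
                if cur.start != prev.end + 1:
                    raise ValueError(
                        f"{chrom} bands are not contiguous at {prev.end}/{cur.start}"
                    )
            if bands[-1].end != self._lengths[chrom]:
                raise ValueError(f"{chrom} bands do not tile the chromosome")

    # -- lookups -----------------------------------------------------------
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def chrom_length(self, chromosome: str) -> int:
        chromosome = normalize_chrom(chromosome)
        try:
            return self._lengths[chromosome]
        except KeyError:
            raise ValueError(f"unknown chromosome {chromosome!r}") from None

    @property
    def genome_size(self) -> int:
        """Total genome length in bp (all chromosomes, X and Y included)."""
        return sum(length for _, length in self.chromosomes)

    def bands_of(self, chromosome: str) -> list[Cytoband]:
        return list(self._bands.get(normalize_chrom(chromosome), []))

    def band_at(self, chromosome: str, pos: int) -> Cytoband:
        chromosome = normalize_chrom(chromosome)
        length = self.chrom_length(chromosome)
        if not 1 <= pos <= length:
            raise ValueError(
                f"position {pos} outside {chromosome} (1-{length})"
            )
        for band in self._bands.get(chromosome, []):
            if band.start <= pos <= band.end:
                return band
        raise ValueError(f"no banding information for {chromosome}")

    def arm_of(self, chromosome: str, pos: int) -> str:
        """Arm label, e.g. ``'1q'`` for a position on the long arm of chr1."""
        band = self.band_at(chromosome, pos)
        return normalize_chrom(chromosome).removeprefix("chr") + band.arm

    def arm_span(self, arm_label: str) -> tuple[str, int, int]:
        """(chromosome, start, end) covered by an arm such as ``'8q'``."""
        arm_label = arm_label.strip()
        arm = arm_label[-1]
        if arm not in ("p", "q") or len(arm_label) < 2:
            raise ValueError(f"malformed arm label {arm_label!r}")
        chromosome = normalize_chrom(arm_label[:-1])
        bands = [b for b in self._bands.get(chromosome, []) if b.arm == arm]
        if not bands:
            raise ValueError(f"no bands for arm {arm_label!r}")
        return chromosome, bands[0].start, bands[-1].end

    def arm_labels(self) -> list[str]:
        """All arm labels in genome order (1p, 1q, 2p, ...)."""
        labels = []
        for chrom in self.chrom_names():
            short = chrom.removeprefix("chr")
            for arm in ("p", "q"):
                if any(b.arm == arm for b in self._bands.get(chrom, [])):
                    labels.append(short + arm)
        return labels


def _read_table(source: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", header=None, comment="#", **kwargs)


def load_genome(chrom_sizes: PathLike, cytobands: PathLike,
                build_name: str = "custom") -> GenomeBuild:
    """Build a :class:`GenomeBuild` from a chrom.sizes file and a UCSC-style
    cytoBand file (chrom, 0-based start, end, band name, stain).

    Chromosomes are ordered 1..22, X, Y regardless of file order.  The
    0-based half-open band starts are converted to the 1-based closed
    convention used throughout the package.
    """
    sizes = _read_table(chrom_sizes, names=["chrom", "length"])
    chroms = sorted(
        [(normalize_chrom(r.chrom), int(r.length)) for r in sizes.itertuples()],
        key=lambda t: chrom_sort_key(t[0]),
    )
    bands_df = _read_table(
        cytobands, names=["chrom", "start0", "end", "name", "stain"]
    )
    known = {c for c, _ in chroms}
    bands = []
    for row in bands_df.itertuples():
        chrom = normalize_chrom(row.chrom)
        if chrom not in known:
            raise ValueError(f"cytoband row on undeclared chromosome {row.chrom!r}")
        name = str(row.name)
        bands.append(
            Cytoband(chrom, int(row.start0) + 1, int(row.end), name, name[0])
        )
    return GenomeBuild(build_name=build_name, chromosomes=chroms, cytobands=bands)


def load_hg18() -> GenomeBuild:
    """The bundled hg18/NCBI36 build (true lengths, arm-level synthetic bands)."""
    data = resources.files("sorcna.data")
    with resources.as_file(data / "hg18.chrom.sizes") as sizes_path, \
            resources.as_file(data / "cytoband_hg18_arms.synthetic.txt") as band_path:
        return load_genome(str(sizes_path), str(band_path), build_name="hg18")


def region_size_mb(start: int, end: int) -> float:
    """Region size in megabases, rounded half-up to one decimal.

    Uses the closed-interval length ``end - start + 1``.
    """
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    size = Decimal(end - start + 1) / Decimal(10**6)
    return float(size.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
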