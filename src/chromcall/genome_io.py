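"""Genome geometry: chromosome sizes, fixed-width target regions, blacklist, tiling.

All coordinates are 0-based half-open (BED convention) throughout the
package; alignment-file 0-based starts are used directly.  A genome is
described by an ordered mapping of chromosome name to length; target
regions are equal-width windows (e.g. promoters as TSS +/- 1 kb); the
background is estimated on a non-overlapping tiling of the genome from
which blacklist-overlapping tiles are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "GenomeTiling",
    "read_chrom_sizes",
    "read_bed_intervals",
    "read_regions_bed",
    "flag_blacklisted",
    "tile_genome",
    "write_regions_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open chromosome span [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share at least 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class RegionSet:
    """An ordered collection of equal-width target windows.

    Region order is stable and must be identical across all samples
    analysed together; downstream tables are aligned to it by position.
    """

    regions: list[GenomicInterval]
    names: list[str]
    width: int
    blacklisted: np.ndarray = field(default=None)  # bool per region

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.names):
            raise ValueError("regions and names must have equal length")
        for iv in self.regions:
            if len(iv) != self.width:
                raise ValueError(
                    f"region {iv.chrom}:{iv.start}-{iv.end} has width "
                    f"{len(iv)}, expected {self.width}"
                )
        if self.blacklisted is None:
            self.blacklisted = np.zeros(len(self.regions), dtype=bool)
        else:
            self.blacklisted = np.asarray(self.blacklisted, dtype=bool)
            if self.blacklisted.shape != (len(self.regions),):
                raise ValueError("blacklisted flag length mismatch")

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class GenomeTiling:
    """Non-overlapping equal-width genome tiles used for background estimation."""

    tiles: list[GenomicInterval]
    tile_width: int
    excluded_count: int = 0

    def __len__(self) -> int:
        return len(self.tiles)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Parse a two-column chromosome-sizes table (name, length).

    Order is preserved; duplicate names and non-positive lengths are errors.
    """
    path = Path(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            name, length_str = fields
            try:
                length = int(length_str)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: length {length_str!r} is not an integer"
                ) from exc
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length {length}")
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    if not sizes:
        raise ValueError(f"{path}: empty chromosome-sizes file")
    return sizes


def _iter_bed_lines(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file as a plain interval list (e.g. a blacklist)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    for lineno, fields in _iter_bed_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def _dedupe_names(names: list[str]) -> list[str]:
    """Suffix duplicate names with .2, .3, ... keeping first occurrence intact."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 1
            out.append(name)
    return out


def read_regions_bed(
    path: str | Path, width: int, sizes: dict[str, int]
) -> RegionSet:
    """Read fixed-width target windows from a BED3/BED4 file.

    Every region must have ``end - start == width`` (a violation aborts,
    naming the offending line).  Regions on chromosomes absent from
    ``sizes``, or extending past a chromosome end, are dropped with a
    warning rather than clipped, because clipping would break the
    fixed-width invariant.
    """
    path = Path(path)
    if width <= 0:
        raise ValueError("width must be positive")
    regions: list[GenomicInterval] = []
    names: list[str] = []
    n_dropped = 0
    k = 0
    for lineno, fields in _iter_bed_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if end - start != width:
            raise ValueError(
                f"{path}:{lineno}: region {chrom}:{start}-{end} has width "
                f"{end - start}, but all regions must have fixed width {width}"
            )
        k += 1
        name = fields[3] if len(fields) >= 4 and fields[3] else f"region_{k}"
        if chrom not in sizes:
            logger.warning(
                "%s:%d: dropping region %s on unknown chromosome %s",
                path, lineno, name, chrom,
            )
            n_dropped += 1
            continue
        if end > sizes[chrom]:
            logger.warning(
                "%s:%d: dropping region %s extending past end of %s (%d > %d)",
                path, lineno, name, chrom, end, sizes[chrom],
            )
            n_dropped += 1
            continue
        regions.append(GenomicInterval(chrom, start, end))
        names.append(name)
    if k == 0:
        raise ValueError(f"{path}: no regions found")
    if n_dropped:
        logger.warning("%s: dropped %d out-of-bounds region(s)", path, n_dropped)
    if not regions:
        raise ValueError(f"{path}: all regions were out of bounds")
    return RegionSet(regions=regions, names=_dedupe_names(names), width=width)


def _overlaps_any(
    iv: GenomicInterval, by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]
) -> bool:
    """Test overlap against per-chromosome sorted (starts, sorted_ends) arrays.

    ``starts`` is sorted by start; ``max_end`` is the running maximum of the
    corresponding ends, so intervals need not be disjoint.
    """
    entry = by_chrom.get(iv.chrom)
    if entry is None:
        return False
    starts, max_end = entry
    # candidates with start < iv.end
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    if hi == 0:
        return False
    # overlap iff some candidate end > iv.start
    return bool(max_end[hi - 1] > iv.start)


def _index_intervals(
    intervals: Iterable[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs], dtype=np.int64)
        ends = np.array([p[1] for p in pairs], dtype=np.int64)
        out[chrom] = (starts, np.maximum.accumulate(ends))
    return out


def flag_blacklisted(
    regions: RegionSet, blacklist: Sequence[GenomicInterval]
) -> RegionSet:
    """Return a copy of ``regions`` with blacklist-overlap flags set.

    A region is flagged iff it overlaps any blacklist interval by at least
    1 bp under half-open semantics.  Region list and order are unchanged.
    """
    index = _index_intervals(blacklist)
    flags = np.array(
        [_overlaps_any(iv, index) for iv in regions.regions], dtype=bool
    )
    return RegionSet(
        regions=list(regions.regions),
        names=list(regions.names),
        width=regions.width,
        blacklisted=flags,
    )


def tile_genome(
    sizes: dict[str, int],
    tile_width: int,
    blacklist: Sequence[GenomicInterval] = (),
) -> GenomeTiling:
    """Partition each chromosome into consecutive tiles of ``tile_width``.

    Trailing partial tiles are dropped (a per-tile background mean requires
    equal tile widths).  A tile with any blacklist overlap is removed
    wholly and counted in ``excluded_count``.
    """
    if tile_width <= 0:
        raise ValueError("tile_width must be positive")
    index = _index_intervals(blacklist)
    tiles: list[GenomicInterval] = []
    excluded = 0
    for chrom, length in sizes.items():
        for start in range(0, length - tile_width + 1, tile_width):
            tile = GenomicInterval(chrom, start, start + tile_width)
            if _overlaps_any(tile, index):
                excluded += 1
            else:
                tiles.append(tile)
    if not tiles and excluded == 0:
        raise ValueError(
            f"tile_width {tile_width} exceeds every chromosome length; no tiles"
        )
    if not tiles:
        raise ValueError("all genome tiles overlap the blacklist; no tiles left")
    return GenomeTiling(tiles=tiles, tile_width=tile_width, excluded_count=excluded)


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED4 (exact coordinate round-trip)."""
    with open(path, "w") as fh:
        for iv, name in zip(regions.regions, regions.names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
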