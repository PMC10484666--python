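"""Desk-scale genomic summaries for CLIP cross-link peaks and m6A sites.

Implements the interval arithmetic behind reader-occupancy questions:
merging replicate cross-link counts, flagging which binding peaks
overlap known m6A sites, and length-normalised per-region percentages
(how iCLIP signal distributes over 3'UTR/CDS/intron/... once region
length is factored out).

Coordinates are BED-style throughout: 0-based, half-open [start, end).
Single-nucleotide cross-links are width-1 intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import BedParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "RegionSummary",
    "OverlapReport",
    "read_bed",
    "write_bed",
    "merge_replicates",
    "intersect",
    "region_percentages",
]

StrandMode = Literal["ignore", "same"]
_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A BED record: 0-based half-open interval with a count and strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    count: int = 0
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)")
        if self.count < 0:
            raise ValidationError("count must be non-negative")
        if self.strand not in _STRANDS:
            raise ValidationError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def overlaps(self, other: "GenomicInterval", strand_mode: StrandMode = "same") -> bool:
        if self.chrom != other.chrom:
            return False
        if strand_mode == "same" and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class RegionSummary:
    """Length-normalised signal distribution over genomic region classes."""

    regions: tuple[str, ...]
    counts: tuple[float, ...]
    lengths: tuple[float, ...]
    densities: tuple[float, ...]
    percents: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region": self.regions,
            "count": self.counts,
            "length": self.lengths,
            "density": self.densities,
            "percent": self.percents,
        })


@dataclass(frozen=True)
class OverlapReport:
    """Per-peak overlap flags against a site set, plus totals."""

    peaks: tuple[GenomicInterval, ...]
    overlapped: tuple[bool, ...]
    matched_sites: tuple[tuple[str, ...], ...]
    strand_mode: StrandMode

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_overlapping(self) -> int:
        return sum(self.overlapped)

    @property
    def fraction_overlapping(self) -> float:
        return self.n_overlapping / self.n_peaks if self.n_peaks else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [p.chrom for p in self.peaks],
            "start": [p.start for p in self.peaks],
            "end": [p.end for p in self.peaks],
            "name": [p.name for p in self.peaks],
            "strand": [p.strand for p in self.peaks],
            "overlaps_m6a": [int(f) for f in self.overlapped],
            "matched_sites": [",".join(m) if m else "." for m in self.matched_sites],
        })


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse BED3-BED6; '#' comment and empty lines are skipped.

    The score column (5th) is interpreted as a cross-link count.
    Malformed lines raise :class:`BedParseError` with the line number.
    """
    intervals = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"expected >= 3 fields, got {len(fields)}", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinates: {exc}", lineno) from exc
            name = fields[3] if len(fields) > 3 else "."
            count = 0
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    count = int(float(fields[4]))
                except ValueError as exc:
                    raise BedParseError(f"non-numeric score: {fields[4]!r}", lineno) from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, count, strand))
            except ValidationError as exc:
                raise BedParseError(str(exc), lineno) from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (chrom, start, end, name, count-as-score, strand)."""
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.count}\t{iv.strand}\n")


def merge_replicates(replicates: Sequence[Sequence[GenomicInterval]]) -> list[GenomicInterval]:
    """Sum cross-link counts across replicates at identical positions.

    Intervals are aggregated on the exact key (chrom, start, end,
    strand); the name of the first occurrence is kept.  Output is
    coordinate-sorted.
    """
    if not replicates:
        raise ValidationError("at least one replicate required")
    merged: dict[tuple, GenomicInterval] = {}
    for rep in replicates:
        for iv in rep:
            key = (iv.chrom, iv.start, iv.end, iv.strand)
            if key in merged:
                prev = merged[key]
                merged[key] = GenomicInterval(iv.chrom, iv.start, iv.end,
                                              prev.name, prev.count + iv.count, iv.strand)
            else:
                merged[key] = iv
    return sorted(merged.values())


def _site_trees(sites: Sequence[GenomicInterval],
                strand_mode: StrandMode) -> dict[tuple, IntervalTree]:
    trees: dict[tuple, IntervalTree] = {}
    for site in sites:
        key = (site.chrom, site.strand) if strand_mode == "same" else (site.chrom,)
        trees.setdefault(key, IntervalTree()).addi(site.start, site.end, site)
    return trees


def intersect(peaks: Sequence[GenomicInterval], sites: Sequence[GenomicInterval],
              strand_mode: StrandMode = "same") -> OverlapReport:
    """Flag each peak that shares >= 1 base with >= 1 site.

    Half-open semantics: a peak [10, 20) does not overlap a site
    [20, 22).  With ``strand_mode='same'`` only co-stranded features can
    overlap.  Matched site names are reported in coordinate order.
    """
    if strand_mode not in ("ignore", "same"):
        raise ValidationError(f"unknown strand_mode {strand_mode!r}")
    trees = _site_trees(sites, strand_mode)
    flags, matches = [], []
    for peak in peaks:
        key = (peak.chrom, peak.strand) if strand_mode == "same" else (peak.chrom,)
        hits = sorted(trees[key].overlap(peak.start, peak.end),
                      key=lambda h: (h.begin, h.end)) if key in trees else []
        flags.append(bool(hits))
        matches.append(tuple(h.data.name for h in hits))
    return OverlapReport(peaks=tuple(peaks), overlapped=tuple(flags),
                         matched_sites=tuple(matches), strand_mode=strand_mode)


def region_percentages(counts_by_region: Mapping[str, float],
                       lengths_by_region: Mapping[str, float]) -> RegionSummary:
    """Length-normalised percentage of signal per region class.

    density = count/length; percent = 100 * density / sum(densities).
    Region keys must match between the two mappings.
    """
    if set(counts_by_region) != set(lengths_by_region):
        raise ValidationError("region keys of counts and lengths must match")
    regions = tuple(sorted(counts_by_region))
    counts, lengths, densities = [], [], []
    for region in regions:
        c = float(counts_by_region[region])
        l = float(lengths_by_region[region])
        if c < 0:
            raise ValidationError(f"negative count for region {region!r}")
        if l <= 0:
            raise ValidationError(f"length for region {region!r} must be positive")
        counts.append(c)
        lengths.append(l)
        densities.append(c / l)
    total = sum(densities)
    if total == 0:
        raise ValidationError("total density is zero; percentages undefined")
    percents = tuple(100.0 * d / total for d in densities)
    return RegionSummary(regions=regions, counts=tuple(counts), lengths=tuple(lengths),
                         densities=tuple(densities), percents=percents)
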