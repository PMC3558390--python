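"""Domain types and format I/O.

All internal coordinates are 0-based, half-open.  Conversions to and from
1-based conventions (RepeatMasker, SAM) happen only at the parse/write
boundary.  ChIP-seq peaks are reduced to single positions (summit when
available, else interval midpoint) at parse time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

REGION_ORDER = ("5LTR", "gag", "pro", "pol", "env", "3LTR")

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def validate_against(self, sizes: "ChromSizes") -> None:
        if self.chrom not in sizes:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > sizes[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {sizes[self.chrom]}"
            )


class ChromSizes:
    """Mapping of chromosome name to length in bp."""

    def __init__(self, sizes: Dict[str, int]):
        if not sizes:
            raise ValueError("empty chromosome size table")
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")
        self._sizes = dict(sizes)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    @property
    def total(self) -> int:
        return sum(self._sizes.values())

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        sizes: Dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 'name length'")
                name = parts[0]
                if name in sizes:
                    raise FormatError(f"{path}:{lineno}: duplicate chromosome {name}")
                try:
                    sizes[name] = int(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
        return cls(sizes)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")


@dataclass
class ProvirusRecord:
    """One annotated retroelement locus with family label and optional
    internal region map (5LTR/gag/pro/pol/env/3LTR sub-intervals)."""

    element_id: str
    family: str
    interval: GenomicInterval
    regions: Optional[Dict[str, GenomicInterval]] = None

    def __post_init__(self) -> None:
        if self.regions:
            for label, sub in self.regions.items():
                if label not in REGION_ORDER:
                    raise ValueError(f"unknown region label {label!r}")
                if sub.chrom != self.interval.chrom:
                    raise ValueError("region on a different chromosome")
                if sub.start < self.interval.start or sub.end > self.interval.end:
                    raise ValueError(f"region {label} outside element interval")
            by_start = sorted(self.regions.values(), key=lambda s: s.start)
            for a, b in zip(by_start, by_start[1:]):
                if b.start < a.end:
                    raise ValueError("overlapping region sub-intervals")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def center(self) -> float:
        return self.interval.center

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (start for +, end for -; start when unknown)."""
        if self.interval.strand == "-":
            return self.interval.end
        return self.interval.start


class MarkerPeakSet:
    """One ChIP-seq factor/mark in one cell type, reduced to point positions
    held as sorted integer arrays per chromosome."""

    def __init__(self, marker: str, cell_type: str,
                 peaks: Dict[str, Sequence[int]]):
        self.marker = marker
        self.cell_type = cell_type
        self._peaks: Dict[str, np.ndarray] = {}
        for chrom, positions in peaks.items():
            arr = np.asarray(sorted(int(p) for p in positions), dtype=np.int64)
            self._peaks[chrom] = arr

    def positions(self, chrom: str) -> np.ndarray:
        return self._peaks.get(chrom, np.empty(0, dtype=np.int64))

    @property
    def chroms(self) -> List[str]:
        return list(self._peaks)

    @property
    def n_peaks(self) -> int:
        return sum(len(a) for a in self._peaks.values())

    def validate_against(self, sizes: ChromSizes) -> None:
        for chrom, arr in self._peaks.items():
            if chrom not in sizes:
                raise ValueError(f"unknown chromosome {chrom!r} in peak set")
            if len(arr) and (arr[0] < 0 or arr[-1] >= sizes[chrom]):
                raise ValueError(f"peak position out of bounds on {chrom}")


@dataclass
class AlignmentRecord:
    """One read with its candidate genomic hits; one hit means unique."""

    read_id: str
    hits: List[GenomicInterval]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.hits:
            raise ValueError(f"read {self.read_id}: empty hit list")
        if self.weight < 0:
            raise ValueError(f"read {self.read_id}: negative weight")

    @property
    def is_unique(self) -> bool:
        return len(self.hits) == 1


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, sizes: Optional[ChromSizes] = None) -> List[GenomicInterval]:
    """Parse a BED3+ file (tab-separated, 0-based half-open).

    Columns beyond 6 are ignored; column 6 (strand), when present, is kept.
    Intervals are validated against `sizes` when given.  File order is
    preserved.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = "."
            if len(parts) >= 6 and parts[5] in ("+", "-"):
                strand = parts[5]
            try:
                iv = GenomicInterval(parts[0], start, end, strand)
                if sizes is not None:
                    iv.validate_against(sizes)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path,
              names: Optional[Sequence[str]] = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_region_bed(path, sizes: Optional[ChromSizes] = None
                    ) -> Dict[str, Dict[str, GenomicInterval]]:
    """Read a BED file whose name column labels provirus-internal regions.

    Names have the form ``<element_id>:<region>`` with region in
    {5LTR, gag, pro, pol, env, 3LTR}.  Returns element_id -> region map.
    """
    out: Dict[str, Dict[str, GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: region BED needs a name column")
            try:
                element_id, region = parts[3].rsplit(":", 1)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: name must be '<element_id>:<region>'"
                ) from exc
            if region not in REGION_ORDER:
                raise FormatError(f"{path}:{lineno}: unknown region {region!r}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            if sizes is not None:
                iv.validate_against(sizes)
            out.setdefault(element_id, {})[region] = iv
    return out


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path, sizes: Optional[ChromSizes] = None,
                          family_filter: Optional[str] = None
                          ) -> List[ProvirusRecord]:
    """Parse a standard RepeatMasker ``.out`` annotation file.

    The file starts with 3 header lines followed by whitespace-separated
    rows.  The 1-based inclusive begin/end columns are converted to 0-based
    half-open; strand column "C" maps to "-".  `family_filter` keeps rows
    whose repeat name *starts with* the filter string.  Unparseable rows are
    skipped with a warning; a file yielding no records is an error.
    """
    records: List[ProvirusRecord] = []
    skipped = 0
    n_rows = 0
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        if lineno <= 3 or not line.strip():
            continue
        n_rows += 1
        parts = line.split()
        try:
            chrom = parts[4]
            begin, end = int(parts[5]), int(parts[6])
            strand = "-" if parts[8] == "C" else "+"
            name = parts[9]
            if begin < 1 or end < begin:
                raise ValueError("bad coordinates")
            iv = GenomicInterval(chrom, begin - 1, end, strand)
            if sizes is not None:
                iv.validate_against(sizes)
        except (IndexError, ValueError) as exc:
            warnings.warn(f"{path}:{lineno}: skipping unparseable row ({exc})")
            skipped += 1
            continue
        if family_filter is not None and not name.startswith(family_filter):
            continue
        records.append(
            ProvirusRecord(element_id=f"{name}_{chrom}_{iv.start}",
                           family=name, interval=iv)
        )
    if skipped:
        logger.warning("%s: skipped %d unparseable rows", path, skipped)
    if n_rows == 0 or (not records and family_filter is None):
        raise FormatError(f"{path}: no parseable annotation rows")
    return records


def write_repeatmasker_out(records: Iterable[ProvirusRecord], path) -> None:
    """Write records in RepeatMasker ``.out`` layout (1-based inclusive)."""
    header = (
        "   SW  perc perc perc  query     position in query           matching"
        "  repeat           position in  repeat\n"
        "score  div. del. ins.  sequence  begin    end          (left)  repeat"
        "           class/family      begin  end (left)   ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, rec in enumerate(records, 1):
            iv = rec.interval
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f"  239  10.0  0.0  0.0  {iv.chrom}  {iv.start + 1}  {iv.end}"
                f"  (0)  {strand}  {rec.family}  LTR/ERV1  1  {iv.length}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# Peaks (BED / narrowPeak)
# ---------------------------------------------------------------------------

def read_peaks(path, marker: str = "", cell_type: str = "",
               mode: str = "summit",
               sizes: Optional[ChromSizes] = None) -> MarkerPeakSet:
    """Read a BED or ENCODE narrowPeak file into point positions.

    mode="summit" uses narrowPeak column 10 (summit offset from start) when
    it is >= 0, falling back to the interval midpoint; mode="midpoint"
    always uses the midpoint.
    """
    if mode not in ("summit", "midpoint"):
        raise ValueError(f"unknown peak mode {mode!r}")
    peaks: Dict[str, List[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            pos = (start + end) // 2
            if mode == "summit" and len(parts) >= 10:
                try:
                    offset = int(parts[9])
                except ValueError:
                    offset = -1
                if offset >= 0:
                    pos = start + offset
            peaks.setdefault(parts[0], []).append(pos)
    pset = MarkerPeakSet(marker=marker, cell_type=cell_type, peaks=peaks)
    if sizes is not None:
        pset.validate_against(sizes)
    return pset


def write_narrowpeak(peaks: MarkerPeakSet, path, half_width: int = 100) -> None:
    """Write peaks as narrowPeak rows centered on each position, with the
    summit offset pointing back at the exact position."""
    with open(path, "w") as fh:
        i = 0
        for chrom in peaks.chroms:
            for pos in peaks.positions(chrom):
                start = max(0, int(pos) - half_width)
                end = int(pos) + half_width
                fh.write(
                    f"{chrom}\t{start}\t{end}\tpeak{i}\t0\t.\t0\t-1\t-1\t{int(pos) - start}\n"
                )
                i += 1


# ---------------------------------------------------------------------------
# Alignments (SAM and tabular)
# ---------------------------------------------------------------------------

TAB_ALIGNMENT_HEADER = "#read_id\tchrom\tstart\tend"


def read_alignments(path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from SAM/BAM or the tabular format.

    Hits sharing a read_id must be consecutive (name-grouped); a read_id
    recurring after other reads raises an error.  Unmapped SAM records are
    dropped and counted in the log.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam"):
        yield from _read_sam(path)
    else:
        yield from _read_tabular(path)


def _grouped(hit_stream: Iterable, what: str) -> Iterator[AlignmentRecord]:
    seen = set()
    current_id: Optional[str] = None
    current_hits: List[GenomicInterval] = []
    for read_id, iv in hit_stream:
        if read_id != current_id:
            if current_id is not None:
                yield AlignmentRecord(current_id, current_hits)
            if read_id in seen:
                raise FormatError(
                    f"{what}: read {read_id!r} is not name-grouped; "
                    "sort/group records by read name first"
                )
            seen.add(read_id)
            current_id = read_id
            current_hits = []
        current_hits.append(iv)
    if current_id is not None:
        yield AlignmentRecord(current_id, current_hits)


def _read_sam(path) -> Iterator[AlignmentRecord]:
    import pysam

    dropped = 0

    def hits():
        nonlocal dropped
        with pysam.AlignmentFile(str(path), check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.reference_name is None:
                    dropped += 1
                    continue
                strand = "-" if rec.is_reverse else "+"
                yield rec.query_name, GenomicInterval(
                    rec.reference_name, rec.reference_start,
                    rec.reference_end or rec.reference_start + 1, strand)

    yield from _grouped(hits(), str(path))
    if dropped:
        logger.info("%s: dropped %d unmapped records", path, dropped)


def _read_tabular(path) -> Iterator[AlignmentRecord]:
    def hits():
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 columns")
                try:
                    iv = GenomicInterval(parts[1], int(parts[2]), int(parts[3]))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
                yield parts[0], iv

    yield from _grouped(hits(), str(path))


def write_alignments_tab(records: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(TAB_ALIGNMENT_HEADER + "\n")
        for rec in records:
            for hit in rec.hits:
                fh.write(f"{rec.read_id}\t{hit.chrom}\t{hit.start}\t{hit.end}\n")


def write_alignments_sam(records: Iterable[AlignmentRecord], path,
                         sizes: ChromSizes) -> None:
    """Write records as name-grouped SAM (secondary flag on extra hits)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for rec in records:
            for i, hit in enumerate(rec.hits):
                flag = 0 if i == 0 else 256
                cigar = f"{hit.length}M"
                fh.write(
                    f"{rec.read_id}\t{flag}\t{hit.chrom}\t{hit.start + 1}\t"
                    f"{0 if flag else 255}\t{cigar}\t*\t0\t0\t*\t*\n"
                )
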