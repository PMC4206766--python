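"""Genomic intervals, peak sets, and replicate-consensus peaks.

All coordinates are 0-based half-open (BED convention). GTF/GFF input is
converted on read by :mod:`chipnet.annotation`. A peak's ``height`` is its
ChIP enrichment in reads per million (RPM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator


class ParseError(ValueError):
    """A malformed line in an input file (message names file and line)."""


class ConfigError(ValueError):
    """Inconsistent configuration, e.g. mismatched genome builds."""


#: RPM boundaries (low_max, medium_max) separating low / medium / high peaks.
#: Smad2 peaks: low <=1.5 RPM, medium 1.5-3 RPM, high >3 RPM.
#: Eomesa peaks: low <=1 RPM, medium 1-1.5 RPM, high >1.5 RPM (reads are
#: split between more peaks, so the scale is lower).
HEIGHT_THRESHOLDS: dict[str, tuple[float, float]] = {
    "Smad2": (1.5, 3.0),
    "Eomesa": (1.0, 1.5),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Central parameter set; every pipeline default lives here.

    proximal_window
        Half-width in bp of the TSS window defining proximal binding
        (peaks within +/-10 kb of a TSS by default).
    min_overlap
        Minimum shared bp for two intervals to count as overlapping.
    de_p_threshold_array / de_p_threshold_rnaseq
        P-value cutoffs for calling responsive genes from microarray
        (P <= 0.02) and RNA-seq (P <= 0.05) differential tables.
    motif_rel_threshold
        Relative PWM score in [0, 1] above which a window is a motif hit.
    pseudocount / background
        PWM regularisation: pseudocount mass distributed by background
        base frequency; background must sum to 1.
    """

    proximal_window: int = 10_000
    min_overlap: int = 1
    de_p_threshold_array: float = 0.02
    de_p_threshold_rnaseq: float = 0.05
    motif_rel_threshold: float = 0.80
    pseudocount: float = 0.8
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.proximal_window <= 0:
            raise ConfigError("proximal_window must be positive")
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")
        for name in ("de_p_threshold_array", "de_p_threshold_rnaseq"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 <= self.motif_rel_threshold <= 1.0:
            raise ConfigError("motif_rel_threshold must be in [0, 1]")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        if len(self.background) != 4 or any(b < 0 for b in self.background):
            raise ConfigError("background must be 4 nonnegative frequencies")
        if not math.isclose(sum(self.background), 1.0, abs_tol=1e-9):
            raise ConfigError("background frequencies must sum to 1")


@dataclass(frozen=True)
class GenomicInterval:
    """One peak or window: half-open [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    height: float | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.height is not None and self.height < 0:
            raise ValueError("height must be nonnegative")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def intervals_overlap(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """True iff a and b share at least ``min_overlap`` bp (strand ignored).

    Half-open semantics: [100,200) and [200,300) do not overlap.
    Symmetric and, for min_overlap <= width, reflexive.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_overlap


@dataclass
class PeakSet:
    """A sorted collection of peaks for one factor on one genome build."""

    factor: str
    genome_build: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=GenomicInterval.sort_key)
        # auto-assign "<factor>_<rank>" ids where missing, then check uniqueness
        assigned = []
        for rank, iv in enumerate(self.intervals, start=1):
            if iv.id is None:
                iv = replace(iv, id=f"{self.factor}_{rank}")
            assigned.append(iv)
        self.intervals = assigned
        ids = [iv.id for iv in self.intervals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peak ids in set {self.factor}: {dupes}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def by_id(self) -> dict[str, GenomicInterval]:
        return {iv.id: iv for iv in self.intervals}

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})


def _parse_int(token: str, what: str, path: object, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: non-integer {what} {token!r}") from None


def read_peaks(
    path: str | Path,
    dialect: str = "bed",
    factor: str | None = None,
    genome_build: str = "",
) -> PeakSet:
    """Read a peak set from BED (3-6 columns) or headered TSV.

    BED: chrom/start/end[/name/score/strand]; a numeric score column is
    stored as the peak height. TSV: header must name chrom, start, end
    and may name height, strand, id. Empty files give an empty PeakSet;
    malformed lines raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    if factor is None:
        factor = path.stem
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")

    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        lines = fh.read().splitlines()

    start_line = 1
    colmap = {"chrom": 0, "start": 1, "end": 2}
    optmap: dict[str, int] = {}
    if dialect == "tsv":
        if not lines:
            return PeakSet(factor=factor, genome_build=genome_build)
        header = lines[0].rstrip("\n").split("\t")
        missing = [c for c in ("chrom", "start", "end") if c not in header]
        if missing:
            raise ParseError(f"{path}: header missing columns {missing}")
        colmap = {c: header.index(c) for c in ("chrom", "start", "end")}
        optmap = {c: header.index(c) for c in ("height", "strand", "id") if c in header}
        lines = lines[1:]
        start_line = 2

    for lineno, raw in enumerate(lines, start=start_line):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
        chrom = cols[colmap["chrom"]]
        start = _parse_int(cols[colmap["start"]], "start", path, lineno)
        end = _parse_int(cols[colmap["end"]], "end", path, lineno)
        if start < 0 or start >= end:
            raise ParseError(
                f"{path}: line {lineno}: invalid coordinates {start}..{end}"
            )
        name, height, strand = None, None, "."
        if dialect == "bed":
            if len(cols) >= 4 and cols[3] != ".":
                name = cols[3]
            if len(cols) >= 5 and cols[4] != ".":
                try:
                    height = float(cols[4])
                except ValueError:
                    height = None  # non-numeric BED score: ignored
            if len(cols) >= 6 and cols[5] in ("+", "-"):
                strand = cols[5]
        else:
            if "id" in optmap and cols[optmap["id"]] != ".":
                name = cols[optmap["id"]]
            if "height" in optmap and cols[optmap["height"]] not in (".", ""):
                try:
                    height = float(cols[optmap["height"]])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric height"
                    ) from None
            if "strand" in optmap and cols[optmap["strand"]] in ("+", "-"):
                strand = cols[optmap["strand"]]
        if height is not None and height < 0:
            raise ParseError(f"{path}: line {lineno}: negative height {height}")
        intervals.append(
            GenomicInterval(chrom, start, end, strand=strand, height=height, id=name)
        )
    return PeakSet(factor=factor, genome_build=genome_build, intervals=intervals)


def _fmt_height(h: float | None) -> str:
    return "." if h is None else format(h, "g")


def write_peaks(peaks: PeakSet, path: str | Path, dialect: str = "bed") -> None:
    """Write a peak set as 6-column BED or headered TSV (tab-separated)."""
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "bed":
            for iv in peaks:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t"
                    f"{_fmt_height(iv.height)}\t{iv.strand}\n"
                )
        elif dialect == "tsv":
            fh.write("chrom\tstart\tend\tid\theight\tstrand\n")
            for iv in peaks:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t"
                    f"{_fmt_height(iv.height)}\t{iv.strand}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def replicate_consensus(rep1: PeakSet, rep2: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Consensus peaks supported by both independent ChIP replicates.

    Peaks from both replicates are grouped into connected components of
    the >=min_overlap bp overlap relation; every component containing at
    least one peak from each replicate yields one consensus interval
    spanning the component's union, with height the maximum member
    height. Single-replicate components are dropped.
    """
    if rep1.genome_build != rep2.genome_build:
        raise ConfigError(
            f"genome build mismatch: {rep1.genome_build!r} vs {rep2.genome_build!r}"
        )
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    # intervals narrower than min_overlap cannot overlap anything by enough:
    # they are singleton components and can never support a consensus peak
    tagged: list[tuple[GenomicInterval, int]] = [
        (iv, 1) for iv in rep1 if iv.width >= min_overlap
    ]
    tagged += [(iv, 2) for iv in rep2 if iv.width >= min_overlap]
    tagged.sort(key=lambda t: t[0].sort_key())

    consensus: list[GenomicInterval] = []

    def flush(group: list[tuple[GenomicInterval, int]]) -> None:
        reps = {tag for _, tag in group}
        if reps != {1, 2}:
            return
        start = min(iv.start for iv, _ in group)
        end = max(iv.end for iv, _ in group)
        heights = [iv.height for iv, _ in group if iv.height is not None]
        consensus.append(
            GenomicInterval(
                group[0][0].chrom, start, end,
                height=max(heights) if heights else None,
            )
        )

    group: list[tuple[GenomicInterval, int]] = []
    max_end = -1
    cur_chrom = None
    for iv, tag in tagged:
        # an incoming interval (starts at or after all group members) overlaps
        # some member by >=min_overlap iff it does so with the max-end member
        joins = (
            group
            and iv.chrom == cur_chrom
            and min(iv.end, max_end) - iv.start >= min_overlap
        )
        if joins:
            group.append((iv, tag))
            max_end = max(max_end, iv.end)
        else:
            if group:
                flush(group)
            group = [(iv, tag)]
            max_end = iv.end
            cur_chrom = iv.chrom
    if group:
        flush(group)

    out = [replace(iv, id=f"{rep1.factor}_consensus_{k}")
           for k, iv in enumerate(sorted(consensus, key=GenomicInterval.sort_key), 1)]
    return PeakSet(factor=rep1.factor, genome_build=rep1.genome_build, intervals=out)


def classify_peak_height(
    height: float,
    factor: str,
    thresholds: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Classify an RPM peak height as low / medium / high.

    Boundaries are inclusive on the low side of each break: low iff
    h <= low_max, medium iff low_max < h <= medium_max, high above.
    """
    if height < 0:
        raise ValueError("height must be nonnegative")
    table = HEIGHT_THRESHOLDS if thresholds is None else thresholds
    if factor not in table:
        raise ValueError(
            f"unknown factor {factor!r}: no height thresholds defined "
            f"(known: {sorted(table)})"
        )
    low_max, medium_max = table[factor]
    if height <= low_max:
        return "low"
    if height <= medium_max:
        return "medium"
    return "high"
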