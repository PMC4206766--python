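"""JASPAR position frequency matrices and log-odds PWM scanning.

A PFM of base counts is regularised with a background-distributed
pseudocount and converted to a log2-odds matrix

    M[b, j] = log2( (counts[b, j] + pc * bg[b]) / (col_total[j] + pc) / bg[b] )

Window scores are rescaled to a *relative score* between the matrix's
minimum and maximum attainable scores, so thresholds are comparable
across motifs (TFBS-suite convention; 0.80 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .association import ContingencyResult, chi_square_2x2
from .intervals import ParseError, PeakSet

BASES = "ACGT"
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

# byte -> base index lookup; N and anything else map to -1 (window skipped)
_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to base indices (A0 C1 G2 T3; other -> -1)."""
    return _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix (rows A, C, G, T) with scoring background."""

    motif_id: str
    counts: np.ndarray
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 0.8
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if counts.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError("every column must have positive total")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive frequencies summing to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @cached_property
    def log_odds(self) -> np.ndarray:
        bg = np.asarray(self.background)[:, None]
        col_total = self.counts.sum(axis=0, keepdims=True)
        p = (self.counts + self.pseudocount * bg) / (col_total + self.pseudocount)
        return np.log2(p / bg)

    @cached_property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @cached_property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @cached_property
    def consensus(self) -> str:
        """Highest-scoring sequence (ties resolved to the earlier base)."""
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))


def read_jaspar(
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.8,
) -> PFM:
    """Read the first motif from a JASPAR-format text file."""
    from Bio import motifs as bio_motifs

    path = Path(path)
    try:
        with open(path) as fh:
            motif = bio_motifs.read(fh, "jaspar")
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise ParseError(f"{path}: cannot parse JASPAR motif: {exc}") from exc
    counts = np.array([motif.counts[b] for b in BASES], dtype=float)
    if counts.size == 0:
        raise ParseError(f"{path}: empty count matrix")
    if (counts < 0).any():
        raise ParseError(f"{path}: negative counts in matrix")
    motif_id = getattr(motif, "matrix_id", None) or motif.name or path.stem
    return PFM(
        motif_id=motif_id,
        counts=counts,
        background=tuple(background),
        pseudocount=pseudocount,
        name=motif.name or "",
    )


def write_jaspar(pfm: PFM, path: str | Path) -> None:
    """Write a PFM in JASPAR 4-row text format (round-trips with read)."""
    with open(path, "w") as fh:
        fh.write(f">{pfm.motif_id} {pfm.name or pfm.motif_id}\n")
        for i, base in enumerate(BASES):
            row = " ".join(format(v, "g") for v in pfm.counts[i])
            fh.write(f"{base} [ {row} ]\n")


@dataclass(frozen=True)
class MotifHit:
    """A PWM match; offset is the window's forward-strand start in the peak."""

    offset: int
    strand: str
    raw_score: float
    rel_score: float
    peak_id: str | None = None


def _window_scores(idx: np.ndarray, lom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window PWM scores and validity (no N) for one strand's matrix."""
    L = lom.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = lom[safe, np.arange(L)].sum(axis=1)
    return scores, valid


def scan_sequence(pfm: PFM, seq: str, rel_threshold: float = 0.80) -> list[MotifHit]:
    """All windows on both strands scoring >= rel_threshold.

    Windows containing N are skipped. Hits are reported with forward-strand
    offsets and ordered by (offset, strand) with '+' before '-'.
    """
    if not 0.0 <= rel_threshold <= 1.0:
        raise ValueError("rel_threshold must be in [0, 1]")
    idx = encode_sequence(seq)
    L = pfm.length
    if idx.size < L:
        return []

    lom = pfm.log_odds
    span = pfm.max_score - pfm.min_score
    hits: list[MotifHit] = []
    for strand, matrix in (("+", lom), ("-", lom[::-1, ::-1])):
        scores, valid = _window_scores(idx, matrix)
        rel = (scores - pfm.min_score) / span
        for offset in np.nonzero(valid & (rel >= rel_threshold))[0]:
            hits.append(
                MotifHit(
                    offset=int(offset),
                    strand=strand,
                    raw_score=float(scores[offset]),
                    rel_score=float(rel[offset]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand != "+"))
    return hits


def best_hit(hits: Sequence[MotifHit]) -> MotifHit | None:
    """Maximal-rel_score hit; ties go to the smallest offset, then + strand."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.rel_score, h.offset, h.strand != "+"))


@dataclass
class PeakHitStats:
    """Per-peak best motif hit and the fraction of peaks with any hit."""

    motif_id: str
    rel_threshold: float
    best_hits: dict[str, MotifHit | None]

    @property
    def n_total(self) -> int:
        return len(self.best_hits)

    @property
    def n_with_hit(self) -> int:
        return sum(1 for h in self.best_hits.values() if h is not None)

    @property
    def fraction(self) -> float:
        return self.n_with_hit / self.n_total if self.n_total else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("peak_id\toffset\tstrand\traw_score\trel_score\n")
            for peak_id in sorted(self.best_hits):
                h = self.best_hits[peak_id]
                if h is None:
                    fh.write(f"{peak_id}\t.\t.\t.\t.\n")
                else:
                    fh.write(
                        f"{peak_id}\t{h.offset}\t{h.strand}\t"
                        f"{h.raw_score:.6g}\t{h.rel_score:.6g}\n"
                    )


def _fetch(genome, chrom: str, start: int, end: int, peak_id: str) -> str:
    if isinstance(genome, Mapping):
        seq = genome[chrom] if chrom in genome else None
        if seq is None or end > len(seq):
            raise ValueError(
                f"peak {peak_id}: {chrom}:{start}-{end} outside genome bounds"
            )
        return str(seq[start:end])
    # pyfaidx.Fasta (or anything indexable by chrom with len-able records)
    if chrom not in genome:
        raise ValueError(f"peak {peak_id}: chromosome {chrom!r} not in genome")
    record = genome[chrom]
    if end > len(record):
        raise ValueError(
            f"peak {peak_id}: {chrom}:{start}-{end} beyond chromosome end"
        )
    return str(record[start:end])


def peak_hit_stats(
    peaks: PeakSet,
    genome,
    pfm: PFM,
    rel_threshold: float = 0.80,
) -> PeakHitStats:
    """Scan every peak sequence; report per-peak best hits and hit fraction.

    ``genome`` may be a FASTA path, an open pyfaidx.Fasta, or a mapping of
    chromosome name to sequence string.
    """
    if isinstance(genome, (str, Path)):
        import pyfaidx

        genome = pyfaidx.Fasta(str(genome))
    best: dict[str, MotifHit | None] = {}
    for peak in peaks:
        seq = _fetch(genome, peak.chrom, peak.start, peak.end, peak.id)
        hits = scan_sequence(pfm, seq, rel_threshold)
        top = best_hit(hits)
        best[peak.id] = None if top is None else replace(top, peak_id=peak.id)
    return PeakHitStats(
        motif_id=pfm.motif_id, rel_threshold=rel_threshold, best_hits=best
    )


@dataclass
class CentralityResult:
    """Positional distribution of best hits around peak midpoints."""

    counts: np.ndarray
    edges: np.ndarray
    mean_abs_offset: float
    null_mean_abs_offsets: np.ndarray  # one value per uniform re-randomisation
    n_hits: int

    @property
    def null_mean(self) -> float:
        return float(self.null_mean_abs_offsets.mean())


def motif_centrality(
    stats: PeakHitStats | dict[str, MotifHit | None],
    peaks: PeakSet,
    motif_length: int,
    bin: int = 100,
    n_null: int = 100,
    seed: int = 0,
) -> CentralityResult:
    """Histogram of best-hit offsets from peak midpoints.

    The offset of a hit is (motif centre - peak midpoint) in bp. The
    observed mean |offset| is reported alongside the same statistic under
    ``n_null`` uniform re-randomisations of hit positions within their
    peaks (central motifs score well below this null).
    """
    best = stats.best_hits if isinstance(stats, PeakHitStats) else stats
    by_id = peaks.by_id
    offsets: list[int] = []
    widths: list[int] = []
    for peak_id, hit in best.items():
        if hit is None:
            continue
        if peak_id not in by_id:
            raise ValueError(f"hit references unknown peak {peak_id!r}")
        peak = by_id[peak_id]
        offsets.append((hit.offset + motif_length // 2) - peak.width // 2)
        widths.append(peak.width)

    if offsets:
        max_half = int(np.ceil(max(w / 2 for w in widths) / bin)) * bin
    else:
        max_half = bin
    edges = np.arange(-max_half, max_half + bin, bin)
    counts, _ = np.histogram(offsets, bins=edges)
    mean_abs = float(np.mean(np.abs(offsets))) if offsets else 0.0

    rng = np.random.default_rng(seed)
    null_means = np.empty(n_null)
    widths_arr = np.array(widths, dtype=int)
    for k in range(n_null):
        if offsets:
            starts = rng.integers(0, np.maximum(widths_arr - motif_length, 0) + 1)
            null_off = (starts + motif_length // 2) - widths_arr // 2
            null_means[k] = np.abs(null_off).mean()
        else:
            null_means[k] = 0.0
    return CentralityResult(
        counts=counts,
        edges=edges,
        mean_abs_offset=mean_abs,
        null_mean_abs_offsets=null_means,
        n_hits=len(offsets),
    )


def motif_set_enrichment(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> ContingencyResult:
    """Chi-square enrichment of motif hit rates between two peak sets.

    ``counts_a``/``counts_b`` are (peaks with hit, peaks without hit).
    Fold is the ratio of hit rates, A over B.
    """
    with_a, without_a = counts_a
    with_b, without_b = counts_b
    result = chi_square_2x2([[with_a, without_a], [with_b, without_b]])
    rate_a = with_a / (with_a + without_a)
    rate_b = with_b / (with_b + without_b)
    fold = rate_a / rate_b if rate_b > 0 else float("inf")
    return replace(result, fold_enrichment=fold)
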