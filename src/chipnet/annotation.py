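"""Gene models, strand-aware TSSs, and TSS-proximal peak assignment.

The central relation of the analysis: a peak is *proximal* to a gene when
it intersects the closed window [tss - W, tss + W] around the gene's
transcription start site, W = 10 kb by default. Signed peak-to-TSS
distances are strand-oriented: negative means upstream of the gene.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval, ParseError, PeakSet


@dataclass(frozen=True)
class GeneModel:
    """A gene body [span_start, span_end) with a strand-aware TSS."""

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not 0 <= self.span_start < self.span_end:
            raise ValueError(f"gene {self.gene_id}: invalid span")

    @property
    def tss(self) -> int:
        """5' end of the gene: span_start on +, span_end - 1 on -."""
        return self.span_start if self.strand == "+" else self.span_end - 1


def read_gene_models(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Parse gene models from GTF or GFF3 (Ensembl dialects, via gffutils).

    1-based inclusive file coordinates are converted to 0-based half-open.
    Records sharing a gene_id with identical coordinates collapse to one
    model; conflicting duplicates are an error.
    """
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise ParseError(f"{path}: cannot parse annotation: {exc}") from exc

    models: dict[str, GeneModel] = {}
    for feat in db.features_of_type(feature_type):
        gene_ids = feat.attributes.get("gene_id") or feat.attributes.get("ID")
        if not gene_ids:
            raise ParseError(
                f"{path}: {feature_type} record at {feat.seqid}:{feat.start} "
                "has no gene_id attribute"
            )
        gene_id = gene_ids[0]
        if feat.strand not in ("+", "-"):
            raise ParseError(
                f"{path}: gene {gene_id}: unknown strand {feat.strand!r}"
            )
        model = GeneModel(
            gene_id=gene_id,
            chrom=feat.seqid,
            strand=feat.strand,
            span_start=feat.start - 1,  # GTF 1-based inclusive -> half-open
            span_end=feat.end,
        )
        prior = models.get(gene_id)
        if prior is not None and prior != model:
            raise ParseError(
                f"{path}: gene {gene_id} has conflicting duplicate records"
            )
        models[gene_id] = model
    return sorted(models.values(), key=lambda g: (g.chrom, g.span_start, g.gene_id))


@dataclass
class ProximalAssignment:
    """Many-to-many gene/peak pairs with signed strand-oriented distances."""

    window: int
    pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs)
        self.gene_to_peaks: dict[str, list[str]] = defaultdict(list)
        self.peak_to_genes: dict[str, list[str]] = defaultdict(list)
        for gene_id, peak_id, _ in self.pairs:
            self.gene_to_peaks[gene_id].append(peak_id)
            self.peak_to_genes[peak_id].append(gene_id)
        self.gene_to_peaks = dict(self.gene_to_peaks)
        self.peak_to_genes = dict(self.peak_to_genes)

    @property
    def bound_genes(self) -> frozenset[str]:
        """Genes with at least one proximal peak."""
        return frozenset(self.gene_to_peaks)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tpeak_id\tdistance\n")
            for gene_id, peak_id, dist in self.pairs:
                fh.write(f"{gene_id}\t{peak_id}\t{dist}\n")


def _signed_distance(peak: GenomicInterval, gene: GeneModel) -> int:
    sign = 1 if gene.strand == "+" else -1
    return (peak.midpoint - gene.tss) * sign


def assign_proximal(
    peaks: PeakSet,
    genes: list[GeneModel],
    window: int = 10_000,
    mode: str = "interval",
) -> ProximalAssignment:
    """Assign peaks to genes whose TSS window they intersect.

    mode="interval" (default): the pair (gene, peak) is included when the
    peak interval intersects the closed window [tss - window, tss + window]
    by >=1 bp. mode="midpoint": the peak midpoint itself must lie inside
    the window (stricter; for sensitivity analysis).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not genes:
        raise ValueError("cannot assign peaks: empty gene collection")
    if mode not in ("interval", "midpoint"):
        raise ValueError(f"unknown mode {mode!r}")

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in genes:
        lo = max(0, gene.tss - window)
        trees[gene.chrom].addi(lo, gene.tss + window + 1, gene)

    pairs: list[tuple[str, str, int]] = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        if mode == "interval":
            hits = tree.overlap(peak.start, peak.end)
        else:
            hits = tree.at(peak.midpoint)
        for node in hits:
            gene = node.data
            pairs.append((gene.gene_id, peak.id, _signed_distance(peak, gene)))
    return ProximalAssignment(window=window, pairs=pairs)


def tss_distance_profile(
    peaks: PeakSet,
    genes: list[GeneModel],
    span: int = 10_000,
    bin: int = 1_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of peak-midpoint distances to the nearest TSS.

    Each peak contributes once, to its nearest TSS on the same chromosome
    (ties broken by lexicographic gene_id); peaks farther than ``span`` or
    on gene-free chromosomes are excluded. Returns (counts, bin_edges)
    with edges from -span to +span in steps of ``bin`` (the final edge is
    inclusive, numpy histogram convention).
    """
    if span % bin != 0:
        raise ValueError("span must be a multiple of bin")
    if not genes:
        raise ValueError("cannot profile: empty gene collection")

    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for gene in genes:
        by_chrom[gene.chrom].append(gene)
    tss_arrays = {
        chrom: (
            np.array([g.tss for g in sorted(gs, key=lambda g: (g.tss, g.gene_id))]),
            sorted(gs, key=lambda g: (g.tss, g.gene_id)),
        )
        for chrom, gs in by_chrom.items()
    }

    distances: list[int] = []
    for peak in peaks:
        entry = tss_arrays.get(peak.chrom)
        if entry is None:
            continue
        tss, ordered = entry
        mid = peak.midpoint
        i = int(np.searchsorted(tss, mid))
        candidates = []
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                # expand over runs of identical TSS positions so that
                # gene_id tie-breaking sees every equidistant gene
                k = j
                while k - 1 >= 0 and tss[k - 1] == tss[j]:
                    k -= 1
                while k < len(tss) and tss[k] == tss[j]:
                    candidates.append(k)
                    k += 1
        best = min(candidates, key=lambda j: (abs(mid - tss[j]), ordered[j].gene_id))
        dist = _signed_distance(peak, ordered[best])
        if abs(dist) <= span:
            distances.append(dist)

    edges = np.arange(-span, span + bin, bin)
    counts, _ = np.histogram(distances, bins=edges)
    return counts, edges
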