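"""Coupled synthetic genome / peak / motif / ortholog / expression fixtures.

Every generator plants a known ground truth and records it, so each
pipeline stage can be checked against what was actually simulated:
peak sets with a planted shared fraction between two factors, peaks
concentrated around TSSs, motif instances embedded centrally at a planted
rate, ortholog maps with planted per-species conservation, and
differential-expression tables in which responsiveness depends on the
gene's binding class at a planted odds ratio.

A single root seed fans out deterministically to per-component child
seeds (numpy SeedSequence spawn keys, one fixed key per component), so a
stage can be regenerated independently and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel
from .association import DETable
from .intervals import GenomicInterval, PeakSet
from .motifs import PFM, write_jaspar

#: fixed spawn keys deriving per-component child seeds from the root seed
COMPONENT_KEYS = {
    "genome": 0,
    "peaks": 1,
    "cofactor": 2,
    "motifs": 3,
    "orthology": 4,
    "expression": 5,
}

_BASES = np.array(list("ACGT"))


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic child generator for one simulation component."""
    key = COMPONENT_KEYS[component]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(genes: list[GeneModel], path: str | Path, source: str = "sim") -> None:
    """Write gene models as GTF gene lines (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.span_start + 1}\t{g.span_end}\t"
                f".\t{g.strand}\t.\t{attrs}\n"
            )


def simulate_genome_annotation(
    n_chroms: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
    gene_length_range: tuple[int, int] = (2_000, 6_000),
    out_fasta: str | Path | None = None,
    out_gtf: str | Path | None = None,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Uniform-random genome with non-overlapping, random-strand genes."""
    rng = component_rng(seed, "genome")
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes % n_chroms):
        per_chrom[i] += 1

    gene_no = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        genome[chrom] = "".join(_BASES[rng.integers(0, 4, size=chrom_length)])
        n = per_chrom[c]
        if n == 0:
            continue
        lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=n)
        free = chrom_length - int(lengths.sum())
        if free < 0:
            raise ValueError(
                f"infeasible packing: {n} genes of total length {lengths.sum()} "
                f"do not fit in {chrom_length} bp"
            )
        weights = rng.random(n + 1)
        gaps = np.floor(weights / weights.sum() * free).astype(int)
        pos = 0
        for k in range(n):
            pos += int(gaps[k])
            start = pos
            end = start + int(lengths[k])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gene_no:04d}",
                    chrom=chrom,
                    strand=strand,
                    span_start=start,
                    span_end=end,
                )
            )
            pos = end

    if out_fasta is not None:
        write_fasta(genome, out_fasta)
    if out_gtf is not None:
        write_gtf(genes, out_gtf)
    return genome, genes


def _gene_free_space(
    genes: list[GeneModel], chrom_sizes: dict[str, int]
) -> dict[str, list[tuple[int, int]]]:
    """Complement of merged gene bodies, per chromosome."""
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in genes:
        spans[g.chrom].append((g.span_start, g.span_end))
    free: dict[str, list[tuple[int, int]]] = {}
    for chrom, size in chrom_sizes.items():
        merged: list[list[int]] = []
        for s, e in sorted(spans[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out, pos = [], 0
        for s, e in merged:
            if s > pos:
                out.append((pos, s))
            pos = e
        if pos < size:
            out.append((pos, size))
        free[chrom] = out
    return free


def _intersect_length(
    intervals_a: list[tuple[int, int]], intervals_b: list[tuple[int, int]]
) -> int:
    total = 0
    for s1, e1 in intervals_a:
        for s2, e2 in intervals_b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _finalize_peakset(
    items: list[tuple[GenomicInterval, dict]],
    factor: str,
    genome_build: str,
) -> tuple[PeakSet, dict[str, dict]]:
    """Sort, assign rank ids, and key the per-peak truth by final id."""
    items.sort(key=lambda t: t[0].sort_key())
    intervals, truth = [], {}
    for rank, (iv, meta) in enumerate(items, start=1):
        peak_id = f"{factor}_{rank}"
        intervals.append(replace(iv, id=peak_id))
        truth[peak_id] = meta
    return PeakSet(factor=factor, genome_build=genome_build, intervals=intervals), truth


def simulate_peaks(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    n_peaks: int,
    proximal_fraction: float,
    seed: int,
    factor: str = "Smad2",
    genome_build: str = "sim1",
    width_range: tuple[int, int] = (200, 800),
    tss_sd: float = 3_000.0,
    window: int = 10_000,
) -> tuple[PeakSet, dict]:
    """Peaks concentrated at TSSs plus uniform background on gene-free space.

    A planted-proximal peak is centred at a uniformly chosen gene's TSS
    plus N(0, tss_sd) noise; background peak centres are uniform over the
    complement of gene bodies. The truth records each peak's planted label
    and the geometric expectation of the background proximal rate (the
    fraction of gene-free space falling within the extended TSS window).
    """
    if not 0.0 <= proximal_fraction <= 1.0:
        raise ValueError("proximal_fraction must be in [0, 1]")
    rng = component_rng(seed, "peaks")
    n_prox = int(round(n_peaks * proximal_fraction))
    n_bg = n_peaks - n_prox

    # peaks of one factor never overlap each other (a peak caller merges
    # overlapping enrichment into one call), so placement is rejection-sampled
    placed: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_sizes}

    def try_place(chrom: str, start: int, width: int) -> int | None:
        start = min(max(start, 0), chrom_sizes[chrom] - width)
        if placed[chrom].overlap(start, start + width):
            return None
        placed[chrom].addi(start, start + width)
        return start

    items: list[tuple[GenomicInterval, dict]] = []
    for _ in range(n_prox):
        for _ in range(200):
            gene = genes[int(rng.integers(0, len(genes)))]
            width = int(rng.integers(width_range[0], width_range[1] + 1))
            center = gene.tss + int(round(rng.normal(0.0, tss_sd)))
            start = try_place(gene.chrom, center - width // 2, width)
            if start is not None:
                break
        else:
            raise RuntimeError("could not place proximal peak without overlap")
        iv = GenomicInterval(gene.chrom, start, start + width,
                             height=float(rng.uniform(0.5, 8.0)))
        items.append((iv, {"planted_proximal": True, "source_gene": gene.gene_id}))

    free = _gene_free_space(genes, chrom_sizes)
    flat = [(chrom, s, e) for chrom in sorted(free) for s, e in free[chrom]]
    lengths = np.array([e - s for _, s, e in flat], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total_free = int(cum[-1])
    for _ in range(n_bg):
        for _ in range(200):
            r = int(rng.integers(0, total_free))
            j = int(np.searchsorted(cum, r, side="right")) - 1
            chrom, s, _ = flat[j]
            center = s + (r - int(cum[j]))
            width = int(rng.integers(width_range[0], width_range[1] + 1))
            start = try_place(chrom, center - width // 2, width)
            if start is not None:
                break
        else:
            raise RuntimeError("could not place background peak without overlap")
        iv = GenomicInterval(chrom, start, start + width,
                             height=float(rng.uniform(0.5, 8.0)))
        items.append((iv, {"planted_proximal": False, "source_gene": None}))

    # expected chance rate of background centres landing proximal: TSS
    # windows extended by the mean peak half-width, intersected with the
    # eligible (gene-free) space
    half = (width_range[0] + width_range[1]) / 4.0
    ext = int(round(window + half))
    tss_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in genes:
        tss_windows[g.chrom].append(
            (max(0, g.tss - ext), min(chrom_sizes[g.chrom], g.tss + ext + 1))
        )
    hit_len = sum(
        _intersect_length(free[c], tss_windows[c]) for c in chrom_sizes
    )
    expected_bg_rate = hit_len / total_free if total_free else 0.0

    peaks, per_peak = _finalize_peakset(items, factor, genome_build)
    truth = {
        "factor": factor,
        "n_peaks": n_peaks,
        "planted_proximal_fraction": proximal_fraction,
        "expected_background_proximal_rate": expected_bg_rate,
        "per_peak": per_peak,
    }
    return peaks, truth


def simulate_cofactor_peaks(
    base: PeakSet,
    chrom_sizes: dict[str, int],
    shared_fraction: float,
    n_extra: int,
    seed: int,
    factor: str = "Eomesa",
    jitter_sd: float = 100.0,
    width_range: tuple[int, int] = (200, 800),
) -> tuple[PeakSet, dict]:
    """A second factor sharing a Bernoulli(p) subset of the base peaks.

    Each selected base peak gets one partner peak whose centre is jittered
    but clamped to guarantee >=1 bp overlap with its own base peak (and
    re-drawn to avoid other base peaks where possible); ``n_extra``
    independent peaks are placed avoiding all base peaks, so the planted
    shared/unshared labels coincide with what share_peaks computes.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = component_rng(seed, "cofactor")

    base_trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_sizes}
    for iv in base:
        base_trees[iv.chrom].addi(iv.start, iv.end, iv.id)
    # cofactor peaks are also mutually non-overlapping (one factor, one call)
    own: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_sizes}

    items: list[tuple[GenomicInterval, dict]] = []
    shared_base: list[str] = []
    for iv in base:
        if rng.random() >= shared_fraction:
            continue
        shared_base.append(iv.id)
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        chrom_len = chrom_sizes[iv.chrom]
        placed = None
        for _ in range(50):
            center = iv.midpoint + int(round(rng.normal(0.0, jitter_sd)))
            start = center - width // 2
            # clamp so the partner overlaps its own base peak by >=1 bp
            start = min(max(start, iv.start - width + 1), iv.end - 1)
            start = min(max(start, 0), chrom_len - width)
            others = {
                node.data
                for node in base_trees[iv.chrom].overlap(start, start + width)
            } - {iv.id}
            if not others and not own[iv.chrom].overlap(start, start + width):
                placed = start
                break
        if placed is None:  # crowded region: centre on the base peak
            placed = min(max(iv.midpoint - width // 2, 0), chrom_len - width)
        own[iv.chrom].addi(placed, placed + width)
        items.append(
            (
                GenomicInterval(iv.chrom, placed, placed + width,
                                height=float(rng.uniform(0.3, 4.0))),
                {"planted_shared": True, "partner_of": iv.id},
            )
        )

    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(sizes)])
    for _ in range(n_extra):
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        for _ in range(200):
            r = int(rng.integers(0, int(cum[-1])))
            j = int(np.searchsorted(cum, r, side="right")) - 1
            chrom = chroms[j]
            start = min(max((r - int(cum[j])) - width // 2, 0),
                        chrom_sizes[chrom] - width)
            if not base_trees[chrom].overlap(start, start + width) and not own[
                chrom
            ].overlap(start, start + width):
                own[chrom].addi(start, start + width)
                items.append(
                    (
                        GenomicInterval(chrom, start, start + width,
                                        height=float(rng.uniform(0.3, 4.0))),
                        {"planted_shared": False, "partner_of": None},
                    )
                )
                break
        else:
            raise RuntimeError("could not place extra peak avoiding base peaks")

    peaks, per_peak = _finalize_peakset(items, factor, base.genome_build)
    truth = {
        "factor": factor,
        "planted_shared_fraction": shared_fraction,
        "shared_base_ids": sorted(shared_base),
        "per_peak": per_peak,
    }
    return peaks, truth


_RC = str.maketrans("ACGT", "TGCA")


def _sample_motif_instance(pfm: PFM, rng: np.random.Generator, use_consensus: bool) -> str:
    if use_consensus:
        return pfm.consensus
    probs = pfm.counts / pfm.counts.sum(axis=0, keepdims=True)
    return "".join(
        "ACGT"[int(rng.choice(4, p=probs[:, j]))] for j in range(pfm.length)
    )


def plant_motifs(
    genome: dict[str, str],
    peaks: PeakSet,
    pfm: PFM,
    rate: float,
    center_sd: float,
    seed: int,
    use_consensus: bool = True,
) -> tuple[dict[str, str], dict]:
    """Write motif instances into a Bernoulli(rate) subset of peak sequences.

    Each planted instance is centred at the peak midpoint plus
    N(0, center_sd) (clamped inside the peak) on a random strand. The
    consensus string is planted by default (maximal detectability);
    PFM-sampled instances are available for power studies. Overlapping
    peaks may overwrite one another's instances; use sparse peak sets
    when exact per-peak truth is needed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = component_rng(seed, "motifs")
    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    L = pfm.length
    planted: dict[str, dict | None] = {}
    for peak in peaks:
        if peak.width < L or rng.random() >= rate:
            planted[peak.id] = None
            continue
        instance = _sample_motif_instance(pfm, rng, use_consensus)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            instance = instance.translate(_RC)[::-1]
        center = peak.midpoint + int(round(rng.normal(0.0, center_sd)))
        start = center - L // 2
        start = min(max(start, peak.start), peak.end - L)
        mutable[peak.chrom][start : start + L] = instance.encode("ascii")
        planted[peak.id] = {"offset": start - peak.start, "strand": strand}

    new_genome = {c: bytes(b).decode("ascii") for c, b in mutable.items()}
    truth = {
        "motif_id": pfm.motif_id,
        "planted_rate": rate,
        "center_sd": center_sd,
        "per_peak": planted,
    }
    return new_genome, truth


def simulate_orthology_and_foreign_sets(
    reference_genes: list[str],
    conservation_fractions: dict[str, float],
    fanout_prob: float,
    seed: int,
    n_unmapped_bound: int = 5,
    n_unbound_orthologs: int = 10,
) -> tuple["OrthologMap", dict[str, frozenset[str]], dict]:
    """Ortholog maps and foreign bound-gene sets with planted conservation.

    Each reference gene is conserved-and-bound in species s with
    probability conservation_fractions[s]. one2many fan-out targets are
    drawn from genes already conserved in that species, so the projected
    per-species sets (and hence conservation classes) equal the planted
    truth exactly. Some bound foreign genes carry no ortholog record
    (exercising the unmapped counter) and some orthologs are unbound.
    """
    from .crossspecies import OrthologMap

    rng = component_rng(seed, "orthology")
    records: list[tuple[str, str, str]] = []
    bound: dict[str, set[str]] = {}
    conserved: dict[str, list[str]] = {}
    for species in sorted(conservation_fractions):
        frac = conservation_fractions[species]
        flags = rng.random(len(reference_genes)) < frac
        cons = [g for g, f in zip(reference_genes, flags) if f]
        conserved[species] = cons
        bound_s: set[str] = set()
        cons_set = set(cons)
        for g in cons:
            foreign = f"{species}_{g}"
            bound_s.add(foreign)
            if len(cons) > 1 and rng.random() < fanout_prob:
                pool = [x for x in cons if x != g]
                extra = pool[int(rng.integers(0, len(pool)))]
                records.append((foreign, g, "one2many"))
                records.append((foreign, extra, "one2many"))
            else:
                records.append((foreign, g, "one2one"))
        for i in range(n_unmapped_bound):
            bound_s.add(f"{species}_orphan{i + 1}")
        for i in range(n_unbound_orthologs):
            target = reference_genes[int(rng.integers(0, len(reference_genes)))]
            records.append((f"{species}_unbound{i + 1}", target, "one2one"))
        bound[species] = bound_s

    classes = {
        g: sum(g in set(conserved[s]) for s in conserved) for g in reference_genes
    }
    truth = {
        "conservation_fractions": dict(conservation_fractions),
        "conserved": {s: sorted(v) for s, v in conserved.items()},
        "classes": classes,
        "n_unmapped_bound_per_species": n_unmapped_bound,
    }
    return (
        OrthologMap(records=tuple(records)),
        {s: frozenset(v) for s, v in bound.items()},
        truth,
    )


def simulate_de_table(
    classes,
    seed: int,
    base_rate: float = 0.1,
    odds_ratios: dict[str, float] | None = None,
    effect_size: float = 1.5,
    p_threshold: float = 0.05,
    direction: str = "up",
    provenance: str = "rnaseq",
) -> tuple[DETable, dict]:
    """Differential-expression table with class-dependent responsiveness.

    A gene in binding class c is responsive with odds base_odds * OR[c].
    Responsive genes get |log2fc| ~ |N(effect_size, 0.5)| signed by
    ``direction`` and P ~ U(0, p_threshold); others get small fold changes
    and P ~ U(p_threshold, 1), so thresholding recovers the planted set.
    """
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must be in (0, 1)")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    odds_ratios = odds_ratios or {}
    labels = classes.labels if hasattr(classes, "labels") else dict(classes)
    rng = component_rng(seed, "expression")

    base_odds = base_rate / (1.0 - base_rate)
    rows = []
    responsive: list[str] = []
    sign = 1.0 if direction == "up" else -1.0
    for gene in sorted(labels):
        odds = base_odds * odds_ratios.get(labels[gene], 1.0)
        p_resp = odds / (1.0 + odds)
        if rng.random() < p_resp:
            responsive.append(gene)
            log2fc = sign * abs(rng.normal(effect_size, 0.5))
            pval = float(rng.uniform(0.0, p_threshold))
        else:
            log2fc = float(rng.normal(0.0, 0.2))
            pval = float(rng.uniform(p_threshold, 1.0))
        rows.append((gene, float(log2fc), pval))

    frame = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"])
    n_per_class: dict[str, int] = {}
    for gene in responsive:
        n_per_class[labels[gene]] = n_per_class.get(labels[gene], 0) + 1
    truth = {
        "base_rate": base_rate,
        "odds_ratios": odds_ratios,
        "p_threshold": p_threshold,
        "direction": direction,
        "responsive": responsive,
        "n_responsive_per_class": n_per_class,
    }
    return DETable(frame=frame, provenance=provenance), truth


def default_motif() -> PFM:
    """Synthetic 10-bp test motif (strong consensus, fully synthetic counts)."""
    consensus = "TGTGGATTAC"
    counts = np.full((4, len(consensus)), 5.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 85.0
    return PFM(motif_id="SYN0001.1", counts=counts, name="synthetic_test_motif")


@dataclasses.dataclass
class BundleParams:
    """Default conditions for a full synthetic fixture bundle."""

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 300
    n_peaks_a: int = 250
    proximal_fraction: float = 0.8
    shared_fraction: float = 0.4
    n_extra_b: int = 250
    motif_rate: float = 0.5
    motif_center_sd: float = 50.0
    conservation_fractions: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"human": 0.5, "mouse": 0.4, "xenopus": 0.3}
    )
    fanout_prob: float = 0.1
    de_base_rate: float = 0.15
    de_odds_ratios: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"common": 4.0}
    )
    de_p_threshold: float = 0.05
    factor_a: str = "Smad2"
    factor_b: str = "Eomesa"


def simulate_bundle(
    outdir: str | Path, seed: int, params: BundleParams | None = None
) -> dict:
    """Generate a complete, mutually consistent fixture bundle on disk.

    Writes genome.fa, genes.gtf, peaks_a.bed, peaks_b.bed, motif.jaspar,
    per-species ortholog maps and bound-gene lists, de_table.tsv, a ready
    pipeline config.yaml, and truth.json recording every planted label.
    Returns the truth dictionary.
    """
    from .annotation import assign_proximal
    from .cooccupancy import gene_binding_classes, share_peaks

    import yaml

    params = params or BundleParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, genes = simulate_genome_annotation(
        params.n_chroms, params.chrom_length, params.n_genes, seed
    )
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    write_gtf(genes, outdir / "genes.gtf")

    peaks_a, truth_a = simulate_peaks(
        genes, chrom_sizes, params.n_peaks_a, params.proximal_fraction, seed,
        factor=params.factor_a,
    )
    peaks_b, truth_b = simulate_cofactor_peaks(
        peaks_a, chrom_sizes, params.shared_fraction, params.n_extra_b, seed,
        factor=params.factor_b,
    )
    from .intervals import write_peaks

    write_peaks(peaks_a, outdir / "peaks_a.bed")
    write_peaks(peaks_b, outdir / "peaks_b.bed")

    pfm = default_motif()
    write_jaspar(pfm, outdir / "motif.jaspar")
    genome, truth_m = plant_motifs(
        genome, peaks_a, pfm, params.motif_rate, params.motif_center_sd, seed
    )
    write_fasta(genome, outdir / "genome.fa")

    # derived gene-level classes drive the simulated expression response
    assign_a = assign_proximal(peaks_a, genes)
    assign_b = assign_proximal(peaks_b, genes)
    sharing = share_peaks(peaks_a, peaks_b)
    universe = {g.gene_id for g in genes}
    classes = gene_binding_classes(assign_a, assign_b, sharing, universe)

    omap, bound, truth_o = simulate_orthology_and_foreign_sets(
        sorted(assign_a.bound_genes),
        params.conservation_fractions,
        params.fanout_prob,
        seed,
    )
    omap.to_tsv(outdir / "orthologs.tsv")
    ortholog_inputs = {}
    for species, genes_s in bound.items():
        bound_path = outdir / f"bound_{species}.txt"
        with open(bound_path, "w") as fh:
            fh.writelines(f"{g}\n" for g in sorted(genes_s))
        ortholog_inputs[species] = {
            "map": "orthologs.tsv",
            "bound_genes": f"bound_{species}.txt",
        }

    de_table, truth_e = simulate_de_table(
        classes,
        seed,
        base_rate=params.de_base_rate,
        odds_ratios=params.de_odds_ratios,
        p_threshold=params.de_p_threshold,
    )
    de_table.to_tsv(outdir / "de_table.tsv")

    config = {
        "genome_build": "sim1",
        "seed": seed,
        "factors": {"a": params.factor_a, "b": params.factor_b},
        "de_provenance": "rnaseq",
        "inputs": {
            "genome_fasta": "genome.fa",
            "annotation": "genes.gtf",
            "peaks_a": "peaks_a.bed",
            "peaks_b": "peaks_b.bed",
            "motif": "motif.jaspar",
            "de_table": "de_table.tsv",
            "orthologs": ortholog_inputs,
        },
        "params": {
            "proximal_window": 10_000,
            "min_overlap": 1,
            "de_p_threshold_rnaseq": params.de_p_threshold,
            "motif_rel_threshold": 0.80,
        },
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    truth = {
        "seed": seed,
        "params": dataclasses.asdict(params),
        "genome": {"chrom_sizes": chrom_sizes, "n_genes": len(genes)},
        "peaks_a": truth_a,
        "peaks_b": truth_b,
        "motifs": truth_m,
        "orthology": truth_o,
        "expression": truth_e,
        "derived_classes": dict(sorted(classes.labels.items())),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
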