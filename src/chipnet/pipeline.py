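"""End-to-end pipeline: consensus -> proximal assignment -> co-occupancy ->
motif scanning -> cross-species conservation -> association statistics.

Driven by a flat YAML config (inputs + parameters); writes per-stage TSV
outputs and a machine-readable JSON report whose manifest (input paths and
checksums), parameter echo, and stage summaries suffice to re-derive every
number in it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotation import assign_proximal, read_gene_models, tss_distance_profile
from .association import (
    binding_response_association,
    read_de_table,
    responsive_sets,
)
from .cooccupancy import gene_binding_classes, share_peaks
from .crossspecies import (
    OrthologMap,
    conservation_classes,
    project_gene_set,
    venn_partition,
    venn_to_tsv,
)
from .intervals import AnalysisConfig, PeakSet, read_peaks, replicate_consensus, write_peaks
from .motifs import motif_centrality, motif_set_enrichment, peak_hit_stats, read_jaspar

log = logging.getLogger("chipnet")


class PipelineConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config: str | Path | dict) -> tuple[dict, Path]:
    """Load a pipeline config; relative input paths resolve against it."""
    if isinstance(config, (str, Path)):
        path = Path(config)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        base = path.parent
    else:
        cfg = dict(config)
        base = Path(cfg.get("base_dir", "."))
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a mapping")
    return cfg, base


def validate_config(cfg: dict, base: Path) -> dict[str, Path]:
    """Check the schema and that every named input file exists.

    Returns the resolved input paths; raises before any stage runs, listing
    every offending field at once.
    """
    problems: list[str] = []
    inputs = cfg.get("inputs")
    if not isinstance(inputs, dict):
        raise PipelineConfigError("config missing 'inputs' section")

    resolved: dict[str, Path] = {}

    def check(field: str, rel: str) -> None:
        p = base / rel
        if not p.exists():
            problems.append(f"inputs.{field}: file not found: {p}")
        else:
            resolved[field] = p

    if "annotation" not in inputs:
        problems.append("inputs.annotation is required")
    has_a = "peaks_a" in inputs or (
        "peaks_a_rep1" in inputs and "peaks_a_rep2" in inputs
    )
    has_b = "peaks_b" in inputs or (
        "peaks_b_rep1" in inputs and "peaks_b_rep2" in inputs
    )
    if not has_a:
        problems.append("inputs.peaks_a (or peaks_a_rep1 + peaks_a_rep2) is required")
    if not has_b:
        problems.append("inputs.peaks_b (or peaks_b_rep1 + peaks_b_rep2) is required")

    for field in (
        "annotation", "genome_fasta", "motif", "de_table",
        "peaks_a", "peaks_b",
        "peaks_a_rep1", "peaks_a_rep2", "peaks_b_rep1", "peaks_b_rep2",
    ):
        if field in inputs:
            check(field, inputs[field])
    for species, entry in (inputs.get("orthologs") or {}).items():
        for key in ("map", "bound_genes"):
            if key not in entry:
                problems.append(f"inputs.orthologs.{species}.{key} is required")
            else:
                check(f"orthologs.{species}.{key}", entry[key])

    known_params = {f.name for f in dataclasses.fields(AnalysisConfig)}
    for key in cfg.get("params") or {}:
        if key not in known_params:
            problems.append(f"params.{key}: unknown parameter")

    if problems:
        raise PipelineConfigError(
            "invalid pipeline configuration:\n  " + "\n  ".join(problems)
        )
    return resolved


def _load_peakset(
    inputs: dict, resolved: dict[str, Path], side: str, factor: str,
    build: str, config: AnalysisConfig, outdir: Path,
) -> PeakSet:
    direct = f"peaks_{side}"
    if direct in resolved:
        dialect = "tsv" if str(resolved[direct]).endswith(".tsv") else "bed"
        return read_peaks(resolved[direct], dialect=dialect, factor=factor,
                          genome_build=build)
    rep1 = read_peaks(resolved[f"peaks_{side}_rep1"], factor=factor, genome_build=build)
    rep2 = read_peaks(resolved[f"peaks_{side}_rep2"], factor=factor, genome_build=build)
    consensus = replicate_consensus(rep1, rep2, min_overlap=config.min_overlap)
    write_peaks(consensus, outdir / f"consensus_{factor}.bed")
    log.info("consensus %s: %d peaks from %d + %d replicate peaks",
             factor, len(consensus), len(rep1), len(rep2))
    return consensus


def run_pipeline(config: str | Path | dict, outdir: str | Path) -> dict:
    """Execute every configured stage in dependency order; return the report."""
    cfg, base = load_config(config)
    resolved = validate_config(cfg, base)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = AnalysisConfig(**{
        k: (tuple(v) if k == "background" else v)
        for k, v in (cfg.get("params") or {}).items()
    })
    factors = cfg.get("factors") or {}
    factor_a = factors.get("a", "factorA")
    factor_b = factors.get("b", "factorB")
    build = cfg.get("genome_build", "")
    seed = int(cfg.get("seed", 0))
    inputs = cfg["inputs"]

    log.info("pipeline start: outdir=%s params=%s seed=%d", outdir, params, seed)
    report: dict = {
        "tool": "chipnet",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "seed": seed,
        "parameters": dataclasses.asdict(params),
        "factors": {"a": factor_a, "b": factor_b},
        "input_manifest": {
            field: {"path": str(p), "sha256": _sha256(p)}
            for field, p in sorted(resolved.items())
        },
        "stages": {},
    }

    # --- peaks (with replicate consensus where replicates are given) ---
    peaks_a = _load_peakset(inputs, resolved, "a", factor_a, build, params, outdir)
    peaks_b = _load_peakset(inputs, resolved, "b", factor_b, build, params, outdir)
    report["stages"]["peaks"] = {
        "n_peaks_a": len(peaks_a), "n_peaks_b": len(peaks_b),
    }

    # --- proximal assignment ---
    genes = read_gene_models(resolved["annotation"])
    universe = {g.gene_id for g in genes}
    assign_a = assign_proximal(peaks_a, genes, window=params.proximal_window)
    assign_b = assign_proximal(peaks_b, genes, window=params.proximal_window)
    assign_a.to_tsv(outdir / f"proximal_{factor_a}.tsv")
    assign_b.to_tsv(outdir / f"proximal_{factor_b}.tsv")
    counts, edges = tss_distance_profile(peaks_a, genes, span=params.proximal_window)
    with open(outdir / f"tss_profile_{factor_a}.tsv", "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for i, c in enumerate(counts):
            fh.write(f"{edges[i]}\t{edges[i + 1]}\t{c}\n")
    report["stages"]["proximal"] = {
        "window": params.proximal_window,
        "n_genes": len(genes),
        "n_bound_genes_a": len(assign_a.bound_genes),
        "n_bound_genes_b": len(assign_b.bound_genes),
        "n_pairs_a": len(assign_a.pairs),
        "n_pairs_b": len(assign_b.pairs),
    }
    log.info("proximal: %d/%d genes bound by %s, %d by %s",
             len(assign_a.bound_genes), len(genes), factor_a,
             len(assign_b.bound_genes), factor_b)

    # --- co-occupancy ---
    sharing = share_peaks(peaks_a, peaks_b, min_overlap=params.min_overlap)
    sharing.summary_tsv(outdir / "sharing_summary.tsv")
    classes = gene_binding_classes(assign_a, assign_b, sharing, universe)
    classes.to_tsv(outdir / "gene_classes.tsv")
    class_counts = classes.class_counts()
    report["stages"]["cooccupancy"] = {
        "sharing": sharing.counts,
        "n_pairs": len(sharing.pair_list),
        "gene_class_counts": class_counts,
    }

    # --- motif scanning ---
    if "genome_fasta" in resolved and "motif" in resolved:
        pfm = read_jaspar(resolved["motif"], background=params.background,
                          pseudocount=params.pseudocount)
        stats_a = peak_hit_stats(peaks_a, resolved["genome_fasta"], pfm,
                                 params.motif_rel_threshold)
        stats_b = peak_hit_stats(peaks_b, resolved["genome_fasta"], pfm,
                                 params.motif_rel_threshold)
        common_ids = sharing.shared_a
        common_peaks = PeakSet(
            factor=f"{factor_a}_shared", genome_build=build,
            intervals=[iv for iv in peaks_a if iv.id in common_ids],
        )
        stats_common = peak_hit_stats(common_peaks, resolved["genome_fasta"], pfm,
                                      params.motif_rel_threshold)
        stats_a.to_tsv(outdir / f"motif_hits_{factor_a}.tsv")
        stats_b.to_tsv(outdir / f"motif_hits_{factor_b}.tsv")
        centrality = motif_centrality(stats_a, peaks_a, pfm.length, seed=seed)
        motif_block = {
            "motif_id": pfm.motif_id,
            "rel_threshold": params.motif_rel_threshold,
            "fraction_a": stats_a.fraction,
            "fraction_b": stats_b.fraction,
            "fraction_common": stats_common.fraction,
            "centrality_mean_abs_offset": centrality.mean_abs_offset,
            "centrality_null_mean": centrality.null_mean,
        }
        if stats_common.n_total:
            for other, stats in (("a", stats_a), ("b", stats_b)):
                enr = motif_set_enrichment(
                    (stats_common.n_with_hit,
                     stats_common.n_total - stats_common.n_with_hit),
                    (stats.n_with_hit, stats.n_total - stats.n_with_hit),
                )
                motif_block[f"enrichment_common_vs_{other}"] = enr.to_dict()
        report["stages"]["motifs"] = motif_block
        log.info("motifs: hit fractions a=%.3f b=%.3f common=%.3f",
                 stats_a.fraction, stats_b.fraction, stats_common.fraction)

    # --- cross-species conservation ---
    orthologs = inputs.get("orthologs") or {}
    if orthologs:
        projected: dict[str, frozenset[str]] = {}
        projection_info = {}
        for species in sorted(orthologs):
            omap = OrthologMap.from_tsv(resolved[f"orthologs.{species}.map"])
            with open(resolved[f"orthologs.{species}.bound_genes"]) as fh:
                foreign = {line.strip() for line in fh if line.strip()}
            proj = project_gene_set(foreign, omap)
            projected[species] = proj.genes
            projection_info[species] = {
                "n_foreign_bound": proj.n_input,
                "n_unmapped": proj.n_unmapped,
                "n_projected": len(proj.genes),
            }
        reference = assign_a.bound_genes
        named = {"reference": reference, **projected}
        venn = venn_partition(dict(list(named.items())[:4]))
        venn_to_tsv(venn, outdir / "venn.tsv")
        table = conservation_classes(reference, projected, reference_name="reference")
        table.to_tsv(outdir / "conservation.tsv")
        table.summary_json(outdir / "conservation_summary.json")
        report["stages"]["cross_species"] = {
            "projection": projection_info,
            "n_reference_bound": len(reference),
            "class_counts": {str(k): v for k, v in table.class_counts().items()},
            "n_conserved_1plus": table.n_conserved(1),
        }

    # --- binding-response association ---
    if "de_table" in resolved:
        provenance = cfg.get("de_provenance", "rnaseq")
        threshold = (
            params.de_p_threshold_array
            if provenance == "array"
            else params.de_p_threshold_rnaseq
        )
        de = read_de_table(resolved["de_table"], provenance=provenance)
        assoc_block: dict = {"provenance": provenance, "p_threshold": threshold}
        rows = []
        for direction in ("up", "down"):
            genes_resp = responsive_sets(de, threshold, direction) & universe
            assoc_block[f"n_{direction}"] = len(genes_resp)
            for focal in ("A_only", "common", "uncommon", "B_only"):
                if class_counts[focal] == 0 or not genes_resp:
                    continue
                result = binding_response_association(
                    classes, genes_resp, universe, focal
                )
                key = f"{direction}_vs_{focal}"
                assoc_block[key] = result.to_dict()
                rows.append((direction, focal, result))
        with open(outdir / "associations.tsv", "w") as fh:
            fh.write("direction\tfocal_class\tchi2\tp_value\tfold_enrichment\todds_ratio\n")
            for direction, focal, r in rows:
                fh.write(
                    f"{direction}\t{focal}\t{r.chi2:.6g}\t{r.p_value:.6g}\t"
                    f"{r.fold_enrichment:.6g}\t{r.odds_ratio:.6g}\n"
                )
        report["stages"]["association"] = assoc_block

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    log.info("pipeline done: report at %s", outdir / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
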