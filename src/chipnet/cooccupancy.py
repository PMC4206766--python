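"""Two-factor peak sharing and gene-level binding classes.

Peak level: an A peak is *shared* when it overlaps at least one B peak.
Gene level: a gene proximal to both factors is *common* when at least one
of its proximal A/B peak pairs overlap each other, *uncommon* when both
factors bind proximally but never at overlapping coordinates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .annotation import ProximalAssignment
from .intervals import ConfigError, PeakSet

#: gene-level binding class labels, in display order
BINDING_CLASSES = ("A_only", "common", "uncommon", "B_only", "none")


@dataclass
class PeakSharing:
    """Partition of two peak sets by mutual overlap."""

    factor_a: str
    factor_b: str
    shared_a: frozenset[str]
    only_a: frozenset[str]
    shared_b: frozenset[str]
    only_b: frozenset[str]
    pair_list: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pair_list = sorted(self.pair_list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared_a": len(self.shared_a),
            "only_a": len(self.only_a),
            "shared_b": len(self.shared_b),
            "only_b": len(self.only_b),
        }

    def summary_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("factor\tn_total\tn_shared\tn_only\n")
            fh.write(
                f"{self.factor_a}\t{len(self.shared_a) + len(self.only_a)}\t"
                f"{len(self.shared_a)}\t{len(self.only_a)}\n"
            )
            fh.write(
                f"{self.factor_b}\t{len(self.shared_b) + len(self.only_b)}\t"
                f"{len(self.shared_b)}\t{len(self.only_b)}\n"
            )


def share_peaks(set_a: PeakSet, set_b: PeakSet, min_overlap: int = 1) -> PeakSharing:
    """Classify peaks of two factors into shared and factor-specific sets."""
    if set_a.genome_build != set_b.genome_build:
        raise ConfigError(
            f"genome build mismatch: {set_a.genome_build!r} vs {set_b.genome_build!r}"
        )
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in set_b:
        trees[iv.chrom].addi(iv.start, iv.end, iv)

    pairs: list[tuple[str, str]] = []
    shared_a: set[str] = set()
    shared_b: set[str] = set()
    for a in set_a:
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        for node in tree.overlap(a.start, a.end):
            b = node.data
            if min(a.end, b.end) - max(a.start, b.start) >= min_overlap:
                pairs.append((a.id, b.id))
                shared_a.add(a.id)
                shared_b.add(b.id)

    all_a = {iv.id for iv in set_a}
    all_b = {iv.id for iv in set_b}
    return PeakSharing(
        factor_a=set_a.factor,
        factor_b=set_b.factor,
        shared_a=frozenset(shared_a),
        only_a=frozenset(all_a - shared_a),
        shared_b=frozenset(shared_b),
        only_b=frozenset(all_b - shared_b),
        pair_list=pairs,
    )


@dataclass
class BindingClassMap:
    """Per-gene label in {A_only, common, uncommon, B_only, none}."""

    factor_a: str
    factor_b: str
    labels: dict[str, str]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in BINDING_CLASSES}
        for label in self.labels.values():
            counts[label] += 1
        return counts

    def genes_in_class(self, label: str) -> frozenset[str]:
        if label not in BINDING_CLASSES:
            raise ValueError(f"unknown binding class {label!r}")
        return frozenset(g for g, lab in self.labels.items() if lab == label)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tbinding_class\n")
            for gene_id in sorted(self.labels):
                fh.write(f"{gene_id}\t{self.labels[gene_id]}\n")


def gene_binding_classes(
    assign_a: ProximalAssignment,
    assign_b: ProximalAssignment,
    sharing: PeakSharing,
    universe: set[str] | frozenset[str],
) -> BindingClassMap:
    """Label every universe gene by its two-factor proximal binding pattern.

    common wins over uncommon: a gene is common as soon as ANY of its
    proximal A/B peak pairs overlap, even if other pairs do not.
    """
    universe = frozenset(universe)
    for name, assignment in (("A", assign_a), ("B", assign_b)):
        stray = assignment.bound_genes - universe
        if stray:
            raise ValueError(
                f"assignment {name} contains genes outside the universe: "
                f"{sorted(stray)[:5]}"
            )

    overlapping = set(sharing.pair_list)
    labels: dict[str, str] = {}
    for gene in universe:
        peaks_a = assign_a.gene_to_peaks.get(gene, ())
        peaks_b = assign_b.gene_to_peaks.get(gene, ())
        if peaks_a and peaks_b:
            common = any((pa, pb) in overlapping for pa in peaks_a for pb in peaks_b)
            labels[gene] = "common" if common else "uncommon"
        elif peaks_a:
            labels[gene] = "A_only"
        elif peaks_b:
            labels[gene] = "B_only"
        else:
            labels[gene] = "none"
    return BindingClassMap(
        factor_a=sharing.factor_a, factor_b=sharing.factor_b, labels=labels
    )
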