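"""Ortholog projection and multi-species conservation of bound gene sets.

Foreign-species proximal-bound gene sets are projected onto reference
gene identifiers through an ortholog map (one2one / one2many / many2many
relations all included by default — "orthologues and possible
orthologues"), then partitioned by Venn membership pattern and summarised
as per-gene conservation classes (number of non-reference species with
proximal binding).
"""

from __future__ import annotations

import itertools
import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")


@dataclass(frozen=True)
class OrthologMap:
    """Deduplicated (source_gene, target_gene, homology_type) records."""

    records: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        deduped = []
        for source, target, htype in self.records:
            if htype not in HOMOLOGY_TYPES:
                raise ValueError(f"unknown homology type {htype!r}")
            if (source, target) in seen:
                continue
            seen[(source, target)] = htype
            deduped.append((source, target, htype))
        object.__setattr__(self, "records", tuple(deduped))

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if lineno == 1 and cols[:3] == ["source_gene", "target_gene", "homology_type"]:
                    continue
                if len(cols) < 3:
                    raise ValueError(f"{path}: line {lineno}: expected 3 columns")
                records.append((cols[0], cols[1], cols[2]))
        return cls(records=tuple(records))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source_gene\ttarget_gene\thomology_type\n")
            for source, target, htype in self.records:
                fh.write(f"{source}\t{target}\t{htype}\n")


@dataclass(frozen=True)
class ProjectionResult:
    """Reference-gene projection of a foreign gene set."""

    genes: frozenset[str]
    n_input: int
    n_unmapped: int


def project_gene_set(
    genes: set[str] | frozenset[str],
    ortholog_map: OrthologMap,
    homology_types: tuple[str, ...] | None = None,
) -> ProjectionResult:
    """Union of reference orthologs of the input genes.

    Inputs without any (allowed-type) ortholog are dropped from the
    projection but counted in ``n_unmapped``.
    """
    allowed = set(HOMOLOGY_TYPES if homology_types is None else homology_types)
    by_source: dict[str, set[str]] = defaultdict(set)
    for source, target, htype in ortholog_map.records:
        if htype in allowed:
            by_source[source].add(target)
    genes = frozenset(genes)
    projected: set[str] = set()
    unmapped = 0
    for g in genes:
        targets = by_source.get(g)
        if targets:
            projected |= targets
        else:
            unmapped += 1
    return ProjectionResult(
        genes=frozenset(projected), n_input=len(genes), n_unmapped=unmapped
    )


def venn_partition(named_sets) -> dict[frozenset[str], int]:
    """Counts for every nonempty membership pattern of 2-4 named sets.

    Accepts a mapping name -> set or a sequence of (name, set) pairs
    (duplicate names are an error). Patterns are disjoint and their
    counts sum to the size of the union.
    """
    if hasattr(named_sets, "items"):
        pairs = list(named_sets.items())
    else:
        pairs = list(named_sets)
    names = [name for name, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names in venn_partition")
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_partition requires between 2 and 4 sets")
    sets = {name: frozenset(s) for name, s in pairs}

    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            counts[frozenset(combo)] = 0
    for element in frozenset().union(*sets.values()):
        pattern = frozenset(name for name in names if element in sets[name])
        counts[pattern] += 1
    return counts


def venn_to_tsv(counts: dict[frozenset[str], int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pattern\tcount\n")
        for pattern in sorted(counts, key=lambda p: (len(p), "&".join(sorted(p)))):
            fh.write(f"{'&'.join(sorted(pattern))}\t{counts[pattern]}\n")


@dataclass
class ConservationTable:
    """Per-reference-gene species membership flags and conservation class."""

    reference_name: str
    table: pd.DataFrame  # bool column per species + int "conservation_class"

    @property
    def species(self) -> list[str]:
        return [c for c in self.table.columns if c != "conservation_class"]

    def class_counts(self) -> dict[int, int]:
        counts = self.table["conservation_class"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in range(len(self.species) + 1)}

    def combination_counts(self) -> dict[frozenset[str], int]:
        """Genes bound in each exact combination of non-reference species."""
        out: dict[frozenset[str], int] = defaultdict(int)
        flags = self.table[self.species]
        for _, row in flags.iterrows():
            out[frozenset(s for s in self.species if row[s])] += 1
        return dict(out)

    def n_conserved(self, min_species: int = 1) -> int:
        return int((self.table["conservation_class"] >= min_species).sum())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    def summary_json(self, path: str | Path) -> None:
        payload = {
            "reference": self.reference_name,
            "n_reference_genes": int(len(self.table)),
            "class_counts": {str(k): v for k, v in self.class_counts().items()},
            "combination_counts": {
                "&".join(sorted(k)) or "(reference only)": v
                for k, v in sorted(
                    self.combination_counts().items(),
                    key=lambda kv: "&".join(sorted(kv[0])),
                )
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def conservation_classes(
    reference_set: set[str] | frozenset[str],
    other_sets: dict[str, set[str] | frozenset[str]],
    reference_name: str = "reference",
) -> ConservationTable:
    """Per-gene conservation classes over already-projected species sets.

    The table is restricted to ``reference_set``; a gene's class is the
    number of non-reference species whose projected bound set contains it.
    """
    genes = sorted(reference_set)
    data = {
        species: [g in frozenset(s) for g in genes]
        for species, s in other_sets.items()
    }
    table = pd.DataFrame(data, index=genes)
    table["conservation_class"] = table.sum(axis=1).astype(int)
    return ConservationTable(reference_name=reference_name, table=table)
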