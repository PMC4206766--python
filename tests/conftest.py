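"""Shared fixtures: a small deterministic fixture bundle and random helpers."""

from __future__ import annotations

import numpy as np
import pytest

from chipnet import (
    BundleParams,
    GeneModel,
    GenomicInterval,
    PeakSet,
    simulate_bundle,
)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One full synthetic bundle shared across tests (seed 11)."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = simulate_bundle(outdir, seed=11, params=BundleParams())
    return outdir, truth


def random_intervals(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    max_pos: int = 5_000,
    max_width: int = 400,
) -> list[GenomicInterval]:
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width + 1))
        out.append(GenomicInterval(chrom, start, start + width, id=f"iv_{i}"))
    return out


def random_peakset(
    rng: np.random.Generator, n: int, factor: str, **kwargs
) -> PeakSet:
    ivs = [
        GenomicInterval(iv.chrom, iv.start, iv.end)
        for iv in random_intervals(rng, n, **kwargs)
    ]
    return PeakSet(factor=factor, genome_build="sim1", intervals=ivs)


def random_genes(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    max_pos: int = 200_000,
) -> list[GeneModel]:
    genes = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(500, 5_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"g{i:03d}",
                chrom=chrom,
                strand=strand,
                span_start=start,
                span_end=start + length,
            )
        )
    return genes
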