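"""Responsive gene sets and binding-response association statistics.

Differential-expression tables (gene, log2 fold change, P) are thresholded
into up/down responsive sets; association between a binding class and
responsiveness is tested with a Pearson chi-square on the 2x2 table
(no continuity correction — the counts here are large and the raw
statistic matches the reported convention). Small term-set enrichment
uses the exact hypergeometric (Fisher) test instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyResult:
    """Chi-square result for a 2x2 association table.

    fold_enrichment is observed/expected for the focal (row 1, col 1)
    cell; odds_ratio is the sample cross-product ratio ad/bc.
    """

    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    fold_enrichment: float
    odds_ratio: float

    def to_dict(self) -> dict:
        return {
            "observed": np.asarray(self.observed).astype(int).tolist(),
            "expected": np.asarray(self.expected).round(4).tolist(),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "fold_enrichment": self.fold_enrichment,
            "odds_ratio": self.odds_ratio,
        }


def chi_square_2x2(observed) -> ContingencyResult:
    """Pearson chi-square (df=1, no Yates correction) on a 2x2 table."""
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero marginal total")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    fold = obs[0, 0] / expected[0, 0]
    denom = obs[0, 1] * obs[1, 0]
    odds = (obs[0, 0] * obs[1, 1]) / denom if denom > 0 else float("inf")
    return ContingencyResult(
        observed=obs.astype(int),
        expected=expected,
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
        fold_enrichment=float(fold),
        odds_ratio=float(odds),
    )


@dataclass
class DETable:
    """A differential-expression table: gene_id, log2fc, pvalue."""

    frame: pd.DataFrame
    provenance: str = ""  # "array" or "rnaseq"

    REQUIRED = ("gene_id", "log2fc", "pvalue")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"DE table missing columns {missing}")
        if self.frame["gene_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids in DE table: {list(dupes[:5])}")
        p = self.frame["pvalue"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path, provenance: str = "") -> DETable:
    frame = pd.read_csv(path, sep="\t")
    return DETable(frame=frame, provenance=provenance)


def responsive_sets(table: DETable, p_threshold: float, direction: str) -> frozenset[str]:
    """Genes with P <= threshold (inclusive) changing in ``direction``.

    direction "up" selects log2fc > 0, "down" log2fc < 0; genes with
    log2fc exactly 0 belong to neither set.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    df = table.frame
    sig = df["pvalue"] <= p_threshold
    fc = df["log2fc"] > 0 if direction == "up" else df["log2fc"] < 0
    return frozenset(df.loc[sig & fc, "gene_id"])


def binding_response_association(
    classes,
    responsive: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    focal_class: str,
) -> ContingencyResult:
    """Chi-square association between one binding class and responsiveness.

    Builds the 2x2 table (in/out focal class) x (responsive / not) over the
    gene universe; the focal cell is focal-and-responsive, so
    fold_enrichment > 1 means the class is enriched for responsive genes.
    """
    labels = classes.labels if hasattr(classes, "labels") else dict(classes)
    universe = frozenset(universe)
    responsive = frozenset(responsive)
    if not responsive <= universe:
        stray = sorted(responsive - universe)[:5]
        raise ValueError(f"responsive genes outside the universe: {stray}")
    if focal_class not in set(labels.values()):
        raise ValueError(f"no gene carries the focal class {focal_class!r}")

    focal = {g for g in universe if labels.get(g) == focal_class}
    a = len(focal & responsive)
    b = len(focal - responsive)
    c = len(responsive - focal)
    d = len(universe) - a - b - c
    return chi_square_2x2([[a, b], [c, d]])


def term_fold_enrichment(
    gene_set: set[str] | frozenset[str],
    term_set: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
) -> tuple[float, float]:
    """Fold enrichment of a term among a gene set, with exact two-sided P.

    fold = (|gene & term| / |gene_set|) / (|term_set| / |universe|);
    P from Fisher's exact test on the induced 2x2 table.
    """
    gene_set, term_set, universe = map(frozenset, (gene_set, term_set, universe))
    if not gene_set or not term_set:
        raise ValueError("gene_set and term_set must be nonempty")
    if not (gene_set <= universe and term_set <= universe):
        raise ValueError("gene_set and term_set must be subsets of the universe")
    k = len(gene_set & term_set)
    fold = (k / len(gene_set)) / (len(term_set) / len(universe))
    table = [
        [k, len(gene_set) - k],
        [len(term_set) - k, len(universe) - len(gene_set) - len(term_set) + k],
    ]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return fold, float(p)


def percent_input(
    ct_target: float, ct_input: float, dilution: float, efficiency: float = 2.0
) -> float:
    """ChIP qPCR percent-of-input from Ct values.

    The input Ct is first adjusted for its dilution factor, then
    percent input = 100 * efficiency**(adjusted input Ct - target Ct).
    """
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ct_input_adj = ct_input - math.log(dilution, efficiency)
    return 100.0 * efficiency ** (ct_input_adj - ct_target)


def qpcr_fold_enrichment(percent_input_chip: float, percent_input_control: float) -> float:
    """Fold enrichment of a ChIP over its IgG control, both as % input."""
    if percent_input_chip <= 0 or percent_input_control <= 0:
        raise ValueError("percent-input values must be positive")
    return percent_input_chip / percent_input_control
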