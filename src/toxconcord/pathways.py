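"""Differential-expression calling, per-pathway summaries and the
overrepresentation statistic.

A gene is differentially expressed (DEG) when |fold regulation| >= 2 and the
replicate t-test gives p < 0.05 (thresholds configurable; the fold bound is
inclusive, the p bound strict).  Pathway summaries report the percentage of
a pathway's genes that are DEG.  Overrepresentation of a DEG list in a gene
set is the right tail of the hypergeometric distribution (Fisher's exact
test one-sided p), the same statistic commercial pathway tools report as the
p-value of overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import AbstractSet, Dict, FrozenSet, Iterable, Mapping

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PathwayCatalog:
    """Named gene sets over a panel background."""

    sets: Dict[str, FrozenSet[str]]
    background: FrozenSet[str]

    def __post_init__(self):
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        self.background = frozenset(self.background)
        for name, genes in self.sets.items():
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"pathway {name!r} contains genes outside the background: {sorted(stray)}"
                )


def call_deg(
    expr: pd.DataFrame, fc_threshold: float = 2.0, alpha: float = 0.05
) -> FrozenSet[str]:
    """Genes with |fold regulation| >= fc_threshold and p < alpha.

    Genes marked ``deg_eligible == False`` (fully censored in both groups)
    never qualify.
    """
    df = expr
    eligible = df["deg_eligible"] if "deg_eligible" in df else pd.Series(True, index=df.index)
    mask = (
        (df["fold_regulation"].abs() >= fc_threshold)
        & (df["p_value"] < alpha)
        & df["p_value"].notna()
        & eligible
    )
    return frozenset(df.loc[mask, "gene"])


def pct_deg(deg: AbstractSet[str], catalog: PathwayCatalog) -> pd.DataFrame:
    """Percentage of DEG per pathway, relative to the pathway's gene count."""
    stray = set(deg) - catalog.background
    if stray:
        logger.warning(
            "pct_deg: %d DEG outside the catalog background ignored (reason=not_on_panel)",
            len(stray),
        )
    deg_in = set(deg) & catalog.background
    rows = []
    for pathway in sorted(catalog.sets):
        genes = catalog.sets[pathway]
        n_deg = len(genes & deg_in)
        rows.append(
            {
                "pathway": pathway,
                "n_genes": len(genes),
                "n_deg": n_deg,
                "pct_deg": 100.0 * n_deg / len(genes) if genes else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "n_genes", "n_deg", "pct_deg"])


def fisher_overlap(
    deg: AbstractSet[str], gene_set: AbstractSet[str], background: AbstractSet[str]
) -> float:
    """Right-tail hypergeometric probability of the observed overlap.

    P(X >= k) where X counts gene-set members in a uniformly random draw of
    |deg| genes from the background.
    """
    deg, gene_set, background = set(deg), set(gene_set), set(background)
    if not deg <= background or not gene_set <= background:
        raise ValueError("deg and gene_set must be subsets of the background")
    k = len(deg & gene_set)
    return float(stats.hypergeom.sf(k - 1, len(background), len(gene_set), len(deg)))
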