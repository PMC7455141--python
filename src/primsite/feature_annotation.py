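"""Genomic feature annotation of integration sites.

Each unique site (the T of its target TA) is assigned to exactly one
category — coding sequence, 5'UTR, 3'UTR, intron, 1 kb upstream of the TSS,
1 kb downstream of the transcript 3' end, or intergenic — evaluated against
every gene whose span (plus flanks) covers the site, with a fixed
precedence so overlapping genes yield a deterministic single call.

Flanks are strand-aware: "upstream" means 5' of the TSS on the gene's own
strand.  The precedence (genic before flank, coding before UTR before
intron) follows common annotation-tool convention and is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .synthetic_data import Gene, GeneModel

logger = logging.getLogger(__name__)

#: categories in default precedence order (highest first); intergenic is
#: the fall-through and always last
DEFAULT_PRECEDENCE: tuple[str, ...] = (
    "cds",
    "utr5",
    "utr3",
    "intron",
    "upstream_1kb",
    "downstream_1kb",
    "intergenic",
)

CATEGORIES = DEFAULT_PRECEDENCE


@dataclass
class CategorySummary:
    """Per-category site counts and percentages over total unique sites."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [self.counts.get(c, 0) for c in CATEGORIES],
                "percentage": [self.percentages.get(c, 0.0) for c in CATEGORIES],
            }
        )


def _gene_category(gene: Gene, position: int, flank: int) -> str | None:
    """This gene's category for the site, or None when out of reach."""
    if gene.start <= position < gene.end:
        for s, e in gene.cds:
            if s <= position < e:
                return "cds"
        for s, e in gene.utr5:
            if s <= position < e:
                return "utr5"
        for s, e in gene.utr3:
            if s <= position < e:
                return "utr3"
        return "intron"
    if gene.strand == "+":
        upstream = (gene.start - flank, gene.start)
        downstream = (gene.end, gene.end + flank)
    else:
        upstream = (gene.end, gene.end + flank)
        downstream = (gene.start - flank, gene.start)
    if upstream[0] <= position < upstream[1]:
        return "upstream_1kb"
    if downstream[0] <= position < downstream[1]:
        return "downstream_1kb"
    return None


class GeneIndex:
    """Interval index over gene spans (padded by the flank) per chromosome."""

    def __init__(self, model: GeneModel, flank: int = 1000):
        self.flank = flank
        self._trees: dict[str, IntervalTree] = {}
        self._warned: set[str] = set()
        for gene in model.genes:
            tree = self._trees.setdefault(gene.chromosome, IntervalTree())
            lo = max(0, gene.start - flank)
            tree.addi(lo, gene.end + flank, gene)

    def classify(
        self, chromosome: str, position: int,
        precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    ) -> str:
        tree = self._trees.get(chromosome)
        if tree is None:
            if chromosome not in self._warned:
                logger.warning(
                    "chromosome %s absent from gene model; classifying intergenic",
                    chromosome,
                )
                self._warned.add(chromosome)
            return "intergenic"
        rank = {c: i for i, c in enumerate(precedence)}
        best = "intergenic"
        for iv in tree.at(position):
            cat = _gene_category(iv.data, position, self.flank)
            if cat is not None and rank[cat] < rank[best]:
                best = cat
        return best


def classify_site(
    chromosome: str,
    position: int,
    model: GeneModel,
    flank: int = 1000,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> str:
    """Category of a single site; see module docstring for the rules."""
    return GeneIndex(model, flank).classify(chromosome, position, precedence)


def classify_sites(
    sites: pd.DataFrame,
    model: GeneModel,
    flank: int = 1000,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.Series:
    """Vector of categories for a site table (chromosome/position columns)."""
    index = GeneIndex(model, flank)
    return pd.Series(
        [
            index.classify(row.chromosome, row.position, precedence)
            for row in sites.itertuples(index=False)
        ],
        index=sites.index,
        name="category",
    )


def summarize_categories(
    sites: pd.DataFrame,
    model: GeneModel,
    flank: int = 1000,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> CategorySummary:
    """Classify every site and tabulate counts and percentages.

    Percentages are over total unique sites (read support is ignored) and
    sum to 100 within floating tolerance.
    """
    if sites is None or sites.empty:
        raise ValueError("category summary is undefined for an empty site table")
    cats = classify_sites(sites, model, flank, precedence)
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    total = int(len(cats))
    percentages = {c: 100.0 * counts[c] / total for c in CATEGORIES}
    return CategorySummary(counts=counts, percentages=percentages, total=total)
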