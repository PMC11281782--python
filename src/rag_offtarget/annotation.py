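"""Breakpoint feature annotation: exon / intron / UTR / promoter / downstream.

Each breakpoint receives a single label, resolved by a fixed precedence so the
six reported categories are mutually exclusive:

    UTR5 == UTR3 > EXON > INTRON > PROMOTER > DOWNSTREAM > INTERGENIC

Ties within a category across genes are broken by nearest TSS, then by
lexicographic gene symbol.  Promoter and downstream windows (default 2 kb
each) are placed strand-aware from the transcript ends and never overlap
their own transcript body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._util import round_half_away
from .io_formats import TranscriptModel

__all__ = [
    "FeatureCategory",
    "FeatureLabel",
    "FeatureIndex",
    "build_feature_index",
    "annotate_breakpoint",
    "feature_distribution",
    "intersect_cancer_genes",
]


class FeatureCategory(str, Enum):
    EXON = "EXON"
    INTRON = "INTRON"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    PROMOTER = "PROMOTER"
    DOWNSTREAM = "DOWNSTREAM"
    INTERGENIC = "INTERGENIC"


# report/category order mirrors the gene-body-then-flanking presentation
CATEGORY_ORDER = [
    FeatureCategory.EXON,
    FeatureCategory.INTRON,
    FeatureCategory.UTR3,
    FeatureCategory.UTR5,
    FeatureCategory.PROMOTER,
    FeatureCategory.DOWNSTREAM,
    FeatureCategory.INTERGENIC,
]

# precedence for single-label resolution (lower rank wins); the two UTRs share
# a rank and cannot overlap each other within one transcript
_PRECEDENCE = {
    FeatureCategory.UTR5: 0,
    FeatureCategory.UTR3: 0,
    FeatureCategory.EXON: 1,
    FeatureCategory.INTRON: 2,
    FeatureCategory.PROMOTER: 3,
    FeatureCategory.DOWNSTREAM: 4,
}


@dataclass
class FeatureLabel:
    category: FeatureCategory
    gene: str | None = None


@dataclass
class FeatureIndex:
    """Interval-indexed gene features; data tuples are (category, gene, tss)."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)
    promoter_bp: int = 2000
    downstream_bp: int = 2000


def build_feature_index(
    models: Sequence[TranscriptModel],
    promoter_bp: int = 2000,
    downstream_bp: int = 2000,
) -> FeatureIndex:
    """Index every exon, intron, UTR, promoter and downstream interval.

    The promoter is ``promoter_bp`` upstream of the TSS (clipped at the contig
    start); the downstream window extends ``downstream_bp`` past the
    transcript end, both placed by strand.
    """
    index = FeatureIndex(promoter_bp=promoter_bp, downstream_bp=downstream_bp)
    for m in models:
        tree = index.trees.setdefault(m.chrom, IntervalTree())
        tss = m.tss
        utr5, utr3 = m.utrs()

        def add(cat: FeatureCategory, ivs: Iterable[tuple[int, int]]) -> None:
            for s, e in ivs:
                s = max(0, s)
                if e > s:
                    tree.addi(s, e, (cat, m.gene, tss))

        add(FeatureCategory.EXON, m.exons)
        add(FeatureCategory.INTRON, m.introns)
        add(FeatureCategory.UTR5, utr5)
        add(FeatureCategory.UTR3, utr3)
        if m.strand == "+":
            add(FeatureCategory.PROMOTER, [(m.start - promoter_bp, m.start)])
            add(FeatureCategory.DOWNSTREAM, [(m.end, m.end + downstream_bp)])
        else:
            add(FeatureCategory.PROMOTER, [(m.end, m.end + promoter_bp)])
            add(FeatureCategory.DOWNSTREAM, [(m.start - downstream_bp, m.start)])
    return index


def annotate_breakpoint(bp: tuple[str, int], index: FeatureIndex) -> FeatureLabel:
    """Label one breakpoint by the documented precedence (pure function)."""
    chrom, pos = bp
    tree = index.trees.get(chrom)
    if tree is None:
        return FeatureLabel(FeatureCategory.INTERGENIC, None)
    overlaps = tree[pos]
    if not overlaps:
        return FeatureLabel(FeatureCategory.INTERGENIC, None)
    best = min(
        (iv.data for iv in overlaps),
        key=lambda d: (_PRECEDENCE[d[0]], abs(pos - d[2]), d[1]),
    )
    return FeatureLabel(best[0], best[1])


def feature_distribution(labels: Sequence[FeatureLabel]) -> pd.DataFrame:
    """Counts and one-decimal percentages per category.

    Percentage = 100 * count / total, rounded half away from zero; an empty
    input yields an empty table (no division).  Categories with zero count are
    omitted, matching the style of published category breakdowns.
    """
    if not labels:
        return pd.DataFrame(columns=["category", "count", "percent"])
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    for lab in labels:
        counts[lab.category] += 1
    total = len(labels)
    rows = [
        {
            "category": cat.value,
            "count": n,
            "percent": round_half_away(100.0 * n / total, 1),
        }
        for cat, n in counts.items()
        if n > 0
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def intersect_cancer_genes(
    per_sample_genes: Mapping[str, set[str]],
    census: set[str],
    genotypes: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample gene / cancer-gene counts and per-genotype means.

    ``census`` is a set of Cancer Gene Census symbols; a hit is simple set
    intersection.  Genotype means are arithmetic means over that genotype's
    samples, one decimal.
    """
    if not census:
        raise ValueError("census gene set is empty")
    rows = []
    for sample in sorted(per_sample_genes):
        genes = per_sample_genes[sample]
        rows.append(
            {
                "sample": sample,
                "n_genes": len(genes),
                "n_cancer_genes": len(genes & census),
                "genotype": (genotypes or {}).get(sample, ""),
            }
        )
    per_sample = pd.DataFrame(
        rows, columns=["sample", "genotype", "n_genes", "n_cancer_genes"]
    )
    if genotypes:
        means = (
            per_sample.groupby("genotype")[["n_genes", "n_cancer_genes"]]
            .mean()
            .reset_index()
        )
        for col in ("n_genes", "n_cancer_genes"):
            means[col] = means[col].map(lambda v: round_half_away(v, 1))
        means = means.rename(
            columns={"n_genes": "mean_genes", "n_cancer_genes": "mean_cancer_genes"}
        )
    else:
        means = pd.DataFrame(columns=["genotype", "mean_genes", "mean_cancer_genes"])
    return per_sample, means


def read_census(path: str) -> set[str]:
    """Read a Cancer Gene Census-style TSV (``Gene Symbol`` column)."""
    df = pd.read_csv(path, sep="\t")
    col = "Gene Symbol" if "Gene Symbol" in df.columns else df.columns[0]
    return set(df[col].astype(str))
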