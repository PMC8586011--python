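"""Gene-feature assignment, coding-impact and repeat classification, and
per-category feature enrichment.

Coding impact (pLoF = predicted loss of function):

* DEL — overlaps at least one CDS interval;
* INS — inserted strictly inside a CDS interval;
* DUP / INV — partially overlap at least one CDS; a DUP/INV containing an
  entire gene span is instead a whole-gene duplication (WDUP) or inversion
  (WINV) for that gene, which is not counted as gene-disruptive.

A single DUP/INV can be WDUP/WINV for one gene and pLoF for another; both
gene lists are recorded and the ``impact`` label takes pLoF whenever any
gene is partially hit.

Gene features follow the precedence CDS > UTR > promoter > intron >
intergenic, with breakpoint-based conditions for UTR/promoter (at least
one of the two interval endpoints falls inside the region) and a
same-gene-span condition for intron.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import Interval, IntervalTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .model import GeneModel, SVCall


@dataclass(slots=True)
class AnnotationRecord:
    sv_id: str
    feature: str
    impact: str  # pLoF | WDUP | WINV | none
    plof_genes: tuple[str, ...]
    whole_genes: tuple[str, ...]
    repeat_class: str = "none"

    @property
    def genes_hit(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys((*self.plof_genes, *self.whole_genes)))


class GeneIndex:
    """Per-chromosome interval indexes over gene spans, CDS, UTRs and
    promoters, for fast SV annotation."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self.span: dict[str, IntervalTree] = {}
        self.cds: dict[str, IntervalTree] = {}
        self.utr: dict[str, IntervalTree] = {}
        self.promoter: dict[str, IntervalTree] = {}
        for g in genes:
            self.span.setdefault(g.chrom, IntervalTree()).add(
                Interval(g.start, g.end, g.gene_id)
            )
            for s, e in g.cds:
                self.cds.setdefault(g.chrom, IntervalTree()).add(
                    Interval(s, e, g.gene_id)
                )
            for s, e in (*g.utr5, *g.utr3):
                self.utr.setdefault(g.chrom, IntervalTree()).add(
                    Interval(s, e, g.gene_id)
                )
            ps, pe = g.promoter
            if pe > ps:
                self.promoter.setdefault(g.chrom, IntervalTree()).add(
                    Interval(ps, pe, g.gene_id)
                )

    @staticmethod
    def _hits(trees: dict[str, IntervalTree], chrom: str,
              start: int, end: int) -> set[str]:
        tree = trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    @staticmethod
    def _point_hits(trees: dict[str, IntervalTree], chrom: str, pos: int) -> set[str]:
        tree = trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}


def classify_coding_impact(
    sv: SVCall, index: GeneIndex
) -> tuple[str, tuple[str, ...], tuple[str, ...]]:
    """Return (impact, partially-hit genes, whole-gene DUP/INV genes)."""
    plof: set[str] = set()
    whole: set[str] = set()
    if sv.sv_type == "INS":
        # insertion point strictly inside a CDS (boundary positions do not
        # interrupt the reading frame)
        tree = index.cds.get(sv.chrom)
        if tree is not None:
            for iv in tree.at(sv.start):
                if iv.begin < sv.start < iv.end:
                    plof.add(iv.data)
    else:
        cds_genes = index._hits(index.cds, sv.chrom, sv.start, sv.end)
        if sv.sv_type == "DEL":
            plof = cds_genes
        else:  # DUP / INV
            for gid in index._hits(index.span, sv.chrom, sv.start, sv.end):
                g = index.genes[gid]
                if sv.start <= g.start and sv.end >= g.end:
                    whole.add(gid)
            plof = cds_genes - whole

    if plof:
        impact = "pLoF"
    elif whole:
        impact = "WDUP" if sv.sv_type == "DUP" else "WINV"
    else:
        impact = "none"
    return impact, tuple(sorted(plof)), tuple(sorted(whole))


def assign_gene_feature(sv: SVCall, index: GeneIndex) -> str:
    """Single gene-feature label with precedence CDS > UTR > promoter >
    intron > intergenic."""
    if index._hits(index.cds, sv.chrom, sv.start, sv.end):
        return "CDS"
    breakpoints = (sv.start, sv.end)
    if any(index._point_hits(index.utr, sv.chrom, bp) for bp in breakpoints):
        return "UTR"
    if any(index._point_hits(index.promoter, sv.chrom, bp) for bp in breakpoints):
        return "promoter"
    # intron: both breakpoints inside the same gene span
    genes_start = index._point_hits(index.span, sv.chrom, sv.start)
    genes_end = index._point_hits(index.span, sv.chrom, sv.end)
    if genes_start & genes_end:
        return "intron"
    return "intergenic"


def annotate_sv(sv: SVCall, index: GeneIndex, sv_id: str = "") -> AnnotationRecord:
    impact, plof_genes, whole_genes = classify_coding_impact(sv, index)
    feature = assign_gene_feature(sv, index)
    return AnnotationRecord(
        sv_id=sv_id,
        feature=feature,
        impact=impact,
        plof_genes=plof_genes,
        whole_genes=whole_genes,
    )


def classify_repeat(
    sv: SVCall,
    repeat_intervals: Sequence[tuple[int, int, str, int | None]],
) -> str:
    """Repeat class of an SV given precomputed repeat annotations on its
    chromosome, as (start, end, family, unit_len-or-None) tuples.

    The family whose union of annotated bases covers more than half of the
    SV length wins; a winning tandem-repeat annotation with repeat unit
    >= 7 bp is a VNTR.  Overlapping annotations of one family are union-ed
    before coverage is computed.
    """
    by_family: dict[str, list[tuple[int, int]]] = {}
    tandem_units: dict[str, int] = {}
    for start, end, family, unit_len in repeat_intervals:
        s, e = max(start, sv.start), min(end, sv.end)
        if e <= s:
            continue
        by_family.setdefault(family, []).append((s, e))
        if unit_len is not None:
            tandem_units[family] = max(tandem_units.get(family, 0), unit_len)

    best_family, best_cov = None, 0
    for family, ivs in by_family.items():
        ivs.sort()
        cov, reach = 0, -1
        for s, e in ivs:
            s = max(s, reach)
            if e > s:
                cov += e - s
                reach = e
            reach = max(reach, e)
        if cov > best_cov:
            best_family, best_cov = family, cov

    if best_family is None or best_cov * 2 <= sv.svlen:
        return "none"
    if tandem_units.get(best_family, 0) >= 7:
        return "VNTR"
    return f"family:{best_family}"


def feature_enrichment(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-(category, feature) enrichment against the whole population.

    ``counts`` is a categories x features table of SV counts.  For each
    cell a 2x2 table [in-category & in-feature, in-category & not;
    not-category & in-feature, not-category & not] is tested with a
    two-sided Fisher exact test; q-values are Benjamini-Hochberg across
    all tested cells.  Cells with a zero margin are reported with NaN.
    """
    total = counts.values.sum()
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    rows = []
    for cat in counts.index:
        for feat in counts.columns:
            a = int(counts.loc[cat, feat])
            b = int(row_sums[cat]) - a
            c = int(col_sums[feat]) - a
            d = int(total) - a - b - c
            if row_sums[cat] == 0 or col_sums[feat] == 0 or \
                    row_sums[cat] == total or col_sums[feat] == total:
                rows.append((cat, feat, np.nan, np.nan))
                continue
            odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append((cat, feat, odds, p))
    df = pd.DataFrame(rows, columns=["category", "feature", "odds_ratio", "p"])
    tested = df["p"].notna()
    df["q"] = np.nan
    if tested.any():
        df.loc[tested, "q"] = multipletests(
            df.loc[tested, "p"].values, method="fdr_bh"
        )[1]
    return df
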