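"""Gene-level allele-specific expression from per-site allele counts.

The quantification funnel mirrors the study design it implements:

1. *Site selection*: keep polymorphic sites covered at least twice from both
   the 129 and the Cast allele, pooled over all samples of the run (one
   global site list).
2. *Aggregation*: per gene and sample, sum the 129 and Cast counts over the
   sites falling in the gene's exons.  Sites shared by exons of overlapping
   genes count for each such gene.
3. *Time-course gene filters*: a gene is quantified for the differentiation
   course iff (a) its course-summed counts exceed 80 from both alleles
   (strict, configurable), (b) its per-site allelic ratios are consistent
   (standard error of the mean <= 0.1 over qualifying sites; genes with a
   single qualifying site pass), and (c) its mean expression over the course
   exceeds 0.5 RPKM.

The relative 129 contribution of a gene is count_129 / (count_129 +
count_cast); multiplied by the total RPKM it gives absolute allelic
expression levels.  A gene with zero total allelic counts has an undefined
ratio, propagated as missing — never as 0 or 0.5.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel

__all__ = [
    "filter_sites",
    "map_sites_to_genes",
    "aggregate_gene_allelic",
    "rpkm",
    "timecourse_gene_filter",
    "consistency_filter",
    "mean_expression_filter",
    "absolute_allelic_rpkm",
    "quantify_timecourse",
]

MIN_SITE_COVERAGE = 2          # "covered at least twice from both" (inclusive)
COURSE_COUNT_CUTOFF = 80       # "> 80 over the complete time course" (strict)
QUALIFYING_SITE_COUNT = 9      # "more than nine counts ... from either allele"
STDEM_CUTOFF = 0.1
MEAN_RPKM_CUTOFF = 0.5


def filter_sites(counts: pd.DataFrame,
                 min_coverage: int = MIN_SITE_COVERAGE) -> pd.DataFrame:
    """Keep sites whose counts pooled across all samples reach the minimum
    from both alleles (boundary inclusive)."""
    pooled = counts.groupby(["chrom", "pos"])[["count_129", "count_cast"]].sum()
    ok = pooled[(pooled["count_129"] >= min_coverage)
                & (pooled["count_cast"] >= min_coverage)].index
    keep = counts.set_index(["chrom", "pos"]).index.isin(ok)
    return counts.loc[keep].reset_index(drop=True)


def _exon_trees(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e, g.gene_id)
    return trees


def map_sites_to_genes(sites: pd.DataFrame,
                       genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Annotate site rows with the gene(s) whose exons contain them.

    Rows are duplicated when a site falls in exons of several overlapping
    genes; intronic/intergenic sites are dropped.  1-based site positions
    are matched against 0-based half-open exons.
    """
    trees = _exon_trees(genes)
    out = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for row in grp.itertuples(index=False):
            for iv in tree.at(row.pos - 1):
                d = row._asdict()
                d["gene"] = iv.data
                out.append(d)
    if not out:
        return sites.iloc[0:0].assign(gene=pd.Series(dtype=str))
    return pd.DataFrame(out)


def aggregate_gene_allelic(sites: pd.DataFrame, genes: Sequence[GeneModel],
                           samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene, per-sample allelic counts summed over exonic sites.

    Returns one row per (gene, sample) for every gene in ``genes`` and every
    sample seen (or listed), with ``count_129, count_cast, n_sites, rel_129``;
    genes without exonic sites carry zero counts and a missing ratio.
    """
    mapped = map_sites_to_genes(sites, genes)
    if samples is None:
        samples = sorted(sites["sample"].unique())
    index = pd.MultiIndex.from_product(
        [[g.gene_id for g in genes], list(samples)], names=["gene", "sample"])
    if mapped.empty:
        agg = pd.DataFrame(0, index=index,
                           columns=["count_129", "count_cast", "n_sites"])
    else:
        grouped = mapped.groupby(["gene", "sample"]).agg(
            count_129=("count_129", "sum"),
            count_cast=("count_cast", "sum"),
            n_sites=("pos", "nunique"),
        )
        agg = grouped.reindex(index, fill_value=0)
    agg = agg.reset_index()
    total = agg["count_129"] + agg["count_cast"]
    agg["rel_129"] = np.where(total > 0, agg["count_129"] / total.where(total > 0, 1),
                              np.nan)
    return agg


def rpkm(count_total: float, exon_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of exon per million mapped reads."""
    if exon_length_bp <= 0 or library_size <= 0:
        raise ValueError("exon length and library size must be positive")
    return 1e9 * count_total / (exon_length_bp * library_size)


def timecourse_gene_filter(gene_table: pd.DataFrame,
                           cutoff: int = COURSE_COUNT_CUTOFF,
                           strict: bool = True) -> pd.DataFrame:
    """Course-coverage filter: both alleles must exceed ``cutoff`` counts
    summed over all time points (strict ``>`` by default)."""
    sums = gene_table.groupby("gene")[["count_129", "count_cast"]].sum()
    if strict:
        ok = (sums["count_129"] > cutoff) & (sums["count_cast"] > cutoff)
    else:
        ok = (sums["count_129"] >= cutoff) & (sums["count_cast"] >= cutoff)
    return pd.DataFrame({
        "gene": sums.index,
        "course_count_129": sums["count_129"].to_numpy(),
        "course_count_cast": sums["count_cast"].to_numpy(),
        "pass_count": ok.to_numpy(),
    })


def consistency_filter(sites: pd.DataFrame, genes: Sequence[GeneModel],
                       qualifying_count: int = QUALIFYING_SITE_COUNT,
                       stdem_cutoff: float = STDEM_CUTOFF) -> pd.DataFrame:
    """Per-site allelic-ratio consistency over the pooled time course.

    Qualifying sites have a course-summed count above ``qualifying_count``
    from either allele.  For genes with >= 2 qualifying sites the standard
    error of the mean (sample SD / sqrt(n)) of the per-site 129 ratios must
    not exceed ``stdem_cutoff``; single-site genes pass.
    """
    mapped = map_sites_to_genes(sites, genes)
    rows = []
    if not mapped.empty:
        per_site = mapped.groupby(["gene", "chrom", "pos"])[
            ["count_129", "count_cast"]].sum().reset_index()
        per_site = per_site[
            (per_site["count_129"] > qualifying_count)
            | (per_site["count_cast"] > qualifying_count)]
        per_site["ratio"] = per_site["count_129"] / (
            per_site["count_129"] + per_site["count_cast"])
        for gene, grp in per_site.groupby("gene"):
            n = len(grp)
            if n >= 2:
                stdem = float(grp["ratio"].std(ddof=1) / np.sqrt(n))
                ok = stdem <= stdem_cutoff
            else:
                stdem, ok = np.nan, True
            rows.append({"gene": gene, "n_qualifying_sites": n,
                         "stdem": stdem, "pass_consistency": ok})
    report = pd.DataFrame(rows, columns=["gene", "n_qualifying_sites",
                                         "stdem", "pass_consistency"])
    # genes with no qualifying site at all: nothing to test, they pass here
    missing = [g.gene_id for g in genes if g.gene_id not in set(report["gene"])]
    if missing:
        report = pd.concat([report, pd.DataFrame({
            "gene": missing, "n_qualifying_sites": 0,
            "stdem": np.nan, "pass_consistency": True})], ignore_index=True)
    return report


def mean_expression_filter(expression: pd.DataFrame,
                           samples: Sequence[str] | None = None,
                           cutoff: float = MEAN_RPKM_CUTOFF) -> pd.DataFrame:
    """Mean-RPKM filter over the course (strict ``>``)."""
    cols = list(samples) if samples is not None else list(expression.columns)
    mean = expression[cols].mean(axis=1)
    return pd.DataFrame({"gene": expression.index, "mean_rpkm": mean.to_numpy(),
                         "pass_expression": (mean > cutoff).to_numpy()})


def absolute_allelic_rpkm(rel_129: float, rpkm_total: float) -> tuple[float, float]:
    """Split a gene's total RPKM into absolute allelic levels."""
    if np.isnan(rel_129):
        return float("nan"), float("nan")
    return rel_129 * rpkm_total, (1.0 - rel_129) * rpkm_total


def quantify_timecourse(counts: pd.DataFrame, genes: Sequence[GeneModel],
                        expression: pd.DataFrame,
                        samples: Sequence[str] | None = None,
                        strict_count_filter: bool = True
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full quantification funnel for a differentiation course.

    Returns ``(records, report)``: per-(gene, sample) allelic records with
    absolute allelic RPKM for quantified genes, and the per-gene filter
    report with the triggering statistic of every filter.
    """
    if samples is None:
        samples = sorted(counts["sample"].unique())
    sites = filter_sites(counts)
    records = aggregate_gene_allelic(sites, genes, samples)

    count_rep = timecourse_gene_filter(records, strict=strict_count_filter)
    cons_rep = consistency_filter(sites, genes)
    expr_rep = mean_expression_filter(expression, samples)

    report = count_rep.merge(cons_rep, on="gene").merge(expr_rep, on="gene", how="left")
    report["pass_expression"] = report["pass_expression"].fillna(False)
    report["mean_rpkm"] = report["mean_rpkm"].astype(float)
    report["quantified"] = (report["pass_count"] & report["pass_consistency"]
                            & report["pass_expression"])

    records = records.merge(report[["gene", "quantified"]], on="gene")
    expr_long = expression.reindex([g.gene_id for g in genes])[list(samples)]
    rpkm_map = expr_long.stack(future_stack=True)
    key = pd.MultiIndex.from_frame(records[["gene", "sample"]])
    records["rpkm_total"] = rpkm_map.reindex(key).to_numpy()
    records["rpkm_129"] = records["rel_129"] * records["rpkm_total"]
    records["rpkm_cast"] = (1.0 - records["rel_129"]) * records["rpkm_total"]
    return records, report
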