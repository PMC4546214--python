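"""Escape from XCI in stably inactivated lines, and allelic-bias calls.

A gene escapes XCI in a line when (i) at least two polymorphic sites show
signal from the inactive X, (ii) more than two counts originate from the Xi
in total, and (iii) the Xi is expressed at more than 10 % of the Xa level —
the ratio cutoff, log2(Xi/Xa) > -3.32.  Note the operational form of
criterion (iii): the published classification thresholds the Xi/Xa *ratio*
at 0.10 (a gene at log2 = -3.2 escapes), which is what this module
implements; on the fraction-of-total scale that corresponds to Xi/(Xi+Xa) >
1/11.

Escape regions are maximal runs of three or more consecutive escaping genes
along the chromosome with no informative subject gene in between; genes
without allelic information are transparent to the run.

Allelic-bias (imprinting-style) calls in undifferentiated cells require at
least two per-site binomial tests significant at p < 0.01, at least 80 % of
them biased toward the same allele, and a gene-level contribution of that
allele above 75 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import binomial_two_sided

__all__ = [
    "EscapeCall",
    "EscapeRegion",
    "BiasCall",
    "XI_RATIO_CUTOFF",
    "LOG2_ESCAPE_CUTOFF",
    "call_escape",
    "call_escape_table",
    "escape_from_log2",
    "detect_escape_regions",
    "compare_escape_sets",
    "call_allelic_bias",
    "cluster_escape_crosstab",
]

XI_RATIO_CUTOFF = 0.10          # Xi/Xa > 10 %, strict
LOG2_ESCAPE_CUTOFF = math.log2(XI_RATIO_CUTOFF)   # -3.32
MIN_XI_SITES = 2                # criterion i
MIN_XI_COUNTS = 3               # criterion ii: "more than two"
MIN_XI_SITE_SIGNAL = 1          # a site "shows signal" with >= 1 Xi count
BIAS_P_CUTOFF = 0.01
BIAS_CONCORDANCE = 0.80
BIAS_CONTRIBUTION = 0.75
NEAR_THRESHOLD_BAND = (0.08, 0.12)


@dataclass(frozen=True)
class EscapeCall:
    gene: str
    line: str
    n_sites_with_xi_signal: int
    xi_count_total: int
    xa_count_total: int
    xi_ratio: float              # Xi / Xa
    xi_fraction: float           # Xi / (Xi + Xa)
    xi_xa_log2: float
    crit_sites: bool
    crit_counts: bool
    crit_ratio: bool

    @property
    def is_escape(self) -> bool:
        return self.crit_sites and self.crit_counts and self.crit_ratio

    @property
    def informative(self) -> bool:
        return self.xi_count_total + self.xa_count_total > 0


@dataclass(frozen=True)
class EscapeRegion:
    chrom: str
    start: int
    end: int
    line: str
    genes: tuple

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class BiasCall:
    gene: str
    n_tested_sites: int
    n_significant_sites: int
    direction: str               # "129", "cast" or ""
    fraction_concordant: float
    total_contribution: float
    is_biased: bool


def call_escape(gene_sites: pd.DataFrame, gene: str, line: str,
                xi_allele: str = "129",
                min_site_signal: int = MIN_XI_SITE_SIGNAL) -> EscapeCall:
    """Three-criteria escape decision from one gene's per-site counts."""
    xi_col = "count_129" if xi_allele == "129" else "count_cast"
    xa_col = "count_cast" if xi_allele == "129" else "count_129"
    xi = int(gene_sites[xi_col].sum()) if len(gene_sites) else 0
    xa = int(gene_sites[xa_col].sum()) if len(gene_sites) else 0
    n_signal = int((gene_sites[xi_col] >= min_site_signal).sum()) if len(gene_sites) else 0
    ratio = xi / xa if xa > 0 else (math.inf if xi > 0 else float("nan"))
    frac = xi / (xi + xa) if xi + xa > 0 else float("nan")
    log2r = (math.log2(ratio) if 0 < ratio < math.inf
             else (math.inf if ratio == math.inf else float("nan")))
    return EscapeCall(
        gene=gene, line=line,
        n_sites_with_xi_signal=n_signal,
        xi_count_total=xi, xa_count_total=xa,
        xi_ratio=ratio, xi_fraction=frac, xi_xa_log2=log2r,
        crit_sites=n_signal >= MIN_XI_SITES,
        crit_counts=xi >= MIN_XI_COUNTS,
        crit_ratio=(not math.isnan(ratio)) and ratio > XI_RATIO_CUTOFF,
    )


def call_escape_table(mapped_sites: pd.DataFrame, genes, line: str,
                      xi_allele: str = "129") -> pd.DataFrame:
    """Escape calls for every gene, ordered along the chromosome.

    ``mapped_sites`` carries per-site counts annotated with ``gene`` (see
    :func:`xcidyn.quantify.map_sites_to_genes`); genes without any counts
    come out uninformative.
    """
    by_gene = dict(iter(mapped_sites.groupby("gene"))) if len(mapped_sites) else {}
    empty = mapped_sites.iloc[0:0]
    rows = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        call = call_escape(by_gene.get(g.gene_id, empty), g.gene_id, line, xi_allele)
        rows.append({
            "gene": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
            "line": line, "n_sites_with_xi_signal": call.n_sites_with_xi_signal,
            "xi_count_total": call.xi_count_total,
            "xa_count_total": call.xa_count_total,
            "xi_ratio": call.xi_ratio, "xi_fraction": call.xi_fraction,
            "xi_xa_log2": call.xi_xa_log2,
            "crit_sites": call.crit_sites, "crit_counts": call.crit_counts,
            "crit_ratio": call.crit_ratio,
            "is_escape": call.is_escape, "informative": call.informative,
        })
    return pd.DataFrame(rows)


def escape_from_log2(xi_xa_log2: float) -> bool:
    """Ratio-test classification of a printed log2(Xi/Xa) value."""
    return bool(xi_xa_log2 > LOG2_ESCAPE_CUTOFF)


def detect_escape_regions(calls: pd.DataFrame, min_genes: int = 3) -> list[EscapeRegion]:
    """Maximal runs of >= ``min_genes`` consecutive informative escapers.

    ``calls`` must be sorted by gene start along one chromosome (the output
    of :func:`call_escape_table`).  Uninformative genes do not break a run.
    """
    regions: list[EscapeRegion] = []
    run: list[pd.Series] = []

    def flush():
        nonlocal run
        if len(run) >= min_genes:
            regions.append(EscapeRegion(
                chrom=run[0]["chrom"], start=int(run[0]["start"]),
                end=int(max(r["end"] for r in run)), line=run[0]["line"],
                genes=tuple(r["gene"] for r in run)))
        run = []

    for _, row in calls.iterrows():
        if not row["informative"]:
            continue
        if row["is_escape"]:
            run.append(row)
        else:
            flush()
    flush()
    return regions


def compare_escape_sets(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Overlap of two escape call sets on the same gene universe.

    Reports the intersection and Jaccard index over escape genes, plus the
    discordant genes with both Xi ratios and a near-threshold flag for genes
    hovering around the 10 % cutoff.
    """
    a = calls_a.set_index("gene")
    b = calls_b.set_index("gene")
    if set(a.index) != set(b.index):
        raise ValueError("call sets must share the same gene universe")
    esc_a = set(a.index[a["is_escape"]])
    esc_b = set(b.index[b["is_escape"]])
    union = esc_a | esc_b
    inter = esc_a & esc_b
    discordant = []
    for gene in sorted(union - inter):
        ra, rb = a.loc[gene, "xi_ratio"], b.loc[gene, "xi_ratio"]
        lo, hi = NEAR_THRESHOLD_BAND
        near = any(lo <= r <= hi for r in (ra, rb) if not math.isnan(r))
        discordant.append({"gene": gene, "xi_ratio_a": ra, "xi_ratio_b": rb,
                           "escape_a": gene in esc_a, "escape_b": gene in esc_b,
                           "near_threshold": near})
    return {
        "n_escape_a": len(esc_a), "n_escape_b": len(esc_b),
        "intersection": sorted(inter),
        "jaccard": len(inter) / len(union) if union else float("nan"),
        "discordant": pd.DataFrame(
            discordant, columns=["gene", "xi_ratio_a", "xi_ratio_b",
                                 "escape_a", "escape_b", "near_threshold"]),
    }


def call_allelic_bias(gene_sites: pd.DataFrame, gene: str,
                      concordance_over_significant: bool = True) -> BiasCall:
    """Allelic-bias call for one gene in an undifferentiated sample.

    Each covered site gets an exact two-sided binomial test against 0.5;
    sites with p < 0.01 are biased toward their majority allele.  By default
    the 80 % concordance is computed over the significant sites (switchable
    to all tested sites).
    """
    tested = gene_sites[(gene_sites["count_129"] + gene_sites["count_cast"]) > 0]
    n_tested = len(tested)
    directions = []
    for row in tested.itertuples(index=False):
        n = row.count_129 + row.count_cast
        p = binomial_two_sided(int(row.count_129), int(n), 0.5)
        if p < BIAS_P_CUTOFF:
            directions.append("129" if row.count_129 > row.count_cast else "cast")
    n_sig = len(directions)
    denom = n_sig if concordance_over_significant else n_tested
    if denom > 0 and n_sig > 0:
        n129 = directions.count("129")
        top, frac = (("129", n129 / denom) if n129 >= n_sig - n129
                     else ("cast", (n_sig - n129) / denom))
    else:
        top, frac = "", 0.0
    tot129 = tested["count_129"].sum()
    tot = tested[["count_129", "count_cast"]].to_numpy().sum()
    contribution = float(max(tot129, tot - tot129) / tot) if tot > 0 else float("nan")
    contrib_dir = ("129" if tot129 * 2 >= tot else "cast") if tot > 0 else ""
    is_biased = (n_sig >= 2 and frac >= BIAS_CONCORDANCE
                 and contribution > BIAS_CONTRIBUTION and top == contrib_dir)
    return BiasCall(gene=gene, n_tested_sites=n_tested, n_significant_sites=n_sig,
                    direction=top if is_biased else top,
                    fraction_concordant=frac, total_contribution=contribution,
                    is_biased=is_biased)


def cluster_escape_crosstab(clustering, escape_calls: pd.DataFrame) -> pd.DataFrame:
    """Escape/subject counts per kinetic cluster, on the shared universe."""
    assign = clustering.assignments.set_index("gene")["label"]
    calls = escape_calls.set_index("gene")
    shared = [g for g in assign.index if g in calls.index]
    rows = []
    for label in clustering.cluster_means.index:
        genes = [g for g in shared if assign[g] == label]
        n_esc = int(calls.loc[genes, "is_escape"].sum()) if genes else 0
        rows.append({"cluster": label, "n_genes": len(genes), "n_escape": n_esc,
                     "n_subject": len(genes) - n_esc,
                     "escape_fraction": n_esc / len(genes) if genes else np.nan})
    return pd.DataFrame(rows)
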