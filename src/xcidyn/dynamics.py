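"""Silencing kinetics on the inactive X during differentiation.

For every quantified gene the Xi/Xa expression ratio (log2) is followed over
the differentiation course and expressed as delta values relative to the
undifferentiated state (T = 0), so delta(0) = 0 and negative deltas mean
silencing of the Xi.  Genes are stratified into four kinetic groups (early /
intermediate / late / not silenced) by Euclidean K-means on their delta
trajectories, and each group is tested for positional enrichment towards the
X-inactivation center (XIC) with an unweighted GSEA running-sum rank test
against a label-permutation null, BH-corrected across groups.

Cluster labels are assigned deterministically: the cluster whose day-8 mean
delta stays above -0.5 (the Xi retains most of its initial relative
expression) is "not_silenced"; the remaining clusters are ranked by their
day-2 mean delta, most negative first: early, intermediate, late.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import GeneModel
from .stats import bh_fdr, notch_compare

__all__ = [
    "KineticClustering",
    "CLUSTER_LABELS",
    "xi_xa_log2",
    "compute_trajectories",
    "kmeans_trajectories",
    "distance_to_xic",
    "gsea_enrichment_score",
    "gsea_distance_test",
    "day2_trend",
    "strata_compare",
    "x_autosome_ratio",
    "xa_upregulation_test",
    "mean_silencing",
]

CLUSTER_LABELS = ("early", "intermediate", "late", "not_silenced")
LOG_RATIO_CAP = 10.0
NOT_SILENCED_DELTA = -0.5
DEFAULT_XIC_POS = 100_700_000  # Xist locus on the reference X


def xi_xa_log2(count_xi: float, count_xa: float,
               cap: float = LOG_RATIO_CAP) -> tuple[float, bool]:
    """log2(Xi/Xa) for one gene at one time point.

    Zero counts on one allele floor/cap the value at ``±cap`` (flagged);
    zero on both alleles yields NaN.
    """
    if count_xi == 0 and count_xa == 0:
        return float("nan"), False
    if count_xa == 0:
        return cap, True
    if count_xi == 0:
        return -cap, True
    return float(np.log2(count_xi / count_xa)), False


@dataclass
class KineticClustering:
    """K-means result with deterministic biological labels."""

    k: int
    assignments: pd.DataFrame      # gene, cluster, label
    cluster_means: pd.DataFrame    # label x timepoint mean deltas

    def genes_in(self, label: str) -> list[str]:
        a = self.assignments
        return a.loc[a["label"] == label, "gene"].tolist()


def compute_trajectories(records: pd.DataFrame, genes: list[GeneModel],
                         timepoints, sample_of, xi_allele: str = "129",
                         xic_pos: int | None = None,
                         x_chrom: str = "chrX") -> pd.DataFrame:
    """Per-gene log2(Xi/Xa) trajectories and deltas relative to T = 0.

    ``records`` is the quantified per-(gene, sample) allelic table;
    ``sample_of`` maps a time point to its sample id.  Only quantified genes
    on ``x_chrom`` with complete trajectories are returned.  Columns:
    ``log2_t<T>``, ``delta_t<T>``, ``mean_rpkm``, ``dist_xic``, ``capped``.
    """
    gmap = {g.gene_id: g for g in genes}
    quantified = records[records.get("quantified", True) == True]  # noqa: E712
    wide_129 = quantified.pivot(index="gene", columns="sample", values="count_129")
    wide_cast = quantified.pivot(index="gene", columns="sample", values="count_cast")
    rpkm = quantified.pivot(index="gene", columns="sample", values="rpkm_total")

    rows = []
    for gene in wide_129.index:
        g = gmap.get(gene)
        if g is None or g.chrom != x_chrom:
            continue
        logs, capped = {}, False
        for t in timepoints:
            s = sample_of[t]
            xi = wide_129.loc[gene, s] if xi_allele == "129" else wide_cast.loc[gene, s]
            xa = wide_cast.loc[gene, s] if xi_allele == "129" else wide_129.loc[gene, s]
            val, flag = xi_xa_log2(xi, xa)
            logs[t] = val
            capped = capped or flag
        if any(math.isnan(v) for v in logs.values()):
            continue
        row = {"gene": gene, "capped": capped,
               "mean_rpkm": float(np.nanmean(
                   [rpkm.loc[gene, sample_of[t]] for t in timepoints]))}
        t0 = timepoints[0]
        for t in timepoints:
            row[f"log2_t{t}"] = logs[t]
            row[f"delta_t{t}"] = logs[t] - logs[t0]
        if xic_pos is not None:
            row["dist_xic"] = distance_to_xic(g, xic_pos, x_chrom)
            row["position"] = g.midpoint
        rows.append(row)
    return pd.DataFrame(rows)


def kmeans_trajectories(trajectories: pd.DataFrame, timepoints, k: int = 4,
                        n_init: int = 10, seed: int = 0,
                        positive_cap: float = 1.0) -> KineticClustering:
    """Cluster delta trajectories with Euclidean K-means and label clusters.

    Positive deltas are clipped at ``positive_cap`` before clustering: for
    silencing kinetics any Xi/Xa increase means "not silenced", and an
    unclipped Xi-only outlier (the Xist locus gains several log2 units)
    otherwise captures a centroid of its own.  Genes with any missing delta
    must be excluded by the caller; fewer genes than ``k`` is an error.
    """
    delta_cols = [f"delta_t{t}" for t in timepoints]
    X = trajectories[delta_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("delta trajectories must be complete (no missing values)")
    if len(X) < k:
        raise ValueError(f"need at least k={k} genes, got {len(X)}")
    X = np.minimum(X, positive_cap)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)

    centers = pd.DataFrame(km.cluster_centers_, columns=delta_cols)
    t_last, t_first = timepoints[-1], timepoints[1] if len(timepoints) > 1 else timepoints[-1]
    day8 = centers[f"delta_t{t_last}"]
    day2 = centers[f"delta_t{t_first}"]

    labels = [None] * k
    candidates = [c for c in range(k) if day8[c] > NOT_SILENCED_DELTA]
    ns = max(candidates, key=lambda c: day8[c]) if candidates else int(day8.idxmax())
    labels[ns] = "not_silenced"
    rest = sorted((c for c in range(k) if c != ns), key=lambda c: day2[c])
    for name, c in zip(("early", "intermediate", "late"), rest):
        labels[c] = name
    # more than 4 clusters: number the extras by day-2 rank
    for i, c in enumerate(rest[3:], 4):
        labels[c] = f"cluster{i}"

    assignments = pd.DataFrame({
        "gene": trajectories["gene"].to_numpy(),
        "cluster": raw,
        "label": [labels[c] for c in raw],
    })
    centers.index = pd.Index(labels, name="label")
    return KineticClustering(k=k, assignments=assignments, cluster_means=centers)


def distance_to_xic(gene: GeneModel, xic_pos: int = DEFAULT_XIC_POS,
                    x_chrom: str = "chrX") -> float:
    """Distance (bp) from the gene midpoint to the X-inactivation center."""
    if gene.chrom != x_chrom:
        raise ValueError(f"{gene.gene_id} is not on {x_chrom}")
    return float(abs(gene.midpoint - xic_pos))


def gsea_enrichment_score(is_member: np.ndarray) -> float:
    """Classic unweighted Kolmogorov–Smirnov-style running-sum score.

    ``is_member`` is the membership indicator over genes already ordered by
    the ranking variable.  Hits step up by sqrt((N-n)/n), misses step down
    by sqrt(n/(N-n)); the score is the running sum's signed extremum.
    """
    m = np.asarray(is_member, dtype=bool)
    N, n = m.size, int(m.sum())
    if n == 0 or n == N:
        return float("nan")
    steps = np.where(m, math.sqrt((N - n) / n), -math.sqrt(n / (N - n)))
    rs = np.cumsum(steps)
    return float(rs[np.argmax(np.abs(rs))])


def gsea_distance_test(clustering: KineticClustering, distances: pd.Series,
                       n_perm: int = 2000, seed: int = 0,
                       exact: bool = False) -> pd.DataFrame:
    """Positional enrichment of each kinetic cluster towards the XIC.

    Genes are ranked by distance to the XIC, ascending; each cluster gets a
    running-sum enrichment score and a two-sided permutation p (label
    shuffles; exhaustive enumeration when ``exact``), BH-corrected across
    clusters.  A positive score marks XIC-proximal enrichment.
    """
    assign = clustering.assignments.set_index("gene")
    genes = [g for g in distances.index if g in assign.index]
    d = distances.loc[genes]
    order = np.argsort(d.to_numpy(), kind="stable")
    ordered_genes = np.asarray(genes)[order]
    labels = assign.loc[ordered_genes, "label"].to_numpy()
    N = len(ordered_genes)
    rng = np.random.default_rng(seed)

    rows = []
    for label in clustering.cluster_means.index:
        member = labels == label
        n = int(member.sum())
        es = gsea_enrichment_score(member)
        if math.isnan(es):
            rows.append({"cluster": label, "n": n, "es": np.nan, "p": np.nan,
                         "mean_distance": np.nan})
            continue
        # mid-p convention: permutations tying the observed |ES| count half,
        # keeping the p-value uniform under the null despite the discrete
        # lattice of running-sum scores
        if exact:
            null = np.abs([gsea_enrichment_score(np.isin(np.arange(N), combo))
                           for combo in itertools.combinations(range(N), n)])
            strict = int(np.sum(null > abs(es) + 1e-9))
            ties = int(np.sum(np.abs(null - abs(es)) <= 1e-9))
            p = (strict + 0.5 * ties) / len(null)
        else:
            strict = ties = 0
            perm = member.copy()
            for _ in range(n_perm):
                rng.shuffle(perm)
                e = abs(gsea_enrichment_score(perm))
                if e > abs(es) + 1e-9:
                    strict += 1
                elif abs(e - abs(es)) <= 1e-9:
                    ties += 1
            # the observed labeling counts as one tying permutation
            p = (strict + 0.5 * (ties + 1)) / (n_perm + 1)
        rows.append({"cluster": label, "n": n, "es": es, "p": p,
                     "mean_distance": float(d[assign.loc[genes, "label"]
                                              .to_numpy() == label].mean())})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return out


def day2_trend(positions, deltas, degree: int = 3) -> dict:
    """Least-squares polynomial of day-2 deltas vs chromosomal position."""
    x = np.asarray(positions, dtype=float)
    y = np.asarray(deltas, dtype=float)
    if x.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} genes for degree {degree}")
    # scale positions to [0, 1] for conditioning; coefficients reported on
    # the original scale via the scaled variable
    span = np.ptp(x)
    if span == 0:
        raise ValueError("rank-deficient design: all positions identical")
    xs = (x - x.min()) / span
    coeffs = np.polynomial.polynomial.polyfit(xs, y, degree)
    fitted = np.polynomial.polynomial.polyval(xs, coeffs)
    return {"coefficients": coeffs, "x_offset": float(x.min()),
            "x_scale": float(span), "fitted": fitted, "residuals": y - fitted}


def trend_minimum(trend: dict, n_grid: int = 2001) -> float:
    """Position (bp) minimizing the fitted trend, by dense evaluation."""
    xs = np.linspace(0.0, 1.0, n_grid)
    ys = np.polynomial.polynomial.polyval(xs, trend["coefficients"])
    return float(trend["x_offset"] + xs[np.argmin(ys)] * trend["x_scale"])


def strata_compare(trajectories: pd.DataFrame, timepoints,
                   rpkm_cutoff: float = 2.0) -> pd.DataFrame:
    """Notch comparison of delta distributions between expression strata.

    Splits genes at mean course RPKM > ``rpkm_cutoff`` (high vs low); at
    each time point the two delta distributions are compared with McGill
    notches.  ``direction`` is +1 when the low stratum sits higher (less
    silenced) than the high stratum.
    """
    high = trajectories[trajectories["mean_rpkm"] > rpkm_cutoff]
    low = trajectories[trajectories["mean_rpkm"] <= rpkm_cutoff]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("both expression strata must hold at least 2 genes")
    rows = []
    for t in timepoints:
        col = f"delta_t{t}"
        res = notch_compare(high[col], low[col])
        rows.append({"timepoint": t, "significant": res["significant"],
                     "direction": res["direction"],
                     "median_high": res["median_a"], "median_low": res["median_b"],
                     "n_high": len(high), "n_low": len(low)})
    return pd.DataFrame(rows)


def x_autosome_ratio(expression: pd.DataFrame, chrom_of: dict,
                     x_chrom: str = "chrX",
                     expressed_cutoff: float = 0.5) -> pd.Series:
    """Mean expressed-gene RPKM on the X over the autosomal mean, per sample."""
    chroms = expression.index.map(chrom_of.get)
    on_x = np.asarray(chroms == x_chrom)
    out = {}
    for col in expression.columns:
        vals = expression[col].to_numpy(dtype=float)
        xe = vals[on_x & (vals > expressed_cutoff)]
        ae = vals[~on_x & (vals > expressed_cutoff)]
        if xe.size == 0 or ae.size == 0:
            raise ValueError(f"no expressed genes on one side in sample {col}")
        out[col] = float(xe.mean() / ae.mean())
    return pd.Series(out)


def xa_upregulation_test(records: pd.DataFrame, sample_t0: str,
                         sample_t_end: str, xa_col: str = "rpkm_cast") -> dict:
    """Active-X upregulation: notch comparison of absolute Xa expression.

    Compares the distribution of absolute Xa allelic RPKM at the last time
    point against T = 0 over quantified genes; direction +1 means the late
    sample is higher (upregulation).
    """
    quantified = records[records.get("quantified", True) == True]  # noqa: E712
    a = quantified.loc[quantified["sample"] == sample_t0, xa_col].dropna()
    b = quantified.loc[quantified["sample"] == sample_t_end, xa_col].dropna()
    return notch_compare(a, b)


def mean_silencing(deltas) -> float:
    """Mean silenced fraction 1 - 2^delta across genes."""
    d = np.asarray(deltas, dtype=float)
    return float(np.mean(1.0 - np.power(2.0, d)))
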