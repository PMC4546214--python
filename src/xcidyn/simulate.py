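"""Synthetic allele-specific RNA-seq and Hi-C data with known ground truth.

The generator emulates the statistical structure of a differentiating
hybrid (129 x Cast) female ESC system with forced inactivation of the
129-derived X: a toy X-like chromosome and one autosome (scaled down ~10x
from mouse), SNP densities of ~1/300 bp on the X and ~1/130 bp elsewhere,
a 0/2/3/4/8-day differentiation course, distance-to-XIC-dependent silencing
kinetics, escape regions occupying whole TADs, NPC-like lines with
completed XCI, and block-structured Hi-C contact matrices with distance
decay.  Every dataset ships with a truth table (kinetic class, silencing
time constant, escape status, TAD id, per-time-point Xi fraction) so every
downstream stage can be scored against what was planted.

Model summary
-------------
* Xi fraction of a silenced gene: f(t) = (0.5 - floor) * exp(-t / tau) +
  floor, with tau increasing with distance to the XIC and with expression
  level.  The tau scale is calibrated numerically so that the mean relative
  Xi/Xa silencing after two days, 1 - r(2)/r(0) with r = f/(1-f), equals
  the configured target (0.46 by default).
* Counts: per-site totals are Poisson in the local expression level; the
  129/Cast split is binomial in the planted Xi fraction (optionally
  beta-binomial).  The active-X allele gains (1 + slope * t) in expression
  over the course.
* NPC lines: silenced genes leak Xi counts at a Poisson rate calibrated so
  ~70 % of informative non-escape genes show zero Xi tags; escape genes
  express the Xi at a uniform 15-50 % share; one Xist-like gene at the XIC
  is expressed almost exclusively from the Xi.
* Hi-C: expected counts L * (1 + |i-j|)^(-alpha), boosted by beta within a
  TAD, Poisson sampled, symmetric; the allele-tagged variant is a binomial
  thinning at the informative-assignment fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import GeneModel
from .tads import BinnedContactMatrix, TadSet

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "NPC_LINES",
    "simulate_gene_models",
    "assign_kinetics",
    "simulate_timecourse_counts",
    "simulate_npc_counts",
    "simulate_hic",
    "simulate_all",
]

NPC_LINES = ("*NPC_129-Xi", "NPC_Cast-Xi", "NPC_129-Xi")
#: Xi allele per NPC line
NPC_XI_ALLELE = {"*NPC_129-Xi": "129", "NPC_Cast-Xi": "cast", "NPC_129-Xi": "129"}

SILENCED_CLASSES = ("early", "intermediate", "late")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.  Defaults are the desk-scale
    conditions used throughout the test-suite: toy chromosomes ~10x smaller
    than mouse, 300 X-linked and 700 autosomal genes."""

    seed: int = 0
    # chromosomes (bp)
    x_chrom: str = "chrX"
    x_length: int = 16_600_000
    autosomes: dict = field(default_factory=lambda: {"chr1": 19_500_000})
    xic_pos: int = 10_070_000
    # polymorphic site spacing (bp per SNP)
    snp_spacing_x: int = 300
    snp_spacing_autosome: int = 130
    # genes
    n_genes_x: int = 300
    n_genes_autosome: int = 700
    # differentiation course (days)
    timepoints: tuple = (0, 2, 3, 4, 8)
    # kinetics
    class_proportions: dict = field(default_factory=lambda: {
        "early": 0.30, "intermediate": 0.30, "late": 0.30, "not_silenced": 0.10})
    tau_base: dict = field(default_factory=lambda: {
        "early": 1.1, "intermediate": 2.8, "late": 7.0})
    silencing_floor: float = 0.02
    day2_silencing_target: float = 0.46
    distance_noise: float = 0.25      # SD of the rank score mixing distance in
    expression_tau_span: float = 0.6  # tau multiplier span across expression ranks
    # escape structure
    escape_region_count: int = 3
    escape_region_lines: dict = field(default_factory=lambda: {
        1: ("*NPC_129-Xi", "NPC_Cast-Xi"),
        2: ("*NPC_129-Xi", "NPC_Cast-Xi"),
        3: ("*NPC_129-Xi",)})
    tad_aligned_regions: bool = True
    n_escape_singletons: int = 6
    escape_fraction_range: tuple = (0.15, 0.5)
    escape_region_min_rpkm: float = 1.0
    # expression / counts
    rpkm_ln_mean: float = 1.0
    rpkm_ln_sd: float = 0.6
    x_autosome_scale: float = 1.5
    library_size: float = 1e7
    site_depth: float = 30.0          # expected counts per site per RPKM
    xa_slope: float = 0.025           # Xa upregulation per day (~+20 % by day 8)
    overdispersion: float = 0.0       # beta-binomial rho; 0 = pure binomial
    # NPC lines
    npc_lines: tuple = NPC_LINES
    npc_xi_zero_prob: float = 0.70
    # Hi-C
    tad_size_range: tuple = (400_000, 1_200_000)
    hic_bin_size: int = 40_000
    hic_diag_level: float = 100.0
    hic_decay: float = 0.8
    hic_tad_boost: float = 3.0
    hic_allelic_fraction: float = 0.5

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        tp = tuple(self.timepoints)
        if tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing from 0")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-scoped deterministic generator."""
        return np.random.default_rng([int(self.seed), stage])

    @property
    def samples(self) -> dict:
        return {t: f"T{t}" for t in self.timepoints}


@dataclass
class SimulatedDataset:
    """All outputs of one seeded run."""

    config: SimulationConfig
    genes: list
    tads: TadSet
    truth: pd.DataFrame
    counts_timecourse: pd.DataFrame
    expression: pd.DataFrame
    counts_npc: pd.DataFrame
    hic: BinnedContactMatrix
    hic_allelic: BinnedContactMatrix


# ---------------------------------------------------------------------------
# gene models, TADs, escape structure
# ---------------------------------------------------------------------------

def _place_genes(rng, chrom, length, n, prefix) -> list[GeneModel]:
    slot = length / n
    genes = []
    for i in range(n):
        span = int(min(0.8 * slot, rng.uniform(10_000, 40_000)))
        start = int(i * slot + rng.uniform(0, max(1.0, slot - span - 1)))
        end = start + span
        k = int(rng.integers(2, 5))
        exon_total = float(rng.uniform(1_200, 2_500))
        chunk = int(exon_total / k)
        exons = []
        for j in range(k):
            es = start + int(j * span / k)
            exons.append((es, min(es + chunk, end)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"{prefix}{i:04d}", chrom, strand, start, end,
                               tuple(exons)))
    return genes


def _partition_tads(rng, length, size_range) -> list[tuple]:
    domains, pos = [], 0
    while pos < length:
        size = int(rng.uniform(*size_range))
        end = min(pos + size, length)
        domains.append((pos, end))
        pos = end
    return domains


def simulate_gene_models(cfg: SimulationConfig):
    """Place genes, partition the X into TADs, plant the escape structure.

    Returns ``(genes, tads, truth)``: all gene models, the true TAD set of
    the X, and the truth-table skeleton (positions, TAD ids, escape regions,
    baseline expression; kinetics come from :func:`assign_kinetics`).
    """
    if cfg.n_genes_x * 10_000 > cfg.x_length:
        raise ValueError("too many X genes for the chromosome length")
    rng = cfg.rng(1)
    genes = _place_genes(rng, cfg.x_chrom, cfg.x_length, cfg.n_genes_x, "gx")
    for chrom, length in sorted(cfg.autosomes.items()):
        if cfg.n_genes_autosome * 5_000 > length:
            raise ValueError("too many autosomal genes for the chromosome length")
        genes += _place_genes(rng, chrom, length, cfg.n_genes_autosome, "ga")

    domains = _partition_tads(rng, cfg.x_length, cfg.tad_size_range)
    tads = TadSet(cfg.x_chrom, cfg.hic_bin_size, domains)

    x_genes = [g for g in genes if g.chrom == cfg.x_chrom]
    order = {g.gene_id: i for i, g in enumerate(x_genes)}
    tad_of = {g.gene_id: tads.domain_of(g.start, g.end) for g in x_genes}

    # the Xist-like gene: nearest gene to the XIC
    xist_gene = min(x_genes, key=lambda g: abs(g.midpoint - cfg.xic_pos)).gene_id

    # escape regions occupy whole TADs, distal to the XIC, non-adjacent
    genes_by_tad: dict[int, list[str]] = {}
    for g in x_genes:
        if tad_of[g.gene_id] is not None:
            genes_by_tad.setdefault(tad_of[g.gene_id], []).append(g.gene_id)
    xic_tad = tads.domain_of(cfg.xic_pos, cfg.xic_pos + 1)
    eligible = []
    for t, members in genes_by_tad.items():
        s, e = tads.domains[t]
        dist = abs(0.5 * (s + e) - cfg.xic_pos)
        if (len(members) >= 3 and t != xic_tad
                and dist > 0.25 * cfg.x_length and xist_gene not in members):
            eligible.append((dist, t))
    eligible.sort(reverse=True)
    region_tads: list[int] = []
    for _, t in eligible:
        if len(region_tads) >= cfg.escape_region_count:
            break
        if all(abs(t - u) > 1 for u in region_tads):
            region_tads.append(t)
    if len(region_tads) < cfg.escape_region_count:
        raise ValueError("could not place the requested number of escape regions")
    region_of = {}
    for rid, t in enumerate(sorted(region_tads), start=1):
        for gid in genes_by_tad[t]:
            region_of[gid] = rid

    # escape singletons, kept clear of regions and of each other
    blocked = {order[gid] for gid in region_of}
    blocked |= {i for b in blocked for i in (b - 1, b - 2, b + 1, b + 2)}
    blocked.add(order[xist_gene])
    candidates = [g.gene_id for g in x_genes
                  if order[g.gene_id] not in blocked]
    singles = []
    for gid in rng.permutation(candidates):
        if len(singles) >= cfg.n_escape_singletons:
            break
        i = order[gid]
        if all(abs(i - order[s]) > 2 for s in singles):
            singles.append(gid)
    singleton_set = set(singles)

    # baseline expression (RPKM at T = 0)
    rows = []
    for g in genes:
        on_x = g.chrom == cfg.x_chrom
        scale = cfg.x_autosome_scale if on_x else 1.0
        base = float(rng.lognormal(cfg.rpkm_ln_mean, cfg.rpkm_ln_sd)) * scale
        region = region_of.get(g.gene_id, 0)
        escape = region > 0 or g.gene_id in singleton_set
        if escape:
            for _ in range(100):
                if base >= cfg.escape_region_min_rpkm:
                    break
                base = float(rng.lognormal(cfg.rpkm_ln_mean, cfg.rpkm_ln_sd)) * scale
        rows.append({
            "gene": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
            "strand": g.strand, "exon_length": g.exon_length,
            "midpoint": g.midpoint,
            "tad_id": tad_of.get(g.gene_id) if on_x else None,
            "escape_region": region, "escape": escape,
            "is_xist": g.gene_id == xist_gene,
            "dist_xic": abs(g.midpoint - cfg.xic_pos) if on_x else np.nan,
            "rpkm_base": base,
        })
    truth = pd.DataFrame(rows)
    return genes, tads, truth


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _xi_fraction(t, tau, floor):
    return (0.5 - floor) * math.exp(-t / tau) + floor


def _ratio(f):
    return f / (1.0 - f)


def assign_kinetics(truth: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Assign kinetic classes, time constants and Xi-fraction curves.

    Silenced genes get tau increasing with distance to the XIC (rank score
    with Gaussian noise, cut at the configured class proportions) and with
    expression level; the global tau scale is calibrated so the mean planted
    day-2 Xi/Xa silencing over silenced genes hits the configured target.
    Escape genes keep a constant Xi fraction; the Xist-like gene expresses
    the Xi almost exclusively after T = 0.
    """
    rng = cfg.rng(2)
    truth = truth.copy()
    on_x = truth["chrom"] == cfg.x_chrom
    xg = truth[on_x]

    klass = pd.Series("autosomal", index=truth.index, dtype=object)
    klass[truth["is_xist"]] = "xist"
    klass[on_x & truth["escape"]] = "not_silenced"

    free = truth.index[on_x & ~truth["escape"] & ~truth["is_xist"]]
    dmax = float(xg["dist_xic"].max())
    score = (truth.loc[free, "dist_xic"] / dmax
             + rng.normal(0.0, cfg.distance_noise, size=len(free)))
    ranked = score.sort_values().index
    n_x = int(on_x.sum())
    n_fixed_ns = int(on_x.sum()) - len(free)  # escape + Xist-like genes
    ns_free = max(0, int(round(cfg.class_proportions["not_silenced"] * n_x))
                  - n_fixed_ns)
    sil_total = len(free) - ns_free
    p = np.array([cfg.class_proportions[c]
                  for c in ("early", "intermediate", "late")])
    quota = np.floor(p / p.sum() * sil_total).astype(int)
    quota[-1] += sil_total - quota.sum()
    cursor = 0
    for c, q in zip(("early", "intermediate", "late"), quota):
        klass[ranked[cursor:cursor + q]] = c
        cursor += q
    klass[ranked[cursor:]] = "not_silenced"
    truth["class"] = klass

    # tau for silenced genes: class base x expression modulation x noise
    expr_rank = truth.loc[on_x, "rpkm_base"].rank(pct=True)
    tau = pd.Series(np.nan, index=truth.index)
    sil = truth.index[truth["class"].isin(SILENCED_CLASSES)]
    half = cfg.expression_tau_span / 2.0
    for i in sil:
        base = cfg.tau_base[truth.at[i, "class"]]
        mod = 1.0 - half + cfg.expression_tau_span * float(expr_rank[i])
        tau[i] = base * mod * float(rng.lognormal(0.0, 0.1))

    # calibrate the global tau scale to the day-2 silencing target; the
    # early class is capped so it is fully silenced (f <= 0.05) by the end
    t2, t_last = cfg.timepoints[1], cfg.timepoints[-1]
    taus = tau[sil].to_numpy()
    is_early = (truth.loc[sil, "class"] == "early").to_numpy()
    fl = cfg.silencing_floor
    tau_cap = t_last / math.log((0.5 - fl) / max(0.05 - fl, 1e-6))

    def effective(scale):
        t = scale * taus
        return np.where(is_early, np.minimum(t, tau_cap), t)

    def day2_mean(scale):
        f2 = (0.5 - fl) * np.exp(-t2 / effective(scale)) + fl
        return float(np.mean(1.0 - _ratio(f2)))

    target = cfg.day2_silencing_target
    scale = brentq(lambda s: day2_mean(s) - target, 1e-3, 1e3, xtol=1e-10)
    tau[sil] = effective(scale)
    truth["tau"] = tau

    # Xi-fraction curves
    fl = cfg.silencing_floor
    esc_f = rng.uniform(*cfg.escape_fraction_range, size=len(truth))
    ns_f = rng.uniform(0.35, 0.5, size=len(truth))
    for t in cfg.timepoints:
        col = np.full(len(truth), 0.5)
        for i in range(len(truth)):
            c = truth["class"].iloc[i]
            if c in SILENCED_CLASSES:
                col[i] = _xi_fraction(t, truth["tau"].iloc[i], fl)
            elif c == "xist":
                col[i] = 0.5 if t == 0 else 0.95
            elif c == "not_silenced":
                col[i] = esc_f[i] if truth["escape"].iloc[i] else ns_f[i]
            # autosomal genes stay at 0.5
        truth[f"xi_frac_t{t}"] = col
    return truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def polymorphic_sites(genes, cfg: SimulationConfig,
                      escape_ids=()) -> dict[str, np.ndarray]:
    """Exonic SNP positions (1-based) per gene, by density per chromosome.

    One catalogue per run (the same sites underlie the differentiation
    course and the NPC profiles).  Planted escape genes are guaranteed at
    least two exonic sites — the generator plants *detectable* escape
    regions, mirroring that reported escapers are by definition genes with
    sufficient polymorphic coverage.
    """
    rng = cfg.rng(6)
    escape_ids = set(escape_ids)
    out = {}
    for g in genes:
        spacing = (cfg.snp_spacing_x if g.chrom == cfg.x_chrom
                   else cfg.snp_spacing_autosome)
        sites: list[int] = []
        for s, e in g.exons:
            # Poisson process with the chromosome's SNP density
            n = rng.poisson((e - s) / spacing)
            if n:
                sites.extend(rng.integers(s, e, size=n))
        pos = np.unique(np.asarray(sites, dtype=np.int64))
        if g.gene_id in escape_ids and len(pos) < 2:
            s0, e0 = g.exons[0]
            pos = np.unique(np.concatenate(
                [pos, np.arange(s0, min(s0 + 2, e0), dtype=np.int64)]))
        out[g.gene_id] = pos + 1
    return out


def _split_counts(rng, n, p, rho):
    """129-allele share of ``n`` counts: binomial, or beta-binomial at rho > 0."""
    if n == 0:
        return 0
    if rho > 0:
        a = p * (1.0 / rho - 1.0)
        b = (1.0 - p) * (1.0 / rho - 1.0)
        p = rng.beta(a, b)
    return int(rng.binomial(n, p))


def simulate_timecourse_counts(truth: pd.DataFrame, genes, cfg: SimulationConfig):
    """Allelic site counts and an RPKM table for the differentiation course.

    Per gene and time point the Xa (Cast) expression is the T = 0 level
    scaled by (1 + slope * t); the Xi (129) expression follows from the
    planted Xi fraction.  Site totals are Poisson, the allele split is
    binomial; the RPKM table is derived from Poisson-sampled whole-gene read
    counts so it is consistent with the count model.
    """
    rng = cfg.rng(3)
    tr = truth.set_index("gene")
    snps = polymorphic_sites(genes, cfg, tr.index[tr["escape"]])

    count_rows = []
    expr = {}
    for t in cfg.timepoints:
        sample = cfg.samples[t]
        rpkm_col = {}
        for g in genes:
            row = tr.loc[g.gene_id]
            f0 = row[f"xi_frac_t{cfg.timepoints[0]}"]
            ft = row[f"xi_frac_t{t}"]
            base = row["rpkm_base"]
            if g.chrom == cfg.x_chrom:
                xa = base * (1.0 - f0) * (1.0 + cfg.xa_slope * t)
                xi = xa * _ratio(ft)
            else:
                xa = xi = base / 2.0
            total = xi + xa
            p129 = xi / total  # Xi carries the 129 allele in the course
            reads = rng.poisson(total * g.exon_length * cfg.library_size / 1e9)
            rpkm_col[g.gene_id] = 1e9 * reads / (g.exon_length * cfg.library_size)
            lam = cfg.site_depth * total
            for pos in snps[g.gene_id]:
                n = int(rng.poisson(lam))
                c129 = _split_counts(rng, n, p129, cfg.overdispersion)
                count_rows.append((g.chrom, int(pos), sample, c129, n - c129))
        expr[sample] = rpkm_col
    counts = pd.DataFrame(count_rows,
                          columns=["chrom", "pos", "sample",
                                   "count_129", "count_cast"])
    # sites shared by overlapping genes would duplicate: sum them
    counts = (counts.groupby(["chrom", "pos", "sample"], as_index=False)
              [["count_129", "count_cast"]].sum())
    expression = pd.DataFrame(expr)
    expression.index.name = "gene"
    return counts, expression


def simulate_npc_counts(truth: pd.DataFrame, genes, cfg: SimulationConfig
                        ) -> pd.DataFrame:
    """Allelic site counts for the NPC lines (stable, completed XCI).

    Non-escape X genes leak Xi counts at a Poisson rate of
    -ln(npc_xi_zero_prob) per gene, so ~70 % of them show zero Xi tags at
    any coverage; escape genes express the Xi at their planted share; the
    Xist-like gene is Xi-only.  Samples are named after the NPC lines; the
    129/Cast orientation follows each line's inactivated allele.
    """
    rng = cfg.rng(4)
    x_genes = [g for g in genes if g.chrom == cfg.x_chrom]
    tr = truth.set_index("gene")
    snps = polymorphic_sites(x_genes, cfg, tr.index[tr["escape"]])
    lam_leak = -math.log(cfg.npc_xi_zero_prob)

    rows = []
    for line in cfg.npc_lines:
        xi_allele = NPC_XI_ALLELE[line]
        for g in x_genes:
            row = tr.loc[g.gene_id]
            base = row["rpkm_base"]
            sites = snps[g.gene_id]
            if len(sites) == 0:
                continue
            escapes_here = bool(row["escape"]) and (
                row["escape_region"] == 0
                or line in cfg.escape_region_lines.get(int(row["escape_region"]), ()))
            if row["is_xist"]:
                f = 0.98
            elif escapes_here:
                f = float(rng.uniform(*cfg.escape_fraction_range))
            else:
                cov = cfg.site_depth * base * len(sites)
                f = min(0.5, lam_leak / max(cov, 1e-9))
            lam_site = cfg.site_depth * base
            for pos in sites:
                n = int(rng.poisson(lam_site))
                xi_counts = _split_counts(rng, n, f, cfg.overdispersion)
                c129 = xi_counts if xi_allele == "129" else n - xi_counts
                rows.append((g.chrom, int(pos), line, c129, n - c129))
    counts = pd.DataFrame(rows, columns=["chrom", "pos", "sample",
                                         "count_129", "count_cast"])
    return (counts.groupby(["chrom", "pos", "sample"], as_index=False)
            [["count_129", "count_cast"]].sum())


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------

def simulate_hic(tads: TadSet, cfg: SimulationConfig,
                 tad_boost: float | None = None):
    """Poisson contact matrices with distance decay and TAD block structure.

    Expected counts lambda(i, j) = L * (1 + |i - j|)^(-alpha), multiplied by
    beta when both bins fall in the same TAD.  Returns the full matrix and
    an allele-tagged variant (binomial thinning at the informative-129
    fraction).
    """
    rng = cfg.rng(5)
    beta = cfg.hic_tad_boost if tad_boost is None else tad_boost
    n = -(-tads.domains[-1][1] // cfg.hic_bin_size) if tads.domains else \
        -(-cfg.x_length // cfg.hic_bin_size)
    n = max(n, -(-cfg.x_length // cfg.hic_bin_size))
    idx = np.arange(n)
    lam = cfg.hic_diag_level * (1.0 + np.abs(idx[:, None] - idx[None, :])) \
        ** (-cfg.hic_decay)
    tad_of = np.full(n, -1)
    for k, (s, e) in enumerate(tads.domains):
        tad_of[s // cfg.hic_bin_size:-(-e // cfg.hic_bin_size)] = k
    same = (tad_of[:, None] == tad_of[None, :]) & (tad_of[:, None] >= 0)
    lam = lam * np.where(same, beta, 1.0)

    upper = np.triu(rng.poisson(lam))
    full = upper + np.triu(upper, 1).T
    thinned_u = rng.binomial(upper.astype(np.int64), cfg.hic_allelic_fraction)
    thinned = thinned_u + np.triu(thinned_u, 1).T
    cm = BinnedContactMatrix(tads.chrom, cfg.hic_bin_size, full.astype(float))
    cm_allelic = BinnedContactMatrix(tads.chrom, cfg.hic_bin_size,
                                     thinned.astype(float))
    return cm, cm_allelic


# ---------------------------------------------------------------------------


def simulate_all(cfg: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage for one seed."""
    genes, tads, truth = simulate_gene_models(cfg)
    truth = assign_kinetics(truth, cfg)
    counts_tc, expression = simulate_timecourse_counts(truth, genes, cfg)
    counts_npc = simulate_npc_counts(truth, genes, cfg)
    hic, hic_allelic = simulate_hic(tads, cfg)
    return SimulatedDataset(config=cfg, genes=genes, tads=tads, truth=truth,
                            counts_timecourse=counts_tc, expression=expression,
                            counts_npc=counts_npc, hic=hic,
                            hic_allelic=hic_allelic)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["timepoints"] = list(cfg.timepoints)
    return d
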