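"""End-to-end orchestration: simulate -> quantify -> dynamics -> escape ->
tads -> report, with a reproducible run manifest.

Every stage writes tab-separated outputs under one run directory and can be
re-run standalone from the files of any earlier stage.  The manifest records
the seed, the configuration snapshot and a SHA-256 checksum per output, so a
re-run with the same seed is verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics as dyn
from . import escape as esc
from . import io as xio
from . import quantify as quant
from . import simulate as sim
from . import tads as tad

__all__ = ["load_config", "run_all", "write_report", "StageError"]

ANALYSIS_DEFAULTS = {
    "k": 4,
    "n_init": 10,
    "n_perm": 2000,
    "strata_rpkm_cutoff": 2.0,
    "expressed_cutoff": 0.5,
    "di_window": 2_000_000,
    "min_tad_bins": 3,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def load_config(path=None, seed: int | None = None
                ) -> tuple[sim.SimulationConfig, dict]:
    """Read the YAML run configuration.

    Top-level keys: ``simulation`` (SimulationConfig fields) and
    ``analysis``; unknown keys raise before any stage runs.
    """
    raw = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"simulation", "analysis"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    sim_kwargs = dict(raw.get("simulation") or {})
    valid = {f.name for f in dataclasses.fields(sim.SimulationConfig)}
    bad = set(sim_kwargs) - valid
    if bad:
        raise ValueError(f"unknown simulation keys: {sorted(bad)}")
    for tup_key in ("timepoints", "npc_lines", "tad_size_range",
                    "escape_fraction_range"):
        if tup_key in sim_kwargs:
            sim_kwargs[tup_key] = tuple(sim_kwargs[tup_key])
    if seed is not None:
        sim_kwargs["seed"] = int(seed)
    analysis = dict(ANALYSIS_DEFAULTS)
    extra = set(raw.get("analysis") or {}) - set(ANALYSIS_DEFAULTS)
    if extra:
        raise ValueError(f"unknown analysis keys: {sorted(extra)}")
    analysis.update(raw.get("analysis") or {})
    return sim.SimulationConfig(**sim_kwargs), analysis


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=False):
    with open(path, "w", encoding="utf-8") as fh:
        cols = list(df.columns)
        if index:
            cols = [df.index.name or "index"] + cols
        fh.write("#" + "\t".join(map(str, cols)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=index)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: sim.SimulationConfig, outdir: Path) -> sim.SimulatedDataset:
    ds = sim.simulate_all(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    xio.write_gene_models(ds.genes, outdir / "genes.bed")
    xio.write_allele_counts(ds.counts_timecourse, outdir / "counts_timecourse.tsv")
    xio.write_allele_counts(ds.counts_npc, outdir / "counts_npc.tsv")
    xio.write_expression(ds.expression, outdir / "expression.tsv")
    _write_tsv(ds.truth, outdir / "truth.tsv")
    xio.write_contact_triplets(ds.hic, outdir / "hic_bins.bed",
                               outdir / "hic_triplets.tsv")
    xio.write_contact_triplets(ds.hic_allelic, outdir / "hic_bins.bed",
                               outdir / "hic_allelic_triplets.tsv")
    xio.write_bed([(ds.tads.chrom, s, e, f"true_tad_{k}")
                   for k, (s, e) in enumerate(ds.tads.domains)],
                  outdir / "tads_true.bed")
    return ds


def stage_quantify(ds: sim.SimulatedDataset, outdir: Path):
    cfg = ds.config
    records, report = quant.quantify_timecourse(
        ds.counts_timecourse, ds.genes, ds.expression,
        samples=[cfg.samples[t] for t in cfg.timepoints])
    _write_tsv(records, outdir / "allelic_records.tsv")
    _write_tsv(report, outdir / "filter_report.tsv")
    return records, report


def stage_dynamics(ds, records, analysis: dict, outdir: Path) -> dict:
    cfg = ds.config
    traj = dyn.compute_trajectories(
        records, ds.genes, cfg.timepoints, cfg.samples,
        xi_allele="129", xic_pos=cfg.xic_pos, x_chrom=cfg.x_chrom)
    if traj.empty:
        raise StageError("dynamics", "no complete X-linked trajectories")
    clustering = dyn.kmeans_trajectories(traj, cfg.timepoints,
                                         k=analysis["k"],
                                         n_init=analysis["n_init"],
                                         seed=cfg.seed)
    gsea = dyn.gsea_distance_test(clustering,
                                  traj.set_index("gene")["dist_xic"],
                                  n_perm=analysis["n_perm"], seed=cfg.seed)
    t2 = cfg.timepoints[1]
    trend = dyn.day2_trend(traj["position"], traj[f"delta_t{t2}"])
    strata = dyn.strata_compare(traj, cfg.timepoints,
                                rpkm_cutoff=analysis["strata_rpkm_cutoff"])
    chrom_of = {g.gene_id: g.chrom for g in ds.genes}
    x_records = records[records["gene"].map(chrom_of) == cfg.x_chrom]
    xa = dyn.xa_upregulation_test(x_records, cfg.samples[cfg.timepoints[0]],
                                  cfg.samples[cfg.timepoints[-1]])
    xa_ratio = dyn.x_autosome_ratio(ds.expression, chrom_of, cfg.x_chrom,
                                    expressed_cutoff=analysis["expressed_cutoff"])

    _write_tsv(traj, outdir / "trajectories.tsv")
    _write_tsv(clustering.assignments, outdir / "clusters.tsv")
    _write_tsv(gsea, outdir / "gsea.tsv")
    coeff = pd.DataFrame({"order": range(len(trend["coefficients"])),
                          "coefficient": trend["coefficients"]})
    _write_tsv(coeff, outdir / "day2_trend.tsv")
    _write_tsv(strata, outdir / "strata_compare.tsv")
    xa_df = pd.DataFrame([{"comparison": "Xa_day_last_vs_day0", **{
        k: v for k, v in xa.items() if not isinstance(v, tuple)}}])
    _write_tsv(xa_df, outdir / "xa_upregulation.tsv")
    _write_tsv(xa_ratio.rename("x_autosome_ratio").to_frame(),
               outdir / "x_autosome_ratio.tsv", index=True)
    return {"trajectories": traj, "clustering": clustering, "gsea": gsea,
            "trend": trend, "strata": strata, "xa_test": xa,
            "x_autosome_ratio": xa_ratio}


def stage_escape(ds, clustering, outdir: Path) -> dict:
    cfg = ds.config
    x_genes = [g for g in ds.genes if g.chrom == cfg.x_chrom]
    sites = quant.filter_sites(ds.counts_npc)
    calls_by_line, regions_by_line = {}, {}
    for line in cfg.npc_lines:
        sub = sites[sites["sample"] == line]
        mapped = quant.map_sites_to_genes(sub, x_genes)
        calls = esc.call_escape_table(mapped, x_genes, line,
                                      xi_allele=sim.NPC_XI_ALLELE[line])
        calls_by_line[line] = calls
        regions_by_line[line] = esc.detect_escape_regions(calls)

    all_calls = pd.concat(calls_by_line.values(), ignore_index=True)
    _write_tsv(all_calls, outdir / "escape_calls.tsv")
    bed_rows = sorted(
        (r.chrom, r.start, r.end, f"{r.line}|{'|'.join(r.genes)}")
        for line in cfg.npc_lines for r in regions_by_line[line])
    xio.write_bed(bed_rows, outdir / "escape_regions.bed")
    crosstab = None
    if clustering is not None:
        crosstab = esc.cluster_escape_crosstab(
            clustering, calls_by_line[cfg.npc_lines[0]])
        _write_tsv(crosstab, outdir / "cluster_escape_crosstab.tsv")
    return {"calls": calls_by_line, "regions": regions_by_line,
            "crosstab": crosstab}


def stage_tads(ds, escape_calls, analysis: dict, outdir: Path) -> dict:
    cfg = ds.config
    norm = tad.normalize_matrix(ds.hic)
    di = tad.directionality_index(norm, window=analysis["di_window"])
    called = tad.call_domains(di, seed=cfg.seed,
                              min_bins=analysis["min_tad_bins"])
    norm_a = tad.normalize_matrix(ds.hic_allelic)
    di_a = tad.directionality_index(norm_a, window=analysis["di_window"])
    called_a = tad.call_domains(di_a, seed=cfg.seed,
                                min_bins=analysis["min_tad_bins"])
    frac, _pairs = tad.boundary_overlap(called, called_a)
    rho = tad.matrix_bin_correlation(ds.hic, ds.hic_allelic)

    x_genes = [g for g in ds.genes if g.chrom == cfg.x_chrom]
    assignment = tad.assign_genes_to_tads(x_genes, called)
    concordance = None
    if escape_calls is not None:
        informative = escape_calls[escape_calls["informative"]]
        concordance = tad.tad_escape_concordance(assignment, informative)
        _write_tsv(concordance, outdir / "tad_escape_concordance.tsv")

    xio.write_bed([(called.chrom, s, e, f"tad_{k}")
                   for k, (s, e) in enumerate(called.domains)],
                  outdir / "tads_called.bed")
    xio.write_bed([(called.chrom, int(b), int(b) + 1, "boundary")
                   for b in called.boundaries], outdir / "tad_boundaries.bed")
    xio.write_wig(di.to_wig(), outdir / "di.wig")
    _write_tsv(pd.DataFrame({"bin": range(len(rho)), "rho": rho}),
               outdir / "hic_bin_correlation.tsv")
    return {"di": di, "tads": called, "tads_allelic": called_a,
            "boundary_overlap": frac, "bin_correlation": rho,
            "assignment": assignment, "concordance": concordance}


def write_report(ds, results: dict, outdir: Path) -> dict:
    """Headline summary tables: clusters with positional enrichment, escape
    summary per line, escape regions, TAD concordance.  A pure function of
    the stage outputs."""
    cfg = ds.config
    clustering = results["dynamics"]["clustering"]
    gsea = results["dynamics"]["gsea"].set_index("cluster")
    rows = []
    for label in clustering.cluster_means.index:
        rows.append({
            "cluster": label,
            "n_genes": int((clustering.assignments["label"] == label).sum()),
            "mean_dist_xic": gsea.loc[label, "mean_distance"],
            "gsea_p": gsea.loc[label, "p"], "gsea_q": gsea.loc[label, "q"],
        })
    cluster_summary = pd.DataFrame(rows)

    esc_rows = []
    for line, calls in results["escape"]["calls"].items():
        informative = calls[calls["informative"]]
        subject = informative[~informative["is_escape"]]
        esc_rows.append({
            "line": line,
            "n_informative": len(informative),
            "n_escape": int(informative["is_escape"].sum()),
            "n_regions": len(results["escape"]["regions"][line]),
            "zero_xi_fraction_subject": float((subject["xi_count_total"] == 0).mean())
            if len(subject) else float("nan"),
        })
    escape_summary = pd.DataFrame(esc_rows)

    region_rows = [{"line": line, "chrom": r.chrom, "start": r.start,
                    "end": r.end, "n_genes": r.n_genes,
                    "genes": ",".join(r.genes)}
                   for line in cfg.npc_lines
                   for r in results["escape"]["regions"][line]]
    regions = pd.DataFrame(region_rows, columns=["line", "chrom", "start",
                                                 "end", "n_genes", "genes"])

    conc = results["tads"]["concordance"]
    conc_summary = pd.DataFrame([{
        "n_scored_tads": 0 if conc is None else len(conc),
        "n_homogeneous": 0 if conc is None else int(
            conc["label"].str.startswith("homogeneous").sum()),
        "boundary_overlap_full_vs_allelic": results["tads"]["boundary_overlap"],
    }])

    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(cluster_summary, outdir / "report_clusters.tsv")
    _write_tsv(escape_summary, outdir / "report_escape.tsv")
    _write_tsv(regions, outdir / "report_regions.tsv")
    _write_tsv(conc_summary, outdir / "report_concordance.tsv")
    return {"clusters": cluster_summary, "escape": escape_summary,
            "regions": regions, "concordance": conc_summary}


# ---------------------------------------------------------------------------

def run_all(cfg: sim.SimulationConfig, outdir, analysis: dict | None = None) -> dict:
    """Execute every stage in order; returns results plus the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = {**ANALYSIS_DEFAULTS, **(analysis or {})}
    results: dict = {}
    t_start = time.time()
    stage_names = []
    try:
        stage = "simulate"
        ds = stage_simulate(cfg, outdir)
        stage_names.append(stage)
        stage = "quantify"
        records, report = stage_quantify(ds, outdir)
        results["quantify"] = {"records": records, "report": report}
        stage_names.append(stage)
        stage = "dynamics"
        results["dynamics"] = stage_dynamics(ds, records, analysis, outdir)
        stage_names.append(stage)
        stage = "escape"
        results["escape"] = stage_escape(
            ds, results["dynamics"]["clustering"], outdir)
        stage_names.append(stage)
        stage = "tads"
        line1 = cfg.npc_lines[0]
        results["tads"] = stage_tads(
            ds, results["escape"]["calls"][line1], analysis, outdir)
        stage_names.append(stage)
        stage = "report"
        results["report"] = write_report(ds, results, outdir)
        stage_names.append(stage)
    except StageError:
        raise
    except Exception as exc:  # tag the failing stage
        raise StageError(stage, str(exc)) from exc

    manifest = {
        "tool": "xcidyn",
        "seed": int(cfg.seed),
        "config": sim.config_to_dict(cfg),
        "analysis": analysis,
        "stages": stage_names,
        "elapsed_s": round(time.time() - t_start, 2),
        "checksums": {p.name: _sha256(p)
                      for p in sorted(outdir.iterdir()) if p.is_file()
                      and p.name != "manifest.yaml"},
    }
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(json.loads(json.dumps(manifest)), fh, sort_keys=True)
    results["dataset"] = ds
    results["manifest"] = manifest
    return results
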