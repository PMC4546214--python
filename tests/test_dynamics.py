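"""Silencing trajectories, kinetic clustering, positional enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from xcidyn import dynamics as dyn
from xcidyn import simulate as sim
from xcidyn.io import GeneModel


class TestXiXaLog2:
    def test_arithmetic(self):
        val, capped = dyn.xi_xa_log2(10, 90)
        assert val == pytest.approx(math.log2(10 / 90))
        assert not capped

    def test_equal_counts_zero(self):
        assert dyn.xi_xa_log2(7, 7)[0] == 0.0

    def test_swap_flips_sign(self):
        assert dyn.xi_xa_log2(3, 12)[0] == -dyn.xi_xa_log2(12, 3)[0]

    def test_zero_allele_capped(self):
        assert dyn.xi_xa_log2(0, 50) == (-10.0, True)
        assert dyn.xi_xa_log2(50, 0) == (10.0, True)

    def test_both_zero_missing(self):
        val, _ = dyn.xi_xa_log2(0, 0)
        assert math.isnan(val)


def _planted_trajectories(n_per=50, seed=0, noise=0.15):
    """Four well-separated synthetic trajectory families."""
    rng = np.random.default_rng(seed)
    templates = {
        "early": [0, -3.0, -4.0, -4.5, -5.0],
        "intermediate": [0, -1.0, -2.0, -3.0, -4.5],
        "late": [0, -0.3, -0.6, -0.9, -1.8],
        "not_silenced": [0, 0.0, 0.0, 0.0, 0.0],
    }
    timepoints = (0, 2, 3, 4, 8)
    rows, labels = [], []
    for name, tpl in templates.items():
        for i in range(n_per):
            row = {"gene": f"{name}_{i}"}
            for t, v in zip(timepoints, tpl):
                row[f"delta_t{t}"] = v + (rng.normal(0, noise) if t else 0.0)
            rows.append(row)
            labels.append(name)
    return pd.DataFrame(rows), labels, timepoints


class TestKmeans:
    def test_recovers_planted_families(self):
        traj, labels, tps = _planted_trajectories(n_per=50)
        clustering = dyn.kmeans_trajectories(traj, tps, seed=0)
        ari = adjusted_rand_score(labels, clustering.assignments["label"])
        assert ari >= 0.9
        # and the deterministic label rule matches the planted names
        acc = (clustering.assignments["label"].to_numpy()
               == np.asarray(labels)).mean()
        assert acc >= 0.9

    def test_duplicate_gene_same_cluster(self):
        traj, _, tps = _planted_trajectories(n_per=10)
        dup = traj.iloc[[0]].assign(gene="dup")
        both = pd.concat([traj, dup], ignore_index=True)
        clustering = dyn.kmeans_trajectories(both, tps, seed=0)
        a = clustering.assignments.set_index("gene")["cluster"]
        assert a[traj.iloc[0]["gene"]] == a["dup"]

    def test_determinism(self):
        traj, _, tps = _planted_trajectories(n_per=20)
        c1 = dyn.kmeans_trajectories(traj, tps, seed=3)
        c2 = dyn.kmeans_trajectories(traj, tps, seed=3)
        pd.testing.assert_frame_equal(c1.assignments, c2.assignments)

    def test_label_rule_invariant_to_row_order(self):
        traj, _, tps = _planted_trajectories(n_per=20, seed=4)
        shuffled = traj.sample(frac=1.0, random_state=9)
        a = dyn.kmeans_trajectories(traj, tps, seed=0).assignments
        b = dyn.kmeans_trajectories(shuffled, tps, seed=0).assignments
        merged = a.merge(b, on="gene", suffixes=("_a", "_b"))
        assert (merged["label_a"] == merged["label_b"]).all()

    def test_too_few_genes(self):
        traj, _, tps = _planted_trajectories(n_per=1)
        with pytest.raises(ValueError, match="at least k"):
            dyn.kmeans_trajectories(traj.head(3), tps, k=4)


class TestDistance:
    def test_examples(self):
        g = GeneModel("Xist_like", "chrX", "-", 100_699_000, 100_701_000)
        assert dyn.distance_to_xic(g, 100_700_000) == 0.0
        g2 = GeneModel("g", "chrX", "+", 95_699_000, 95_701_000)
        assert dyn.distance_to_xic(g2, 100_700_000) == pytest.approx(5e6)

    def test_symmetric(self):
        up = GeneModel("u", "chrX", "+", 90, 110)
        dn = GeneModel("d", "chrX", "+", 290, 310)
        assert dyn.distance_to_xic(up, 200) == dyn.distance_to_xic(dn, 200)

    def test_autosomal_rejected(self):
        g = GeneModel("a", "chr1", "+", 0, 10)
        with pytest.raises(ValueError):
            dyn.distance_to_xic(g, 100)


def _es_oracle(member):
    """Running-sum extremum by direct loop."""
    member = np.asarray(member, dtype=bool)
    N, n = len(member), member.sum()
    up, down = math.sqrt((N - n) / n), -math.sqrt(n / (N - n))
    best, rs = 0.0, 0.0
    for m in member:
        rs += up if m else down
        if abs(rs) > abs(best):
            best = rs
    return best


class TestGsea:
    def test_score_matches_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(4, 30))
            n = int(rng.integers(1, N))
            member = np.zeros(N, bool)
            member[rng.choice(N, n, replace=False)] = True
            assert dyn.gsea_enrichment_score(member) == pytest.approx(
                _es_oracle(member), abs=1e-12)

    def _clustering(self, labels, genes):
        assign = pd.DataFrame({"gene": genes, "cluster": 0, "label": labels})
        means = pd.DataFrame(index=pd.Index(sorted(set(labels)), name="label"))
        return dyn.KineticClustering(k=len(set(labels)), assignments=assign,
                                     cluster_means=means)

    def test_extreme_cluster_minimal_p(self):
        genes = [f"g{i}" for i in range(30)]
        labels = ["near"] * 8 + ["far"] * 22
        distances = pd.Series(np.arange(30, dtype=float) * 1e5, index=genes)
        res = dyn.gsea_distance_test(self._clustering(labels, genes), distances,
                                     n_perm=499, seed=0).set_index("cluster")
        assert res.loc["near", "es"] > 0
        assert res.loc["near", "p"] <= 1 / 500 + 1e-12

    def test_exact_enumeration_n4(self):
        # N=4, n=2: all 6 arrangements enumerated by hand via the oracle
        genes = list("abcd")
        labels = ["in", "in", "out", "out"]
        distances = pd.Series([1.0, 2.0, 3.0, 4.0], index=genes)
        res = dyn.gsea_distance_test(self._clustering(labels, genes), distances,
                                     exact=True).set_index("cluster")
        es_obs = abs(_es_oracle([True, True, False, False]))
        null = np.array([abs(_es_oracle(np.isin(range(4), c)))
                         for c in itertools.combinations(range(4), 2)])
        # mid-p: arrangements tying the observed score count half
        expected = (np.sum(null > es_obs + 1e-9)
                    + 0.5 * np.sum(np.abs(null - es_obs) <= 1e-9)) / 6
        assert res.loc["in", "p"] == pytest.approx(expected)

    def test_permutation_converges_to_exact(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(8)]
        labels = ["in" if i in (0, 2, 5) else "out" for i in range(8)]
        distances = pd.Series(rng.uniform(0, 1e6, 8), index=genes)
        cl = self._clustering(labels, genes)
        exact = dyn.gsea_distance_test(cl, distances, exact=True
                                       ).set_index("cluster").loc["in", "p"]
        sampled = dyn.gsea_distance_test(cl, distances, n_perm=4000, seed=2
                                         ).set_index("cluster").loc["in", "p"]
        assert sampled == pytest.approx(exact, abs=0.03)

    def test_null_p_values_uniform(self):
        # random clusters on random distances: p ~ U(0,1) over 500 replicates
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(40)]
        pvals = []
        for _ in range(500):
            member = rng.choice(40, 8, replace=False)
            labels = ["in" if i in member else "out" for i in range(40)]
            distances = pd.Series(rng.uniform(0, 1e6, 40), index=genes)
            res = dyn.gsea_distance_test(self._clustering(labels, genes),
                                         distances, n_perm=199,
                                         seed=int(rng.integers(2**31)))
            pvals.append(res.set_index("cluster").loc["in", "p"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_cluster_missing(self):
        genes = list("abcd")
        labels = ["in"] * 4
        distances = pd.Series([1.0, 2.0, 3.0, 4.0], index=genes)
        res = dyn.gsea_distance_test(self._clustering(labels, genes), distances,
                                     n_perm=9, seed=0)
        assert res["p"].isna().all()


class TestDay2Trend:
    def test_exact_cubic(self):
        x = np.linspace(0, 1.66e7, 50)
        xs = (x - x.min()) / np.ptp(x)
        y = 1.0 - 2.0 * xs + 0.5 * xs ** 2 + 0.25 * xs ** 3
        trend = dyn.day2_trend(x, y)
        assert np.max(np.abs(trend["residuals"])) <= 1e-10

    def test_constant_deltas(self):
        x = np.linspace(0, 1e6, 20)
        trend = dyn.day2_trend(x, np.full(20, -1.5))
        assert trend["coefficients"][0] == pytest.approx(-1.5, abs=1e-8)
        assert np.allclose(trend["coefficients"][1:], 0, atol=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            dyn.day2_trend([1, 2, 3], [0, 0, 0], degree=3)

    def test_planted_dip_near_xic(self, pipeline_run):
        results, _ = pipeline_run
        cfg = results["dataset"].config
        minimum = dyn.trend_minimum(results["dynamics"]["trend"])
        assert abs(minimum - cfg.xic_pos) <= 2e6


class TestStrata:
    def test_identical_strata_not_significant(self):
        rng = np.random.default_rng(0)
        deltas = rng.normal(-1, 0.5, 200)
        traj = pd.DataFrame({
            "gene": [f"g{i}" for i in range(200)],
            "mean_rpkm": np.where(np.arange(200) < 100, 1.0, 5.0),
            "delta_t0": 0.0, "delta_t2": deltas})
        res = dyn.strata_compare(traj, (0, 2))
        assert not res.loc[res["timepoint"] == 2, "significant"].iloc[0]

    def test_cutoff_above_all_genes(self):
        traj = pd.DataFrame({"gene": ["a", "b"], "mean_rpkm": [1.0, 1.5],
                             "delta_t0": 0.0, "delta_t2": [-1.0, -2.0]})
        with pytest.raises(ValueError):
            dyn.strata_compare(traj, (0, 2), rpkm_cutoff=10.0)

    def test_planted_low_stratum_silences_faster(self, pipeline_run):
        results, _ = pipeline_run
        strata = results["dynamics"]["strata"]
        mid = strata[strata["timepoint"].isin([2, 3, 4])]
        assert (mid["significant"] & (mid["direction"] == -1)).any()


class TestDosage:
    def test_identical_distributions_ratio_one(self):
        expr = pd.DataFrame({"s1": np.tile([1.0, 2.0, 3.0], 20)},
                            index=[f"g{i}" for i in range(60)])
        chrom_of = {f"g{i}": ("chrX" if i < 30 else "chr1") for i in range(60)}
        assert dyn.x_autosome_ratio(expr, chrom_of)["s1"] == pytest.approx(1.0)

    def test_doubled_x_expression(self):
        vals = np.tile([1.0, 2.0, 3.0], 10)
        expr = pd.DataFrame({"s1": np.concatenate([2 * vals, vals])},
                            index=[f"g{i}" for i in range(60)])
        chrom_of = {f"g{i}": ("chrX" if i < 30 else "chr1") for i in range(60)}
        assert dyn.x_autosome_ratio(expr, chrom_of)["s1"] == pytest.approx(2.0)

    def test_planted_1p5_scaling(self, pipeline_run):
        results, _ = pipeline_run
        cfg = results["dataset"].config
        t0 = results["dynamics"]["x_autosome_ratio"]["T0"]
        assert t0 == pytest.approx(cfg.x_autosome_scale, abs=0.15)

    def test_xa_upregulation_detected(self, pipeline_run):
        results, _ = pipeline_run
        xa = results["dynamics"]["xa_test"]
        assert xa["significant"] and xa["direction"] == 1

    def test_flat_xa_not_significant(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(1, 0.6, 300)
        records = pd.DataFrame({
            "gene": [f"g{i}" for i in range(300)] * 2,
            "sample": ["T0"] * 300 + ["T8"] * 300,
            "rpkm_cast": np.concatenate([vals, np.roll(vals, 7)]),
            "quantified": True})
        res = dyn.xa_upregulation_test(records, "T0", "T8")
        assert not res["significant"]


class TestMeanSilencing:
    def test_formula(self):
        assert dyn.mean_silencing([-1.0]) == pytest.approx(0.5)
        assert dyn.mean_silencing([0.0, -1.0]) == pytest.approx(0.25)

    def test_recovers_generator_calibration(self, pipeline_run):
        results, _ = pipeline_run
        cfg = results["dataset"].config
        traj = results["dynamics"]["trajectories"].set_index("gene")
        assign = results["dynamics"]["clustering"].assignments.set_index("gene")
        silenced = assign[assign["label"].isin(sim.SILENCED_CLASSES)].index
        measured = dyn.mean_silencing(traj.loc[silenced, "delta_t2"])
        assert measured == pytest.approx(cfg.day2_silencing_target, abs=0.03)
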