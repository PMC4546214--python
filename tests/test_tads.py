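"""Contact binning, balancing, directionality index, TAD calling."""

import numpy as np
import pandas as pd
import pytest

from xcidyn import simulate as sim
from xcidyn import tads as tad
from xcidyn.io import GeneModel
from xcidyn.tads import BinnedContactMatrix, TadSet


def _matrix(m):
    return BinnedContactMatrix("chrX", 40_000, np.asarray(m, dtype=float))


class TestBinContacts:
    def test_single_pair(self):
        cm = tad.bin_contacts([(10_000, 50_000)], "chrX", 120_000)
        assert cm.matrix[0, 1] == cm.matrix[1, 0] == 1

    def test_self_pair_on_diagonal(self):
        cm = tad.bin_contacts([(10_000, 20_000)], "chrX", 120_000)
        assert cm.matrix[0, 0] == 1

    def test_pair_count_conserved(self):
        rng = np.random.default_rng(0)
        pairs = rng.integers(0, 400_000, size=(500, 2))
        cm = tad.bin_contacts(pairs, "chrX", 400_000)
        assert np.triu(cm.matrix).sum() == 500

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            tad.bin_contacts([(10_000, 999_999)], "chrX", 120_000)


class TestNormalize:
    def test_balanced_matrix_fixed_point(self):
        m = _matrix(np.ones((5, 5)))
        out = tad.normalize_matrix(m)
        assert np.allclose(out.matrix, m.matrix)

    def test_row_sums_equalized(self):
        rng = np.random.default_rng(1)
        raw = rng.poisson(20.0, (30, 30)).astype(float)
        m = _matrix(np.triu(raw) + np.triu(raw, 1).T)
        out = tad.normalize_matrix(m, tol=1e-8)
        sums = out.matrix.sum(axis=0)
        assert sums.std() / sums.mean() < 1e-6
        assert np.allclose(out.matrix, out.matrix.T)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        raw = rng.poisson(15.0, (20, 20)).astype(float)
        sym = np.triu(raw) + np.triu(raw, 1).T
        a = tad.normalize_matrix(_matrix(sym), tol=1e-10).matrix
        b = tad.normalize_matrix(_matrix(2 * sym), tol=1e-10).matrix
        ratio = b[a > 0] / a[a > 0]
        assert np.allclose(ratio, ratio[0])

    def test_zero_matrix_warned(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = tad.normalize_matrix(_matrix(np.zeros((4, 4))))
        assert out.matrix.sum() == 0

    def test_zero_rows_left_zero(self):
        m = np.ones((5, 5))
        m[2, :] = m[:, 2] = 0
        out = tad.normalize_matrix(_matrix(m))
        assert out.matrix[2].sum() == 0


class TestDirectionalityIndex:
    def test_balanced_bin_is_zero(self):
        m = np.zeros((3, 3))
        m[1, 0] = m[0, 1] = 20
        m[1, 2] = m[2, 1] = 20
        di = tad.directionality_index(_matrix(m), window=40_000)
        assert di.values[1] == 0.0

    def test_formula_example(self):
        # A = 10 upstream, B = 30 downstream -> E = 20, DI = +10
        m = np.zeros((3, 3))
        m[1, 0] = m[0, 1] = 10
        m[1, 2] = m[2, 1] = 30
        di = tad.directionality_index(_matrix(m), window=40_000)
        assert di.values[1] == pytest.approx(10.0)

    def test_window_validation(self):
        with pytest.raises(ValueError, match="multiple"):
            tad.directionality_index(_matrix(np.ones((4, 4))), window=50_000)

    def test_antisymmetric_under_mirroring(self):
        # mirroring the matrix reverses and negates the DI track
        rng = np.random.default_rng(3)
        for _ in range(10):
            raw = rng.poisson(8.0, (50, 50)).astype(float)
            sym = np.triu(raw) + np.triu(raw, 1).T
            di = tad.directionality_index(_matrix(sym)).values
            mirrored = tad.directionality_index(_matrix(sym[::-1, ::-1])).values
            assert np.allclose(mirrored, -di[::-1], atol=1e-9)


@pytest.fixture(scope="module")
def planted_hic():
    cfg = sim.SimulationConfig(seed=2)
    _, tads_true, _ = sim.simulate_gene_models(cfg)
    cm, cma = sim.simulate_hic(tads_true, cfg)
    return cfg, tads_true, cm, cma


class TestCallDomains:
    def test_boundaries_recovered_within_one_bin(self, planted_hic):
        cfg, tads_true, cm, _ = planted_hic
        di = tad.directionality_index(tad.normalize_matrix(cm))
        called = tad.call_domains(di, seed=0)
        cb = called.boundaries
        for b in tads_true.boundaries:
            assert np.min(np.abs(cb - b)) <= cfg.hic_bin_size

    def test_no_structure_few_spurious_domains(self, planted_hic):
        cfg, tads_true, _, _ = planted_hic
        cm, _ = sim.simulate_hic(tads_true, cfg, tad_boost=1.0)
        di = tad.directionality_index(tad.normalize_matrix(cm))
        called = tad.call_domains(di, seed=0)
        assert len(called.domains) <= cm.n_bins / 100

    def test_scale_invariance(self, planted_hic):
        _, _, cm, _ = planted_hic
        doubled = BinnedContactMatrix(cm.chrom, cm.bin_size, cm.matrix * 2)
        di1 = tad.directionality_index(tad.normalize_matrix(cm))
        di2 = tad.directionality_index(tad.normalize_matrix(doubled))
        d1 = tad.call_domains(di1, seed=0)
        d2 = tad.call_domains(di2, seed=0)
        assert d1.domains == d2.domains

    def test_all_zero_track(self):
        di = tad.DirectionalityTrack("chrX", 40_000, 2_000_000, np.zeros(50))
        assert tad.call_domains(di).domains == []

    def test_thinned_copy_same_domains(self, planted_hic):
        # the allele-tagged (thinned) matrix yields the same domain calls
        cfg, _, cm, cma = planted_hic
        full = tad.call_domains(
            tad.directionality_index(tad.normalize_matrix(cm)), seed=0)
        allelic = tad.call_domains(
            tad.directionality_index(tad.normalize_matrix(cma)), seed=0)
        frac, _ = tad.boundary_overlap(full, allelic, tol=cfg.hic_bin_size)
        assert frac == 1.0


class TestAlleleSpecificMatrix:
    def _pairs(self, tags):
        return pd.DataFrame({
            "pos_a": [10_000] * len(tags), "pos_b": [90_000] * len(tags),
            "tag_a": [t[0] for t in tags], "tag_b": [t[1] for t in tags]})

    def test_untagged_pairs_dropped(self):
        with pytest.warns(UserWarning, match="no allele-tagged"):
            cm = tad.allele_specific_matrix(self._pairs([("", ""), ("", "")]),
                                            "chrX", 200_000)
        assert cm.matrix.sum() == 0

    def test_tagged_only_equals_bin_contacts(self):
        pairs = self._pairs([("129", ""), ("", "129"), ("cast", "")])
        cm = tad.allele_specific_matrix(pairs, "chrX", 200_000)
        ref = tad.bin_contacts([(10_000, 90_000)] * 2, "chrX", 200_000)
        assert np.array_equal(cm.matrix, ref.matrix)


class TestCorrelations:
    def test_self_correlation_is_one(self, planted_hic):
        _, _, cm, _ = planted_hic
        rho = tad.matrix_bin_correlation(cm, cm)
        interior = rho[30:-30]
        assert np.all(np.isnan(interior) | (interior > 0.999999))
        assert np.nanmin(interior) > 0.999999

    def test_independent_matrices_low_correlation(self):
        rng = np.random.default_rng(4)
        a = rng.poisson(10.0, (120, 120)).astype(float)
        b = rng.poisson(10.0, (120, 120)).astype(float)
        ma = _matrix(np.triu(a) + np.triu(a, 1).T)
        mb = _matrix(np.triu(b) + np.triu(b, 1).T)
        rho = tad.matrix_bin_correlation(ma, mb)
        assert np.nanmean(np.abs(rho)) < 0.2

    def test_flank_truncation(self):
        m = _matrix(np.eye(6) + 1)
        rho = tad.matrix_bin_correlation(m, m, flank=25)
        assert len(rho) == 6  # no error at the edges

    def test_boundary_correlation_identical(self, planted_hic):
        _, tads_true, cm, _ = planted_hic
        rho = tad.boundary_correlation(cm, cm, tads_true.boundaries[1:-1])
        assert np.all(rho[~np.isnan(rho)] > 0.999999)

    def test_random_baseline_centered(self, planted_hic):
        _, _, cm, _ = planted_hic
        null = tad.random_correlation_baseline(cm, cm, n_iter=300, seed=0)
        assert abs(np.nanmean(null)) < 0.1

    def test_random_baseline_deterministic_and_empty(self, planted_hic):
        _, _, cm, cma = planted_hic
        a = tad.random_correlation_baseline(cm, cma, n_iter=50, seed=5)
        b = tad.random_correlation_baseline(cm, cma, n_iter=50, seed=5)
        assert np.array_equal(a, b, equal_nan=True)
        assert tad.random_correlation_baseline(cm, cma, n_iter=0, seed=1).size == 0


class TestBoundaryOverlap:
    def _tads(self, starts, size=10):
        bs = 40_000
        return TadSet("chrX", bs, [(s * bs, (s + size) * bs) for s in starts])

    def test_identical(self):
        t = self._tads([0, 20, 40])
        frac, pairs = tad.boundary_overlap(t, t)
        assert frac == 1.0

    def test_one_bin_offset_matched(self):
        a = self._tads([0, 20])
        b = self._tads([1, 21])
        frac, _ = tad.boundary_overlap(a, b, tol=40_000)
        assert frac == 1.0  # <= is inclusive

    def test_two_bin_offset_unmatched(self):
        a = self._tads([0])
        b = self._tads([2])
        frac, _ = tad.boundary_overlap(a, b, tol=40_000)
        assert frac == 0.0

    def test_empty_undefined(self):
        a = self._tads([0])
        empty = TadSet("chrX", 40_000, [])
        frac, pairs = tad.boundary_overlap(a, empty)
        assert np.isnan(frac) and pairs == []


class TestGeneAssignment:
    TADS = TadSet("chrX", 40_000, [(0, 400_000), (400_000, 800_000)])

    def test_fully_inside(self):
        g = GeneModel("g", "chrX", "+", 100_000, 150_000)
        out = tad.assign_genes_to_tads([g], self.TADS)
        assert out.iloc[0]["body_tad"] == 0
        assert out.iloc[0]["promoter_tad"] == 0

    def test_straddling_with_upstream_promoter(self):
        g = GeneModel("g", "chrX", "+", 395_000, 500_000)
        out = tad.assign_genes_to_tads([g], self.TADS)
        assert out.iloc[0]["body_tad"] == 1
        assert out.iloc[0]["promoter_tad"] == 0

    def test_gap_unassigned(self):
        tads = TadSet("chrX", 40_000, [(0, 200_000), (600_000, 800_000)])
        g = GeneModel("g", "chrX", "+", 300_000, 350_000)
        out = tad.assign_genes_to_tads([g], tads)
        assert out.iloc[0]["unassigned"]


class TestConcordance:
    def _assignment(self, tads_of):
        return pd.DataFrame({"gene": list(tads_of), "body_tad": list(
            tads_of.values()), "promoter_tad": list(tads_of.values()),
            "unassigned": False})

    def _calls(self, escape_of):
        return pd.DataFrame({"gene": list(escape_of),
                             "is_escape": list(escape_of.values())})

    def test_homogeneous_and_mixed(self):
        assignment = self._assignment({"a": 0, "b": 0, "c": 1, "d": 1})
        calls = self._calls({"a": True, "b": True, "c": True, "d": False})
        out = tad.tad_escape_concordance(assignment, calls).set_index("tad")
        assert out.loc[0, "label"] == "homogeneous-escape"
        assert out.loc[1, "label"] == "mixed"

    def test_uninformative_tads_excluded(self):
        assignment = self._assignment({"a": 0, "b": 1})
        calls = self._calls({"a": False})  # gene b uninformative
        out = tad.tad_escape_concordance(assignment, calls)
        assert list(out["tad"]) == [0]

    def test_planted_regions_concordant(self, pipeline_run):
        # every TAD fully occupied by a planted escape region is scored
        # homogeneous-escape against the called TADs
        results, _ = pipeline_run
        conc = results["tads"]["concordance"]
        assert (conc["label"] == "homogeneous-escape").sum() >= 3
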