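import numpy as np
import pandas as pd
import pytest

from feralscan.depth import (
    DepthMatrix,
    call_pav_genes,
    call_pav_regions,
    cnv_index,
    genotype_deletion,
    normalize_depth,
)
from feralscan.variants import build_windows


def grid5k(length=100_000):
    return build_windows({"chr1A": length}, 5_000)


class TestNormalizeDepth:
    def test_uniform_depth_gives_unit_ncn(self):
        g = grid5k()
        dm = DepthMatrix(np.full((2, g.n_windows), 7.0), ["a", "b"], g)
        ncn, kept = normalize_depth(dm)
        assert np.allclose(ncn, 1.0)

    def test_zero_window_gives_zero_ncn(self):
        g = grid5k()
        depth = np.full((1, g.n_windows), 10.0)
        depth[0, 3] = 0.0
        ncn, _ = normalize_depth(DepthMatrix(depth, ["a"], g))
        assert ncn[0, 3] == 0.0

    def test_scale_invariance(self):
        g = grid5k()
        depth = np.abs(np.random.default_rng(0).normal(10, 2, (1, g.n_windows)))
        n1, _ = normalize_depth(DepthMatrix(depth, ["a"], g))
        n2, _ = normalize_depth(DepthMatrix(2 * depth, ["a"], g))
        assert np.allclose(n1, n2)

    def test_zero_coverage_sample_dropped(self):
        g = grid5k()
        depth = np.vstack([np.full(g.n_windows, 5.0), np.zeros(g.n_windows)])
        with pytest.warns(UserWarning):
            ncn, kept = normalize_depth(DepthMatrix(depth, ["a", "b"], g))
        assert kept == ["a"]


class TestPavRegions:
    def test_selection_thresholds(self):
        g = grid5k(20_000)
        ncn_self = np.array([1.0, 1.0, 0.7, 1.0])
        ncn_other = np.array([0.1, 0.9, 0.1, 0.19])
        calls = call_pav_regions(ncn_self, ncn_other, g)
        starts = {c.start for c in calls}
        assert starts == {0, 15_000}  # window 1 fails lo, window 2 fails hi

    def test_merge_boundary_strict(self):
        # selected windows with a 9,999 bp gap merge; 10,000 bp gap does not
        win = pd.DataFrame(
            {
                "chrom": ["chr1A"] * 4,
                "start": [0, 5_000, 14_999, 30_000],
                "end": [5_000, 10_000, 19_999, 35_000],
            }
        )
        from feralscan.variants import WindowGrid

        g = WindowGrid(windows=win, size=5_000, step=5_000)
        sel_self = np.ones(4)
        merged = call_pav_regions(sel_self, np.zeros(4), g)
        # gaps: 0 (adjacent), 4,999, 10,001 -> first three merge, last apart
        assert [(c.start, c.end, c.n_windows) for c in merged] == [
            (0, 19_999, 3),
            (30_000, 35_000, 1),
        ]
        win2 = win.copy()
        win2.loc[2, "start"], win2.loc[2, "end"] = 20_000, 25_000
        g2 = WindowGrid(windows=win2, size=5_000, step=5_000)
        merged2 = call_pav_regions(np.ones(4), np.zeros(4), g2)
        # gap of exactly 10,000 between 10,000 and 20,000: not merged;
        # the 5,000 gap between 25,000 and 30,000 still merges
        assert [(c.start, c.end, c.n_windows) for c in merged2] == [
            (0, 10_000, 2),
            (20_000, 35_000, 2),
        ]

    def test_truth_recovery_noise_free(self):
        from feralscan.synthetic import (
            CohortConfig,
            DeletionTruth,
            generate_cohort,
            generate_depth_matrix,
        )

        cfg = CohortConfig(
            n_per_group={"DE": 1, "DO": 1},
            chromosomes=[("chr1A", 500_000)],
            n_sites=50,
            deletions=[
                DeletionTruth("chr1A", 100_000, 150_000, "DE", 1.0),
                DeletionTruth("chr1A", 300_000, 320_000, "DE", 1.0),
            ],
            seed=0,
        )
        t, frame, truth = generate_cohort(cfg)
        g = build_windows({"chr1A": 500_000}, 5_000)
        dm = generate_depth_matrix(t.samples, truth, g, 10.0, noise="none")
        carrier = t.samples.index("DE000")
        ncn_other = dm.depth[carrier] / 10.0  # carrier vs its own flat coverage
        calls = call_pav_regions(np.ones(g.n_windows), ncn_other, g)
        assert [(c.start, c.end) for c in calls] == [
            (100_000, 150_000),
            (300_000, 320_000),
        ]

    def test_merge_idempotent_and_order_free(self):
        g = grid5k(50_000)
        rng = np.random.default_rng(1)
        sel = rng.random(g.n_windows) < 0.4
        calls = call_pav_regions(sel.astype(float) * 2, np.zeros(g.n_windows), g)
        # shuffling window rows leaves merged calls unchanged
        perm = rng.permutation(g.n_windows)
        from feralscan.variants import WindowGrid

        g2 = WindowGrid(
            windows=g.windows.iloc[perm].reset_index(drop=True), size=g.size, step=g.step
        )
        calls2 = call_pav_regions(
            (sel.astype(float) * 2)[perm], np.zeros(g.n_windows), g2
        )
        assert [(c.start, c.end) for c in calls] == [(c.start, c.end) for c in calls2]


class TestPavGenes:
    def test_gene_in_deletion_called(self):
        g = grid5k(50_000)
        ncn_other = np.ones(g.n_windows)
        ncn_other[2:6] = 0.0  # 10-30 kb absent
        genes = pd.DataFrame(
            {
                "chrom": ["chr1A", "chr1A"],
                "start": [12_000, 40_000],
                "end": [18_000, 45_000],
                "name": ["geneA", "geneB"],
            }
        )
        out = call_pav_genes(genes, np.ones(g.n_windows), ncn_other, g)
        assert out.loc[out["name"] == "geneA", "pav"].iloc[0]
        assert not out.loc[out["name"] == "geneB", "pav"].iloc[0]

    def test_intermediate_ncn_not_called(self):
        g = grid5k(10_000)
        genes = pd.DataFrame(
            {"chrom": ["chr1A"], "start": [0], "end": [10_000], "name": ["g"]}
        )
        out = call_pav_genes(genes, np.ones(2), np.full(2, 0.5), g)
        assert not out["pav"].iloc[0]

    def test_gene_containment_agrees_with_regions(self):
        g = grid5k(100_000)
        ncn_other = np.ones(g.n_windows)
        ncn_other[4:10] = 0.05
        regions = call_pav_regions(np.ones(g.n_windows), ncn_other, g)
        genes = pd.DataFrame(
            {
                "chrom": ["chr1A"],
                "start": [regions[0].start + 1_000],
                "end": [regions[0].end - 1_000],
                "name": ["inside"],
            }
        )
        out = call_pav_genes(genes, np.ones(g.n_windows), ncn_other, g)
        assert out["pav"].iloc[0]

    def test_zero_length_gene_rejected(self):
        g = grid5k(10_000)
        genes = pd.DataFrame(
            {"chrom": ["chr1A"], "start": [100], "end": [100], "name": ["g"]}
        )
        with pytest.raises(ValueError):
            call_pav_genes(genes, np.ones(2), np.ones(2), g)


class TestCnvIndex:
    def test_sign_convention(self):
        # DE deleted (NCN 0), DO normal (NCN 1) -> +1
        g = grid5k(10_000)
        ncn = np.array([[0.0, 1.0], [1.0, 1.0]])
        track = cnv_index(ncn, ["de1", "do1"], ["de1"], ["do1"], g)
        assert track["cnv_index"].iloc[0] == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        g = grid5k(10_000)
        ncn = np.ones((4, 2))
        track = cnv_index(ncn, list("abcd"), ["a", "b"], ["c", "d"], g)
        assert np.allclose(track["cnv_index"], 0.0)

    def test_swap_antisymmetry(self):
        g = grid5k(20_000)
        rng = np.random.default_rng(2)
        ncn = rng.random((6, 4))
        samples = list("abcdef")
        fwd = cnv_index(ncn, samples, ["a", "b", "c"], ["d", "e", "f"], g)
        rev = cnv_index(ncn, samples, ["d", "e", "f"], ["a", "b", "c"], g)
        assert np.allclose(fwd["cnv_index"], -rev["cnv_index"])

    def test_truth_windows_rank_top(self):
        from feralscan.synthetic import (
            CohortConfig,
            DeletionTruth,
            generate_cohort,
            generate_depth_matrix,
        )

        cfg = CohortConfig(
            n_per_group={"DE": 20, "DO": 20},
            chromosomes=[("chr1A", 1_000_000)],
            n_sites=50,
            deletions=[DeletionTruth("chr1A", 300_000, 400_000, "DE", 0.9)],
            seed=3,
        )
        t, frame, truth = generate_cohort(cfg)
        g = build_windows({"chr1A": 1_000_000}, 100_000)
        dm = generate_depth_matrix(t.samples, truth, g, 10.0, seed=4)
        ncn, kept = normalize_depth(dm)
        de = frame.loc[frame["group"] == "DE", "sample"].tolist()
        do = frame.loc[frame["group"] == "DO", "sample"].tolist()
        track = cnv_index(ncn, kept, de, do, g)
        assert track["cnv_index"].idxmax() == 3  # the 300-400 kb window


class TestGenotypeDeletion:
    def test_threshold_bands(self):
        g = grid5k(10_000)
        ncn = np.array([[0.05, 0.05], [0.95, 0.95], [0.5, 0.5]])
        out = genotype_deletion(ncn, ["a", "b", "c"], g, "chr1A", 0, 10_000)
        assert list(out["call"]) == ["deleted", "present", "unknown"]

    def test_region_outside_grid_rejected(self):
        g = grid5k(10_000)
        with pytest.raises(ValueError):
            genotype_deletion(np.ones((1, 2)), ["a"], g, "chr9Z", 0, 1_000)

    def test_truth_recovery_noise_free(self):
        from feralscan.synthetic import (
            CohortConfig,
            DeletionTruth,
            generate_cohort,
            generate_depth_matrix,
        )

        cfg = CohortConfig(
            n_per_group={"DE": 50, "DO": 52},
            chromosomes=[("chr3D", 60_000_000)],
            n_sites=50,
            deletions=[DeletionTruth("chr3D", 55_500_000, 56_300_000, "DE", 1.0)],
            seed=5,
        )
        t, frame, truth = generate_cohort(cfg)
        g = build_windows({"chr3D": 60_000_000}, 100_000)
        dm = generate_depth_matrix(t.samples, truth, g, 10.0, noise="none")
        ncn, kept = normalize_depth(dm)
        out = genotype_deletion(ncn, kept, g, "chr3D", 55_500_000, 56_300_000)
        called = set(out.loc[out["call"] == "deleted", "sample"])
        assert called == truth.deletions[0][1]
        assert len(called) == 50
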