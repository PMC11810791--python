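"""Copy-number ratios, segmentation, and concordance: oracles and invariances."""

import numpy as np
import pytest

from igcpipe import presets
from igcpipe.cnv import (
    BinGrid,
    concordance,
    concordance_matrix,
    group_concordance_test,
    normalize_ratios,
    segment_profile,
)
from igcpipe.synth.cn import CNGroundTruth, quadratic_gc_bias, simulate_cn_cells


def uniform_grid(n_bins=400, chrom="chr1", bin_len=1000):
    starts = np.arange(n_bins) * bin_len
    return BinGrid(
        np.array([chrom] * n_bins, dtype=object),
        starts,
        starts + bin_len,
        np.full(n_bins, 0.45),
    )


class TestBinGrid:
    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            BinGrid(
                np.array(["chr1", "chr1"], dtype=object),
                np.array([0, 500]),
                np.array([1000, 1500]),
                np.array([0.4, 0.4]),
            )

    def test_tsv_round_trip(self, tmp_path):
        grid = uniform_grid(10)
        grid.to_tsv(tmp_path / "bins.tsv")
        back = BinGrid.from_tsv(tmp_path / "bins.tsv")
        np.testing.assert_array_equal(back.start, grid.start)
        np.testing.assert_allclose(back.gc, grid.gc)


class TestNormalizeRatios:
    def test_uniform_counts_give_unit_ratios(self):
        grid = uniform_grid(100)
        prof = normalize_ratios(np.full(100, 50.0), grid)
        np.testing.assert_allclose(prof.ratio, 1.0)

    def test_depth_and_wgd_scale_invariance(self):
        grid = uniform_grid(100)
        rng = np.random.default_rng(1)
        counts = rng.poisson(100, 100).astype(float) + 1
        a = normalize_ratios(counts, grid)
        b = normalize_ratios(2 * counts, grid)
        np.testing.assert_allclose(a.ratio, b.ratio)

    def test_median_is_one(self):
        grid = uniform_grid(101)
        counts = np.random.default_rng(2).poisson(80, 101).astype(float) + 1
        prof = normalize_ratios(counts, grid)
        assert np.median(prof.ratio) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_ratios(np.zeros(50), uniform_grid(50))

    def test_gc_correction_flattens_planted_bias(self):
        truth = presets.pc3_cn_preset()
        bias = quadratic_gc_bias(strength=0.8)
        counts = simulate_cn_cells(truth, 1, seed=3, gc_bias=bias).iloc[0].to_numpy()
        raw = normalize_ratios(counts, truth.grid, gc_correct=False)
        corr = normalize_ratios(counts, truth.grid, gc_correct=True)
        base = truth.cn_states == 2
        # corrected baseline bins hug ratio 1 more tightly than uncorrected
        assert np.std(corr.ratio[base]) < np.std(raw.ratio[base])


class TestSegmentation:
    def test_flat_profile_single_segment_per_chromosome(self):
        grid = uniform_grid(60)
        prof = normalize_ratios(np.full(60, 100.0), grid)
        seg = segment_profile(prof, seed=0)
        assert len(np.unique(seg.segment_id)) == 1

    def test_noise_free_step_exact_breakpoint(self):
        grid = uniform_grid(400)
        counts = np.where(np.arange(400) < 200, 100.0, 150.0)
        prof = normalize_ratios(counts, grid)
        seg = segment_profile(prof, seed=0)
        ids = seg.segment_id
        assert len(np.unique(ids)) == 2
        assert int(np.flatnonzero(np.diff(ids))[0]) + 1 == 200
        np.testing.assert_allclose(
            np.unique(seg.segment_ratio), sorted([prof.ratio[:200].mean(), prof.ratio[200:].mean()])
        )

    def test_pc3_preset_segment_means(self):
        truth = presets.pc3_cn_preset()
        counts = simulate_cn_cells(truth, 1, seed=17).iloc[0].to_numpy()
        prof = segment_profile(normalize_ratios(counts, truth.grid), seed=17)
        chr1 = truth.grid.chrom == "chr1"
        chr10 = truth.grid.chrom == "chr10"
        assert prof.segment_ratio[chr1].mean() == pytest.approx(1.5, rel=0.10)
        assert prof.segment_ratio[chr10].mean() == pytest.approx(0.5, rel=0.10)


class TestConcordance:
    def test_identical_profiles_give_one(self):
        grid = uniform_grid(50)
        counts = np.random.default_rng(4).poisson(100, 50).astype(float) + 1
        p = normalize_ratios(counts, grid)
        assert concordance(p, p) == pytest.approx(1.0)

    def test_wgd_copy_gives_one(self):
        grid = uniform_grid(50)
        counts = np.random.default_rng(5).poisson(100, 50).astype(float) + 1
        a = normalize_ratios(counts, grid)
        b = normalize_ratios(2 * counts, grid)
        assert concordance(a, b) == pytest.approx(1.0)

    def test_hand_profiles_match_direct_pearson(self):
        grid = uniform_grid(6)
        ra = np.array([1.0, 1.0, 1.5, 1.5, 0.5, 0.5])
        rb = np.array([1.0, 1.2, 1.4, 1.6, 0.6, 0.4])
        pa = normalize_ratios(ra * 1000, grid)
        pb = normalize_ratios(rb * 1000, grid)
        # brute-force Pearson from the definition, on log2(ratio + 0.01)
        xa = np.log2(pa.ratio + 0.01)
        xb = np.log2(pb.ratio + 0.01)
        num = np.sum((xa - xa.mean()) * (xb - xb.mean()))
        den = np.sqrt(np.sum((xa - xa.mean()) ** 2) * np.sum((xb - xb.mean()) ** 2))
        assert concordance(pa, pb) == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_profile_flagged_nan(self):
        grid = uniform_grid(20)
        flat = normalize_ratios(np.full(20, 100.0), grid)
        other = normalize_ratios(np.arange(1.0, 21.0), grid)
        assert np.isnan(concordance(flat, other))

    def test_symmetry(self):
        grid = uniform_grid(30)
        rng = np.random.default_rng(6)
        a = normalize_ratios(rng.poisson(100, 30) + 1.0, grid)
        b = normalize_ratios(rng.poisson(100, 30) + 1.0, grid)
        assert concordance(a, b) == pytest.approx(concordance(b, a))


class TestGroupConcordance:
    def _profiles(self, mat, grid):
        return [normalize_ratios(row, grid, cell_id=str(i)) for i, row in enumerate(mat)]

    def test_identical_cells_degenerate_ties(self):
        grid = uniform_grid(40)
        base = np.random.default_rng(7).poisson(100, 40).astype(float) + 1
        profs = self._profiles([base] * 6, grid)
        mat = concordance_matrix(profs, ["A"] * 3 + ["B"] * 3)
        res = group_concordance_test(mat, "A", "B")
        assert all(m == pytest.approx(1.0) for m in res["medians"].values())
        assert all(c["p"] == 1.0 for c in res["comparisons"])

    def test_two_clones_cross_group_lower(self):
        truth = presets.pc3_cn_preset()
        grid = truth.grid
        states2 = truth.cn_states.copy()
        states2[grid.chrom == "chr3"] = 4  # second clone gains chr3
        truth2 = CNGroundTruth(grid=grid, cn_states=states2, reads_per_cell=200_000)
        truth1 = CNGroundTruth(grid=grid, cn_states=truth.cn_states, reads_per_cell=200_000)
        profs = []
        for t, seed in [(truth1, 10), (truth2, 20)]:
            counts = simulate_cn_cells(t, 3, seed=seed)
            for cid, row in counts.iterrows():
                profs.append(
                    segment_profile(normalize_ratios(row.to_numpy(), grid, cell_id=f"{seed}_{cid}"), seed=0)
                )
        mat = concordance_matrix(profs, ["A"] * 3 + ["B"] * 3)
        res = group_concordance_test(mat, "A", "B")
        assert res["medians"]["cross"] < res["medians"]["within_A"]
        assert res["medians"]["cross"] < res["medians"]["within_B"]

    def test_small_group_warns(self):
        grid = uniform_grid(40)
        rng = np.random.default_rng(8)
        profs = self._profiles(rng.poisson(100, (4, 40)) + 1.0, grid)
        mat = concordance_matrix(profs, ["A", "B", "B", "B"])
        with pytest.warns(UserWarning, match="within-group comparison omitted"):
            res = group_concordance_test(mat, "A", "B")
        assert "within_A" not in res["medians"]
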