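"""Generators: determinism, planted structure, and validation errors."""

import numpy as np
import pytest

from igcpipe import imaging, presets
from igcpipe.synth.cn import CNGroundTruth, simulate_cn_cells
from igcpipe.synth.cohort import CohortPreset, simulate_cohort
from igcpipe.synth.rna import Program, RNAPreset, simulate_rna_counts
from igcpipe.synth.slides import CellClassSpec, SlideSpec, render_slide

from conftest import small_slide_spec


class TestRenderSlide:
    def test_zero_cells_pure_background(self):
        spec = SlideSpec(width=64, height=64, cell_classes=[], noise_sd=0.0,
                         background_level=150.0, seed=1)
        image, truth = render_slide(spec)
        assert len(truth) == 0
        for ch in image.channels.values():
            np.testing.assert_allclose(ch, 150.0)

    def test_single_ctc_diameter_forced(self):
        spec = SlideSpec(
            width=96, height=96, seed=3, noise_sd=0.0,
            cell_classes=[CellClassSpec(
                "CTC", 1, 15.0, 0.0, 22.0, 0.0,
                {"DAPI": 3000.0, "EPI": 3000.0, "CD45": 0.0, "VAR": 0.0})],
        )
        image, truth = render_slide(spec)
        mask = imaging.segment_channel(image.channel("DAPI"), offset=1000.0)
        d = imaging.equivalent_diameter(mask.mask.sum(), spec.pixel_size)
        assert d == pytest.approx(15.0, abs=1.0)

    def test_seed_determinism_byte_identical(self):
        spec = small_slide_spec(seed=9)
        img1, t1 = render_slide(spec)
        img2, t2 = render_slide(spec)
        for ch in img1.channels:
            np.testing.assert_array_equal(img1.channel(ch), img2.channel(ch))
        assert t1.equals(t2)

    def test_ground_truth_counts_match_spec(self):
        spec = small_slide_spec(seed=5, igc=1, wbc=40, ctc=6)
        _, truth = render_slide(spec)
        counts = truth["label"].value_counts().to_dict()
        assert counts == {"WBC": 40, "CTC": 6, "CTC_IGC": 1}

    def test_infeasible_packing_raises(self):
        spec = SlideSpec(
            width=70, height=70, seed=0,
            cell_classes=[CellClassSpec(
                "WBC", 40, 8.0, 0.1, 10.0, 0.1,
                {"DAPI": 3000.0, "EPI": 0.0, "CD45": 3000.0, "VAR": 0.0})],
        )
        with pytest.raises(RuntimeError, match="overlap|crowded"):
            render_slide(spec)

    def test_igc_doubling_invariant_enforced(self):
        ctc = CellClassSpec("CTC", 1, 12.0, 0.1, 20.0, 0.1, {"DAPI": 3000.0})
        igc = CellClassSpec("CTC_IGC", 1, 20.0, 0.1, 30.0, 0.1, {"DAPI": 3000.0})
        with pytest.raises(ValueError, match="2x"):
            SlideSpec(width=200, height=200, cell_classes=[ctc, igc])


class TestSimulateCNCells:
    def test_uniform_state_proportions_follow_length(self):
        from igcpipe.cnv import BinGrid

        starts = np.array([0, 1000, 4000])
        grid = BinGrid(np.array(["chr1"] * 3, dtype=object), starts,
                       np.array([1000, 4000, 8000]), np.full(3, 0.45))
        truth = CNGroundTruth(grid=grid, cn_states=np.array([2, 2, 2]),
                              reads_per_cell=100_000)
        np.testing.assert_allclose(truth.bin_probabilities(), [1 / 8, 3 / 8, 4 / 8])

    def test_wgd_leaves_probabilities_and_draws_unchanged(self):
        truth1 = presets.pc3_cn_preset(wgd_factor=1)
        truth2 = presets.pc3_cn_preset(wgd_factor=2)
        np.testing.assert_allclose(truth1.bin_probabilities(), truth2.bin_probabilities())
        c1 = simulate_cn_cells(truth1, 2, seed=12)
        c2 = simulate_cn_cells(truth2, 2, seed=12)
        assert c1.equals(c2)

    def test_pc3_chr1_chr10_count_ratio(self):
        truth = presets.pc3_cn_preset()
        counts = simulate_cn_cells(truth, 50, seed=21)
        mean_per_bin = counts.to_numpy().mean(axis=0)
        chr1 = mean_per_bin[truth.grid.chrom == "chr1"].mean()
        chr10 = mean_per_bin[truth.grid.chrom == "chr10"].mean()
        assert chr1 / chr10 == pytest.approx(3.0, rel=0.05)

    def test_all_zero_states_rejected(self):
        truth = presets.pc3_cn_preset()
        bad = CNGroundTruth(grid=truth.grid, cn_states=np.zeros(len(truth.grid), int))
        with pytest.raises(ValueError, match="all-zero"):
            simulate_cn_cells(bad, 1, seed=0)

    def test_invalid_args(self):
        truth = presets.pc3_cn_preset()
        with pytest.raises(ValueError):
            simulate_cn_cells(truth, 0, seed=0)
        with pytest.raises(ValueError):
            CNGroundTruth(grid=truth.grid, cn_states=truth.cn_states, wgd_factor=0)


class TestSimulateRNA:
    def test_planted_fold_change_recovered_in_count_space(self):
        preset = RNAPreset(
            n_genes=300,
            conditions={"CTRL": 40, "TREAT": 40},
            programs=[Program("one", np.array([7]), 3.0, ["TREAT"])],
            dispersion=0.1,
            program_baseline=(3.0, 4.0),
        )
        counts, meta, _ = simulate_rna_counts(preset, seed=4)
        g = counts.iloc[7]
        ratio = g[meta["condition"] == "TREAT"].mean() / g[meta["condition"] == "CTRL"].mean()
        assert ratio == pytest.approx(8.0, rel=0.25)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match=">= 3.0"):
            Program("weak", np.array([0]), 1.0, ["A"])
        with pytest.raises(ValueError, match=">= 20"):
            RNAPreset(n_genes=10, conditions={"A": 5}, programs=[])
        with pytest.raises(ValueError, match="universe"):
            RNAPreset(n_genes=10, conditions={"A": 20},
                      programs=[Program("p", np.array([99]), 3.0, ["A"])])

    def test_determinism(self):
        preset = presets.rna_null_preset(n_genes=100, n_cells=20)
        c1, *_ = simulate_rna_counts(preset, seed=8)
        c2, *_ = simulate_rna_counts(preset, seed=8)
        assert c1.equals(c2)


class TestSimulateCohort:
    def test_preset_A_patient_counts(self):
        cohort, slides = simulate_cohort(presets.cohort_preset_A(), seed=17)
        assert cohort["matched"].sum() == 31
        assert (~cohort["matched"]).sum() == 13
        matched = cohort[cohort["matched"]]
        assert matched["blood_igc_truth"].sum() == 3
        assert matched["marrow_igc_truth"].sum() == 25
        assert all(s["marrow"] is not None for s in slides.values())
        assert sum(s["blood"] is not None for s in slides.values()) == 31

    def test_zero_positive_preset_all_negative(self):
        preset = CohortPreset(n_matched=4, n_marrow_only=2, blood_igc_positive=0,
                              marrow_igc_positive=0, marrow_only_igc_positive=0,
                              wbc_per_slide=10, ctc_per_slide=3,
                              slide_width=300, slide_height=300)
        cohort, slides = simulate_cohort(preset, seed=1)
        assert not cohort["blood_igc_truth"].any()
        assert not cohort["marrow_igc_truth"].any()
        _, truth = render_slide(slides["P001"]["marrow"])
        assert "CTC_IGC" not in truth["label"].tolist()

    def test_positive_slides_carry_planted_igc(self):
        preset = presets.cohort_preset_A()
        cohort, slides = simulate_cohort(preset, seed=17)
        pid = cohort.loc[cohort["marrow_igc_truth"], "patient_id"].iloc[0]
        _, truth = render_slide(slides[pid]["marrow"])
        counts = truth["label"].value_counts()
        assert counts["CTC_IGC"] == preset.igc_per_positive_slide
        assert counts["CTC"] == preset.ctc_per_slide
        assert counts["WBC"] == preset.wbc_per_slide

    def test_validation(self):
        with pytest.raises(ValueError):
            CohortPreset(n_matched=4, n_marrow_only=0, blood_igc_positive=5,
                         marrow_igc_positive=5)
        with pytest.raises(ValueError, match="faster"):
            CohortPreset(n_matched=4, n_marrow_only=0, blood_igc_positive=0,
                         marrow_igc_positive=1, hazard_pos=0.01, hazard_neg=0.02)


def test_mtx_round_trip(tmp_path):
    from igcpipe.synth.rna import read_counts_mtx, write_counts_mtx

    preset = presets.rna_null_preset(n_genes=50, n_cells=20)
    counts, cell_meta, gene_meta = simulate_rna_counts(preset, seed=6)
    write_counts_mtx(counts, cell_meta, gene_meta, tmp_path / "mtx")
    back_counts, back_cells, back_genes = read_counts_mtx(tmp_path / "mtx")
    assert back_counts.equals(counts)
    assert list(back_cells["condition"]) == list(cell_meta["condition"])
    assert list(back_genes["biotype"]) == list(gene_meta["biotype"])
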