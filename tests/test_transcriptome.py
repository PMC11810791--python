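"""Differential expression, set intersections, enrichment, and scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from igcpipe import presets
from igcpipe.synth.rna import Program, RNAPreset, simulate_rna_counts
from igcpipe.transcriptome import (
    biotype_breakdown,
    de_test,
    normalize_cpm,
    overrepresentation,
    read_gmt,
    shared_upregulated,
    signature_score,
    up_genes,
    write_gmt,
)


class TestNormalizeCPM:
    def test_single_gene_takes_whole_library(self):
        counts = pd.DataFrame({"c1": [10, 0]}, index=["g1", "g2"])
        out = normalize_cpm(counts)
        assert out.loc["g1", "c1"] == pytest.approx(np.log2(1 + 1e6))

    def test_depth_invariance(self):
        counts = pd.DataFrame({"c1": [10, 30], "c2": [20, 60]}, index=["g1", "g2"])
        out = normalize_cpm(counts)
        np.testing.assert_allclose(out["c1"], out["c2"])

    def test_hand_matrix(self):
        counts = pd.DataFrame({"c1": [1, 3, 0], "c2": [2, 2, 4]}, index=list("abc"))
        out = normalize_cpm(counts)
        assert out.loc["a", "c1"] == pytest.approx(np.log2(1 + 1e6 * 1 / 4))
        assert out.loc["c", "c2"] == pytest.approx(np.log2(1 + 1e6 * 4 / 8))

    def test_zero_libsize_names_cell(self):
        counts = pd.DataFrame({"good": [1], "empty": [0]}, index=["g"])
        with pytest.raises(ValueError, match="empty"):
            normalize_cpm(counts)


class TestBenjaminiHochberg:
    def test_hand_vector(self):
        # step-up BH on {0.001, 0.01, 0.02, 0.8} with m = 4
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.001, 0.01, 0.02, 0.8], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.004, 0.02, 0.0266667, 0.8], rtol=1e-5)


class TestDETest:
    def _null_counts(self, seed=0, n_genes=400, n=30):
        preset = presets.rna_null_preset(n_genes=n_genes, n_cells=n)
        return simulate_rna_counts(preset, seed=seed)

    def test_identical_groups_nothing_passes(self):
        counts, meta, _ = self._null_counts(seed=3)
        de = de_test(counts, meta["condition"], "CTRL", "TREAT", batch=meta["batch"])
        assert len(up_genes(de)) == 0

    def test_planted_gene_passes_thresholds(self):
        preset = RNAPreset(
            n_genes=500,
            conditions={"CTRL": 40, "TREAT": 40},
            programs=[Program("p", np.array([5, 6, 7]), 3.0, ["TREAT"])],
        )
        counts, meta, _ = simulate_rna_counts(preset, seed=11)
        de = de_test(counts, meta["condition"], "CTRL", "TREAT", batch=meta["batch"])
        assert {"gene_00005", "gene_00006", "gene_00007"} <= up_genes(de)

    def test_group_too_small_rejected(self):
        counts, meta, _ = self._null_counts()
        bad = meta["condition"].copy()
        bad.iloc[:] = "CTRL"
        bad.iloc[0] = "TREAT"
        with pytest.raises(ValueError, match="cells per group"):
            de_test(counts, bad, "CTRL", "TREAT")

    def test_detection_filter_excludes_silent_genes(self):
        counts, meta, _ = self._null_counts(seed=5)
        counts.iloc[0, :] = 0  # silent everywhere
        de = de_test(counts, meta["condition"], "CTRL", "TREAT")
        assert not de.iloc[0]["tested"]
        assert np.isnan(de.iloc[0]["p"])

    def test_label_permutation_p_uniform(self):
        counts, meta, _ = self._null_counts(seed=7, n_genes=600, n=25)
        de = de_test(counts, meta["condition"], "CTRL", "TREAT")
        p = de.loc[de["tested"], "p"].dropna()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestSharedUpregulated:
    def _fake_de(self, genes_up, universe=("a", "b", "c", "d", "e")):
        df = pd.DataFrame(
            {"lfc": 0.0, "p": 0.9, "q": 0.9, "tested": True}, index=list(universe)
        )
        df.loc[list(genes_up), ["lfc", "q"]] = [3.0, 1e-6]
        return df

    def test_pairwise_intersection(self):
        res = shared_upregulated(
            {"d1": self._fake_de({"a", "b", "c"}), "d2": self._fake_de({"b", "c", "d"})},
            lines={"L": ["d1", "d2"]},
        )
        assert res.line_sets["L"] == {"b", "c"}
        assert res.survivor_set == {"b", "c"}

    def test_disjoint_sets_empty_survivor(self):
        res = shared_upregulated(
            {"d1": self._fake_de({"a"}), "d2": self._fake_de({"b"})},
            lines={"L1": ["d1"], "L2": ["d2"]},
        )
        assert res.survivor_set == set()

    def test_missing_comparison_rejected(self):
        with pytest.raises(KeyError, match="d2"):
            shared_upregulated({"d1": self._fake_de({"a"})}, lines={"L": ["d1", "d2"]})

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(13)
        de = {
            k: pd.DataFrame(
                {
                    "lfc": rng.normal(1.5, 1.0, 200),
                    "q": rng.uniform(0, 0.05, 200),
                    "tested": True,
                },
                index=[f"g{i}" for i in range(200)],
            )
            for k in ["a1", "a2", "b1", "b2"]
        }
        lines = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        strict = shared_upregulated(de, lines, lfc_thresh=1.5, fdr_thresh=0.01)
        relaxed = shared_upregulated(de, lines, lfc_thresh=1.0, fdr_thresh=0.03)
        assert strict.survivor_set <= relaxed.survivor_set
        for line in lines:
            assert strict.line_sets[line] <= relaxed.line_sets[line]


class TestBiotypeBreakdown:
    def test_all_protein_coding(self):
        bt = pd.Series("protein_coding", index=["g1", "g2"])
        out = biotype_breakdown(["g1", "g2"], bt)
        assert out.loc[0, "percent"] == 100.0

    def test_empty_set(self):
        out = biotype_breakdown([], pd.Series(dtype=object))
        assert len(out) == 0
        assert out.attrs["n_genes"] == 0

    def test_unannotated_counted_as_tec(self):
        bt = pd.Series({"g1": "protein_coding"})
        out = biotype_breakdown(["g1", "gX"], bt).set_index("biotype")
        assert out.loc["TEC", "count"] == 1


class TestOverrepresentation:
    def test_query_equals_set_is_top_hit(self):
        universe = [f"g{i}" for i in range(100)]
        query = set(universe[:10])
        lib = {"hit": set(universe[:10]), "decoy": set(universe[50:90])}
        out = overrepresentation(query, universe, lib)
        assert out.iloc[0]["set"] == "hit"
        assert out.iloc[0]["p"] < out.iloc[1]["p"]

    def test_fisher_matches_hypergeometric_tail(self):
        # 2x2 table (10, 90, 40, 860): brute-force tail of the hypergeometric
        universe = [f"g{i}" for i in range(1000)]
        lib_set = set(universe[:100])
        query = set(universe[:10]) | set(universe[100:140])
        out = overrepresentation(query, universe, {"s": lib_set}).iloc[0]
        expected = sum(
            stats.hypergeom.pmf(k, 1000, 100, 50) for k in range(10, 51)
        )
        assert out["overlap"] == 10
        assert out["p"] == pytest.approx(expected, rel=1e-8)

    def test_disjoint_set_null_result(self):
        universe = [f"g{i}" for i in range(50)]
        out = overrepresentation(universe[:5], universe, {"s": universe[40:]}).iloc[0]
        assert out["odds_ratio"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation([], [], {"s": ["a"]})


class TestSignatureScore:
    def _logcpm(self, seed=0, n_genes=60, n_cells=30):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.poisson(3, (n_genes, n_cells)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"c{i}" for i in range(n_cells)],
        )
        return normalize_cpm(counts)

    def test_bounded_unit_interval(self):
        x = self._logcpm()
        s = signature_score(x, [f"g{i}" for i in range(10)])
        assert ((s >= 0) & (s <= 1)).all()

    def test_on_cells_score_higher_than_off_cells(self):
        preset = RNAPreset(
            n_genes=400,
            conditions={"OFF": 40, "ON": 40},
            programs=[Program("sig", np.arange(20), 3.0, ["ON"])],
        )
        counts, meta, _ = simulate_rna_counts(preset, seed=2)
        scores = signature_score(normalize_cpm(counts), [f"gene_{i:05d}" for i in range(20)])
        on = scores[meta["condition"] == "ON"].mean()
        off = scores[meta["condition"] == "OFF"].mean()
        assert on > off

    def test_signature_all_genes_degenerate_warns(self):
        # with every gene expressed in every cell and the signature covering
        # all genes, the rank component is identical across cells
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(3, (20, 10)) + 1,
            index=[f"g{i}" for i in range(20)],
            columns=[f"c{i}" for i in range(10)],
        )
        x = normalize_cpm(counts)
        with pytest.warns(UserWarning, match="degenerate"):
            s = signature_score(x, list(x.index))
        assert ((s >= 0) & (s <= 1)).all()

    def test_single_cell_returns_half_with_warning(self):
        x = self._logcpm(n_genes=30, n_cells=1)
        with pytest.warns(UserWarning, match="degenerate"):
            s = signature_score(x, ["g0", "g1"])
        assert s.iloc[0] == pytest.approx(0.5)

    def test_no_signature_gene_rejected(self):
        x = self._logcpm()
        with pytest.raises(ValueError):
            signature_score(x, ["absent_gene"])


def test_gmt_round_trip(tmp_path):
    lib = {"setA": {"g1", "g2"}, "setB": {"g3"}}
    path = tmp_path / "lib.gmt"
    write_gmt(lib, path)
    assert read_gmt(path) == lib
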