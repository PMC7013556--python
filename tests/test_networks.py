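"""TR co-expression network, footprint edges, coverage, disease overlay."""

import numpy as np
import pandas as pd
import pytest

from tests.helpers import all_pairs_edges
from trophodiff.networks import (
    FootprintEdgeSet,
    attach_correlations,
    build_tr_coexpression_network,
    discordance_tightness,
    disease_overlay,
    footprint_edge_map,
    module_coverage_report,
    promoter_window,
    tr_timing,
)


def _profiles(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T.astype(float)


class TestCoexpressionNetwork:
    def test_identical_profiles_fully_connected(self):
        days = np.arange(8.0)
        prof = _profiles({f"g{i}": days + i for i in range(6)})  # r = 1 pairs
        tr = pd.Series([True, True] + [False] * 4, index=prof.index)
        net = build_tr_coexpression_network(prof, prof.index, tr)
        assert (net.connectivity() == 5).all()

    def test_anticorrelated_pair_connected_by_absolute_rule(self):
        days = np.arange(8.0)
        prof = _profiles({"t": days, "g": -days})
        tr = pd.Series([True, False], index=["t", "g"])
        net = build_tr_coexpression_network(prof, prof.index, tr)
        assert net.graph.has_edge("t", "g")
        assert net.graph.edges["t", "g"]["r"] == pytest.approx(-1.0)

    def test_no_tr_genes_warns_empty(self):
        prof = _profiles({"a": np.arange(8.0), "b": np.arange(8.0)})
        with pytest.warns(UserWarning, match="TR"):
            net = build_tr_coexpression_network(
                prof, prof.index, pd.Series(False, index=prof.index))
        assert net.graph.number_of_edges() == 0

    def test_edges_match_bruteforce_all_pairs(self, small_synthetic):
        _, expr, ann, truth, de = small_synthetic
        de_genes = de.de_genes()[:150]
        prof = expr.day_means(genes=de_genes)
        tr = ann.loc[de_genes, "is_tr"]
        net = build_tr_coexpression_network(prof, de_genes, tr, r_min=0.9)
        expected = all_pairs_edges(prof, list(de_genes[tr]), 0.9)
        got = {frozenset((u, v)) for u, v in net.graph.edges}
        assert got == expected

    def test_connectivity_invariant_to_relabeling(self, small_synthetic):
        _, expr, ann, truth, de = small_synthetic
        de_genes = de.de_genes()[:100]
        prof = expr.day_means(genes=de_genes)
        tr = ann.loc[de_genes, "is_tr"]
        net1 = build_tr_coexpression_network(prof, de_genes, tr)
        rename = {g: f"x_{g}" for g in prof.index}
        prof2 = prof.rename(index=rename)
        tr2 = tr.rename(index=rename)
        net2 = build_tr_coexpression_network(
            prof2, [rename[g] for g in de_genes], tr2)
        k1 = sorted(net1.connectivity())
        k2 = sorted(net2.connectivity())
        assert k1 == k2


class TestTRTiming:
    def test_immediate_slow_and_non_de_assignment(self, noise_free_data):
        expr, ann, truth = noise_free_data
        from trophodiff.de import build_de_table
        de = build_de_table(expr)
        timing = tr_timing(de, ann["is_tr"])
        arche = truth.module_label.map(truth.archetype)
        for gene in timing["day1"]:
            assert arche[gene].startswith("immediate")
        for gene in timing["later"]:
            assert arche[gene] == "slow_persistent_up"
        non_de = set(truth.genes[~de.is_de])
        assert not (timing["day1"] | timing["later"]) & non_de

    def test_slow_gene_crossing_on_day3_in_later_set(self):
        # slow ramp: |log2FC| crosses 1.0 between day 2 (0.8) and day 3 (1.2)
        from tests.conftest import matrix_from_day_values
        from trophodiff.de import build_de_table
        vals = {d: np.repeat([[8.0 + 2.0 * min(d / 5, 1),
                               8.0]], 3, axis=0).T.reshape(2, 3)
                for d in range(8)}
        expr = matrix_from_day_values(vals)
        de = build_de_table(expr)
        timing = tr_timing(de, pd.Series([True, True], index=expr.genes))
        assert "g0" in timing["later"] and "g1" not in (timing["day1"]
                                                        | timing["later"])


class TestFootprintEdges:
    bed_cols = ["chrom", "start", "end", "name", "score", "strand"]

    def _frame(self, rows):
        return pd.DataFrame(rows, columns=self.bed_cols)

    def test_interval_arithmetic_example(self):
        footprints = self._frame([("chr1", 100, 120, "fp", ".", ".")])
        motifs = self._frame([("chr1", 105, 115, "TFX", ".", ".")])
        tss = self._frame([("chr1", 5000, 5001, "geneA", ".", "+")])
        edges = footprint_edge_map(footprints, motifs, tss)
        assert edges.edge_pairs() == {("TFX", "geneA")}

    def test_motif_outside_footprint_no_edge(self):
        footprints = self._frame([("chr1", 100, 120, "fp", ".", ".")])
        motifs = self._frame([("chr1", 300, 310, "TFX", ".", ".")])
        tss = self._frame([("chr1", 5000, 5001, "geneA", ".", "+")])
        assert footprint_edge_map(footprints, motifs, tss).edge_pairs() == set()

    def test_motif_outside_promoter_no_edge(self):
        footprints = self._frame([("chr1", 50000, 50020, "fp", ".", ".")])
        motifs = self._frame([("chr1", 50005, 50015, "TFX", ".", ".")])
        tss = self._frame([("chr1", 5000, 5001, "geneA", ".", "+")])
        assert footprint_edge_map(footprints, motifs, tss).edge_pairs() == set()

    def test_minus_strand_window_reflection(self):
        # gene on '-' strand at 10000: upstream = larger coordinates
        footprints = self._frame([("chr1", 12000, 12030, "fp", ".", ".")])
        motifs = self._frame([("chr1", 12005, 12015, "TFX", ".", ".")])
        tss = self._frame([("chr1", 10000, 10001, "geneB", ".", "-")])
        edges = footprint_edge_map(footprints, motifs, tss)
        assert edges.edge_pairs() == {("TFX", "geneB")}
        ws, we = promoter_window(10000, "-", (-5000, 1000))
        assert (we - ws) == 6000 and ws <= 12005 and 12015 <= we

    def test_union_vs_intersection_of_footprint_files(self):
        fp1 = self._frame([("chr1", 100, 120, "fp", ".", ".")])
        fp2 = self._frame([("chr1", 110, 130, "fp", ".", ".")])
        motifs = self._frame([("chr1", 100, 108, "TFX", ".", ".")])
        tss = self._frame([("chr1", 3000, 3001, "geneA", ".", "+")])
        union = footprint_edge_map([fp1, fp2], motifs, tss, mode="union")
        inter = footprint_edge_map([fp1, fp2], motifs, tss, mode="intersection")
        assert union.edge_pairs() == {("TFX", "geneA")}
        assert inter.edge_pairs() == set()   # shared footprint is [110,120)

    def test_order_invariance_and_duplicate_collapse(self):
        footprints = self._frame([("chr1", 100, 140, "fp", ".", ".")])
        motifs = self._frame([
            ("chr1", 105, 115, "TFX", ".", "."),
            ("chr1", 120, 130, "TFX", ".", "."),
        ])
        tss = self._frame([("chr1", 3000, 3001, "geneA", ".", "+")])
        e1 = footprint_edge_map(footprints, motifs, tss)
        e2 = footprint_edge_map(footprints, motifs.iloc[::-1], tss)
        assert e1.edges["n_support"].tolist() == [2]
        pd.testing.assert_frame_equal(
            e1.edges[["tf", "target", "n_support"]],
            e2.edges[["tf", "target", "n_support"]])


class TestAttachCorrelations:
    def _edge_set(self):
        return FootprintEdgeSet(pd.DataFrame(
            [("tfA", "g1", "chr1", 0, 10, 0, 20, 1),
             ("tfB", "g2", "chr1", 0, 10, 0, 20, 1)],
            columns=["tf", "target", "motif_chrom", "motif_start", "motif_end",
                     "fp_start", "fp_end", "n_support"]))

    def test_identical_profiles_retained_with_r1(self):
        days = np.arange(8.0)
        prof = _profiles({"tfA": days, "g1": 2 * days, "tfB": days,
                          "g2": -days + 3})
        out = attach_correlations(self._edge_set(), prof)
        assert set(zip(out.edges["tf"], out.edges["target"])) == {
            ("tfA", "g1"), ("tfB", "g2")}
        assert out.edges.set_index("tf").at["tfA", "r"] == pytest.approx(1.0)

    def test_exact_boundary_dropped(self):
        # construct two profiles with r exactly 0.6
        x = np.array([1.0, -1, 0, 0, 0, 0, 0, 0])
        y = 0.6 * x + np.sqrt(1 - 0.36) * np.array([0, 0, 1, -1, 0, 0, 0, 0])
        prof = _profiles({"tfA": x, "g1": y, "tfB": x, "g2": x})
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(0.6, abs=1e-12)
        out = attach_correlations(self._edge_set(), prof)
        assert ("tfA", "g1") not in set(zip(out.edges["tf"],
                                            out.edges["target"]))
        assert ("tfB", "g2") in set(zip(out.edges["tf"], out.edges["target"]))

    def test_unmappable_tf_counted_not_silent(self):
        days = np.arange(8.0)
        prof = _profiles({"g1": days, "g2": days})
        mapping = {"tfB": "g1"}
        out = attach_correlations(self._edge_set(), prof, tf_gene_map=mapping)
        assert out.n_unmapped_tfs == 1 and out.unmapped_tfs == ["tfA"]

    def test_matches_direct_recomputation(self, small_synthetic):
        cfg, expr, ann, truth, de = small_synthetic
        from trophodiff.synthetic import generate_footprint_fixtures
        fix = generate_footprint_fixtures(truth, cfg)
        raw = footprint_edge_map(fix.footprints, fix.motifs, fix.tss,
                                 window=cfg.promoter_window)
        prof = expr.day_means()
        out = attach_correlations(raw, prof, min_abs_r=0.6)
        expected = {
            (tf, tgt) for tf, tgt in raw.edge_pairs()
            if abs(np.corrcoef(prof.loc[tf], prof.loc[tgt])[0, 1]) > 0.6
        }
        assert set(zip(out.edges["tf"], out.edges["target"])) == expected


class TestCoverageReport:
    def _edges(self, pairs):
        return FootprintEdgeSet(pd.DataFrame(
            [(tf, g, "chr1", 0, 1, 0, 2, 1) for tf, g in pairs],
            columns=["tf", "target", "motif_chrom", "motif_start", "motif_end",
                     "fp_start", "fp_end", "n_support"]))

    def test_full_coverage_sets_all_flags(self):
        groups = {"placental": {"p1", "p2"}, "non-placental": {"n1"}}
        edges = self._edges([("tf", g) for g in ("p1", "p2", "n1")])
        rep = module_coverage_report(edges, groups)
        row = rep.loc["tf"]
        assert row["coverage_placental"] == 1.0
        assert row["both_ge_4pct"] and row["placental_ge_10pct"]

    def test_partial_coverage_arithmetic(self):
        groups = {"placental": {f"p{i}" for i in range(40)},
                  "non-placental": {f"n{i}" for i in range(60)}}
        edges = self._edges([("tf", "p0"), ("tf", "p1"), ("tf", "n0")])
        row = module_coverage_report(edges, groups).loc["tf"]
        assert row["coverage_placental"] == pytest.approx(0.05)
        assert row["coverage_non-placental"] == pytest.approx(1 / 60)
        assert not row["both_ge_4pct"]            # non-placental below 4%
        assert row["placental_ge_5pct"]
        assert not row["non-placental_ge_5pct"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            module_coverage_report(self._edges([]), {"placental": set()})


class TestDiseaseOverlay:
    def test_sign_rule_classification(self, small_synthetic):
        _, expr, ann, truth, de = small_synthetic
        gene = de.de_genes()[ann.loc[de.de_genes(), "is_tr"]][0]
        fc_diff = de.signed_max_log2fc[gene]
        disease = pd.DataFrame({"log2fc": [-2 * np.sign(fc_diff)],
                                "fdr": [0.01]}, index=[gene])
        overlay = disease_overlay(de, ann["is_tr"], disease)
        assert list(overlay.discordant) == [gene]

    def test_absent_gene_excluded(self, small_synthetic):
        _, expr, ann, truth, de = small_synthetic
        disease = pd.DataFrame({"log2fc": [], "fdr": []})
        overlay = disease_overlay(de, ann["is_tr"], disease)
        assert len(overlay.table) == 0

    def test_missing_fdr_column_rejected(self, small_synthetic):
        _, expr, ann, truth, de = small_synthetic
        disease = pd.DataFrame({"log2fc": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="fdr"):
            disease_overlay(de, ann["is_tr"], disease)


class TestDiscordanceTightness:
    def test_identical_profiles_give_minimal_p(self):
        days = np.arange(8.0)
        rng = np.random.default_rng(0)
        prof = {f"t{i}": days + rng.normal(0, 0.5, 8) for i in range(20)}
        prof.update({f"c{i}": days * (1 + 0.01 * i) for i in range(4)})
        profiles = _profiles(prof)
        tight = pd.Index([f"c{i}" for i in range(4)])
        pool = pd.Index(list(profiles.index))
        stat, p = discordance_tightness(profiles, tight, pool,
                                        n_permutations=200, seed=1)
        assert stat > 0.999
        assert p <= 0.05

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        profiles = pd.DataFrame(rng.normal(size=(40, 8)),
                                index=[f"g{i}" for i in range(40)])
        pool = profiles.index
        small_ps = 0
        for seed in range(50):
            rng2 = np.random.default_rng(100 + seed)
            subset = pd.Index(rng2.choice(pool, size=5, replace=False))
            _, p = discordance_tightness(profiles, subset, pool,
                                         n_permutations=99, seed=seed)
            small_ps += p < 0.1
        assert 1 <= small_ps <= 16

    def test_preconditions(self):
        profiles = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 8)),
                                index=list("abcde"))
        with pytest.raises(ValueError, match=">= 2"):
            discordance_tightness(profiles, ["a"], profiles.index)
        with pytest.raises(ValueError, match="permutation"):
            discordance_tightness(profiles, ["a", "b"], profiles.index,
                                  n_permutations=0)
        stat, p = discordance_tightness(profiles, ["a", "b"], profiles.index,
                                        n_permutations=50, seed=2)
        assert 1 / 51 <= p <= 1.0
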