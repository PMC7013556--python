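"""Co-expression modules: adjacency, TOM, tree cut, groups, trajectories."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tests.conftest import matrix_from_day_values
from trophodiff import coexpression as cx
from trophodiff.de import build_de_table
from trophodiff.synthetic import (
    ModuleSpec,
    SyntheticConfig,
    archetype_template,
    generate_timecourse,
)


def _tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Independent direct transcription of the TOM definition."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestProfiles:
    def test_day_means_average_replicates(self):
        expr = matrix_from_day_values({0: [[5, 6, 7]], 1: [[1, 2, 3]]})
        prof = cx.day_mean_profiles(expr)
        assert prof.loc["g0", 0] == pytest.approx(6.0)
        assert prof.loc["g0", 1] == pytest.approx(2.0)

    def test_noise_free_profile_equals_planted_archetype(self, noise_free_data):
        expr, _, truth = noise_free_data
        gene = truth.planted_module_genes().index[0]
        mod = truth.module_label[gene]
        prof = cx.day_mean_profiles(expr, [gene]).loc[gene]
        template = archetype_template(truth.archetype[mod], np.arange(8))
        expected = prof.iloc[0] + truth.amplitude[gene] * template
        np.testing.assert_allclose(prof.to_numpy(), expected, atol=1e-9)

    def test_unknown_gene_rejected(self, noise_free_data):
        expr, _, _ = noise_free_data
        with pytest.raises(KeyError):
            cx.day_mean_profiles(expr, ["nope"])


class TestTOM:
    def test_complete_graph_gives_unit_tom(self):
        a = np.ones((4, 4)) - np.eye(4)
        tom = _tom_from_adjacency(a)
        days = np.arange(8, dtype=float)
        profiles = pd.DataFrame([days, 2 * days + 1, 3 * days],
                                index=list("abc"))
        ours, _ = cx.tom_matrix(profiles, beta=6)
        np.testing.assert_allclose(ours, 1.0, atol=1e-12)
        np.testing.assert_allclose(tom, 1.0, atol=1e-12)

    def test_three_node_hand_example(self):
        # a12 = a13 = 1, a23 = 0 -> TOM23 = (1*1 + 0)/(1 + 1 - 0) = 0.5
        a = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        tom = _tom_from_adjacency(a)
        assert tom[1, 2] == pytest.approx(0.5)

    def test_disconnected_pair_has_zero_overlap(self):
        a = np.zeros((2, 2))
        tom = _tom_from_adjacency(a)
        assert tom[0, 1] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_tom_bounds_symmetry_and_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        profiles = pd.DataFrame(rng.normal(size=(12, 8)))
        tom, _ = cx.tom_matrix(profiles, beta=6)
        assert ((tom >= 0) & (tom <= 1)).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)
        corr, _ = cx.correlation_matrix(profiles)
        direct = _tom_from_adjacency(cx.adjacency_matrix(corr, 6))
        np.testing.assert_allclose(tom, direct, atol=1e-10)

    def test_constant_profiles_dropped_with_warning(self):
        profiles = pd.DataFrame([[1.0] * 8, np.arange(8), np.arange(8)[::-1]],
                                index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            tom, genes = cx.tom_matrix(profiles, beta=2)
        assert list(genes) == ["b", "c"]


class TestSoftPower:
    def test_degenerate_all_correlated_falls_back(self):
        days = np.arange(8, dtype=float)
        profiles = pd.DataFrame([days * s + o for s, o in
                                 [(1, 0), (2, 1), (-1, 3), (0.5, 2)]])
        with pytest.warns(UserWarning, match="falling back"):
            beta, scan = cx.pick_soft_power(profiles)
        assert beta == 9

    def test_target_zero_returns_first_power(self, small_synthetic):
        _, expr, _, truth, de = small_synthetic
        profiles = expr.day_means(genes=de.de_genes()[:100])
        beta, _ = cx.pick_soft_power(profiles, target_r2=0.0)
        assert beta == 1

    def test_matches_independent_rescan(self, small_synthetic):
        """The chosen power equals a plain re-computation of the same scan."""
        _, expr, _, truth, de = small_synthetic
        profiles = expr.day_means(genes=de.de_genes())
        target = 0.3
        with np.errstate(all="ignore"):
            beta, scan = cx.pick_soft_power(profiles, target_r2=target)
        corr, _ = cx.correlation_matrix(profiles)
        chosen = None
        r2s = {}
        for b in range(1, 21):
            a = np.abs(corr) ** b
            np.fill_diagonal(a, 0)
            r2s[b] = cx.scale_free_fit(a.sum(axis=1))
            if chosen is None and np.isfinite(r2s[b]) and r2s[b] >= target:
                chosen = b
        # the scan itself must agree point by point; the choice follows
        np.testing.assert_allclose(scan["r2"].to_numpy(),
                                   [r2s[b] for b in range(1, 21)], atol=1e-12)
        assert beta == (chosen if chosen is not None else 9)


class TestDetectModules:
    def test_noise_free_recovery_is_exact(self, noise_free_data):
        expr, _, truth = noise_free_data
        planted = truth.planted_module_genes()
        profiles = expr.day_means(genes=planted.index)
        tom, genes = cx.tom_matrix(profiles, beta=9)
        modules = cx.detect_modules(tom, genes, min_size=20)
        assert len(modules.module_names) == 3
        ari = adjusted_rand_score(planted.loc[genes], modules.labels)
        assert ari == pytest.approx(1.0)

    def test_min_size_larger_than_n_unassigns_everything(self):
        rng = np.random.default_rng(0)
        profiles = pd.DataFrame(rng.normal(size=(10, 8)))
        tom, genes = cx.tom_matrix(profiles, beta=2)
        with pytest.warns(UserWarning, match="unassigned"):
            modules = cx.detect_modules(tom, genes, min_size=50)
        assert (modules.labels == cx.UNASSIGNED).all()

    def test_gene_order_invariance(self, noise_free_data):
        expr, _, truth = noise_free_data
        planted = truth.planted_module_genes()
        profiles = expr.day_means(genes=planted.index)
        shuffled = profiles.sample(frac=1.0, random_state=4)
        tom1, g1 = cx.tom_matrix(profiles, beta=9)
        tom2, g2 = cx.tom_matrix(shuffled, beta=9)
        m1 = cx.detect_modules(tom1, g1, min_size=20).labels.sort_index()
        m2 = cx.detect_modules(tom2, g2, min_size=20).labels.sort_index()
        assert adjusted_rand_score(m1, m2) == pytest.approx(1.0)

    def test_labels_ordered_by_size_with_colors(self, noise_free_data):
        expr, _, truth = noise_free_data
        planted = truth.planted_module_genes()
        tom, genes = cx.tom_matrix(expr.day_means(genes=planted.index), beta=9)
        modules = cx.detect_modules(tom, genes, min_size=20)
        sizes = [len(modules.genes_in(m)) for m in modules.module_names]
        assert sizes == sorted(sizes, reverse=True)
        assert modules.colors["M1"] == "turquoise"


class TestModuleGroups:
    def test_zero_ppe_flags_mean_no_placental(self, noise_free_data):
        expr, _, truth = noise_free_data
        planted = truth.planted_module_genes()
        tom, genes = cx.tom_matrix(expr.day_means(genes=planted.index), beta=9)
        modules = cx.detect_modules(tom, genes, min_size=20)
        with pytest.warns(UserWarning, match="no PPE"):
            groups = cx.classify_module_groups(
                modules, pd.Series(False, index=genes))
        assert set(groups.values()) == {"non-placental"}

    def test_ppe_rich_module_classified_placental(self, noise_free_data):
        expr, _, truth = noise_free_data
        planted = truth.planted_module_genes()
        tom, genes = cx.tom_matrix(expr.day_means(genes=planted.index), beta=9)
        modules = cx.detect_modules(tom, genes, min_size=20)
        # plant 50% PPE in M1, 5% elsewhere
        rng = np.random.default_rng(1)
        flags = pd.Series(rng.random(len(genes)) < 0.05, index=genes)
        m1 = modules.genes_in("M1")
        flags.loc[m1[: len(m1) // 2]] = True
        groups = cx.classify_module_groups(modules, flags)
        assert groups["M1"] == "placental"

    def test_or_below_one_never_placental(self):
        genes = pd.Index([f"g{i}" for i in range(100)])
        labels = pd.Series(["M1"] * 50 + ["M2"] * 50, index=genes)
        modules = cx.ModuleSet(labels, {"M1": "turquoise", "M2": "blue",
                                        cx.UNASSIGNED: "grey"}, beta=6)
        flags = pd.Series([False] * 50 + [True] * 30 + [False] * 20,
                          index=genes)
        groups = cx.classify_module_groups(modules, flags)
        assert groups["M1"] == "non-placental"


class TestTrajectories:
    def test_flat_genes_give_zero_curve(self):
        genes = pd.Index(["a", "b"])
        labels = pd.Series(["M1", "M1"], index=genes)
        modules = cx.ModuleSet(labels, {"M1": "turquoise"}, beta=6,
                               groups={"M1": "non-placental"})
        fc = pd.DataFrame(np.zeros((2, 7)), index=genes, columns=range(1, 8))
        per_mod, per_grp = cx.module_trajectories(modules, fc)
        assert (per_mod.loc["M1"] == 0).all()

    def test_slow_module_curve_increases_to_day5(self, noise_free_data):
        expr, _, truth = noise_free_data
        slow = truth.module_label[
            truth.module_label.map(truth.archetype) == "slow_persistent_up"
        ].index
        labels = pd.Series("M1", index=slow)
        modules = cx.ModuleSet(labels, {"M1": "turquoise"}, beta=6,
                               groups={"M1": "placental"})
        fc, _ = build_de_table(expr).fc_day0, None
        per_mod, _ = cx.module_trajectories(modules, fc)
        curve = per_mod.loc["M1", [1, 2, 3, 4, 5]]
        assert (np.diff(curve) > 0).all()
        assert per_mod.loc["M1", 5] == pytest.approx(per_mod.loc["M1", 7])

    def test_group_curve_is_size_weighted_member_mean(self, small_synthetic):
        _, expr, ann, truth, de = small_synthetic
        planted = truth.planted_module_genes()
        tom, genes = cx.tom_matrix(expr.day_means(genes=planted.index),
                                   beta=9, signed=True)
        modules = cx.detect_modules(tom, genes, min_size=20)
        cx.classify_module_groups(modules, ann["is_ppe"])
        per_mod, per_grp = cx.module_trajectories(modules, de.fc_day0)
        for grp in per_grp.index:
            members = [m for m, g in modules.groups.items() if g == grp]
            sizes = np.array([len(modules.genes_in(m)) for m in members])
            weighted = (per_mod.loc[members].T @ sizes) / sizes.sum()
            np.testing.assert_allclose(per_grp.loc[grp], weighted, atol=1e-10)


class TestSlowPlacentalContrast:
    def test_placental_group_lags_then_catches_up(self, small_synthetic):
        """Slow placental modules change less on day 1, relative to their own
        maximum, than the fast non-placental group — the study's qualitative
        two-phase contrast."""
        _, expr, ann, truth, de = small_synthetic
        planted = truth.planted_module_genes()
        tom, genes = cx.tom_matrix(expr.day_means(genes=planted.index),
                                   beta=9, signed=True)
        modules = cx.detect_modules(tom, genes, min_size=20)
        cx.classify_module_groups(modules, ann["is_ppe"])
        _, per_grp = cx.module_trajectories(modules, de.fc_day0)
        assert {"placental", "non-placental"} <= set(per_grp.index)
        rel = per_grp.div(per_grp.max(axis=1), axis=0)
        assert rel.loc["placental", 1] < rel.loc["non-placental", 1]
        assert per_grp.loc["placental", 5] > per_grp.loc["placental", 1]
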