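"""Divergence matrices, random grafting, and Blomberg's K."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

import grassdiv as g
from conftest import star_tree


def dendropy_patristic(ptree: g.PhylogeneticTree) -> pd.DataFrame:
    """Independent oracle: dendropy's own path-sum patristic distances."""
    pdm = ptree.tree.phylogenetic_distance_matrix()
    labels = ptree.tip_labels
    taxa = {t.label: t for t in ptree.tree.taxon_namespace}
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        d = pdm.patristic_distance(taxa[a], taxa[b])
        out.loc[a, b] = out.loc[b, a] = d
    return out


class TestDivergenceMatrix:
    def test_cherry_geometry(self):
        tree = dendropy.Tree.get(data="(A:3,B:3):0;", schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
        d = g.divergence_matrix(g.PhylogeneticTree(tree))
        assert d.to_frame().loc["A", "B"] == pytest.approx(3.0)

    def test_zero_length_split_gives_zero(self):
        tree = dendropy.Tree.get(data="((A:0,B:0):2,C:2):0;", schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
        d = g.divergence_matrix(g.PhylogeneticTree(tree)).to_frame()
        assert d.loc["A", "B"] == 0.0
        assert d.loc["A", "C"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_sum_oracle(self, seed):
        ptree = g.simulate_tree(10 + 2 * seed, seed=seed, depth=5.0)
        ours = g.divergence_matrix(ptree, convention="patristic").to_frame()
        oracle = dendropy_patristic(ptree)
        np.testing.assert_allclose(ours.loc[oracle.index, oracle.columns].to_numpy(),
                                   oracle.to_numpy(), atol=1e-9)

    def test_half_patristic_is_time_since_mrca(self, small_tree):
        full = g.divergence_matrix(small_tree, convention="patristic").matrix
        half = g.divergence_matrix(small_tree, convention="half_patristic").matrix
        np.testing.assert_allclose(half, full / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_ultrametric_inequality(self, seed):
        ptree = g.simulate_tree(12, seed=100 + seed, depth=1.0)
        d = g.divergence_matrix(ptree).matrix
        n = d.shape[0]
        for i, j, k in itertools.combinations(range(n), 3):
            assert d[i, j] <= max(d[i, k], d[j, k]) + 1e-9


class TestGrafting:
    @pytest.fixture(scope="class")
    @staticmethod
    def pruned():
        full = g.simulate_tree(40, seed=7, depth=10.0)
        labs = full.tip_labels
        genus = full.genus_index()
        # pick 3 species whose genera keep at least one other member
        missing = [members[0] for members in genus.values() if len(members) >= 2][:3]
        keep = [l for l in labs if l not in missing]
        t = full.tree.clone(depth=1)
        t.retain_taxa_with_labels(keep)
        t.is_rooted = True
        return g.PhylogeneticTree(t), missing, full

    def test_all_species_present_and_ultrametric(self, pruned):
        backbone, missing, _ = pruned
        gs = g.graft_missing_species(backbone, missing, n_topologies=5, seed=3)
        assert gs.grafted_species == missing and not gs.dropped_species
        for t in gs.trees:
            assert set(t.tip_labels) == set(backbone.tip_labels) | set(missing)
            assert t.ultrametricity_deviation() < 1e-6

    def test_backbone_divergences_unchanged(self, pruned):
        backbone, missing, _ = pruned
        before = g.divergence_matrix(backbone).to_frame()
        gs = g.graft_missing_species(backbone, missing, n_topologies=3, seed=3)
        orig = backbone.tip_labels
        for t in gs.trees:
            after = g.divergence_matrix(t).to_frame().loc[orig, orig]
            np.testing.assert_allclose(after.to_numpy(), before.loc[orig, orig].to_numpy(),
                                       atol=1e-9)

    def test_graft_lands_within_genus_clade(self, pruned):
        backbone, missing, _ = pruned
        gs = g.graft_missing_species(backbone, missing, n_topologies=5, seed=9)
        tip_depth = max(backbone.tip_depths().values())
        # depth of each node in the backbone
        node_depth = {backbone.tree.seed_node: 0.0}
        for nd in backbone.tree.preorder_node_iter():
            if nd is not backbone.tree.seed_node:
                node_depth[nd] = node_depth[nd.parent_node] + nd.edge.length
        for t in gs.trees:
            d = g.divergence_matrix(t).to_frame()
            for sp in missing:
                congeners = [l for l in backbone.tip_labels
                             if g.genus_of(l) == g.genus_of(sp)]
                taxa = [backbone.tree.taxon_namespace.get_taxon(c) for c in congeners]
                clade_root = (backbone.tree.find_node_for_taxon(taxa[0]) if len(taxa) == 1
                              else backbone.tree.mrca(taxa=taxa))
                parent = clade_root.parent_node
                # attachment is on the genus clade or its stem, so the grafted
                # tip coalesces with a congener no deeper than the stem origin
                bound = tip_depth - (node_depth[parent] if parent is not None else 0.0)
                assert d.loc[sp, congeners].min() <= bound + 1e-9

    def test_single_congener_becomes_sister(self):
        t = dendropy.Tree.get(data="(Poa_a:2,(Fes_b:1,Car_c:1):1):0;",
                              schema="newick", preserve_underscores=True)
        t.is_rooted = True
        backbone = g.PhylogeneticTree(t)
        # Poa_a's stem runs from the root (depth 0) to its tip, age 2
        gs = g.graft_missing_species(backbone, ["Poa_x"], n_topologies=10, seed=2)
        for tt in gs.trees:
            d = g.divergence_matrix(tt).to_frame()
            assert d.loc["Poa_x", "Poa_a"] <= 2.0 + 1e-9
            # sister relationship: closest relative is the lone congener
            assert d.loc["Poa_x"].drop("Poa_x").idxmin() == "Poa_a"

    def test_determinism(self, pruned):
        backbone, missing, _ = pruned
        a = g.graft_missing_species(backbone, missing, n_topologies=4, seed=42)
        b = g.graft_missing_species(backbone, missing, n_topologies=4, seed=42)
        for ta, tb in zip(a.trees, b.trees):
            assert ta.as_newick() == tb.as_newick()

    def test_no_congener_dropped_with_warning(self, pruned):
        backbone, _, _ = pruned
        gs = g.graft_missing_species(backbone, ["Zzz_unknown"], n_topologies=2, seed=1)
        assert gs.dropped_species == ["Zzz_unknown"]
        for t in gs.trees:
            assert "Zzz_unknown" not in t.tip_labels


class TestBlombergK:
    def test_star_phylogeny_k_is_one(self, rng):
        star = star_tree(15, depth=2.0)
        x = pd.Series(rng.normal(size=15), index=star.tip_labels)
        res = g.blomberg_k(star, x, n_permutations=0)
        assert res.K == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self, small_tree, rng):
        x = pd.Series(rng.normal(size=small_tree.n_tips), index=small_tree.tip_labels)
        k1 = g.blomberg_k(small_tree, x, n_permutations=0).K
        k2 = g.blomberg_k(small_tree, 3.5 * x - 7.0, n_permutations=0).K
        assert k2 == pytest.approx(k1, rel=1e-9)

    def test_constant_trait_errors(self, small_tree):
        x = pd.Series(1.0, index=small_tree.tip_labels)
        with pytest.raises(g.ValidationError, match="constant"):
            g.blomberg_k(small_tree, x)

    def test_bm_signal_beats_permuted(self):
        """BM traits score higher K than their tip-permuted counterparts."""
        ks_bm, ks_perm = [], []
        for rep in range(30):
            t = g.simulate_tree(50, seed=300 + rep, depth=1.0)
            tr = g.simulate_traits(t, n_traits=1, signal=1.0, seed=rep,
                                   trait_names=["x"], trait_means={})
            x = tr.values["x"]
            ks_bm.append(g.blomberg_k(t, x, n_permutations=0).K)
            perm = pd.Series(np.random.default_rng(rep).permutation(x.to_numpy()),
                             index=x.index)
            ks_perm.append(g.blomberg_k(t, perm, n_permutations=0).K)
        assert np.median(ks_bm) > np.median(ks_perm)
        assert 0.7 < np.mean(ks_bm) < 1.3

    def test_permutation_p_detects_bm(self):
        t = g.simulate_tree(50, seed=77, depth=1.0)
        tr = g.simulate_traits(t, n_traits=1, signal=1.0, seed=8, trait_names=["x"],
                               trait_means={})
        res = g.blomberg_k(t, tr.values["x"], n_permutations=199, seed=5)
        assert res.p_value < 0.05
        assert 0 < res.p_value <= 1

    def test_seed_determinism(self, small_tree, rng):
        x = pd.Series(rng.normal(size=small_tree.n_tips), index=small_tree.tip_labels)
        r1 = g.blomberg_k(small_tree, x, n_permutations=99, seed=3)
        r2 = g.blomberg_k(small_tree, x, n_permutations=99, seed=3)
        assert (r1.K, r1.p_value) == (r2.K, r2.p_value)
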