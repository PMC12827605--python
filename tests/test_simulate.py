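import numpy as np
import pytest

from pathwayevo.io import tree_to_newick
from pathwayevo.screen import filter_hits
from pathwayevo.simulate import (
    SimConfig,
    assign_clades,
    emit_annotation,
    emit_gene_tree,
    emit_hit_table,
    expand_traits_to_matrix,
    simulate_dataset,
    simulate_species_tree,
    simulate_trait_history,
)
from pathwayevo.synteny import detect_clusters_for_species
from pathwayevo.treescreen import prune_long_branches, assess_monophyly
from pathwayevo.treeutil import leaf_labels, node_leafsets


class TestSpeciesTree:
    def test_deterministic_given_seed(self):
        t1 = simulate_species_tree(SimConfig(seed=1, n_species=5))
        t2 = simulate_species_tree(SimConfig(seed=1, n_species=5))
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_binary_tree_arithmetic(self):
        t = simulate_species_tree(SimConfig(seed=2, n_species=50))
        assert len(leaf_labels(t)) == 50
        internals = [n for n in t.preorder_internal_node_iter()]
        assert len(internals) == 49

    def test_different_seeds_differ(self):
        t1 = simulate_species_tree(SimConfig(seed=1, n_species=20))
        t2 = simulate_species_tree(SimConfig(seed=2, n_species=20))
        assert tree_to_newick(t1) != tree_to_newick(t2)

    def test_clades_are_monophyletic_cover(self):
        t = simulate_species_tree(SimConfig(seed=3, n_species=30))
        clades = assign_clades(t, 5)
        assert set(clades.values()) == set("ABCDE")
        assert set(clades) == set(leaf_labels(t))
        leafsets = {ls for ls in node_leafsets(t).values()}
        for label in "ABCDE":
            members = frozenset(l for l, c in clades.items() if c == label)
            assert members in leafsets


class TestTraitHistory:
    def tree(self):
        return simulate_species_tree(SimConfig(seed=4, n_species=20))

    def test_null_process_all_present(self):
        cfg = SimConfig(seed=4, loss_rate=0.0, hgt_rate=0.0)
        hist = simulate_trait_history(self.tree(), cfg, "t", np.random.default_rng(0))
        assert all(hist.leaf_states.values())
        assert hist.loss_edges == [] and hist.hgt == {}

    def test_forced_loss_excises_exact_subtree(self):
        tree = self.tree()
        leafsets = node_leafsets(tree)
        target = next(ls for n, ls in leafsets.items() if n.parent_node and len(ls) == 3)
        cfg = SimConfig(seed=4, hgt_rate=0.0)
        hist = simulate_trait_history(
            tree, cfg, "t", np.random.default_rng(0), forced_losses=[target]
        )
        absent = {l for l, s in hist.leaf_states.items() if not s}
        assert absent == set(target)

    def test_poisson_mean_matches_loss_rate(self):
        tree = simulate_species_tree(SimConfig(seed=5, n_species=40))
        cfg = SimConfig(seed=5, loss_rate=1.5, hgt_rate=0.0)
        rng = np.random.default_rng(123)
        counts = [
            len(simulate_trait_history(tree, cfg, f"t{i}", rng).loss_edges)
            for i in range(200)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 1.5) <= 3 * se

    def test_transfers_only_on_lost_leaves(self):
        tree = self.tree()
        cfg = SimConfig(seed=4, loss_rate=2.0, hgt_rate=2.0)
        rng = np.random.default_rng(7)
        for i in range(20):
            hist = simulate_trait_history(tree, cfg, f"t{i}", rng)
            for leaf in hist.hgt:
                assert not hist.vertical_states[leaf]
                assert hist.leaf_states[leaf]


class TestGeneTree:
    def test_no_transfer_keeps_focal_monophyletic(self):
        tree = simulate_species_tree(SimConfig(seed=6, n_species=15))
        cfg = SimConfig(seed=6)
        hist = simulate_trait_history(tree, cfg, "t", np.random.default_rng(1), n_losses=3, n_hgt=0)
        gtree, gmap = emit_gene_tree(tree, hist, cfg, np.random.default_rng(2))
        focal = {l for l, g in gmap.items() if g == "focal"}
        assert focal == {l for l, s in hist.leaf_states.items() if s}
        assert assess_monophyly(gtree, focal).status == "monophyletic"

    def test_planted_transfer_breaks_monophyly(self):
        tree = simulate_species_tree(SimConfig(seed=8, n_species=15))
        cfg = SimConfig(seed=8)
        hist = simulate_trait_history(tree, cfg, "t", np.random.default_rng(1), n_losses=2, n_hgt=1)
        assert hist.hgt
        gtree, gmap = emit_gene_tree(tree, hist, cfg, np.random.default_rng(2))
        focal = {l for l, g in gmap.items() if g == "focal"}
        assert assess_monophyly(gtree, focal).status == "non-monophyletic"

    def test_long_branch_decoys_pruned_downstream(self):
        tree = simulate_species_tree(SimConfig(seed=9, n_species=10))
        cfg = SimConfig(seed=9, long_branch_decoys=2)
        hist = simulate_trait_history(tree, cfg, "t", np.random.default_rng(1), n_losses=0, n_hgt=0)
        gtree, gmap = emit_gene_tree(tree, hist, cfg, np.random.default_rng(2))
        pruned, removed = prune_long_branches(gtree)
        assert removed == ["decoy_1", "decoy_2"]

    def test_no_present_leaves_is_error(self):
        tree = simulate_species_tree(SimConfig(seed=9, n_species=10))
        cfg = SimConfig(seed=9)
        leafsets = node_leafsets(tree)
        root_children = [leafsets[c] for c in tree.seed_node.child_nodes()]
        hist = simulate_trait_history(
            tree, cfg, "t", np.random.default_rng(1), forced_losses=root_children
        )
        with pytest.raises(ValueError, match="no present leaves"):
            emit_gene_tree(tree, hist, cfg, np.random.default_rng(2))


class TestHitEmission:
    def test_noiseless_hits_recover_truth_through_filter(self, clean_dataset):
        cfg, path, truth = clean_dataset
        hits, flags = emit_hit_table(truth.matrix, cfg, np.random.default_rng(5))
        kept = filter_hits(hits)
        pairs = {(h.subject_species, h.query_id) for h in kept}
        expected = {
            (sp, enz)
            for sp in truth.matrix.index
            for enz in truth.matrix.columns
            if truth.matrix.at[sp, enz]
        }
        assert pairs == expected

    def test_decoys_always_fail_the_filter(self):
        import pandas as pd

        matrix = pd.DataFrame(False, index=[f"s{i}" for i in range(40)], columns=["AcsA"])
        cfg = SimConfig(seed=12, false_hit_rate=1.0)
        hits, flags = emit_hit_table(matrix, cfg, np.random.default_rng(3))
        assert hits and not any(flags)
        assert filter_hits(hits) == []

    def test_mag_species_emit_extra_weak_hits(self):
        import pandas as pd

        matrix = pd.DataFrame(True, index=["m1", "s1"], columns=["AcsA"])
        cfg = SimConfig(seed=13)
        hits, _ = emit_hit_table(matrix, cfg, np.random.default_rng(4), mag_species=["m1"])
        assert sum(h.subject_species == "m1" for h in hits) == 3
        assert sum(h.subject_species == "s1" for h in hits) == 1


class TestAnnotationEmission:
    def test_clustered_and_dispersed_species_yield_expected_calls(self, clean_dataset):
        cfg, path, truth = clean_dataset
        loci, clustered = emit_annotation(truth.matrix, cfg, np.random.default_rng(6))
        for sp, is_clustered in clustered.items():
            calls = detect_clusters_for_species(loci, sp)
            assert len(calls) == 1
            assert calls[0].is_clustered == is_clustered
            assert calls[0].concat_eligible == is_clustered

    def test_species_without_acsa_get_no_call(self, clean_dataset):
        cfg, path, truth = clean_dataset
        loci, clustered = emit_annotation(truth.matrix, cfg, np.random.default_rng(6))
        no_acsa = [sp for sp in truth.matrix.index if not truth.matrix.at[sp, "AcsA"]]
        for sp in no_acsa:
            assert detect_clusters_for_species(loci, sp) == []
            assert sp not in clustered


class TestDatasetDeterminism:
    def test_byte_identical_rerun(self, tmp_path):
        cfg = SimConfig(seed=31, n_species=12)
        simulate_dataset(cfg, tmp_path / "a")
        simulate_dataset(cfg, tmp_path / "b")
        files_a = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(tmp_path / "b") for p in (tmp_path / "b").rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_truth_matrix_consistent_with_histories(self, clean_dataset):
        cfg, path, truth = clean_dataset
        rebuilt = expand_traits_to_matrix(truth.histories, list(truth.matrix.index))
        assert rebuilt.equals(truth.matrix)
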