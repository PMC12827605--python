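import numpy as np
import pytest

from pathwayevo.io import parse_newick, tree_to_newick
from pathwayevo.screen import Thresholds
from pathwayevo.simulate import SimConfig, simulate_trait_history, emit_gene_tree
from pathwayevo.treescreen import (
    VERDICT_HGT,
    VERDICT_UNRESOLVED,
    VERDICT_VERTICAL,
    classify_hgt,
    prune_long_branches,
    split_focal_groups,
    assess_monophyly,
)
from pathwayevo.treeutil import leaf_labels

from conftest import monophyly_oracle, random_tree


class TestPruneLongBranches:
    def test_pendant_above_cutoff_removed_at_cutoff_kept(self):
        t = parse_newick("((A:1.6,B:1.5):0.1,(C:0.2,D:0.2):0.1);")
        pruned, removed = prune_long_branches(t)
        assert removed == ["A"]
        assert sorted(leaf_labels(pruned)) == ["B", "C", "D"]

    def test_no_long_branches_identity(self):
        t = parse_newick("((A:0.1,B:0.2)90:0.1,C:0.3);")
        pruned, removed = prune_long_branches(t)
        assert removed == []
        assert tree_to_newick(pruned) == tree_to_newick(t)

    def test_degree_two_suppression_sums_lengths(self):
        t = parse_newick("((A:2.0,B:0.2):0.3,C:0.3);")
        pruned, removed = prune_long_branches(t)
        assert removed == ["A"]
        (b,) = [l for l in pruned.leaf_node_iter() if l.taxon.label == "B"]
        assert b.edge.length == pytest.approx(0.5)

    def test_missing_branch_length_is_hard_error(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(ValueError, match="branch length"):
            prune_long_branches(t)

    def test_applied_once_not_iterated(self):
        # B's pendant becomes 1.6 only after A is pruned; a single pass keeps it
        t = parse_newick("(((A:2.0,B:0.9):0.7,C:0.2):0.1,D:0.1);")
        pruned, removed = prune_long_branches(t)
        assert removed == ["A"]
        assert "B" in leaf_labels(pruned)


class TestMonophyly:
    def test_clean_split_is_monophyletic(self):
        t = parse_newick("((f1:1,f2:1)99:1,(x1:1,x2:1):1);")
        v = assess_monophyly(t, {"f1", "f2"})
        assert v.status == "monophyletic"
        assert v.clade_support == 99

    def test_interleaved_leaves_are_not(self):
        t = parse_newick("((f1:1,x1:1):1,(f2:1,x2:1):1);")
        v = assess_monophyly(t, {"f1", "f2"})
        assert v.status == "non-monophyletic"
        assert len(v.largest_focal_clade) == 1

    def test_rooting_invariance(self):
        # the focal pair spans the root; the bipartition view still sees it
        t = parse_newick("((f1:1,(x1:1,x2:1):1):1,f2:1);")
        v = assess_monophyly(t, {"f1", "f2"})
        assert v.status == "monophyletic"

    def test_empty_focal_set_is_error(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(ValueError, match="non-empty"):
            assess_monophyly(t, set())

    def test_matches_bipartition_oracle_on_random_trees(self):
        rng = np.random.default_rng(5)
        for i in range(60):
            t = random_tree(seed=100 + i, n=12)
            leaves = leaf_labels(t)
            k = int(rng.integers(2, 11))
            focal = set(rng.choice(leaves, size=k, replace=False).tolist())
            got = assess_monophyly(t, focal).status == "monophyletic"
            assert got == monophyly_oracle(t, focal)


class TestSplitFocalGroups:
    def test_two_supported_groups(self):
        t = parse_newick(
            "(((f1:1,f2:1)100:1,(x1:1,x2:1)80:1)90:1,((f3:1,f4:1)96:1,x3:1)85:1);"
        )
        groups = split_focal_groups(t, {"f1", "f2", "f3", "f4"})
        assert len(groups) == 2
        assert all(g.distinct for g in groups)
        assert sorted(len(g.leaves) for g in groups) == [2, 2]

    def test_monophyletic_focal_set_single_group(self):
        t = parse_newick("((f1:1,(f2:1,f3:1)97:1)100:1,(x1:1,x2:1):1);")
        groups = split_focal_groups(t, {"f1", "f2", "f3"})
        assert len(groups) == 1
        assert groups[0].leaves == frozenset({"f1", "f2", "f3"})

    def test_scattered_singletons_never_distinct(self):
        t = parse_newick(
            "(((f1:1,x1:1)99:1,(f2:1,x2:1)99:1)99:1,((f3:1,x3:1)99:1,x4:1)99:1);"
        )
        groups = split_focal_groups(t, {"f1", "f2", "f3"})
        assert len(groups) == 3
        assert all(len(g.leaves) == 1 for g in groups)
        assert not any(g.distinct for g in groups)

    def test_groups_numbered_by_decreasing_size(self):
        t = parse_newick(
            "(((f1:1,(f2:1,f3:1)100:1)100:1,x1:1)90:1,(f4:1,x2:1)88:1);"
        )
        groups = split_focal_groups(t, {"f1", "f2", "f3", "f4"})
        assert [g.number for g in groups] == [1, 2]
        assert len(groups[0].leaves) > len(groups[1].leaves)


class TestClassifyHgt:
    GROUPS = {
        "f1": "A", "f2": "A", "f3": "B",
        "p1": "PVC", "p2": "PVC", "p3": "PVC",
        "m1": "Myxococcota", "m2": "Myxococcota",
    }

    def nested_tree(self, support=98):
        # f3 nests inside the PVC clade with the given support
        return parse_newick(
            f"(((f1:1,f2:1)100:1,(m1:1,m2:1)100:1)100:1,"
            f"((p1:1,f3:1){support}:1,(p2:1,p3:1)100:1)100:1);"
        )

    def test_nested_focal_leaf_called_transfer_with_donor(self):
        calls = classify_hgt(self.nested_tree(), {"f1", "f2", "f3"}, self.GROUPS)
        by_id = {c.sequence_id: c for c in calls}
        assert by_id["f3"].verdict == VERDICT_HGT
        assert by_id["f3"].donor_group == "PVC"
        assert by_id["f3"].nest_support == 98
        assert by_id["f1"].verdict == VERDICT_VERTICAL
        assert by_id["f2"].verdict == VERDICT_VERTICAL

    def test_weak_nesting_support_is_unresolved_never_vertical(self):
        calls = classify_hgt(self.nested_tree(support=80), {"f1", "f2", "f3"}, self.GROUPS)
        by_id = {c.sequence_id: c for c in calls}
        assert by_id["f3"].verdict == VERDICT_UNRESOLVED
        assert by_id["f3"].donor_group is None

    def test_verdicts_partition_focal_set(self):
        calls = classify_hgt(self.nested_tree(), {"f1", "f2", "f3"}, self.GROUPS)
        assert len(calls) == 3
        assert len({c.sequence_id for c in calls}) == 3

    def test_unmapped_leaf_is_hard_error(self):
        groups = dict(self.GROUPS)
        del groups["p2"]
        with pytest.raises(ValueError, match="group map"):
            classify_hgt(self.nested_tree(), {"f1", "f2", "f3"}, groups)

    def test_no_transfer_no_noise_all_vertical(self):
        cfg = SimConfig(seed=9, n_species=12, hgt_rate=0.0)
        tree = random_tree(9, 12)
        hist = simulate_trait_history(tree, cfg, "t", np.random.default_rng(1), n_losses=2, n_hgt=0)
        gtree, gmap = emit_gene_tree(tree, hist, cfg, np.random.default_rng(2))
        focal = {l for l, g in gmap.items() if g == "focal"}
        v = assess_monophyly(gtree, focal)
        assert v.status == "monophyletic"
        calls = classify_hgt(gtree, focal, gmap, focal_groups={"focal"})
        assert all(c.verdict == VERDICT_VERTICAL for c in calls)

    def test_planted_transfer_recovered_from_generator(self):
        cfg = SimConfig(seed=21, n_species=15)
        tree = random_tree(21, 15)
        hist = simulate_trait_history(tree, cfg, "t", np.random.default_rng(3), n_losses=2, n_hgt=1)
        assert hist.hgt, "history must contain the planted transfer"
        gtree, gmap = emit_gene_tree(tree, hist, cfg, np.random.default_rng(4))
        focal = {l for l, g in gmap.items() if g == "focal"}
        calls = classify_hgt(gtree, focal, gmap, focal_groups={"focal"})
        predicted = {c.sequence_id: c.donor_group for c in calls if c.verdict == VERDICT_HGT}
        assert predicted == hist.hgt
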