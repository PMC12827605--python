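import itertools

import numpy as np
import pytest

from pathwayevo.io import parse_newick
from pathwayevo.scenario import (
    GAIN,
    HGT_GAIN,
    LOSS,
    TraitProfile,
    ancestor_report,
    build_scenario,
    dollo_reconstruct,
    fitch_min_changes,
    replay_state,
    scenario_replay_ok,
)
from pathwayevo.simulate import SimConfig, simulate_trait_history
from pathwayevo.treeutil import leaf_labels

from conftest import (
    all_rooted_trees,
    brute_force_dollo,
    brute_force_min_changes,
    random_tree,
    tuple_to_newick,
)

CLADES = ["A", "B", "C", "D", "E", "OUT"]


class TestFitch:
    def test_uniform_states_cost_nothing(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        count, labeling = fitch_min_changes(t, {l: True for l in "abcd"})
        assert count == 0
        assert all(labeling.values())

    def test_single_clade_flip_costs_one(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        count, _ = fitch_min_changes(t, {"a": True, "b": True, "c": False, "d": False})
        assert count == 1

    def test_missing_leaf_state_is_error(self):
        t = parse_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="missing a state"):
            fitch_min_changes(t, {"a": True, "b": False})

    def test_matches_exhaustive_oracle_on_five_leaves(self):
        leaves = ["L0", "L1", "L2", "L3", "L4"]
        for tup in all_rooted_trees(leaves):
            t = parse_newick(tuple_to_newick(tup) + ";")
            for bits in itertools.product([False, True], repeat=5):
                states = dict(zip(leaves, bits))
                got, labeling = fitch_min_changes(t, states)
                assert got == brute_force_min_changes(tup, list(bits), leaves)
                # the returned labeling achieves the count
                achieved = _changes_of_labeling(t, states, labeling)
                assert achieved == got


def _changes_of_labeling(tree, leaf_states, labeling):
    from pathwayevo.treeutil import node_leafsets

    leafsets = node_leafsets(tree)
    changes = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        a = labeling[leafsets[node]]
        b = labeling[leafsets[node.parent_node]]
        if a != b:
            changes += 1
    return changes


class TestDollo:
    def test_present_everywhere_gains_at_root(self, backbone):
        rec = dollo_reconstruct(backbone, {l: True for l in CLADES})
        assert rec.gain_edge == frozenset(CLADES)
        assert rec.loss_edges == ()
        assert rec.event_count == 1

    def test_all_absent_reports_never_present(self, backbone):
        rec = dollo_reconstruct(backbone, {l: False for l in CLADES})
        assert rec.never_present
        assert rec.event_count == 0

    def test_codh_acs_clade_pattern_single_loss_on_a_stem(self, backbone):
        states = {"A": False, "B": True, "C": True, "D": True, "E": True, "OUT": False}
        rec = dollo_reconstruct(backbone, states)
        assert rec.gain_edge == frozenset("ABCDE")
        assert rec.loss_edges == (frozenset("A"),)

    def test_matches_single_gain_exhaustive_oracle(self):
        leaves = ["L0", "L1", "L2", "L3", "L4"]
        trees = list(all_rooted_trees(leaves))[::13]  # a spread of topologies
        for tup in trees:
            t = parse_newick(tuple_to_newick(tup) + ";")
            for bits in itertools.product([False, True], repeat=5):
                if not any(bits):
                    continue
                rec = dollo_reconstruct(t, dict(zip(leaves, bits)))
                assert rec.event_count == brute_force_dollo(tup, list(bits), leaves)

    def test_never_cheaper_than_fitch(self):
        for i in range(20):
            t = random_tree(seed=300 + i, n=10)
            rng = np.random.default_rng(i)
            states = {l: bool(rng.integers(2)) for l in leaf_labels(t)}
            if not any(states.values()):
                continue
            fitch, _ = fitch_min_changes(t, states)
            rec = dollo_reconstruct(t, states)
            assert rec.event_count >= fitch


class TestBuildScenario:
    def test_empty_recode_equals_plain_dollo(self, backbone):
        states = {"A": False, "B": True, "C": True, "D": True, "E": True, "OUT": False}
        scenario = build_scenario(backbone, [TraitProfile("t", states)])
        rec = dollo_reconstruct(backbone, states)
        evs = scenario.events["t"]
        assert {e.edge for e in evs if e.etype == LOSS} == set(rec.loss_edges)
        assert [e.edge for e in evs if e.etype == GAIN] == [rec.gain_edge]

    def test_gcs_recode_moves_loss_to_ab_stem(self, backbone):
        states = {"A": True, "B": False, "C": True, "D": True, "E": True, "OUT": False}
        scenario = build_scenario(
            backbone, [TraitProfile("GCS", states, hgt_recode={"A": "PVC"})]
        )
        evs = scenario.events["GCS"]
        losses = [e.edge for e in evs if e.etype == LOSS]
        hgts = [(e.edge, e.donor) for e in evs if e.etype == HGT_GAIN]
        assert losses == [frozenset("AB")]
        assert hgts == [(frozenset("A"), "PVC")]

    def test_recode_requires_present_state(self):
        with pytest.raises(ValueError, match="must be present"):
            TraitProfile("t", {"A": False}, hgt_recode={"A": "PVC"})

    def test_non_monophyletic_recode_warns_and_splits(self, backbone, caplog):
        states = {l: True for l in CLADES}
        with caplog.at_level("WARNING"):
            scenario = build_scenario(
                backbone,
                [TraitProfile("t", states, hgt_recode={"A": "PVC", "C": "PVC"})],
            )
        assert "not monophyletic" in caplog.text
        hgts = [e for e in scenario.events["t"] if e.etype == HGT_GAIN]
        assert {e.edge for e in hgts} == {frozenset("A"), frozenset("C")}

    def test_replay_reproduces_observed_states_on_random_histories(self):
        cfg = SimConfig(seed=50, n_species=25, loss_rate=2.5, hgt_rate=1.0)
        tree = random_tree(50, 25)
        rng = np.random.default_rng(99)
        for k in range(30):
            hist = simulate_trait_history(tree, cfg, f"t{k}", rng)
            if not any(hist.leaf_states.values()):
                continue
            profile = TraitProfile(f"t{k}", hist.leaf_states, hist.hgt)
            scenario = build_scenario(tree, [profile])
            assert scenario_replay_ok(scenario, tree, [profile])

    def test_recovers_planted_events_when_identifiable(self):
        cfg = SimConfig(seed=60, n_species=50, loss_rate=2.0, hgt_rate=0.0)
        tree = random_tree(60, 50)
        rng = np.random.default_rng(8)
        n_identifiable = 0
        for k in range(200):
            hist = simulate_trait_history(tree, cfg, f"t{k}", rng)
            if not hist.identifiable:
                continue
            n_identifiable += 1
            rec = dollo_reconstruct(tree, hist.vertical_states)
            assert sorted(rec.loss_edges) == sorted(map(frozenset, hist.loss_edges))
        assert n_identifiable > 100  # most planted histories are recoverable


class TestAncestorReport:
    def scenario_for_backbone(self, backbone):
        fdhg = {"A": True, "B": True, "C": True, "D": True, "E": True, "OUT": False}
        acs = {"A": False, "B": True, "C": True, "D": True, "E": True, "OUT": False}
        gcs = {"A": True, "B": False, "C": True, "D": True, "E": True, "OUT": False}
        return build_scenario(
            backbone,
            [
                TraitProfile("FdhG", fdhg),
                TraitProfile("CODH/ACS", acs),
                TraitProfile("GCS", gcs, hgt_recode={"A": "PVC"}),
            ],
        )

    def test_phylum_mrca_has_all_key_gene_sets(self, backbone):
        scenario = self.scenario_for_backbone(backbone)
        report = ancestor_report(scenario, backbone, frozenset("ABCDE"))
        assert report.set_index("trait")["present"].all()

    def test_root_above_gain_is_absent(self, backbone):
        scenario = self.scenario_for_backbone(backbone)
        report = ancestor_report(scenario, backbone, frozenset(CLADES))
        assert not report.set_index("trait")["present"].any()

    def test_leaf_replay_matches_observation(self, backbone):
        scenario = self.scenario_for_backbone(backbone)
        present, via_hgt = replay_state(scenario, backbone, "GCS", "A")
        assert present and via_hgt
        present, _ = replay_state(scenario, backbone, "GCS", "B")
        assert not present

    def test_unknown_node_is_error(self, backbone):
        scenario = self.scenario_for_backbone(backbone)
        with pytest.raises(ValueError):
            replay_state(scenario, backbone, "GCS", frozenset({"A", "C"}))
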