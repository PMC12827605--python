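"""Ancestral gain/loss/HGT scenarios for binary gene-content traits.

The default model is Dollo parsimony: a trait is gained once, on the edge
above the most recent common ancestor of the species that carry it, and
explained everywhere else by independent losses (one loss per maximal
absent subtree).  This matches the biology of multi-gene pathway sets,
whose re-invention is implausible but whose loss is routine; re-appearance
is explained only by horizontal transfer.  Presence calls attributed to
horizontal acquisition are therefore recoded to "absent" before the
vertical reconstruction, and an ``hgt_gain`` event (with its donor group)
is placed on the stem of each maximal recoded clade afterwards.

Unconstrained Fitch small parsimony is kept as a diagnostic
(:func:`fitch_min_changes`): when gain-free parsimony is much cheaper than
Dollo for a trait, the single-gain assumption deserves scrutiny.

Edges are identified by the frozenset of leaf labels below them, which is
stable across re-reading the same tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import dendropy
import pandas as pd

from .treeutil import (
    clone_tree,
    find_mrca,
    is_binary,
    leaf_label,
    node_leafsets,
)

log = logging.getLogger(__name__)

Edge = FrozenSet[str]

GAIN = "gain"
LOSS = "loss"
HGT_GAIN = "hgt_gain"
#: replay order when several events share an edge
_EVENT_ORDER = {GAIN: 0, LOSS: 1, HGT_GAIN: 2}


@dataclass(frozen=True)
class Event:
    edge: Edge
    trait_id: str
    etype: str  # gain | loss | hgt_gain
    donor: Optional[str] = None

    def __post_init__(self) -> None:
        if self.etype not in _EVENT_ORDER:
            raise ValueError(f"unknown event type {self.etype!r}")
        if (self.etype == HGT_GAIN) != (self.donor is not None):
            raise ValueError("donor must be given exactly for hgt_gain events")


@dataclass(frozen=True)
class TraitProfile:
    """Leaf states for one trait, plus the species whose presence is
    attributed to horizontal acquisition (mapped to their donor group)."""

    trait_id: str
    leaf_states: Mapping[str, bool]
    hgt_recode: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [s for s in self.hgt_recode if not self.leaf_states.get(s, False)]
        if bad:
            raise ValueError(
                f"trait {self.trait_id}: hgt_recode species must be present: {sorted(bad)}"
            )


@dataclass
class EventScenario:
    """Per-edge events and root states for a set of traits; the machine-
    readable evolutionary scenario."""

    root_state: Dict[str, bool]
    events: Dict[str, List[Event]]  # trait_id -> events
    never_present: List[str] = field(default_factory=list)

    def total_events(self, trait_id: str) -> int:
        return len(self.events.get(trait_id, []))

    def events_on_edge(self, trait_id: str, edge: Edge) -> List[Event]:
        evs = [e for e in self.events.get(trait_id, []) if e.edge == edge]
        return sorted(evs, key=lambda e: _EVENT_ORDER[e.etype])

    def frame(self) -> pd.DataFrame:
        rows = []
        for trait_id in sorted(self.events):
            for e in sorted(
                self.events[trait_id],
                key=lambda e: (len(e.edge), sorted(e.edge), _EVENT_ORDER[e.etype]),
            ):
                rows.append(
                    {
                        "trait": trait_id,
                        "edge": "|".join(sorted(e.edge)),
                        "event": e.etype,
                        "donor": e.donor or "",
                    }
                )
        return pd.DataFrame(rows, columns=["trait", "edge", "event", "donor"])


# ---------------------------------------------------------------------------
# Fitch small parsimony
# ---------------------------------------------------------------------------

def fitch_min_changes(
    tree: dendropy.Tree, leaf_states: Mapping[str, bool]
) -> Tuple[int, Dict[Edge, bool]]:
    """Minimum number of binary state changes over the tree, with one
    optimal internal labeling (keyed by the leafset below each node).

    Soft polytomies are resolved arbitrarily (flagged in the log); the
    change count is computed on the resolved tree.
    """
    work = tree
    if not is_binary(tree):
        log.warning("tree has polytomies; resolving arbitrarily for Fitch parsimony")
        work = clone_tree(tree)
        work.resolve_polytomies()
    leafsets = node_leafsets(work)
    missing = [l for l in leafsets[work.seed_node] if l not in leaf_states]
    if missing:
        raise ValueError(f"leaves missing a state: {sorted(missing)}")

    # bottom-up pass: Fitch state sets, counting forced unions
    sets: Dict[dendropy.Node, frozenset] = {}
    changes = 0
    for node in work.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            sets[node] = frozenset([bool(leaf_states[leaf_label(node)])])
            continue
        inter = frozenset([True, False])
        for k in kids:
            inter = inter & sets[k]
        if inter:
            sets[node] = inter
        else:
            union = frozenset()
            for k in kids:
                union = union | sets[k]
            sets[node] = union
            changes += 1

    # top-down pass: pick states
    labeling: Dict[Edge, bool] = {}
    state_of: Dict[dendropy.Node, bool] = {}
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            state = True in sets[node]  # prefer "present" at the root on ties
        else:
            parent = state_of[node.parent_node]
            state = parent if parent in sets[node] else (True in sets[node])
        state_of[node] = state
        labeling[leafsets[node]] = state
    return changes, labeling


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DolloReconstruction:
    trait_id: str
    gain_edge: Optional[Edge]  # None when the trait is never present
    loss_edges: Tuple[Edge, ...]
    never_present: bool = False

    @property
    def event_count(self) -> int:
        return 0 if self.never_present else 1 + len(self.loss_edges)


def dollo_reconstruct(
    tree: dendropy.Tree, leaf_states: Mapping[str, bool], trait_id: str = "trait"
) -> DolloReconstruction:
    """Single-gain reconstruction: the gain sits on the stem of the MRCA of
    all present leaves; losses are the stems of the maximal subtrees below
    it that contain no present leaf (one loss per maximal absent subtree,
    so children of a polytomy are reported individually)."""
    leafsets = node_leafsets(tree)
    all_leaves = leafsets[tree.seed_node]
    missing = [l for l in all_leaves if l not in leaf_states]
    if missing:
        raise ValueError(f"leaves missing a state: {sorted(missing)}")
    present = frozenset(l for l in all_leaves if leaf_states[l])
    if not present:
        return DolloReconstruction(trait_id, None, (), never_present=True)
    mrca = find_mrca(tree, present)
    losses: List[Edge] = []
    stack = list(mrca.child_nodes())
    while stack:
        node = stack.pop()
        below = leafsets[node]
        if below & present:
            stack.extend(node.child_nodes())
        else:
            losses.append(below)
    losses.sort(key=lambda e: (len(e), sorted(e)))
    return DolloReconstruction(trait_id, leafsets[mrca], tuple(losses))


# ---------------------------------------------------------------------------
# scenario assembly and replay
# ---------------------------------------------------------------------------

def _maximal_recoded_clades(
    tree: dendropy.Tree, recoded: Mapping[str, str]
) -> List[Tuple[Edge, str]]:
    """Maximal subtrees all of whose leaves are recoded with one donor."""
    leafsets = node_leafsets(tree)
    out: List[Tuple[Edge, str]] = []

    def donor_of(leafset: Edge) -> Optional[str]:
        donors = {recoded[l] for l in leafset if l in recoded}
        if len(donors) == 1 and all(l in recoded for l in leafset):
            return donors.pop()
        return None

    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        below = leafsets[node]
        donor = donor_of(below)
        if donor is not None:
            out.append((below, donor))
        else:
            stack.extend(node.child_nodes())
    return sorted(out, key=lambda x: (len(x[0]), sorted(x[0])))


def build_scenario(tree: dendropy.Tree, traits: Sequence[TraitProfile]) -> EventScenario:
    """Dollo reconstruction with HGT-aware recoding, per trait.

    Horizontally acquired presence is recoded to absent first, so that
    transferred copies never pull the vertical gain upward; an ``hgt_gain``
    event with the donor group is then placed on the stem of each maximal
    recoded clade.  A warning is logged when a recoded species set is not
    monophyletic (events are then placed per maximal sub-clade)."""
    root_state: Dict[str, bool] = {}
    events: Dict[str, List[Event]] = {}
    never: List[str] = []
    leafsets = node_leafsets(tree)
    all_leaves = leafsets[tree.seed_node]
    for trait in traits:
        recoded_states = {
            l: (bool(trait.leaf_states[l]) and l not in trait.hgt_recode)
            for l in all_leaves
        }
        evs: List[Event] = []
        rec = dollo_reconstruct(tree, recoded_states, trait.trait_id)
        if rec.never_present:
            if not trait.hgt_recode:
                never.append(trait.trait_id)
        else:
            evs.append(Event(rec.gain_edge, trait.trait_id, GAIN))
            evs.extend(Event(e, trait.trait_id, LOSS) for e in rec.loss_edges)
        clades = _maximal_recoded_clades(tree, trait.hgt_recode)
        donors = {d for s, d in trait.hgt_recode.items()}
        if trait.hgt_recode and len(clades) > len(donors):
            log.warning(
                "trait %s: recoded species are not monophyletic; placing %d hgt_gain events",
                trait.trait_id, len(clades),
            )
        for edge, donor in clades:
            evs.append(Event(edge, trait.trait_id, HGT_GAIN, donor))
        root_state[trait.trait_id] = False  # gain always sits on an edge
        events[trait.trait_id] = evs
    return EventScenario(root_state=root_state, events=events, never_present=never)


def replay_state(
    scenario: EventScenario,
    tree: dendropy.Tree,
    trait_id: str,
    target: Edge | str,
) -> Tuple[bool, bool]:
    """Replay events from the root down to ``target`` (a leaf label or the
    leafset identifying a node); returns (present, via_hgt)."""
    if isinstance(target, str):
        target = frozenset([target])
    leafsets = node_leafsets(tree)
    node = None
    for n, ls in leafsets.items():
        if ls == target:
            node = n
            break
    if node is None:
        raise ValueError(f"no node with leafset {sorted(target)}")
    path = []
    while node is not None:
        path.append(node)
        node = node.parent_node
    path.reverse()
    state = scenario.root_state.get(trait_id, False)
    via_hgt = False
    for n in path:
        for e in scenario.events_on_edge(trait_id, leafsets[n]):
            if e.etype == GAIN:
                state, via_hgt = True, False
            elif e.etype == LOSS:
                state, via_hgt = False, False
            else:
                state, via_hgt = True, True
    return state, via_hgt


def ancestor_report(
    scenario: EventScenario, tree: dendropy.Tree, node_leaves: Edge | Sequence[str]
) -> pd.DataFrame:
    """Per-trait presence at the MRCA of ``node_leaves`` (a leaf label set).

    The MRCA's stem-edge events are included in the replay: a gain on the
    stem above a node counts as present at that node."""
    want = frozenset([node_leaves]) if isinstance(node_leaves, str) else frozenset(node_leaves)
    mrca = find_mrca(tree, want)
    leafsets = node_leafsets(tree)
    edge = leafsets[mrca]
    rows = []
    for trait_id in sorted(scenario.events):
        present, via_hgt = replay_state(scenario, tree, trait_id, edge)
        rows.append(
            {
                "trait": trait_id,
                "present": present,
                "via_hgt": via_hgt,
            }
        )
    return pd.DataFrame(rows, columns=["trait", "present", "via_hgt"])


def scenario_replay_ok(
    scenario: EventScenario, tree: dendropy.Tree, traits: Sequence[TraitProfile]
) -> bool:
    """Invariant check: replaying root-to-leaf events reproduces every
    observed (pre-recoding) leaf state."""
    for trait in traits:
        for leaf, observed in trait.leaf_states.items():
            got, _ = replay_state(scenario, tree, trait.trait_id, leaf)
            if got != bool(observed):
                return False
    return True


def annotated_newick(
    scenario: EventScenario, tree: dendropy.Tree, traits: Sequence[str]
) -> str:
    """Newick string with per-node comments giving event counts."""
    work = clone_tree(tree)
    leafsets = node_leafsets(work)
    for node in work.preorder_node_iter():
        edge = leafsets[node]
        n_ev = sum(
            1
            for t in traits
            for e in scenario.events.get(t, [])
            if e.edge == edge
        )
        if n_ev:
            node.comments = [f"events={n_ev}"]
    from .io import tree_to_newick  # local import to avoid a cycle

    return tree_to_newick(work)
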