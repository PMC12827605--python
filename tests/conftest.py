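import dendropy
import numpy as np
import pytest

from pathwayevo.io import parse_newick
from pathwayevo.records import HitRecord
from pathwayevo.screen import Thresholds
from pathwayevo.simulate import SimConfig, simulate_dataset, simulate_species_tree


@pytest.fixture
def thresholds():
    return Thresholds()


def make_hit(**kw):
    base = dict(
        query_id="AcsA",
        subject_id="sp001|AcsA_1",
        subject_species="sp001",
        percent_identity=55.0,
        align_length=500,
        evalue=1e-20,
        bitscore=400.0,
        query_coverage=90.0,
        is_mag_derived=False,
        taxid="t0001",
    )
    base.update(kw)
    return HitRecord(**base)


@pytest.fixture
def hit_factory():
    return make_hit


@pytest.fixture
def backbone():
    """Clade-level backbone: five focal clades A-E plus an outgroup."""
    return parse_newick("(((((A:0.1,B:0.1):0.1,C:0.1):0.1,D:0.1):0.1,E:0.1):0.1,OUT:0.2);")


def random_tree(seed: int, n: int) -> dendropy.Tree:
    return simulate_species_tree(SimConfig(seed=seed, n_species=n))


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """A noiseless synthetic dataset: zero dropout, zero false hits."""
    out = tmp_path_factory.mktemp("ds")
    cfg = SimConfig(seed=7, n_species=30, hgt_rate=0.5)
    truth = simulate_dataset(cfg, out)
    return cfg, out, truth


# ---------------------------------------------------------------------------
# independent oracles (used by unit and acceptance tests)
# ---------------------------------------------------------------------------

def all_rooted_trees(leaves):
    """Every rooted binary topology on the labeled leaves, as nested tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    for sub in all_rooted_trees(leaves[:-1]):
        yield from _insert(sub, leaves[-1])


def _insert(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for nl in _insert(left, leaf):
            yield (nl, right)
        for nr in _insert(right, leaf):
            yield (left, nr)


def tuple_to_newick(tree) -> str:
    if isinstance(tree, tuple):
        return f"({tuple_to_newick(tree[0])},{tuple_to_newick(tree[1])})"
    return str(tree)


def tree_edges(tree, leaf_index):
    """(child, parent) node-id pairs; leaves get their index from
    ``leaf_index``, internal nodes fresh ids counting upward."""
    edges = []
    counter = [max(leaf_index.values()) + 1]

    def walk(node):
        if not isinstance(node, tuple):
            return leaf_index[node]
        nid = counter[0]
        counter[0] += 1
        for child in node:
            edges.append((walk(child), nid))
        return nid

    root = walk(tree)
    return edges, root, counter[0]


def brute_force_min_changes(tree, pattern, leaf_names):
    """Minimum state changes by exhaustive enumeration of all internal
    labelings (independent of the Fitch implementation)."""
    leaf_index = {name: i for i, name in enumerate(leaf_names)}
    edges, root, n_nodes = tree_edges(tree, leaf_index)
    n_leaves = len(leaf_names)
    n_internal = n_nodes - n_leaves
    best = None
    for mask in range(2 ** n_internal):
        states = list(pattern) + [bool(mask >> i & 1) for i in range(n_internal)]
        changes = sum(1 for a, b in edges if states[a] != states[b])
        if best is None or changes < best:
            best = changes
    return best


def brute_force_dollo(tree, pattern, leaf_names):
    """Minimum changes under the single-gain constraint, by exhaustive
    labeling enumeration: at most one absent->present transition along the
    tree (counting a virtual absent state above the root)."""
    leaf_index = {name: i for i, name in enumerate(leaf_names)}
    edges, root, n_nodes = tree_edges(tree, leaf_index)
    n_leaves = len(leaf_names)
    n_internal = n_nodes - n_leaves
    best = None
    for mask in range(2 ** n_internal):
        states = list(pattern) + [bool(mask >> i & 1) for i in range(n_internal)]
        gains = sum(1 for a, b in edges if states[a] and not states[b])
        if states[root]:
            gains += 1  # gain on the root's stem
        if gains > 1:
            continue
        changes = sum(1 for a, b in edges if states[a] != states[b])
        if states[root]:
            changes += 1
        if best is None or changes < best:
            best = changes
    return best


def monophyly_oracle(tree: dendropy.Tree, focal) -> bool:
    """Exhaustive all-edges bipartition check via dendropy's bitmask
    encoding (independent of the package's leafset recursion)."""
    work = dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick",
        preserve_underscores=True,
    )
    work.encode_bipartitions()
    tns = work.taxon_namespace
    full = tns.all_taxa_bitmask()
    focal_bm = 0
    for label in focal:
        focal_bm |= tns.taxon_bitmask(tns.get_taxon(label))
    for edge in work.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = edge.bipartition.leafset_bitmask
        if side == focal_bm or (side ^ full) == focal_bm:
            return True
    return False
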