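"""Helpers on top of :class:`dendropy.Tree`.

Trees are held as dendropy objects throughout.  Two conventions are layered
on top:

* bootstrap supports live on internal nodes as an integer attribute
  ``support`` (``None`` when absent); readers/writers translate between
  this attribute and Newick internal-node labels;
* unrooted trees are stored rooted at an arbitrary basal polytomy with
  ``tree.is_rooted`` False; topology logic that must be rooting-agnostic
  (monophyly) works on edge bipartitions, not subtrees.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Optional

import dendropy


def get_support(node: dendropy.Node) -> Optional[int]:
    """Bootstrap support of the edge above ``node`` (internal nodes only)."""
    return getattr(node, "support", None)


def set_support(node: dendropy.Node, value: Optional[int]) -> None:
    node.support = value  # type: ignore[attr-defined]


def leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or ""


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf_label(l) for l in tree.leaf_node_iter()]


def node_leafsets(tree: dendropy.Tree) -> Dict[dendropy.Node, FrozenSet[str]]:
    """Map every node to the frozenset of leaf labels below it (postorder)."""
    out: Dict[dendropy.Node, FrozenSet[str]] = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            out[node] = frozenset([leaf_label(node)])
        else:
            s: set[str] = set()
            for k in kids:
                s.update(out[k])
            out[node] = frozenset(s)
    return out


def find_mrca(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of ``labels`` in the rooted representation."""
    want = frozenset(labels)
    if not want:
        raise ValueError("cannot take MRCA of an empty label set")
    sets = node_leafsets(tree)
    best = None
    best_size = None
    for node, ls in sets.items():
        if want <= ls and (best_size is None or len(ls) < best_size):
            best, best_size = node, len(ls)
    if best is None:
        missing = want - frozenset(leaf_labels(tree))
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    return best


def build_tree(root: dendropy.Node, rooted: bool = True) -> dendropy.Tree:
    """Wrap a manually built node structure into a Tree with a shared taxon
    namespace for the leaves."""
    tree = dendropy.Tree(seed_node=root)
    tns = dendropy.TaxonNamespace()
    for lf in tree.leaf_node_iter():
        if lf.taxon is None:
            lf.taxon = dendropy.Taxon(label=lf.label)
            lf.label = None
    tree.taxon_namespace = tns
    for lf in tree.leaf_node_iter():
        tns.add_taxon(lf.taxon)
    tree.is_rooted = rooted
    return tree


def new_leaf(label: str, length: Optional[float] = None) -> dendropy.Node:
    node = dendropy.Node(label=label)
    node.edge.length = length
    return node


def new_internal(
    children: list[dendropy.Node],
    length: Optional[float] = None,
    support: Optional[int] = None,
) -> dendropy.Node:
    node = dendropy.Node()
    node.edge.length = length
    set_support(node, support)
    for c in children:
        node.add_child(c)
    return node


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep copy preserving branch lengths, supports and rootedness."""

    def rec(node: dendropy.Node) -> dendropy.Node:
        kids = node.child_nodes()
        if not kids:
            return new_leaf(leaf_label(node), node.edge.length)
        return new_internal([rec(k) for k in kids], node.edge.length, get_support(node))

    return build_tree(rec(tree.seed_node), rooted=bool(tree.is_rooted))


def is_binary(tree: dendropy.Tree) -> bool:
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            return False
    return True


def suppress_unifurcations(tree: dendropy.Tree) -> None:
    """Remove degree-2 nodes, summing the two adjoining branch lengths."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder_node_iter()):
            kids = node.child_nodes()
            if len(kids) == 1 and node.parent_node is not None:
                child = kids[0]
                if node.edge.length is not None or child.edge.length is not None:
                    child.edge.length = (node.edge.length or 0.0) + (
                        child.edge.length or 0.0
                    )
                parent = node.parent_node
                parent.remove_child(node)
                parent.add_child(child)
                changed = True
        # collapse a unifurcating root by promoting its single child
        root = tree.seed_node
        kids = root.child_nodes()
        if len(kids) == 1 and kids[0].child_nodes():
            tree.seed_node = kids[0]
            tree.seed_node.parent_node = None
            tree.seed_node.edge.length = None
            changed = True
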