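"""Synthetic-data generator with ground-truth logs.

Every input the pipeline consumes can be generated here, so that each stage
is testable offline against a known truth:

* a rooted binary species tree (Yule shape) whose leaves are cut into
  clades A-E;
* per-trait binary gene content evolved Dollo-style: present at the root,
  lost on edges drawn without ancestor/descendant overlap (so planted
  losses are recoverable), optionally regained by planted horizontal
  transfer from an external donor group;
* gene trees consistent with the planted history: vertical copies mirror
  the species tree, transferred copies are grafted inside their donor's
  clade in an external-group scaffold; bootstrap supports are 100 on true
  clades unless deliberately degraded;
* hit tables whose e-values/coverages land on the correct side of the
  screening thresholds (present cells pass, decoys fail), with extra weak
  hits for MAG-flagged species;
* annotation tables placing CODH/ACS subunits either in a contiguous
  cluster or dispersed.

All randomness flows through one ``numpy`` Generator seeded from
``SimConfig.seed``; outputs are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from . import io as pio
from .records import GeneLocus, HitRecord, TaxonMeta, default_enzyme_defs
from .scenario import Edge
from .treeutil import (
    build_tree,
    leaf_label,
    new_internal,
    new_leaf,
    node_leafsets,
    set_support,
)

#: default per-trait gene sets: a trait is a unit of gain/loss; complexes
#: expand to their subunits in the truth matrix.
DEFAULT_TRAITS: Dict[str, Tuple[str, ...]] = {
    "cytFdh": ("cytFdh",),
    "FdhG": ("FdhG",),
    "CODH/ACS": ("AcsA", "AcsB", "AcsC", "AcsD", "AcsE"),
    "GCS": ("GCSPa", "GCSPb", "GCST", "GCSL", "GCSH"),
    "GR": ("GR1", "GR2", "GR3", "GR4", "GR5"),
    "PFO": ("PFO",),
    "PSP": ("PSP",),
    "SHMT": ("SHMT",),
    "Fhs": ("Fhs",),
    "FchA": ("FchA",),
    "FolD": ("FolD",),
    "MetF": ("MetF",),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Rates are per trait over the whole tree: ``loss_rate`` is the expected
    number of planted losses (Poisson), ``hgt_rate`` the expected number of
    planted transfers.  E-value decades are sampled log10-uniformly within
    the configured ranges so the screening boundaries are exercised
    densely; coverage ranges are percent.
    """

    seed: int
    n_species: int = 30
    birth_rate: float = 1.0
    loss_rate: float = 1.5
    hgt_rate: float = 0.3
    false_hit_rate: float = 0.0
    dropout_rate: float = 0.0
    true_evalue_log10: Tuple[float, float] = (-100.0, -6.0)
    false_evalue_log10: Tuple[float, float] = (-5.0, -1.0)
    true_coverage: Tuple[float, float] = (70.0, 100.0)
    false_coverage: Tuple[float, float] = (30.0, 69.9)
    mag_fraction: float = 0.1
    n_clades: int = 5
    external_groups: Tuple[str, ...] = (
        "Myxococcota", "PVC", "Nitrospirota", "Epsilonproteobacteria",
    )
    external_clade_size: int = 3
    cluster_fraction: float = 0.8
    support_true: int = 100
    long_branch_decoys: int = 0
    traits: Tuple[str, ...] = tuple(DEFAULT_TRAITS)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("false_hit_rate", "dropout_rate", "mag_fraction", "cluster_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")


@dataclass
class TraitHistory:
    trait_id: str
    leaf_states: Dict[str, bool]          # observed: vertical or transferred
    vertical_states: Dict[str, bool]      # vertical descent only
    loss_edges: List[Edge]
    hgt: Dict[str, str]                   # recipient leaf -> donor group
    identifiable: bool                    # planted losses recoverable by minimal reconstruction


@dataclass
class TruthLog:
    """Ground truth for one generated dataset."""

    matrix: pd.DataFrame                  # species x enzyme bool
    histories: Dict[str, TraitHistory]
    hit_is_true: List[bool] = field(default_factory=list)
    clustered: Dict[str, bool] = field(default_factory=dict)
    clade_map: Dict[str, str] = field(default_factory=dict)

    @property
    def homoplasy_fraction(self) -> float:
        hs = list(self.histories.values())
        if not hs:
            return 0.0
        return sum(0 if h.identifiable else 1 for h in hs) / len(hs)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> dendropy.Tree:
    """Rooted binary tree by a Yule (pure-birth) split process; leaves are
    labeled sp001.. in traversal order; internal supports set to 100."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    root = new_internal([new_leaf("_0"), new_leaf("_1")])
    leaves = root.child_nodes()
    while len(leaves) < cfg.n_species:
        i = int(rng.integers(len(leaves)))
        node = leaves[i]
        node.add_child(new_leaf("_a"))
        node.add_child(new_leaf("_b"))
        node.label = None
        leaves = leaves[:i] + node.child_nodes() + leaves[i + 1 :]
    tree = build_tree(root, rooted=True)
    k = 1
    for lf in tree.leaf_node_iter():
        lf.taxon.label = f"sp{k:03d}"
        k += 1
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = 0.01 + float(rng.exponential(1.0 / cfg.birth_rate)) * 0.1
        if node.child_nodes():
            set_support(node, 100)
    return tree


def assign_clades(tree: dendropy.Tree, k: int = 5) -> Dict[str, str]:
    """Cut the tree into k monophyletic groups by repeatedly splitting the
    largest subtree; groups are labeled A.. in leaf traversal order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    groups: List[dendropy.Node] = [tree.seed_node]
    leafsets = node_leafsets(tree)
    order = {leaf_label(l): i for i, l in enumerate(tree.leaf_node_iter())}
    while len(groups) < k:
        splittable = [g for g in groups if g.child_nodes()]
        if not splittable:
            raise ValueError(f"tree too small to cut into {k} groups")
        biggest = max(
            splittable,
            key=lambda g: (len(leafsets[g]), -min(order[l] for l in leafsets[g])),
        )
        groups.remove(biggest)
        groups.extend(biggest.child_nodes())
    groups.sort(key=lambda g: min(order[l] for l in leafsets[g]))
    out: Dict[str, str] = {}
    for i, g in enumerate(groups):
        label = chr(ord("A") + i)
        for l in leafsets[g]:
            out[l] = label
    return out


# ---------------------------------------------------------------------------
# trait histories
# ---------------------------------------------------------------------------

def simulate_trait_history(
    tree: dendropy.Tree,
    cfg: SimConfig,
    trait_id: str,
    rng: Optional[np.random.Generator] = None,
    forced_losses: Optional[Sequence[Edge]] = None,
    n_losses: Optional[int] = None,
    n_hgt: Optional[int] = None,
) -> TraitHistory:
    """Dollo-style history: present at the root, Poisson(loss_rate) losses
    planted on edges chosen without ancestor/descendant overlap (so each
    planted loss is a maximal absent subtree), then Poisson(hgt_rate)
    transfers regaining the trait on vertically lost leaves.

    ``forced_losses`` plants losses on exactly the given edges (leafsets);
    ``n_losses``/``n_hgt`` override the Poisson draws.  Transfers are only
    planted when at least two vertical carriers remain, so the planted
    signal is recoverable by nestedness classification.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    leafsets = node_leafsets(tree)
    all_leaves = sorted(leafsets[tree.seed_node])
    edges = sorted(
        (ls for node, ls in leafsets.items() if node.parent_node is not None),
        key=lambda e: (len(e), sorted(e)),
    )
    parent_of: Dict[Edge, Edge] = {
        leafsets[node]: leafsets[node.parent_node]
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    }

    chosen: List[Edge] = []
    if forced_losses is not None:
        chosen = [frozenset(e) for e in forced_losses]
        for e in chosen:
            if e not in set(edges):
                raise ValueError(f"forced loss edge {sorted(e)} is not an edge of the tree")
    else:
        k = int(rng.poisson(cfg.loss_rate)) if n_losses is None else n_losses
        for _ in range(k):
            taken: set[str] = set().union(*chosen) if chosen else set()
            eligible = [e for e in edges if not (e & taken)]
            if not eligible:
                break
            chosen.append(eligible[int(rng.integers(len(eligible)))])

    absent = set().union(*chosen) if chosen else set()
    vertical = {l: l not in absent for l in all_leaves}

    # identifiability: a planted loss is recoverable by a minimal
    # single-gain reconstruction only if (a) the trait survives somewhere,
    # (b) the loss's parent lineage retains a present leaf (else sibling
    # losses merge upward), and (c) the loss lies inside the subtree of the
    # survivors' MRCA (a loss outside it is absorbed into a lower gain)
    present_set = frozenset(set(all_leaves) - absent)
    identifiable = bool(present_set)
    if identifiable:
        mrca_set = min(
            (ls for ls in list(edges) + [frozenset(all_leaves)] if present_set <= ls),
            key=len,
        )
        for e in chosen:
            if not (parent_of[e] - absent) or not (parent_of[e] <= mrca_set):
                identifiable = False

    hgt: Dict[str, str] = {}
    n_vertical = sum(vertical.values())
    m = int(rng.poisson(cfg.hgt_rate)) if n_hgt is None else n_hgt
    if m and n_vertical >= 2:
        lost_leaves = sorted(l for l in all_leaves if not vertical[l])
        for _ in range(m):
            candidates = [l for l in lost_leaves if l not in hgt]
            if not candidates:
                break
            leaf = candidates[int(rng.integers(len(candidates)))]
            donor = cfg.external_groups[int(rng.integers(len(cfg.external_groups)))]
            hgt[leaf] = donor

    leaf_states = {l: vertical[l] or (l in hgt) for l in all_leaves}
    return TraitHistory(
        trait_id=trait_id,
        leaf_states=leaf_states,
        vertical_states=vertical,
        loss_edges=sorted(chosen, key=lambda e: (len(e), sorted(e))),
        hgt=hgt,
        identifiable=identifiable,
    )


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def _restrict(node: dendropy.Node, keep: FrozenSet[str], leafsets, jitter) -> Optional[dendropy.Node]:
    below = leafsets[node]
    if not (below & keep):
        return None
    kids = node.child_nodes()
    if not kids:
        return new_leaf(leaf_label(node), jitter(node.edge.length))
    sub = [_restrict(k, keep, leafsets, jitter) for k in kids]
    sub = [s for s in sub if s is not None]
    if len(sub) == 1:
        only = sub[0]
        if node.edge.length is not None and only.edge.length is not None:
            only.edge.length = only.edge.length + jitter(node.edge.length)
        return only
    return new_internal(sub, jitter(node.edge.length), None)


def _group_clade(name: str, size: int, length: float = 0.1) -> dendropy.Node:
    leaves = [new_leaf(f"{name}_{i + 1}", length) for i in range(size)]
    node = leaves[0]
    for extra in leaves[1:]:
        node = new_internal([node, extra], length, None)
    return node


def emit_gene_tree(
    tree: dendropy.Tree,
    hist: TraitHistory,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    degrade_transfer_support: Optional[int] = None,
) -> Tuple[dendropy.Tree, Dict[str, str]]:
    """Gene tree implied by a trait history.

    Vertical carriers form a subtree mirroring the species tree; external
    groups form a caterpillar scaffold; each transferred copy is grafted as
    sister to a leaf of its donor clade.  Supports are ``support_true`` on
    every internal node; ``degrade_transfer_support`` lowers the support of
    each transfer's attachment edge.  Returns the tree and a leaf -> group
    map (focal species keep the label "focal"; callers overlay clade
    labels from taxon metadata as needed).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    present_vertical = frozenset(l for l, s in hist.vertical_states.items() if s)
    if not present_vertical and not hist.hgt:
        raise ValueError(f"trait {hist.trait_id}: no present leaves; cannot emit a gene tree")

    def jitter(x):
        if x is None:
            return None
        return float(x) * float(rng.uniform(0.8, 1.25))

    leafsets = node_leafsets(tree)
    group_map: Dict[str, str] = {}
    parts: List[dendropy.Node] = []
    if present_vertical:
        focal_root = _restrict(tree.seed_node, present_vertical, leafsets, jitter)
        focal_root.edge.length = 0.2
        parts.append(focal_root)
        for l in present_vertical:
            group_map[l] = "focal"
    donor_leaves: Dict[str, List[dendropy.Node]] = {}
    group_roots: Dict[str, dendropy.Node] = {}
    for grp in cfg.external_groups:
        clade = _group_clade(grp, cfg.external_clade_size)
        group_roots[grp] = clade
        donor_leaves[grp] = [n for n in _iter_leaves(clade)]
        for lf in donor_leaves[grp]:
            group_map[leaf_label(lf)] = grp

    # caterpillar over [focal, groups...]
    spine = parts + [group_roots[g] for g in cfg.external_groups]
    assembled = spine[0]
    for nxt in spine[1:]:
        assembled = new_internal([assembled, nxt], 0.1, cfg.support_true)

    root = assembled
    tree_out = build_tree(root, rooted=True)
    for node in tree_out.preorder_internal_node_iter():
        if getattr(node, "support", None) is None:
            set_support(node, cfg.support_true)

    # graft transferred copies inside their donor clades
    for leaf, donor in sorted(hist.hgt.items()):
        host = donor_leaves[donor][0]
        new_copy = new_leaf(leaf, 0.05)
        parent = host.parent_node
        pair = new_internal([], host.edge.length, None)
        set_support(
            pair,
            cfg.support_true if degrade_transfer_support is None else degrade_transfer_support,
        )
        if parent is None:
            raise RuntimeError("donor clade has no internal structure to graft into")
        parent.remove_child(host)
        host.edge.length = 0.05
        pair.add_child(host)
        pair.add_child(new_copy)
        parent.add_child(pair)
        donor_leaves[donor] = donor_leaves[donor][1:] + [host]
        group_map[leaf] = "focal"

    for i in range(cfg.long_branch_decoys):
        decoy = new_leaf(f"decoy_{i + 1}", 2.0)
        tree_out.seed_node.add_child(decoy)
        group_map[f"decoy_{i + 1}"] = "other"

    tree_out = build_tree(tree_out.seed_node, rooted=True)
    return tree_out, group_map


def _iter_leaves(node: dendropy.Node):
    stack = [node]
    while stack:
        n = stack.pop()
        kids = n.child_nodes()
        if not kids:
            yield n
        else:
            stack.extend(kids)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def emit_hit_table(
    matrix: pd.DataFrame,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    mag_species: Sequence[str] = (),
    taxid_map: Optional[Dict[str, str]] = None,
) -> Tuple[List[HitRecord], List[bool]]:
    """Hits implied by a truth matrix (species rows x enzyme columns).

    Present cells emit one passing hit (e-value below 1e-5, coverage >= 70)
    unless dropped out; absent cells emit a failing decoy at
    ``false_hit_rate`` (half bad e-value, half bad coverage).  MAG species
    emit two extra weak-but-passing hits per present cell so the MAG
    e-value filter has something to remove.  Returns the records and a
    parallel true-homolog flag list.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mags = frozenset(mag_species)
    taxid_map = taxid_map or {}
    records: List[HitRecord] = []
    truth_flags: List[bool] = []

    def make(sp: str, enz: str, evalue: float, cov: float, copy: int) -> HitRecord:
        return HitRecord(
            query_id=enz,
            subject_id=f"{sp}|{enz}_{copy}",
            subject_species=sp,
            percent_identity=float(np.round(rng.uniform(35, 95), 1)),
            align_length=int(rng.integers(150, 900)),
            evalue=evalue,
            bitscore=float(np.round(rng.uniform(80, 1200), 1)),
            query_coverage=float(np.round(cov, 1)),
            is_mag_derived=sp in mags,
            taxid=taxid_map.get(sp, ""),
        )

    for sp in matrix.index:
        for enz in matrix.columns:
            if bool(matrix.at[sp, enz]):
                if rng.random() < cfg.dropout_rate:
                    continue
                ev = 10.0 ** float(rng.uniform(*cfg.true_evalue_log10))
                cov = float(rng.uniform(*cfg.true_coverage))
                records.append(make(sp, enz, ev, cov, 1))
                truth_flags.append(True)
                if sp in mags:
                    for copy in (2, 3):
                        ev_weak = 10.0 ** float(rng.uniform(-8.0, -6.0))
                        records.append(
                            make(sp, enz, ev_weak, float(rng.uniform(*cfg.true_coverage)), copy)
                        )
                        truth_flags.append(True)
            elif rng.random() < cfg.false_hit_rate:
                if rng.random() < 0.5:
                    ev = 10.0 ** float(rng.uniform(*cfg.false_evalue_log10))
                    cov = float(rng.uniform(*cfg.true_coverage))
                else:
                    ev = 10.0 ** float(rng.uniform(*cfg.true_evalue_log10))
                    cov = float(rng.uniform(*cfg.false_coverage))
                records.append(make(sp, enz, ev, cov, 1))
                truth_flags.append(False)
    return records, truth_flags


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def emit_annotation(
    matrix: pd.DataFrame,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[GeneLocus], Dict[str, bool]]:
    """Genome annotation implied by the truth matrix.

    Species with the complete CODH/ACS set place acsA-acsE contiguously
    (clustered, probability ``cluster_fraction``) or scatter acsA onto a
    separate contig away from its partners (dispersed).  Filler genes pad
    every contig.  Returns loci (with locus indices assigned) and the truth
    clustered-flag per species that carries AcsA.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    subunits = ["AcsA", "AcsB", "AcsC", "AcsD", "AcsE"]
    loci: List[GeneLocus] = []
    truth: Dict[str, bool] = {}

    def gene(sp, contig, pos, strand, tag, product):
        start = pos * 1000 + 1
        return GeneLocus(sp, contig, start, start + 899, strand, tag, product)

    for sp in matrix.index:
        have = [s for s in subunits if s in matrix.columns and bool(matrix.at[sp, s])]
        tagno = 0

        def tag():
            nonlocal tagno
            tagno += 1
            return f"{sp}_g{tagno:04d}"

        pos = 0
        for _ in range(3):  # leading filler
            loci.append(gene(sp, "c1", pos, "+", tag(), "hyp"))
            pos += 1
        if "AcsA" in have:
            clustered = bool(rng.random() < cfg.cluster_fraction)
            truth[sp] = clustered
            if clustered:
                for s in have:
                    loci.append(gene(sp, "c1", pos, "+", tag(), s))
                    pos += 1
            else:
                for s in have:
                    if s == "AcsA":
                        continue
                    loci.append(gene(sp, "c1", pos, "+", tag(), s))
                    pos += 1
                # anchor far away on its own contig
                loci.append(gene(sp, "c2", 5, "+", tag(), "AcsA"))
                for p in (0, 1, 2):
                    loci.append(gene(sp, "c2", p, "-", tag(), "hyp"))
        else:
            for s in have:
                loci.append(gene(sp, "c1", pos, "+", tag(), s))
                pos += 1
        for _ in range(3):  # trailing filler
            loci.append(gene(sp, "c1", pos, "+", tag(), "hyp"))
            pos += 1
    return pio._assign_locus_indices(loci), truth


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

def expand_traits_to_matrix(
    histories: Dict[str, TraitHistory], species: Sequence[str]
) -> pd.DataFrame:
    """Species x enzyme truth matrix: a complex trait present in a species
    marks all its subunits present."""
    enzymes: List[str] = []
    for t in histories:
        enzymes.extend(DEFAULT_TRAITS[t])
    mat = pd.DataFrame(False, index=list(species), columns=enzymes)
    for t, hist in histories.items():
        for sp, present in hist.leaf_states.items():
            if present:
                for enz in DEFAULT_TRAITS[t]:
                    mat.at[sp, enz] = True
    return mat


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> TruthLog:
    """Generate a complete dataset directory plus truth logs.

    Files written: ``species_tree.nwk``, ``gene_trees/<trait>.nwk``,
    ``gene_trees/<trait>.groups.tsv`` (leaf -> group), ``hits.tsv``,
    ``annotation.tsv``, ``taxa.tsv``, ``enzymes.tsv`` and a ``truth/``
    subdirectory (``matrix.tsv``, ``events.tsv``, ``hgt.tsv``,
    ``clusters.tsv``, ``hit_flags.tsv``).
    """
    outdir = Path(outdir)
    (outdir / "gene_trees").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    tree = simulate_species_tree(cfg, rng)
    clade_map = assign_clades(tree, cfg.n_clades)
    species = [leaf_label(l) for l in tree.leaf_node_iter()]
    pio.write_newick(tree, outdir / "species_tree.nwk")

    n_mags = math.floor(cfg.mag_fraction * len(species))
    mag_species = sorted(
        rng.choice(np.array(species), size=n_mags, replace=False).tolist()
    ) if n_mags else []
    taxid_map = {sp: f"t{i + 1:04d}" for i, sp in enumerate(species)}

    histories: Dict[str, TraitHistory] = {}
    for trait in cfg.traits:
        histories[trait] = simulate_trait_history(tree, cfg, trait, rng)

    matrix = expand_traits_to_matrix(histories, species)
    pio.write_matrix_tsv(matrix, outdir / "truth" / "matrix.tsv")

    # taxon metadata: autotrophs = species with a complete carbon-fixation set
    meta = []
    for sp in species:
        wl = all(matrix.at[sp, e] for e in DEFAULT_TRAITS["CODH/ACS"]) and (
            matrix.at[sp, "cytFdh"] or matrix.at[sp, "FdhG"]
        )
        rgly = all(matrix.at[sp, e] for e in DEFAULT_TRAITS["GCS"]) and (
            matrix.at[sp, "cytFdh"] or matrix.at[sp, "FdhG"]
        )
        meta.append(
            TaxonMeta(
                species=sp,
                clade=clade_map[sp],
                is_mag=sp in mag_species,
                is_autotroph=bool(wl or rgly) if rng.random() < 0.8 else None,
            )
        )
    pio.write_taxon_meta(meta, outdir / "taxa.tsv")
    pio.write_enzyme_defs(default_enzyme_defs(), outdir / "enzymes.tsv")

    hits, flags = emit_hit_table(matrix, cfg, rng, mag_species, taxid_map)
    pio.write_hit_table(hits, outdir / "hits.tsv")
    with open(outdir / "truth" / "hit_flags.tsv", "w") as fh:
        fh.write("index\tis_true\n")
        for i, f in enumerate(flags):
            fh.write(f"{i}\t{str(f).lower()}\n")

    loci, clustered = emit_annotation(matrix, cfg, rng)
    pio.write_annotation_table(loci, outdir / "annotation.tsv")
    with open(outdir / "truth" / "clusters.tsv", "w") as fh:
        fh.write("species\tclustered\n")
        for sp in sorted(clustered):
            fh.write(f"{sp}\t{str(clustered[sp]).lower()}\n")

    for trait, hist in histories.items():
        if not any(hist.leaf_states.values()):
            continue
        gtree, group_map = emit_gene_tree(tree, hist, cfg, rng)
        safe = trait.replace("/", "_")
        pio.write_newick(gtree, outdir / "gene_trees" / f"{safe}.nwk")
        with open(outdir / "gene_trees" / f"{safe}.groups.tsv", "w") as fh:
            fh.write("leaf\tgroup\n")
            for leaf in sorted(group_map):
                grp = group_map[leaf]
                if grp == "focal":
                    grp = clade_map.get(leaf, "other")
                fh.write(f"{leaf}\t{grp}\n")

    with open(outdir / "truth" / "events.tsv", "w") as fh:
        fh.write("trait\tevent\tedge\tdonor\tidentifiable\n")
        for trait, hist in histories.items():
            for e in hist.loss_edges:
                fh.write(
                    f"{trait}\tloss\t{'|'.join(sorted(e))}\t\t{str(hist.identifiable).lower()}\n"
                )
            for leaf, donor in sorted(hist.hgt.items()):
                fh.write(f"{trait}\thgt_gain\t{leaf}\t{donor}\t{str(hist.identifiable).lower()}\n")
    with open(outdir / "truth" / "hgt.tsv", "w") as fh:
        fh.write("trait\trecipient\tdonor\n")
        for trait, hist in histories.items():
            for leaf, donor in sorted(hist.hgt.items()):
                fh.write(f"{trait}\t{leaf}\t{donor}\n")

    return TruthLog(
        matrix=matrix,
        histories=histories,
        hit_is_true=flags,
        clustered=clustered,
        clade_map=clade_map,
    )
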