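# Methods

This note documents the models, rules and numerical choices behind
`pathwayevo`, and what the synthetic benchmarks do and do not show.

## Problem setting

The package reconstructs the evolutionary history of two carbon-fixation
pathways — Wood–Ljungdahl (WL) and reductive glycine (rGly) — across a
bacterial phylum divided into five clades (A–E).  Both pathways start
with formate dehydrogenase (FDH); WL additionally needs the five-subunit
CODH/ACS complex (AcsA–AcsE), rGly the five glycine-cleavage-system
proteins (GCSPα, GCSPβ, GCST, GCSL, GCSH).  Evidence comes in four
forms: protein similarity-search hits against predicted proteomes, gene
order on contigs, per-gene maximum-likelihood trees with bootstrap
supports, and a species tree.  The pipeline consumes these standard
artifacts; it does not run the searches or infer the trees.

## Screening model

A hit is a homolog iff *e*-value < `evalue_max` (default 10⁻⁵, strict
inequality) **and** query coverage ≥ `min_query_coverage` (default 70 %,
inclusive).  Coverage is accepted only on the 0–100 scale; values in
(0, 1) are rejected rather than rescaled, to surface unit bugs.  The
reader records coverage as given (per-hit); whether a search engine
reports it per-HSP or aggregated per subject is upstream of this
package.

Two further curation steps apply when assembling sequence sets for tree
building (not for presence calls):

* **MAG thinning** — among hits whose subject genome is a
  metagenome-assembled genome, only the best `⌈n × 0.10⌉` by *e*-value
  survive, per query enzyme.  The ceiling guarantees one survivor
  whenever any MAG hit exists; ties break by bitscore (descending) then
  subject id, so reruns are bit-identical.
* **Taxid representatives** — at most one hit per taxid from a declared
  panel, best *e*-value first with the same tie-break.

Presence requires ≥ 1 surviving hit per (species, enzyme) cell; no
copy-number threshold.  Every present cell carries provenance (subject
ids, best *e*-value).

## Pathway rules

WL = FDH ∧ CODH/ACS complete; rGly = FDH ∧ GCS complete, where FDH means
either catalytic-subunit family (cytoplasmic Fdh or FdhG) and "complete"
means every declared subunit present.  Calls are monotone: adding a
present cell can never turn a call off (tested by brute force over all
4096 governing-subunit patterns).  Autotrophy consistency is purely
descriptive: a flagged autotroph should have at least one called pathway
plus a viable downstream route — PFO ∧ PSP ∧ SHMT for WL; for rGly
either a complete glycine-reductase complex or the serine route
(SHMT ∧ PFO).  Both routes are reported separately, and species with
complete pathway gene sets but no demonstrated autotrophy are flagged as
such, never reclassified.

## Synteny rule

The CODH/ACS gene cluster marks a WL-functional AcsA; standalone
AcsA homologs (CooS-like) do not act in acetyl-CoA synthesis.  "Cluster"
is operationalised as chain extension on the anchor's contig: walking
outward in locus order, the next subunit gene joins if at most
`cluster_max_gap` (default 2) non-subunit genes intervene since the last
member, otherwise that direction stops.  A copy is concatenation-eligible
with ≥ `cluster_min_partners` (default 3) partners.  The rule is
strand-agnostic (co-orientation is reported, not required) and invariant
under reversing a contig's coordinate system; increasing the gap
tolerance can only add partners (both properties are tested).  The gap
tolerance is a design choice — small enough to exclude genome-distant
copies, tolerant of small insertions; any value in the tested range
reproduces the contiguous-cluster and dispersed-copy fixtures.

## Gene-tree screening

* **Long-branch pruning** removes leaves whose *pendant* branch exceeds
  `long_branch_cutoff` (default 1.5 substitutions/site, strict), once,
  never iterated; long internal branches are logged but kept, since the
  exclusion targets individual runaway sequences.  Degree-2 nodes left
  behind are suppressed with branch lengths summed.
* **Monophyly** is an edge-bipartition property — some edge separates
  exactly the focal leaves from the rest — so the verdict is invariant
  under re-rooting and is well defined for unrooted trees.
* **Group splitting** reports the maximal all-focal clades, numbered by
  decreasing size; a group is "distinct" when its stem support reaches
  `group_support_min` (default 95).
* **HGT classification** operationalises nestedness per focal leaf:
  leaves inside the largest all-focal clade are *vertical*; otherwise the
  smallest enclosing clade containing a non-focal leaf is examined.  If
  its stem support is missing or below `hgt_support_min` (default 95)
  the verdict is *unresolved* — degraded support never silently becomes
  *vertical*.  With sufficient support, a single foreign group must
  contribute a strict majority (> `majority_fraction`, default 0.5) of
  the non-focal leaves for an *hgt_candidate* call with that donor;
  otherwise *unresolved*.  The support threshold is deliberately
  conservative and configurable: real gene trees carry informative
  clades at lower support, and lowering the threshold trades resolution
  for confidence.  The three verdicts always partition the focal set.

## Scenario model

Dollo parsimony is the default: a multi-gene trait is gained once — on
the stem of the MRCA of its carriers — and otherwise explained by
independent losses, one per maximal absent subtree.  This matches the
biology of pathway gene sets (re-invention implausible, loss routine)
and makes HGT the only mechanism of re-appearance.  Presence attributed
to transfer is therefore **recoded to absent before** the
reconstruction, so transferred copies never pull the vertical gain
upward; an `hgt_gain(donor)` event is then placed on the stem of each
maximal recoded clade (with a warning when the recoded species are not
monophyletic, as in a donor that seeded two separate clades).  Polytomies
are soft: each child of a polytomy is reported individually, losses are
never merged into the stem.  Unconstrained Fitch small parsimony (ties
resolved toward presence at the root, parent state preferred below) is
retained as a diagnostic for traits where gain-free parsimony is much
cheaper than single-gain.

The scenario satisfies a replay invariant, enforced by tests: replaying
root→leaf events reproduces every observed (pre-recoding) leaf state,
with `hgt_gain` restoring presence.  An ancestor report replays events
down to any node; a node's stem events count as applying at that node.

Edges are identified by the set of leaves below them, which is stable
across re-reading the same tree and is how events are written to the
scenario table.

## Synthetic-data generator

The generator emulates the statistical structure the inference assumes:

* **Species tree** — Yule (pure-birth) topology, default 30 species,
  exponential branch lengths (scaled by the birth rate, default 1.0),
  cut into five monophyletic clades A–E by repeatedly splitting the
  largest subtree.
* **Trait histories** — present at the root; Poisson(`loss_rate`,
  default 1.5 per trait) losses planted on edges chosen without
  ancestor/descendant overlap, so each planted loss is a maximal absent
  subtree; Poisson(`hgt_rate`, default 0.3) transfers regain the trait
  on vertically lost leaves, with donors drawn from four external groups.
  Transfers are planted only when ≥ 2 vertical carriers remain, since a
  single-leaf "core" cannot anchor nestedness classification.  A planted
  history is flagged *identifiable* when every loss lies inside the
  survivors' MRCA subtree and its parent lineage retains a carrier;
  non-identifiable histories (sibling losses that merge, losses absorbed
  into a lower gain) are reported as the homoplasy fraction and excluded
  from loss-recovery scoring, never from the dataset.
* **Gene trees** — vertical carriers mirror the species tree (branch
  lengths jittered ×U(0.8, 1.25)); external groups form a caterpillar
  scaffold; transferred copies are grafted as sister to a donor-clade
  leaf.  True clades get support 100; a degrade option lowers the
  transfer attachment support to create unresolved cases; optional
  decoy leaves with pendant length 2.0 exercise long-branch pruning.
* **Hit tables** — present cells emit *e*-values 10^U(−100, −6) and
  coverage U(70, 100); decoys for absent cells (at `false_hit_rate`)
  fail exactly one threshold: *e*-value 10^U(−5, −1) or coverage
  U(30, 69.9).  Log-uniform decades exercise the boundary densely, and
  the half-open ranges sit exactly on the strict/inclusive sides of the
  cutoffs.  MAG species emit two extra weak-but-passing copies per
  present cell so the MAG filter has work to do.
* **Annotation** — CODH/ACS carriers are clustered (acsA–acsE
  contiguous) with probability 0.8, else the AcsA copy is scattered to a
  separate contig; filler genes pad every contig.

All randomness flows through one numpy Generator seeded from
`SimConfig.seed`; dataset directories are byte-identical across reruns.

What passing the synthetic benchmarks shows: the implementation computes
the stated rules exactly and recovers planted signal perfectly in the
noiseless regime.  What it does not show: robustness to the failure
modes of real data — annotation errors, partial assemblies, gene-tree
estimation error, compositional attraction — which enter upstream of
this package's inputs.

## Verification design

Every non-trivial computation is checked against an independent route:
Fitch against brute-force enumeration of all internal labelings over all
945 rooted six-leaf topologies × 64 leaf patterns; Dollo against
exhaustive single-gain-constrained labeling enumeration; monophyly
against dendropy's bitmask bipartition encoding on 500 random 12-leaf
trees; HGT classification against generator truth on a 100-tree
planted-transfer benchmark; and the full pipeline against the truth logs
of a noiseless 30-species, 12-trait dataset.  Benchmark sizes were
chosen to keep the default suite in seconds while still sweeping the
full combinatorial space where that is feasible (six leaves for Fitch,
five for Dollo).

## Known limitations

* The HGT rule is topological nestedness, not event-cost reconciliation;
  a transfer whose donor group is absent from the tree, or one that
  replaces the resident copy in place (leaving the focal clade intact),
  is invisible to it.
* Dollo identifiability is inherently limited: sibling losses covering a
  full subtree are reconstructed as one loss on the parent stem, and
  losses above the carriers' MRCA are absorbed into a lower gain.  The
  generator reports the affected fraction rather than hiding it.
* Presence calls ignore domain architecture; the upstream
  domain-structure filter is modelled as an optional pre-filtered input,
  not recomputed.
* The methyl-branch enzymes have no completeness rule; they are
  screened and reported per enzyme only.
* The shipped clade-level backbone is a transcribed six-taxon topology
  (five clades plus outgroup) for worked-scenario computations;
  species-level scenario placement requires the user's own species tree.
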