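# pathwayevo

Ancestral gain/loss/HGT reconstruction of carbon-fixation pathway gene
content across a bacterial phylum.

Many anaerobic bacteria fix CO₂ through the **Wood–Ljungdahl (WL)
pathway** (formate dehydrogenase + the five-subunit CODH/ACS complex,
AcsA–AcsE) or the **reductive glycine (rGly) pathway** (formate
dehydrogenase + the five glycine-cleavage-system proteins, GCSPα, GCSPβ,
GCST, GCSL, GCSH run in reverse).  Given protein-homology hit tables,
genome annotation, a species tree and per-gene trees, `pathwayevo` infers
which extant species carry each pathway and how that distribution arose —
which gene sets the phylum's common ancestor possessed, where they were
lost, and where they were regained by horizontal gene transfer (HGT).

The pipeline chains five inferences:

1. **Homolog screening** — a hit counts as a homolog iff
   *e*-value < 10⁻⁵ (strict) and query coverage ≥ 70 %; metagenome-derived
   (MAG) hits are additionally thinned to their best ⌈10 %⌉ by *e*-value
   before tree building, and one representative is kept per declared NCBI
   taxid.  The result is a species × enzyme presence/absence matrix with
   per-cell provenance.
2. **Pathway calls** — WL = FDH ∧ (AcsA ∧ … ∧ AcsE);
   rGly = FDH ∧ (GCSPα ∧ … ∧ GCSH), where FDH means either
   catalytic-subunit family (cytoplasmic Fdh or FdhG).  Downstream
   enzymes (PFO, PSP, SHMT; glycine reductase) qualify whether a called
   pathway could sustain autotrophy.
3. **Synteny** — an AcsA copy is a WL candidate only if it clusters on its
   contig with the other CODH/ACS subunits (chain extension tolerating ≤ 2
   intervening genes); standalone copies are CooS-like and not counted.
4. **Gene-tree screening** — leaves on pendant branches > 1.5
   substitutions/site are pruned; monophyly of the focal phylum is tested
   as an edge bipartition (rooting-free); focal sequences nested inside a
   foreign clade with bootstrap support ≥ 95 are called HGT candidates
   with that clade as donor, and weaker support yields "unresolved",
   never "vertical".
5. **Scenario** — per gene set, **Dollo parsimony** on the species tree:
   one gain on the stem of the carriers' MRCA, one loss per maximal
   absent subtree; horizontally acquired presence is recoded to absent
   before the reconstruction and restored as an `hgt_gain(donor)` event on
   the recoded clade's stem.  Unconstrained Fitch parsimony is available
   as a diagnostic.

A synthetic-data generator (`pathwayevo.simulate`) produces every input
with ground-truth logs, so the whole chain is verifiable offline.

## Worked example

```sh
pathwayevo simulate --seed 11 --n-species 12 --out demo
pathwayevo all --data demo --out demo_out
```

`demo_out/presence_report.txt` is the per-species presence/pathway table
(autotrophs marked ●, unknown ?):

```
species  clade  autotroph  FDH  CODH/ACS  GCS  WL  rGly
-------  -----  ---------  ---  --------  ---  --  ----
sp001    A      ●          +    +         +    +   +
sp002    A      ●          +    -         +    -   +
sp003    A      ●          +    -         +    -   +
sp004    A      ●          +    +         +    +   +
sp005    B      ●          +    +         +    +   +
...
```

sp002/sp003 lack the complete CODH/ACS set, so only rGly is called for
them; every species keeps FDH, so no pathway is blocked at the first
step.  `demo_out/scenario.tsv` lists the reconstructed events per gene
set; an edge is named by the leaves below it:

```
trait     edge                 event     donor
CODH/ACS  sp002|sp003          loss
CODH/ACS  sp001|...|sp012      gain
FdhG      sp007                hgt_gain  Myxococcota
FdhG      sp006|...|sp010      loss
```

Read: the CODH/ACS set was gained on the phylum stem and lost once on the
stem of the (sp002, sp003) clade; FdhG was lost in the sp006–sp010 clade
and regained in sp007 by transfer from the Myxococcota.
`demo_out/ancestors.tsv` replays the events down to the phylum's MRCA —
here every gene set is reconstructed present (`via_hgt False`), i.e. the
common ancestor carried the key enzymes of both pathways.

The same stages are importable as a library (`filter_hits`,
`build_presence_matrix`, `call_pathways`, `detect_cluster`,
`assess_monophyly`, `classify_hgt`, `dollo_reconstruct`,
`build_scenario`, …); see `docs/methods.md` for the model and parameter
details.

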