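"""pathwayevo: ancestral gain/loss/HGT reconstruction of carbon-fixation
pathway gene content across a bacterial phylum.

The package turns protein-homology hit tables, genome annotation, and
gene/species trees into (1) a curated species x enzyme presence/absence
matrix, (2) Wood-Ljungdahl / reductive-glycine pathway-completeness calls,
(3) CODH/ACS synteny-cluster calls, (4) per-gene-tree monophyly and
horizontal-transfer verdicts, and (5) a Dollo-parsimony event scenario
(gains, losses, HGT gains with donors) on the species tree.  A synthetic
data generator with truth logs makes every stage verifiable offline.
"""

from importlib import resources

from .records import (
    COMPLEX_SUBUNITS,
    DEFAULT_GROUP_VOCAB,
    EnzymeDef,
    GeneLocus,
    HitRecord,
    TaxonMeta,
    default_enzyme_defs,
)
from .screen import (
    PresenceMatrix,
    Thresholds,
    build_presence_matrix,
    filter_hits,
    mag_evalue_filter,
    select_representatives,
)
from .pathways import (
    PathwayCall,
    autotrophy_consistency,
    call_complex_complete,
    call_fdh,
    call_pathways,
)
from .synteny import ClusterCall, classify_acsa_copies, detect_cluster
from .treescreen import (
    HGTCall,
    MonophylyVerdict,
    classify_hgt,
    prune_long_branches,
    split_focal_groups,
    assess_monophyly,
)
from .scenario import (
    Event,
    EventScenario,
    TraitProfile,
    ancestor_report,
    build_scenario,
    dollo_reconstruct,
    fitch_min_changes,
)
from .simulate import SimConfig, TruthLog, simulate_dataset, simulate_species_tree
from .pipeline import RunConfig, run_pipeline

__version__ = "0.1.0"


def load_clade_backbone():
    """The transcribed clade-level backbone tree (((((A,B),C),D),E),OUT).

    Clades A-E are the focal phylum's five clades collapsed to single tips;
    OUT is the outgroup.  This is a transcribed topology fixture, not
    measured data.
    """
    from .io import parse_newick

    text = (
        resources.files("pathwayevo.data").joinpath("backbone_clades.nwk").read_text()
    )
    return parse_newick(text)
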