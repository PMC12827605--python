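"""Synteny-cluster detection for the CODH/ACS gene cluster.

A genuine Wood-Ljungdahl CODH (AcsA) is encoded in a cluster with the other
four complex subunits (AcsB-AcsE); standalone AcsA homologs (CooS-like) sit
elsewhere in the genome and do not act in acetyl-CoA synthesis.  The
detector walks outward from an anchor AcsA copy along its contig and
extends the cluster gene-by-gene, tolerating at most ``cluster_max_gap``
intervening non-subunit genes between consecutive cluster members.
Clustering is strand-agnostic: operonic co-orientation is reported but not
required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence

import pandas as pd

from .records import GeneLocus
from .screen import Thresholds

ANCHOR_LABEL = "AcsA"
PARTNER_LABELS = ("AcsB", "AcsC", "AcsD", "AcsE")
MEMBER_LABELS = (ANCHOR_LABEL,) + PARTNER_LABELS


@dataclass(frozen=True)
class ClusterCall:
    species: str
    anchor_locus: str  # locus_tag of the anchor AcsA copy
    partner_subunits_found: FrozenSet[str]
    is_clustered: bool
    concat_eligible: bool
    co_oriented: bool = True  # all cluster members on the anchor strand

    def __post_init__(self) -> None:
        assert not self.is_clustered or self.partner_subunits_found
        # concat eligibility is set by the caller from cluster_min_partners


def detect_cluster(
    loci: Sequence[GeneLocus],
    anchor: GeneLocus,
    t: Thresholds = Thresholds(),
    member_labels: Sequence[str] = MEMBER_LABELS,
    partner_labels: Sequence[str] = PARTNER_LABELS,
) -> ClusterCall:
    """Chain-extension cluster detection around one anchor copy.

    Only loci on the anchor's contig matter.  Starting at the anchor, the
    chain extends independently left and right in locus order: the next
    subunit gene joins if at most ``t.cluster_max_gap`` non-subunit genes
    intervene since the last member, otherwise that direction stops.
    """
    if anchor not in loci:
        raise ValueError(
            f"anchor {anchor.locus_tag} not among the supplied loci for {anchor.species}"
        )
    members = frozenset(member_labels)
    partners = frozenset(partner_labels)
    contig = sorted(
        (l for l in loci if l.species == anchor.species and l.contig == anchor.contig),
        key=lambda l: l.locus_index,
    )
    pos = next(i for i, l in enumerate(contig) if l == anchor)

    found: set[str] = set()
    chain: List[GeneLocus] = [anchor]
    for step in (1, -1):
        last = pos
        i = pos + step
        while 0 <= i < len(contig):
            if contig[i].product_label in members:
                # gap = intervening non-subunit genes since the last member
                if abs(i - last) - 1 <= t.cluster_max_gap:
                    if contig[i].product_label in partners:
                        found.add(contig[i].product_label)
                    chain.append(contig[i])
                    last = i
                else:
                    break
            i += step

    return ClusterCall(
        species=anchor.species,
        anchor_locus=anchor.locus_tag,
        partner_subunits_found=frozenset(found),
        is_clustered=bool(found),
        concat_eligible=len(found) >= t.cluster_min_partners,
        co_oriented=all(l.strand == anchor.strand for l in chain),
    )


def detect_clusters_for_species(
    loci: Sequence[GeneLocus], species: str, t: Thresholds = Thresholds()
) -> List[ClusterCall]:
    """One ClusterCall per AcsA copy of the species (empty when none)."""
    sp_loci = [l for l in loci if l.species == species]
    anchors = [l for l in sp_loci if l.product_label == ANCHOR_LABEL]
    return [detect_cluster(sp_loci, a, t) for a in anchors]


WL_CANDIDATE = "WL-candidate"
STANDALONE = "standalone CooS-like"


@dataclass
class AcsACopyAnnotation:
    species: str
    anchor_locus: str
    label: str  # WL_CANDIDATE or STANDALONE


def classify_acsa_copies(
    calls_per_species: Dict[str, Sequence[ClusterCall]],
) -> tuple[List[AcsACopyAnnotation], Dict[str, str]]:
    """Annotate each AcsA copy as WL-candidate (clustered) or standalone
    CooS-like (unclustered), and summarise per species whether both kinds
    co-occur."""
    annotations: List[AcsACopyAnnotation] = []
    summary: Dict[str, str] = {}
    for species, calls in calls_per_species.items():
        labels = []
        for c in calls:
            lab = WL_CANDIDATE if c.is_clustered else STANDALONE
            labels.append(lab)
            annotations.append(AcsACopyAnnotation(species, c.anchor_locus, lab))
        kinds = set(labels)
        if not labels:
            summary[species] = "no AcsA"
        elif kinds == {WL_CANDIDATE, STANDALONE}:
            summary[species] = "both kinds"
        elif kinds == {WL_CANDIDATE}:
            summary[species] = "clustered only"
        else:
            summary[species] = "standalone only"
    return annotations, summary


def cluster_calls_frame(calls: Sequence[ClusterCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": c.species,
                "anchor_locus": c.anchor_locus,
                "partners": ",".join(sorted(c.partner_subunits_found)),
                "n_partners": len(c.partner_subunits_found),
                "is_clustered": c.is_clustered,
                "concat_eligible": c.concat_eligible,
                "co_oriented": c.co_oriented,
            }
            for c in calls
        ],
        columns=[
            "species", "anchor_locus", "partners", "n_partners",
            "is_clustered", "concat_eligible", "co_oriented",
        ],
    )


def clusters_to_bed(
    calls: Sequence[ClusterCall], loci: Sequence[GeneLocus]
) -> List[str]:
    """BED lines (0-based half-open) spanning each detected cluster's anchor
    contig extent; conversion from the 1-based inclusive internal model is
    start-1 / end."""
    by_tag = {(l.species, l.locus_tag): l for l in loci}
    lines = []
    for c in calls:
        if not c.is_clustered:
            continue
        anchor = by_tag[(c.species, c.anchor_locus)]
        contig_members = [
            l
            for l in loci
            if l.species == c.species
            and l.contig == anchor.contig
            and l.product_label in MEMBER_LABELS
        ]
        start = min(l.start for l in contig_members) - 1
        end = max(l.end for l in contig_members)
        lines.append(f"{anchor.contig}\t{start}\t{end}\t{c.species}:{c.anchor_locus}")
    return lines
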