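"""Homolog screening: thresholds, hit curation and the presence/absence matrix.

The screening chain mirrors standard comparative-genomics practice for
calling gene presence from protein similarity searches:

1. :func:`filter_hits` — homolog definition: e-value strictly below the
   cutoff (default 1e-5) and query coverage at least the cutoff
   (default 70%);
2. :func:`mag_evalue_filter` — among hits whose subject genome is a
   metagenome-assembled genome (MAG), only the best ~10% by e-value are
   retained (MAG proteomes are noisy; the bulk of weak MAG hits is dropped
   before tree building);
3. :func:`select_representatives` — one best hit per NCBI taxid from a
   declared taxid panel, to cover diversity without redundancy;
4. :func:`build_presence_matrix` — species x enzyme boolean calls with full
   per-cell provenance.

Steps 2-3 curate sequence sets for phylogenetics; presence calls use step 1
only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .records import HitRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """All numeric cutoffs used across the pipeline.

    evalue_max
        homolog e-value cutoff, exclusive (keep iff evalue < evalue_max).
    min_query_coverage
        homolog query-coverage cutoff in percent, inclusive.
    mag_keep_fraction
        fraction of MAG-derived hits kept by the MAG e-value filter
        (ceil(n * fraction) best hits survive).
    long_branch_cutoff
        pendant branch length (substitutions/site) above which a leaf is
        pruned from gene trees, exclusive (prune iff length > cutoff).
    hgt_support_min
        minimum bootstrap support for a nesting clade to ground a
        horizontal-transfer verdict.
    group_support_min
        minimum bootstrap support for a focal clade to count as a
        "distinct group" when the focal set splits.
    cluster_max_gap
        maximum number of intervening non-subunit genes tolerated between
        consecutive members of a synteny cluster.
    cluster_min_partners
        minimum number of partner subunits clustered with an anchor for the
        copy to be eligible for concatenated analysis.
    majority_fraction
        strict lower bound on the fraction of non-focal leaves a donor
        group must contribute inside the nesting clade.
    """

    evalue_max: float = 1e-5
    min_query_coverage: float = 70.0
    mag_keep_fraction: float = 0.10
    long_branch_cutoff: float = 1.5
    hgt_support_min: int = 95
    group_support_min: int = 95
    cluster_max_gap: int = 2
    cluster_min_partners: int = 3
    majority_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not (0 <= self.min_query_coverage <= 100):
            raise ValueError("min_query_coverage must be in [0, 100]")
        if not (0 < self.mag_keep_fraction <= 1):
            raise ValueError("mag_keep_fraction must be in (0, 1]")
        if self.long_branch_cutoff <= 0:
            raise ValueError("long_branch_cutoff must be positive")
        for name in ("hgt_support_min", "group_support_min"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100]")
        if self.cluster_max_gap < 0 or self.cluster_min_partners < 0:
            raise ValueError("cluster thresholds must be non-negative")
        if not (0 <= self.majority_fraction < 1):
            raise ValueError("majority_fraction must be in [0, 1)")


def filter_hits(hits: Sequence[HitRecord], t: Thresholds = Thresholds()) -> List[HitRecord]:
    """Keep homologs: evalue strictly below cutoff AND coverage at least the
    cutoff.  Order preserved; idempotent."""
    return [
        h
        for h in hits
        if h.evalue < t.evalue_max and h.query_coverage >= t.min_query_coverage
    ]


def _hit_rank_key(h: HitRecord) -> Tuple[float, float, str]:
    # best first: smallest evalue, then largest bitscore, then lexicographic id
    return (h.evalue, -h.bitscore, h.subject_id)


def mag_evalue_filter(hits: Sequence[HitRecord], t: Thresholds = Thresholds()) -> List[HitRecord]:
    """Drop the weakest MAG-derived hits for one query enzyme.

    Among MAG-derived hits, only the best ``ceil(n * mag_keep_fraction)``
    by e-value survive (ties: bitscore descending, then subject id).  The
    ceiling guarantees at least one survivor whenever any MAG hit exists.
    Non-MAG hits are never touched; input order is preserved.
    """
    mag_idx = [i for i, h in enumerate(hits) if h.is_mag_derived]
    if not mag_idx:
        return list(hits)
    n_keep = math.ceil(len(mag_idx) * t.mag_keep_fraction)
    ranked = sorted(mag_idx, key=lambda i: _hit_rank_key(hits[i]))
    keep = set(ranked[:n_keep])
    return [h for i, h in enumerate(hits) if not h.is_mag_derived or i in keep]


def select_representatives(
    hits: Sequence[HitRecord], allowed_taxids: Iterable[str]
) -> List[HitRecord]:
    """One best hit per taxid, restricted to the allowed taxid panel.

    Hits with an empty taxid are dropped with a warning; hits whose taxid
    is outside the panel are dropped silently.  Output preserves input
    order of the winners.
    """
    allowed = frozenset(allowed_taxids)
    best: Dict[str, int] = {}
    for i, h in enumerate(hits):
        if not h.taxid:
            log.warning("dropping hit %s -> %s with empty taxid", h.query_id, h.subject_id)
            continue
        if h.taxid not in allowed:
            continue
        j = best.get(h.taxid)
        if j is None or _hit_rank_key(h) < _hit_rank_key(hits[j]):
            best[h.taxid] = i
    winners = sorted(best.values())
    return [hits[i] for i in winners]


@dataclass
class PresenceMatrix:
    """Species x enzyme boolean presence calls with per-cell provenance.

    ``provenance[(species, enzyme)]`` lists the supporting subject ids;
    ``best_evalue`` records the smallest supporting e-value per cell.
    Provenance is non-empty exactly for present cells.
    """

    species: List[str]
    enzymes: List[str]
    values: pd.DataFrame  # bool, species rows x enzyme columns
    provenance: Dict[Tuple[str, str], List[str]] = field(default_factory=dict)
    best_evalue: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def present(self, species: str, enzyme: str) -> bool:
        return bool(self.values.at[species, enzyme])

    def row(self, species: str) -> Dict[str, bool]:
        return {e: bool(v) for e, v in self.values.loc[species].items()}

    def provenance_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": sp,
                "enzyme": enz,
                "subject_ids": ",".join(subjects),
                "best_evalue": self.best_evalue[(sp, enz)],
            }
            for (sp, enz), subjects in sorted(self.provenance.items())
        ]
        return pd.DataFrame(rows, columns=["species", "enzyme", "subject_ids", "best_evalue"])


def build_presence_matrix(
    filtered_hits: Sequence[HitRecord],
    species: Sequence[str],
    enzymes: Sequence[str],
) -> PresenceMatrix:
    """Call a cell present iff at least one surviving hit pairs that species
    with that enzyme (query id = enzyme id).  Hits naming unknown species or
    enzymes are ignored with a warning."""
    sp_set, enz_set = frozenset(species), frozenset(enzymes)
    values = pd.DataFrame(False, index=list(species), columns=list(enzymes))
    provenance: Dict[Tuple[str, str], List[str]] = {}
    best: Dict[Tuple[str, str], float] = {}
    for h in filtered_hits:
        if h.subject_species not in sp_set:
            log.warning("hit subject species %r not in species list; ignored", h.subject_species)
            continue
        if h.query_id not in enz_set:
            log.warning("hit query %r not in enzyme list; ignored", h.query_id)
            continue
        key = (h.subject_species, h.query_id)
        values.at[key] = True
        provenance.setdefault(key, []).append(h.subject_id)
        best[key] = min(best.get(key, float("inf")), h.evalue)
    return PresenceMatrix(list(species), list(enzymes), values, provenance, best)
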