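"""Core domain records shared across the pipeline.

The pipeline moves between five tabular representations: protein
similarity-search hits, genome annotation loci, taxon metadata, enzyme
(subunit) definitions, and numeric screening thresholds.  Each is a small
validated dataclass; file parsing lives in :mod:`pathwayevo.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet

#: Clade labels used for the focal phylum.
FOCAL_CLADES = ("A", "B", "C", "D", "E")

#: Default controlled vocabulary for taxon group labels: focal clades plus
#: the external comparison groups gene trees are screened against.
DEFAULT_GROUP_VOCAB = FOCAL_CLADES + (
    "Myxococcota",
    "PVC",
    "Nitrospirota",
    "Epsilonproteobacteria",
    "other",
)

#: Canonical subunit composition of the multi-subunit complexes.  The
#: CO-dehydrogenase/acetyl-CoA synthase (CODH/ACS) complex and the glycine
#: cleavage system (GCS) each have exactly five subunits; the glycine
#: reductase (GR) complex is modelled with five generic subunits.
COMPLEX_SUBUNITS = {
    "CODH/ACS": ("AcsA", "AcsB", "AcsC", "AcsD", "AcsE"),
    "GCS": ("GCSPa", "GCSPb", "GCST", "GCSL", "GCSH"),
    "GR": ("GR1", "GR2", "GR3", "GR4", "GR5"),
}

VALID_COMPLEXES = ("FDH", "CODH/ACS", "GCS", "GR", "none")
VALID_PATHWAY_ROLES = ("WL", "rGly", "downstream")


@dataclass(frozen=True)
class HitRecord:
    """One protein similarity-search hit (BLAST tabular style plus coverage).

    ``query_coverage`` is on the 0-100 percent scale; ``evalue`` is the
    search e-value.  ``is_mag_derived`` flags hits whose subject genome is a
    metagenome-assembled genome (MAG); ``taxid`` is the subject's taxonomy
    identifier when known (empty string otherwise).
    """

    query_id: str
    subject_id: str
    subject_species: str
    percent_identity: float
    align_length: int
    evalue: float
    bitscore: float
    query_coverage: float
    is_mag_derived: bool = False
    taxid: str = ""

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValueError(
                f"query_coverage must be on the 0-100 scale, got {self.query_coverage}"
            )
        if 0.0 < self.query_coverage < 1.0:
            # A sub-1 coverage almost certainly means a 0-1 fraction was
            # supplied; reject rather than silently rescale.
            raise ValueError(
                f"query_coverage {self.query_coverage} looks like a 0-1 fraction; "
                "supply percent on the 0-100 scale"
            )
        if self.align_length <= 0:
            raise ValueError("align_length must be positive")


@dataclass(frozen=True)
class GeneLocus:
    """One annotated gene on a contig (1-based inclusive coordinates)."""

    species: str
    contig: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product_label: str
    locus_index: int = 0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"locus {self.locus_tag}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class TaxonMeta:
    """Per-species metadata: clade/group label, MAG flag, autotrophy flag.

    ``is_autotroph`` is True/False when the literature settles it and None
    when unknown.
    """

    species: str
    clade: str
    is_mag: bool = False
    is_autotroph: bool | None = None

    def validate_clade(self, vocab: tuple[str, ...] = DEFAULT_GROUP_VOCAB) -> None:
        if self.clade not in vocab:
            raise ValueError(
                f"unknown clade/group label {self.clade!r} for {self.species}; "
                f"expected one of {sorted(vocab)}"
            )


@dataclass(frozen=True)
class EnzymeDef:
    """One enzyme subunit role: which complex it belongs to and which
    pathway(s) it serves."""

    enzyme_id: str
    complex: str = "none"
    pathway_roles: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.complex not in VALID_COMPLEXES:
            raise ValueError(
                f"unknown complex {self.complex!r}; expected one of {VALID_COMPLEXES}"
            )
        bad = set(self.pathway_roles) - set(VALID_PATHWAY_ROLES)
        if bad:
            raise ValueError(f"unknown pathway roles {sorted(bad)}")


def validate_enzyme_defs(defs: list[EnzymeDef]) -> None:
    """Check complex completeness: every declared multi-subunit complex must
    list exactly its canonical subunits, each exactly once."""
    ids = [d.enzyme_id for d in defs]
    dupes = {e for e in ids if ids.count(e) > 1}
    if dupes:
        raise ValueError(f"duplicate enzyme ids: {sorted(dupes)}")
    by_complex: dict[str, list[str]] = {}
    for d in defs:
        by_complex.setdefault(d.complex, []).append(d.enzyme_id)
    for cx, subunits in COMPLEX_SUBUNITS.items():
        declared = by_complex.get(cx)
        if declared is None:
            continue
        missing = set(subunits) - set(declared)
        extra = set(declared) - set(subunits)
        if missing or extra:
            name = {"CODH/ACS": "CODH/ACS", "GCS": "GCS", "GR": "GR"}[cx]
            parts = []
            if missing:
                parts.append(f"missing {sorted(missing)}")
            if extra:
                parts.append(f"unexpected {sorted(extra)}")
            raise ValueError(
                f"incomplete {name} complex definition: " + "; ".join(parts)
            )


def default_enzyme_defs() -> list[EnzymeDef]:
    """The built-in enzyme/pathway definition table.

    Covers the two formate-dehydrogenase catalytic-subunit families
    (cytoplasmic Fdh and FdhG), the five CODH/ACS subunits, the five
    glycine-cleavage-system proteins, the methyl-branch enzymes shared by
    the Wood-Ljungdahl (WL) and reductive glycine (rGly) routes, and the
    downstream enzymes used for autotrophy-consistency checks.
    """
    defs = [
        EnzymeDef("cytFdh", "FDH", frozenset({"WL", "rGly"})),
        EnzymeDef("FdhG", "FDH", frozenset({"WL", "rGly"})),
    ]
    for sub in COMPLEX_SUBUNITS["CODH/ACS"]:
        defs.append(EnzymeDef(sub, "CODH/ACS", frozenset({"WL"})))
    for sub in COMPLEX_SUBUNITS["GCS"]:
        defs.append(EnzymeDef(sub, "GCS", frozenset({"rGly"})))
    for sub in COMPLEX_SUBUNITS["GR"]:
        defs.append(EnzymeDef(sub, "GR", frozenset({"downstream"})))
    # methyl-branch enzymes shared between WL and rGly
    for e in ("Fhs", "FchA", "FolD", "MetF"):
        defs.append(EnzymeDef(e, "none", frozenset({"WL", "rGly"})))
    # downstream amino-acid synthesis enzymes
    for e in ("PFO", "PSP", "SHMT"):
        defs.append(EnzymeDef(e, "none", frozenset({"downstream"})))
    validate_enzyme_defs(defs)
    return defs
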