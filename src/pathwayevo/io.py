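"""Readers and writers for every external representation the pipeline touches.

Formats
-------
hit table
    BLAST tabular (outfmt-6 style) extended with a mandatory 13th column
    ``qcov`` (query coverage, percent) and an optional 14th column
    ``staxid``.  ``#`` comment lines are ignored; an optional header line
    starting with ``qseqid`` is recognised.  The subject species is taken
    from the part of ``sseqid`` before the first ``|`` (the whole id when
    there is no ``|``).
trees
    Newick.  Bootstrap supports are internal-node labels by default; a flag
    selects the dialect where supports ride in bracket comments after the
    branch length (``):0.05[95]``).
annotation
    Tab-separated locus table with header
    ``species contig start end strand locus_tag product`` (1-based inclusive
    coordinates, GFF convention), or a GFF3 subset (``CDS`` rows with
    ``locus_tag``/``product`` attributes).
taxon metadata / enzyme definitions / matrices
    Tab-separated with header rows.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd

from .records import (
    DEFAULT_GROUP_VOCAB,
    EnzymeDef,
    GeneLocus,
    HitRecord,
    TaxonMeta,
    validate_enzyme_defs,
)
from .treeutil import get_support, set_support

log = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qcov",
]

ANNOTATION_COLUMNS = ["species", "contig", "start", "end", "strand", "locus_tag", "product"]


class NewickError(ValueError):
    """Malformed Newick input."""


def subject_species(subject_id: str) -> str:
    return subject_id.split("|", 1)[0]


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path, mag_species: Iterable[str] = ()) -> list[HitRecord]:
    """Parse a hit table; ``is_mag_derived`` is set from ``mag_species``
    membership of the subject species.

    Malformed lines raise ``ValueError`` naming the line number; a table
    with fewer than 13 columns raises an error naming the missing ``qcov``
    column.  An empty table returns an empty list with a warning.
    """
    mags = frozenset(mag_species)
    records: list[HitRecord] = []
    n_data = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "qseqid":  # header line
                if "qcov" not in fields:
                    raise ValueError(
                        f"{path}: header is missing the required 'qcov' column"
                    )
                continue
            n_data += 1
            if len(fields) < 13:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 standard columns plus 'qcov' "
                    f"(13 total), got {len(fields)}; the 'qcov' column is required"
                )
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric evalue {fields[10]!r}"
                ) from exc
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    subject_species=subject_species(fields[1]),
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    evalue=evalue,
                    bitscore=float(fields[11]),
                    query_coverage=float(fields[12]),
                    is_mag_derived=subject_species(fields[1]) in mags,
                    taxid=fields[13] if len(fields) > 13 else "",
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if n_data == 0:
        log.warning("hit table %s contains no data lines", path)
    assert len(records) == n_data  # nothing is silently dropped
    return records


def write_hit_table(records: Sequence[HitRecord], path: str | Path) -> None:
    """Write records in the extended tabular format (round-trips with
    :func:`read_hit_table`).  Positional columns not retained in
    :class:`HitRecord` (mismatch, gapopen, coordinates) are written as 0."""
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS + ["staxid"]) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        repr(r.percent_identity),
                        str(r.align_length),
                        "0", "0", "0", "0", "0", "0",
                        repr(r.evalue),
                        repr(r.bitscore),
                        repr(r.query_coverage),
                        r.taxid,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(
                    f"unbalanced parentheses: unmatched ')' at character {offset}"
                )
    if depth != 0:
        raise NewickError(
            f"unbalanced parentheses: {depth} '(' left open at end of input "
            f"(character {len(text)})"
        )


_NUM_RE = re.compile(r"^\d+(\.\d+)?$")


def parse_newick(text: str, supports_in_comments: bool = False) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Internal-node labels that look numeric are interpreted as integer
    bootstrap supports (attribute ``support``) and removed from the label,
    unless ``supports_in_comments`` selects the ``):length[support]``
    dialect.  Rootedness: an explicit ``[&R]``/``[&U]`` token wins;
    otherwise a bifurcating basal node means rooted and a basal polytomy
    means unrooted.
    """
    _check_parentheses(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises various DataError subclasses
        raise NewickError(f"could not parse Newick: {exc}") from exc
    explicit = tree.is_rooted  # True / False / None (unstated)
    if explicit is None:
        tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    for node in tree.preorder_node_iter():
        if not node.child_nodes():
            continue
        if supports_in_comments:
            vals = [c.strip("&") for c in (node.edge.comments or []) + (node.comments or [])]
            vals = [v for v in vals if _NUM_RE.match(v)]
            set_support(node, int(round(float(vals[0]))) if vals else None)
        elif node.label is not None and _NUM_RE.match(node.label):
            set_support(node, int(round(float(node.label))))
            node.label = None
        else:
            set_support(node, None)
    return tree


def read_newick(path: str | Path, supports_in_comments: bool = False) -> dendropy.Tree:
    return parse_newick(Path(path).read_text(), supports_in_comments=supports_in_comments)


def tree_to_newick(tree: dendropy.Tree, supports_in_comments: bool = False) -> str:
    for node in tree.preorder_internal_node_iter():
        sup = get_support(node)
        if supports_in_comments:
            node.comments = [str(sup)] if sup is not None else []
        else:
            node.label = str(sup) if sup is not None else None
    text = tree.as_string(
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
        real_value_format_specifier="",
    )
    return text


def write_newick(tree: dendropy.Tree, path: str | Path, supports_in_comments: bool = False) -> None:
    Path(path).write_text(tree_to_newick(tree, supports_in_comments=supports_in_comments))


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def _assign_locus_indices(loci: list[GeneLocus]) -> list[GeneLocus]:
    """Sort within each (species, contig) by start and assign 1-based ranks."""
    out: list[GeneLocus] = []
    bykey: dict[tuple[str, str], list[GeneLocus]] = {}
    for l in loci:
        bykey.setdefault((l.species, l.contig), []).append(l)
    for key in bykey:
        ordered = sorted(bykey[key], key=lambda l: (l.start, l.end, l.locus_tag))
        for i, l in enumerate(ordered, start=1):
            out.append(
                GeneLocus(
                    species=l.species, contig=l.contig, start=l.start, end=l.end,
                    strand=l.strand, locus_tag=l.locus_tag,
                    product_label=l.product_label, locus_index=i,
                )
            )
    return out


def _check_duplicates(loci: list[GeneLocus]) -> None:
    seen: set[tuple[str, str]] = set()
    for l in loci:
        key = (l.species, l.locus_tag)
        if key in seen:
            raise ValueError(f"duplicate (species, locus_tag): {key}")
        seen.add(key)


def read_annotation_table(path: str | Path) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    loci = [
        GeneLocus(
            species=row.species, contig=row.contig,
            start=int(row.start), end=int(row.end), strand=row.strand,
            locus_tag=row.locus_tag, product_label=row.product,
        )
        for row in df.itertuples()
    ]
    _check_duplicates(loci)
    return _assign_locus_indices(loci)


_GFF_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def read_annotation_gff(path: str | Path) -> list[GeneLocus]:
    """Read the GFF3 subset used for annotation: CDS rows carrying
    ``locus_tag`` and ``product`` attributes; the seqid column doubles as
    the contig and the source column as the species."""
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attr = dict(_GFF_ATTR_RE.findall(attrs))
            if "locus_tag" not in attr:
                raise ValueError(f"{path}:{lineno}: CDS without locus_tag attribute")
            loci.append(
                GeneLocus(
                    species=source, contig=seqid, start=int(start), end=int(end),
                    strand=strand, locus_tag=attr["locus_tag"],
                    product_label=attr.get("product", ""),
                )
            )
    _check_duplicates(loci)
    return _assign_locus_indices(loci)


def write_annotation_table(loci: Sequence[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for l in loci:
            fh.write(
                f"{l.species}\t{l.contig}\t{l.start}\t{l.end}\t{l.strand}\t"
                f"{l.locus_tag}\t{l.product_label}\n"
            )


# ---------------------------------------------------------------------------
# taxon metadata / enzyme definitions
# ---------------------------------------------------------------------------

def read_taxon_meta(
    path: str | Path, vocab: tuple[str, ...] = DEFAULT_GROUP_VOCAB
) -> list[TaxonMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    need = {"species", "clade", "is_mag", "is_autotroph"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing taxon-meta columns {sorted(missing)}")
    out: list[TaxonMeta] = []
    for row in df.itertuples():
        auto_raw = str(row.is_autotroph).strip().lower()
        auto: bool | None
        if auto_raw in ("true", "1", "yes"):
            auto = True
        elif auto_raw in ("false", "0", "no"):
            auto = False
        else:
            auto = None
        meta = TaxonMeta(
            species=row.species,
            clade=row.clade,
            is_mag=str(row.is_mag).strip().lower() in ("true", "1", "yes"),
            is_autotroph=auto,
        )
        meta.validate_clade(vocab)
        out.append(meta)
    return out


def write_taxon_meta(meta: Sequence[TaxonMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tclade\tis_mag\tis_autotroph\n")
        for m in meta:
            auto = "unknown" if m.is_autotroph is None else str(m.is_autotroph).lower()
            fh.write(f"{m.species}\t{m.clade}\t{str(m.is_mag).lower()}\t{auto}\n")


def read_enzyme_defs(path: str | Path) -> list[EnzymeDef]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    need = {"enzyme", "complex", "pathway_roles"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing enzyme-def columns {sorted(missing)}")
    defs = []
    for row in df.itertuples():
        roles = frozenset(
            r.strip() for r in str(row.pathway_roles).split(",") if r.strip() and r.strip() != "nan"
        )
        defs.append(EnzymeDef(row.enzyme, row.complex, roles))
    validate_enzyme_defs(defs)
    return defs


def write_enzyme_defs(defs: Sequence[EnzymeDef], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("enzyme\tcomplex\tpathway_roles\n")
        for d in defs:
            fh.write(f"{d.enzyme_id}\t{d.complex}\t{','.join(sorted(d.pathway_roles))}\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.astype(int).to_csv(path, sep="\t", index_label="species")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="species").astype(bool)
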