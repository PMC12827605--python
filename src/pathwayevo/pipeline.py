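"""End-to-end pipeline orchestration.

Stages run in order: screen -> pathways -> synteny -> trees -> scenario ->
report.  Inputs live in a dataset directory (the layout written by
:func:`pathwayevo.simulate.simulate_dataset`); every artifact is written to
an output directory together with a manifest recording input checksums and
the effective thresholds, so reruns are auditable and byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import io as pio
from .pathways import autotrophy_consistency, call_pathways, calls_frame
from .records import FOCAL_CLADES
from .report import format_table, render_presence_report
from .scenario import TraitProfile, ancestor_report, annotated_newick, build_scenario
from .screen import Thresholds, build_presence_matrix, filter_hits
from .simulate import DEFAULT_TRAITS
from .synteny import classify_acsa_copies, cluster_calls_frame, detect_clusters_for_species
from .treescreen import (
    VERDICT_HGT,
    classify_hgt,
    hgt_calls_frame,
    prune_long_branches,
    split_focal_groups,
    assess_monophyly,
)
from .treeutil import leaf_label

log = logging.getLogger(__name__)

STAGES = ("screen", "pathways", "synteny", "trees", "scenario", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    data_dir: Path
    out_dir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: Sequence[str] = STAGES
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"data_dir", "out_dir", "thresholds", "stages", "seed", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        tdict = raw.get("thresholds") or {}
        tfields = {f.name for f in dataclasses.fields(Thresholds)}
        bad = set(tdict) - tfields
        if bad:
            raise ValueError(f"unknown threshold keys: {sorted(bad)}")
        stages = raw.get("stages") or STAGES
        bad_stages = set(stages) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")
        return cls(
            data_dir=Path(raw["data_dir"]),
            out_dir=Path(raw["out_dir"]),
            thresholds=Thresholds(**tdict),
            stages=tuple(stages),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Dict[str, Path]:
    """Execute the selected stages; returns a name -> path map of artifacts.

    Any stage failure raises :class:`StageError` naming the stage.  The
    manifest (``manifest.json``) echoes the effective thresholds and the
    sha256 of every input consumed.
    """
    data, out = Path(cfg.data_dir), Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = cfg.thresholds
    artifacts: Dict[str, Path] = {}
    inputs_seen: Dict[str, str] = {}

    def need(stage: str, rel: str) -> Path:
        p = data / rel
        if not p.exists():
            raise StageError(stage, f"required input {p} is missing")
        inputs_seen[rel] = _sha256(p)
        return p

    matrix = None
    calls = None
    hgt_by_trait: Dict[str, Dict[str, str]] = {}

    if "screen" in cfg.stages:
        log.info("[screen] filtering hits and building the presence matrix")
        taxa = pio.read_taxon_meta(need("screen", "taxa.tsv"))
        enzymes = pio.read_enzyme_defs(need("screen", "enzymes.tsv"))
        mag_species = {m.species for m in taxa if m.is_mag}
        hits = pio.read_hit_table(need("screen", "hits.tsv"), mag_species)
        kept = filter_hits(hits, t)
        matrix = build_presence_matrix(
            kept, [m.species for m in taxa], [d.enzyme_id for d in enzymes]
        )
        artifacts["presence"] = out / "presence.tsv"
        pio.write_matrix_tsv(matrix.values, artifacts["presence"])
        artifacts["provenance"] = out / "provenance.tsv"
        matrix.provenance_frame().to_csv(artifacts["provenance"], sep="\t", index=False)

    if "pathways" in cfg.stages:
        log.info("[pathways] calling pathway completeness")
        if matrix is None:
            raise StageError("pathways", "presence matrix unavailable (run the screen stage)")
        taxa = pio.read_taxon_meta(need("pathways", "taxa.tsv"))
        enzymes = pio.read_enzyme_defs(need("pathways", "enzymes.tsv"))
        try:
            calls = call_pathways(matrix, enzymes)
        except (KeyError, ValueError) as exc:
            raise StageError("pathways", str(exc)) from exc
        artifacts["pathway_calls"] = out / "pathway_calls.tsv"
        calls_frame(calls).to_csv(artifacts["pathway_calls"], sep="\t", index=False)
        artifacts["autotrophy"] = out / "autotrophy.tsv"
        autotrophy_consistency(calls, taxa).to_csv(artifacts["autotrophy"], sep="\t", index=False)

    if "synteny" in cfg.stages:
        log.info("[synteny] detecting CODH/ACS clusters")
        loci = pio.read_annotation_table(need("synteny", "annotation.tsv"))
        species = sorted({l.species for l in loci})
        calls_by_sp = {sp: detect_clusters_for_species(loci, sp, t) for sp in species}
        flat = [c for sp in species for c in calls_by_sp[sp]]
        artifacts["cluster_calls"] = out / "cluster_calls.tsv"
        cluster_calls_frame(flat).to_csv(artifacts["cluster_calls"], sep="\t", index=False)
        annotations, summary = classify_acsa_copies(calls_by_sp)
        artifacts["acsa_copies"] = out / "acsa_copies.tsv"
        pd.DataFrame(
            [
                {"species": a.species, "anchor_locus": a.anchor_locus, "label": a.label,
                 "species_summary": summary[a.species]}
                for a in annotations
            ],
            columns=["species", "anchor_locus", "label", "species_summary"],
        ).to_csv(artifacts["acsa_copies"], sep="\t", index=False)

    if "trees" in cfg.stages:
        log.info("[trees] screening gene trees")
        gdir = data / "gene_trees"
        if not gdir.is_dir():
            raise StageError("trees", f"gene-tree directory {gdir} is missing")
        verdict_rows = []
        (out / "tree_verdicts").mkdir(exist_ok=True)
        for nwk in sorted(gdir.glob("*.nwk")):
            trait = nwk.stem.replace("_", "/") if nwk.stem.startswith("CODH") else nwk.stem
            groups_path = gdir / f"{nwk.stem}.groups.tsv"
            if not groups_path.exists():
                raise StageError("trees", f"missing group map {groups_path}")
            inputs_seen[str(nwk.relative_to(data))] = _sha256(nwk)
            inputs_seen[str(groups_path.relative_to(data))] = _sha256(groups_path)
            gtree = pio.read_newick(nwk)
            group_map = dict(
                pd.read_csv(groups_path, sep="\t", dtype=str).values.tolist()
            )
            gtree, removed = prune_long_branches(gtree, t)
            leaves = {leaf_label(l) for l in gtree.leaf_node_iter()}
            group_map = {k: v for k, v in group_map.items() if k in leaves}
            focal = {l for l, g in group_map.items() if g in FOCAL_CLADES}
            if not focal:
                log.warning("tree %s has no focal leaves after pruning; skipped", nwk.name)
                continue
            mono = assess_monophyly(gtree, focal)
            groups = split_focal_groups(gtree, focal, t)
            hcalls = classify_hgt(gtree, focal, group_map, t, focal_groups=FOCAL_CLADES)
            hgt_by_trait[trait] = {
                c.sequence_id: c.donor_group for c in hcalls if c.verdict == VERDICT_HGT
            }
            df = hgt_calls_frame(hcalls)
            df.insert(0, "trait", trait)
            df["monophyly"] = mono.status
            df["n_focal_groups"] = len(groups)
            df["pruned_long_branches"] = ",".join(removed)
            df.to_csv(out / "tree_verdicts" / f"{nwk.stem}.tsv", sep="\t", index=False)
            verdict_rows.append(df)
        artifacts["tree_verdicts"] = out / "tree_verdicts.tsv"
        combined = (
            pd.concat(verdict_rows, ignore_index=True)
            if verdict_rows
            else pd.DataFrame(
                columns=["trait", "sequence_id", "recipient_group", "donor_group",
                         "nest_support", "verdict", "monophyly", "n_focal_groups",
                         "pruned_long_branches"]
            )
        )
        combined.to_csv(artifacts["tree_verdicts"], sep="\t", index=False)

    if "scenario" in cfg.stages:
        log.info("[scenario] reconstructing gain/loss/HGT events")
        stree_path = data / "species_tree.nwk"
        if not stree_path.exists():
            raise StageError("scenario", f"species tree {stree_path} is missing")
        inputs_seen["species_tree.nwk"] = _sha256(stree_path)
        stree = pio.read_newick(stree_path)
        if matrix is None:
            raise StageError("scenario", "presence matrix unavailable (run the screen stage)")
        species = [leaf_label(l) for l in stree.leaf_node_iter()]
        traits: List[TraitProfile] = []
        for trait_id, enzymes_of in DEFAULT_TRAITS.items():
            have = [e for e in enzymes_of if e in matrix.enzymes]
            if not have:
                continue
            states = {
                sp: all(matrix.present(sp, e) for e in have) for sp in species
                if sp in matrix.species
            }
            if set(states) != set(species):
                raise StageError(
                    "scenario",
                    f"species tree leaves missing from the presence matrix: "
                    f"{sorted(set(species) - set(states))}",
                )
            recode = {
                sp: donor
                for sp, donor in hgt_by_trait.get(trait_id, {}).items()
                if states.get(sp, False)
            }
            traits.append(TraitProfile(trait_id, states, recode))
        scenario = build_scenario(stree, traits)
        artifacts["scenario"] = out / "scenario.tsv"
        scenario.frame().to_csv(artifacts["scenario"], sep="\t", index=False)
        artifacts["ancestors"] = out / "ancestors.tsv"
        ancestor_report(scenario, stree, frozenset(species)).to_csv(
            artifacts["ancestors"], sep="\t", index=False
        )
        artifacts["annotated_tree"] = out / "scenario_annotated.nwk"
        artifacts["annotated_tree"].write_text(
            annotated_newick(scenario, stree, [tp.trait_id for tp in traits])
        )

    if "report" in cfg.stages:
        log.info("[report] rendering the presence/pathway table")
        if calls is None:
            raise StageError("report", "pathway calls unavailable (run the pathways stage)")
        taxa = pio.read_taxon_meta(need("report", "taxa.tsv"))
        table = render_presence_report(calls, taxa)
        artifacts["presence_report"] = out / "presence_report.tsv"
        table.to_csv(artifacts["presence_report"], sep="\t", index=False)
        artifacts["presence_report_txt"] = out / "presence_report.txt"
        artifacts["presence_report_txt"].write_text(format_table(table))

    manifest = {
        "stages": list(cfg.stages),
        "seed": cfg.seed,
        "thresholds": dataclasses.asdict(t),
        "inputs_sha256": dict(sorted(inputs_seen.items())),
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
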