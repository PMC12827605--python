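"""Pathway-completeness calls from the presence/absence matrix.

A species is called capable of the Wood-Ljungdahl (WL) pathway when it
encodes a formate-dehydrogenase catalytic subunit (either the cytoplasmic
Fdh family or the FdhG family) together with all five subunits of the
CODH/ACS complex, and capable of the reductive glycine (rGly) pathway when
FDH is present together with all five glycine-cleavage-system proteins.
Downstream amino-acid-synthesis checks (pyruvate:ferredoxin oxidoreductase,
phosphoserine phosphatase, serine hydroxymethyltransferase; glycine
reductase) qualify whether a called pathway could actually sustain
autotrophic growth; they never alter the pathway call itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .records import COMPLEX_SUBUNITS, EnzymeDef, TaxonMeta
from .screen import PresenceMatrix

FDH_VARIANTS = ("cytFdh", "FdhG")
DOWNSTREAM_WL = ("PFO", "PSP", "SHMT")


@dataclass(frozen=True)
class PathwayCall:
    species: str
    fdh_present: bool
    codh_acs_complete: bool
    gcs_complete: bool
    wl_called: bool
    rgly_called: bool
    downstream_wl_ok: bool
    gr_complete: bool
    serine_route_ok: bool

    def __post_init__(self) -> None:
        assert self.wl_called == (self.fdh_present and self.codh_acs_complete)
        assert self.rgly_called == (self.fdh_present and self.gcs_complete)


def _require(row: Dict[str, bool], enzymes: Sequence[str]) -> None:
    missing = [e for e in enzymes if e not in row]
    if missing:
        raise KeyError(f"presence matrix is missing enzyme columns {missing}")


def call_fdh(row: Dict[str, bool]) -> bool:
    """FDH is present when either catalytic-subunit family is encoded."""
    _require(row, FDH_VARIANTS)
    return bool(row["cytFdh"] or row["FdhG"])


def call_complex_complete(
    row: Dict[str, bool], complex_id: str, enzyme_defs: Optional[Sequence[EnzymeDef]] = None
) -> bool:
    """True iff every declared subunit of the complex is present."""
    if enzyme_defs is not None:
        subunits = [d.enzyme_id for d in enzyme_defs if d.complex == complex_id]
    else:
        subunits = list(COMPLEX_SUBUNITS.get(complex_id, ()))
    if not subunits:
        raise ValueError(f"complex {complex_id!r} has no declared subunits")
    _require(row, subunits)
    return all(row[s] for s in subunits)


def call_pathways(
    matrix: PresenceMatrix, enzyme_defs: Optional[Sequence[EnzymeDef]] = None
) -> List[PathwayCall]:
    calls = []
    for sp in matrix.species:
        row = matrix.row(sp)
        fdh = call_fdh(row)
        acs = call_complex_complete(row, "CODH/ACS", enzyme_defs)
        gcs = call_complex_complete(row, "GCS", enzyme_defs)
        gr = call_complex_complete(row, "GR", enzyme_defs)
        _require(row, DOWNSTREAM_WL)
        calls.append(
            PathwayCall(
                species=sp,
                fdh_present=fdh,
                codh_acs_complete=acs,
                gcs_complete=gcs,
                wl_called=fdh and acs,
                rgly_called=fdh and gcs,
                downstream_wl_ok=all(row[e] for e in DOWNSTREAM_WL),
                gr_complete=gr,
                serine_route_ok=bool(row["SHMT"] and row["PFO"]),
            )
        )
    return calls


def calls_frame(calls: Sequence[PathwayCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": c.species,
                "FDH": c.fdh_present,
                "CODH/ACS": c.codh_acs_complete,
                "GCS": c.gcs_complete,
                "WL": c.wl_called,
                "rGly": c.rgly_called,
                "downstream_WL": c.downstream_wl_ok,
                "GR": c.gr_complete,
                "serine_route": c.serine_route_ok,
            }
            for c in calls
        ]
    )


def autotrophy_consistency(
    calls: Sequence[PathwayCall], meta: Sequence[TaxonMeta]
) -> pd.DataFrame:
    """Consistency table between literature autotrophy flags and called
    pathways.  Purely descriptive: no call is altered.

    status per species:

    - ``consistent`` — flagged autotroph with at least one pathway called
      and a viable downstream route (WL: PFO+PSP+SHMT; rGly: complete
      glycine reductase OR the serine route SHMT+PFO);
    - ``pathway-without-downstream`` — autotroph with a pathway called but
      no downstream route recovered;
    - ``inconsistent`` — autotroph with neither pathway called;
    - ``genes-without-demonstrated-autotrophy`` — non-autotroph that
      nevertheless carries a complete pathway gene set;
    - ``not-applicable`` — autotrophy unknown;
    - ``ok`` — non-autotroph without a called pathway.
    """
    meta_by_sp = {m.species: m for m in meta}
    rows = []
    for c in calls:
        m = meta_by_sp.get(c.species)
        auto = m.is_autotroph if m is not None else None
        any_pathway = c.wl_called or c.rgly_called
        wl_supported = c.wl_called and c.downstream_wl_ok
        rgly_supported = c.rgly_called and (c.gr_complete or c.serine_route_ok)
        if auto is None:
            status = "not-applicable"
        elif auto:
            if wl_supported or rgly_supported:
                status = "consistent"
            elif any_pathway:
                status = "pathway-without-downstream"
            else:
                status = "inconsistent"
        else:
            status = "genes-without-demonstrated-autotrophy" if any_pathway else "ok"
        rows.append(
            {
                "species": c.species,
                "is_autotroph": "unknown" if auto is None else str(auto).lower(),
                "WL": c.wl_called,
                "rGly": c.rgly_called,
                "downstream_WL": c.downstream_wl_ok,
                "GR": c.gr_complete,
                "serine_route": c.serine_route_ok,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
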