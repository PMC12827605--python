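"""Human-readable summaries of pipeline outputs."""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import pandas as pd

from .pathways import PathwayCall
from .records import TaxonMeta


def render_presence_report(
    calls: Sequence[PathwayCall], meta: Sequence[TaxonMeta] = ()
) -> pd.DataFrame:
    """One row per species, ordered by clade: FDH / CODH/ACS / GCS presence
    and the WL / rGly pathway calls, with the autotrophy flag.  A pure
    function of the pathway-call table — nothing is recomputed."""
    meta_by_sp: Dict[str, TaxonMeta] = {m.species: m for m in meta}
    rows = []
    for c in calls:
        m = meta_by_sp.get(c.species)
        rows.append(
            {
                "species": c.species,
                "clade": m.clade if m else "",
                "autotroph": _flag(m.is_autotroph if m else None),
                "FDH": _pm(c.fdh_present),
                "CODH/ACS": _pm(c.codh_acs_complete),
                "GCS": _pm(c.gcs_complete),
                "WL": _pm(c.wl_called),
                "rGly": _pm(c.rgly_called),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["species", "clade", "autotroph", "FDH", "CODH/ACS", "GCS", "WL", "rGly"],
    )
    if len(df):
        df = df.sort_values(["clade", "species"], kind="stable").reset_index(drop=True)
    return df


def _pm(v: bool) -> str:
    return "+" if v else "-"


def _flag(v: Optional[bool]) -> str:
    if v is None:
        return "?"
    return "●" if v else ""


def format_table(df: pd.DataFrame) -> str:
    """Fixed-width text rendering (header always shown, even when empty)."""
    widths = {
        col: max(len(str(col)), *(len(str(v)) for v in df[col])) if len(df) else len(str(col))
        for col in df.columns
    }
    lines = ["  ".join(str(c).ljust(widths[c]) for c in df.columns)]
    lines.append("  ".join("-" * widths[c] for c in df.columns))
    for _, row in df.iterrows():
        lines.append("  ".join(str(row[c]).ljust(widths[c]) for c in df.columns))
    return "\n".join(lines) + "\n"
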