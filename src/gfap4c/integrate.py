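"""Candidate integration: condition-exclusive set logic and the final
candidate table (bait-associated AND LIF+-expressed genes, with promoter
STAT3 flags and peak-distance bins).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

TABLE_COLUMNS = [
    "accession", "symbol", "copies_NPC", "copies_LIFplus", "copies_LIFminus",
    "fold_LIFplus_NPC", "fold_LIFminus_NPC", "stat3_site", "distance_bin",
]


def exclusive_association_sets(
    sets: dict[str, set],
) -> tuple[dict[str, set], dict[frozenset, int]]:
    """Per-condition exclusive gene sets and pairwise overlap counts.

    ``exclusive[c]`` holds the genes associated in condition ``c`` and in
    no other condition; the overlap counts are reported for each
    unordered condition pair.
    """
    names = list(sets)
    exclusive = {}
    for name in names:
        others = set().union(*(sets[o] for o in names if o != name)) \
            if len(names) > 1 else set()
        exclusive[name] = sets[name] - others
    overlaps = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlaps[frozenset((a, b))] = len(sets[a] & sets[b])
    return exclusive, overlaps


def integrate_candidates(
    assoc_exclusive: set[str],
    expr_exclusive: set[str],
    copies: pd.DataFrame,
    distance_bins: dict[str, str] | None = None,
    stat3_flags: dict[str, bool] | None = None,
    symbols: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build the candidate table: genes in both exclusive sets.

    ``copies`` is indexed by gene id with NPC / LIF+ / LIF- columns. Rows
    are sorted by LIF+/NPC fold descending, the published table's order;
    fold columns are recomputed from the copies columns (denominator
    guarded at 0.01 copies).
    """
    candidates = sorted(assoc_exclusive & expr_exclusive)
    rows = []
    for gid in candidates:
        npc, lifp, lifm = (
            float(copies.loc[gid, c]) for c in ("NPC", "LIF+", "LIF-")
        )
        den = max(npc, 0.01)
        rows.append(
            {
                "accession": gid,
                "symbol": (symbols or {}).get(gid, gid),
                "copies_NPC": npc,
                "copies_LIFplus": lifp,
                "copies_LIFminus": lifm,
                "fold_LIFplus_NPC": lifp / den,
                "fold_LIFminus_NPC": lifm / den,
                "stat3_site": bool((stat3_flags or {}).get(gid, False)),
                "distance_bin": (distance_bins or {}).get(gid, ""),
            }
        )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return table.sort_values(
        "fold_LIFplus_NPC", ascending=False, kind="stable"
    ).reset_index(drop=True)


def format_table(table: pd.DataFrame) -> pd.DataFrame:
    """Round copies and fold columns to 2 decimals for output."""
    out = table.copy()
    for col in (
        "copies_NPC", "copies_LIFplus", "copies_LIFminus",
        "fold_LIFplus_NPC", "fold_LIFminus_NPC",
    ):
        out[col] = out[col].round(2)
    return out


def load_table1() -> pd.DataFrame:
    """The packaged verbatim transcription of the published 18-gene table.

    The STAT3 column's circle/cross marks are mapped to booleans; copies
    and printed fold columns are numeric as printed (2 decimals).
    """
    with resources.files("gfap4c.data").joinpath("table1.tsv").open(
        encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, sep="\t")
    df["stat3_site"] = df["stat3_site"].map({"○": True, "×": False})
    if df["stat3_site"].isna().any():
        raise ValueError("unrecognised STAT3 mark in packaged table")
    return df
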