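"""Bundled published tsRNA tables and their consistency checks.

Two tab-separated fixtures ship with the package: the top differentially
expressed tsRNAs ranked by fold change (table 1) and the candidate set
taken forward to target prediction (table 2).  Each row carries the tsRNA
ID, subtype, length, log fold change, adjusted p and regulation call.

``check_table_consistency`` re-derives the length from the ID grammar and
the subtype from the placement coordinates and compares both against the
printed columns — a self-consistency check of the classifier and parser
against published data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .align import classify_subtype, parse_tsrna_id


def load_table(which: int) -> pd.DataFrame:
    """Load bundled table 1 (top up/down) or 2 (bioinformatics candidates)."""
    if which not in (1, 2):
        raise ValueError("table number must be 1 or 2")
    ref = resources.files("tsrnakit.data") / f"table{which}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def infer_subtype_from_id(tsrna_id: str) -> str:
    """Classify a published ID: start 1 means a 5' fragment (the mature
    length is then irrelevant), otherwise the fragment is taken to reach
    the mature 3' terminus so its end coordinate equals the mature length."""
    p = parse_tsrna_id(tsrna_id)
    if p["start"] == 1:
        return classify_subtype(p["start"], p["end"], p["end"] + 40)
    return classify_subtype(p["start"], p["end"], p["end"])


def check_table_consistency(table: pd.DataFrame) -> pd.DataFrame:
    """Parsed-vs-printed comparison per row (length and subtype)."""
    rows = []
    for row in table.itertuples(index=False):
        p = parse_tsrna_id(row.tsRNA_ID)
        rows.append({
            "tsRNA_ID": row.tsRNA_ID,
            "printed_length": int(row.Length),
            "parsed_length": p["length"],
            "length_ok": p["length"] == int(row.Length),
            "printed_type": row.Type,
            "derived_type": infer_subtype_from_id(row.tsRNA_ID),
        })
    out = pd.DataFrame(rows)
    out["type_ok"] = out["printed_type"] == out["derived_type"]
    out["ok"] = out["length_ok"] & out["type_ok"]
    return out
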