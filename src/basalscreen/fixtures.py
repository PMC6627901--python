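"""Packaged screening result tables and their summaries.

Two reference tables ship with the package: per-drug dose-response AUC for
25 HNSCC cell lines (10 basal-like, 15 non-basal-like) across six drugs,
and Bliss synergy scores for the nine pairwise combinations of the three
EGFR-directed drugs with Cobimetinib, Gedatolisib, and Trastuzumab (with
missing entries).  The values are consumed as fixed inputs — they are
summarized, compared between subtype groups, and used as anchors in
tests, but never recomputed.  A SHA-256 checksum guards each file against
silent edits.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .stats import AssociationResult
from .synergy import compare_synergy_by_group

__all__ = ["load_table1", "load_table2", "summarize_single_agent",
           "summarize_combinations"]

_CHECKSUMS = {
    "table1_single_agent_auc.tsv":
        "29a9bd78de8f1026d53a04705a41f004f324f9d9898ce606ee3624523f256fde",
    "table2_bliss_scores.tsv":
        "004b7441414b79c23e16a68760f105ced4dae432f74e9f486b98f250ae7c6dd5",
}


def _load(name: str) -> pd.DataFrame:
    raw = resources.files("basalscreen.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    from io import BytesIO
    df = pd.read_csv(BytesIO(raw), sep="\t", na_values=["NA"])
    return df.set_index("cell_line")


def load_table1() -> pd.DataFrame:
    """Single-agent AUC per (cell line, drug), with subtype column."""
    df = _load("table1_single_agent_auc.tsv")
    _check_composition(df)
    return df


def load_table2() -> pd.DataFrame:
    """Bliss synergy score per (cell line, combination), with subtype column."""
    df = _load("table2_bliss_scores.tsv")
    _check_composition(df)
    return df


def _check_composition(df: pd.DataFrame) -> None:
    counts = df["subtype"].value_counts()
    if counts.get("Basal", 0) != 10 or counts.get("Non-Basal", 0) != 15:
        raise ValueError(f"unexpected screen composition: {counts.to_dict()}")


def _group_compare(df: pd.DataFrame) -> dict[str, AssociationResult]:
    labels = df["subtype"].str.lower().replace({"non-basal": "non-basal"})
    out = {}
    for col in df.columns.drop("subtype"):
        out[col] = compare_synergy_by_group(df[col], labels)
    return out


def summarize_single_agent(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-drug mean AUC over all lines plus basal vs non-basal Welch t."""
    if df is None:
        df = load_table1()
    comps = _group_compare(df)
    rows = []
    for drug, res in comps.items():
        rows.append({
            "drug": drug,
            "mean_auc": float(df[drug].mean()),
            "mean_basal": res.extra["mean_a"],
            "mean_nonbasal": res.extra["mean_b"],
            "t_statistic": res.statistic,
            "p_value": res.p_value,
            "direction": res.effect_direction,
        })
    return pd.DataFrame(rows).set_index("drug")


def summarize_combinations(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-combination mean Bliss score with NA accounting and group test."""
    if df is None:
        df = load_table2()
    comps = _group_compare(df)
    rows = []
    for combo, res in comps.items():
        rows.append({
            "combination": combo,
            "mean_score": float(df[combo].mean()),
            "n_missing": int(df[combo].isna().sum()),
            "mean_basal": res.extra["mean_a"],
            "mean_nonbasal": res.extra["mean_b"],
            "t_statistic": res.statistic,
            "p_value": res.p_value,
            "direction": res.effect_direction,
        })
    return pd.DataFrame(rows).set_index("combination")
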