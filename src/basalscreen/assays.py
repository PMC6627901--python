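"""Quantification math for the validation assays.

Relative qPCR expression uses the 2^-ddCt method: the target Ct is
normalized to the mean Ct of the reference genes (equivalent to a
geometric mean on the linear scale), the treated dCt is referenced to the
control dCt, and the fold change is 2 to the minus ddCt.  Amplification
efficiency is assumed to be exactly 2 per cycle.

Clonogenic survival uses plating efficiency (untreated colonies per seeded
cell) and the surviving fraction (treated colonies per seeded cell,
normalized by the plating efficiency).  A colony is a clone of more than
64 cells; counts are integers bounded by the seeding number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QPCRMeasurement", "ddct_fold_change",
    "plating_efficiency", "surviving_fraction",
    "analyze_qpcr_table", "analyze_clonogenic_table",
]


@dataclass
class QPCRMeasurement:
    sample: str
    condition: str              # treated | control
    ct_target: float
    ct_refs: dict = field(default_factory=dict)  # reference gene -> Ct

    def __post_init__(self) -> None:
        cts = [self.ct_target, *self.ct_refs.values()]
        if not self.ct_refs:
            raise ValueError("need at least one reference gene")
        if any(not (0 < ct < 45) for ct in cts):
            raise ValueError("Ct values must lie in (0, 45)")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - float(np.mean(list(self.ct_refs.values())))


def ddct_fold_change(treated: QPCRMeasurement, control: QPCRMeasurement) -> float:
    """Relative expression of treated vs control by 2^-ddCt."""
    if set(treated.ct_refs) != set(control.ct_refs):
        raise ValueError("reference gene sets differ between conditions")
    ddct = treated.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))


def plating_efficiency(colonies_untreated: int, cells_seeded: int) -> float:
    """Untreated colonies divided by cells seeded."""
    if cells_seeded <= 0:
        raise ValueError("cells_seeded must be positive")
    if not 0 <= colonies_untreated <= cells_seeded:
        raise ValueError("colony count outside [0, cells_seeded]")
    return colonies_untreated / cells_seeded


def surviving_fraction(colonies_treated: int, cells_seeded: int, pe: float) -> float:
    """Treated colonies per seeded cell, normalized by plating efficiency."""
    if pe <= 0:
        raise ValueError("plating efficiency must be positive")
    if cells_seeded <= 0:
        raise ValueError("cells_seeded must be positive")
    if colonies_treated < 0:
        raise ValueError("negative colony count")
    return colonies_treated / (cells_seeded * pe)


def analyze_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Fold change per treated sample from a Ct table.

    Expects columns ``sample``, ``condition``, ``ct_target`` and one
    ``ct_<gene>`` column per reference gene; exactly one control row.
    """
    ref_cols = [c for c in table.columns if c.startswith("ct_") and c != "ct_target"]
    if not ref_cols:
        raise ValueError("no reference gene columns (ct_<gene>)")
    controls = table[table["condition"] == "control"]
    if len(controls) != 1:
        raise ValueError(f"expected exactly one control row, got {len(controls)}")
    ctrl_row = controls.iloc[0]
    control = QPCRMeasurement(
        sample=str(ctrl_row["sample"]), condition="control",
        ct_target=float(ctrl_row["ct_target"]),
        ct_refs={c[3:]: float(ctrl_row[c]) for c in ref_cols},
    )
    rows = []
    for _, r in table[table["condition"] != "control"].iterrows():
        m = QPCRMeasurement(
            sample=str(r["sample"]), condition=str(r["condition"]),
            ct_target=float(r["ct_target"]),
            ct_refs={c[3:]: float(r[c]) for c in ref_cols},
        )
        fold = ddct_fold_change(m, control)
        rows.append({"sample": m.sample, "fold_change": fold,
                     "pct_inhibition": 100.0 * (1.0 - fold)})
    return pd.DataFrame(rows)


def analyze_clonogenic_table(table: pd.DataFrame) -> pd.DataFrame:
    """PE and SF per condition from a colony-count table.

    Expects columns ``condition``, ``cells_seeded``, ``colonies`` with an
    ``untreated`` condition present; replicates are pooled before the
    ratio so unequal seeding densities are handled.
    """
    if "untreated" not in set(table["condition"]):
        raise ValueError("no untreated condition for plating efficiency")
    untr = table[table["condition"] == "untreated"]
    pe = untr["colonies"].sum() / untr["cells_seeded"].sum()
    if pe == 0:
        raise ValueError("zero plating efficiency; surviving fraction undefined")
    rows = [{"condition": "untreated", "plating_efficiency": pe, "surviving_fraction": 1.0}]
    for cond, grp in table[table["condition"] != "untreated"].groupby("condition"):
        sf = grp["colonies"].sum() / (grp["cells_seeded"].sum() * pe)
        rows.append({"condition": cond, "plating_efficiency": pe,
                     "surviving_fraction": float(sf)})
    return pd.DataFrame(rows)
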