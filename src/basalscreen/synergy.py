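"""Bliss independence synergy scoring of two-drug dose matrices.

For two non-interacting drugs producing fractional inhibitions a and b,
the Bliss reference predicts combined inhibition a + b - ab (here on the
percentage scale: ya + yb - ya*yb/100).  The synergy score of a matrix is
the arithmetic mean, over all combination cells with both doses positive,
of observed minus expected inhibition in percentage points: 0 means
independence, positive values synergy, negative antagonism.  The score
averages the raw cell-wise excess; no response-surface smoothing is
applied, so the reported number is exactly the mean Bliss excess of the
measured grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import AssociationResult, two_sample_t

logger = logging.getLogger(__name__)

__all__ = ["DoseMatrix", "SynergyResult", "bliss_expected", "bliss_synergy_score",
           "compare_synergy_by_group"]


@dataclass
class DoseMatrix:
    """Two-drug inhibition grid with single-agent axes.

    Row 0 / column 0 hold the single-agent responses (the other drug at
    dose 0); entry (0, 0) is the untreated well and must be 0.  Inhibition
    is in percent, clipped to [0, 100]; missing cells may be NaN.
    """

    cell_line: str
    drug_row: str
    drug_col: str
    row_concs: np.ndarray
    col_concs: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        self.row_concs = np.asarray(self.row_concs, dtype=float)
        self.col_concs = np.asarray(self.col_concs, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.inhibition.shape != (self.row_concs.size, self.col_concs.size):
            raise ValueError("inhibition shape does not match concentration axes")
        if self.row_concs[0] != 0.0 or self.col_concs[0] != 0.0:
            raise ValueError("first row/column concentration must be 0 (single-agent axis)")
        if not np.isclose(self.inhibition[0, 0], 0.0, atol=1e-9):
            raise ValueError("untreated entry (0,0) must be 0")

    def transpose(self) -> "DoseMatrix":
        return DoseMatrix(
            cell_line=self.cell_line, drug_row=self.drug_col, drug_col=self.drug_row,
            row_concs=self.col_concs, col_concs=self.row_concs,
            inhibition=self.inhibition.T,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cell_line: str,
                   drug_row: str, drug_col: str) -> "DoseMatrix":
        """Build from long CSV columns (rowdrug_conc_M, coldrug_conc_M, inhibition_pct)."""
        pivot = frame.pivot(index="rowdrug_conc_M", columns="coldrug_conc_M",
                            values="inhibition_pct").sort_index().sort_index(axis=1)
        return cls(cell_line, drug_row, drug_col,
                   pivot.index.to_numpy(), pivot.columns.to_numpy(),
                   pivot.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rc in enumerate(self.row_concs):
            for j, cc in enumerate(self.col_concs):
                rows.append((rc, cc, self.inhibition[i, j]))
        return pd.DataFrame(rows, columns=["rowdrug_conc_M", "coldrug_conc_M",
                                           "inhibition_pct"])


@dataclass
class SynergyResult:
    cell_line: str
    drug_row: str
    drug_col: str
    bliss_expected: np.ndarray   # combination cells only
    excess: np.ndarray           # observed - expected, percentage points
    score: float                 # mean excess over non-missing combination cells
    n_cells: int
    n_missing: int
    unreliable: bool = field(default=False)  # >50% combination cells missing


def bliss_expected(ya, yb):
    """Expected combined inhibition (percent) under Bliss independence."""
    ya = np.asarray(ya, dtype=float)
    yb = np.asarray(yb, dtype=float)
    if np.any((ya < 0) | (ya > 100)) or np.any((yb < 0) | (yb > 100)):
        raise ValueError("inhibitions must lie in [0, 100]")
    out = ya + yb - ya * yb / 100.0
    return float(out) if out.ndim == 0 else out


def bliss_synergy_score(matrix: DoseMatrix) -> SynergyResult:
    """Score a dose matrix against the Bliss independence reference.

    Missing (NaN) combination cells are excluded from the mean and counted;
    a result with more than half of its combination cells missing is
    flagged unreliable.
    """
    inhib = np.clip(matrix.inhibition, 0.0, 100.0)
    if inhib.shape[0] < 2 or inhib.shape[1] < 2:
        raise ValueError("matrix has no combination cells")
    single_row = inhib[1:, 0]   # drug_row alone
    single_col = inhib[0, 1:]   # drug_col alone
    if np.isnan(single_row).any():
        raise ValueError(f"single-agent axis for {matrix.drug_row} has missing values")
    if np.isnan(single_col).any():
        raise ValueError(f"single-agent axis for {matrix.drug_col} has missing values")
    expected = bliss_expected(single_row[:, None], single_col[None, :])
    observed = inhib[1:, 1:]
    excess = observed - expected
    n_cells = excess.size
    n_missing = int(np.isnan(excess).sum())
    if n_missing == n_cells:
        raise ValueError("all combination cells missing")
    score = float(np.nanmean(excess))
    unreliable = n_missing > n_cells / 2
    if unreliable:
        logger.warning("synergy score for %s %s+%s based on %d/%d cells",
                       matrix.cell_line, matrix.drug_row, matrix.drug_col,
                       n_cells - n_missing, n_cells)
    return SynergyResult(
        cell_line=matrix.cell_line, drug_row=matrix.drug_row, drug_col=matrix.drug_col,
        bliss_expected=expected, excess=excess, score=score,
        n_cells=n_cells, n_missing=n_missing, unreliable=unreliable,
    )


def compare_synergy_by_group(
    scores: pd.Series, group_labels: pd.Series, variant: str = "welch",
    p_threshold: float = 0.05,
) -> AssociationResult:
    """Two-sample t-test of synergy scores between two groups.

    Missing scores are dropped per group and their count reported in
    ``extra['n_missing']``.  Groups are taken in sorted label order with
    'basal' first when present.
    """
    scores = pd.Series(scores).astype(float)
    labels = pd.Series(group_labels).reindex(scores.index)
    uniq = sorted(labels.dropna().unique(), key=lambda s: (s != "basal", s))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    a = scores[labels == uniq[0]]
    b = scores[labels == uniq[1]]
    n_missing = int(a.isna().sum() + b.isna().sum())
    res = two_sample_t(a.dropna(), b.dropna(), variant=variant, p_threshold=p_threshold)
    res.extra["groups"] = tuple(uniq)
    res.extra["n_missing"] = n_missing
    res.extra["mean_a"] = float(a.dropna().mean())
    res.extra["mean_b"] = float(b.dropna().mean())
    return res
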