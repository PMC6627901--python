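"""Viability normalization, 4PL curve fitting, and response descriptors.

Raw plate signal is converted to a viability fraction against control and
blank wells, technical replicates are averaged, and each (cell line, drug)
series is fit with the four-parameter logistic model

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

on log10 concentration.  Two descriptors summarise each curve: the fitted
IC50 and the area under the observed viability curve over log10
concentration (``auc_raw``), also reported normalised by the log10 span
(``auc_norm``) so that a completely unresponsive curve scores 1.  AUC is
inversely related to drug sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthdata import four_pl

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseCurve",
    "DoseResponseFit",
    "normalize_viability",
    "curves_from_plate",
    "fit_four_param_logistic",
    "compute_response_auc",
    "fit_plate",
]

DEFAULT_CLIP = (-0.05, 1.2)


@dataclass
class DoseResponseCurve:
    """Replicate-averaged viability fractions over increasing concentration."""

    cell_line: str
    drug: str
    concentrations: np.ndarray  # molar, strictly increasing
    viability: np.ndarray       # fraction per concentration
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.size != self.viability.size:
            raise ValueError("concentration/viability length mismatch")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")
        if not (np.diff(self.concentrations) > 0).all():
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class DoseResponseFit:
    cell_line: str
    drug: str
    top: float
    bottom: float
    ic50: float
    hill: float
    auc_raw: float
    auc_norm: float
    fit_r: float
    converged: bool
    message: str = ""


def normalize_viability(signal, control_signal, blank_signal, clip=DEFAULT_CLIP):
    """Fractional viability (signal - blank)/(control - blank), clipped.

    The clip bounds allow modest fluorescence overshoot above the untreated
    control (default upper bound 1.2) and slight negative values from blank
    subtraction noise (default lower bound -0.05).
    """
    signal = np.asarray(signal, dtype=float)
    control = np.asarray(control_signal, dtype=float)
    blank = np.asarray(blank_signal, dtype=float)
    if np.any(control <= blank):
        raise ValueError("control signal must exceed blank signal")
    frac = (signal - blank) / (control - blank)
    return np.clip(frac, *clip)


def curves_from_plate(plate: pd.DataFrame, clip=DEFAULT_CLIP) -> list[DoseResponseCurve]:
    """Build replicate-averaged curves from a long-format plate table."""
    required = {"cell_line", "drug", "concentration_M", "signal",
                "control_signal", "blank_signal"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    plate = plate.copy()
    plate["viability"] = normalize_viability(
        plate["signal"], plate["control_signal"], plate["blank_signal"], clip
    )
    curves = []
    for (line, drug), grp in plate.groupby(["cell_line", "drug"], sort=True):
        mean = grp.groupby("concentration_M", sort=True)["viability"].mean()
        curves.append(
            DoseResponseCurve(
                cell_line=line, drug=drug,
                concentrations=mean.index.to_numpy(),
                viability=mean.to_numpy(),
                replicates=grp[["concentration_M", "replicate", "viability"]]
                if "replicate" in grp else None,
            )
        )
    return curves


def compute_response_auc(concentrations, viability) -> tuple[float, float]:
    """Trapezoidal AUC of viability over log10 molar concentration.

    Returns ``(auc_raw, auc_norm)`` where auc_norm divides by the log10
    span, so constant viability v gives auc_norm = v.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viability, dtype=float)
    if c.size < 2:
        raise ValueError("need >=2 concentrations for AUC")
    x = np.log10(c)
    raw = float(np.trapezoid(v, x))
    return raw, raw / float(x[-1] - x[0])


def _model_log10(x, top, bottom, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - log_ic50)))


def fit_four_param_logistic(curve: DoseResponseCurve) -> DoseResponseFit:
    """Least-squares 4PL fit with deterministic multi-start initialisation.

    Hill starts at {0.5, 1, 2}; the IC50 start is the concentration whose
    observed viability is nearest the half-range between the curve's
    extremes; the start with the lowest residual wins.  Flat data (no
    detectable response) yields ``converged=False`` with the AUC still
    computed; an IC50 extrapolated more than 10^3-fold outside the tested
    range is likewise flagged unconverged.
    """
    c, v = curve.concentrations, curve.viability
    if c.size < 4:
        raise ValueError("need >=4 concentrations for 4PL fitting")
    if not np.isfinite(v).all():
        raise ValueError("non-finite viabilities")
    auc_raw, auc_norm = compute_response_auc(c, v)
    x = np.log10(c)

    if np.ptp(v) < 1e-12:
        return DoseResponseFit(
            curve.cell_line, curve.drug,
            top=float(v[0]), bottom=float(v[0]), ic50=float("nan"),
            hill=float("nan"), auc_raw=auc_raw, auc_norm=auc_norm,
            fit_r=float("nan"), converged=False, message="flat response",
        )

    half = (v.max() + v.min()) / 2.0
    x0_ic50 = x[int(np.argmin(np.abs(v - half)))]
    bounds = (
        [0.0, -0.2, x[0] - 3.0, 0.01],
        [1.5, 1.0, x[-1] + 3.0, 10.0],
    )
    best = None
    for hill0 in (0.5, 1.0, 2.0):
        p0 = [min(max(v.max(), 0.0), 1.5), max(v.min(), -0.2), x0_ic50, hill0]
        try:
            popt, _ = curve_fit(_model_log10, x, v, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((v - _model_log10(x, *popt)) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return DoseResponseFit(
            curve.cell_line, curve.drug, float("nan"), float("nan"),
            float("nan"), float("nan"), auc_raw, auc_norm, float("nan"),
            False, "optimizer failed",
        )
    (top, bottom, log_ic50, hill), resid = best
    fitted = _model_log10(x, top, bottom, log_ic50, hill)
    if np.std(fitted) < 1e-12 or np.std(v) < 1e-12:
        fit_r = float("nan")
    else:
        fit_r = float(np.corrcoef(fitted, v)[0, 1])
    in_range = (x[0] - 3.0) < log_ic50 < (x[-1] + 3.0)
    converged = bool(in_range and np.isfinite(fit_r))
    return DoseResponseFit(
        curve.cell_line, curve.drug,
        top=float(top), bottom=float(bottom), ic50=float(10.0 ** log_ic50),
        hill=float(hill), auc_raw=auc_raw, auc_norm=auc_norm,
        fit_r=fit_r, converged=converged,
    )


def fit_plate(plate: pd.DataFrame, clip=DEFAULT_CLIP) -> pd.DataFrame:
    """Fit every (cell line, drug) series of a plate table.

    Returns a tidy frame with one row per curve: 4PL parameters, AUC
    descriptors, fit correlation and convergence flag.
    """
    rows = []
    for curve in curves_from_plate(plate, clip):
        f = fit_four_param_logistic(curve)
        rows.append({
            "cell_line": f.cell_line, "drug": f.drug, "top": f.top,
            "bottom": f.bottom, "ic50_M": f.ic50, "hill": f.hill,
            "auc_raw": f.auc_raw, "auc_norm": f.auc_norm,
            "fit_r": f.fit_r, "converged": f.converged,
        })
    return pd.DataFrame(rows)
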