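"""Seeded generators for every input the screening pipeline consumes.

The generators emulate the structure of a basal vs non-basal HNSCC
cell-line screen: multi-cohort log2 expression matrices with four
transcriptomic subtypes (basal, classical, mesenchymal, atypical) and
per-dataset batch effects, 13-point dose-response plates with
subtype-dependent potency for EGFR-directed drugs, 6x6 Bliss-null
combination matrices with injected excess inhibition, subtype-biased
binary mutation calls, qPCR Ct tables, and binomial clonogenic colony
counts.

Determinism: one root seed spawns independent per-generator streams in a
fixed, documented order (see ``_STREAMS``), so drawing from one generator
never perturbs another and adding a generator keeps existing outputs
byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "ExpressionDataset",
    "DEFAULT_DRUG_PANEL",
    "EGFR_DRUGS",
    "simulate_expression",
    "simulate_cell_line_panels",
    "simulate_dose_response",
    "simulate_combination_matrix",
    "simulate_mutations",
    "simulate_qpcr",
    "simulate_clonogenic",
    "write_manifest",
]

SUBTYPES = ("basal", "classical", "mesenchymal", "atypical")

# Independent random streams spawned from the root seed, in fixed order.
_STREAMS = {
    "expression": 0,
    "dose_response": 1,
    "combination": 2,
    "mutations": 3,
    "qpcr": 4,
    "clonogenic": 5,
    "cell_lines": 6,
}

# Single-agent screening ranges: 13 concentrations, 2.5-fold dilution.
# Small molecules span 0.5 nM - 30 uM; the antibodies use their own ranges.
DEFAULT_DRUG_PANEL = {
    "Afatinib": {"c0": 0.5e-9, "fold": 2.5, "n": 13, "egfr": True},
    "Erlotinib": {"c0": 0.5e-9, "fold": 2.5, "n": 13, "egfr": True},
    "Cetuximab": {"c0": 0.1e-9, "fold": 2.5, "n": 13, "egfr": True},
    "Gedatolisib": {"c0": 0.5e-9, "fold": 2.5, "n": 13, "egfr": False},
    "Cobimetinib": {"c0": 0.5e-9, "fold": 2.5, "n": 13, "egfr": False},
    "Trastuzumab": {"c0": 0.4e-9, "fold": 2.5, "n": 13, "egfr": False},
}
EGFR_DRUGS = tuple(d for d, v in DEFAULT_DRUG_PANEL.items() if v["egfr"])

# Combination matrices: six concentrations of each compound.
DEFAULT_COMBO_RANGES = {
    "default": {"c0": 1.3e-9, "fold": 6.0, "n": 6},
    "Cetuximab": {"c0": 0.37e-9, "fold": 12.0, "n": 6},
    "Trastuzumab": {"c0": 1.54e-9, "fold": 12.0, "n": 6},
}


def _default_subtype_proportions() -> dict:
    # basal ~30% of tumors; remainder split over the other three subtypes
    return {"basal": 0.30, "classical": 0.25, "mesenchymal": 0.25, "atypical": 0.20}


def _default_mutation_rates() -> dict:
    # (rate in basal, rate in non-basal); CDKN2A mirrors 6/10 vs 2/15
    return {
        "CDKN2A": (0.6, 0.133),
        "PTEN": (0.2, 0.067),
        "EGFR": (0.2, 0.067),
        "HIST1H3B": (0.05, 0.15),
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic screen, fully determined by ``seed``."""

    seed: int = 0
    n_genes: int = 200
    n_samples_per_dataset: int = 60
    n_datasets: int = 3
    subtype_proportions: dict = field(default_factory=_default_subtype_proportions)
    n_marker_genes: int = 20          # per-subtype signature size, EREG/AREG first
    marker_effect: float = 2.0        # log2 shift of basal markers in basal samples
    noise_sd: float = 0.5             # log2 expression noise SD
    batch_scale_range: tuple = (0.8, 1.25)
    batch_offset_sd: float = 0.5
    mutation_rates: dict = field(default_factory=_default_mutation_rates)
    potency_shift: float = 1.0        # log10 IC50 drop for basal lines, EGFR drugs
    synergy_delta: dict = field(default_factory=dict)  # (subtype, "A+B") -> points
    viability_clip: tuple = (-0.05, 1.2)
    signal_blank: float = 50.0
    signal_control: float = 1050.0
    signal_noise_sd: float = 0.02     # fraction of dynamic range
    combo_noise_sd: float = 0.0       # percentage points on inhibition
    qpcr_noise_sd: float = 0.0        # cycles
    qpcr_base_ct: float = 25.0
    qpcr_ref_ct: float = 15.0

    def __post_init__(self) -> None:
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions sum to {total}, not 1")
        if min(self.n_genes, self.n_samples_per_dataset, self.n_datasets) <= 0:
            raise ValueError("counts must be positive")
        for gene, (rb, rn) in self.mutation_rates.items():
            if not (0 <= rb <= 1 and 0 <= rn <= 1):
                raise ValueError(f"mutation rate for {gene} outside [0,1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Dedicated random stream for one generator family."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)

    @property
    def marker_genes(self) -> list[str]:
        named = ["EREG", "AREG"]
        extra = [f"BASAL_M{i}" for i in range(2, self.n_marker_genes)]
        return (named + extra)[: self.n_marker_genes]

    def gene_names(self) -> list[str]:
        """Gene universe: basal markers, other subtype signatures, background."""
        names = list(self.marker_genes)
        for st in SUBTYPES[1:]:
            names += [f"{st.upper()[:4]}_M{i}" for i in range(self.n_marker_genes)]
        n_bg = self.n_genes - len(names)
        if n_bg < 0:
            raise ValueError("n_genes too small for the signature gene sets")
        names += [f"G{i:04d}" for i in range(n_bg)]
        return names

    def signature_genes(self, subtype: str) -> list[str]:
        if subtype == "basal":
            return self.marker_genes
        return [f"{subtype.upper()[:4]}_M{i}" for i in range(self.n_marker_genes)]


@dataclass
class ExpressionDataset:
    """One cohort's log2 expression matrix with optional subtype labels."""

    dataset_id: str
    values: pd.DataFrame                      # genes x samples
    subtype_labels: pd.Series | None = None   # per sample

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene labels")
        if self.subtype_labels is not None and not self.subtype_labels.index.equals(
            self.values.columns
        ):
            raise ValueError("subtype labels do not match sample columns")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)


def _subtype_counts(n: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of n samples over subtypes."""
    raw = {st: n * proportions[st] for st in proportions}
    counts = {st: int(np.floor(v)) for st, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(proportions, key=lambda st: raw[st] - counts[st], reverse=True)
    for st in order[:short]:
        counts[st] += 1
    return counts


def simulate_expression(config: SimulationConfig) -> list[ExpressionDataset]:
    """Simulate ``n_datasets`` labelled cohorts of log2 expression.

    Each subtype up-regulates its own signature genes by ``marker_effect``
    log2 units (the basal signature leads with EREG and AREG); every
    dataset then gets a multiplicative batch scale and additive offset.
    """
    rng = config.rng("expression")
    genes = config.gene_names()
    base = rng.normal(7.0, 1.0, size=len(genes))  # shared per-gene baseline
    gene_idx = {g: i for i, g in enumerate(genes)}

    datasets = []
    for d in range(config.n_datasets):
        n = config.n_samples_per_dataset
        counts = _subtype_counts(n, config.subtype_proportions)
        labels = [st for st in SUBTYPES for _ in range(counts.get(st, 0))]
        rng.shuffle(labels)
        samples = [f"D{d}_S{i:03d}" for i in range(n)]

        mat = np.tile(base[:, None], (1, n)) + rng.normal(
            0.0, config.noise_sd, size=(len(genes), n)
        )
        for j, st in enumerate(labels):
            for g in config.signature_genes(st):
                mat[gene_idx[g], j] += config.marker_effect

        scale = rng.uniform(*config.batch_scale_range)
        offset = rng.normal(0.0, config.batch_offset_sd)
        mat = mat * scale + offset

        values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
        datasets.append(
            ExpressionDataset(
                dataset_id=f"dataset{d}",
                values=values,
                subtype_labels=pd.Series(labels, index=values.columns, name="subtype"),
            )
        )
    return datasets


def simulate_cell_line_panels(
    config: SimulationConfig,
    n_lines: int = 25,
    n_basal: int = 10,
    absent_from_panel2: int = 2,
) -> tuple[list[ExpressionDataset], pd.Series]:
    """Two cell-line expression panels sharing most lines, plus true labels.

    Emulates the situation where the same cell lines are profiled by two
    independent expression panels: the lines carry one true subtype (basal
    lines up-regulate the basal signature; the rest are spread over the
    other three subtypes), each panel adds its own noise and batch
    effects, and the last ``absent_from_panel2`` non-basal lines are
    missing from the second panel.  Returns ``([panel1, panel2],
    true_subtypes)``; panel sample labels are the cell-line names.
    """
    if not 0 < n_basal < n_lines:
        raise ValueError("need 0 < n_basal < n_lines")
    rng = config.rng("cell_lines")
    genes = config.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    base = rng.normal(7.0, 1.0, size=len(genes))

    lines = [f"CL{i:02d}" for i in range(n_lines)]
    others = [st for st in SUBTYPES if st != "basal"]
    labels = ["basal"] * n_basal + [others[i % 3] for i in range(n_lines - n_basal)]
    true = pd.Series(labels, index=pd.Index(lines, name="cell_line"), name="subtype")

    panels = []
    for p in range(2):
        members = lines if p == 0 else lines[: n_lines - absent_from_panel2]
        mat = np.tile(base[:, None], (1, len(members))) + rng.normal(
            0.0, config.noise_sd, size=(len(genes), len(members))
        )
        for j, line in enumerate(members):
            for g in config.signature_genes(true[line]):
                mat[gene_idx[g], j] += config.marker_effect
        scale = rng.uniform(*config.batch_scale_range)
        offset = rng.normal(0.0, config.batch_offset_sd)
        values = pd.DataFrame(mat * scale + offset,
                              index=pd.Index(genes, name="gene"), columns=members)
        panels.append(
            ExpressionDataset(dataset_id=f"panel{p + 1}", values=values,
                              subtype_labels=true.loc[members].copy())
        )
    return panels, true


def four_pl(c: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic viability fraction, decreasing with dose."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def concentration_grid(c0: float, fold: float, n: int) -> np.ndarray:
    return c0 * fold ** np.arange(n)


def _true_curve_params(rng, subtype: str, drug: str, spec: dict, config: SimulationConfig):
    grid = concentration_grid(spec["c0"], spec["fold"], spec["n"])
    lo, hi = np.log10(grid[2]), np.log10(grid[-3])
    log_ic50 = rng.uniform(lo, hi)
    if spec.get("egfr") and subtype == "basal":
        log_ic50 -= config.potency_shift
    return {
        "top": 1.0,
        "bottom": float(rng.uniform(0.0, 0.1)),
        "ic50": float(10.0 ** log_ic50),
        "hill": float(rng.uniform(0.8, 1.5)),
    }


def simulate_dose_response(
    config: SimulationConfig,
    cell_lines_with_subtype: dict[str, str],
    drug_panel: dict | None = None,
    true_params: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a single-agent viability plate in long format.

    Returns ``(plate, truth)``: the plate has one row per (cell line, drug,
    concentration, replicate) with raw fluorescence-like signal plus control
    and blank wells; the truth table records the generating 4PL parameters.
    Basal lines are more potent (log10 IC50 shifted down by
    ``potency_shift``) for EGFR-directed drugs.
    """
    if drug_panel is None:
        drug_panel = DEFAULT_DRUG_PANEL
    if not drug_panel:
        raise ValueError("empty drug panel")
    if not cell_lines_with_subtype:
        raise ValueError("no cell lines")
    rng = config.rng("dose_response")
    span = config.signal_control - config.signal_blank
    rows, truth_rows = [], []
    for line, subtype in cell_lines_with_subtype.items():
        for drug, spec in drug_panel.items():
            if true_params and (line, drug) in true_params:
                params = true_params[(line, drug)]
            else:
                params = _true_curve_params(rng, subtype, drug, spec, config)
            grid = concentration_grid(spec["c0"], spec["fold"], spec["n"])
            viab = four_pl(grid, **params)
            for ci, c in enumerate(grid):
                for rep in range(3):
                    noise = rng.normal(0.0, config.signal_noise_sd) * span
                    signal = config.signal_blank + span * viab[ci] + noise
                    rows.append((line, drug, c, rep + 1, signal,
                                 config.signal_control, config.signal_blank))
            truth_rows.append({"cell_line": line, "drug": drug, "subtype": subtype, **params})
    plate = pd.DataFrame(
        rows,
        columns=["cell_line", "drug", "concentration_M", "replicate",
                 "signal", "control_signal", "blank_signal"],
    )
    return plate, pd.DataFrame(truth_rows)


def simulate_combination_matrix(
    config: SimulationConfig,
    cell_line: str,
    subtype: str,
    drug_a: str,
    drug_b: str,
    single_agent_params: dict | None = None,
):
    """Simulate one two-drug 6x6 inhibition matrix (plus single-agent axes).

    Combined inhibition is the Bliss expectation of the two single-agent
    inhibitions plus the configured excess ``synergy_delta[(subtype,
    "A+B")]`` (percentage points, default 0) plus Gaussian noise, clipped
    to [0, 100].
    """
    from .synergy import DoseMatrix, bliss_expected  # local import, no cycle at module load

    # per-(line, combo) substream: reproducible and independent of call order
    tag = zlib.crc32(f"{cell_line}|{drug_a}|{drug_b}".encode())
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS["combination"], tag))
    )

    def axis(drug):
        spec = DEFAULT_COMBO_RANGES.get(drug, DEFAULT_COMBO_RANGES["default"])
        return concentration_grid(spec["c0"], spec["fold"], spec["n"])

    ca, cb = axis(drug_a), axis(drug_b)
    if single_agent_params is None:
        single_agent_params = {}
    pa = single_agent_params.get(drug_a) or _true_curve_params(
        rng, subtype, drug_a,
        {**DEFAULT_COMBO_RANGES.get(drug_a, DEFAULT_COMBO_RANGES["default"]),
         "egfr": drug_a in EGFR_DRUGS},
        config,
    )
    pb = single_agent_params.get(drug_b) or _true_curve_params(
        rng, subtype, drug_b,
        {**DEFAULT_COMBO_RANGES.get(drug_b, DEFAULT_COMBO_RANGES["default"]),
         "egfr": drug_b in EGFR_DRUGS},
        config,
    )
    inhib_a = 100.0 * (1.0 - four_pl(ca, **pa))
    inhib_b = 100.0 * (1.0 - four_pl(cb, **pb))
    delta = config.synergy_delta.get((subtype, f"{drug_a}+{drug_b}"), 0.0)

    row_concs = np.concatenate([[0.0], ca])
    col_concs = np.concatenate([[0.0], cb])
    grid = np.zeros((len(row_concs), len(col_concs)))
    grid[1:, 0] = inhib_a
    grid[0, 1:] = inhib_b
    for i, ya in enumerate(inhib_a):
        for j, yb in enumerate(inhib_b):
            val = bliss_expected(ya, yb) + delta
            if config.combo_noise_sd > 0:
                val += rng.normal(0.0, config.combo_noise_sd)
            grid[i + 1, j + 1] = val
    grid = np.clip(grid, 0.0, 100.0)
    grid[0, 0] = 0.0
    return DoseMatrix(
        cell_line=cell_line, drug_row=drug_a, drug_col=drug_b,
        row_concs=row_concs, col_concs=col_concs, inhibition=grid,
    )


def simulate_mutations(
    config: SimulationConfig, cell_lines_with_subtype: dict[str, str]
) -> pd.DataFrame:
    """Binary mutation calls, Bernoulli per (cell line, gene).

    The per-gene rate depends on whether the line is basal, mirroring
    mutations enriched in one subtype.
    """
    rng = config.rng("mutations")
    lines = list(cell_lines_with_subtype)
    data = {}
    for gene, (rate_basal, rate_non) in config.mutation_rates.items():
        p = np.array([
            rate_basal if cell_lines_with_subtype[l] == "basal" else rate_non
            for l in lines
        ])
        data[gene] = (rng.random(len(lines)) < p).astype(int)
    return pd.DataFrame(data, index=pd.Index(lines, name="cell_line"))


def simulate_qpcr(
    config: SimulationConfig,
    true_fold_changes: dict[str, float],
    reference_genes: tuple[str, ...] = ("RPLP0", "UBB"),
) -> pd.DataFrame:
    """Simulate Ct values for treated samples vs an untreated control.

    Relative expression r maps to Ct as base_ct - log2(r); reference genes
    sit at a fixed Ct.  One control row plus one row per entry of
    ``true_fold_changes`` (sample -> fold change vs control).
    """
    rng = config.rng("qpcr")
    rows = [{"sample": "control", "condition": "control",
             "ct_target": config.qpcr_base_ct + (rng.normal(0, config.qpcr_noise_sd)
                                                 if config.qpcr_noise_sd else 0.0),
             **{f"ct_{g}": config.qpcr_ref_ct for g in reference_genes}}]
    for sample, fold in true_fold_changes.items():
        if fold <= 0:
            raise ValueError("fold changes must be positive")
        ct = config.qpcr_base_ct - np.log2(fold)
        if config.qpcr_noise_sd:
            ct += rng.normal(0, config.qpcr_noise_sd)
        rows.append({"sample": sample, "condition": "treated", "ct_target": ct,
                     **{f"ct_{g}": config.qpcr_ref_ct for g in reference_genes}})
    return pd.DataFrame(rows)


def simulate_clonogenic(
    config: SimulationConfig,
    pe: float,
    sf_true: float,
    n_seeded: int,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate colony counts: treated wells Binomial(n_seeded, pe*sf_true),
    untreated wells Binomial(n_seeded, pe)."""
    if n_seeded <= 0:
        raise ValueError("n_seeded must be positive")
    if not 0 < pe <= 1 or not 0 <= pe * sf_true <= 1:
        raise ValueError("pe and pe*sf_true must lie in (0,1] and [0,1]")
    rng = config.rng("clonogenic")
    rows = []
    for rep in range(n_replicates):
        rows.append({"condition": "untreated", "replicate": rep + 1,
                     "cells_seeded": n_seeded,
                     "colonies": int(rng.binomial(n_seeded, pe))})
        rows.append({"condition": "treated", "replicate": rep + 1,
                     "cells_seeded": n_seeded,
                     "colonies": int(rng.binomial(n_seeded, pe * sf_true))})
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, config: SimulationConfig, **extra) -> None:
    """Record the seed and full config next to generated files."""
    payload = {"config": asdict(config), **extra}
    payload["config"]["mutation_rates"] = {
        k: list(v) for k, v in config.mutation_rates.items()
    }
    payload["config"]["synergy_delta"] = {
        f"{k[0]}|{k[1]}": v for k, v in config.synergy_delta.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
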