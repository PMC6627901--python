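"""End-to-end orchestration of the synthetic screening analysis.

Stage order: simulate -> classify -> doseresponse -> synergy -> associate
-> assays -> report.  Every stage writes plain TSV intermediates with a
``# key=value`` manifest header (seed, config hash, package version) so
any stage can be inspected and replayed; re-running with the same seed
reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assays import analyze_clonogenic_table, analyze_qpcr_table
from .doseresponse import fit_plate
from .fixtures import summarize_combinations, summarize_single_agent
from .stats import association_frame, mutation_association
from .subtyping import (build_centroids, consensus_basal_call,
                        identify_common_de_genes, predict_dataset,
                        scale_and_aggregate, select_markers)
from .synergy import bliss_synergy_score, compare_synergy_by_group
from .synthdata import (DEFAULT_DRUG_PANEL, EGFR_DRUGS, SimulationConfig,
                        simulate_cell_line_panels, simulate_clonogenic,
                        simulate_combination_matrix, simulate_dose_response,
                        simulate_expression, simulate_mutations, simulate_qpcr)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("simulate", "classify", "doseresponse", "synergy", "associate", "assays")
# each stage requires all of its listed prerequisites to be enabled
_DEPENDENCIES = {
    "classify": ("simulate",),
    "doseresponse": ("classify",),
    "synergy": ("classify",),
    "associate": ("classify", "doseresponse"),
    "assays": ("simulate",),
}

COMBINATIONS = tuple(
    f"{a}+{b}" for a in ("Afatinib", "Cetuximab", "Erlotinib")
    for b in ("Cobimetinib", "Gedatolisib", "Trastuzumab")
)


def _default_synergy_delta() -> dict:
    # basal-biased excess for the combinations the screen singles out
    return {
        ("basal", "Cetuximab+Trastuzumab"): 10.0,
        ("basal", "Afatinib+Trastuzumab"): 8.0,
        ("basal", "Afatinib+Gedatolisib"): 8.0,
    }


def _default_knockdown() -> dict:
    # three independent siRNAs, all beyond 90% knockdown
    return {"siEREG1": 0.08, "siEREG2": 0.06, "siEREG3": 0.09}


@dataclass
class PipelineConfig:
    """Toggles, thresholds and simulation parameters for one run."""

    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    n_cell_lines: int = 25
    n_basal_lines: int = 10
    absent_from_panel2: int = 2
    de_fdr: float = 0.05
    fc_threshold: float = 1.0
    auc_threshold: float = 0.8
    p_threshold: float = 0.1          # mutation-association flag threshold
    combo_noise_sd: float = 2.0       # percentage points
    synergy_delta: dict = field(default_factory=_default_synergy_delta)
    knockdown_folds: dict = field(default_factory=_default_knockdown)
    clonogenic_pe: float = 0.4
    clonogenic_sf: float = 0.5
    clonogenic_seeded: int = 250
    sim: SimulationConfig | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        for stage, deps in _DEPENDENCIES.items():
            if self.stages[stage]:
                missing = [d for d in deps if not self.stages[d]]
                if missing:
                    raise ValueError(
                        f"stage '{stage}' requires {missing} to be enabled"
                    )
        if self.sim is None:
            self.sim = SimulationConfig(
                seed=self.seed,
                synergy_delta=dict(self.synergy_delta),
                combo_noise_sd=self.combo_noise_sd,
            )

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        cfg["synergy_delta"] = {f"{k[0]}|{k[1]}": v for k, v in self.synergy_delta.items()}
        cfg["sim"]["synergy_delta"] = dict(cfg["synergy_delta"])
        cfg["sim"]["mutation_rates"] = {k: list(v) for k, v in
                                        self.sim.mutation_rates.items()}
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "seed": self.seed,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "version": __version__,
        }


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in manifest.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages; returns all in-memory results.

    Raises at the first failing stage with the stage name in the message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = config.manifest()
    sim = config.sim
    results: dict = {"manifest": manifest}

    def stage(name):
        logger.info("stage %s", name)
        return config.stages[name]

    try:
        if stage("simulate"):
            cohorts = simulate_expression(sim)
            for ds in cohorts:
                ds.write_tsv(outdir / f"expression_{ds.dataset_id}.tsv")
            results["cohorts"] = cohorts
            logger.info("simulate: %d cohorts of %d x %d", len(cohorts),
                        sim.n_genes, sim.n_samples_per_dataset)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        if stage("classify"):
            cohorts = results["cohorts"]
            genes = identify_common_de_genes(cohorts, fdr=config.de_fdr)
            if not genes:
                raise ValueError("no common differentially expressed genes")
            aggregated = scale_and_aggregate(cohorts)
            centroids = build_centroids(aggregated, genes)
            markers = select_markers(
                aggregated.values.loc[genes],
                aggregated.subtype_labels.map(
                    lambda s: "basal" if s == "basal" else "non-basal"),
                fc_threshold=config.fc_threshold,
                auc_threshold=config.auc_threshold,
            )
            panels, true_subtypes = simulate_cell_line_panels(
                sim, config.n_cell_lines, config.n_basal_lines,
                config.absent_from_panel2,
            )
            calls = {}
            for panel in panels:
                std = scale_and_aggregate([panel])
                pred = predict_dataset(std, centroids)
                pred.index = [s.split(":", 1)[1] for s in pred.index]
                calls[panel.dataset_id] = pred
            consensus_rows = []
            for line in true_subtypes.index:
                per_panel = []
                for panel in panels:
                    if line in calls[panel.dataset_id].index:
                        p = calls[panel.dataset_id].loc[line, "predicted"]
                        per_panel.append("basal" if p == "basal" else "non-basal")
                    else:
                        per_panel.append("absent")
                cc = consensus_basal_call(*per_panel, cell_line=line)
                consensus_rows.append({
                    "cell_line": line, "panel1": cc.call_dataset1,
                    "panel2": cc.call_dataset2, "consensus": cc.consensus,
                    "true_subtype": true_subtypes[line],
                })
            consensus = pd.DataFrame(consensus_rows).set_index("cell_line")
            results.update(centroids=centroids, markers=markers,
                           consensus=consensus, true_subtypes=true_subtypes,
                           de_genes=genes)
            _write(centroids.centroid_matrix, outdir / "centroids.tsv", manifest)
            _write(consensus, outdir / "consensus_calls.tsv", manifest)
            _write(pd.DataFrame([dataclasses.asdict(m) for m in markers]),
                   outdir / "markers.tsv", manifest, index=False)
            logger.info("classify: %d DE genes, %d/%d lines called basal",
                        len(genes), (consensus["consensus"] == "basal").sum(),
                        len(consensus))
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    try:
        if stage("doseresponse"):
            consensus = results["consensus"]
            usable = consensus[consensus["consensus"] != "unclassified"]
            lines = {l: ("basal" if c == "basal" else "nonbasal")
                     for l, c in usable["consensus"].items()}
            # the generator keys potency on the true subtype label
            gen_labels = {l: ("basal" if c == "basal" else "other")
                          for l, c in lines.items()}
            plate, truth = simulate_dose_response(sim, gen_labels, DEFAULT_DRUG_PANEL)
            fits = fit_plate(plate, clip=sim.viability_clip)
            auc = fits.pivot(index="cell_line", columns="drug", values="auc_norm")
            plate.to_csv(outdir / "plate.csv", index=False)
            _write(fits, outdir / "dose_response_fits.tsv", manifest, index=False)
            _write(auc, outdir / "auc_table.tsv", manifest)
            results.update(plate=plate, dr_truth=truth, fits=fits, auc=auc,
                           screen_labels=pd.Series(lines))
            logger.info("doseresponse: fit %d curves, %d unconverged",
                        len(fits), int((~fits["converged"]).sum()))
    except Exception as exc:
        raise RuntimeError(f"stage 'doseresponse' failed: {exc}") from exc

    try:
        if stage("synergy"):
            consensus = results["consensus"]
            usable = consensus[consensus["consensus"] != "unclassified"]
            labels = usable["consensus"]
            rows = []
            for line, lab in labels.items():
                for combo in COMBINATIONS:
                    drug_a, drug_b = combo.split("+")
                    mat = simulate_combination_matrix(
                        sim, line, "basal" if lab == "basal" else "other",
                        drug_a, drug_b)
                    res = bliss_synergy_score(mat)
                    rows.append({"cell_line": line, "subtype": lab,
                                 "combination": combo, "score": res.score,
                                 "n_missing": res.n_missing,
                                 "unreliable": res.unreliable})
            scores_long = pd.DataFrame(rows)
            scores = scores_long.pivot(index="cell_line", columns="combination",
                                       values="score")
            comps = []
            for combo in COMBINATIONS:
                r = compare_synergy_by_group(scores[combo], labels)
                comps.append({"combination": combo, "t": r.statistic,
                              "p": r.p_value, "mean_basal": r.extra["mean_a"],
                              "mean_nonbasal": r.extra["mean_b"],
                              "direction": r.effect_direction})
            synergy_comparison = pd.DataFrame(comps).set_index("combination")
            _write(scores, outdir / "bliss_scores.tsv", manifest)
            _write(synergy_comparison, outdir / "synergy_by_subtype.tsv", manifest)
            results.update(bliss_scores=scores, synergy_comparison=synergy_comparison)
            logger.info("synergy: scored %d matrices", len(scores_long))
    except Exception as exc:
        raise RuntimeError(f"stage 'synergy' failed: {exc}") from exc

    try:
        if stage("associate"):
            consensus = results["consensus"]
            usable = consensus[consensus["consensus"] != "unclassified"]
            gen_labels = {l: ("basal" if c == "basal" else "other")
                          for l, c in usable["consensus"].items()}
            mutations = simulate_mutations(sim, gen_labels)
            assoc = mutation_association(results["auc"], mutations,
                                         p_threshold=config.p_threshold)
            assoc_df = association_frame(assoc)
            # subtype vs response, per drug (Welch t)
            subtype_rows = []
            for drug in results["auc"].columns:
                r = compare_synergy_by_group(results["auc"][drug],
                                             usable["consensus"])
                subtype_rows.append({"drug": drug, "t": r.statistic,
                                     "p": r.p_value,
                                     "mean_basal": r.extra["mean_a"],
                                     "mean_nonbasal": r.extra["mean_b"],
                                     "direction": r.effect_direction})
            subtype_assoc = pd.DataFrame(subtype_rows).set_index("drug")
            _write(mutations, outdir / "mutations.tsv", manifest)
            _write(assoc_df, outdir / "mutation_association.tsv", manifest,
                   index=False)
            _write(subtype_assoc, outdir / "subtype_association.tsv", manifest)
            results.update(mutations=mutations, mutation_assoc=assoc_df,
                           subtype_assoc=subtype_assoc)
            logger.info("associate: %d (gene,drug) tests, %d flagged",
                        len(assoc_df), int(assoc_df["flagged"].sum())
                        if len(assoc_df) else 0)
    except Exception as exc:
        raise RuntimeError(f"stage 'associate' failed: {exc}") from exc

    try:
        if stage("assays"):
            ct = simulate_qpcr(sim, config.knockdown_folds)
            qpcr = analyze_qpcr_table(ct)
            colonies = simulate_clonogenic(sim, config.clonogenic_pe,
                                           config.clonogenic_sf,
                                           config.clonogenic_seeded)
            clono = analyze_clonogenic_table(colonies)
            ct.to_csv(outdir / "qpcr_ct.csv", index=False)
            colonies.to_csv(outdir / "colonies.csv", index=False)
            _write(qpcr, outdir / "qpcr_fold_changes.tsv", manifest, index=False)
            _write(clono, outdir / "clonogenic_summary.tsv", manifest, index=False)
            results.update(qpcr=qpcr, clonogenic=clono)
    except Exception as exc:
        raise RuntimeError(f"stage 'assays' failed: {exc}") from exc

    # report: packaged reference-table summaries alongside the synthetic run
    table1_summary = summarize_single_agent()
    table2_summary = summarize_combinations()
    _write(table1_summary, outdir / "reference_single_agent_summary.tsv", manifest)
    _write(table2_summary, outdir / "reference_combination_summary.tsv", manifest)
    results.update(table1_summary=table1_summary, table2_summary=table2_summary)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results
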