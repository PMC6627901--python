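"""Cross-dataset molecular subtype harmonization and basal calling.

The workflow mirrors consensus subtype transfer between expression
cohorts: differentially expressed genes shared by all labelled cohorts are
found with a moderated t-test (basal vs rest, Benjamini-Hochberg per
cohort), each cohort is gene-wise standardized and the cohorts aggregated,
per-subtype centroids are built on the shared genes, and new samples are
assigned the subtype whose centroid they correlate with most strongly
(Pearson).  A cell line profiled in two independent expression panels is
called basal only when both panels predict basal; it is non-basal when
both predict non-basal, or when one predicts non-basal and the line is
absent from the other panel.  Discordant predictions, and a basal
prediction with the line absent from the second panel, are left
unclassified and excluded downstream.

Marker genes of the basal subtype are ranked by two criteria: log2 fold
change (basal mean minus non-basal mean) and the ROC AUC of the gene's
expression as a basal/non-basal discriminator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .stats import benjamini_hochberg, moderated_t
from .synthdata import SUBTYPES, ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CentroidSet", "SubtypeCall", "ConsensusCall", "MarkerScore",
    "identify_common_de_genes", "build_centroids", "compare_centroids",
    "scale_and_aggregate", "predict_subtype", "predict_dataset",
    "consensus_basal_call", "roc_auc", "select_markers",
]


@dataclass
class CentroidSet:
    """Mean standardized expression profile per subtype over a gene panel."""

    subtypes: tuple
    centroid_matrix: pd.DataFrame  # genes x subtypes
    source: str = "aggregated"

    def __post_init__(self) -> None:
        if len(set(self.subtypes)) != len(self.subtypes):
            raise ValueError("duplicate subtype labels")
        if self.centroid_matrix.empty:
            raise ValueError("empty gene list")
        if not np.isfinite(self.centroid_matrix.to_numpy()).all():
            raise ValueError("non-finite centroid values")

    @property
    def genes(self) -> pd.Index:
        return self.centroid_matrix.index


@dataclass
class SubtypeCall:
    sample_id: str
    correlations: dict          # subtype -> Pearson r
    predicted: str
    margin: float               # best r minus second-best r
    tie: bool = False


@dataclass
class ConsensusCall:
    cell_line: str
    call_dataset1: str          # basal | non-basal | absent
    call_dataset2: str
    consensus: str              # basal | non-basal | unclassified


@dataclass
class MarkerScore:
    gene: str
    log2_fold_change: float
    roc_auc: float
    selected: bool


def _basal_rest_split(ds: ExpressionDataset):
    if ds.subtype_labels is None:
        raise ValueError(f"{ds.dataset_id} has no subtype labels")
    labels = ds.subtype_labels
    if labels.nunique() < 2:
        raise ValueError(f"{ds.dataset_id} has a single subtype")
    basal = labels.index[labels == "basal"]
    rest = labels.index[labels != "basal"]
    return ds.values[basal], ds.values[rest]


def identify_common_de_genes(datasets, fdr: float = 0.05) -> list[str]:
    """Genes basal-vs-rest differential in every dataset, same direction.

    Per dataset a moderated t compares basal samples against all others
    with BH control at ``fdr``; the returned genes are significant and
    direction-concordant in every dataset, ordered by decreasing mean
    absolute log2 fold change.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets")
    shared = datasets[0].genes
    for ds in datasets[1:]:
        shared = shared.intersection(ds.genes)
    if len(shared) == 0:
        raise ValueError("datasets share no genes")

    selected = None
    direction: dict[str, list[int]] = {}
    fold: dict[str, list[float]] = {}
    for ds in datasets:
        basal, rest = _basal_rest_split(ds)
        results = moderated_t(basal.loc[shared], rest.loc[shared])
        p_adj = benjamini_hochberg([r.p_value for r in results])
        sig = set()
        for r, q in zip(results, p_adj):
            if q <= fdr:
                sig.add(r.feature)
            direction.setdefault(r.feature, []).append(r.effect_direction)
            fold.setdefault(r.feature, []).append(r.extra["log2_fc"])
        selected = sig if selected is None else (selected & sig)

    out = [
        g for g in selected
        if len(set(direction[g])) == 1 and direction[g][0] != 0
    ]
    out.sort(key=lambda g: -float(np.mean(np.abs(fold[g]))))
    return out


def scale_and_aggregate(datasets) -> ExpressionDataset:
    """Gene-wise standardize each dataset, then column-bind on shared genes.

    Standardization uses the population SD (divisor n).  Genes with zero
    variance in any dataset are dropped with a log entry.  Sample ids are
    prefixed with the dataset id; dataset of origin and subtype labels (if
    present everywhere) are carried along.
    """
    datasets = list(datasets)
    shared = datasets[0].genes
    for ds in datasets[1:]:
        shared = shared.intersection(ds.genes)
    if len(shared) == 0:
        raise ValueError("datasets share no genes")

    blocks, label_parts, origin_parts = [], [], []
    drop: set = set()
    for ds in datasets:
        sub = ds.values.loc[shared]
        sd = sub.std(axis=1, ddof=0)
        zero = sd.index[sd == 0]
        if len(zero):
            logger.info("%s: dropping %d zero-variance genes", ds.dataset_id, len(zero))
            drop.update(zero)
    keep = shared.difference(pd.Index(sorted(drop)))
    if len(keep) == 0:
        raise ValueError("no genes left after dropping zero-variance genes")
    keep = pd.Index([g for g in shared if g in set(keep)])  # preserve order

    have_labels = all(ds.subtype_labels is not None for ds in datasets)
    for ds in datasets:
        sub = ds.values.loc[keep]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
        z.columns = [f"{ds.dataset_id}:{s}" for s in sub.columns]
        blocks.append(z)
        origin_parts.extend([ds.dataset_id] * sub.shape[1])
        if have_labels:
            label_parts.extend(ds.subtype_labels.tolist())
    values = pd.concat(blocks, axis=1)
    labels = pd.Series(label_parts, index=values.columns, name="subtype") if have_labels else None
    agg = ExpressionDataset(dataset_id="aggregated", values=values, subtype_labels=labels)
    agg.dataset_of_origin = pd.Series(origin_parts, index=values.columns, name="dataset")
    return agg


def build_centroids(dataset: ExpressionDataset, genes=None) -> CentroidSet:
    """Per-subtype arithmetic mean profile over ``genes``.

    Every subtype present in the labels must have at least one sample.
    """
    if dataset.subtype_labels is None:
        raise ValueError("dataset has no subtype labels")
    genes = dataset.genes if genes is None else pd.Index(genes)
    missing = genes.difference(dataset.genes)
    if len(missing):
        raise ValueError(f"genes absent from dataset: {list(missing)[:5]}")
    labels = dataset.subtype_labels
    subtypes = tuple(st for st in SUBTYPES if st in set(labels)) or tuple(sorted(set(labels)))
    cols = {}
    for st in subtypes:
        members = labels.index[labels == st]
        if len(members) == 0:
            raise ValueError(f"subtype {st} has no samples")
        cols[st] = dataset.values.loc[genes, members].mean(axis=1)
    return CentroidSet(subtypes=subtypes,
                       centroid_matrix=pd.DataFrame(cols, index=genes),
                       source=dataset.dataset_id)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((a * b).sum() / denom)


def compare_centroids(set_a: CentroidSet, set_b: CentroidSet) -> pd.DataFrame:
    """Pearson correlation of every centroid in A against every one in B."""
    shared = set_a.genes.intersection(set_b.genes)
    if len(shared) < 3:
        raise ValueError("need >=3 shared genes")
    out = pd.DataFrame(index=list(set_a.subtypes), columns=list(set_b.subtypes),
                       dtype=float)
    for si in set_a.subtypes:
        a = set_a.centroid_matrix.loc[shared, si].to_numpy()
        for sj in set_b.subtypes:
            b = set_b.centroid_matrix.loc[shared, sj].to_numpy()
            r = _pearson(a, b)
            if np.isnan(r):
                logger.warning("zero-variance centroid in (%s, %s)", si, sj)
            out.loc[si, sj] = r
    return out


def predict_subtype(sample_profile: pd.Series, centroids: CentroidSet) -> SubtypeCall:
    """Nearest-centroid call by Pearson correlation.

    Ties are broken by the centroid set's fixed subtype order and flagged.
    Pearson correlation makes the call invariant to any positive affine
    transform of the profile.
    """
    profile = pd.Series(sample_profile).astype(float)
    shared = centroids.genes.intersection(profile.index)
    if len(shared) < 3:
        raise ValueError("need >=3 genes shared with the centroids")
    x = profile.loc[shared].to_numpy()
    if np.std(x) == 0:
        raise ValueError("zero-variance sample profile")
    corrs = {
        st: _pearson(x, centroids.centroid_matrix.loc[shared, st].to_numpy())
        for st in centroids.subtypes
    }
    best = max(centroids.subtypes, key=lambda st: (corrs[st], -centroids.subtypes.index(st)))
    ranked = sorted(corrs.values(), reverse=True)
    margin = float(ranked[0] - ranked[1]) if len(ranked) > 1 else float("inf")
    tie = len(ranked) > 1 and ranked[0] == ranked[1]
    name = sample_profile.name if isinstance(sample_profile, pd.Series) else None
    return SubtypeCall(sample_id=str(name), correlations=corrs,
                       predicted=best, margin=margin, tie=tie)


def predict_dataset(dataset: ExpressionDataset, centroids: CentroidSet) -> pd.DataFrame:
    """Call every sample of a dataset; returns a tidy frame of calls."""
    rows = []
    for s in dataset.samples:
        call = predict_subtype(dataset.values[s], centroids)
        rows.append({"sample": s, "predicted": call.predicted,
                     "margin": call.margin, "tie": call.tie,
                     **{f"r_{st}": call.correlations[st] for st in centroids.subtypes}})
    return pd.DataFrame(rows).set_index("sample")


_CONSENSUS_TABLE = {
    ("basal", "basal"): "basal",
    ("non-basal", "non-basal"): "non-basal",
    ("non-basal", "absent"): "non-basal",
    ("absent", "non-basal"): "non-basal",
    ("basal", "non-basal"): "unclassified",
    ("non-basal", "basal"): "unclassified",
    ("basal", "absent"): "unclassified",
    ("absent", "basal"): "unclassified",
}


def consensus_basal_call(call1: str, call2: str, cell_line: str = "") -> ConsensusCall:
    """Consensus basal status from two panel predictions.

    Basal requires basal in both panels; non-basal requires non-basal in
    both, or non-basal in one with the line absent from the other.
    Discordant calls and (basal, absent) are unclassified.
    """
    key = (call1, call2)
    if key == ("absent", "absent"):
        raise ValueError("cell line absent from both datasets")
    if key not in _CONSENSUS_TABLE:
        raise ValueError(f"invalid calls {key}; expected basal/non-basal/absent")
    return ConsensusCall(cell_line=cell_line, call_dataset1=call1,
                         call_dataset2=call2, consensus=_CONSENSUS_TABLE[key])


def roc_auc(values, binary_labels) -> float:
    """Empirical ROC AUC (rank/U-statistic form, ties counted half)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(binary_labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, v))


def select_markers(
    expr: pd.DataFrame,
    labels: pd.Series,
    fc_threshold: float = 1.0,
    auc_threshold: float = 0.8,
) -> list[MarkerScore]:
    """Score genes as basal markers by log2 fold change and ROC AUC.

    ``expr`` is genes x samples (log2); ``labels`` marks samples basal /
    non-basal.  A gene is selected when log2FC >= fc_threshold and
    AUC >= auc_threshold; output is ordered by AUC descending, ties by
    absolute fold change.
    """
    if not 0 <= auc_threshold <= 1:
        raise ValueError("auc_threshold must lie in [0,1]")
    labels = pd.Series(labels).reindex(expr.columns)
    is_basal = (labels == "basal").to_numpy().astype(int)
    if is_basal.sum() == 0 or is_basal.sum() == len(labels):
        raise ValueError("both classes must be present")
    basal_cols = expr.columns[is_basal == 1]
    rest_cols = expr.columns[is_basal == 0]
    out = []
    for gene in expr.index:
        row = expr.loc[gene]
        lfc = float(row[basal_cols].mean() - row[rest_cols].mean())
        auc = roc_auc(row.to_numpy(), is_basal)
        out.append(MarkerScore(
            gene=str(gene), log2_fold_change=lfc, roc_auc=auc,
            selected=bool(lfc >= fc_threshold and auc >= auc_threshold),
        ))
    out.sort(key=lambda m: (-m.roc_auc, -abs(m.log2_fold_change)))
    return out
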