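"""Subtype harmonization: DE genes, centroids, prediction, consensus, markers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from basalscreen.subtyping import (build_centroids, compare_centroids,
                                   consensus_basal_call,
                                   identify_common_de_genes, predict_dataset,
                                   predict_subtype, roc_auc,
                                   scale_and_aggregate, select_markers)
from basalscreen.synthdata import (SimulationConfig, ExpressionDataset,
                                   simulate_expression)
from conftest import brute_force_pearson, brute_force_roc_auc


def small_config(seed, **kw):
    defaults = dict(n_genes=120, n_marker_genes=10, n_samples_per_dataset=60,
                    n_datasets=3, marker_effect=2.0, noise_sd=0.5)
    defaults.update(kw)
    return SimulationConfig(seed=seed, **defaults)


def toy_dataset(values, labels=None, dataset_id="toy"):
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    lab = pd.Series(labels, index=df.columns) if labels is not None else None
    return ExpressionDataset(dataset_id=dataset_id, values=df, subtype_labels=lab)


# ---------------------------------------------------------------- DE genes

def test_common_de_genes_recovers_injected_markers():
    """All injected basal markers found; no background gene leaks in."""
    n_clean = 0
    for seed in range(50):
        cfg = small_config(seed)
        genes = identify_common_de_genes(simulate_expression(cfg), fdr=0.05)
        assert set(cfg.marker_genes) <= set(genes)
        background = [g for g in genes if g.startswith("G")]
        n_clean += not background
    assert n_clean >= 0.95 * 50


def test_common_de_genes_null_intersection_empty():
    """No effect anywhere: the 3-dataset intersection is almost always empty."""
    n_empty = 0
    for seed in range(100):
        cfg = small_config(seed, marker_effect=0.0, noise_sd=1.0)
        genes = identify_common_de_genes(simulate_expression(cfg), fdr=0.05)
        n_empty += not genes
    assert n_empty >= 99


def test_common_de_genes_single_dataset_degenerate():
    cfg = small_config(0, n_datasets=1)
    ds = simulate_expression(cfg)
    genes = identify_common_de_genes(ds, fdr=0.05)
    assert set(cfg.marker_genes) <= set(genes)


def test_common_de_genes_errors():
    cfg = small_config(0, n_datasets=1)
    ds = simulate_expression(cfg)[0]
    flat = ExpressionDataset("one", ds.values,
                             pd.Series("basal", index=ds.values.columns))
    with pytest.raises(ValueError, match="single subtype"):
        identify_common_de_genes([flat])


# ---------------------------------------------------------------- centroids

def test_build_centroids_equals_column_means():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(8, 20))
    labels = ["basal"] * 5 + ["classical"] * 5 + ["mesenchymal"] * 5 + ["atypical"] * 5
    ds = toy_dataset(values, labels)
    cents = build_centroids(ds)
    for st in cents.subtypes:
        members = [s for s, l in zip(ds.samples, labels) if l == st]
        expected = ds.values[members].to_numpy().mean(axis=1)
        assert np.allclose(cents.centroid_matrix[st].to_numpy(), expected)


def test_build_centroids_singletons_equal_samples():
    ds = toy_dataset(np.arange(12).reshape(3, 4),
                     ["basal", "classical", "mesenchymal", "atypical"])
    cents = build_centroids(ds)
    for j, st in enumerate(ds.subtype_labels):
        assert np.allclose(cents.centroid_matrix[st].to_numpy(),
                           ds.values.iloc[:, j].to_numpy())


def test_compare_centroids_matches_brute_force():
    rng = np.random.default_rng(1)
    ds = toy_dataset(rng.normal(size=(10, 8)),
                     ["basal", "basal", "classical", "classical",
                      "mesenchymal", "mesenchymal", "atypical", "atypical"])
    cents = build_centroids(ds)
    mat = compare_centroids(cents, cents)
    assert np.allclose(np.diag(mat.to_numpy(dtype=float)), 1.0, atol=1e-12)
    for si in cents.subtypes:
        for sj in cents.subtypes:
            expect = brute_force_pearson(cents.centroid_matrix[si],
                                         cents.centroid_matrix[sj])
            assert mat.loc[si, sj] == pytest.approx(expect, abs=1e-12)


def test_compare_centroids_anticorrelated():
    cm = pd.DataFrame({"basal": [1.0, 2.0, 3.0, 1.5]}, index=list("abcd"))
    from basalscreen.subtyping import CentroidSet
    a = CentroidSet(("basal",), cm)
    b = CentroidSet(("classical",), (-cm).rename(columns={"basal": "classical"}))
    assert compare_centroids(a, b).iloc[0, 0] == pytest.approx(-1.0)


# ------------------------------------------------------- scale & aggregate

def test_scale_and_aggregate_zero_mean_unit_sd():
    cfg = small_config(3)
    agg = scale_and_aggregate(simulate_expression(cfg))
    for d in agg.dataset_of_origin.unique():
        cols = agg.samples[agg.dataset_of_origin == d]
        block = agg.values[cols]
        assert np.allclose(block.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(block.std(axis=1, ddof=0), 1.0, atol=1e-12)


def test_scale_and_aggregate_batch_scale_invariance():
    cfg = small_config(4, n_datasets=1)
    ds = simulate_expression(cfg)[0]
    scaled = ExpressionDataset("scaled", ds.values * 10.0, ds.subtype_labels)
    a = scale_and_aggregate([ds]).values.to_numpy()
    b = scale_and_aggregate([scaled]).values.to_numpy()
    assert np.allclose(a, b, atol=1e-9)


def test_scale_and_aggregate_restricts_to_shared_genes():
    rng = np.random.default_rng(5)
    d1 = toy_dataset(rng.normal(size=(6, 4)))
    d2v = pd.DataFrame(rng.normal(size=(6, 4)),
                       index=["g2", "g3", "g4", "g5", "x1", "x2"],
                       columns=["t0", "t1", "t2", "t3"])
    d2 = ExpressionDataset("d2", d2v)
    agg = scale_and_aggregate([d1, d2])
    assert set(agg.genes) == {"g2", "g3", "g4", "g5"}
    assert agg.values.shape == (4, 8)


# ---------------------------------------------------------------- predict

def test_predict_subtype_recovers_centroid_member():
    rng = np.random.default_rng(6)
    ds = toy_dataset(rng.normal(size=(12, 8)),
                     ["basal", "basal", "classical", "classical",
                      "mesenchymal", "mesenchymal", "atypical", "atypical"])
    cents = build_centroids(ds)
    call = predict_subtype(cents.centroid_matrix["classical"], cents)
    assert call.predicted == "classical"
    assert call.correlations["classical"] == pytest.approx(1.0)
    assert call.margin >= 0


def test_predict_subtype_affine_invariance():
    rng = np.random.default_rng(7)
    ds = toy_dataset(rng.normal(size=(10, 8)),
                     ["basal", "basal", "classical", "classical",
                      "mesenchymal", "mesenchymal", "atypical", "atypical"])
    cents = build_centroids(ds)
    profile = pd.Series(rng.normal(size=10), index=ds.genes)
    base = predict_subtype(profile, cents)
    shifted = predict_subtype(3.5 * profile + 11.0, cents)
    assert shifted.predicted == base.predicted
    for st in cents.subtypes:
        assert shifted.correlations[st] == pytest.approx(base.correlations[st])


def test_predict_subtype_correlations_brute_force():
    rng = np.random.default_rng(8)
    ds = toy_dataset(rng.normal(size=(5, 4)),
                     ["basal", "classical", "mesenchymal", "atypical"])
    cents = build_centroids(ds)
    profile = pd.Series(rng.normal(size=5), index=ds.genes)
    call = predict_subtype(profile, cents)
    for st in cents.subtypes:
        assert call.correlations[st] == pytest.approx(
            brute_force_pearson(profile, cents.centroid_matrix[st]), abs=1e-12)


def test_predict_subtype_zero_variance_profile_errors():
    ds = toy_dataset(np.arange(12).reshape(3, 4),
                     ["basal", "classical", "mesenchymal", "atypical"])
    cents = build_centroids(ds)
    with pytest.raises(ValueError, match="zero-variance"):
        predict_subtype(pd.Series(1.0, index=ds.genes), cents)


def test_classifier_accuracy_on_aggregated_data():
    """Basal-vs-rest nearest-centroid accuracy >=95% at effect 2, noise 0.5."""
    accs = []
    for seed in range(20):
        cfg = SimulationConfig(seed=seed, marker_effect=2.0, noise_sd=0.5)
        datasets = simulate_expression(cfg)
        genes = identify_common_de_genes(datasets, fdr=0.05)
        agg = scale_and_aggregate(datasets)
        cents = build_centroids(agg, genes)
        pred = predict_dataset(agg, cents)
        p = pred["predicted"].to_numpy()
        t = agg.subtype_labels.to_numpy()
        accs.append(np.mean((p == "basal") == (t == "basal")))
    assert np.mean(accs) >= 0.95


def test_classifier_accuracy_monotone_in_effect():
    """Basal detection accuracy never degrades as the marker effect grows."""
    mean_acc = []
    for effect in (0.5, 1.0, 2.0):
        accs = []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, marker_effect=effect, noise_sd=0.5)
            datasets = simulate_expression(cfg)
            agg = scale_and_aggregate(datasets)
            cents = build_centroids(agg)  # full gene set: selection-free probe
            pred = predict_dataset(agg, cents)
            p = pred["predicted"].to_numpy()
            t = agg.subtype_labels.to_numpy()
            accs.append(np.mean((p == "basal") == (t == "basal")))
        mean_acc.append(np.mean(accs))
    assert mean_acc[0] <= mean_acc[1] + 1e-9
    assert mean_acc[1] <= mean_acc[2] + 1e-9


# --------------------------------------------------------------- consensus

@pytest.mark.parametrize("c1,c2,expected", [
    ("basal", "basal", "basal"),
    ("non-basal", "non-basal", "non-basal"),
    ("non-basal", "absent", "non-basal"),
    ("absent", "non-basal", "non-basal"),
    ("basal", "non-basal", "unclassified"),
    ("non-basal", "basal", "unclassified"),
    ("basal", "absent", "unclassified"),
    ("absent", "basal", "unclassified"),
])
def test_consensus_truth_table(c1, c2, expected):
    assert consensus_basal_call(c1, c2).consensus == expected


def test_consensus_invalid_inputs():
    with pytest.raises(ValueError, match="absent from both"):
        consensus_basal_call("absent", "absent")
    with pytest.raises(ValueError, match="invalid"):
        consensus_basal_call("basal", "maybe")


# ----------------------------------------------------------------- ROC AUC

def test_roc_auc_reference_values():
    assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(1.0)
    assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert roc_auc([5, 5, 5, 5], [0, 0, 1, 1]) == pytest.approx(0.5)


def test_roc_auc_matches_pair_counting():
    rng = np.random.default_rng(9)
    for _ in range(20):
        v = rng.integers(0, 6, size=12).astype(float)  # ties likely
        y = rng.integers(0, 2, size=12)
        if y.sum() in (0, 12):
            continue
        assert roc_auc(v, y) == pytest.approx(brute_force_roc_auc(v, y))


def test_roc_auc_complement_under_negation():
    rng = np.random.default_rng(10)
    v = rng.normal(size=30)  # continuous, tie-free
    y = np.r_[np.ones(12, int), np.zeros(18, int)]
    assert roc_auc(v, y) + roc_auc(-v, y) == pytest.approx(1.0)


def test_roc_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], [1, 1])


# ----------------------------------------------------------------- markers

def test_select_markers_injected_marker_scores_high():
    cfg = small_config(11, noise_sd=0.3)
    agg = scale_and_aggregate(simulate_expression(cfg))
    labels = agg.subtype_labels.map(lambda s: "basal" if s == "basal" else "non-basal")
    markers = {m.gene: m for m in select_markers(agg.values, labels,
                                                 fc_threshold=0.5,
                                                 auc_threshold=0.8)}
    assert markers["EREG"].selected and markers["EREG"].roc_auc > 0.9
    assert markers["AREG"].selected and markers["AREG"].roc_auc > 0.9


def test_select_markers_null_gene_not_selected():
    rng = np.random.default_rng(12)
    n = 200
    expr = pd.DataFrame(rng.normal(size=(1, n)), index=["null_gene"],
                        columns=[f"s{i}" for i in range(n)])
    labels = pd.Series(["basal"] * 60 + ["non-basal"] * 140, index=expr.columns)
    (score,) = select_markers(expr, labels, fc_threshold=0.5, auc_threshold=0.8)
    se = np.sqrt((60 + 140 + 1) / (12 * 60 * 140))  # null AUC standard error
    assert abs(score.roc_auc - 0.5) < 3 * se
    assert not score.selected


def test_select_markers_infinite_threshold_selects_nothing():
    rng = np.random.default_rng(13)
    expr = pd.DataFrame(rng.normal(size=(5, 20)),
                        columns=[f"s{i}" for i in range(20)])
    expr.index = [f"g{i}" for i in range(5)]
    labels = pd.Series(["basal"] * 10 + ["non-basal"] * 10, index=expr.columns)
    markers = select_markers(expr, labels, fc_threshold=np.inf, auc_threshold=0.5)
    assert not any(m.selected for m in markers)
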