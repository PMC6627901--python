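"""Association statistics for subtype / mutation / drug-response comparisons.

The module wraps the classical tests (two-sample t, one-way ANOVA,
Yates-corrected chi-squared, Fisher exact, hypergeometric enrichment) around
a single tidy result container, and implements an empirical-Bayes moderated
t-test in the limma tradition: feature-wise sample variances are shrunk
toward a common prior estimated by moment matching on the log variances,
which stabilises inference when each feature has few replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "two_sample_t",
    "moderated_t",
    "one_way_anova",
    "chi2_yates",
    "fisher_exact",
    "hypergeometric_enrichment",
    "mutation_association",
    "benjamini_hochberg",
    "estimate_variance_prior",
]


@dataclass
class AssociationResult:
    """Outcome of one association test.

    ``effect_direction`` is the sign of (group A mean - group B mean) where
    the notion applies, else 0.  ``flagged`` records whether ``p_value``
    fell below the threshold the caller configured.
    """

    test: str
    statistic: float
    p_value: float
    effect_direction: int = 0
    n_per_group: tuple = ()
    flagged: bool = False
    feature: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _direction(mean_a: float, mean_b: float) -> int:
    return int(np.sign(mean_a - mean_b))


def two_sample_t(x, y, variant: str = "welch", p_threshold: float = 0.05) -> AssociationResult:
    """Two-sided two-sample t-test.

    ``variant='welch'`` (default) does not assume equal variances; use
    ``'pooled'`` for the classical equal-variance statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >=2 non-missing values")
    if variant not in {"welch", "pooled"}:
        raise ValueError(f"unknown variant {variant!r}")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):  # both groups constant and identical
        stat, p = 0.0, 1.0
    return AssociationResult(
        test="t",
        statistic=stat,
        p_value=p,
        effect_direction=_direction(x.mean(), y.mean()),
        n_per_group=(x.size, y.size),
        flagged=p < p_threshold,
    )


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match an inverse-chi-square prior (d0, s0^2) to sample variances.

    Follows the standard empirical-Bayes construction: with z = log(s^2),
    E[z] = log(s0^2) + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2) and
    Var[z] = psi'(df/2) + psi'(d0/2), so d0 comes from inverting the
    trigamma function on the excess variance of z.  Returns
    (inf, exp-mean-adjusted s0^2) when the observed variances are less
    dispersed than chi-square sampling alone would produce.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return math.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return math.inf, float(math.exp(np.mean(e)))
    # Newton inversion of trigamma(d0/2) = excess
    y = 0.5 + 1.0 / excess  # starting value, good for both tails
    for _ in range(50):
        tri = special.polygamma(1, y)
        delta = tri * (1.0 - tri / excess) / special.polygamma(2, y)
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    d0 = 2.0 * float(y)
    s02 = float(math.exp(np.mean(e) + special.digamma(y) - math.log(y)))
    return d0, s02


def moderated_t(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    p_threshold: float = 0.05,
    min_features: int = 10,
    prior_df: float | None = None,
) -> list[AssociationResult]:
    """Feature-wise moderated t-test between two sample groups.

    Rows are features, columns samples.  Feature variances are shrunk as
    s~^2 = (d0*s0^2 + d*s^2)/(d0 + d) with (d0, s0^2) estimated from the
    ensemble of features; the t statistic is referred to a t distribution
    with d0 + d degrees of freedom.  With fewer than ``min_features``
    features the prior cannot be estimated reliably and the ordinary
    two-sample t (d0 = 0) is used instead (logged).  ``prior_df`` forces a
    specific d0 (0 recovers the ordinary t exactly; ``inf`` fully pools).
    """
    a = pd.DataFrame(group_a)
    b = pd.DataFrame(group_b)
    if not a.index.equals(b.index):
        raise ValueError("feature indices of the two groups differ")
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >=2 samples")
    df_resid = na + nb - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    mean_a = a.mean(axis=1).to_numpy()
    mean_b = b.mean(axis=1).to_numpy()
    var_a = a.var(axis=1, ddof=1).to_numpy()
    var_b = b.var(axis=1, ddof=1).to_numpy()
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df_resid

    if prior_df is not None:
        d0 = float(prior_df)
        _, s02 = estimate_variance_prior(s2, df_resid)
        if d0 == 0:
            s02 = 0.0
    elif len(a) < min_features:
        logger.info(
            "moderated_t: only %d features (<%d); falling back to ordinary t",
            len(a), min_features,
        )
        d0, s02 = 0.0, 0.0
    else:
        d0, s02 = estimate_variance_prior(s2, df_resid)

    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)

    out = []
    for i, feat in enumerate(a.index):
        out.append(
            AssociationResult(
                test="moderated_t",
                statistic=float(t[i]),
                p_value=float(min(p[i], 1.0)),
                effect_direction=_direction(mean_a[i], mean_b[i]),
                n_per_group=(na, nb),
                flagged=bool(p[i] < p_threshold),
                feature=str(feat),
                extra={"prior_df": d0, "prior_var": s02, "log2_fc": float(mean_a[i] - mean_b[i])},
            )
        )
    return out


def one_way_anova(groups, p_threshold: float = 0.05) -> AssociationResult:
    """One-way fixed-effects ANOVA across >=2 groups of >=2 values each."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise ValueError("need >=2 groups with >=2 values each")
    res = sps.f_oneway(*arrays)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):
        stat, p = 0.0, 1.0
    return AssociationResult(
        test="anova",
        statistic=stat,
        p_value=p,
        n_per_group=tuple(g.size for g in arrays),
        flagged=p < p_threshold,
    )


def chi2_yates(table, p_threshold: float = 0.05) -> AssociationResult:
    """Chi-squared test on a 2x2 table with the Yates continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=True)
    return AssociationResult(
        test="chi2_yates",
        statistic=float(stat),
        p_value=float(p),
        n_per_group=tuple(int(v) for v in t.sum(axis=1)),
        flagged=p < p_threshold,
    )


def fisher_exact(table, p_threshold: float = 0.05) -> AssociationResult:
    """Fisher's exact test (two-sided) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2x2 table of nonnegative integers")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return AssociationResult(
        test="fisher",
        statistic=float(odds),
        p_value=float(p),
        n_per_group=tuple(int(v) for v in t.sum(axis=1)),
        flagged=p < p_threshold,
    )


def hypergeometric_enrichment(
    hits_in_set: int, set_size: int, hits_total: int, universe: int,
    p_threshold: float = 0.05,
) -> AssociationResult:
    """Upper-tail hypergeometric enrichment p-value, P(X >= hits_in_set)."""
    if hits_in_set > min(set_size, hits_total) or max(set_size, hits_total) > universe:
        raise ValueError("inconsistent counts")
    if min(hits_in_set, set_size, hits_total, universe) < 0:
        raise ValueError("counts must be nonnegative")
    p = float(sps.hypergeom.sf(hits_in_set - 1, universe, hits_total, set_size))
    return AssociationResult(
        test="hypergeom",
        statistic=float(hits_in_set),
        p_value=min(p, 1.0),
        n_per_group=(set_size, universe),
        flagged=p < p_threshold,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def mutation_association(
    auc_table: pd.DataFrame,
    mutation_table: pd.DataFrame,
    p_threshold: float = 0.1,
) -> list[AssociationResult]:
    """Associate mutation status with drug response AUC per (gene, drug).

    ``auc_table`` is cell line x drug; ``mutation_table`` cell line x gene,
    binary.  For each gene with >=2 mutated and >=2 wild-type lines, a
    moderated t compares mutated vs wild-type AUC per drug, with variance
    moderation pooled across the drug panel.  A negative direction means the
    mutated lines have lower AUC, i.e. the mutation sensitises.  Genes with
    too few lines in either class are skipped and logged.
    """
    if auc_table.empty or mutation_table.empty:
        raise ValueError("empty input table")
    lines = auc_table.index.intersection(mutation_table.index)
    auc = auc_table.loc[lines]
    mut = mutation_table.loc[lines]
    results: list[AssociationResult] = []
    for gene in mut.columns:
        status = mut[gene].astype(int)
        mutated = lines[status == 1]
        wild = lines[status == 0]
        if len(mutated) < 2 or len(wild) < 2:
            logger.info("mutation_association: %s skipped (%d mutated / %d WT)",
                        gene, len(mutated), len(wild))
            continue
        # features = drugs; moderation borrows strength across the panel
        per_drug = moderated_t(
            auc.loc[mutated].T, auc.loc[wild].T,
            p_threshold=p_threshold, min_features=2,
        )
        for r in per_drug:
            r.extra["gene"] = gene
            r.extra["drug"] = r.feature
            r.feature = f"{gene}:{r.extra['drug']}"
        results.extend(per_drug)
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of association results."""
    rows = []
    for r in results:
        rows.append({
            "feature": r.feature,
            "test": r.test,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "direction": r.effect_direction,
            "flagged": r.flagged,
            **{k: v for k, v in r.extra.items() if np.isscalar(v) or isinstance(v, str)},
        })
    return pd.DataFrame(rows)
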