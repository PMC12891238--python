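"""Cohort-level statistics on immune-subset proportions and repertoire summaries.

Covers the stratification layer of the pipeline: paired tissue contrasts of
subset proportions, unsupervised k-means patient grouping on tumor profiles,
one-vs-rest enrichment regression per subset and group, B-subset ANOVA after
renormalizing to the CD19+ compartment, chi-squared clinical associations,
and feature-vs-subset Pearson correlations.

All proportions are analyzed untransformed, matching the paired/unpaired
t-test conventions used for such matrices; log2 fold changes are descriptive
only (computed on group means with a pseudo-proportion epsilon).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .airr_io import ProportionMatrix

logger = logging.getLogger(__name__)

__all__ = ["tissue_contrasts", "kmeans_groups", "group_enrichment",
           "bcell_subset_anova", "clinical_association", "correlate_with_subsets",
           "silhouette_scan"]


def _values(m: ProportionMatrix | pd.DataFrame) -> pd.DataFrame:
    return m.values if isinstance(m, ProportionMatrix) else m


def tissue_contrasts(matrix_a: ProportionMatrix | pd.DataFrame,
                     matrix_b: ProportionMatrix | pd.DataFrame,
                     epsilon: float = 0.01, alpha: float = 0.05) -> pd.DataFrame:
    """Per-subset paired t-tests between two tissues with Bonferroni correction.

    log2FC = log2((mean_A + eps) / (mean_B + eps)) describes the direction
    (positive = enriched in A); the test itself is a paired t on raw
    proportions over the shared patients.
    """
    a, b = _values(matrix_a), _values(matrix_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared patients")
    subsets = [s for s in a.columns if s in b.columns]
    m = len(subsets)
    rows = []
    for s in subsets:
        x, y = a.loc[shared, s].to_numpy(), b.loc[shared, s].to_numpy()
        if np.allclose(x, y):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(x, y)
        log2fc = float(np.log2((x.mean() + epsilon) / (y.mean() + epsilon)))
        q = min(1.0, float(p) * m)
        rows.append({"subset": s, "log2fc": log2fc, "t": float(t_stat),
                     "p": float(p), "q": q,
                     "direction": "A" if log2fc > 0 else ("B" if log2fc < 0 else "none"),
                     "significant": q < alpha, "n_patients": len(shared)})
    return pd.DataFrame(rows)


def kmeans_groups(matrix: ProportionMatrix | pd.DataFrame, k: int = 4,
                  n_init: int = 10, seed: int = 0) -> pd.Series:
    """K-means patient grouping on a patients x subsets matrix.

    Returns patient -> group id (1-based), with group ids relabeled by size
    descending (ties by smallest member id) so output labels are stable.
    """
    values = _values(matrix)
    n = len(values)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(values.to_numpy(dtype=float))
    sizes = pd.Series(raw).value_counts()
    first_member = {lab: values.index[raw == lab][0] for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_member[lab]))
    relabel = {lab: i + 1 for i, lab in enumerate(order)}
    return pd.Series([relabel[lab] for lab in raw], index=values.index, name="group")


def silhouette_scan(matrix: ProportionMatrix | pd.DataFrame,
                    k_range: tuple[int, int] = (2, 8), n_init: int = 10,
                    seed: int = 0) -> pd.DataFrame:
    """Mean silhouette score for each candidate k (utility for choosing k)."""
    from sklearn.metrics import silhouette_score

    values = _values(matrix).to_numpy(dtype=float)
    rows = []
    for k in range(k_range[0], min(k_range[1], len(values) - 1) + 1):
        labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit_predict(values)
        rows.append({"k": k, "silhouette": float(silhouette_score(values, labels))})
    return pd.DataFrame(rows)


def group_enrichment(matrix: ProportionMatrix | pd.DataFrame,
                     groups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest enrichment per subset x group.

    Under intercept + group-indicator coding the regression coefficient is
    exactly the group mean minus the rest mean (percentage points); the
    reported t and p come from the equivalent two-sample equal-variance
    t-test.  Bonferroni corrects over all subset x group tests; singleton
    groups are excluded with a warning.
    """
    values = _values(matrix)
    groups = groups.reindex(values.index)
    labels = [g for g in sorted(groups.unique()) if (groups == g).sum() >= 2]
    dropped = set(groups.unique()) - set(labels)
    if dropped:
        logger.warning("excluding singleton group(s): %s", sorted(dropped))
    m = len(values.columns) * len(labels)
    rows = []
    for g in labels:
        in_g = (groups == g).to_numpy()
        for s in values.columns:
            x = values[s].to_numpy(dtype=float)
            beta = float(x[in_g].mean() - x[~in_g].mean())
            if np.ptp(x) == 0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(x[in_g], x[~in_g], equal_var=True)
            q = min(1.0, float(p) * m)
            rows.append({"subset": s, "group": g, "beta": beta,
                         "t": float(t_stat), "p": float(p), "q": q,
                         "direction": "enriched" if beta > 0 else ("depleted" if beta < 0 else "none"),
                         "significant": q < alpha})
    return pd.DataFrame(rows)


def bcell_subset_anova(matrix: ProportionMatrix | pd.DataFrame,
                       b_subsets: list[str], groups: pd.Series,
                       alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA per B subset after renormalizing to the CD19+ total.

    Each patient's B-subset values are divided by their summed B-subset
    (CD19+) proportion, so renormalized rows sum to 1; patients with a zero
    CD19+ total are excluded with a log message.  Subsets significant by
    ANOVA get pairwise unpaired t-tests between groups.  Returns
    ``(anova_table, pairwise_table)``.
    """
    values = _values(matrix)[list(b_subsets)]
    totals = values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("excluding patient(s) with zero CD19+ total: %s",
                       list(values.index[zero]))
    values = values.loc[~zero].div(totals[~zero], axis=0)
    groups = groups.reindex(values.index)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    anova_rows, pair_rows = [], []
    for s in b_subsets:
        samples = [values.loc[groups == g, s].to_numpy() for g in labels]
        if np.ptp(np.concatenate(samples)) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*samples)
        anova_rows.append({"subset": s, "F": float(f_stat), "p": float(p),
                           "significant": p < alpha})
        if p < alpha:
            for i, gi in enumerate(labels):
                for gj in labels[i + 1:]:
                    t_stat, tp = stats.ttest_ind(
                        values.loc[groups == gi, s], values.loc[groups == gj, s],
                        equal_var=True)
                    pair_rows.append({"subset": s, "group_a": gi, "group_b": gj,
                                      "t": float(t_stat), "p": float(tp)})
    return pd.DataFrame(anova_rows), pd.DataFrame(pair_rows)


def clinical_association(groups: pd.Series, clinical: pd.Series) -> dict:
    """Pearson chi-squared association between group and a clinical category."""
    aligned = pd.concat([groups, clinical], axis=1, join="inner")
    aligned.columns = ["group", "clinical"]
    if aligned["group"].nunique() < 2 or aligned["clinical"].nunique() < 2:
        raise ValueError("both variables need >= 2 levels")
    table = pd.crosstab(aligned["group"], aligned["clinical"])
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p": float(p), "df": int(df), "table": table}


def correlate_with_subsets(feature: pd.Series,
                           matrix: ProportionMatrix | pd.DataFrame,
                           method: str = "pearson") -> pd.DataFrame:
    """Correlate a per-patient feature with every subset's proportions.

    Returns one row per subset (R, two-sided p, n), sorted by |R| descending;
    zero-variance subsets get a NaN R with ``undefined`` set.
    """
    values = _values(matrix)
    shared = feature.dropna().index.intersection(values.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 patients with both values")
    f = feature.loc[shared].to_numpy(dtype=float)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for s in values.columns:
        x = values.loc[shared, s].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(f) == 0:
            rows.append({"subset": s, "R": np.nan, "p": np.nan,
                         "n": len(shared), "undefined": True})
            continue
        r, p = corr(f, x)
        rows.append({"subset": s, "R": float(r), "p": float(p),
                     "n": len(shared), "undefined": False})
    out = pd.DataFrame(rows)
    return out.reindex(out["R"].abs().sort_values(ascending=False, na_position="last").index
                       ).reset_index(drop=True)
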