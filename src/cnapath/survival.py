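"""Outcome association: two-group stratification, Kaplan-Meier, log-rank.

Given a per-sample pathway score matrix (e.g. expression-derived pathway
activity and consistency metrics) and clinical follow-up, each pathway's
cohort is split into two groups and the groups' survival experience is
compared. Kaplan-Meier estimation and the log-rank test are delegated to
lifelines; stratification offers k-means (default), median split, and a
hierarchical-clustering cut.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .intervals import ValidationError
from .targeting import PathwayTargetingResult  # noqa: F401  (shared report style)

logger = logging.getLogger(__name__)

STRATIFY_METHODS = ("two_means", "median_split", "hierarchical_cut")


def _as_feature_matrix(scores) -> np.ndarray:
    """Coerce scores to an (n_samples, n_features) float array."""
    a = np.asarray(scores, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    elif a.ndim == 2:
        a = a.T  # accept (n_features, n_samples) layout
    else:
        raise ValidationError("scores must be a vector or a features x samples matrix")
    if not np.all(np.isfinite(a)):
        raise ValidationError("scores must be finite")
    return a


def stratify_two_groups(
    scores, method: str = "two_means", seed: int = 0
) -> np.ndarray:
    """Label each sample 0 or 1 from its pathway score(s).

    Group 1 is always the higher-scoring group (larger mean standardized
    score), so labels are comparable across methods. ``two_means`` runs
    2-cluster k-means with 10 restarts on standardized scores;
    ``median_split`` thresholds the mean standardized score at its
    median; ``hierarchical_cut`` cuts a Ward dendrogram into two.
    """
    if method not in STRATIFY_METHODS:
        raise ValidationError(f"unknown stratification method {method!r}")
    X = _as_feature_matrix(scores)
    n = X.shape[0]
    if n < 4:
        raise ValidationError(f"need at least 4 samples to stratify, got {n}")
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValidationError("scores are constant; no stratification possible")
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    if method == "two_means":
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        labels = km.fit_predict(Z)
    elif method == "median_split":
        summary = Z.mean(axis=1)
        labels = (summary >= np.median(summary)).astype(int)
    else:
        tree = linkage(Z, method="ward")
        labels = fcluster(tree, t=2, criterion="maxclust") - 1
    labels = np.asarray(labels, dtype=int)
    # orient: group 1 = higher mean score
    if Z[labels == 1].mean() < Z[labels == 0].mean():
        labels = 1 - labels
    return labels


def km_curve(
    times: Sequence[float], events: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate for one group.

    Returns ``(times, S(t))`` step pairs starting at ``S(0) = 1``; the
    estimate is non-increasing and drops only at event times. Censored
    subjects at a tied time remain at risk for events at that time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("empty group: no survival curve")
    if np.any(t < 0):
        raise ValidationError("follow-up times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence[int]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=int)
    if set(np.unique(g)) - {0, 1}:
        raise ValidationError("groups must be labelled 0/1")
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise ValidationError("both groups must be non-empty")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def survival_screen(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    pathways: Sequence[str] | None = None,
    method: str = "two_means",
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen pathways for survival separation of their two score groups.

    ``scores`` is pathways x samples; ``clinical`` has columns
    ``sample_id``, ``time``, ``event``. Samples missing from either side
    are dropped with a warning. The report carries raw log-rank p-values
    with a flag at ``p < alpha`` and Bonferroni-adjusted significance —
    the two-stage reporting used when a marginal screen is followed by
    family-wise control.
    """
    required = {"sample_id", "time", "event"}
    if not required <= set(clinical.columns):
        raise ValidationError(f"clinical table needs columns {sorted(required)}")
    clin = clinical.set_index("sample_id")
    common = [s for s in scores.columns if s in clin.index]
    dropped = (len(scores.columns) - len(common)) + (len(clin) - len(common))
    if dropped:
        logger.warning("%d sample(s) unmatched between scores and clinical; dropped", dropped)
    if pathways is None:
        pathways = list(scores.index)
    rows = []
    for pw in pathways:
        if pw not in scores.index:
            logger.warning("pathway %s absent from score matrix; skipped", pw)
            continue
        vec = scores.loc[pw, common].to_numpy(dtype=float)
        try:
            labels = stratify_two_groups(vec, method=method, seed=seed)
        except ValidationError as exc:
            logger.warning("pathway %s not stratifiable (%s); skipped", pw, exc)
            continue
        t = clin.loc[common, "time"].to_numpy(dtype=float)
        e = clin.loc[common, "event"].to_numpy(dtype=int)
        stat, p = logrank_test(t, e, labels)
        rows.append((pw, int((labels == 0).sum()), int((labels == 1).sum()), stat, p))
    report = pd.DataFrame(
        rows, columns=["pathway_id", "n_group0", "n_group1", "logrank_stat", "p"]
    )
    if len(report):
        m = len(report)
        report["p_adjusted"] = np.minimum(1.0, m * report["p"])
        report["significant_raw"] = report["p"] < alpha
        report["significant_bonferroni"] = report["p"] < alpha / m
        report = report.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        for col in ("p_adjusted", "significant_raw", "significant_bonferroni"):
            report[col] = pd.Series(dtype=float if col == "p_adjusted" else bool)
    return report
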