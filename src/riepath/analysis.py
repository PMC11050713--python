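"""Downstream statistics over an activation matrix.

Dysregulation calls threshold each tumor's pathway score against the
normal cohort's score distribution (mean + k*sd). The reproducibility
score asks how well pairwise sample similarity in pathway-score space
preserves similarity in gene space. The prognostic screen log-rank-tests
survival of dysregulated vs near-normal patients per pathway, and the
clustering benchmark measures how well top differential pathways separate
tumor from normal samples (adjusted Rand index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .scoring import (
    NORMAL,
    TUMOR,
    ActivationMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    score_all,
)

__all__ = [
    "DysregulationCalls",
    "SurvivalTable",
    "classify_dysregulation",
    "dysregulation_summaries",
    "reproducibility_score",
    "jaccard_similarity",
    "logrank_screen",
    "ari_benchmark",
]

logger = logging.getLogger("riepath")

SD_FLOOR = 1e-12  # avoids zero-width thresholds when normal scores tie exactly


class AnalysisError(ValueError):
    pass


@dataclass
class DysregulationCalls:
    """Binary pathways x tumor-samples call matrix with its thresholds.

    ``thresholds`` stores per pathway the normal-score mean, sd (ddof=1,
    floored at 1e-12) and multiplier k; reapplying them to the scores
    reproduces ``calls`` exactly.
    """

    calls: pd.DataFrame       # pathways x tumor samples, values in {0, 1}
    thresholds: pd.DataFrame  # columns: mean, sd, k

    def __post_init__(self) -> None:
        vals = set(np.unique(self.calls.to_numpy()))
        if not vals <= {0, 1}:
            raise AnalysisError(f"calls must be binary, found values {sorted(vals)[:5]}")


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days) and event indicator (1 = observed)."""

    data: pd.DataFrame  # index: sample ids; columns: time, event

    def __post_init__(self) -> None:
        d = self.data
        if not {"time", "event"} <= set(d.columns):
            raise AnalysisError("survival table needs 'time' and 'event' columns")
        if (d["time"] < 0).any():
            raise AnalysisError("survival times must be nonnegative")
        if not set(d["event"].unique()) <= {0, 1}:
            raise AnalysisError("event indicator must be 0 or 1")
        if d.index.duplicated().any():
            raise AnalysisError("duplicate sample ids in survival table")


def classify_dysregulation(
    activation: ActivationMatrix,
    labels: pd.Series,
    k: float = 2.0,
) -> DysregulationCalls:
    """Call each tumor sample dysregulated / near-normal per pathway.

    Tumor *i* is dysregulated on pathway *P* iff
    ``score[P, i] > mean(normal scores of P) + k * sd(normal scores of P)``
    (strict inequality; sd uses ddof=1 and is floored at 1e-12). Pathways
    with fewer than two normal scores are excluded with a warning.
    """
    labels = labels.loc[activation.sample_ids]
    normal_ids = list(labels.index[labels == NORMAL])
    tumor_ids = list(labels.index[labels == TUMOR])
    if not tumor_ids:
        raise AnalysisError("no tumor samples to classify")
    rows, thr = {}, {}
    for pathway in activation.pathway_names:
        normal_scores = activation.scores.loc[pathway, normal_ids].to_numpy()
        if normal_scores.size < 2:
            logger.warning("pathway %s excluded: fewer than 2 normal scores", pathway)
            continue
        mean = float(np.mean(normal_scores))
        sd = max(float(np.std(normal_scores, ddof=1)), SD_FLOOR)
        cutoff = mean + k * sd
        rows[pathway] = (activation.scores.loc[pathway, tumor_ids] > cutoff).astype(int)
        thr[pathway] = {"mean": mean, "sd": sd, "k": float(k)}
    if not rows:
        raise AnalysisError("no pathway had enough normal scores")
    calls = pd.DataFrame(rows).T[tumor_ids]
    calls.index.name = "pathway"
    thresholds = pd.DataFrame(thr).T[["mean", "sd", "k"]]
    thresholds.index.name = "pathway"
    return DysregulationCalls(calls=calls, thresholds=thresholds)


def dysregulation_summaries(calls: DysregulationCalls) -> dict:
    """Cohort-level summaries of a call matrix.

    Returns per-sample fraction of dysregulated pathways, per-pathway
    fraction of dysregulated samples, and the count of pathways
    dysregulated in every patient.
    """
    c = calls.calls
    return {
        "per_sample_fraction": c.mean(axis=0),
        "per_pathway_fraction": c.mean(axis=1),
        "n_pathways_dysregulated_in_all": int((c.sum(axis=1) == c.shape[1]).sum()),
    }


def _cosine_gram(values: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(values, axis=0)
    if (norms == 0).any():
        raise AnalysisError("zero-norm sample column: cosine similarity undefined")
    unit = values / norms
    return unit.T @ unit


def reproducibility_score(X: pd.DataFrame, A: pd.DataFrame) -> float:
    """How well pathway-score space preserves gene-space sample similarity.

    ``RS = N^2 / sum_{a,b} (Sim(X_a, X_b) - Sim(A_a, A_b))^2`` over all
    ordered sample pairs (the diagonal contributes zero), with Sim the
    cosine similarity of sample columns. A vanishing denominator (pathway
    space reproduces gene-space similarity exactly) returns ``inf``.
    """
    if list(X.columns) != list(A.columns):
        raise AnalysisError("X and A must share the same ordered sample columns")
    if X.shape[1] < 2:
        raise AnalysisError("need at least 2 samples")
    n = X.shape[1]
    diff = _cosine_gram(X.to_numpy(float)) - _cosine_gram(A.to_numpy(float))
    denom = float(np.sum(diff**2))
    if denom == 0.0:
        logger.warning("reproducibility denominator is zero; returning inf")
        return float("inf")
    return n**2 / denom


def jaccard_similarity(u, v) -> float:
    """|u ∩ v| / |u ∪ v|; two empty sets give 0 by convention."""
    u, v = set(u), set(v)
    union = u | v
    if not union:
        return 0.0
    return len(u & v) / len(union)


def jaccard_matrix(sets_by_group: dict[str, set], zero_diagonal: bool = True) -> pd.DataFrame:
    """Pairwise Jaccard similarities of biomarker sets across groups.

    ``zero_diagonal`` zeroes self-comparisons, the display convention of
    pan-cancer overlap heatmaps (the set formula itself gives 1 there).
    """
    names = list(sets_by_group)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b in names:
            out.loc[a, b] = jaccard_similarity(sets_by_group[a], sets_by_group[b])
    if zero_diagonal:
        np.fill_diagonal(out.values, 0.0)
    return out


def logrank_screen(
    calls: DysregulationCalls,
    survival: SurvivalTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pathway log-rank test of dysregulated vs near-normal survival.

    Flags a pathway as a candidate prognostic biomarker when the raw
    log-rank p-value is below *alpha* (BH-adjusted values are reported
    alongside). Pathways whose dysregulated or near-normal group is empty
    are excluded with a reason rather than crashing.
    """
    samples = [s for s in calls.calls.columns if s in survival.data.index]
    if len(samples) < 2:
        raise AnalysisError("fewer than 2 tumor samples have survival records")
    surv = survival.data.loc[samples]
    records, excluded = [], {}
    for pathway in calls.calls.index:
        grp = calls.calls.loc[pathway, samples].to_numpy()
        n_dys, n_near = int(grp.sum()), int((1 - grp).sum())
        if n_dys == 0 or n_near == 0:
            excluded[pathway] = f"empty group (dysregulated={n_dys}, near-normal={n_near})"
            continue
        res = logrank_test(
            surv.loc[grp == 1, "time"],
            surv.loc[grp == 0, "time"],
            event_observed_A=surv.loc[grp == 1, "event"],
            event_observed_B=surv.loc[grp == 0, "event"],
        )
        records.append(
            {
                "pathway": pathway,
                "statistic": float(res.test_statistic),
                "p": float(res.p_value),
                "n_dysreg": n_dys,
                "n_near_normal": n_near,
                "call_rate": n_dys / (n_dys + n_near),
            }
        )
    for pathway, reason in excluded.items():
        logger.warning("pathway %s excluded from survival screen: %s", pathway, reason)
    if not records:
        return pd.DataFrame(
            columns=["pathway", "statistic", "p", "p_adj", "n_dysreg",
                     "n_near_normal", "call_rate", "significant"]
        ).set_index("pathway")
    out = pd.DataFrame(records).set_index("pathway")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p"] < alpha
    out.attrs["excluded"] = excluded
    return out[["statistic", "p", "p_adj", "n_dysreg", "n_near_normal", "call_rate", "significant"]]


def _top_differential_pathways(
    activation: ActivationMatrix, labels: pd.Series, top_k: int
) -> list[str]:
    """Rank pathways by Welch t-test (tumor vs normal scores), BH-adjusted."""
    labels = labels.loc[activation.sample_ids]
    tumor = activation.scores.loc[:, labels == TUMOR].to_numpy()
    normal = activation.scores.loc[:, labels == NORMAL].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = ttest_ind(tumor, normal, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    order = pd.DataFrame(
        {"p_adj": p_adj, "p": p}, index=activation.pathway_names
    ).sort_values(["p_adj", "p"], kind="mergesort")
    return list(order.index[:top_k])


def ari_benchmark(
    X: ExpressionMatrix,
    sets: GeneSetCollection,
    config: RunConfig | None = None,
) -> list[float]:
    """Seeded tumor/normal clustering benchmark; one ARI per repeat.

    Each repeat subsamples tumors and normals, scores them, selects the top
    differential pathways (Welch t-test, BH adjustment), Ward-clusters the
    samples on those pathway scores into two groups and records the
    adjusted Rand index against the true labels.
    """
    config = config or RunConfig()
    tumors, normals = X.tumor_ids, X.normal_ids
    if len(tumors) < config.benchmark_n_tumor or len(normals) < config.benchmark_n_normal:
        raise AnalysisError(
            f"need >= {config.benchmark_n_tumor} tumor and >= "
            f"{config.benchmark_n_normal} normal samples, have "
            f"{len(tumors)} / {len(normals)}"
        )
    rng = np.random.default_rng(config.seed)
    aris: list[float] = []
    for _ in range(config.benchmark_repeats):
        t_sel = list(rng.choice(tumors, size=config.benchmark_n_tumor, replace=False))
        n_sel = list(rng.choice(normals, size=config.benchmark_n_normal, replace=False))
        sub = X.subset_samples(t_sel + n_sel)
        activation = score_all(sub, sets, config)
        top = _top_differential_pathways(activation, sub.labels, config.benchmark_top_k)
        features = activation.scores.loc[top].T.to_numpy()  # samples x pathways
        Z = linkage(features, method="ward", metric="euclidean")
        pred = fcluster(Z, t=2, criterion="maxclust")
        truth = (sub.labels.loc[activation.sample_ids] == TUMOR).astype(int).to_numpy()
        aris.append(float(adjusted_rand_score(truth, pred)))
    return aris
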