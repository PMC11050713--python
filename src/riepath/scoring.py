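"""Pathway-restricted covariance estimation and per-sample dysregulation scores.

The score of sample *i* on pathway *P* is built in three steps:

1. estimate the reference covariance ``C`` of the pathway's genes across the
   normal cohort;
2. re-estimate the covariance with sample *i* appended to the normals
   (the "leave-one-in" perturbed point ``A_i``);
3. report the tangent-space distance between ``C`` and ``A_i`` under the
   affine-invariant metric — the displacement that one extra sample causes.

Normal samples need their own scores for thresholding, but appending a
sample already in the reference moves nothing; they are therefore scored by
jackknife: the reference for normal *s* is the covariance of the other
normals, and the perturbed point is the covariance of all normals. A
"duplicate" mode (append a literal copy of *s*) is available for comparison.

Pathway gene counts routinely exceed the normal cohort size, so the raw
sample covariance can be singular and the manifold machinery undefined.
Covariances are shrunk toward mu*I (mu = mean diagonal) with an analytic
Ledoit–Wolf-style intensity estimated once per pathway from the normal
cohort and reused for every perturbed covariance, so reference and
perturbed points share identical regularization; an eigenvalue floor is a
last-resort repair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf_shrinkage

from .config import RunConfig
from .manifold import SPDPoint, tangent_distance, tangent_vectorize

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ActivationMatrix",
    "ScoringError",
    "PathwaySkipped",
    "restrict_to_pathway",
    "estimate_covariance",
    "score_pathway",
    "score_all",
]

logger = logging.getLogger("riepath")

TUMOR = "tumor"
NORMAL = "normal"

# Relative eigenvalue floor: lambda_min is lifted to FLOOR_SCALE * trace/N.
FLOOR_SCALE = 1e-6
# Absolute floor used when the covariance is identically zero (trace 0).
ABS_FLOOR = 1e-6


class ScoringError(ValueError):
    """Raised for invalid inputs to the scoring pipeline."""


class PathwaySkipped(Exception):
    """Signals that a pathway cannot be scored (too few genes, degenerate)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples log2-expression with per-sample tumor/normal labels."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    labels: pd.Series     # index: sample ids, values in {"tumor", "normal"}

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ScoringError(f"duplicate gene ids: {dup[:5]}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ScoringError(f"duplicate sample ids: {dup[:5]}")
        if self.values.isna().any().any():
            raise ScoringError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ScoringError(f"samples missing from labels: {missing[:5]}")
        self.labels = self.labels.loc[self.values.columns]
        bad = sorted(set(self.labels.unique()) - {TUMOR, NORMAL})
        if bad:
            raise ScoringError(f"labels must be 'tumor' or 'normal', got {bad}")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def normal_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == NORMAL])

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == TUMOR])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[sample_ids].copy(), self.labels.loc[sample_ids].copy())


@dataclass
class GeneSetCollection:
    """Ordered mapping pathway name -> member gene ids (deduplicated)."""

    entries: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.entries.items():
            if name in cleaned:
                raise ScoringError(f"duplicate pathway name {name!r}")
            seen: dict[str, None] = dict.fromkeys(g.strip() for g in genes if g.strip())
            if not seen:
                raise ScoringError(f"pathway {name!r} has no member genes")
            cleaned[name] = list(seen)
        self.entries = cleaned

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def names(self) -> list[str]:
        return list(self.entries)


@dataclass
class ActivationMatrix:
    """Pathways x samples dysregulation scores plus per-pathway bookkeeping.

    ``meta[pathway]`` records the genes actually used and those dropped for
    not being in the expression matrix; ``skipped[pathway]`` records why a
    pathway was left out entirely.
    """

    scores: pd.DataFrame  # index: pathway names, columns: sample ids
    meta: dict[str, dict] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.scores.values < 0).any():
            raise ScoringError("activation scores must be nonnegative (they are distances)")

    @property
    def pathway_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# covariance estimation
# ---------------------------------------------------------------------------

def restrict_to_pathway(
    X: ExpressionMatrix, genes: list[str], min_genes: int = 2
) -> tuple[pd.DataFrame, list[str]]:
    """Rows of *X* for the pathway's genes, in pathway order.

    Returns ``(submatrix, dropped)`` where *dropped* lists pathway genes
    absent from the expression matrix. Raises :class:`PathwaySkipped` when
    fewer than *min_genes* genes survive the intersection.
    """
    index = set(X.values.index)
    present = [g for g in genes if g in index]
    dropped = [g for g in genes if g not in index]
    if len(present) < min_genes:
        raise PathwaySkipped(
            f"only {len(present)} of {len(genes)} genes present (minimum {min_genes})"
        )
    return X.values.loc[present], dropped


def _floor_eigenvalues(S: np.ndarray) -> np.ndarray:
    n = S.shape[0]
    trace = float(np.trace(S))
    eps = FLOOR_SCALE * trace / n if trace > 0 else ABS_FLOOR
    w, V = np.linalg.eigh(S)
    if w[0] > eps:
        return S
    w = np.maximum(w, eps)
    out = (V * w) @ V.T
    return 0.5 * (out + out.T)


def lw_intensity(values: np.ndarray) -> float:
    """Analytic Ledoit–Wolf shrinkage intensity for a genes x samples block."""
    values = np.asarray(values, float)
    if values.shape[0] == 1:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = float(ledoit_wolf_shrinkage(values.T))
    if not np.isfinite(alpha):
        alpha = 1.0
    return min(max(alpha, 0.0), 1.0)


def _covariance_matrix(
    values: np.ndarray,
    shrinkage: str = "lw",
    intensity: float | None = None,
) -> np.ndarray:
    """Shrunk, floored sample covariance as a plain ndarray (internal)."""
    values = np.atleast_2d(np.asarray(values, float))
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ScoringError(f"need >= 2 samples to estimate covariance, got {n_samples}")
    S = np.atleast_2d(np.cov(values, ddof=1))
    trace = float(np.trace(S))
    if trace <= 0:
        logger.warning("all-constant expression block: returning floor * identity")
        return ABS_FLOOR * np.eye(n_genes)
    if shrinkage == "none":
        alpha = 0.0
    elif shrinkage == "fixed":
        if intensity is None:
            raise ScoringError("fixed shrinkage requires an intensity")
        alpha = float(intensity)
    elif shrinkage == "lw":
        alpha = lw_intensity(values) if intensity is None else float(intensity)
    else:
        raise ScoringError(f"unknown shrinkage mode {shrinkage!r}")
    mu = trace / n_genes
    shrunk = (1.0 - alpha) * S + alpha * mu * np.eye(n_genes)
    shrunk = 0.5 * (shrunk + shrunk.T)
    if FLOOR_SCALE <= alpha <= 1.0:
        # S is PSD, so lambda_min(shrunk) >= alpha * mu > FLOOR_SCALE * mu,
        # which is the floor; the repair provably cannot trigger
        return shrunk
    return _floor_eigenvalues(shrunk)


def estimate_covariance(
    values: np.ndarray,
    shrinkage: str = "lw",
    intensity: float | None = None,
) -> SPDPoint:
    """Shrunk, floored covariance of a genes x samples block; certified SPD.

    The raw estimate is the sample covariance across samples (denominator
    E - 1), shrunk toward mu*I with mu the mean diagonal. ``shrinkage``:
    ``"lw"`` (analytic intensity unless *intensity* overrides it),
    ``"fixed"`` (requires *intensity*), ``"none"``. Eigenvalues are floored
    at ``1e-6 * trace/N`` (absolute 1e-6 for an all-constant block).
    """
    return SPDPoint(_covariance_matrix(values, shrinkage, intensity))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _score_between(C: SPDPoint, A: SPDPoint) -> float:
    return tangent_distance(tangent_vectorize(C, A))


def _inv_sqrt(mat: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(mat)
    out = (V * (1.0 / np.sqrt(w))) @ V.T
    return 0.5 * (out + out.T)


def _fast_distance(Cih: np.ndarray, A: np.ndarray) -> float:
    """Geodesic distance given a precomputed C^{-1/2} of the reference.

    Same arithmetic as tangent_vectorize + tangent_distance (the whitened
    eigenvalues are all that survive the norm), without rebuilding the
    tangent vector per sample.
    """
    W = Cih @ A @ Cih
    lam = np.linalg.eigvalsh(0.5 * (W + W.T))
    if lam[0] <= 0:
        raise ScoringError("whitened covariance lost positive definiteness")
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def score_pathway(
    X_sub: pd.DataFrame,
    labels: pd.Series,
    config: RunConfig | None = None,
) -> pd.Series:
    """Score every sample of one pathway-restricted expression block.

    ``X_sub`` is genes x samples restricted to one pathway; ``labels``
    assigns each column tumor/normal. Tumors are scored leave-one-in
    against the normal reference; normals by jackknife (or duplication,
    per ``config.normal_mode``). Returns a score per sample, ordered as
    the input columns; all scores are nonnegative.
    """
    config = config or RunConfig()
    labels = labels.loc[X_sub.columns]
    normal_ids = list(labels.index[labels == NORMAL])
    if len(normal_ids) < config.min_normals:
        raise ScoringError(
            f"{len(normal_ids)} normal samples, below the minimum {config.min_normals}"
        )
    Xn = X_sub[normal_ids].to_numpy()

    # one shrinkage intensity per pathway, estimated from the normal cohort
    # and reused everywhere, so reference and perturbed covariances share
    # identical regularization
    if config.shrinkage == "lw":
        alpha: float | None = lw_intensity(Xn)
    elif config.shrinkage == "fixed":
        alpha = config.shrinkage_intensity
    else:
        alpha = None

    try:
        C = _covariance_matrix(Xn, config.shrinkage, alpha)
        Cih = _inv_sqrt(C)  # cached whitener of the reference point
        Xall = X_sub.to_numpy()
        is_normal = (labels == NORMAL).to_numpy()
        normal_pos = {s: i for i, s in enumerate(normal_ids)}
        scores = np.empty(Xall.shape[1])
        for j, sample in enumerate(X_sub.columns):
            if is_normal[j] and config.normal_mode == "jackknife":
                keep = [i for s, i in normal_pos.items() if s != sample]
                C_minus = _covariance_matrix(Xn[:, keep], config.shrinkage, alpha)
                # reference excludes s; perturbed point is all normals
                scores[j] = _fast_distance(_inv_sqrt(C_minus), C)
            else:
                # tumors, and normals in "duplicate" mode: leave-one-in
                A = _covariance_matrix(
                    np.hstack([Xn, Xall[:, j : j + 1]]), config.shrinkage, alpha
                )
                scores[j] = _fast_distance(Cih, A)
    except (ScoringError, np.linalg.LinAlgError) as exc:
        raise PathwaySkipped(f"degenerate covariance: {exc}") from exc

    return pd.Series(scores, index=X_sub.columns, name="score")


def score_all(
    X: ExpressionMatrix,
    sets: GeneSetCollection,
    config: RunConfig | None = None,
) -> ActivationMatrix:
    """Pathway x sample score matrix over a whole gene-set collection.

    Pathways with fewer than ``config.min_pathway_genes`` genes after
    intersection with the expression matrix, or with degenerate covariance,
    are skipped (with reasons recorded), never fatal; zero scoreable
    pathways is an error. Deterministic given inputs and config.
    """
    config = config or RunConfig()
    if len(X.normal_ids) < config.min_normals:
        raise ScoringError(
            f"{len(X.normal_ids)} normal samples, below the minimum {config.min_normals}"
        )
    rows: dict[str, pd.Series] = {}
    meta: dict[str, dict] = {}
    skipped: dict[str, str] = {}
    for name, genes in sets:
        try:
            X_sub, dropped = restrict_to_pathway(X, genes, config.min_pathway_genes)
            rows[name] = score_pathway(X_sub, X.labels, config)
            meta[name] = {"genes_used": list(X_sub.index), "genes_dropped": dropped}
        except PathwaySkipped as exc:
            skipped[name] = str(exc)
            logger.warning("pathway %s skipped: %s", name, exc)
    if not rows:
        raise ScoringError("no scoreable pathways (all skipped)")
    scores = pd.DataFrame(rows).T
    scores.index.name = "pathway"
    return ActivationMatrix(scores=scores, meta=meta, skipped=skipped)
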