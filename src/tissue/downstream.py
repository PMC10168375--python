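"""Uncertainty-aware cell filtering, weighted PCA, evaluation, stability.

The 67% prediction interval width (alpha = 0.33) approximates an asymmetric
standard error per cell-gene entry. Filtering z-scores widths per gene,
averages per cell and removes the high-uncertainty mode found by Otsu's
method (per class when labels are given). Weighted PCA instead down-weights
wide-interval entries 10:1 in a Delchambre weighted covariance
decomposition. The stability score quantifies how reproducible a 2-D layout
is across replicates after rigid (Procrustes) alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    adjusted_rand_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .calibration import build_calibration
from .core_data import PredictionMatrix, SpatialDataset
from .intervals import IntervalSet, build_intervals
from .uncertainty import variability_from_coords

__all__ = [
    "FilterResult",
    "WPCAWeights",
    "uncertainty_scores",
    "otsu_threshold",
    "filter_cells",
    "wpca_weights",
    "weighted_pca",
    "eval_harness",
    "stability_score",
    "uncertainty_filter_pipeline",
]

FILTER_ALPHA = 0.33  # 67% prediction interval


def uncertainty_scores(
    intervals: IntervalSet,
    pred: PredictionMatrix | None = None,
    standardize: str = "width",
) -> np.ndarray:
    """Per-cell uncertainty: mean over genes of per-gene z-scored widths.

    Widths w_ij = u_ij - l_ij are standardised within each gene by the
    gene's width mean/sd (``standardize="width"``, default); genes with
    zero width variance contribute z = 0. ``standardize="expression"``
    standardises widths by the gene's *predicted expression* mean/sd
    instead (an alternative reading of the procedure; requires ``pred``).
    """
    w = intervals.width
    if standardize == "width":
        mu = w.mean(axis=0)
        sd = w.std(axis=0)
    elif standardize == "expression":
        if pred is None:
            raise ValueError("standardize='expression' requires pred")
        mu = pred.values.mean(axis=0)
        sd = pred.values.std(axis=0)
    else:
        raise ValueError(f"unknown standardize {standardize!r}")
    z = np.zeros_like(w)
    ok = sd > 0
    z[:, ok] = (w[:, ok] - mu[ok]) / sd[ok]
    return z.mean(axis=1)


def otsu_threshold(values: Sequence[float] | np.ndarray, n_bins: int = 256) -> float:
    """Otsu's between-class-variance threshold on a 1-D sample.

    The value range is split into ``n_bins`` equal-width bins and the
    interior bin edge maximising omega0 * omega1 * (mu0 - mu1)^2 — with the
    classes split as (v <= edge, v > edge) on the actual values — is
    returned. Constant input yields +inf (no split; nothing filtered).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = v[0], v[-1]
    if lo == hi:
        return np.inf
    edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    n = v.size
    csum = np.concatenate([[0.0], np.cumsum(v)])
    # count of values <= edge per candidate edge
    n0 = np.searchsorted(v, edges, side="right")
    valid = (n0 > 0) & (n0 < n)
    n0 = n0[valid]
    edges = edges[valid]
    if edges.size == 0:
        return np.inf
    mu0 = csum[n0] / n0
    mu1 = (csum[-1] - csum[n0]) / (n - n0)
    between = (n0 / n) * ((n - n0) / n) * (mu0 - mu1) ** 2
    # many edges inside one inter-value gap tie exactly; return the middle
    # of the tied run so the threshold sits inside the gap, not on a value
    tied = np.flatnonzero(between >= between.max() - 1e-12 * between.max())
    return float(edges[tied[len(tied) // 2]])


@dataclass
class FilterResult:
    """Outcome of uncertainty-based cell filtering."""

    cell_scores: np.ndarray
    threshold: dict[str, float]  # per class ("" = global)
    kept: list[str]
    removed: list[str]
    kept_mask: np.ndarray


def filter_cells(
    scores: np.ndarray,
    labels: Sequence | np.ndarray | None = None,
    cell_ids: Sequence[str] | None = None,
    n_bins: int = 256,
) -> FilterResult:
    """Remove cells whose uncertainty score exceeds the Otsu threshold.

    With labels, thresholds are determined independently within each class
    so inter-class uncertainty differences do not drive the filtering.
    Cells strictly above their threshold are removed; a class of size 1 is
    never filtered.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    ids = (
        [str(c) for c in cell_ids]
        if cell_ids is not None
        else [str(i) for i in range(scores.size)]
    )
    keep = np.ones(scores.size, dtype=bool)
    thresholds: dict[str, float] = {}
    if labels is None:
        thr = otsu_threshold(scores, n_bins=n_bins)
        thresholds[""] = thr
        keep = ~(scores > thr)
    else:
        labels = np.asarray(labels)
        for lab in pd.unique(labels):
            mask = labels == lab
            if mask.sum() < 2:
                warnings.warn(f"class {lab!r} has a single cell; never removed")
                thresholds[str(lab)] = np.inf
                continue
            thr = otsu_threshold(scores[mask], n_bins=n_bins)
            thresholds[str(lab)] = thr
            keep[mask] = ~(scores[mask] > thr)
    return FilterResult(
        cell_scores=scores,
        threshold=thresholds,
        kept=[i for i, k in zip(ids, keep) if k],
        removed=[i for i, k in zip(ids, keep) if not k],
        kept_mask=keep,
    )


@dataclass
class WPCAWeights:
    weights: np.ndarray
    scheme: str


def wpca_weights(intervals: IntervalSet, scheme: str = "binary") -> WPCAWeights:
    """Per-entry weights from inverse 67%-interval widths.

    v_ij = 1 / max(w_ij, eps) with eps = 1e-8 x the global mean width, then
    v is normalised per gene by the gene's mean. ``binary``: entries at or
    above the pooled 20th percentile get weight 1.0, the rest 0.1 (a
    ten-fold ratio). ``log``: weight = log(1 + normalised v).
    """
    w = intervals.width
    eps = 1e-8 * max(w.mean(), np.finfo(float).tiny)
    v = 1.0 / np.maximum(w, eps)
    v = v / v.mean(axis=0)
    if scheme == "binary":
        cut = np.percentile(v, 20)
        return WPCAWeights(np.where(v >= cut, 1.0, 0.1), scheme)
    if scheme == "log":
        return WPCAWeights(np.log1p(v), scheme)
    raise ValueError(f"unknown scheme {scheme!r}")


def weighted_pca(
    data: np.ndarray,
    weights: np.ndarray | WPCAWeights,
    n_components: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted PCA: eigen-decomposition of the weighted covariance matrix
    followed by per-cell weighted least squares.

    The weighted covariance is
    C_jk = sum_i w_ij w_ik (x_ij - mu_j)(x_ik - mu_k) / sum_i w_ij w_ik
    with weighted per-gene means mu. The embedding solves, per cell,
    min_t sum_j w_ij^2 (x_ij - mu_j - (P^T t)_j)^2. With uniform weights
    this reduces exactly to standard PCA (up to component sign).

    Returns (components [n_components x p], embedding [n x n_components]).
    """
    if isinstance(weights, WPCAWeights):
        weights = weights.weights
    X = np.asarray(data, dtype=float)
    W = np.asarray(weights, dtype=float)
    if W.shape != X.shape:
        raise ValueError("weights must match the data shape")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")

    wsum = W.sum(axis=0)
    mu = np.where(wsum > 0, (W * X).sum(axis=0) / np.where(wsum > 0, wsum, 1.0),
                  X.mean(axis=0))
    Xc = X - mu
    WX = W * Xc
    denom = W.T @ W
    C = WX.T @ WX
    C = np.divide(C, denom, out=np.zeros_like(C), where=denom > 0)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:n_components]
    P = evecs[:, order].T  # (n_components, p)
    # deterministic sign: largest-magnitude loading positive
    for r in range(P.shape[0]):
        if P[r, np.argmax(np.abs(P[r]))] < 0:
            P[r] = -P[r]

    emb = np.empty((X.shape[0], P.shape[0]))
    zero_rows = ~(W > 0).any(axis=1)
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} cells have all-zero weights; "
            "using unweighted projection for them"
        )
    for i in range(X.shape[0]):
        if zero_rows[i]:
            emb[i] = P @ Xc[i]
            continue
        w2 = W[i] ** 2
        A = (P * w2) @ P.T
        b = (P * w2) @ Xc[i]
        try:
            emb[i] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            emb[i] = np.linalg.lstsq(A, b, rcond=None)[0]
    return P, emb


# ---------------------------------------------------------------------------
# downstream evaluation harness
# ---------------------------------------------------------------------------

def eval_harness(
    features: np.ndarray,
    labels: Sequence | np.ndarray,
    task: str = "classify",
    seed: int = 0,
    n_pcs: int = 15,
) -> pd.DataFrame:
    """Standard downstream-task metrics on a feature matrix.

    ``classify``: stratified 5-fold CV of an L1-penalised logistic
    regression (standardised inputs), reporting fold-averaged accuracy,
    ROC-AUC and macro F1. ``cluster``: k-means with k = n_classes on the
    top ``n_pcs`` PCs, scored by adjusted Rand index against the labels.
    ``separability``: training accuracy of a linear-kernel SVC on the top
    ``n_pcs`` PCs.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = pd.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")

    if task == "classify":
        accs, aucs, f1s = [], [], []
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        for train, test in skf.split(X, y):
            clf = make_pipeline(
                StandardScaler(),
                LogisticRegression(
                    l1_ratio=1.0, solver="liblinear", random_state=seed
                ),
            ).fit(X[train], y[train])
            yhat = clf.predict(X[test])
            accs.append(accuracy_score(y[test], yhat))
            f1s.append(f1_score(y[test], yhat, average="macro"))
            proba = clf.predict_proba(X[test])
            if len(classes) == 2:
                pos = list(clf.classes_).index(clf.classes_[-1])
                aucs.append(
                    roc_auc_score(y[test] == clf.classes_[-1], proba[:, pos])
                )
            else:
                aucs.append(
                    roc_auc_score(y[test], proba, multi_class="ovr",
                                  average="macro", labels=clf.classes_)
                )
        rows = [
            ("accuracy", float(np.mean(accs))),
            ("roc_auc", float(np.mean(aucs))),
            ("macro_f1", float(np.mean(f1s))),
        ]
    elif task == "cluster":
        emb = _standardized_pcs(X, n_pcs, seed)
        km = KMeans(n_clusters=len(classes), n_init=10, random_state=seed).fit(emb)
        rows = [("ari", float(adjusted_rand_score(y, km.labels_)))]
    elif task == "separability":
        emb = _standardized_pcs(X, n_pcs, seed)
        svc = SVC(kernel="linear", random_state=seed).fit(emb, y)
        rows = [("linear_separability",
                 float(accuracy_score(y, svc.predict(emb))))]
    else:
        raise ValueError(f"unknown task {task!r}")
    return pd.DataFrame(rows, columns=["metric", "value"])


def _standardized_pcs(X: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    Z = StandardScaler().fit_transform(X)
    k = min(n_pcs, Z.shape[0] - 1, Z.shape[1])
    return PCA(n_components=k, random_state=seed).fit_transform(Z)


# ---------------------------------------------------------------------------
# replicate-alignment stability score
# ---------------------------------------------------------------------------

def stability_score(
    embeddings: Sequence[np.ndarray],
    ids: Sequence[Sequence[str]] | None = None,
) -> pd.Series:
    """Per-cell positional variance across rigidly aligned 2-D layouts.

    Every layout is centred and aligned to the first (reference) layout by
    orthogonal Procrustes (rotation/reflection, no scaling) on the cells it
    shares with the reference. A cell's score is the mean squared deviation
    of its aligned positions from their centroid, taken across the layouts
    containing it, divided by the mean squared distance of reference
    positions to their centroid (global normalisation). Cells appearing in
    fewer than two layouts score NaN.
    """
    if len(embeddings) < 2:
        raise ValueError("need at least 2 layouts")
    embeddings = [np.asarray(E, dtype=float) for E in embeddings]
    if ids is None:
        if len({E.shape[0] for E in embeddings}) != 1:
            raise ValueError("layouts differ in size; provide cell ids")
        ids = [[str(i) for i in range(E.shape[0])] for E in embeddings]
    ids = [[str(c) for c in layout_ids] for layout_ids in ids]

    ref_ids, ref = ids[0], embeddings[0]
    ref = ref - ref.mean(axis=0)
    ref_pos = {c: ref[i] for i, c in enumerate(ref_ids)}
    norm = float(np.mean(np.sum(ref**2, axis=1)))
    if norm == 0:
        raise ValueError("degenerate reference layout (all cells coincide)")

    aligned: dict[str, list[np.ndarray]] = {c: [ref_pos[c]] for c in ref_ids}
    for layout_ids, E in zip(ids[1:], embeddings[1:]):
        shared = [c for c in layout_ids if c in ref_pos]
        if len(shared) < 3:
            raise ValueError("fewer than 3 cells shared with the reference")
        pos = {c: E[i] for i, c in enumerate(layout_ids)}
        Y_s = np.array([pos[c] for c in shared])
        X_s = np.array([ref_pos[c] for c in shared])
        center = Y_s.mean(axis=0)
        R, _ = orthogonal_procrustes(Y_s - center, X_s - X_s.mean(axis=0))
        shift = X_s.mean(axis=0)
        for c in layout_ids:
            aligned.setdefault(c, []).append((pos[c] - center) @ R + shift)

    scores = {}
    for c, positions in aligned.items():
        if len(positions) < 2:
            scores[c] = np.nan
            continue
        P = np.asarray(positions)
        scores[c] = float(np.mean(np.sum((P - P.mean(axis=0)) ** 2, axis=1)))
    return pd.Series(scores).sort_index() / norm


# ---------------------------------------------------------------------------
# end-to-end filtering pipeline
# ---------------------------------------------------------------------------

def uncertainty_filter_pipeline(
    measured: SpatialDataset,
    pred: PredictionMatrix,
    k_g: int | str = 1,
    k_c: int | str = 1,
    seed: int = 0,
    K: int = 15,
    labels: Sequence | np.ndarray | None = None,
) -> FilterResult:
    """Compose variability -> calibration -> 67% intervals -> Otsu filter.

    ``labels`` defaults to the dataset's own labels when present.
    """
    _, _, U = variability_from_coords(pred, measured.coords, K=K)
    model = build_calibration(measured, pred, U, k_g=k_g, k_c=k_c, seed=seed)
    iv = build_intervals(pred, U, model, alpha=FILTER_ALPHA)
    scores = uncertainty_scores(iv)
    if labels is None:
        labels = measured.label_array()
    return filter_cells(scores, labels=labels, cell_ids=measured.cell_ids)
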