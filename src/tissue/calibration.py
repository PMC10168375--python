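"""Calibration scores and stratified gene x cell calibration-score sets.

The nonconformity score for a measured/predicted pair is

    s_ij = |X_ij - Xhat_ij| / U_ij,

the absolute prediction error in units of the cell-centric variability.
Scores are split by the sign of the error into a *lower* set (measured
below prediction) and an *upper* set (measured above), which is what makes
the downstream prediction intervals asymmetric — appropriate for skewed
transcript-count data. A score with X = Xhat belongs to both sides.

Scores can further be stratified into k_g gene groups x k_c cell groups
(k-means on PCA embeddings of the predicted expression), each holding its
own score sets; groups too small to calibrate on their own (< min_set_size
scores on either side) fall back to the union of all scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy.stats import wasserstein_distance
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .core_data import PredictionMatrix, SpatialDataset
from .uncertainty import VariabilityMatrix

__all__ = [
    "Stratification",
    "CalibrationModel",
    "compute_scores",
    "stratify",
    "auto_select_k",
    "build_calibration",
    "group_diagnostics",
    "save_calibration",
    "load_calibration",
]

SIDE_LOWER, SIDE_UPPER, SIDE_BOTH = "lower", "upper", "both"


def compute_scores(
    measured: SpatialDataset,
    pred: PredictionMatrix,
    U: VariabilityMatrix,
) -> pd.DataFrame:
    """Calibration score and side for every (cell, gene) pair.

    Returns a long-format frame with columns ``cell`` (index), ``gene``
    (index into ``pred.gene_ids``), ``s`` and ``side``.
    """
    X, Xhat, Uv = _aligned_arrays(measured, pred, U)
    s = np.abs(X - Xhat) / Uv
    n, p = s.shape
    side = np.where(X > Xhat, SIDE_UPPER, np.where(X < Xhat, SIDE_LOWER, SIDE_BOTH))
    return pd.DataFrame(
        {
            "cell": np.repeat(np.arange(n), p),
            "gene": np.tile(np.arange(p), n),
            "s": s.ravel(),
            "side": side.ravel(),
        }
    )


def _aligned_arrays(measured, pred, U):
    missing = [g for g in pred.gene_ids if g not in set(measured.gene_ids)]
    if missing:
        raise ValueError(f"predicted genes absent from measured panel: {missing}")
    cols = [measured.gene_ids.index(g) for g in pred.gene_ids]
    X = measured.values[:, cols]
    Uv = np.asarray(U.values, dtype=float)
    if Uv.shape != pred.values.shape or X.shape != pred.values.shape:
        raise ValueError("measured / predicted / variability shapes disagree")
    if np.any(Uv < 1.0 - 1e-9):
        raise AssertionError("cell-centric variability below its intercept of 1")
    return X, pred.values, Uv


# ---------------------------------------------------------------------------
# stratified grouping
# ---------------------------------------------------------------------------

def _pca_embed(mat: np.ndarray, n_pcs: int, seed: int) -> tuple[PCA, np.ndarray]:
    k = max(1, min(n_pcs, mat.shape[0] - 1, mat.shape[1]))
    pca = PCA(n_components=k, random_state=seed)
    return pca, pca.fit_transform(mat)


def _kmeans(emb: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)


@dataclass
class Stratification:
    """Gene and cell group assignments plus the embeddings that made them.

    Group labels are 1-based. The fitted PCA/k-means objects are retained so
    genes (or cells) outside the calibration panel can be mapped to the
    nearest stratification centroid at deployment time.
    """

    k_g: int
    k_c: int
    n_pcs: int
    seed: int
    gene_ids: list[str]
    gene_group: dict[str, int]
    gene_pca: PCA | None
    gene_centroids: np.ndarray | None  # (k_g, d) in gene-PC space
    strata_genes: dict[int, list[str]]  # g -> gene ids of the stratum
    cell_group: dict[int, np.ndarray]  # g -> (n_cells,) labels in 1..k_c
    cell_pca: dict[int, PCA | None] = field(default_factory=dict)
    cell_centroids: dict[int, np.ndarray | None] = field(default_factory=dict)
    n_cells: int = 0
    cell_ids: list[str] | None = None

    def assign_genes(self, pred: PredictionMatrix) -> np.ndarray:
        """Gene-group label per gene of ``pred`` (nearest centroid if unseen)."""
        out = np.empty(pred.n_genes, dtype=int)
        for j, gid in enumerate(pred.gene_ids):
            if gid in self.gene_group:
                out[j] = self.gene_group[gid]
            elif self.k_g == 1:
                out[j] = 1
            else:
                if pred.n_cells != self.n_cells:
                    raise ValueError(
                        "cannot map a new gene: cell dimension differs from "
                        "the calibration panel"
                    )
                z = self.gene_pca.transform(pred.values[:, j][None, :])
                d = np.linalg.norm(self.gene_centroids - z, axis=1)
                out[j] = int(np.argmin(d)) + 1
        return out

    def assign_cells(self, pred: PredictionMatrix, g: int) -> np.ndarray:
        """Cell-group label per cell of ``pred`` within gene stratum ``g``."""
        same_cells = pred.n_cells == self.n_cells and (
            pred.cell_ids is None
            or self.cell_ids is None
            or pred.cell_ids == self.cell_ids
        )
        if same_cells:
            return self.cell_group[g]
        if self.k_c == 1:
            return np.ones(pred.n_cells, dtype=int)
        cols = {gid: j for j, gid in enumerate(pred.gene_ids)}
        want = self.strata_genes[g]
        if not all(gid in cols for gid in want):
            raise ValueError(
                "cannot map new cells: stratum genes missing from prediction"
            )
        sub = pred.values[:, [cols[gid] for gid in want]]
        z = self.cell_pca[g].transform(sub)
        d = np.linalg.norm(
            z[:, None, :] - self.cell_centroids[g][None, :, :], axis=2
        )
        return np.argmin(d, axis=1) + 1

    def assign(self, pred: PredictionMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Per-entry (gene-group, cell-group) labels, each (n_cells, n_genes)."""
        gg = self.assign_genes(pred)
        G = np.broadcast_to(gg, (pred.n_cells, pred.n_genes)).copy()
        C = np.empty((pred.n_cells, pred.n_genes), dtype=int)
        for g in np.unique(gg):
            C[:, gg == g] = self.assign_cells(pred, int(g))[:, None]
        return G, C


def stratify(
    pred: PredictionMatrix,
    k_g: int,
    k_c: int,
    n_pcs: int = 15,
    seed: int = 0,
) -> Stratification:
    """Cluster genes, then cells within each gene stratum.

    Genes are k-means clustered (k = k_g) on the first ``n_pcs`` principal
    components of the transposed prediction matrix; within each gene
    stratum, cells are clustered (k = k_c) on the first ``n_pcs`` PCs of the
    prediction matrix restricted to that stratum's genes. Deterministic
    given ``seed``.
    """
    if k_g < 1 or k_c < 1:
        raise ValueError("k_g and k_c must be >= 1")
    if k_g > pred.n_genes:
        raise ValueError(f"k_g={k_g} exceeds {pred.n_genes} genes")
    if k_c > pred.n_cells:
        raise ValueError(f"k_c={k_c} exceeds {pred.n_cells} cells")

    gene_pca = gene_centroids = None
    if k_g == 1:
        gene_labels = np.ones(pred.n_genes, dtype=int)
    else:
        gene_pca, gene_emb = _pca_embed(pred.values.T, n_pcs, seed)
        km = _kmeans(gene_emb, k_g, seed)
        gene_labels = km.labels_ + 1
        gene_centroids = km.cluster_centers_

    strat = Stratification(
        k_g=k_g,
        k_c=k_c,
        n_pcs=n_pcs,
        seed=seed,
        gene_ids=list(pred.gene_ids),
        gene_group={g: int(l) for g, l in zip(pred.gene_ids, gene_labels)},
        gene_pca=gene_pca,
        gene_centroids=gene_centroids,
        strata_genes={},
        cell_group={},
        n_cells=pred.n_cells,
        cell_ids=list(pred.cell_ids) if pred.cell_ids is not None else None,
    )
    for g in range(1, k_g + 1):
        cols = np.flatnonzero(gene_labels == g)
        strat.strata_genes[g] = [pred.gene_ids[j] for j in cols]
        if k_c == 1 or cols.size == 0:
            strat.cell_group[g] = np.ones(pred.n_cells, dtype=int)
            strat.cell_pca[g] = None
            strat.cell_centroids[g] = None
            continue
        pca, emb = _pca_embed(pred.values[:, cols], n_pcs, seed)
        km = _kmeans(emb, k_c, seed)
        strat.cell_group[g] = km.labels_ + 1
        strat.cell_pca[g] = pca
        strat.cell_centroids[g] = km.cluster_centers_
    return strat


def _silhouette_search(emb: np.ndarray, k_max: int, seed: int) -> int:
    """Line search k = 2, 3, ...; stop at the first silhouette decrease."""
    best_k, best_s = 1, -np.inf
    prev = -np.inf
    for k in range(2, min(k_max, emb.shape[0] - 1) + 1):
        labels = _kmeans(emb, k, seed).labels_
        try:
            if len(np.unique(labels)) < 2:
                raise ValueError("degenerate clustering")
            s = silhouette_score(emb, labels)
        except ValueError:
            break  # undefined silhouette counts as a decrease
        if s > best_s:
            best_k, best_s = k, s
        if s < prev:
            break
        prev = s
    return best_k if np.isfinite(best_s) else 1


def auto_select_k(
    pred: PredictionMatrix, k_max: int = 10, seed: int = 0, n_pcs: int = 15
) -> tuple[int, int]:
    """Silhouette-guided selection of (k_g, k_c).

    k_g: cluster genes on the PCs of the transposed prediction matrix for
    increasing k until the silhouette score drops, keeping the argmax.
    k_c: the same search clustering cells on the PCs of the prediction
    matrix. Both capped at ``k_max``.
    """
    if pred.n_genes < 3 or pred.n_cells < 3:
        raise ValueError("need at least 3 genes and 3 cells for auto selection")
    _, gene_emb = _pca_embed(pred.values.T, n_pcs, seed)
    k_g = _silhouette_search(gene_emb, k_max, seed)
    _, cell_emb = _pca_embed(pred.values, n_pcs, seed)
    k_c = _silhouette_search(cell_emb, k_max, seed)
    return k_g, k_c


# ---------------------------------------------------------------------------
# the calibration model
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Stratified lower/upper calibration-score sets.

    ``lower_scores`` / ``upper_scores`` hold each group's own scores; a
    group whose lower *or* upper set has fewer than ``min_set_size`` scores
    is flagged in ``fallback_used`` and served the union of all scores
    (per side) by :meth:`effective_scores`.
    """

    k_g: int
    k_c: int
    strat: Stratification
    lower_scores: dict[tuple[int, int], np.ndarray]
    upper_scores: dict[tuple[int, int], np.ndarray]
    fallback_used: dict[tuple[int, int], bool]
    union_lower: np.ndarray
    union_upper: np.ndarray
    calib_variability: dict[tuple[int, int], np.ndarray]
    min_set_size: int = 100
    seed: int = 0
    # per-score (cell, gene) provenance, parallel to the sorted score arrays
    lower_index: dict[tuple[int, int], np.ndarray] | None = None
    upper_index: dict[tuple[int, int], np.ndarray] | None = None
    gene_ids: list[str] | None = None
    cell_ids: list[str] | None = None

    def groups(self) -> list[tuple[int, int]]:
        return [(g, c) for g in range(1, self.k_g + 1) for c in range(1, self.k_c + 1)]

    def effective_scores(self, g: int, c: int, side: str) -> np.ndarray:
        raw = {SIDE_LOWER: self.lower_scores, SIDE_UPPER: self.upper_scores}[side]
        union = {SIDE_LOWER: self.union_lower, SIDE_UPPER: self.union_upper}[side]
        return union if self.fallback_used[(g, c)] else raw[(g, c)]

    def assign(self, pred: PredictionMatrix) -> tuple[np.ndarray, np.ndarray]:
        return self.strat.assign(pred)


def build_calibration(
    measured: SpatialDataset,
    pred: PredictionMatrix,
    U: VariabilityMatrix,
    k_g: int | str = 1,
    k_c: int | str = 1,
    seed: int = 0,
    min_set_size: int = 100,
    n_pcs: int = 15,
) -> CalibrationModel:
    """Compute scores and allocate them to stratified (gene, cell) groups.

    ``k_g``/``k_c`` may be integers or ``"auto"`` (silhouette search).
    """
    if k_g == "auto" or k_c == "auto":
        ag, ac = auto_select_k(pred, seed=seed, n_pcs=n_pcs)
        k_g = ag if k_g == "auto" else int(k_g)
        k_c = ac if k_c == "auto" else int(k_c)
    k_g, k_c = int(k_g), int(k_c)

    X, Xhat, Uv = _aligned_arrays(measured, pred, U)
    s = np.abs(X - Xhat) / Uv
    if s.size == 0:
        raise ValueError("empty calibration score set")
    strat = stratify(pred, k_g, k_c, n_pcs=n_pcs, seed=seed)
    G, C = strat.assign(pred)

    is_upper = X >= Xhat  # ties contribute to both sides
    is_lower = X <= Xhat
    flat = (G - 1) * k_c + (C - 1)
    lower, upper, fallback, calib_u = {}, {}, {}, {}
    lower_index, upper_index = {}, {}
    for g in range(1, k_g + 1):
        for c in range(1, k_c + 1):
            in_grp = flat == (g - 1) * k_c + (c - 1)
            for side_mask, scores, index in (
                (is_lower, lower, lower_index),
                (is_upper, upper, upper_index),
            ):
                cells, genes = np.nonzero(in_grp & side_mask)
                vals = s[cells, genes]
                order = np.argsort(vals, kind="stable")
                scores[(g, c)] = vals[order]
                index[(g, c)] = np.stack([cells[order], genes[order]])
            fallback[(g, c)] = (
                len(lower[(g, c)]) < min_set_size
                or len(upper[(g, c)]) < min_set_size
            )
            calib_u[(g, c)] = Uv[in_grp]
    return CalibrationModel(
        k_g=k_g,
        k_c=k_c,
        strat=strat,
        lower_scores=lower,
        upper_scores=upper,
        fallback_used=fallback,
        union_lower=np.sort(s[is_lower]),
        union_upper=np.sort(s[is_upper]),
        calib_variability=calib_u,
        min_set_size=min_set_size,
        seed=seed,
        lower_index=lower_index,
        upper_index=upper_index,
        gene_ids=list(pred.gene_ids),
        cell_ids=list(pred.cell_ids) if pred.cell_ids is not None else None,
    )


def group_diagnostics(
    model: CalibrationModel,
    pred: PredictionMatrix,
    U: VariabilityMatrix,
) -> dict[tuple[int, int], float]:
    """Wasserstein-1 distance between a deployment group's cell-centric
    variability values and its calibration subset's, per (g, c) group.

    Zero when the deployment values coincide with the calibration subset —
    i.e. the calibration set is perfectly representative of the group.
    """
    G, C = model.assign(pred)
    Uv = np.asarray(U.values, dtype=float)
    out = {}
    for g, c in model.groups():
        mask = (G == g) & (C == c)
        if not mask.any() or model.calib_variability[(g, c)].size == 0:
            out[(g, c)] = np.nan
            continue
        out[(g, c)] = float(
            wasserstein_distance(Uv[mask], model.calib_variability[(g, c)])
        )
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_calibration(model: CalibrationModel, out_dir: str | Path) -> None:
    """Write the model as groups.tsv (one score per row) + meta.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for (g, c) in model.groups():
        for side, scores, index in (
            (SIDE_LOWER, model.lower_scores[(g, c)], model.lower_index),
            (SIDE_UPPER, model.upper_scores[(g, c)], model.upper_index),
        ):
            if index is not None and model.cell_ids is not None:
                cells = [model.cell_ids[i] for i in index[(g, c)][0]]
            elif index is not None:
                cells = index[(g, c)][0]
            else:
                cells = [""] * len(scores)
            if index is not None and model.gene_ids is not None:
                genes = [model.gene_ids[j] for j in index[(g, c)][1]]
            elif index is not None:
                genes = index[(g, c)][1]
            else:
                genes = [""] * len(scores)
            frames.append(
                pd.DataFrame(
                    {"cell": cells, "gene": genes, "g": g, "c": c,
                     "s": scores, "side": side}
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(
        out_dir / "groups.tsv", sep="\t", index=False
    )
    meta = {
        "k_g": model.k_g,
        "k_c": model.k_c,
        "seed": model.seed,
        "min_set_size": model.min_set_size,
        "fallback": {f"{g},{c}": bool(v) for (g, c), v in model.fallback_used.items()},
        "gene_group": model.strat.gene_group,
    }
    (out_dir / "meta.yaml").write_text(yaml.safe_dump(meta))


def load_calibration(in_dir: str | Path) -> CalibrationModel:
    """Reload score sets written by :func:`save_calibration`.

    The reloaded model retrieves quantiles for the calibration panel's own
    groups; the fitted embeddings for mapping unseen genes/cells are not
    serialized.
    """
    in_dir = Path(in_dir)
    meta = yaml.safe_load((in_dir / "meta.yaml").read_text())
    df = pd.read_csv(in_dir / "groups.tsv", sep="\t")
    k_g, k_c = int(meta["k_g"]), int(meta["k_c"])
    lower, upper, fallback = {}, {}, {}
    for g in range(1, k_g + 1):
        for c in range(1, k_c + 1):
            sub = df[(df.g == g) & (df.c == c)]
            lower[(g, c)] = np.sort(sub[sub.side == SIDE_LOWER].s.to_numpy())
            upper[(g, c)] = np.sort(sub[sub.side == SIDE_UPPER].s.to_numpy())
            fallback[(g, c)] = bool(meta["fallback"][f"{g},{c}"])
    gene_group = {str(k): int(v) for k, v in meta["gene_group"].items()}
    strat = Stratification(
        k_g=k_g,
        k_c=k_c,
        n_pcs=15,
        seed=int(meta["seed"]),
        gene_ids=list(gene_group),
        gene_group=gene_group,
        gene_pca=None,
        gene_centroids=None,
        strata_genes={
            g: [gid for gid, l in gene_group.items() if l == g]
            for g in range(1, k_g + 1)
        },
        cell_group={},
    )
    return CalibrationModel(
        k_g=k_g,
        k_c=k_c,
        strat=strat,
        lower_scores=lower,
        upper_scores=upper,
        fallback_used=fallback,
        union_lower=np.sort(df[df.side == SIDE_LOWER].s.to_numpy()),
        union_upper=np.sort(df[df.side == SIDE_UPPER].s.to_numpy()),
        calib_variability={k: np.array([]) for k in lower},
        min_set_size=int(meta["min_set_size"]),
        seed=int(meta["seed"]),
    )
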