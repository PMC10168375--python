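"""Baseline spatial gene-expression predictor and the cross-validation harness.

The conformal machinery in this package wraps *any* predictor satisfying
:class:`PredictorContract`: a callable mapping (spatial panel restricted to
training genes, preprocessed reference, target gene list) to a
:class:`~tissue.core_data.PredictionMatrix`. External tools (SpaGE, Tangram,
integration-based kNN imputation, gimVI, ...) plug in through this contract.

The built-in baseline, :func:`knn_joint_predict`, embeds spatial and
reference cells jointly with a plain PCA on the shared gene panel and
averages each spatial cell's k nearest reference neighbours. It is a
deliberate simplification of integration-based kNN imputation (no batch
integration step) so the whole framework is testable without external
dependencies; it is not equivalent to those methods on real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_data import PredictionMatrix, ReferenceDataset, SpatialDataset

__all__ = [
    "PredictorContract",
    "FoldPlan",
    "knn_joint_predict",
    "crossval_predict",
    "register_predictor",
    "get_predictor",
]


@runtime_checkable
class PredictorContract(Protocol):
    """Any callable predicting target-gene expression for spatial cells.

    Implementations must not read held-out spatial measurements of the
    target genes; only the training panel and the reference are available.
    """

    def __call__(
        self,
        spatial_panel: SpatialDataset,
        reference: ReferenceDataset,
        target_genes: Sequence[str],
    ) -> PredictionMatrix: ...


_PREDICTOR_REGISTRY: dict[str, Callable] = {}


def register_predictor(name: str) -> Callable[[Callable], Callable]:
    """Register a predictor callable under ``name`` for CLI/config lookup."""

    def deco(fn: Callable) -> Callable:
        _PREDICTOR_REGISTRY[name] = fn
        return fn

    return deco


def get_predictor(name: str) -> Callable:
    try:
        return _PREDICTOR_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown predictor {name!r}; registered: "
            f"{sorted(_PREDICTOR_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class FoldPlan:
    """Seeded assignment of genes to cross-validation folds.

    Genes are sorted, shuffled with ``seed`` and dealt round-robin, so the
    assignment depends only on the gene *set*, not on input order; fold
    sizes differ by at most one.
    """

    n_folds: int
    assignment: dict[str, int]
    seed: int

    @classmethod
    def build(cls, gene_ids: Sequence[str], n_folds: int, seed: int) -> "FoldPlan":
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if n_folds > len(gene_ids):
            raise ValueError(
                f"n_folds={n_folds} exceeds the {len(gene_ids)}-gene panel"
            )
        rng = np.random.default_rng(seed)
        genes = sorted(gene_ids)
        rng.shuffle(genes)
        return cls(n_folds, {g: i % n_folds for i, g in enumerate(genes)}, seed)

    def fold_genes(self, fold: int) -> list[str]:
        return sorted(g for g, f in self.assignment.items() if f == fold)


def knn_joint_predict(
    spatial_panel: SpatialDataset,
    reference: ReferenceDataset,
    target_genes: Sequence[str],
    k: int = 10,
    n_components: int | None = None,
) -> PredictionMatrix:
    """Predict target genes by kNN averaging in a joint PCA embedding.

    The genes shared between the spatial panel and the reference are
    z-scored on the stacked (spatial + reference) matrix, the stack is
    projected onto its first ``min(30, p_shared)`` principal components,
    and each spatial cell's prediction for a target gene is the unweighted
    mean of that gene over its ``k`` nearest reference cells (Euclidean
    distance in the embedding).
    """
    ref_index = {g: i for i, g in enumerate(reference.gene_ids)}
    missing = [g for g in target_genes if g not in ref_index]
    if missing:
        raise ValueError(f"target genes absent from reference: {missing}")
    shared = [g for g in spatial_panel.gene_ids if g in ref_index]
    if len(shared) < 2:
        raise ValueError("need at least 2 genes shared with the reference")

    Xs = spatial_panel.values[:, [spatial_panel.gene_ids.index(g) for g in shared]]
    Yr = reference.values[:, [ref_index[g] for g in shared]]
    stacked = np.vstack([Xs, Yr])
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    nonzero = sd > 0  # zero-variance genes carry no embedding information
    if not nonzero.any():
        raise ValueError("all shared genes have zero variance in the stack")
    Z = (stacked[:, nonzero] - mu[nonzero]) / sd[nonzero]

    if n_components is None:
        n_components = min(30, int(nonzero.sum()))
    n_components = min(n_components, Z.shape[0] - 1, Z.shape[1])
    emb = PCA(n_components=n_components, random_state=0).fit_transform(Z)
    emb_s, emb_r = emb[: spatial_panel.n_cells], emb[spatial_panel.n_cells :]

    m = reference.n_cells
    if k > m:
        warnings.warn(f"k={k} exceeds the {m}-cell reference; clamping to {m}")
        k = m
    nn = NearestNeighbors(n_neighbors=k).fit(emb_r)
    _, idx = nn.kneighbors(emb_s)
    targets = reference.values[:, [ref_index[g] for g in target_genes]]
    pred = targets[idx].mean(axis=1)
    return PredictionMatrix(
        pred, list(target_genes), source="knn_joint", cell_ids=list(spatial_panel.cell_ids)
    )


@register_predictor("knn")
def _knn_default(spatial_panel, reference, target_genes):
    return knn_joint_predict(spatial_panel, reference, target_genes)


def crossval_predict(
    spatial: SpatialDataset,
    reference: ReferenceDataset,
    predictor: PredictorContract | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> PredictionMatrix:
    """Predict every measured spatial gene under gene-wise cross-validation.

    The panel is split into ``n_folds`` folds; each fold's genes are
    predicted by a model that only sees the other folds' spatial
    measurements. These held-out predictions are what the calibration
    scores are computed from. The output gene order matches the spatial
    panel and records each gene's fold.
    """
    if predictor is None:
        predictor = get_predictor("knn")
    plan = FoldPlan.build(spatial.gene_ids, n_folds, seed)
    n, p = spatial.n_cells, spatial.n_genes
    values = np.empty((n, p))
    fold_id = np.empty(p, dtype=int)
    col = {g: j for j, g in enumerate(spatial.gene_ids)}
    for f in range(n_folds):
        held_out = plan.fold_genes(f)
        # canonical order: the training panel (hence the joint embedding)
        # is identical whatever the input gene order
        train = sorted(g for g in spatial.gene_ids if plan.assignment[g] != f)
        try:
            pred = predictor(spatial.subset_genes(train), reference, held_out)
        except Exception as exc:  # pragma: no cover - context for plug-ins
            raise RuntimeError(f"predictor failed on fold {f}: {exc}") from exc
        for j, g in enumerate(pred.gene_ids):
            values[:, col[g]] = pred.values[:, j]
            fold_id[col[g]] = f
    return PredictionMatrix(
        values,
        list(spatial.gene_ids),
        source=getattr(predictor, "__name__", "predictor") + "+cv",
        fold_id=fold_id,
        cell_ids=list(spatial.cell_ids),
    )
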