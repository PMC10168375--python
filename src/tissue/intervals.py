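"""Conformal quantile retrieval, asymmetric prediction intervals, coverage.

For confidence level 1 - alpha the interval for cell i, gene j is

    [ Xhat_ij - U_ij * q_alpha^(l),  Xhat_ij + U_ij * q_alpha^(u) ]

where q_alpha^(l/u) is the ceil((n+1)(1-alpha))/n-th quantile (an order
statistic, no interpolation) of the lower/upper calibration-score set of the
entry's stratified group. Lower bounds are never clipped at zero: predictions
may live on transformed scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import SIDE_LOWER, SIDE_UPPER, CalibrationModel
from .core_data import PredictionMatrix, SpatialDataset
from .uncertainty import VariabilityMatrix

__all__ = [
    "IntervalSet",
    "CoverageCurve",
    "conformal_quantile",
    "build_intervals",
    "coverage_curve",
    "default_alpha_grid",
    "write_intervals",
    "write_coverage",
]


def default_alpha_grid() -> np.ndarray:
    """Evaluation grid alpha = 0.02, 0.04, ..., 0.98."""
    return np.round(np.arange(0.02, 0.99, 0.02), 10)


def conformal_quantile(scores: np.ndarray | Sequence[float], alpha: float) -> float:
    """The r-th smallest score with r = clamp(ceil((n+1)(1-alpha)), 1, n)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("empty calibration score set")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    r = int(np.ceil((n + 1) * (1.0 - alpha)))
    r = min(max(r, 1), n)
    return float(np.partition(scores, r - 1)[r - 1])


@dataclass
class IntervalSet:
    """Asymmetric prediction intervals at confidence 1 - alpha."""

    alpha: float
    lower: np.ndarray  # (n_cells, n_genes)
    upper: np.ndarray
    q_lower: dict[tuple[int, int], float]
    q_upper: dict[tuple[int, int], float]
    gene_ids: list[str] | None = None
    cell_ids: list[str] | None = None

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def build_intervals(
    pred: PredictionMatrix,
    U: VariabilityMatrix,
    model: CalibrationModel,
    alpha: float,
) -> IntervalSet:
    """Intervals for every entry of ``pred`` from group-specific quantiles.

    Genes (and cells) outside the calibration panel are assigned to the
    stratified group with the nearest stratification centroid.
    """
    Uv = np.asarray(U.values, dtype=float)
    if Uv.shape != pred.values.shape:
        raise ValueError("variability and prediction shapes disagree")
    G, C = model.assign(pred)
    q_l = np.empty_like(pred.values)
    q_u = np.empty_like(pred.values)
    q_lower, q_upper = {}, {}
    for g, c in model.groups():
        mask = (G == g) & (C == c)
        ql = conformal_quantile(model.effective_scores(g, c, SIDE_LOWER), alpha)
        qu = conformal_quantile(model.effective_scores(g, c, SIDE_UPPER), alpha)
        q_lower[(g, c)], q_upper[(g, c)] = ql, qu
        if mask.any():
            q_l[mask] = ql
            q_u[mask] = qu
    return IntervalSet(
        alpha=float(alpha),
        lower=pred.values - Uv * q_l,
        upper=pred.values + Uv * q_u,
        q_lower=q_lower,
        q_upper=q_upper,
        gene_ids=list(pred.gene_ids),
        cell_ids=list(pred.cell_ids) if pred.cell_ids is not None else None,
    )


@dataclass
class CoverageCurve:
    """Empirical coverage as a function of alpha, plus its calibration error."""

    alphas: np.ndarray
    empirical: np.ndarray
    calibration_error: float


def coverage_curve(
    measured_heldout: SpatialDataset | np.ndarray,
    intervals_by_alpha: Mapping[float, IntervalSet] | Sequence[IntervalSet],
) -> CoverageCurve:
    """Empirical coverage per alpha and the area-based calibration error.

    ``empirical(alpha)`` is the fraction of held-out measured values inside
    their interval; the calibration error is the trapezoidal integral over
    the alpha grid of |empirical(alpha) - (1 - alpha)|.
    """
    if isinstance(intervals_by_alpha, Mapping):
        items = sorted(intervals_by_alpha.items())
    else:
        items = sorted((iv.alpha, iv) for iv in intervals_by_alpha)
    alphas = np.array([a for a, _ in items], dtype=float)
    if alphas.size >= 2 and np.any(np.diff(alphas) <= 0):
        raise ValueError("alpha grid must be strictly increasing")
    X = (
        measured_heldout.values
        if isinstance(measured_heldout, SpatialDataset)
        else np.asarray(measured_heldout, dtype=float)
    )
    empirical = np.array(
        [np.mean((X >= iv.lower) & (X <= iv.upper)) for _, iv in items]
    )
    err = (
        float(np.trapezoid(np.abs(empirical - (1.0 - alphas)), alphas))
        if alphas.size >= 2
        else float(np.abs(empirical - (1.0 - alphas)).item())
    )
    return CoverageCurve(alphas, empirical, err)


def write_intervals(iv: IntervalSet, pred: PredictionMatrix, path: str | Path) -> None:
    """Long-format TSV: (cell_id, gene_id, pred, lower, upper, alpha)."""
    n, p = pred.values.shape
    cells = iv.cell_ids if iv.cell_ids is not None else [str(i) for i in range(n)]
    genes = iv.gene_ids if iv.gene_ids is not None else list(pred.gene_ids)
    pd.DataFrame(
        {
            "cell_id": np.repeat(cells, p),
            "gene_id": np.tile(genes, n),
            "pred": pred.values.ravel(),
            "lower": iv.lower.ravel(),
            "upper": iv.upper.ravel(),
            "alpha": iv.alpha,
        }
    ).to_csv(path, sep="\t", index=False)


def write_coverage(curve: CoverageCurve, path: str | Path) -> None:
    pd.DataFrame({"alpha": curve.alphas, "empirical": curve.empirical}).to_csv(
        path, sep="\t", index=False
    )
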