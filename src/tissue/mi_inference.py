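"""Multiple-imputation sampling and uncertainty-aware hypothesis testing.

Plausible alternative predictions are generated by resampling calibration
scores: for each cell-gene entry a score s is drawn uniformly from the union
of its group's lower and upper sets (each side truncated at its own 80%
conformal quantile to temper outliers) and the prediction is perturbed by
delta * s * U, with delta = +1 for upper-set draws and -1 for lower-set
draws. The unperturbed prediction is imputation 1 of the D imputations.

Inference then pools within- and between-imputation variability (Rubin's
rules) in a modified two-sample t-test, or — for arbitrary per-imputation
tests such as rank-sum — combines per-imputation p-values through a probit
transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calibration import SIDE_LOWER, SIDE_UPPER, CalibrationModel
from .core_data import PredictionMatrix
from .intervals import conformal_quantile
from .uncertainty import VariabilityMatrix

__all__ = [
    "ImputationEnsemble",
    "MITestResult",
    "CombinedPValue",
    "sample_imputations",
    "mi_ttest",
    "mi_combine_pvalues",
    "mi_pvalue_hook",
    "de_scan",
]

_P_EPS = 1e-300


@dataclass
class ImputationEnsemble:
    """D perturbed copies of a prediction matrix for MI inference.

    Imputations are regenerated deterministically from per-imputation child
    seeds rather than stored, so D can be large without holding D matrices
    in memory; ``imputation(0)`` is the unperturbed prediction.
    """

    pred: PredictionMatrix
    U: VariabilityMatrix
    D: int
    seed: int
    truncation_alpha: float = 0.2
    # per-group pools of (score, sign) pairs, and entry membership
    _pool_scores: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _pool_signs: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _entries: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _child_seeds: list = field(default_factory=list, repr=False)

    def perturbation(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        """Sampled scores S^(d) and signs delta^(d) for imputation d >= 1."""
        if not 1 <= d < self.D:
            raise IndexError(f"perturbed imputations are 1..{self.D - 1}")
        rng = np.random.default_rng(self._child_seeds[d - 1])
        shape = self.pred.values.shape
        S = np.zeros(shape).ravel()
        delta = np.zeros(shape).ravel()
        for gid in sorted(self._entries):
            idx = self._entries[gid]
            draws = rng.integers(0, self._pool_scores[gid].size, size=idx.size)
            S[idx] = self._pool_scores[gid][draws]
            delta[idx] = self._pool_signs[gid][draws]
        return S.reshape(shape), delta.reshape(shape)

    def imputation(self, d: int) -> np.ndarray:
        """The d-th imputation (0-based; d = 0 is the original prediction)."""
        if d == 0:
            return self.pred.values
        S, delta = self.perturbation(d)
        return self.pred.values + delta * S * self.U.values

    def __iter__(self) -> Iterator[np.ndarray]:
        return (self.imputation(d) for d in range(self.D))

    @property
    def imputations(self) -> list[np.ndarray]:
        """All D imputations, materialized."""
        return [self.imputation(d) for d in range(self.D)]


def sample_imputations(
    pred: PredictionMatrix,
    U: VariabilityMatrix,
    model: CalibrationModel,
    D: int,
    seed: int = 0,
) -> ImputationEnsemble:
    """Build a D-imputation ensemble from a calibration model.

    Each cell-gene entry samples independently, with replacement, from the
    union of its stratified group's lower and upper score sets; each side is
    pre-truncated at its own conformal quantile for alpha = 0.2 (the 80%
    prediction interval) before pooling.
    """
    if D < 2:
        raise ValueError("D must be >= 2 (between-imputation variance needs it)")
    ens = ImputationEnsemble(pred=pred, U=U, D=D, seed=seed)
    G, C = model.assign(pred)
    flat_gid = ((G - 1) * model.k_c + (C - 1)).ravel()
    for g, c in model.groups():
        gid = (g - 1) * model.k_c + (c - 1)
        idx = np.flatnonzero(flat_gid == gid)
        if idx.size == 0:
            continue
        lo = model.effective_scores(g, c, SIDE_LOWER)
        up = model.effective_scores(g, c, SIDE_UPPER)
        lo = lo[lo <= conformal_quantile(lo, ens.truncation_alpha)]
        up = up[up <= conformal_quantile(up, ens.truncation_alpha)]
        ens._pool_scores[gid] = np.concatenate([lo, up])
        ens._pool_signs[gid] = np.concatenate(
            [-np.ones(lo.size), np.ones(up.size)]
        )
        ens._entries[gid] = idx
    ens._child_seeds = list(np.random.SeedSequence(seed).spawn(D - 1))
    return ens


# ---------------------------------------------------------------------------
# modified two-sample t-test under multiple imputation
# ---------------------------------------------------------------------------

@dataclass
class MITestResult:
    mu_MI: float
    s_W2: float
    s_B2: float
    s_MI2: float
    t_MI: float
    df: float
    p: float
    n_A: int
    n_B: int


def _group_stats(
    M: np.ndarray, A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean difference and pooled-variance term for one imputation."""
    nA, nB = A.size, B.size
    mu = M[A].mean(axis=0) - M[B].mean(axis=0)
    varA = M[A].var(axis=0, ddof=1)
    varB = M[B].var(axis=0, ddof=1)
    pooled = ((nA - 1) * varA + (nB - 1) * varB) / (nA + nB - 2)
    return mu, (1.0 / nA + 1.0 / nB) * pooled


def _mi_from_stats(
    mu_d: np.ndarray, s2_d: np.ndarray, n_A: int, n_B: int
) -> tuple[np.ndarray, ...]:
    """Pool per-imputation stats (D, p) into MI statistics, vectorised."""
    D = mu_d.shape[0]
    mu_MI = mu_d.mean(axis=0)
    s_W2 = s2_d.mean(axis=0)
    s_B2 = mu_d.var(axis=0, ddof=1)
    s_MI2 = s_W2 + (1.0 + 1.0 / D) * s_B2

    t = np.zeros_like(mu_MI)
    df = np.zeros_like(mu_MI)
    p = np.ones_like(mu_MI)

    degenerate = s_B2 <= 0
    ok = ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = mu_MI[ok] / np.sqrt(s_MI2[ok])
        df[ok] = (D - 1) * (1.0 + D * s_W2[ok] / ((D + 1) * s_B2[ok])) ** 2
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])

    # all imputations identical -> classical pooled two-sample t-test on
    # the original prediction
    if degenerate.any():
        d0_mu, d0_s2 = mu_d[0, degenerate], s2_d[0, degenerate]
        dfd = float(n_A + n_B - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            td = np.where(d0_s2 > 0, d0_mu / np.sqrt(d0_s2), 0.0)
            td = np.where((d0_s2 <= 0) & (d0_mu != 0), np.inf * np.sign(d0_mu), td)
        pd_ = np.where(
            (d0_s2 <= 0) & (d0_mu == 0), 1.0, 2.0 * stats.t.sf(np.abs(td), dfd)
        )
        t[degenerate] = td
        df[degenerate] = dfd
        p[degenerate] = pd_
    return mu_MI, s_W2, s_B2, s_MI2, t, df, np.clip(p, 0.0, 1.0)


def mi_ttest(
    ensemble: ImputationEnsemble,
    gene: str | int,
    group_A: Sequence[int] | np.ndarray,
    group_B: Sequence[int] | np.ndarray,
) -> MITestResult:
    """Modified two-sample t-test for one gene between cell sets A and B.

    Per imputation d the classical mean difference mu_d and variance s_d^2
    are computed; across imputations the within- (s_W^2) and between-
    imputation (s_B^2) variances are pooled into
    s_MI^2 = s_W^2 + (1 + 1/D) s_B^2 and
    t = mu_MI / sqrt(s_MI^2) with
    df = (D-1) (1 + D s_W^2 / ((D+1) s_B^2))^2; the p-value is two-sided.
    When s_B^2 = 0 the test degenerates to the classical pooled t-test on
    the original prediction with df = n_A + n_B - 2.
    """
    j = ensemble.pred.gene_ids.index(gene) if isinstance(gene, str) else int(gene)
    A = np.asarray(group_A, dtype=int)
    B = np.asarray(group_B, dtype=int)
    if A.size < 2 or B.size < 2:
        raise ValueError("both groups need at least 2 cells")
    if np.intersect1d(A, B).size:
        raise ValueError("groups A and B must be disjoint")
    mu_d = np.empty((ensemble.D, 1))
    s2_d = np.empty((ensemble.D, 1))
    for d in range(ensemble.D):
        col = ensemble.imputation(d)[:, [j]]
        mu_d[d], s2_d[d] = _group_stats(col, A, B)
    mu, sW2, sB2, sMI2, t, df, p = _mi_from_stats(mu_d, s2_d, A.size, B.size)
    return MITestResult(
        mu_MI=float(mu[0]),
        s_W2=float(sW2[0]),
        s_B2=float(sB2[0]),
        s_MI2=float(sMI2[0]),
        t_MI=float(t[0]),
        df=float(df[0]),
        p=float(p[0]),
        n_A=int(A.size),
        n_B=int(B.size),
    )


# ---------------------------------------------------------------------------
# probit combination of per-imputation p-values
# ---------------------------------------------------------------------------

@dataclass
class CombinedPValue:
    p_values: np.ndarray
    transformed: np.ndarray
    z_MI: float
    p_MI: float


def _combine_matrix(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise probit combination of an (m, p) p-value matrix."""
    if np.any((P <= 0) | (P >= 1)):
        warnings.warn("p-values at 0 or 1 clamped before probit transform")
    P = np.clip(P, _P_EPS, 1.0 - 1e-16)
    z = stats.norm.ppf(P)
    z_MI = z.mean(axis=0) / np.sqrt(1.0 + z.var(axis=0, ddof=1))
    return z_MI, stats.norm.cdf(z_MI)


def mi_combine_pvalues(p_list: Sequence[float] | np.ndarray) -> CombinedPValue:
    """Combine per-imputation p-values via the probit transform.

    p~_i = probit(p_i); z_MI = mean(p~) / sqrt(1 + Var(p~));
    p_MI = inverse-probit(z_MI). Constant inputs are returned unchanged.
    """
    P = np.asarray(p_list, dtype=float)
    if P.ndim != 1 or P.size < 2:
        raise ValueError("need at least 2 p-values to combine")
    z_MI, p_MI = _combine_matrix(P[:, None])
    transformed = stats.norm.ppf(np.clip(P, _P_EPS, 1.0 - 1e-16))
    return CombinedPValue(
        p_values=P, transformed=transformed, z_MI=float(z_MI[0]), p_MI=float(p_MI[0])
    )


def mi_pvalue_hook(
    ensemble: ImputationEnsemble,
    test: Callable[[np.ndarray], float],
) -> CombinedPValue:
    """Run an arbitrary per-imputation test and combine its p-values.

    ``test`` receives one imputation matrix (cells x genes) and returns a
    single p-value — e.g. a spatially-variable-gene test closed over the
    cell coordinates.
    """
    ps = [float(test(ensemble.imputation(d))) for d in range(ensemble.D)]
    return mi_combine_pvalues(ps)


# ---------------------------------------------------------------------------
# one-vs-all differential expression scan
# ---------------------------------------------------------------------------

def de_scan(
    ensemble: ImputationEnsemble,
    labels: Sequence | np.ndarray,
    mode: str = "ttest",
    fdr: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-versus-all differential expression over all genes and labels.

    ``mode="ttest"`` runs the MI-modified t-test of each label's cells
    against the rest; ``mode="rank"`` runs a one-sided rank-sum test per
    imputation and combines p-values with the probit rule. Within each
    label, p-values are Benjamini-Hochberg corrected across genes and
    ``significant`` marks q <= fdr.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != ensemble.pred.n_cells:
        raise ValueError("labels must align with the prediction's cells")
    uniq = [l for l in pd.unique(labels)]
    if len(uniq) < 2:
        raise ValueError("need at least 2 labels for a one-vs-all scan")
    if mode not in ("ttest", "rank"):
        raise ValueError(f"unknown mode {mode!r}")

    usable, groups = [], {}
    for lab in uniq:
        A = np.flatnonzero(labels == lab)
        if A.size < 2:
            warnings.warn(f"label {lab!r} has < 2 cells; skipped")
            continue
        usable.append(lab)
        groups[lab] = (A, np.flatnonzero(labels != lab))

    p_genes = ensemble.pred.n_genes
    stat = {lab: None for lab in usable}
    pval = {}
    if mode == "ttest":
        mu_d = {lab: np.empty((ensemble.D, p_genes)) for lab in usable}
        s2_d = {lab: np.empty((ensemble.D, p_genes)) for lab in usable}
        for d in range(ensemble.D):
            M = ensemble.imputation(d)
            for lab in usable:
                A, B = groups[lab]
                mu_d[lab][d], s2_d[lab][d] = _group_stats(M, A, B)
        for lab in usable:
            A, B = groups[lab]
            *_, t, _df, p = _mi_from_stats(mu_d[lab], s2_d[lab], A.size, B.size)
            stat[lab], pval[lab] = t, p
    else:
        P = {lab: np.empty((ensemble.D, p_genes)) for lab in usable}
        for d in range(ensemble.D):
            M = ensemble.imputation(d)
            for lab in usable:
                A, B = groups[lab]
                res = stats.mannwhitneyu(M[A], M[B], alternative=alternative, axis=0)
                P[lab][d] = res.pvalue
        for lab in usable:
            z_MI, p_MI = _combine_matrix(P[lab])
            stat[lab], pval[lab] = z_MI, p_MI

    frames = []
    for lab in usable:
        q = multipletests(pval[lab], method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "gene": ensemble.pred.gene_ids,
                    "label": lab,
                    "statistic": stat[lab],
                    "p": pval[lab],
                    "q": q,
                    "significant": q <= fdr,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
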