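"""Hermetic spatial-count simulator with prediction-bias injection.

Emulates a reference-free zero-inflated negative binomial (ZINB) spatial
simulation: cells scattered uniformly in the unit square, split into two
groups 'A' and 'B' by a linear boundary, counts drawn from
ZINB(zero proportion 0.05, dispersion 0.5, mean 2) with an optional planted
fold change in group B. "Predicted" expression is then manufactured by
corrupting the ground truth with either

* shifted Gaussian prediction error — N(mu, 1) noise on half the genes in
  group B, N(0, 1) everywhere else (a differential-expression false-positive
  stress test: the truth has no group difference), or
* mix-in bias — a fraction of group-A cells have their predictions replaced,
  gene-wise, by uniform draws from group-B truth values (cell-identity
  corruption that degrades clustering and visualisation).

The NB is parameterised by mean m and size r = dispersion, so
variance = m + m^2 / r. Cells are ordered by their position along the
boundary normal (group A first), so a cell index maps to the same group in
every seeded replicate of a design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import PredictionMatrix, SpatialDataset

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_counts",
    "inject_de_bias",
    "inject_mixin",
    "de_design",
    "mixin_design",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults follow the two-group ZINB design."""

    n_cells: int = 980
    n_genes: int = 1000
    zero_prop: float = 0.05
    dispersion: float = 0.5
    mean: float = 2.0
    boundary_normal: tuple[float, float] = (1.0, 0.0)  # vertical split line
    n_group_a: int = 465
    de_fraction: float = 0.0  # fraction of genes with a planted fold change
    log_fc: float = 0.0  # group-B mean is mean * 2**log_fc for those genes
    bias_mu: float = 0.0
    mixin_prop: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_prop <= 1.0:
            raise ValueError("zero_prop must be in [0, 1]")
        if self.mean <= 0 or self.dispersion <= 0:
            raise ValueError("mean and dispersion must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.mixin_prop <= 1.0:
            raise ValueError("mixin_prop must be in [0, 1]")
        if self.bias_mu < 0:
            raise ValueError("bias_mu must be >= 0")


def de_design(seed: int = 0, bias_mu: float = 0.0) -> SimConfig:
    """Null two-group design: 465 'A' + 515 'B' cells, 1000 genes, no true
    expression difference; bias_mu controls the injected prediction bias."""
    return SimConfig(n_group_a=465, de_fraction=0.0, log_fc=0.0,
                     bias_mu=bias_mu, seed=seed)


def mixin_design(seed: int = 0, mixin_prop: float = 0.5) -> SimConfig:
    """Two-cluster design: 476 'A' + 504 'B' cells, 500 signal genes with a
    doubled fold change in 'B' plus 500 noise genes; mixin_prop controls the
    fraction of 'A' cells whose predictions mimic 'B'."""
    return SimConfig(n_group_a=476, de_fraction=0.5, log_fc=1.0,
                     mixin_prop=mixin_prop, seed=seed)


@dataclass
class SimOutput:
    """Ground truth plus (optionally) the corrupted 'predicted' matrix."""

    truth: SpatialDataset
    group: dict[str, str]  # cell_id -> 'A' | 'B'
    config: SimConfig
    predicted: PredictionMatrix | None = None
    biased_genes: set[str] = field(default_factory=set)
    signal_genes: set[str] = field(default_factory=set)
    mixed_cells: list[str] = field(default_factory=list)

    @property
    def group_array(self) -> np.ndarray:
        return np.asarray([self.group[c] for c in self.truth.cell_ids], dtype=object)


def simulate_counts(config: SimConfig) -> SimOutput:
    """Draw coordinates, group assignment and ZINB counts.

    Cells are uniform in the unit square; the ``n_group_a`` cells lowest
    along the boundary normal are group 'A' (a rank split along the normal,
    equivalent to a linear boundary placed to hit the exact group sizes).
    Genes in the planted-fold-change set have NB mean
    ``mean * 2**log_fc`` in group B instead of ``mean``.
    """
    n, p = config.n_cells, config.n_genes
    if not 2 <= config.n_group_a <= n - 2:
        raise ValueError("the boundary must assign at least 2 cells per group")
    rng = np.random.default_rng(config.seed)
    coords = rng.uniform(size=(n, 2))
    normal = np.asarray(config.boundary_normal, dtype=float)
    proj = coords @ normal
    order = np.argsort(proj, kind="stable")
    coords = coords[order]
    is_b = np.arange(n) >= config.n_group_a

    n_de = int(round(config.de_fraction * p))
    de_genes = rng.choice(p, size=n_de, replace=False) if n_de else np.array([], int)
    mean = np.full((n, p), config.mean)
    mean[np.ix_(is_b, de_genes)] = config.mean * 2.0**config.log_fc

    r = config.dispersion  # NB size; variance = m + m^2 / r
    counts = rng.negative_binomial(r, r / (r + mean)).astype(float)
    counts[rng.uniform(size=(n, p)) < config.zero_prop] = 0.0

    cell_ids = [f"cell{i}" for i in range(n)]
    gene_ids = [f"gene{j}" for j in range(p)]
    group = {c: ("B" if b else "A") for c, b in zip(cell_ids, is_b)}
    truth = SpatialDataset(counts, coords, cell_ids, gene_ids, labels=dict(group))
    return SimOutput(
        truth=truth, group=group, config=config,
        signal_genes={gene_ids[j] for j in de_genes},
    )


def inject_de_bias(sim: SimOutput, bias_mu: float, seed: int = 0) -> SimOutput:
    """Corrupt the truth with shifted Gaussian prediction error.

    A seeded half of the genes (floor(p/2)) receives N(bias_mu, 1) noise in
    group-B cells; every other entry receives N(0, 1). The result mimics a
    predictor that is systematically biased for one cell group.
    """
    truth = sim.truth
    n, p = truth.n_cells, truth.n_genes
    rng = np.random.default_rng(seed)
    biased = rng.choice(p, size=p // 2, replace=False)
    noise = rng.standard_normal((n, p))
    is_b = sim.group_array == "B"
    noise[np.ix_(is_b, biased)] += bias_mu
    pred = PredictionMatrix(
        truth.values + noise, list(truth.gene_ids), source="sim+de_bias",
        cell_ids=list(truth.cell_ids),
    )
    out = replace_sim(sim, predicted=pred,
                      biased_genes={truth.gene_ids[j] for j in biased})
    return out


def inject_mixin(sim: SimOutput, mixin_prop: float, seed: int = 0) -> SimOutput:
    """Corrupt the truth with group-B mix-in bias on a fraction of A cells.

    ``round(mixin_prop * n_A)`` group-A cells are selected; every gene of a
    selected cell is replaced by a uniform draw from the group-B truth
    values of that gene. All non-replaced entries receive N(0, 1) noise.
    """
    if not 0.0 <= mixin_prop <= 1.0:
        raise ValueError("mixin_prop must be in [0, 1]")
    truth = sim.truth
    n, p = truth.n_cells, truth.n_genes
    rng = np.random.default_rng(seed)
    grp = sim.group_array
    a_idx = np.flatnonzero(grp == "A")
    b_idx = np.flatnonzero(grp == "B")
    n_mix = int(round(mixin_prop * a_idx.size))
    mixed = rng.choice(a_idx, size=n_mix, replace=False)

    values = truth.values + rng.standard_normal((n, p))
    if n_mix:
        Vb = truth.values[b_idx]
        draws = rng.integers(0, b_idx.size, size=(n_mix, p))
        values[mixed] = Vb[draws, np.arange(p)]
    pred = PredictionMatrix(
        values, list(truth.gene_ids), source="sim+mixin",
        cell_ids=list(truth.cell_ids),
    )
    return replace_sim(sim, predicted=pred,
                       mixed_cells=[truth.cell_ids[i] for i in sorted(mixed)])


def replace_sim(sim: SimOutput, **kw) -> SimOutput:
    out = SimOutput(truth=sim.truth, group=sim.group, config=sim.config,
                    predicted=sim.predicted, biased_genes=set(sim.biased_genes),
                    signal_genes=set(sim.signal_genes),
                    mixed_cells=list(sim.mixed_cells))
    for k, v in kw.items():
        setattr(out, k, v)
    return out
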