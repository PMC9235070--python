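"""Synthetic data generators.

Three generators cover the study designs used throughout the package:

* :func:`simulate_mixture` — the 10-gene / 500-cell / 5-population tumor
  mixture toy.  Population *i* has centroid ``c_i`` with ``1/sqrt(2)`` in
  components ``2i-1`` and ``2i`` and zeros elsewhere (unit norm, pairwise
  orthogonal); each cell is its population centroid plus i.i.d. Gaussian
  noise of standard deviation sigma.  The 500 cells are allocated to five
  tumors in three cases of increasing intra-tumoral heterogeneity:
  case 1 — each tumor is one pure population; case 2 — 60 cells from one
  population plus 10 from each of the other four; case 3 — 20 cells from
  every population in every tumor.

* :func:`simulate_hierarchy_suite` — several datasets over a common gene
  universe with planted co-expression blocks, some shared between datasets
  (the ground truth for meta gene clusters) and some private to a single
  dataset (expected to end up as orphans).  Genes in a block load on a
  per-block latent factor so that gene clustering recovers the blocks.

* :func:`simulate_bulk_survival` — bulk expression with one planted
  coherent block (genes share a latent factor with a target pairwise
  correlation) and exponential survival times whose log-hazard is
  proportional to that factor, censored at a fixed quantile.

All generators are deterministic given their seed; population-to-tumor
allocation in the mixture is a fixed slicing so that only the Gaussian
noise consumes random draws.
"""

from __future__ import annotations

import dataclasses
import numpy as np

from .io_preprocess import ExpressionMatrix, SurvivalTable

__all__ = [
    "MixtureSimConfig",
    "simulate_mixture",
    "HierarchySuite",
    "simulate_hierarchy_suite",
    "simulate_bulk_survival",
]


@dataclasses.dataclass
class MixtureSimConfig:
    """Configuration of the tumor-mixture toy data."""

    case: int = 1
    sigma: float = 0.1
    n_genes: int = 10
    n_populations: int = 5
    cells_per_population: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case not in (1, 2, 3):
            raise ValueError(f"case must be 1, 2 or 3, got {self.case}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_genes < 2 * self.n_populations:
            raise ValueError("need at least two genes per population centroid")
        if self.case == 2 and self.cells_per_population % 10:
            raise ValueError("case 2 requires cells_per_population divisible by 10")
        if self.case == 3 and self.cells_per_population % self.n_populations:
            raise ValueError(
                "case 3 requires cells_per_population divisible by n_populations"
            )


def _centroids(n_populations: int, n_genes: int) -> np.ndarray:
    C = np.zeros((n_populations, n_genes))
    for i in range(n_populations):
        C[i, 2 * i] = C[i, 2 * i + 1] = 1.0 / np.sqrt(2.0)
    return C


def _allocate(cfg: MixtureSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Population label and tumor index per cell, in fixed deterministic order."""
    P, per = cfg.n_populations, cfg.cells_per_population
    pop = np.repeat(np.arange(P), per)
    tumor = np.empty(P * per, dtype=int)
    idx = [np.flatnonzero(pop == p) for p in range(P)]
    if cfg.case == 1:
        for p in range(P):
            tumor[idx[p]] = p
    elif cfg.case == 2:
        # 60% of a population stays home, the rest is spread evenly
        home = int(round(per * 0.6))
        away = (per - home) // (P - 1)
        for p in range(P):
            ids = idx[p]
            tumor[ids[:home]] = p
            others = [t for t in range(P) if t != p]
            for j, t in enumerate(others):
                tumor[ids[home + j * away : home + (j + 1) * away]] = t
    else:
        share = per // P
        for p in range(P):
            ids = idx[p]
            for t in range(P):
                tumor[ids[t * share : (t + 1) * share]] = t
    return pop, tumor


def simulate_mixture(cfg: MixtureSimConfig) -> ExpressionMatrix:
    """Generate the tumor-mixture toy data for one case and noise level.

    The returned matrix is fully observed; tumor labels are ``T1..T5`` and
    the ground-truth population of each cell is kept in ``cell_type_of`` as
    ``pop1..pop5``.
    """
    rng = np.random.default_rng(cfg.seed)
    C = _centroids(cfg.n_populations, cfg.n_genes)
    pop, tumor = _allocate(cfg)
    n = pop.size
    X = C[pop] + rng.normal(0.0, cfg.sigma, size=(n, cfg.n_genes))
    cells = [f"cell{i+1}" for i in range(n)]
    genes = [f"g{j+1}" for j in range(cfg.n_genes)]
    tumor_of = {c: f"T{tumor[i]+1}" for i, c in enumerate(cells)}
    pop_of = {c: f"pop{pop[i]+1}" for i, c in enumerate(cells)}
    return ExpressionMatrix(
        genes, cells, X.T, np.ones((cfg.n_genes, n), dtype=bool), tumor_of, pop_of
    )


# ---------------------------------------------------------------------------
# multi-dataset hierarchy suite with planted shared blocks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HierarchySuite:
    """Datasets with planted gene blocks and their ground truth.

    ``blocks`` maps block name -> gene set; ``block_datasets`` maps block
    name -> indices of the datasets where the block is active (co-expressed).
    """

    datasets: list[ExpressionMatrix]
    blocks: dict[str, set[str]]
    block_datasets: dict[str, list[int]]

    def shared_blocks(self) -> dict[str, set[str]]:
        return {
            name: genes
            for name, genes in self.blocks.items()
            if len(self.block_datasets[name]) >= 2
        }

    def private_blocks(self) -> dict[str, set[str]]:
        return {
            name: genes
            for name, genes in self.blocks.items()
            if len(self.block_datasets[name]) == 1
        }


def simulate_hierarchy_suite(
    n_datasets: int = 3,
    n_genes: int | None = None,
    *,
    n_shared_blocks: int = 2,
    n_private_blocks: int = 1,
    block_size: int = 48,
    n_cells: int = 60,
    n_tumors: int = 3,
    block_rho: float = 0.4,
    sub_rho: float = 0.25,
    quarter_rho: float = 0.2,
    seed: int = 0,
) -> HierarchySuite:
    """Generate datasets over a common gene universe with planted blocks.

    Shared blocks are active (co-expressed) in every dataset; each dataset
    additionally has ``n_private_blocks`` blocks of its own.  Blocks are
    disjoint gene sets; remaining genes are independent background noise.

    Blocks are internally hierarchical, mirroring real co-expression
    modules: every gene of an active block loads on the block's latent
    factor (variance share ``block_rho``); each half of the block
    additionally loads on a half-specific factor (share ``sub_rho``) and
    each quarter on a quarter-specific factor (share ``quarter_rho``).
    Gene clustering therefore keeps the block together at coarse
    resolutions and progressively splits it at fine ones, so the block's
    lineage spans several distinct nodes (and edges) of the reduced
    hierarchy — the structure the cross-dataset alignment is designed to
    recover.

    Each dataset's matrix holds only the genes measured (and surviving
    filtering) in that dataset: the shared blocks, its own private blocks,
    and — when ``n_genes`` exceeds the planted total — a leftover pool of
    genes present in every dataset but grouped into *filler* blocks with a
    random dataset-specific grouping.  Real transcriptomes have
    co-expression structure in essentially every retained gene; fully
    unstructured noise genes would produce chaotic, heavily cross-linked
    cluster hierarchies unlike any real dataset.  With the default
    ``n_genes=None`` the universe is exactly the planted blocks.
    """
    total_blocks = n_shared_blocks + n_datasets * n_private_blocks
    if n_genes is None:
        n_genes = total_blocks * block_size
    if total_blocks * block_size > n_genes:
        raise ValueError(
            f"{total_blocks} disjoint blocks of {block_size} genes exceed "
            f"{n_genes} genes"
        )
    if block_rho + sub_rho + quarter_rho >= 1.0:
        raise ValueError("block_rho + sub_rho + quarter_rho must stay below 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{j+1}" for j in range(n_genes)]
    blocks: dict[str, set[str]] = {}
    block_datasets: dict[str, list[int]] = {}
    cursor = 0
    for b in range(n_shared_blocks):
        name = f"shared{b+1}"
        blocks[name] = set(genes[cursor : cursor + block_size])
        block_datasets[name] = list(range(n_datasets))
        cursor += block_size
    for d in range(n_datasets):
        for b in range(n_private_blocks):
            name = f"private_d{d+1}_{b+1}"
            blocks[name] = set(genes[cursor : cursor + block_size])
            block_datasets[name] = [d]
            cursor += block_size

    a = np.sqrt(block_rho)
    c = np.sqrt(sub_rho)
    q = np.sqrt(quarter_rho)
    noise_scale = np.sqrt(1.0 - block_rho - sub_rho - quarter_rho)
    datasets: list[ExpressionMatrix] = []
    gene_pos = {g: j for j, g in enumerate(genes)}
    def plant(X, ordered, rng):
        f_block = rng.normal(0.0, 1.0, size=X.shape[1])
        half = len(ordered) // 2
        for sub in (ordered[:half], ordered[half:]):
            f_sub = rng.normal(0.0, 1.0, size=X.shape[1])
            quarter = len(sub) // 2
            for piece in (sub[:quarter], sub[quarter:]):
                f_quarter = rng.normal(0.0, 1.0, size=X.shape[1])
                rows = [gene_pos[g] for g in piece]
                X[rows] = (
                    a * f_block[None, :]
                    + c * f_sub[None, :]
                    + q * f_quarter[None, :]
                    + noise_scale * X[rows]
                )

    planted = set().union(*blocks.values())
    leftovers = [g for g in genes if g not in planted]
    for d in range(n_datasets):
        X = rng.normal(0.0, 1.0, size=(n_genes, n_cells))
        tumor_idx = np.repeat(np.arange(n_tumors), int(np.ceil(n_cells / n_tumors)))[
            :n_cells
        ]
        active: set[str] = set()
        for name, members in blocks.items():
            if d in block_datasets[name]:
                plant(X, sorted(members, key=lambda g: gene_pos[g]), rng)
                active |= members
        # dataset-specific filler blocks over the leftover gene pool
        if leftovers:
            order = rng.permutation(len(leftovers))
            n_fillers = max(len(leftovers) // block_size, 1)
            for chunk in np.array_split(order, n_fillers):
                plant(X, [leftovers[i] for i in chunk], rng)
        measured = sorted(active | set(leftovers), key=lambda g: gene_pos[g])
        rows = [gene_pos[g] for g in measured]
        cells = [f"D{d+1}c{i+1}" for i in range(n_cells)]
        tumor_of = {c: f"P{tumor_idx[i]+1}" for i, c in enumerate(cells)}
        datasets.append(
            ExpressionMatrix(
                measured,
                cells,
                X[rows],
                np.ones((len(measured), n_cells), dtype=bool),
                tumor_of,
            )
        )
    return HierarchySuite(datasets, blocks, block_datasets)


# ---------------------------------------------------------------------------
# bulk expression + survival with a planted prognostic block
# ---------------------------------------------------------------------------

def simulate_bulk_survival(
    n_samples: int = 500,
    n_genes: int = 300,
    *,
    block_size: int = 40,
    block_rho: float = 0.6,
    hazard_beta: float = 0.0,
    censor_quantile: float = 0.8,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SurvivalTable, set[str]]:
    """Bulk expression with one coherent block tied to survival.

    The first ``block_size`` genes share a latent factor with target pairwise
    correlation ``block_rho``; survival times are exponential with log-hazard
    ``hazard_beta * factor`` and censored at the ``censor_quantile`` of the
    observed times.  Returns the matrix, the survival table and the planted
    block's gene set.
    """
    if not np.isfinite(hazard_beta):
        raise ValueError("hazard_beta must be finite")
    rng = np.random.default_rng(seed)
    f = rng.normal(0.0, 1.0, size=n_samples)
    X = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    a = np.sqrt(block_rho)
    X[:block_size] = a * f[None, :] + np.sqrt(1.0 - block_rho) * X[:block_size]
    rate = np.exp(hazard_beta * f)
    times = rng.exponential(1.0 / rate)
    cutoff = np.quantile(times, censor_quantile)
    event = times <= cutoff
    times = np.minimum(times, cutoff)
    genes = [f"B{j+1}" for j in range(n_genes)]
    samples = [f"s{i+1}" for i in range(n_samples)]
    matrix = ExpressionMatrix(
        genes,
        samples,
        X,
        np.ones_like(X, dtype=bool),
        {s: "bulk" for s in samples},
    )
    survival = SurvivalTable(samples, times, event)
    return matrix, survival, set(genes[:block_size])
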