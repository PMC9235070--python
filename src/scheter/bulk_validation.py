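"""Validation of single-cell gene clusters in bulk expression and survival data.

Three checks ask whether a gene cluster derived from single-cell data keeps
its meaning in bulk cohorts:

* **Expression coherence** — the distribution of pairwise Pearson
  correlations among the cluster's member genes is compared with the
  background distribution among randomly selected genes (default 8000, or
  all genes when fewer exist) using the p_diff statistic.  Positive values
  mean the cluster is more coherently co-expressed than background.

* **Prognostic association** — a univariate Cox proportional-hazards model
  is fitted per gene (Breslow tie handling); the member genes' coefficient
  distribution is compared with the all-gene background by p_diff.
  Positive deviation means member expression is associated with shorter
  survival.

* **Rank enrichment** — reduced clusters are sorted by either p_diff score;
  a random walk over the sorted list increments at each member of a meta
  cluster.  After normalization the walk is a CDF-like curve C1 compared
  against the straight line C0 joining its endpoints; enrichment of members
  near the top is scored by the classical one-sided Kolmogorov-Smirnov
  p-value ``exp(-2 n D+^2)`` on the n-cluster curves.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .heterogeneity import DEFAULT_EPSILON, DEFAULT_N_SAMPLES, p_diff
from .io_preprocess import ExpressionMatrix, SurvivalTable

__all__ = [
    "coherence_pdiff",
    "cox_coefficients",
    "cox_pdiff",
    "rank_enrichment",
]

DEFAULT_BACKGROUND_N = 8000


def _pairwise_correlations(values: np.ndarray) -> np.ndarray:
    """Upper-triangle Pearson correlations between rows, NaNs dropped."""
    R = np.corrcoef(values)
    iu = np.triu_indices(values.shape[0], k=1)
    r = R[iu]
    return r[np.isfinite(r)]


def coherence_pdiff(
    cluster_genes: Sequence[str],
    bulk: ExpressionMatrix,
    *,
    background_n: int = DEFAULT_BACKGROUND_N,
    epsilon: float = DEFAULT_EPSILON,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> float | None:
    """p_diff of member-gene pairwise correlations vs a random background.

    The background is ``background_n`` genes sampled once without
    replacement (all genes when the matrix is smaller).  Returns None with
    a warning when fewer than two member genes map into the matrix.
    """
    rng = np.random.default_rng(seed)
    present = [g for g in cluster_genes if g in set(bulk.genes)]
    if len(present) < 2:
        warnings.warn("fewer than two cluster genes present in the bulk matrix")
        return None
    idx = bulk.gene_index(present)
    member_r = _pairwise_correlations(bulk.values[idx])
    n_bg = min(background_n, bulk.n_genes)
    bg_idx = rng.choice(bulk.n_genes, size=n_bg, replace=False)
    background_r = _pairwise_correlations(bulk.values[bg_idx])
    return p_diff(member_r, background_r, epsilon=epsilon, n_samples=n_samples, seed=rng)


def cox_coefficients(
    bulk: ExpressionMatrix, survival: SurvivalTable
) -> tuple[pd.Series, int]:
    """Univariate Cox regression coefficient per gene.

    Fits one proportional-hazards model per gene on the bulk values with
    Breslow tie handling; genes whose fit fails to converge are skipped.
    Returns the coefficients (indexed by gene) and the skipped-fit count.
    """
    surv = survival.align(bulk.cells)
    base = pd.DataFrame(
        {"time": surv.time, "event": surv.event.astype(int)}, index=bulk.cells
    )
    coefs: dict[str, float] = {}
    skipped = 0
    for i, gene in enumerate(bulk.genes):
        df = base.copy()
        df["x"] = bulk.values[i]
        if df["x"].std(ddof=0) == 0:
            skipped += 1
            continue
        fitter = CoxPHFitter(baseline_estimation_method="breslow")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(df, duration_col="time", event_col="event")
            coefs[gene] = float(fitter.params_["x"])
        except (ConvergenceError, ValueError):
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} per-gene Cox fits skipped")
    return pd.Series(coefs, dtype=float), skipped


def cox_pdiff(
    cluster_genes: Sequence[str],
    bulk: ExpressionMatrix,
    survival: SurvivalTable,
    *,
    epsilon: float = DEFAULT_EPSILON,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    coefficients: pd.Series | None = None,
) -> float | None:
    """p_diff of member-gene Cox coefficients vs the all-gene background.

    ``coefficients`` may carry precomputed per-gene coefficients so the
    expensive fits are shared across clusters.  Cox coefficients are not
    bounded by [-1, 1]; both distributions are rescaled by the background's
    maximum absolute value before the p_diff estimate, with epsilon scaled
    identically, which leaves the statistic's meaning unchanged.
    """
    if coefficients is None:
        coefficients, _ = cox_coefficients(bulk, survival)
    member = coefficients.reindex([g for g in cluster_genes]).dropna()
    if len(member) < 2:
        warnings.warn("fewer than two member genes with Cox coefficients")
        return None
    background = coefficients.to_numpy()
    scale = np.abs(background).max()
    if scale == 0:
        return 0.0
    return p_diff(
        member.to_numpy() / scale,
        background / scale,
        epsilon=epsilon / scale,
        n_samples=n_samples,
        seed=seed,
    )


def rank_enrichment(
    member_clusters: Sequence,
    sorted_clusters: Sequence,
) -> tuple[float, float]:
    """One-sided KS enrichment of meta-cluster members near the top of a list.

    ``sorted_clusters`` is the full list of reduced clusters sorted by
    descending p_diff; ``member_clusters`` the meta cluster's members.  The
    member-count random walk, normalized to end at 1, is compared with the
    straight line joining its endpoints; returns ``(D_plus, p)`` where
    ``D_plus`` is the maximal positive deviation and ``p = exp(-2 n D+^2)``
    with n the number of clusters.
    """
    members = set(member_clusters)
    if not members:
        raise ValueError("meta cluster has no members")
    n = len(sorted_clusters)
    if not members <= set(sorted_clusters):
        raise ValueError("sorted list does not cover all member clusters")
    walk = np.cumsum([1 if c in members else 0 for c in sorted_clusters])
    total = walk[-1]
    c1 = walk / total
    c0 = np.arange(1, n + 1) / n
    d_plus = float(np.max(c1 - c0))
    p = float(np.exp(-2.0 * n * max(d_plus, 0.0) ** 2))
    return d_plus, min(p, 1.0)
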