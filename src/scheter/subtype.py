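"""Marker-panel extension and correlation-based subtype prediction.

A marker panel (PAM50-style) that separates bulk tumor subtypes loses power
in single-cell data, where many panel genes are sparsely observed.  The
panel is therefore extended with co-expressed companion genes: the panel is
subdivided into a few expression groups (consensus k-means, k=3 by
default); every non-panel gene's correlations with the panel are averaged
within each group; genes are ranked per bulk dataset by the maximum
group-level average correlation, and the genes appearing in the top-n list
of *both* reference datasets form the extended panel.

Cells are then classified by correlating their extended-panel expression
(pairwise-complete Pearson, so dropout entries are simply skipped) with
every sample of a subtype-labelled bulk reference and assigning the subtype
with the highest average correlation.  Cells whose best average correlation
stays at background level can be filtered with a threshold, and patients
are called by the plurality subtype of their classified cells.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import consensus_kmeans
from .io_preprocess import ExpressionMatrix

__all__ = [
    "SubtypeReference",
    "extend_panel",
    "predict_cell_subtype",
    "predict_cells",
    "predict_patient_subtype",
]


@dataclasses.dataclass
class SubtypeReference:
    """Subtype-labelled bulk reference expression over a marker panel."""

    matrix: ExpressionMatrix
    subtype_of: dict[str, str]          # sample -> subtype
    panel: list[str]

    def __post_init__(self) -> None:
        missing = [s for s in self.matrix.cells if s not in self.subtype_of]
        if missing:
            raise ValueError(f"reference samples without subtype: {missing[:5]}")
        present = set(self.matrix.genes)
        self.panel = [g for g in self.panel if g in present]
        if not self.panel:
            raise ValueError("no panel gene present in the reference matrix")

    @property
    def subtypes(self) -> list[str]:
        return sorted(set(self.subtype_of.values()))


def _group_average_correlations(
    bulk: ExpressionMatrix, panel: Sequence[str], groups: Mapping[str, int]
) -> pd.DataFrame:
    """Max-over-group average correlation of every non-panel gene with the panel."""
    panel = [g for g in panel if g in set(bulk.genes)]
    others = [g for g in bulk.genes if g not in set(panel)]
    pidx = bulk.gene_index(panel)
    oidx = bulk.gene_index(others)
    Z = bulk.values - bulk.values.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, ddof=0)
    sd[sd == 0] = np.nan
    Zn = Z / sd[:, None]
    corr = (Zn[oidx] @ Zn[pidx].T) / bulk.n_cells
    frame = pd.DataFrame(corr, index=others, columns=panel)
    out = {}
    for gid in sorted(set(groups.values())):
        cols = [g for g in panel if groups[g] == gid]
        if cols:
            out[gid] = frame[cols].mean(axis=1)
    return pd.DataFrame(out)


def extend_panel(
    panel: Sequence[str],
    bulk_a: ExpressionMatrix,
    bulk_b: ExpressionMatrix,
    *,
    n_groups: int = 3,
    top_n: int = 200,
    seed: int = 0,
) -> tuple[list[str], dict[str, int]]:
    """Companion genes co-expressed with the panel in both bulk datasets.

    Returns the extended gene list (intersection of both datasets' top-n
    non-panel genes by max group-level average correlation) and the panel's
    group labels.  Panel genes missing from a matrix are dropped with a
    warning.
    """
    present = set(bulk_a.genes) & set(bulk_b.genes)
    kept = [g for g in panel if g in present]
    dropped = [g for g in panel if g not in present]
    if dropped:
        warnings.warn(f"panel genes absent from a bulk matrix: {dropped[:5]}")
    if not kept:
        raise ValueError("no panel gene shared by both bulk matrices")
    labels = consensus_kmeans(bulk_a.subset_genes(kept), min(n_groups, len(kept)), seed=seed)
    groups = {g: int(l) for g, l in zip(kept, labels)}
    tops = []
    for bulk in (bulk_a, bulk_b):
        ranks = _group_average_correlations(bulk, kept, groups).max(axis=1)
        ranks = ranks.dropna().sort_values(ascending=False)
        tops.append(list(ranks.index[:top_n]))
    extended = [g for g in tops[0] if g in set(tops[1])]
    return extended, groups


def _pairwise_complete_corr(x: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    xs, ys = x[mask], y[mask]
    if xs.size < 3 or xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def predict_cell_subtype(
    cell_values: np.ndarray,
    cell_observed: np.ndarray,
    ref: SubtypeReference,
    min_shared: int = 3,
) -> tuple[str | None, dict[str, float]]:
    """Assign a cell to the subtype with the highest average correlation.

    ``cell_values``/``cell_observed`` are aligned with the reference panel
    order.  Correlations with every reference sample use only the cell's
    observed panel genes; the full per-subtype average-correlation vector is
    returned so a minimum-correlation filter can be applied downstream.
    Cells with fewer than ``min_shared`` observed panel genes are
    unclassified (None).
    """
    mask = np.asarray(cell_observed, dtype=bool)
    if mask.sum() < min_shared:
        return None, {}
    pidx = ref.matrix.gene_index(ref.panel)
    R = ref.matrix.values[pidx]
    x = np.asarray(cell_values, dtype=float)
    per_sample = np.array(
        [_pairwise_complete_corr(x, R[:, j], mask) for j in range(R.shape[1])]
    )
    avg: dict[str, float] = {}
    samples = ref.matrix.cells
    for subtype in ref.subtypes:
        cols = [j for j, s in enumerate(samples) if ref.subtype_of[s] == subtype]
        vals = per_sample[cols]
        vals = vals[np.isfinite(vals)]
        avg[subtype] = float(vals.mean()) if vals.size else np.nan
    if all(np.isnan(v) for v in avg.values()):
        return None, avg
    best = max((s for s in avg if np.isfinite(avg[s])), key=lambda s: avg[s])
    return best, avg


def predict_cells(
    sc: ExpressionMatrix, ref: SubtypeReference, min_corr: float | None = None
) -> pd.DataFrame:
    """Classify every cell of a single-cell matrix against the reference.

    Returns a frame indexed by cell with the call, the per-subtype average
    correlations and a ``passed`` flag for the ``min_corr`` filter (best
    average correlation strictly above the threshold).
    """
    shared = [g for g in ref.panel if g in set(sc.genes)]
    ref_shared = SubtypeReference(
        ref.matrix.subset_genes(shared), dict(ref.subtype_of), shared
    )
    idx = sc.gene_index(shared)
    rows = []
    for j, cell in enumerate(sc.cells):
        call, avg = predict_cell_subtype(
            sc.values[idx, j], sc.observed[idx, j], ref_shared
        )
        best = max((v for v in avg.values() if np.isfinite(v)), default=np.nan)
        row = {"cell": cell, "subtype": call, "best_corr": best}
        row.update({f"corr_{s}": avg.get(s, np.nan) for s in ref.subtypes})
        if min_corr is not None:
            row["passed"] = bool(np.isfinite(best) and best > min_corr)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell")


def predict_patient_subtype(
    cell_calls: pd.DataFrame, tumor_of: Mapping[str, str]
) -> pd.DataFrame:
    """Plurality subtype per tumor plus the subtype composition fractions.

    Unclassified cells are ignored; tumors with no classified cell are
    absent from the output.  A plurality tie is broken toward the subtype
    whose cells have the higher mean best-correlation and flagged as
    ambiguous.
    """
    rows = []
    frame = cell_calls.dropna(subset=["subtype"])
    for tumor in sorted({tumor_of[c] for c in frame.index}):
        cells = [c for c in frame.index if tumor_of[c] == tumor]
        sub = frame.loc[cells]
        counts = sub["subtype"].value_counts()
        top = counts[counts == counts.max()]
        ambiguous = len(top) > 1
        if ambiguous:
            means = {
                s: sub.loc[sub["subtype"] == s, "best_corr"].mean() for s in top.index
            }
            call = max(sorted(means), key=lambda s: means[s])
        else:
            call = top.index[0]
        fractions = (counts / counts.sum()).to_dict()
        rows.append(
            {
                "tumor": tumor,
                "subtype": call,
                "ambiguous": ambiguous,
                "n_cells": int(counts.sum()),
                **{f"frac_{s}": f for s, f in fractions.items()},
            }
        )
    return pd.DataFrame(rows).set_index("tumor")
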