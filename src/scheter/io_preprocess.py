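"""Expression-matrix containers, file I/O, and preprocessing.

The central container is :class:`ExpressionMatrix`: a gene x cell (or gene x
sample, for bulk data) real matrix together with an observation mask marking
dropout/missing entries and a cell -> tumor (patient) label map.  Input data
are assumed to be already depth-normalized (RPKM/FPKM-like); no count
normalization is performed here.

Preprocessing follows three steps commonly applied to sparse single-cell
expression tables:

* genes with more than a given fraction of missing entries are removed
  (default 70%, strict: a gene missing exactly 70% of its entries is kept);
* remaining missing entries are imputed, either with the per-gene mean over
  observed entries or with zeros;
* bulk matrices (fully observed) may be rank-transformed per gene to their
  empirical CDF values, which makes downstream correlation and regression
  statistics invariant to monotone per-gene distortions.

Supported file formats are delimited text (genes in rows, cells in columns),
Matrix-Market triplets plus side files of row/column names, GMT gene-set
collections, and delimited survival tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "SurvivalTable",
    "ParseError",
    "filter_sparse_genes",
    "impute",
    "cdf_transform",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
]

#: Text tokens interpreted as a missing (dropout) entry.  Zeros are observed
#: values, not dropouts.
MISSING_TOKENS = {"", "na", "nan"}


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene x cell expression values with a dropout mask and cell labels.

    Parameters
    ----------
    genes
        Ordered unique gene identifiers (rows).
    cells
        Ordered cell/sample identifiers (columns).
    values
        Real matrix of shape ``(len(genes), len(cells))``.  Entries whose
        ``observed`` flag is False are ignored by all statistics.
    observed
        Boolean mask of the same shape; True marks a valid entry.
    tumor_of
        Map cell -> tumor/patient label.  Every cell must be labelled.
    cell_type_of
        Optional map cell -> cell-type label (e.g. ``cancer`` vs a normal
        subtype).
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    observed: np.ndarray
    tumor_of: dict[str, str]
    cell_type_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.observed.shape != self.values.shape:
            raise ValueError("observed mask shape differs from values shape")
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            raise ValueError(
                f"duplicate gene identifiers: {sorted(dupes[dupes.duplicated()])[:5]}"
            )
        missing = [c for c in self.cells if c not in self.tumor_of]
        if missing:
            raise ValueError(f"cells without tumor label: {missing[:5]}")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([pos[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    def tumor_labels(self) -> np.ndarray:
        """Per-column tumor labels, aligned with ``cells``."""
        return np.array([self.tumor_of[c] for c in self.cells])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            [self.genes[i] for i in idx],
            list(self.cells),
            self.values[idx],
            self.observed[idx],
            dict(self.tumor_of),
            dict(self.cell_type_of) if self.cell_type_of else None,
        )

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cells)}
        idx = np.array([pos[c] for c in cells], dtype=int)
        return ExpressionMatrix(
            list(self.genes),
            [self.cells[i] for i in idx],
            self.values[:, idx],
            self.observed[:, idx],
            {c: self.tumor_of[c] for c in cells},
            {c: self.cell_type_of[c] for c in cells} if self.cell_type_of else None,
        )

    def select_cell_type(self, cell_type: str) -> "ExpressionMatrix":
        if self.cell_type_of is None:
            raise ValueError("matrix carries no cell-type labels")
        keep = [c for c in self.cells if self.cell_type_of[c] == cell_type]
        return self.subset_cells(keep)


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets plus the universe of genes they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.universe = set(self.universe) | set().union(*self.sets.values())


@dataclasses.dataclass
class SurvivalTable:
    """Per-sample survival/censoring times and event indicators."""

    samples: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if not (len(self.samples) == len(self.time) == len(self.event)):
            raise ValueError("samples, time and event lengths differ")
        if (self.time < 0).any():
            raise ValueError("negative survival times")

    def align(self, samples: Sequence[str]) -> "SurvivalTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in samples], dtype=int)
        return SurvivalTable(list(samples), self.time[idx], self.event[idx])


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def filter_sparse_genes(
    m: ExpressionMatrix, max_missing_frac: float = 0.7
) -> ExpressionMatrix:
    """Drop genes whose missing fraction exceeds ``max_missing_frac``.

    The comparison is strict: a gene with missing fraction exactly equal to
    the threshold is kept.  The cell set is unchanged; the result may be
    empty.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be within [0, 1]")
    missing_frac = 1.0 - m.observed.mean(axis=1)
    keep = np.flatnonzero(missing_frac <= max_missing_frac)
    return ExpressionMatrix(
        [m.genes[i] for i in keep],
        list(m.cells),
        m.values[keep],
        m.observed[keep],
        dict(m.tumor_of),
        dict(m.cell_type_of) if m.cell_type_of else None,
    )


def impute(m: ExpressionMatrix, strategy: str = "mean") -> ExpressionMatrix:
    """Fill missing entries, by per-gene observed mean or by zero.

    The mean strategy requires at least one observed entry per gene and
    leaves the row mean unchanged.  Observed entries are never altered.
    """
    if strategy not in ("mean", "zero"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    values = m.values.copy()
    if strategy == "zero":
        values[~m.observed] = 0.0
    else:
        counts = m.observed.sum(axis=1)
        if (counts == 0).any():
            bad = m.genes[int(np.flatnonzero(counts == 0)[0])]
            raise ValueError(
                f"gene {bad!r} has no observed entries; mean imputation undefined"
            )
        sums = np.where(m.observed, m.values, 0.0).sum(axis=1)
        means = sums / counts
        rows, cols = np.nonzero(~m.observed)
        values[rows, cols] = means[rows]
    return ExpressionMatrix(
        list(m.genes),
        list(m.cells),
        values,
        np.ones_like(m.observed, dtype=bool),
        dict(m.tumor_of),
        dict(m.cell_type_of) if m.cell_type_of else None,
    )


def cdf_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each gene's values by their empirical CDF over samples.

    Ranks are tie-averaged and scaled by the sample count, so outputs lie in
    (0, 1] and the per-gene maximum maps to 1.  Requires a fully observed
    matrix (intended for bulk data).
    """
    if not m.observed.all():
        raise ValueError("cdf_transform requires a fully observed matrix")
    n = m.n_cells
    ranks = np.apply_along_axis(lambda r: rankdata(r, method="average"), 1, m.values)
    return ExpressionMatrix(
        list(m.genes),
        list(m.cells),
        ranks / n,
        np.ones_like(m.observed, dtype=bool),
        dict(m.tumor_of),
        dict(m.cell_type_of) if m.cell_type_of else None,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_labels_frame(df: pd.DataFrame) -> tuple[dict[str, str], dict[str, str] | None]:
    tumor_of = dict(zip(df["cell"].astype(str), df["tumor"].astype(str)))
    cell_type_of = None
    if "cell_type" in df.columns:
        cell_type_of = dict(zip(df["cell"].astype(str), df["cell_type"].astype(str)))
    return tumor_of, cell_type_of


def read_labels(path: str | Path) -> tuple[dict[str, str], dict[str, str] | None]:
    """Read a cell-label table with columns ``cell``, ``tumor`` [, ``cell_type``]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell", "tumor"):
        if col not in df.columns:
            raise ParseError(f"label table missing column {col!r}", line=1)
    return _parse_labels_frame(df)


def write_labels(m: ExpressionMatrix, path: str | Path) -> None:
    rows = {"cell": m.cells, "tumor": [m.tumor_of[c] for c in m.cells]}
    if m.cell_type_of is not None:
        rows["cell_type"] = [m.cell_type_of[c] for c in m.cells]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    *,
    sep: str = "\t",
    gene_names: str | Path | None = None,
    cell_names: str | Path | None = None,
    default_tumor: str = "T0",
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or Matrix-Market files.

    Delimited text holds genes in rows and cells in columns with a header row
    of cell identifiers; empty fields, ``NA`` and ``NaN`` denote missing
    entries.  A ``.mtx`` file is read as a sparse triplet matrix whose
    explicitly stored entries are the observed ones, accompanied by one gene
    name and one cell name per line in the two side files.

    Without a label file every cell is assigned the ``default_tumor`` label
    (useful for bulk matrices, where samples need no patient grouping).
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if gene_names is None or cell_names is None:
            raise ValueError("Matrix-Market input requires gene_names and cell_names")
        sparse = scipy.io.mmread(matrix_path).tocsr()
        genes = Path(gene_names).read_text().split()
        cells = Path(cell_names).read_text().split()
        if sparse.shape != (len(genes), len(cells)):
            raise ParseError(
                f"matrix shape {sparse.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        observed = np.zeros(sparse.shape, dtype=bool)
        coo = sparse.tocoo()
        observed[coo.row, coo.col] = True
        values = np.zeros(sparse.shape)
        values[coo.row, coo.col] = coo.data
    else:
        genes, cells, values, observed = _read_delimited(matrix_path, sep)
    if labels_path is not None:
        tumor_of, cell_type_of = read_labels(labels_path)
        unlabeled = [c for c in cells if c not in tumor_of]
        if unlabeled:
            raise ParseError(f"cells missing from label table: {unlabeled[:5]}")
    else:
        tumor_of, cell_type_of = {c: default_tumor for c in cells}, None
    return ExpressionMatrix(genes, cells, values, observed, tumor_of, cell_type_of)


def _read_delimited(path: Path, sep: str) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError("empty header row", line=1)
        cells = header.split(sep)
        if cells and cells[0] in ("", "gene", "gene_id"):
            cells = cells[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        mask: list[list[bool]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) != len(cells) + 1:
                raise ParseError(
                    f"expected {len(cells) + 1} fields, found {len(fields)}", lineno
                )
            genes.append(fields[0])
            vals, obs = [], []
            for tok in fields[1:]:
                if tok.strip().lower() in MISSING_TOKENS:
                    vals.append(np.nan)
                    obs.append(False)
                else:
                    try:
                        vals.append(float(tok))
                    except ValueError:
                        raise ParseError(f"non-numeric entry {tok!r}", lineno) from None
                    obs.append(True)
            rows.append(vals)
            mask.append(obs)
    if len(set(genes)) != len(genes):
        seen: set[str] = set()
        dupes = {g for g in genes if g in seen or seen.add(g)}
        raise ParseError(f"duplicate gene identifiers: {sorted(dupes)[:5]}")
    return genes, cells, np.array(rows, dtype=float), np.array(mask, dtype=bool)


def write_expression(m: ExpressionMatrix, path: str | Path, *, sep: str = "\t") -> None:
    """Write delimited text with ``NA`` for missing entries (round-trips)."""
    with open(path, "w") as fh:
        fh.write(sep.join(["gene"] + list(m.cells)) + "\n")
        for i, g in enumerate(m.genes):
            toks = [
                format(m.values[i, j], ".17g") if m.observed[i, j] else "NA"
                for j in range(m.n_cells)
            ]
            fh.write(sep.join([g] + toks) + "\n")


def read_gmt(path: str | Path, universe: Iterable[str] = ()) -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description and >=1 member", lineno)
            name = fields[0]
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}", lineno)
            members = {g for g in fields[2:] if g}
            if not members:
                raise ParseError(f"gene set {name!r} has no members", lineno)
            sets[name] = members
    return GeneSetCollection(sets, set(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, ""] + sorted(members)) + "\n")


def read_survival(path: str | Path, *, sep: str = "\t") -> SurvivalTable:
    """Read a survival table with columns ``sample``, ``time``, ``event``."""
    df = pd.read_csv(path, sep=sep)
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ParseError(f"survival table missing column {col!r}", line=1)
    return SurvivalTable(
        df["sample"].astype(str).tolist(),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy().astype(bool),
    )


def write_survival(table: SurvivalTable, path: str | Path, *, sep: str = "\t") -> None:
    pd.DataFrame(
        {"sample": table.samples, "time": table.time, "event": table.event.astype(int)}
    ).to_csv(path, sep=sep, index=False)
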