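"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices come in 10x "triplet" form (MatrixMarket coordinate file plus
features and barcodes TSVs, genes as rows / barcodes as columns); spot
coordinates come from the Visium ``tissue_positions`` CSV; gene sets are GMT
lines; results go out as TSV tables.  Counts are held spots x genes internally
(analysis-major), so triplet input is transposed on load.

Gene identity is the symbol string, case-sensitive, no aliasing.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A file parses but violates a structural invariant."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Spot x gene UMI counts with ordered identifier lists.

    Invariants: unique spot and gene ids, non-negative integral counts,
    matrix shape matching the id lists.
    """

    spot_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    counts: np.ndarray  # (n_spots, n_genes) integer

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.gene_ids)} genes"
            )
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValidationError("duplicate spot ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if counts.size:
            if not np.issubdtype(counts.dtype, np.integer):
                if not np.all(np.equal(np.mod(counts, 1), 0)):
                    raise ValidationError("counts contain non-integer entries")
                counts = counts.astype(np.int64)
            if counts.min(initial=0) < 0:
                raise ValidationError("counts contain negative entries")
        object.__setattr__(self, "counts", np.asarray(counts, dtype=np.int64))

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def subset_spots(self, spot_ids: Sequence[str]) -> "CountMatrix":
        index = {s: i for i, s in enumerate(self.spot_ids)}
        rows = [index[s] for s in spot_ids]
        return CountMatrix(tuple(spot_ids), self.gene_ids, self.counts[rows])


@dataclass(frozen=True)
class PositionsTable:
    """Rows of the Visium tissue_positions CSV.

    ``array_row``/``array_col`` follow the Visium convention in which the two
    coordinates share parity for every spot; violations are rejected.
    """

    barcode: tuple[str, ...]
    in_tissue: np.ndarray  # bool
    array_row: np.ndarray  # int
    array_col: np.ndarray  # int
    px_row: np.ndarray  # float
    px_col: np.ndarray  # float

    def __post_init__(self) -> None:
        n = len(self.barcode)
        for name in ("in_tissue", "array_row", "array_col", "px_row", "px_col"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"column {name} has wrong length")
            object.__setattr__(self, name, arr)
        if len(set(self.barcode)) != n:
            raise ValidationError("duplicate barcodes in positions table")
        pairs = list(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(set(pairs)) != n:
            raise ValidationError("duplicate (array_row, array_col) pairs")
        bad = (self.array_row - self.array_col) % 2 != 0
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"array_row/array_col parity violation for barcode "
                f"{self.barcode[i]!r}: ({self.array_row[i]}, {self.array_col[i]})"
            )

    def __len__(self) -> int:
        return len(self.barcode)

    def tissue_only(self) -> "PositionsTable":
        keep = np.flatnonzero(np.asarray(self.in_tissue, dtype=bool))
        return PositionsTable(
            tuple(self.barcode[i] for i in keep),
            self.in_tissue[keep],
            self.array_row[keep],
            self.array_col[keep],
            self.px_row[keep],
            self.px_col[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": list(self.barcode),
                "in_tissue": self.in_tissue.astype(int),
                "array_row": self.array_row,
                "array_col": self.array_col,
                "px_row": self.px_row,
                "px_col": self.px_col,
            }
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets; insertion order preserved, symbols unique per set."""

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate symbols in gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_id_column(path: str | Path, column: int | None = None) -> list[str]:
    """Read one id per line from a (possibly gzipped) TSV.

    Cell Ranger ``features.tsv`` carries (gene_id, symbol, type); the symbol
    column is used when present.  ``barcodes.tsv`` has a single column.
    """
    ids: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if column is not None:
                ids.append(fields[min(column, len(fields) - 1)])
            else:
                ids.append(fields[1] if len(fields) >= 2 else fields[0])
    return ids


def read_counts_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Load a 10x triplet bundle and return counts transposed to spots x genes.

    The MatrixMarket file stores genes as rows and barcodes as columns
    (Cell Ranger convention); entries absent from the sparse file are zero.
    """
    genes = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path, column=0)
    try:
        mat = mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = coo_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape[0]} x {mat.shape[1]} but id files list "
            f"{len(genes)} features and {len(barcodes)} barcodes"
        )
    dense = np.asarray(mat.todense())
    if dense.size and not np.all(np.equal(np.mod(dense, 1), 0)):
        raise ValidationError(f"non-integer entries in {matrix_path}")
    if dense.size and dense.min() < 0:
        raise ValidationError(f"negative entries in {matrix_path}")
    return CountMatrix(tuple(barcodes), tuple(genes), dense.T.astype(np.int64))


def write_counts_triplet(
    matrix: CountMatrix,
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write a CountMatrix as a 10x triplet bundle (genes x barcodes)."""
    coo = coo_matrix(matrix.counts.T)
    mmwrite(str(matrix_path), coo, field="integer")
    with open(features_path, "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(barcodes_path, "w") as fh:
        for b in matrix.spot_ids:
            fh.write(f"{b}\n")


_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "px_row", "px_col"]


def read_tissue_positions(path: str | Path) -> PositionsTable:
    """Read a tissue_positions CSV, with or without a header line.

    Header presence is detected by the literal first field ``barcode``
    (dialects differ across Space Ranger versions).  All rows are returned;
    callers filter on ``in_tissue``.
    """
    with _open_text(path) as fh:
        first = fh.readline()
    has_header = first.split(",")[0].strip().strip('"') == "barcode"
    df = pd.read_csv(
        path,
        header=0 if has_header else None,
        names=_POSITION_COLUMNS,
        dtype={0: str},
    )
    if df.shape[1] != 6:
        raise FormatError(f"expected 6 columns in {path}, found {df.shape[1]}")
    return PositionsTable(
        tuple(df["barcode"].astype(str)),
        df["in_tissue"].to_numpy().astype(bool),
        df["array_row"].to_numpy().astype(np.int64),
        df["array_col"].to_numpy().astype(np.int64),
        df["px_row"].to_numpy().astype(float),
        df["px_col"].to_numpy().astype(float),
    )


def write_tissue_positions(positions: PositionsTable, path: str | Path, header: bool = True) -> None:
    positions.to_frame().to_csv(path, index=False, header=header)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read GMT gene sets: ``name <TAB> description <TAB> gene1 <TAB> ...``.

    The description field is discarded; duplicate symbols within a line are
    deduplicated preserving first occurrence.
    """
    sets: dict[str, tuple[str, ...]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = tuple(genes)
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    sort_by: str | Sequence[str] | None = "__first__",
) -> None:
    """Write a result table as TSV with a header row.

    Row order is deterministic: sorted by the first column unless the caller
    supplies ``sort_by`` (a column name or list), or ``None`` to keep the
    given order.  Floats are written with 12 significant digits so a
    write/read round trip reproduces values.
    """
    if table.columns.duplicated().any():
        raise ValidationError("duplicate column names in result table")
    out = table
    if sort_by == "__first__":
        sort_by = [table.columns[0]] if len(table.columns) else None
    if sort_by is not None:
        out = table.sort_values(list(np.atleast_1d(sort_by)), kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
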