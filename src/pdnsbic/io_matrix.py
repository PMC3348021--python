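"""Expression-matrix and bicluster I/O.

Expression matrices are plain delimited text: a header row of condition
names and a first column of gene identifiers.  Biclusters travel either as
JSON records (gene/condition identifiers plus score and provenance) or as a
BicAT-style two-line text block (one line of gene ids, one line of
condition ids, blank-line separated).

All in-memory indices are 0-based; files and logs always carry identifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBiclusterError,
    DimensionError,
    IdentifierResolutionError,
    MatrixFormatError,
)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A real-valued genes x conditions matrix with unique identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_conditions)
        Expression values; units are arbitrary and never transformed here.
    gene_ids, condition_ids : sequences of str
        Unique row / column identifiers.

    At least 2 genes and 3 conditions are required so that the pairwise
    condition encoding is non-degenerate.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(
            self, "condition_ids", tuple(str(c) for c in self.condition_ids)
        )
        if values.ndim != 2:
            raise DimensionError("expression values must be a 2-D matrix")
        n, m = values.shape
        if n < 2:
            raise DimensionError(f"need at least 2 genes, got {n}")
        if m < 3:
            raise DimensionError(f"need at least 3 conditions, got {m}")
        if len(self.gene_ids) != n or len(self.condition_ids) != m:
            raise MatrixFormatError("identifier lists do not match matrix shape")
        if len(set(self.gene_ids)) != n:
            raise MatrixFormatError("duplicate gene identifiers")
        if len(set(self.condition_ids)) != m:
            raise MatrixFormatError("duplicate condition identifiers")
        if not np.all(np.isfinite(values)):
            raise MatrixFormatError(
                "non-finite entries present (use impute=True to row-mean impute)"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise IdentifierResolutionError(f"unknown gene id {gene_id!r}") from None

    def condition_index(self, condition_id: str) -> int:
        try:
            return self.condition_ids.index(condition_id)
        except ValueError:
            raise IdentifierResolutionError(
                f"unknown condition id {condition_id!r}"
            ) from None


@dataclass(frozen=True)
class Bicluster:
    """A submatrix selection (gene indices x condition indices) with its score.

    ``asr`` is the Average Spearman's Rho of the selected submatrix, in
    [-1, 1], or ``None`` when not (yet) evaluated.
    """

    genes: tuple[int, ...]
    conditions: tuple[int, ...]
    asr: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(int(g) for g in self.genes))
        object.__setattr__(self, "conditions", tuple(int(c) for c in self.conditions))
        if len(set(self.genes)) != len(self.genes):
            raise DegenerateBiclusterError("duplicate gene indices in bicluster")
        if len(set(self.conditions)) != len(self.conditions):
            raise DegenerateBiclusterError("duplicate condition indices in bicluster")
        if self.asr is not None:
            if len(self.genes) < 2 or len(self.conditions) < 2:
                raise DegenerateBiclusterError(
                    "a scored bicluster needs at least 2 genes and 2 conditions"
                )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        if self.genes and not (0 <= min(self.genes) and max(self.genes) < matrix.n_genes):
            raise DegenerateBiclusterError("gene index out of matrix bounds")
        if self.conditions and not (
            0 <= min(self.conditions) and max(self.conditions) < matrix.n_conditions
        ):
            raise DegenerateBiclusterError("condition index out of matrix bounds")


def read_expression_matrix(
    path: str | Path, delimiter: str = "\t", impute: bool = False
) -> ExpressionMatrix:
    """Read a delimited expression matrix (header = conditions, col 1 = genes).

    Non-numeric cells are a parse error; missing values (empty or NA cells)
    are an error unless ``impute`` is set, in which case they are replaced by
    the mean of the remaining values of their row.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise DimensionError(f"{path}: empty matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # cells that were text (not recognised NA markers) fail numeric coercion
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"non-numeric cell at gene {df.index[r]!r}, condition {df.columns[c]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        if not impute:
            raise MatrixFormatError(
                "missing/non-finite cells present; pass impute=True to row-mean impute"
            )
        values = _impute_row_mean(values)
    return ExpressionMatrix(values, tuple(map(str, df.index)), tuple(map(str, df.columns)))


def _impute_row_mean(values: np.ndarray) -> np.ndarray:
    values = values.copy()
    mask = ~np.isfinite(values)
    for i in np.nonzero(mask.any(axis=1))[0]:
        row = values[i]
        good = np.isfinite(row)
        if not good.any():
            raise MatrixFormatError(f"row {i} has no finite values to impute from")
        row[~good] = row[good].mean()
    return values


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    df = pd.DataFrame(
        matrix.values, index=list(matrix.gene_ids), columns=list(matrix.condition_ids)
    )
    df.to_csv(path, sep=delimiter)


def write_biclusters(
    biclusters: Sequence[Bicluster],
    path: str | Path,
    matrix: ExpressionMatrix,
    format: str = "json",
    provenance: dict | None = None,
) -> None:
    """Write biclusters as JSON records or BicAT-style text blocks.

    JSON records carry identifiers, the ASR score and an optional provenance
    block (seed, parameters, version).  The text format is two lines per
    bicluster -- space-separated gene ids then condition ids -- separated by
    blank lines.
    """
    path = Path(path)
    if format == "json":
        records = []
        for b in biclusters:
            rec = {
                "gene_ids": [matrix.gene_ids[g] for g in b.genes],
                "condition_ids": [matrix.condition_ids[c] for c in b.conditions],
                "asr": b.asr,
            }
            if provenance is not None:
                rec["provenance"] = provenance
            records.append(rec)
        path.write_text(json.dumps(records, indent=2) + "\n")
    elif format == "bicat-text":
        blocks = []
        for b in biclusters:
            blocks.append(
                " ".join(matrix.gene_ids[g] for g in b.genes)
                + "\n"
                + " ".join(matrix.condition_ids[c] for c in b.conditions)
                + "\n"
            )
        path.write_text("\n".join(blocks))
    else:
        raise ValueError(f"unknown bicluster format {format!r}")


def read_biclusters(path: str | Path, matrix: ExpressionMatrix) -> list[Bicluster]:
    """Read a bicluster file (JSON schema or two-line text) against a matrix.

    Identifiers are resolved to 0-based indices; an unknown identifier is a
    resolution error.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    biclusters: list[Bicluster] = []
    if stripped.startswith("[") or stripped.startswith("{"):
        data = json.loads(text)
        if isinstance(data, dict):
            data = [data]
        for rec in data:
            genes = tuple(matrix.gene_index(g) for g in rec["gene_ids"])
            conds = tuple(matrix.condition_index(c) for c in rec["condition_ids"])
            biclusters.append(Bicluster(genes, conds, rec.get("asr")))
    else:
        lines = [ln.strip() for ln in text.splitlines()]
        blocks: list[list[str]] = [[]]
        for ln in lines:
            if not ln:
                if blocks[-1]:
                    blocks.append([])
            else:
                blocks[-1].append(ln)
        if blocks and not blocks[-1]:
            blocks.pop()
        for block in blocks:
            if len(block) != 2:
                raise MatrixFormatError(
                    "text bicluster block must be exactly 2 lines (genes, conditions)"
                )
            genes = tuple(matrix.gene_index(g) for g in block[0].split())
            conds = tuple(matrix.condition_index(c) for c in block[1].split())
            biclusters.append(Bicluster(genes, conds))
    for b in biclusters:
        b.validate_against(matrix)
    return biclusters


def read_bicluster(path: str | Path, matrix: ExpressionMatrix) -> Bicluster:
    """Read a single bicluster (first record of the file)."""
    biclusters = read_biclusters(path, matrix)
    if not biclusters:
        raise MatrixFormatError(f"{path}: no bicluster records found")
    return biclusters[0]
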