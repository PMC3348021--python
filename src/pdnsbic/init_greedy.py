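"""Greedy and random initial biclusters for the search.

Two classic seed generators are provided in simplified form: MSR-guided
single-node deletion in the style of Cheng & Church (drop the row or column
contributing most to the mean squared residue until the residue falls below
delta), and an OPSM-style greedy grower that builds a condition ordering
supported by as many strictly increasing gene rows as possible.  Seeds only
need reasonable quality; the search does the refinement.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateBiclusterError
from .io_matrix import Bicluster, ExpressionMatrix
from .scoring import _residues, msr


def cc_initial(
    matrix: ExpressionMatrix, delta: float, rng: np.random.Generator | None = None
) -> Bicluster:
    """MSR node deletion: shrink the full matrix until MSR <= delta.

    At each step the single row or column with the largest mean squared
    residue contribution is removed (ties: lowest index; a tied row beats a
    tied column).  Deterministic; the rng parameter exists for interface
    uniformity with the other initializers.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rows = list(range(matrix.n_genes))
    cols = list(range(matrix.n_conditions))
    while True:
        sub = matrix.values[np.ix_(rows, cols)]
        res2 = _residues(sub) ** 2
        if res2.mean() <= delta:
            break
        if len(rows) <= 2 and len(cols) <= 2:
            raise DegenerateBiclusterError(
                f"cannot reach MSR <= {delta} above the 2x2 minimum; increase delta"
            )
        row_scores = res2.mean(axis=1) if len(rows) > 2 else None
        col_scores = res2.mean(axis=0) if len(cols) > 2 else None
        best_row = (
            (float(row_scores.max()), int(row_scores.argmax()))
            if row_scores is not None
            else None
        )
        best_col = (
            (float(col_scores.max()), int(col_scores.argmax()))
            if col_scores is not None
            else None
        )
        if best_col is None or (best_row is not None and best_row[0] >= best_col[0]):
            rows.pop(best_row[1])
        else:
            cols.pop(best_col[1])
    return Bicluster(tuple(rows), tuple(cols))


def opsm_initial(
    matrix: ExpressionMatrix,
    model_width: int,
    rng: np.random.Generator | None = None,
) -> Bicluster:
    """OPSM-style greedy growth of an order-preserving submatrix.

    Starting from the ordered condition pair supported by the most strictly
    increasing gene rows, the ordering is greedily extended one condition at
    a time (trying every insertion position) until it has ``model_width``
    conditions, each step maximizing support.  Ties prefer the lowest
    condition index, then the earliest insertion position.  Returns the
    supporting genes with the conditions in the discovered order.
    """
    m = matrix.n_conditions
    if not (2 <= model_width <= m):
        raise ValueError(f"model_width must lie in [2, {m}]")
    values = matrix.values

    def support(order: list[int]) -> int:
        diffs = np.diff(values[:, order], axis=1)
        return int((diffs > 0).all(axis=1).sum())

    best_pair: list[int] | None = None
    best_support = -1
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            s = support([a, b])
            if s > best_support:
                best_support, best_pair = s, [a, b]
    order = best_pair
    while len(order) < model_width:
        best_step: tuple[int, int, int] | None = None  # (-support, cond, pos)
        for c in range(m):
            if c in order:
                continue
            for pos in range(len(order) + 1):
                trial = order[:pos] + [c] + order[pos:]
                key = (-support(trial), c, pos)
                if best_step is None or key < best_step:
                    best_step = key
        c, pos = best_step[1], best_step[2]
        order = order[:pos] + [c] + order[pos:]
    diffs = np.diff(values[:, order], axis=1)
    genes = tuple(int(g) for g in np.nonzero((diffs > 0).all(axis=1))[0])
    if len(genes) < 2:
        raise DegenerateBiclusterError(
            "fewer than 2 genes support the grown condition order; reduce model_width"
        )
    return Bicluster(genes, tuple(order))


def random_initial(
    matrix: ExpressionMatrix,
    n_genes: int,
    n_conditions: int,
    rng: np.random.Generator,
) -> Bicluster:
    """Uniform random bicluster of the requested dimensions."""
    if not (2 <= n_genes <= matrix.n_genes):
        raise ValueError(f"n_genes must lie in [2, {matrix.n_genes}]")
    if not (2 <= n_conditions <= matrix.n_conditions):
        raise ValueError(f"n_conditions must lie in [2, {matrix.n_conditions}]")
    genes = np.sort(rng.choice(matrix.n_genes, size=n_genes, replace=False))
    conds = np.sort(rng.choice(matrix.n_conditions, size=n_conditions, replace=False))
    return Bicluster(tuple(int(g) for g in genes), tuple(int(c) for c in conds))
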