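"""Bicluster coherence scores: Spearman's rho, ASR and MSR.

The Average Spearman's Rho (ASR) of a bicluster (I', J') is

    ASR(I', J') = 2 * max{ sum_{i<j in I'} rho_ij / (|I'|(|I'|-1)),
                           sum_{k<l in J'} rho_kl / (|J'|(|J'|-1)) }

where rho_ij is the Spearman rank correlation between gene rows i and j
restricted to the conditions J', and rho_kl between condition columns k and
l restricted to the genes I'.  Because the divisor counts ordered pairs, the
factor 2 makes each term the plain mean over unordered pairs; ASR lies in
[-1, 1] and equals 1 exactly when either all gene rows or all condition
columns are pairwise rank-identical.

The Mean Squared Residue (MSR) is the classic additive-model score: the mean
of squared residues a_ij - a_iJ - a_Ij + a_IJ over the submatrix, zero for
any additive (row effect + column effect) block.  It backs the greedy
node-deletion initializer only; the search itself is rank-based.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateBiclusterError
from .io_matrix import Bicluster, ExpressionMatrix


class ScoreValue(float):
    """A float tagged with the kind of score it carries ('asr', 'msr', 'rho')."""

    kind: str

    def __new__(cls, value: float, kind: str) -> "ScoreValue":
        obj = super().__new__(cls, value)
        obj.kind = kind
        return obj

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ScoreValue({float(self)!r}, kind={self.kind!r})"


def spearman_rho(x: np.ndarray, y: np.ndarray) -> ScoreValue:
    """Spearman rank correlation with average ranks for ties.

    Both vectors are rank-transformed (fractional ranks on ties) and the
    Pearson correlation of the rank vectors is returned.  A vector with zero
    rank variance (all values tied) has no rank ordering to correlate, so the
    result is 0 by convention rather than undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 2:
        raise DegenerateBiclusterError("correlation needs vectors of length >= 2")
    rx = rankdata(x)
    ry = rankdata(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    ssx = dx @ dx
    ssy = dy @ dy
    if ssx == 0.0 or ssy == 0.0:
        return ScoreValue(0.0, "rho")
    # single square root so rank-identical vectors score exactly +/-1
    value = float((dx @ dy) / np.sqrt(ssx * ssy))
    return ScoreValue(min(1.0, max(-1.0, value)), "rho")


def _mean_pairwise_spearman(rows: np.ndarray) -> float:
    """Mean Spearman rho over all unordered pairs of rows of a 2-D array.

    Zero-variance rows contribute rho = 0 against every partner.
    """
    k = rows.shape[0]
    ranks = rankdata(rows, axis=1)
    dev = ranks - ranks.mean(axis=1, keepdims=True)
    ss = (dev * dev).sum(axis=1)
    ss_safe = np.where(ss > 0.0, ss, 1.0)  # zero-variance rows have dev == 0
    corr = (dev @ dev.T) / np.sqrt(np.outer(ss_safe, ss_safe))
    corr = np.clip(corr, -1.0, 1.0)
    iu = np.triu_indices(k, 1)
    return float(corr[iu].mean())


def asr(matrix: ExpressionMatrix, bicluster: Bicluster) -> ScoreValue:
    """Average Spearman's Rho of a bicluster on the original expression values.

    Computed on the raw (not trinarized) submatrix: the larger of the mean
    pairwise rank correlation among gene rows and among condition columns.
    Requires at least a 2 x 2 selection.
    """
    if bicluster.n_genes < 2 or bicluster.n_conditions < 2:
        raise DegenerateBiclusterError("ASR needs at least 2 genes and 2 conditions")
    bicluster.validate_against(matrix)
    sub = matrix.values[np.ix_(bicluster.genes, bicluster.conditions)]
    row_term = _mean_pairwise_spearman(sub)
    col_term = _mean_pairwise_spearman(sub.T)
    return ScoreValue(max(row_term, col_term), "asr")


def msr(
    matrix: ExpressionMatrix,
    genes: tuple[int, ...] | list[int] | np.ndarray,
    conditions: tuple[int, ...] | list[int] | np.ndarray,
) -> ScoreValue:
    """Mean Squared Residue of the selected submatrix (0 for additive blocks)."""
    genes = np.asarray(genes, dtype=int)
    conditions = np.asarray(conditions, dtype=int)
    if genes.size < 1 or conditions.size < 1:
        raise DegenerateBiclusterError("MSR needs a non-empty selection")
    sub = matrix.values[np.ix_(genes, conditions)]
    return ScoreValue(float(np.mean(_residues(sub) ** 2)), "msr")


def _residues(sub: np.ndarray) -> np.ndarray:
    """Residues a_ij - a_iJ - a_Ij + a_IJ of a submatrix."""
    row_means = sub.mean(axis=1, keepdims=True)
    col_means = sub.mean(axis=0, keepdims=True)
    return sub - row_means - col_means + sub.mean()
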