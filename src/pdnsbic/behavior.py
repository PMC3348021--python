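"""Trinary behavior matrix and the configuration encoding of biclusters.

The behavior matrix M' recodes an n x m expression matrix as n rows over
all m(m-1)/2 unordered condition pairs: for pair (k, q), k < q, the entry
is +1 if expression rises from condition k to q, -1 if it falls and 0 if
it is exactly equal.  Each row of M' is the trajectory pattern of a gene
across combined conditions; the search operates on sub-selections of M'.

A configuration s = (I', K) is a gene subset plus a subset of pair-columns.
Encoding a bicluster takes all pairs internal to its condition set; decoding
maps a configuration back to conditions, keeping only conditions combined
with at least half of the other selected conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateBiclusterError
from .io_matrix import Bicluster, ExpressionMatrix


@dataclass(frozen=True)
class BehaviorMatrix:
    """Trinary matrix over unordered condition pairs.

    ``pair_index`` lists the (k, q), k < q, condition pairs in lexicographic
    order; column l of ``trits`` corresponds to ``pair_index[l]``.
    """

    trits: np.ndarray  # (n_genes, n_pairs) int8 in {-1, 0, 1}
    pair_index: tuple[tuple[int, int], ...]
    n_conditions: int

    def __post_init__(self) -> None:
        m = self.n_conditions
        expected = m * (m - 1) // 2
        if self.trits.shape[1] != expected or len(self.pair_index) != expected:
            raise ValueError("pair-column count must be m(m-1)/2")

    @property
    def n_genes(self) -> int:
        return self.trits.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.trits.shape[1]

    def column_of_pair(self, k: int, q: int) -> int:
        """Column index for the unordered pair {k, q} (lexicographic layout)."""
        if k == q:
            raise ValueError("a pair needs two distinct conditions")
        if k > q:
            k, q = q, k
        m = self.n_conditions
        # columns (0,1),(0,2),...,(0,m-1),(1,2),... ; offset of block k plus (q-k-1)
        return k * (2 * m - k - 1) // 2 + (q - k - 1)


def build_behavior_matrix(matrix: ExpressionMatrix) -> BehaviorMatrix:
    """Recode an expression matrix into its trinary behavior matrix.

    Comparison is exact on the stored floating-point values (no tolerance):
    the trichotomy rises / equal / falls is taken literally.
    """
    values = matrix.values
    m = matrix.n_conditions
    pairs = [(k, q) for k in range(m) for q in range(k + 1, m)]
    ks = np.fromiter((k for k, _ in pairs), dtype=int)
    qs = np.fromiter((q for _, q in pairs), dtype=int)
    trits = np.sign(values[:, qs] - values[:, ks]).astype(np.int8)
    return BehaviorMatrix(trits, tuple(pairs), m)


@dataclass(frozen=True)
class Configuration:
    """Search state s = (I', K): gene indices plus pair-column indices.

    Freshly encoded configurations carry all pairs internal to the source
    bicluster's condition set; after moves K may be any non-empty subset of
    the pair-columns.
    """

    genes: tuple[int, ...]
    pair_columns: tuple[int, ...]
    behavior: BehaviorMatrix

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(sorted(int(g) for g in self.genes)))
        object.__setattr__(
            self, "pair_columns", tuple(sorted(int(c) for c in self.pair_columns))
        )
        if len(set(self.genes)) != len(self.genes):
            raise DegenerateBiclusterError("duplicate genes in configuration")
        if len(set(self.pair_columns)) != len(self.pair_columns):
            raise DegenerateBiclusterError("duplicate pair-columns in configuration")
        if not self.genes or not self.pair_columns:
            raise DegenerateBiclusterError("configuration must be non-empty")

    @property
    def submatrix(self) -> np.ndarray:
        """The trinary sub-matrix restricted to (genes, pair_columns)."""
        return self.behavior.trits[np.ix_(self.genes, self.pair_columns)]

    def condition_set(self) -> tuple[int, ...]:
        """Union of pair endpoints of K (unfiltered; no coverage rule)."""
        conds: set[int] = set()
        for l in self.pair_columns:
            k, q = self.behavior.pair_index[l]
            conds.add(k)
            conds.add(q)
        return tuple(sorted(conds))


def encode(bicluster: Bicluster, behavior: BehaviorMatrix) -> Configuration:
    """Encode a bicluster as a configuration over the behavior matrix.

    K collects every pair-column whose two endpoints both lie in the
    bicluster's condition set, hence |K| = |J'|(|J'|-1)/2.
    """
    if bicluster.n_conditions < 2:
        raise DegenerateBiclusterError("encoding needs at least 2 conditions")
    if bicluster.n_genes < 2:
        raise DegenerateBiclusterError("encoding needs at least 2 genes")
    conds = sorted(bicluster.conditions)
    cols = [
        behavior.column_of_pair(k, q)
        for i, k in enumerate(conds)
        for q in conds[i + 1 :]
    ]
    return Configuration(tuple(bicluster.genes), tuple(cols), behavior)


def decode(config: Configuration, coverage: float = 0.5) -> Bicluster:
    """Decode a configuration back to a bicluster with the coverage rule.

    Selected conditions are the union of K's pair endpoints.  A condition
    survives only while it is combined (co-occurs in a pair of K) with at
    least ``coverage`` of the other currently-selected conditions.  Each
    round drops every condition below the coverage fraction simultaneously
    (pairs with a dropped endpoint stop counting) and the rounds iterate to
    a fixpoint; genes pass through unchanged.
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0, 1]")
    pairs = [config.behavior.pair_index[l] for l in config.pair_columns]
    selected = sorted({c for pair in pairs for c in pair})
    while len(selected) >= 2:
        active = set(selected)
        degree = {c: 0 for c in selected}
        for k, q in pairs:
            if k in active and q in active:
                degree[k] += 1
                degree[q] += 1
        n_other = len(selected) - 1
        drop = [c for c in selected if degree[c] < coverage * n_other]
        if not drop:
            break
        selected = [c for c in selected if c not in set(drop)]
    if len(selected) < 2:
        raise DegenerateBiclusterError("fewer than 2 conditions survive decoding")
    return Bicluster(config.genes, tuple(selected))
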