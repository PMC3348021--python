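"""Bicluster pattern and the two pattern-driven move operators.

The bicluster pattern P of a configuration is, per pair-column, the
dominating trinary value over the configuration's genes, together with the
frequency of that value (dominance).  Genes and columns are judged against
P: a gene's quality is its fraction of positions agreeing with P, a
column's quality is the fraction of its entries equal to the pattern value.

mv_g drops every gene below the quality threshold alpha and admits outside
genes at or above it (columns untouched).  mv_c prunes weakly-dominated
pair-columns, expels conditions whose pairs are badly dominated on average,
and admits outside conditions whose pairs dominate at or above beta over
the same genes (genes untouched).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BehaviorMatrix, Configuration

# dominating-value tie-break: prefer a trend over "no change"
_TIE_PRIORITY = np.array([1, -1, 0], dtype=np.int8)


@dataclass(frozen=True)
class BiclusterPattern:
    """Per-column dominating value and its frequency for a configuration."""

    values: np.ndarray  # int8 in {-1, 0, 1}, one per configuration column
    dominance: np.ndarray  # fraction in [1/3, 1], frequency of the dominating value


@dataclass(frozen=True)
class MoveResult:
    """Outcome of one move-operator application."""

    kind: str  # 'gene' or 'column'
    removed: tuple[int, ...]
    added: tuple[int, ...]
    reason: str | None = None  # set when the move was rejected as a no-op

    @property
    def is_identity(self) -> bool:
        return not self.removed and not self.added


def _dominating(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dominating value and frequency per column of a trinary matrix."""
    counts = np.stack([(sub == v).sum(axis=0) for v in _TIE_PRIORITY])
    # argmax returns the first maximal row, i.e. the tie-break priority order
    winner = _TIE_PRIORITY[np.argmax(counts, axis=0)]
    dominance = counts.max(axis=0) / sub.shape[0]
    return winner, dominance


def compute_pattern(config: Configuration) -> BiclusterPattern:
    """Bicluster pattern of a configuration (dominating trit per column)."""
    values, dominance = _dominating(config.submatrix)
    return BiclusterPattern(values, dominance)


def gene_quality(gene_row: np.ndarray, pattern: BiclusterPattern) -> float:
    """Fraction of pair-columns where a gene's trits agree with the pattern."""
    gene_row = np.asarray(gene_row)
    if gene_row.shape != pattern.values.shape:
        raise ValueError("gene row and pattern lengths differ")
    return float((gene_row == pattern.values).mean())


def column_quality(column: np.ndarray, pattern_value: int) -> float:
    """Fraction of a column's entries equal to a pattern value."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty column")
    return float((column == pattern_value).mean())


def _all_gene_qualities(
    behavior: BehaviorMatrix, pair_columns: tuple[int, ...], pattern: BiclusterPattern
) -> np.ndarray:
    """Quality of every gene of the backing matrix against the pattern."""
    sub = behavior.trits[:, list(pair_columns)]
    return (sub == pattern.values).mean(axis=1)


def mv_g(
    config: Configuration,
    pattern: BiclusterPattern,
    alpha: float,
    max_add: int | None = None,
) -> tuple[Configuration, MoveResult]:
    """Gene move: drop genes below alpha, admit outside genes at/above alpha.

    All bad genes (quality < alpha w.r.t. the pre-move pattern) are removed;
    candidates are genes of the backing behavior matrix outside the
    configuration whose quality over the configuration's columns is >= alpha,
    added best-first (ties by gene index) up to ``max_add`` (None = all).
    Columns are never touched.  A move that would leave fewer than 2 genes is
    rejected and reported as a no-op.
    """
    quality = _all_gene_qualities(config.behavior, config.pair_columns, pattern)
    members = np.array(config.genes)
    member_mask = np.zeros(config.behavior.n_genes, dtype=bool)
    member_mask[members] = True

    removed = tuple(int(g) for g in members[quality[members] < alpha])
    kept = [int(g) for g in members if quality[g] >= alpha]

    outside = np.nonzero(~member_mask)[0]
    good = outside[quality[outside] >= alpha]
    order = sorted(good, key=lambda g: (-quality[g], g))
    if max_add is not None:
        order = order[:max_add]
    added = tuple(int(g) for g in order)

    new_genes = tuple(sorted(kept + list(added)))
    if len(new_genes) < 2:
        return config, MoveResult(
            "gene", (), (), reason="rejected: fewer than 2 genes would remain"
        )
    if new_genes == config.genes:
        return config, MoveResult("gene", (), ())
    new_config = Configuration(new_genes, config.pair_columns, config.behavior)
    return new_config, MoveResult("gene", removed, added)


def mv_c(
    config: Configuration,
    pattern: BiclusterPattern,
    beta: float,
    max_add: int | None = None,
) -> tuple[Configuration, MoveResult]:
    """Column move: swap badly-patterned conditions, pruning weak pair-columns.

    A pair-column is weak when the frequency of its dominating value over
    the current genes falls below beta; every weak column is dropped.  A
    selected condition is bad when the mean dominance of its pair-columns in
    K falls below beta; a bad condition is expelled outright (all its
    remaining columns go too).  Candidate conditions are those outside the
    current selection whose mean pair dominance against the surviving
    conditions reaches beta; up to ``max_add`` of them (None = as many as
    were expelled) are admitted best-first (ties by condition index),
    contributing only their pair-columns that individually reach beta.
    Genes are never touched.  A move that would leave no columns is rejected
    as a no-op.
    """
    behavior = config.behavior
    genes = list(config.genes)
    dominance_all = _dominating(behavior.trits[genes, :])[1]

    k_cols = list(config.pair_columns)
    selected = sorted({c for l in k_cols for c in behavior.pair_index[l]})
    cols_of = {c: [l for l in k_cols if c in behavior.pair_index[l]] for c in selected}
    cond_quality = {c: float(dominance_all[cols_of[c]].mean()) for c in selected}
    bad_conds = [c for c in selected if cond_quality[c] < beta]
    survivors = [c for c in selected if c not in set(bad_conds)]
    if len(survivors) < 2:
        return config, MoveResult(
            "column", (), (), reason="rejected: fewer than 2 conditions would remain"
        )
    bad_set = set(bad_conds)
    kept = [
        l
        for l in k_cols
        if dominance_all[l] >= beta and not (set(behavior.pair_index[l]) & bad_set)
    ]

    candidates = []
    for c in range(behavior.n_conditions):
        if c in set(selected):
            continue
        cand_cols = [behavior.column_of_pair(c, j) for j in survivors]
        quality = float(dominance_all[cand_cols].mean())
        if quality >= beta:
            candidates.append((-quality, c))
    candidates.sort()
    cap = len(bad_conds) if max_add is None else max_add
    admitted = [c for _, c in candidates[:cap]]

    new_cols = set(kept)
    incoming = survivors + admitted
    for c in admitted:
        for j in incoming:
            if j == c:
                continue
            l = behavior.column_of_pair(c, j)
            if dominance_all[l] >= beta:
                new_cols.add(l)

    if not new_cols:
        return config, MoveResult(
            "column", (), (), reason="rejected: no columns would remain"
        )
    new_cols = tuple(sorted(new_cols))
    if new_cols == config.pair_columns:
        return config, MoveResult("column", (), ())
    removed = tuple(c for c in config.pair_columns if c not in set(new_cols))
    added = tuple(c for c in new_cols if c not in set(config.pair_columns))
    new_config = Configuration(config.genes, new_cols, behavior)
    return new_config, MoveResult("column", removed, added)
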