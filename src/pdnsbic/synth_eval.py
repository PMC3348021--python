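"""Synthetic expression matrices with implanted trend-coherent biclusters.

The generator implants groups of genes that share a common expression
trajectory over a subset of conditions — the structure the rank-based
search is designed to find — inside an i.i.d. Gaussian (or permuted)
background, then shuffles rows and columns.  Member rows follow a shared
condition trend t_j, per-gene transformed (shifted, positively scaled, or
passed through a strictly increasing map) and perturbed by Gaussian noise,
so at zero noise every member pair is perfectly rank-correlated on the
member conditions.

Recovered biclusters are scored against the implanted truth with Jaccard
indices over cells, genes and conditions, greedily pairing found and truth
blocks by descending cell Jaccard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_matrix import Bicluster, ExpressionMatrix


@dataclass(frozen=True)
class ImplantSpec:
    """One implanted bicluster: dimensions, trend family and noise level.

    trend: 'shift' (t_j + per-gene offset), 'scale' (t_j times a positive
    per-gene factor) or 'monotone' (an arbitrary strictly increasing per-gene
    map of t_j).  noise_sd is the s.d. of the additive Gaussian noise, in the
    same units as the unit-variance trend; the default 0.38 puts the mean
    member-pair Spearman correlation of a shift-trend block near 0.9.
    """

    n_genes: int
    n_conditions: int
    trend: str = "shift"
    noise_sd: float = 0.38

    def __post_init__(self) -> None:
        if self.trend not in ("shift", "scale", "monotone"):
            raise ValueError(f"unknown trend type {self.trend!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_genes < 2 or self.n_conditions < 2:
            raise ValueError("implanted blocks must be at least 2x2")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic matrix."""

    n_genes: int = 300
    n_conditions: int = 25
    biclusters: tuple[ImplantSpec, ...] = (ImplantSpec(30, 8, "shift", 0.38),)
    background: str = "normal"  # 'normal' or 'permuted'
    background_mean: float = 0.0
    background_sd: float = 1.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "biclusters", tuple(self.biclusters))
        if self.background not in ("normal", "permuted"):
            raise ValueError(f"unknown background {self.background!r}")
        if not self.allow_overlap:
            if sum(b.n_genes for b in self.biclusters) > self.n_genes or sum(
                b.n_conditions for b in self.biclusters
            ) > self.n_conditions:
                raise ValueError(
                    "implanted blocks do not fit disjointly; "
                    "enlarge the matrix or set allow_overlap"
                )


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, list[Bicluster]]:
    """Build the matrix and the ground-truth bicluster memberships.

    Deterministic under ``spec.seed``: the same spec always yields a
    bit-identical matrix and truth.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_conditions
    values = rng.normal(spec.background_mean, spec.background_sd, size=(n, m))
    if spec.background == "permuted":
        # permute within each row: same marginals, no cross-gene structure
        for i in range(n):
            values[i] = values[i, rng.permutation(m)]

    truth_blocks: list[tuple[np.ndarray, np.ndarray]] = []
    g_off = c_off = 0
    for block in spec.biclusters:
        if spec.allow_overlap:
            g_idx = np.sort(rng.choice(n, size=block.n_genes, replace=False))
            c_idx = np.sort(rng.choice(m, size=block.n_conditions, replace=False))
        else:
            g_idx = np.arange(g_off, g_off + block.n_genes)
            c_idx = np.arange(c_off, c_off + block.n_conditions)
            g_off += block.n_genes
            c_off += block.n_conditions
        values[np.ix_(g_idx, c_idx)] = _implant(block, rng)
        truth_blocks.append((g_idx, c_idx))

    row_perm = rng.permutation(n)
    col_perm = rng.permutation(m)
    values = values[np.ix_(row_perm, col_perm)]
    row_new = np.argsort(row_perm)  # old index -> new position
    col_new = np.argsort(col_perm)

    truth = [
        Bicluster(
            tuple(sorted(int(row_new[g]) for g in g_idx)),
            tuple(sorted(int(col_new[c]) for c in c_idx)),
        )
        for g_idx, c_idx in truth_blocks
    ]
    matrix = ExpressionMatrix(
        values,
        tuple(f"g{i}" for i in range(n)),
        tuple(f"c{j}" for j in range(m)),
    )
    return matrix, truth


def _implant(block: ImplantSpec, rng: np.random.Generator) -> np.ndarray:
    """Member cells: shared unit-variance trend, per-gene transform, noise.

    The trend assigns each member condition a distinct expression level —
    evenly spaced levels in shuffled order, scaled to unit variance — so the
    implanted genes share a definite up/down trajectory on every member
    condition pair (a Gaussian trend would leave near-tied pairs with no
    concordant direction to recover).
    """
    k, c = block.n_genes, block.n_conditions
    levels = np.linspace(-1.0, 1.0, c)
    levels /= levels.std()
    t = rng.permutation(levels)
    if block.trend == "shift":
        base = t[None, :] + rng.normal(0.0, 1.0, size=(k, 1))
    elif block.trend == "scale":
        base = t[None, :] * np.exp(rng.normal(0.0, 0.5, size=(k, 1)))
    else:  # monotone: per-gene strictly increasing map of the trend ranks
        order = np.argsort(np.argsort(t))  # rank of each condition in the trend
        base = np.empty((k, c))
        for i in range(k):
            levels = np.sort(rng.normal(0.0, 1.0, size=c))
            base[i] = levels[order]
    return base + rng.normal(0.0, block.noise_sd, size=(k, c))


def overlap_seed(
    truth: Bicluster,
    matrix: ExpressionMatrix,
    keep_genes: int,
    keep_conditions: int,
    rng: np.random.Generator,
) -> Bicluster:
    """A benchmark seed bicluster partially overlapping an implanted truth.

    Keeps ``keep_genes`` truth genes and ``keep_conditions`` truth conditions
    (sampled uniformly) and pads back to the truth's dimensions with uniform
    outsiders, e.g. keeping 24/30 genes and 6/8 conditions of a 30 x 8 block
    yields a seed covering 60% of the truth's cells.
    """
    if not (0 <= keep_genes <= truth.n_genes) or not (
        0 <= keep_conditions <= truth.n_conditions
    ):
        raise ValueError("keep counts must not exceed the truth's dimensions")
    out_g = np.setdiff1d(np.arange(matrix.n_genes), np.array(truth.genes))
    out_c = np.setdiff1d(np.arange(matrix.n_conditions), np.array(truth.conditions))
    genes = sorted(rng.choice(np.array(truth.genes), keep_genes, replace=False))
    conds = sorted(rng.choice(np.array(truth.conditions), keep_conditions, replace=False))
    genes += sorted(rng.choice(out_g, truth.n_genes - keep_genes, replace=False))
    conds += sorted(rng.choice(out_c, truth.n_conditions - keep_conditions, replace=False))
    return Bicluster(tuple(sorted(int(g) for g in genes)),
                     tuple(sorted(int(c) for c in conds)))


@dataclass(frozen=True)
class MatchReport:
    """Recovery quality of found biclusters against the implanted truth.

    Aggregate scores average the best greedy pairing over truth blocks
    (an unmatched truth block scores 0); ``pairs`` lists
    (truth_index, found_index or None, cell/gene/condition Jaccard).
    """

    cell_jaccard: float
    gene_jaccard: float
    condition_jaccard: float
    pairs: tuple[tuple[int, int | None, float, float, float], ...]


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _cells(b: Bicluster) -> set[tuple[int, int]]:
    return {(g, c) for g in b.genes for c in b.conditions}


def match_score(found: list[Bicluster], truth: list[Bicluster]) -> MatchReport:
    """Greedy best-pairing Jaccard between found and implanted biclusters."""
    cell = np.zeros((len(truth), len(found)))
    for ti, t in enumerate(truth):
        for fi, f in enumerate(found):
            cell[ti, fi] = _jaccard(_cells(t), _cells(f))
    pairs: list[tuple[int, int | None, float, float, float]] = []
    used_f: set[int] = set()
    # pair by descending cell Jaccard
    order = sorted(
        ((ti, fi) for ti in range(len(truth)) for fi in range(len(found))),
        key=lambda tf: (-cell[tf], tf),
    )
    matched_t: set[int] = set()
    for ti, fi in order:
        if ti in matched_t or fi in used_f:
            continue
        matched_t.add(ti)
        used_f.add(fi)
        t, f = truth[ti], found[fi]
        pairs.append(
            (
                ti,
                fi,
                float(cell[ti, fi]),
                _jaccard(set(t.genes), set(f.genes)),
                _jaccard(set(t.conditions), set(f.conditions)),
            )
        )
    for ti in range(len(truth)):
        if ti not in matched_t:
            pairs.append((ti, None, 0.0, 0.0, 0.0))
    pairs.sort(key=lambda p: p[0])
    n_t = max(len(truth), 1)
    return MatchReport(
        cell_jaccard=sum(p[2] for p in pairs) / n_t,
        gene_jaccard=sum(p[3] for p in pairs) / n_t,
        condition_jaccard=sum(p[4] for p in pairs) / n_t,
        pairs=tuple(pairs),
    )
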