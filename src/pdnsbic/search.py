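"""Pattern-driven neighborhood search: descent, perturbation, iterated runs.

One descent repeatedly applies the two move operators (by default proposing
both and taking the better candidate), accepting a move only when the ASR
of the candidate — scored on the candidate's genes over the union of its
pair endpoints — strictly increases.  A descent ends when the ASR reaches ``asr_threshold``, when
neither operator improves (local optimum), or after ``max_descent_iters``
iterations.

The outer loop records the best configuration seen (compared by the ASR of
its decoded bicluster), perturbs the best bicluster by randomly replacing a
fraction (default 10%) of its genes and of its conditions, and restarts the
descent from the perturbed solution.  The run stops after
``max_stagnant_perturbations`` consecutive cycles without improving the
best decoded ASR.  Everything is a pure function of the inputs and the
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .behavior import Configuration, build_behavior_matrix, decode, encode
from .errors import DegenerateBiclusterError
from .io_matrix import Bicluster, ExpressionMatrix
from .pattern_moves import compute_pattern, mv_c, mv_g
from .scoring import asr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchParams:
    """Tunable parameters of the search.

    alpha, beta : gene / column quality thresholds in (0, 1].
    asr_threshold : descent stops early once the configuration ASR reaches it.
    max_descent_iters : iteration cap Y of one descent.
    max_stagnant_perturbations : stop after Z perturbation cycles without
        improvement of the best decoded ASR.
    perturb_fraction : fraction of genes and of conditions replaced per
        perturbation (counts are rounded up, so at least one of each moves).
    decode_coverage : the final decoding keeps conditions combined with at
        least this fraction of the other selected conditions.
    max_add_genes / max_add_columns : caps on additions per move.  Small
        gene batches (default 5) let the strict-ASR acceptance vet each
        admission; None admits every qualifying gene.  The column default
        (None) admits one condition per condition expelled.
    move_order : which operator a descent iteration tries ('gc' = genes then
        columns first-improvement, 'cg' = the reverse, 'best' = evaluate both
        and take the better candidate; default).
    seed : seed for the perturbation RNG.
    """

    alpha: float = 0.8
    beta: float = 0.8
    asr_threshold: float = 0.7
    max_descent_iters: int = 100
    max_stagnant_perturbations: int = 50
    perturb_fraction: float = 0.10
    decode_coverage: float = 0.50
    max_add_genes: int | None = 5
    max_add_columns: int | None = None
    move_order: str = "best"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.move_order not in ("gc", "cg", "best"):
            raise ValueError("move_order must be 'gc', 'cg' or 'best'")
        for name in ("alpha", "beta", "perturb_fraction", "decode_coverage"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not (-1.0 <= self.asr_threshold <= 1.0):
            raise ValueError("asr_threshold must lie in [-1, 1]")
        if self.max_descent_iters < 1 or self.max_stagnant_perturbations < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass
class TraceRecord:
    iteration: int
    operator: str
    asr_before: float
    asr_after: float
    n_genes: int
    n_columns: int
    accepted: bool


@dataclass
class SearchTrace:
    """Per-move records plus the best decoded ASR after each cycle."""

    records: list[TraceRecord] = field(default_factory=list)
    best_asr_history: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "records": [asdict(r) for r in self.records],
            "best_asr_history": list(self.best_asr_history),
        }


def config_asr(config: Configuration, matrix: ExpressionMatrix) -> float:
    """ASR of a configuration on the union of its pair endpoints.

    During search no coverage filtering is applied; the 50% rule only enters
    at final decoding.
    """
    conditions = config.condition_set()
    return float(asr(matrix, Bicluster(config.genes, conditions)))


def descent(
    config: Configuration,
    matrix: ExpressionMatrix,
    params: SearchParams,
    trace: SearchTrace | None = None,
) -> tuple[Configuration, SearchTrace]:
    """Improve a configuration by strict-ascent moves on the ASR."""
    if trace is None:
        trace = SearchTrace()
    current_asr = config_asr(config, matrix)
    operators = {"gc": ("mv_g", "mv_c"), "cg": ("mv_c", "mv_g"),
                 "best": ("mv_g", "mv_c")}[params.move_order]
    moves = {"mv_g": _gene_move, "mv_c": _column_move}
    for iteration in range(params.max_descent_iters):
        if current_asr >= params.asr_threshold:
            break
        pattern = compute_pattern(config)
        evaluated: list[tuple[float, str, Configuration]] = []
        for name in operators:
            candidate, result = moves[name](config, pattern, params)
            if result.is_identity:
                continue
            candidate_asr = config_asr(candidate, matrix)
            evaluated.append((candidate_asr, name, candidate))
            if candidate_asr > current_asr and params.move_order != "best":
                break  # first-improvement in the configured order
        improving = [e for e in evaluated if e[0] > current_asr]
        chosen = max(improving, key=lambda e: e[0]) if improving else None
        for candidate_asr, name, candidate in evaluated:
            trace.records.append(
                TraceRecord(
                    iteration,
                    name,
                    current_asr,
                    candidate_asr,
                    len(candidate.genes),
                    len(candidate.pair_columns),
                    chosen is not None and candidate is chosen[2],
                )
            )
        if chosen is None:
            break  # local optimum
        current_asr, _, config = chosen
    return config, trace


def _gene_move(config, pattern, params):
    return mv_g(config, pattern, params.alpha, params.max_add_genes)


def _column_move(config, pattern, params):
    return mv_c(config, pattern, params.beta, params.max_add_columns)


def perturb(
    bicluster: Bicluster,
    matrix: ExpressionMatrix,
    fraction: float,
    rng: np.random.Generator,
) -> Bicluster:
    """Replace ceil(fraction * size) genes and conditions by random outsiders.

    Members to drop and outsiders to admit are drawn uniformly without
    replacement; the bicluster's dimensions are preserved.  If an outside
    pool is too small, as many elements as possible are replaced and a
    warning is logged.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    genes = _replace_some(
        bicluster.genes, matrix.n_genes, math.ceil(fraction * bicluster.n_genes), rng
    )
    conditions = _replace_some(
        bicluster.conditions,
        matrix.n_conditions,
        math.ceil(fraction * bicluster.n_conditions),
        rng,
    )
    return Bicluster(tuple(sorted(genes)), tuple(sorted(conditions)))


def _replace_some(
    members: tuple[int, ...], universe: int, count: int, rng: np.random.Generator
) -> list[int]:
    pool = np.setdiff1d(np.arange(universe), np.array(members, dtype=int))
    if pool.size < count:
        logger.warning(
            "replacement pool (%d) smaller than requested count (%d); replacing %d",
            pool.size,
            count,
            pool.size,
        )
        count = int(pool.size)
    out = list(members)
    if count == 0:
        return out
    drop = rng.choice(len(out), size=count, replace=False)
    add = rng.choice(pool, size=count, replace=False)
    keep = [g for i, g in enumerate(out) if i not in set(drop.tolist())]
    return keep + [int(a) for a in add]


def pdns_run(
    matrix: ExpressionMatrix,
    initial: Bicluster,
    params: SearchParams,
) -> tuple[Bicluster, SearchTrace]:
    """Full iterated local search from one initial bicluster.

    Encode the initial bicluster, descend, record the best configuration by
    the ASR of its decoded bicluster, then repeatedly perturb the best
    bicluster and descend again until ``max_stagnant_perturbations``
    consecutive cycles bring no improvement.  Returns the decoded best
    bicluster with its ASR, plus the full search trace.
    """
    initial.validate_against(matrix)
    behavior = build_behavior_matrix(matrix)
    rng = np.random.default_rng(params.seed)
    trace = SearchTrace()

    best_bicluster: Bicluster | None = None
    best_asr = -np.inf

    config = encode(initial, behavior)
    stagnant = 0
    while True:
        config, trace = descent(config, matrix, params, trace)
        candidate = _decoded_with_asr(config, matrix, params)
        if candidate is not None and candidate.asr > best_asr:
            best_bicluster, best_asr = candidate, candidate.asr
            stagnant = 0
        else:
            stagnant += 1
        trace.best_asr_history.append(best_asr)
        if best_bicluster is None:
            # pathological seed that never decodes; restart from a perturbed seed
            restart = perturb(initial, matrix, params.perturb_fraction, rng)
            config = encode(restart, behavior)
            if stagnant >= params.max_stagnant_perturbations:
                raise DegenerateBiclusterError(
                    "search never produced a decodable bicluster"
                )
            continue
        if stagnant >= params.max_stagnant_perturbations:
            break
        perturbed = perturb(best_bicluster, matrix, params.perturb_fraction, rng)
        config = encode(perturbed, behavior)
    return best_bicluster, trace


def _decoded_with_asr(
    config: Configuration, matrix: ExpressionMatrix, params: SearchParams
) -> Bicluster | None:
    """Decode and score a configuration; None when decoding degenerates."""
    try:
        bicluster = decode(config, params.decode_coverage)
    except DegenerateBiclusterError:
        return None
    if bicluster.n_genes < 2 or bicluster.n_conditions < 2:
        return None
    score = float(asr(matrix, bicluster))
    return Bicluster(bicluster.genes, bicluster.conditions, score)
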