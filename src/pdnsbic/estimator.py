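"""Scikit-learn style estimator wrapping the pattern-driven search.

``PDNSBiclustering`` follows the sklearn biclustering conventions
(``SpectralBiclustering`` et al.): ``fit(X)`` runs the iterated local
search once per initial bicluster and exposes the results as boolean
membership arrays ``rows_`` and ``columns_`` plus the richer
``biclusters_found_`` list.  The functional modules remain the primitive
layer; this class only orchestrates them.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, BiclusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import DegenerateBiclusterError
from .init_greedy import cc_initial, opsm_initial, random_initial
from .io_matrix import Bicluster, ExpressionMatrix
from .scoring import msr
from .search import SearchParams, pdns_run


class PDNSBiclustering(BiclusterMixin, BaseEstimator):
    """Pattern-driven neighborhood search biclustering.

    Parameters
    ----------
    alpha, beta : float, default 0.8
        Gene / pair-column quality thresholds of the move operators.
    asr_threshold : float, default 0.7
        Descent stops early once the configuration ASR reaches this value.
    max_descent_iters : int, default 100
        Iteration cap of one descent phase.
    max_stagnant_perturbations : int, default 50
        Stop after this many perturbation cycles without improvement.
    perturb_fraction : float, default 0.1
        Fraction of genes and conditions replaced per perturbation.
    decode_coverage : float, default 0.5
        Decoding keeps conditions combined with at least this fraction of
        the other selected conditions.
    init : {'random', 'cc', 'opsm'} or list of (genes, conditions), default 'random'
        Seed strategy, or explicit initial biclusters as index-tuple pairs.
    n_init : int, default 1
        Number of random seeds (ignored for 'cc'/'opsm'/explicit seeds).
    init_genes, init_conditions : int, default 20 / 5
        Dimensions of random seeds.
    cc_delta : float or None, default None
        MSR target of the node-deletion seed; None uses half the full-matrix
        MSR (shrinks to a clearly-better-than-average block).
    opsm_model_width : int, default 4
        Length of the condition ordering grown by the OPSM-style seed.
    max_add_genes, max_add_columns : int or None
        Caps on per-move additions (None = operator defaults).
    move_order : {'best', 'gc', 'cg'}, default 'best'
        Whether a descent iteration evaluates both operators and takes the
        better candidate, or tries them in a fixed first-improvement order.
    random_state : int, default 0
        Seed for every stochastic component.

    Attributes
    ----------
    rows_, columns_ : bool arrays of shape (n_biclusters, n) / (n_biclusters, m)
        Membership indicators, one row per recovered bicluster.
    biclusters_found_ : list of Bicluster
        Recovered biclusters with their ASR scores, best first.
    asr_values_ : ndarray
        ASR of each recovered bicluster.
    """

    def __init__(
        self,
        alpha: float = 0.8,
        beta: float = 0.8,
        asr_threshold: float = 0.7,
        max_descent_iters: int = 100,
        max_stagnant_perturbations: int = 50,
        perturb_fraction: float = 0.1,
        decode_coverage: float = 0.5,
        init: str | list = "random",
        n_init: int = 1,
        init_genes: int = 20,
        init_conditions: int = 5,
        cc_delta: float | None = None,
        opsm_model_width: int = 4,
        max_add_genes: int | None = 5,
        max_add_columns: int | None = None,
        move_order: str = "best",
        random_state: int = 0,
    ) -> None:
        self.alpha = alpha
        self.beta = beta
        self.asr_threshold = asr_threshold
        self.max_descent_iters = max_descent_iters
        self.max_stagnant_perturbations = max_stagnant_perturbations
        self.perturb_fraction = perturb_fraction
        self.decode_coverage = decode_coverage
        self.init = init
        self.n_init = n_init
        self.init_genes = init_genes
        self.init_conditions = init_conditions
        self.cc_delta = cc_delta
        self.opsm_model_width = opsm_model_width
        self.max_add_genes = max_add_genes
        self.max_add_columns = max_add_columns
        self.move_order = move_order
        self.random_state = random_state

    def fit(self, X, y=None) -> "PDNSBiclustering":
        """Run the search on a genes x conditions matrix."""
        X = check_array(X, ensure_min_samples=2, ensure_min_features=3)
        matrix = ExpressionMatrix(
            X,
            tuple(f"g{i}" for i in range(X.shape[0])),
            tuple(f"c{j}" for j in range(X.shape[1])),
        )
        params = SearchParams(
            alpha=self.alpha,
            beta=self.beta,
            asr_threshold=self.asr_threshold,
            max_descent_iters=self.max_descent_iters,
            max_stagnant_perturbations=self.max_stagnant_perturbations,
            perturb_fraction=self.perturb_fraction,
            decode_coverage=self.decode_coverage,
            max_add_genes=self.max_add_genes,
            max_add_columns=self.max_add_columns,
            move_order=self.move_order,
            seed=self.random_state,
        )
        seeds = self._initial_biclusters(matrix)
        found: list[Bicluster] = []
        traces = []
        for seed_bicluster in seeds:
            try:
                best, trace = pdns_run(matrix, seed_bicluster, params)
            except DegenerateBiclusterError:
                continue
            found.append(best)
            traces.append(trace)
        found.sort(key=lambda b: (-(b.asr or -np.inf), b.genes, b.conditions))
        self.biclusters_found_ = found
        self.traces_ = traces
        self.asr_values_ = np.array([b.asr for b in found], dtype=float)
        n, m = X.shape
        self.rows_ = np.zeros((len(found), n), dtype=bool)
        self.columns_ = np.zeros((len(found), m), dtype=bool)
        for i, b in enumerate(found):
            self.rows_[i, list(b.genes)] = True
            self.columns_[i, list(b.conditions)] = True
        return self

    def _initial_biclusters(self, matrix: ExpressionMatrix) -> list[Bicluster]:
        if isinstance(self.init, str):
            rng = np.random.default_rng(self.random_state)
            if self.init == "random":
                return [
                    random_initial(
                        matrix,
                        min(self.init_genes, matrix.n_genes),
                        min(self.init_conditions, matrix.n_conditions),
                        rng,
                    )
                    for _ in range(self.n_init)
                ]
            if self.init == "cc":
                delta = self.cc_delta
                if delta is None:
                    delta = 0.5 * float(
                        msr(
                            matrix,
                            tuple(range(matrix.n_genes)),
                            tuple(range(matrix.n_conditions)),
                        )
                    )
                return [cc_initial(matrix, delta, rng)]
            if self.init == "opsm":
                width = min(self.opsm_model_width, matrix.n_conditions)
                return [opsm_initial(matrix, width, rng)]
            raise ValueError(f"unknown init strategy {self.init!r}")
        seeds = []
        for genes, conditions in self.init:
            seeds.append(Bicluster(tuple(genes), tuple(conditions)))
        return seeds

    def get_best_bicluster(self) -> Bicluster:
        """The highest-ASR bicluster found by :meth:`fit`."""
        check_is_fitted(self, "biclusters_found_")
        if not self.biclusters_found_:
            raise DegenerateBiclusterError("no bicluster was recovered")
        return self.biclusters_found_[0]
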