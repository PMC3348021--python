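import math

import numpy as np
import pytest

from pdnsbic import (
    Bicluster,
    ImplantSpec,
    SearchParams,
    SyntheticSpec,
    build_behavior_matrix,
    config_asr,
    descent,
    encode,
    generate,
    pdns_run,
    perturb,
)

from conftest import make_matrix


class TestSearchParams:
    def test_zero_perturb_fraction_rejected(self):
        with pytest.raises(ValueError):
            SearchParams(perturb_fraction=0.0)

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            SearchParams(alpha=1.5)
        with pytest.raises(ValueError):
            SearchParams(asr_threshold=2.0)


class TestDescent:
    def repair_fixture(self):
        # noise-free 8x5 implanted block; the seed misses 2 member genes and
        # carries 2 background genes that disagree with the block pattern on
        # more than 30% of the pair-columns
        spec = SyntheticSpec(
            n_genes=20,
            n_conditions=8,
            biclusters=(ImplantSpec(8, 5, "shift", 0.0),),
            seed=37,
        )
        matrix, truth = generate(spec)
        t = truth[0]
        outside = [g for g in range(20) if g not in set(t.genes)]
        seed = Bicluster(tuple(sorted(list(t.genes)[:6] + outside[:2])), t.conditions)
        return matrix, t, seed

    def test_repairs_seed_to_implanted_block(self):
        matrix, truth, seed = self.repair_fixture()
        bm = build_behavior_matrix(matrix)
        config = encode(seed, bm)
        params = SearchParams(alpha=0.7, beta=0.7, asr_threshold=1.0)
        out, trace = descent(config, matrix, params)
        assert set(out.genes) == set(truth.genes)
        assert config_asr(out, matrix) == 1.0

    def test_already_good_config_returned_unchanged(self):
        matrix, truth, _ = self.repair_fixture()
        bm = build_behavior_matrix(matrix)
        config = encode(Bicluster(truth.genes, truth.conditions), bm)
        params = SearchParams(alpha=0.7, beta=0.7, asr_threshold=0.9)
        out, trace = descent(config, matrix, params)
        assert out is config
        assert not [r for r in trace.records if r.accepted]

    def test_accepted_asr_strictly_increases(self):
        matrix, truth, seed = self.repair_fixture()
        bm = build_behavior_matrix(matrix)
        params = SearchParams(alpha=0.7, beta=0.7, asr_threshold=1.0)
        _, trace = descent(encode(seed, bm), matrix, params)
        accepted = [r for r in trace.records if r.accepted]
        assert accepted, "fixture should require repair moves"
        for r in accepted:
            assert r.asr_after > r.asr_before
        afters = [r.asr_after for r in accepted]
        assert afters == sorted(afters)
        assert all(b > a for a, b in zip(afters, afters[1:]))


class TestPerturb:
    def big_matrix(self, n, m):
        return make_matrix(np.zeros((n, m)))

    def test_ten_percent_of_100x20_replaces_10_and_2(self):
        matrix = self.big_matrix(150, 30)
        b = Bicluster(tuple(range(100)), tuple(range(20)))
        rng = np.random.default_rng(0)
        out = perturb(b, matrix, 0.10, rng)
        assert out.n_genes == 100 and out.n_conditions == 20
        assert len(set(b.genes) - set(out.genes)) == 10
        assert len(set(b.conditions) - set(out.conditions)) == 2

    @pytest.mark.parametrize("size", [2, 3, 7, 10, 99, 100, 999, 1000])
    def test_ceiling_formula_for_replacement_counts(self, size):
        matrix = self.big_matrix(2 * size + 2, 5)
        b = Bicluster(tuple(range(size)), (0, 1, 2))
        out = perturb(b, matrix, 0.10, np.random.default_rng(1))
        assert len(set(b.genes) - set(out.genes)) == math.ceil(0.10 * size)

    def test_same_seed_same_result(self):
        matrix = self.big_matrix(40, 12)
        b = Bicluster(tuple(range(10)), tuple(range(6)))
        one = perturb(b, matrix, 0.25, np.random.default_rng(9))
        two = perturb(b, matrix, 0.25, np.random.default_rng(9))
        assert one == two

    def test_small_pool_replaces_what_it_can(self, caplog):
        matrix = self.big_matrix(10, 5)
        b = Bicluster(tuple(range(9)), (0, 1, 2))  # gene pool has 1 outsider
        out = perturb(b, matrix, 0.5, np.random.default_rng(2))
        assert out.n_genes == 9
        assert len(set(out.genes) - set(b.genes)) == 1


class TestPdnsRun:
    def recovery_fixture(self, seed=0):
        spec = SyntheticSpec(
            n_genes=60,
            n_conditions=12,
            biclusters=(ImplantSpec(12, 6, "shift", 0.0),),
            seed=seed,
        )
        return generate(spec)

    def test_optimal_initial_is_returned_immediately(self):
        matrix, truth = self.recovery_fixture()
        t = truth[0]
        params = SearchParams(alpha=0.7, beta=0.7, asr_threshold=0.9,
                              max_stagnant_perturbations=3)
        best, trace = pdns_run(matrix, Bicluster(t.genes, t.conditions), params)
        assert best.asr == 1.0
        assert set(best.genes) == set(t.genes)
        assert set(best.conditions) == set(t.conditions)
        # the very first descent finds the entry config already optimal
        assert trace.best_asr_history[0] == 1.0

    def test_bit_reproducible_under_fixed_seed(self):
        matrix, truth = self.recovery_fixture(3)
        initial = Bicluster(tuple(range(8)), tuple(range(5)))
        params = SearchParams(alpha=0.6, beta=0.6, asr_threshold=0.95,
                              max_descent_iters=20,
                              max_stagnant_perturbations=5, seed=11)
        b1, t1 = pdns_run(matrix, initial, params)
        b2, t2 = pdns_run(matrix, initial, params)
        assert b1 == b2
        assert t1.best_asr_history == t2.best_asr_history
        assert [r.__dict__ for r in t1.records] == [r.__dict__ for r in t2.records]

    def test_best_history_non_decreasing_and_halts(self):
        rng = np.random.default_rng(123)
        for trial in range(5):
            matrix = make_matrix(rng.normal(size=(25, 8)))
            genes = tuple(sorted(rng.choice(25, 6, replace=False)))
            conds = tuple(sorted(rng.choice(8, 4, replace=False)))
            params = SearchParams(alpha=0.6, beta=0.6, asr_threshold=0.95,
                                  max_descent_iters=10,
                                  max_stagnant_perturbations=4, seed=trial)
            best, trace = pdns_run(matrix, Bicluster(genes, conds), params)
            hist = trace.best_asr_history
            assert all(b >= a for a, b in zip(hist, hist[1:]))
            assert best.asr == hist[-1]
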