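import numpy as np
import pytest

from pdnsbic import (
    Bicluster,
    BiclusterPattern,
    Configuration,
    build_behavior_matrix,
    column_quality,
    compute_pattern,
    encode,
    gene_quality,
    mv_c,
    mv_g,
)
from pdnsbic.pattern_moves import _all_gene_qualities, _dominating

from conftest import make_matrix


def trit_config(trits, genes=None, cols=None, n_conditions=None):
    """Build a Configuration directly from a trinary matrix (rows = genes)."""
    trits = np.asarray(trits, dtype=np.int8)
    n, p = trits.shape
    if n_conditions is None:
        # smallest m with m(m-1)/2 >= p
        m = 2
        while m * (m - 1) // 2 < p:
            m += 1
    else:
        m = n_conditions
    full = np.zeros((n, m * (m - 1) // 2), dtype=np.int8)
    full[:, :p] = trits
    from pdnsbic.behavior import BehaviorMatrix

    pairs = tuple((k, q) for k in range(m) for q in range(k + 1, m))
    bm = BehaviorMatrix(full, pairs, m)
    genes = tuple(range(n)) if genes is None else genes
    cols = tuple(range(p)) if cols is None else cols
    return Configuration(genes, cols, bm)


class TestComputePattern:
    def test_identical_rows_give_full_dominance(self):
        config = trit_config([[1, -1, 0], [1, -1, 0], [1, -1, 0]])
        p = compute_pattern(config)
        np.testing.assert_array_equal(p.values, [1, -1, 0])
        np.testing.assert_array_equal(p.dominance, [1.0, 1.0, 1.0])

    def test_majority_column(self):
        config = trit_config(np.array([[1], [1], [-1], [0]]))
        p = compute_pattern(config)
        assert p.values[0] == 1
        assert p.dominance[0] == pytest.approx(0.5)

    def test_tie_prefers_trend_over_no_change(self):
        config = trit_config(np.array([[1], [-1]]))
        assert compute_pattern(config).values[0] == 1
        config = trit_config(np.array([[0], [-1]]))
        assert compute_pattern(config).values[0] == -1


class TestQualities:
    def test_identical_row_scores_100_percent(self):
        p = BiclusterPattern(np.array([1, 0, -1], dtype=np.int8), np.ones(3))
        assert gene_quality(np.array([1, 0, -1]), p) == 1.0

    def test_partial_concordance_counts_positions(self):
        p = BiclusterPattern(np.array([1, 1, 1, 0, -1, -1], dtype=np.int8), np.ones(6))
        row = np.array([1, 1, 0, 0, -1, 1])
        assert gene_quality(row, p) == pytest.approx(4 / 6)

    def test_column_quality_counts_matches(self):
        assert column_quality(np.array([1, 1, -1, 0]), 1) == pytest.approx(0.5)
        assert column_quality(np.array([1, 1, 1]), 1) == 1.0


class TestMoveGenes:
    def quality_fixture(self):
        # 6 config genes over 10 columns; genes 4 and 5 disagree with the
        # pattern on 50% of columns (below alpha = 0.7), the rest agree fully;
        # one outside gene agrees on 9/10 columns and one on 4/10.
        pattern_row = [1, 1, -1, 0, 1, -1, -1, 1, 0, 1]
        bad = [1, 1, -1, 0, 1, 1, 1, -1, 1, -1]
        good_outside = [1, 1, -1, 0, 1, -1, -1, 1, 0, -1]
        poor_outside = [0, 0, 1, 1, -1, -1, -1, 1, 0, -1]
        rows = [pattern_row] * 4 + [bad, bad, good_outside, poor_outside]
        return trit_config(rows, genes=tuple(range(6)))

    def test_bad_genes_removed_good_added(self):
        config = self.quality_fixture()
        pattern = compute_pattern(config)
        new, result = mv_g(config, pattern, alpha=0.7)
        assert set(result.removed) == {4, 5}
        assert result.added == (6,)
        assert new.genes == (0, 1, 2, 3, 6)
        assert new.pair_columns == config.pair_columns  # genes-only operator

    def test_identity_when_everyone_qualifies(self):
        config = trit_config([[1, -1, 0, 1]] * 4)
        pattern = compute_pattern(config)
        new, result = mv_g(config, pattern, alpha=0.7)
        assert result.is_identity
        assert new is config

    def test_quality_contract_on_random_configs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            m = make_matrix(rng.normal(size=(15, 6)))
            bm = build_behavior_matrix(m)
            genes = tuple(sorted(rng.choice(15, 6, replace=False)))
            conds = tuple(sorted(rng.choice(6, 4, replace=False)))
            config = encode(Bicluster(genes, conds), bm)
            pattern = compute_pattern(config)
            alpha = float(rng.uniform(0.4, 0.9))
            new, result = mv_g(config, pattern, alpha)
            if result.reason is not None:
                continue
            quality = _all_gene_qualities(bm, config.pair_columns, pattern)
            assert all(quality[g] >= alpha for g in new.genes)
            assert new.pair_columns == config.pair_columns

    def test_addition_cap_takes_best_first(self):
        config = self.quality_fixture()
        pattern = compute_pattern(config)
        _, capped = mv_g(config, pattern, alpha=0.3, max_add=1)
        # both outside genes qualify at alpha=0.3; the 9/10 one wins the cap
        assert capped.added == (6,)


class TestMoveColumns:
    def test_weak_column_pruned_strong_conditions_kept(self):
        # complete K over 3 conditions; one pair-column weakly dominated
        rng = np.random.default_rng(0)
        values = rng.normal(size=(8, 4))
        values[:, 0] = np.arange(8)  # c0 < c1 for everyone
        values[:, 1] = np.arange(8) + 10
        values[:, 2] = np.arange(8) + 20  # c1 < c2 likewise
        m = make_matrix(values)
        bm = build_behavior_matrix(m)
        config = encode(Bicluster(tuple(range(8)), (0, 1, 2)), bm)
        dom = _dominating(bm.trits[list(config.genes), :])[1]
        weak = [l for l in config.pair_columns if dom[l] < 0.7]
        pattern = compute_pattern(config)
        new, result = mv_c(config, pattern, beta=0.7)
        assert set(result.removed) >= set(weak)
        assert new.genes == config.genes  # columns-only operator

    def test_identity_when_all_columns_strong(self):
        values = np.arange(10.0)[:, None] + np.array([0.0, 1.0, 2.0, 3.0])[None, :]
        m = make_matrix(values)
        bm = build_behavior_matrix(m)
        config = encode(Bicluster(tuple(range(10)), (0, 1, 2, 3)), bm)
        pattern = compute_pattern(config)
        new, result = mv_c(config, pattern, beta=0.7)
        assert result.is_identity

    def test_dominance_contract_on_random_configs(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            m = make_matrix(rng.normal(size=(15, 7)))
            bm = build_behavior_matrix(m)
            genes = tuple(sorted(rng.choice(15, 7, replace=False)))
            conds = tuple(sorted(rng.choice(7, 4, replace=False)))
            config = encode(Bicluster(genes, conds), bm)
            pattern = compute_pattern(config)
            beta = float(rng.uniform(0.4, 0.9))
            new, result = mv_c(config, pattern, beta)
            if result.reason is not None:
                continue
            dom = _dominating(bm.trits[list(genes), :])[1]
            assert all(dom[l] >= beta for l in new.pair_columns)
            assert new.genes == config.genes

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(12, 6)))
        bm = build_behavior_matrix(m)
        config = encode(Bicluster((0, 1, 2, 3, 4), (0, 1, 2, 3)), bm)
        pattern = compute_pattern(config)
        first = mv_c(config, pattern, 0.6)
        second = mv_c(config, pattern, 0.6)
        assert first[0].pair_columns == second[0].pair_columns
        assert first[1] == second[1]
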