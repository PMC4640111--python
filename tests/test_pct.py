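import itertools

import numpy as np
import pytest

import parsimotif as pm
from parsimotif.pct import PCT, all_partitions, count_pcts

from conftest import fig1_pct


def brute_force_best(raw, depth, n, m):
    """Enumeration oracle: score every structure with bic_score and take the max."""
    best = -np.inf
    for pct in pm.enumerate_pcts(depth, m, cap=100_000):
        best = max(best, pm.bic_score(pct, raw, n))
    return best


class TestStructure:
    def test_minimal_and_maximal_contexts(self):
        assert pm.PCT.minimal(2).contexts() == [
            frozenset("".join(t) for t in itertools.product("ACGT", repeat=2))
        ]
        singles = pm.PCT.maximal(1).contexts()
        assert sorted(map(sorted, singles)) == [["A"], ["C"], ["G"], ["T"]]

    def test_five_context_tree(self):
        ctxs = {frozenset(c) for c in fig1_pct().contexts()}
        assert ctxs == {
            frozenset({"AA", "AG", "AT", "CA", "CG", "CT"}),
            frozenset({"GA", "GG", "GT", "TA", "TG", "TT"}),
            frozenset({"AC", "GC"}),
            frozenset({"CC"}),
            frozenset({"TC"}),
        }

    def test_contexts_partition_for_every_enumerated_tree(self):
        for pct in pm.enumerate_pcts(2, 2, cap=100):
            ctxs = pct.contexts()
            union = set().union(*ctxs)
            assert union == {"".join(t) for t in itertools.product("AC", repeat=2)}
            assert sum(len(c) for c in ctxs) == len(union)  # disjoint

    def test_invalid_trees_rejected(self):
        from parsimotif.pct import PCTNode

        with pytest.raises(ValueError, match="partition"):
            PCT((PCTNode((0, 1), ()),))  # labels miss G,T
        with pytest.raises(ValueError, match="same depth"):
            PCT((PCTNode((0, 1), (PCTNode((0, 1, 2, 3), ()),)), PCTNode((2, 3), ())))

    def test_serialization_round_trips(self):
        for pct in [pm.PCT.minimal(0), pm.PCT.minimal(3), pm.PCT.maximal(2), fig1_pct()]:
            assert PCT.from_text(pct.to_text()) == pct
            assert PCT.from_json(pct.to_json()) == pct


class TestAggregation:
    def test_minimal_collapses_to_column_sums(self, rng):
        raw = rng.integers(0, 10, size=(16, 4))
        agg = pm.aggregate_counts(raw, pm.PCT.minimal(2))
        np.testing.assert_array_equal(agg, raw.sum(axis=0, keepdims=True))

    def test_maximal_is_identity(self, rng):
        raw = rng.integers(0, 10, size=(4, 4))
        np.testing.assert_array_equal(pm.aggregate_counts(raw, pm.PCT.maximal(1)), raw)

    def test_five_context_tree_hand_aggregation(self, rng):
        raw = rng.integers(0, 5, size=(16, 4))
        pct = fig1_pct()
        agg = pm.aggregate_counts(raw, pct)
        code = {"".join(t): sum(4 ** (1 - i) * "ACGT".index(ch) for i, ch in enumerate(t))
                for t in map("".join, itertools.product("ACGT", repeat=2))}
        for leaf, members in enumerate(pct.contexts()):
            np.testing.assert_array_equal(agg[leaf], sum(raw[code[s]] for s in members))
        assert agg.sum() == raw.sum()

    def test_depth_mismatch_errors(self):
        with pytest.raises(ValueError, match="does not match"):
            pm.aggregate_counts(np.zeros((4, 4)), pm.PCT.minimal(2))


class TestBicScore:
    def test_hand_computed_values(self):
        raw = np.array([[3, 1, 0, 0]])
        expected = 3 * np.log(0.75) + np.log(0.25) - 1.5 * np.log(4)
        assert pm.bic_score(pm.PCT.minimal(0), raw, 4) == pytest.approx(expected)
        assert pm.bic_score(pm.PCT.minimal(0), raw, 4) == pytest.approx(-4.3287, abs=1e-4)
        uniform = np.array([[1, 1, 1, 1]])
        assert pm.bic_score(pm.PCT.minimal(0), uniform, 4) == pytest.approx(-7.6246, abs=1e-4)

    def test_minimal_depth_invariance(self, rng):
        """A fully merged PCT of any depth scores exactly like the depth-0 PCT."""
        col = rng.integers(1, 30, size=(1, 4))
        n = int(col.sum())
        base = pm.bic_score(pm.PCT.minimal(0), col, n)
        for d in (1, 2, 3):
            # distribute the same column counts over arbitrary contexts
            table = np.zeros((4**d, 4), dtype=int)
            for a in range(4):
                ctxs = rng.integers(0, 4**d, size=col[0, a])
                np.add.at(table, (ctxs, a), 1)
            assert pm.bic_score(pm.PCT.minimal(d), table, n) == pytest.approx(base)

    def test_zero_sample_errors(self):
        with pytest.raises(ValueError):
            pm.bic_score(pm.PCT.minimal(0), np.zeros((1, 4)), 0)


class TestMaximize:
    def test_depth_zero_trivial(self):
        raw = np.array([[5, 3, 2, 1]])
        scored = pm.maximize_bic(raw, 0, 11)
        assert scored.pct == pm.PCT.minimal(0)
        assert scored.score == pytest.approx(pm.bic_score(scored.pct, raw, 11))

    @pytest.mark.parametrize("depth,m,shape", [(1, 4, (4, 4)), (2, 2, (4, 2)), (2, 3, (9, 3))])
    def test_oracle_equivalence(self, depth, m, shape, rng):
        for _ in range(100):
            raw = rng.integers(0, 25, size=shape)
            n = int(raw.sum())
            if n == 0:
                continue
            scored = pm.maximize_bic(raw, depth, n, m=m)
            assert scored.score == pytest.approx(brute_force_best(raw, depth, n, m))
            assert pm.bic_score(scored.pct, raw, n) == pytest.approx(scored.score)

    def test_monotone_in_depth(self, rng):
        """Deeper structure spaces contain every shallower optimum."""
        sites = pm.SiteSet(4, ["".join("ACGT"[a] for a in row)
                               for row in rng.integers(0, 4, size=(50, 4))])
        prev = -np.inf
        for d in range(0, 3):
            raw = pm.context_counts(sites, 4, d)
            score = pm.maximize_bic(raw, min(d, 3), len(sites)).score
            assert score >= prev - 1e-9
            prev = score

    def test_iid_data_selects_minimal(self, rng):
        # 16 contexts x multinomial(312, uniform) columns: no dependence
        raw = rng.multinomial(312, np.full(4, 0.25), size=16)
        scored = pm.maximize_bic(raw, 2, int(raw.sum()))
        assert scored.pct.n_leaves == 1

    def test_tie_break_prefers_fewer_leaves(self):
        # all-zero counts except one context: every structure has equal likelihood 0
        raw = np.zeros((4, 4), dtype=int)
        raw[0, 0] = 7
        scored = pm.maximize_bic(raw, 1, 7)
        assert scored.pct.n_leaves == 1


class TestEnumeration:
    @pytest.mark.parametrize("depth,m,expected", [(1, 4, 15), (2, 2, 6), (0, 4, 1)])
    def test_structure_counts(self, depth, m, expected):
        structures = list(pm.enumerate_pcts(depth, m, cap=1000))
        assert len(structures) == expected
        assert len(set(structures)) == expected  # each exactly once
        assert count_pcts(depth, m) == expected

    def test_cap_guard(self):
        with pytest.raises(ValueError, match="cap"):
            list(pm.enumerate_pcts(2, 4, cap=100))

    def test_partition_count_is_bell_number(self):
        assert len(all_partitions(4)) == 15
        assert len(all_partitions(3)) == 5
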