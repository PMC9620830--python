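"""Aggregation methods: hand oracles, closed forms, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from listagg import (
    AggregationError,
    Dataset,
    GeneList,
    ListKind,
    UnavailableMethodError,
    UnknownMethodError,
    available_methods,
    birra,
    borda,
    build_rank_matrix,
    maic,
    mc3,
    repeat_choice,
    rra,
    run_method,
    stuart,
    vote_counting,
)
from listagg.aggregate import mc3_transition_matrix, stuart_scores


def ds(*lists, universe=None):
    return Dataset.from_lists(lists, universe=universe)


def rl(name, *entities, category=None):
    return GeneList(name, category or name, ListKind.RANKED, entities)


def ul(name, *entities, category=None):
    return GeneList(name, category or name, ListKind.UNRANKED, entities)


class TestRankMatrix:
    def test_ranked_column_definition(self):
        mat = build_rank_matrix(ds(rl("l", "a", "b"), universe="abcd"))
        col = dict(zip(mat.entities, mat.values[:, 0]))
        assert col == {"a": 0.25, "b": 0.5, "c": 1.0, "d": 1.0}

    def test_unranked_half_length_rule(self):
        mat = build_rank_matrix(ds(ul("u", "a", "b", "c"), universe="abcd"))
        col = dict(zip(mat.entities, mat.values[:, 0]))
        assert col == {"a": 0.375, "b": 0.375, "c": 0.375, "d": 1.0}

    def test_exclude_unranked_columns(self):
        mat = build_rank_matrix(
            ds(rl("l", "a"), ul("u", "b"), universe="ab"), include_unranked=False
        )
        assert mat.list_names == ("l",)

    def test_ranked_column_strictly_increasing_down_the_list(self):
        mat = build_rank_matrix(ds(rl("l", "c", "a", "b"), universe="abcd"))
        ranks = dict(zip(mat.entities, mat.values[:, 0]))
        assert ranks["c"] < ranks["a"] < ranks["b"] < ranks["d"] == 1.0


class TestBorda:
    def test_mean_on_symmetric_lists(self, toy_dataset):
        res = borda(toy_dataset, "MEAN")
        assert res.scores["a"] == res.scores["b"] == pytest.approx(0.5)
        assert res.scores["c"] == pytest.approx(1.0)
        assert res.ranking[-1] == "c"

    def test_geo_on_symmetric_lists(self, toy_dataset):
        res = borda(toy_dataset, "GEO")
        expected = math.sqrt((1 / 3) * (2 / 3))
        assert res.scores["a"] == pytest.approx(expected)
        assert res.scores["b"] == pytest.approx(expected)
        assert res.scores["c"] == pytest.approx(1.0)

    @pytest.mark.parametrize("stat", ["MEAN", "MED", "GEO"])
    def test_single_list_returns_its_order(self, stat):
        res = borda(ds(rl("l", "b", "c", "a")), stat)
        assert res.ranking == ("b", "c", "a")

    def test_no_usable_lists_is_an_error(self):
        with pytest.raises(AggregationError, match="no usable lists"):
            borda(ds(ul("u", "a", "b")), "MEAN", mix=False)

    def test_unknown_stat(self, toy_dataset):
        with pytest.raises(ValueError, match="stat"):
            borda(toy_dataset, "MODE")


class TestVoteCounting:
    def test_counts(self):
        d = ds(rl("a1", "g1", "g2"), ul("a2", "g1"), rl("a3", "g3"), universe=["g1", "g2", "g3"])
        res = vote_counting(d)
        assert res.scores == {"g1": 2.0, "g2": 1.0, "g3": 1.0}
        assert res.ranking[0] == "g1"

    def test_unranked_permutation_invariance(self):
        a = vote_counting(ds(rl("r", "x", "y"), ul("u", "p", "q"), universe="pqxy"))
        b = vote_counting(ds(rl("r", "x", "y"), ul("u", "q", "p"), universe="pqxy"))
        assert a.ranking == b.ranking and a.scores == b.scores

    def test_tie_break_matches_exhaustive_rule(self):
        # independent oracle: count desc, mean normalized rank over ranked
        # lists asc, entity id asc — computed with plain python
        import itertools

        universe = ["g1", "g2", "g3"]
        for perm1 in itertools.permutations(universe):
            for perm2 in itertools.permutations(universe, 2):
                d = ds(rl("r1", *perm1), rl("r2", *perm2), universe=universe)
                res = vote_counting(d)
                g = len(universe)
                counts = {e: sum(e in gl.entities for gl in d.lists) for e in universe}
                mean_rank = {
                    e: np.mean(
                        [
                            (gl.entities.index(e) + 1) / g if e in gl.entities else 1.0
                            for gl in d.lists
                        ]
                    )
                    for e in universe
                }
                expected = sorted(universe, key=lambda e: (-counts[e], mean_rank[e], e))
                assert list(res.ranking) == expected


class TestRepeatChoice:
    def test_single_ranked_list_then_absent_by_id(self):
        res = repeat_choice(ds(rl("l", "c", "a"), universe="abcd"))
        assert res.ranking == ("c", "a", "b", "d")

    def test_unranked_tie_refined_by_second_list(self):
        res = repeat_choice(ds(ul("u", "a", "b"), rl("r", "b", "a")))
        assert res.ranking[:2] == ("b", "a")

    def test_duplicate_lists_idempotent(self):
        order = ("c", "a", "b")
        res = repeat_choice(ds(rl("l1", *order), rl("l2", *order)))
        assert res.ranking == order

    def test_depends_on_list_order(self):
        a = repeat_choice(ds(rl("l1", "a", "b"), rl("l2", "b", "a")))
        b = repeat_choice(ds(rl("l2", "b", "a"), rl("l1", "a", "b")))
        assert a.ranking == ("a", "b") and b.ranking == ("b", "a")


class TestRRA:
    def test_single_list_score_is_uniform_cdf(self):
        res = rra(ds(rl("l", "a", "b", "c", "d")))
        assert res.scores["a"] == pytest.approx(0.25)
        assert res.scores["d"] == pytest.approx(1.0)

    def test_two_list_closed_form(self):
        # both lists rank g first among 10: r=(0.1, 0.1);
        # rho = min(1-(1-0.1)^2, 0.1^2) = 0.01, Bonferroni x2
        universe = [f"g{i}" for i in range(10)]
        rest = universe[1:]
        d = ds(rl("l1", "g0", *rest), rl("l2", "g0", *rest), universe=universe)
        res = rra(d)
        assert res.scores["g0"] == pytest.approx(0.02)
        assert res.ranking[0] == "g0"

    def test_absent_everywhere_scores_one(self):
        res = rra(ds(rl("l", "a"), universe="ab"))
        assert res.scores["b"] == pytest.approx(1.0)


class TestStuart:
    def test_single_list_score_is_rank(self):
        res = stuart(ds(rl("l", "a", "b")))
        assert res.scores["a"] == pytest.approx(0.5)
        assert res.scores["b"] == pytest.approx(1.0)

    def test_two_list_recursion_by_hand(self):
        # r = (0.1, 0.1): 2!*(0.1*0.1 - 0.1^2/2) = 0.01
        assert stuart_scores(np.array([[0.1, 0.1]]))[0] == pytest.approx(0.01)

    def test_certain_event(self):
        assert stuart_scores(np.array([[1.0, 1.0, 1.0]]))[0] == pytest.approx(1.0)

    def test_matches_brute_force_inclusion_exclusion(self):
        # independent oracle: P(U_(k) <= r_k for all k) by dense Monte Carlo
        rng = np.random.default_rng(3)
        r = np.sort(rng.uniform(0.2, 0.9, size=3))
        u = np.sort(rng.uniform(size=(200_000, 3)), axis=1)
        mc = np.all(u <= r, axis=1).mean()
        exact = stuart_scores(r[None, :])[0]
        assert abs(exact - mc) < 4 * math.sqrt(mc * (1 - mc) / 200_000)


class TestMC3:
    def test_unanimous_pair_absorbs_as_teleport_vanishes(self):
        d = ds(rl("l1", "a", "b"), rl("l2", "a", "b"))
        res = mc3(d, teleport=1e-6)
        assert res.scores["a"] > 0.99
        assert res.ranking[0] == "a"

    def test_perfect_cycle_is_uniform(self):
        d = ds(rl("l1", "a", "b"), rl("l2", "b", "c"), rl("l3", "c", "a"))
        res = mc3(d)
        assert res.scores["a"] == pytest.approx(1 / 3, abs=1e-8)
        assert res.scores["b"] == pytest.approx(1 / 3, abs=1e-8)

    def test_matches_dense_eigen_solution(self):
        rng = np.random.default_rng(0)
        ents = [f"g{i}" for i in range(5)]
        for _ in range(5):
            lists = [
                rl(f"l{j}", *rng.permutation(ents)[: rng.integers(3, 6)])
                for j in range(3)
            ]
            d = ds(*lists, universe=ents)
            res = mc3(d, tol=1e-12)
            p, states = mc3_transition_matrix(d)
            vals, vecs = np.linalg.eig(p.T)
            pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
            pi /= pi.sum()
            for s, v in zip(states, pi):
                assert res.scores[s] == pytest.approx(v, abs=1e-8)

    def test_requires_ranked_list(self):
        with pytest.raises(AggregationError, match="RANKED"):
            mc3(ds(ul("u", "a", "b")))

    def test_off_support_entities_appended_by_id(self):
        res = mc3(ds(rl("l", "b", "a"), universe="abcz"))
        assert res.ranking[2:] == ("c", "z")


class TestBIRRA:
    def _pair(self, order):
        return ds(rl("l1", *order), rl("l2", *order))

    def test_identical_lists_preserve_input_order(self):
        order = tuple(f"g{i:02d}" for i in np.random.default_rng(5).permutation(30))
        res = birra(self._pair(order), n_bins=5)
        assert res.ranking[: len(order)] == order

    def test_column_exchangeability(self):
        rng = np.random.default_rng(8)
        o1 = tuple(f"g{i}" for i in rng.permutation(20))
        o2 = tuple(f"g{i}" for i in rng.permutation(20))
        a = birra(ds(rl("l1", *o1), rl("l2", *o2)), n_bins=4)
        b = birra(ds(rl("l2", *o2), rl("l1", *o1)), n_bins=4)
        assert a.ranking == b.ranking

    def test_informative_list_has_wider_odds_range(self):
        rng = np.random.default_rng(1)
        truth = [f"g{i:03d}" for i in range(300)]
        noise_order = list(truth)
        rng.shuffle(noise_order)
        d = ds(rl("informative", *truth[:150]), rl("noise", *noise_order[:150]),
               universe=truth)
        res = birra(d, n_bins=10)
        ranges = res.extras["list_log_odds_range"]
        assert ranges["informative"] > ranges["noise"]

    def test_degenerate_bins_reduced_with_warning(self):
        d = self._pair(("a", "b", "c"))
        with pytest.warns(UserWarning, match="reducing"):
            birra(d, n_bins=50)

    def test_requires_two_ranked_lists(self):
        with pytest.raises(AggregationError, match=">= 2 RANKED"):
            birra(ds(rl("l", "a", "b")))


class TestMAIC:
    def test_two_category_symmetric_unranked_lists(self):
        d = ds(
            ul("u1", "a", "b", category="c1"),
            ul("u2", "a", "b", category="c2"),
            universe="abz",
        )
        res = maic(d)
        assert res.list_weights["u1"] == pytest.approx(res.list_weights["u2"])
        w = res.list_weights["u1"]
        assert res.scores["a"] == pytest.approx(2 * w)
        assert res.scores["z"] == 0.0

    def test_duplicate_list_in_category_does_not_double_count(self):
        base = ds(
            ul("u1", "a", "b", category="c1"),
            ul("other", "b", "c", category="c2"),
            universe="abc",
        )
        dup = ds(
            ul("u1", "a", "b", category="c1"),
            ul("u1b", "a", "b", category="c1"),
            ul("other", "b", "c", category="c2"),
            universe="abc",
        )
        res_base, res_dup = maic(base), maic(dup)
        for e in "abc":
            assert res_dup.scores[e] == pytest.approx(res_base.scores[e], rel=1e-6)

    def test_weights_gauge_max_one(self, toy_dataset):
        res = maic(toy_dataset)
        assert max(res.list_weights.values()) == pytest.approx(1.0)
        assert all(w >= 0 for w in res.list_weights.values())

    def test_accepts_mixed_input(self, mixed_dataset):
        res = maic(mixed_dataset)
        assert res.used_unranked
        assert set(res.ranking) == mixed_dataset.universe


class TestDispatch:
    def test_mix_variant_equals_plain_on_ranked_only(self, toy_dataset):
        for mix_name, plain_name in [
            ("rMixMEAN", "rMEAN"),
            ("rMixGEO", "rGEO"),
            ("rMixMED", "rMED"),
            ("MixStuart", "Stuart"),
        ]:
            a = run_method(mix_name, toy_dataset)
            b = run_method(plain_name, toy_dataset)
            assert a.ranking == b.ranking
            assert a.scores == b.scores

    def test_plain_variant_ignores_unranked(self, mixed_dataset):
        ranked_only = Dataset.from_lists(
            mixed_dataset.ranked_lists(), universe=mixed_dataset.universe
        )
        a = run_method("rGEO", mixed_dataset)
        b = run_method("rGEO", ranked_only)
        assert a.ranking == b.ranking
        assert not a.used_unranked

    def test_unavailable_method_recognized(self, toy_dataset):
        with pytest.raises(UnavailableMethodError, match="BiGbottom"):
            run_method("BiGbottom", toy_dataset)

    def test_unknown_method_lists_registry(self, toy_dataset):
        with pytest.raises(UnknownMethodError, match="rMEAN"):
            run_method("Borda", toy_dataset)

    def test_registry_covers_all_method_names(self):
        assert set(available_methods()) == {
            "rMEAN", "rMED", "rGEO", "rMixMEAN", "rMixMED", "rMixGEO",
            "Stuart", "MixStuart", "RRA", "VC", "RepeatChoice", "MC3",
            "BIRRA", "MAIC",
        }


def _random_dataset(rng, n_ent=8, n_lists=3, with_unranked=True):
    ents = [f"g{i}" for i in range(n_ent)]
    lists = []
    for j in range(n_lists):
        k = int(rng.integers(2, n_ent + 1))
        perm = list(rng.permutation(ents)[:k])
        kind = (
            ListKind.UNRANKED
            if with_unranked and j == n_lists - 1
            else ListKind.RANKED
        )
        lists.append(GeneList(f"l{j}", f"c{j}", kind, tuple(perm)))
    return Dataset.from_lists(lists, universe=ents)


ORDER_FREE_METHODS = [
    "rMEAN", "rMED", "rGEO", "rMixMEAN", "rMixGEO", "Stuart", "MixStuart",
    "RRA", "VC", "MC3", "BIRRA", "MAIC",
]


class TestInvariances:
    @pytest.mark.parametrize("method", ORDER_FREE_METHODS)
    def test_list_order_invariance(self, method):
        rng = np.random.default_rng(13)
        d = _random_dataset(rng)
        shuffled = Dataset.from_lists(d.lists[::-1], universe=d.universe)
        a = run_method(method, d)
        b = run_method(method, shuffled)
        assert a.ranking == b.ranking

    @pytest.mark.parametrize("method", ORDER_FREE_METHODS + ["RepeatChoice"])
    def test_score_equivariance_under_relabelling(self, method):
        rng = np.random.default_rng(21)
        d = _random_dataset(rng)
        ents = sorted(d.universe)
        new_ids = [f"h{i}" for i in rng.permutation(len(ents))]
        bij = dict(zip(ents, new_ids))
        relabelled = Dataset.from_lists(
            [
                GeneList(gl.name, gl.category, gl.kind, tuple(bij[e] for e in gl.entities))
                for gl in d.lists
            ],
            universe=[bij[e] for e in ents],
        )
        a = run_method(method, d)
        b = run_method(method, relabelled)
        for e in ents:
            assert b.scores[bij[e]] == pytest.approx(a.scores[e], rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("method", ORDER_FREE_METHODS + ["RepeatChoice"])
    def test_ranking_equivariance_under_order_preserving_relabelling(self, method):
        rng = np.random.default_rng(34)
        d = _random_dataset(rng)
        bij = {e: f"x_{e}" for e in d.universe}  # preserves lexicographic order
        relabelled = Dataset.from_lists(
            [
                GeneList(gl.name, gl.category, gl.kind, tuple(bij[e] for e in gl.entities))
                for gl in d.lists
            ],
            universe=[bij[e] for e in d.universe],
        )
        a = run_method(method, d)
        b = run_method(method, relabelled)
        assert tuple(bij[e] for e in a.ranking) == b.ranking

    @given(st.integers(min_value=0, max_value=50))
    def test_mix_equals_plain_without_unranked_lists(self, seed):
        rng = np.random.default_rng(seed)
        d = _random_dataset(rng, with_unranked=False)
        for mix_name, plain_name in [("rMixMEAN", "rMEAN"), ("rMixGEO", "rGEO"),
                                     ("MixStuart", "Stuart")]:
            assert run_method(mix_name, d).ranking == run_method(plain_name, d).ranking
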