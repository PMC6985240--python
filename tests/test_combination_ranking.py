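import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_panel, random_surface
from qpop import (
    CombinationAssignment,
    Regimen,
    count_combinations,
    enumerate_combinations,
    locate_regimen,
    rank_combinations,
    top_combinations,
)
from qpop.errors import ValidationError
from qpop.surface import QuadraticSurface


class TestEnumerate:
    def test_paper_counts(self):
        # 11 drugs, 2 non-zero levels: the printed totals
        assert len(enumerate_combinations(11, 5, 2)) == 14784
        assert len(enumerate_combinations(11, 3, 2)) == 1320

    def test_tiny_exhaustive(self):
        combos = enumerate_combinations(2, 1, 1)
        assert [(c.members, c.levels) for c in combos] == [((0,), (1,)), ((1,), (1,))]

    def test_matches_nested_loop_oracle(self):
        ours = [(c.members, c.levels) for c in enumerate_combinations(5, 2, 3)]
        assert ours == oracles.enumerate_nested(5, 2, 3)

    def test_no_duplicates(self):
        combos = enumerate_combinations(6, 3, 2)
        assert len(set((c.members, c.levels) for c in combos)) == len(combos)

    def test_k_larger_than_n(self):
        with pytest.raises(ValidationError):
            enumerate_combinations(3, 4, 2)

    def test_k_zero(self):
        with pytest.raises(ValidationError):
            enumerate_combinations(3, 0, 2)

    @given(n=st.integers(1, 8), k=st.integers(1, 8), L=st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_count_formula(self, n, k, L):
        if k > n:
            return
        combos = enumerate_combinations(n, k, L)
        assert len(combos) == count_combinations(n, k, L) == len(
            oracles.enumerate_nested(n, k, L)
        )


class TestRank:
    def test_matches_score_then_sort_oracle(self, rng):
        for n in (3, 4, 6):
            panel = make_panel(n)
            surface = random_surface(panel, rng)
            for k in range(1, n + 1):
                ranking = rank_combinations(surface, k)
                oracle_order, oracle_scores = oracles.score_then_sort(
                    surface.coefficients, n, k, panel.L
                )
                assert list(ranking.order) == oracle_order
                np.testing.assert_allclose(ranking.scores, oracle_scores, atol=1e-12)

    def test_strong_single_drug_dominates_top(self):
        panel = make_panel(5)
        beta_lin = np.zeros(5)
        beta_lin[2] = -1.0  # favors drug d2 at level 2 (coded +1)
        surface = QuadraticSurface(panel=panel, beta0=1.0, beta_lin=beta_lin,
                                   beta_quad=np.zeros(5), beta_int=np.zeros(10))
        ranking = rank_combinations(surface, 2)
        # every entry until d2-free combos start must contain drug index 2
        n_with = count_combinations(4, 1, 2) * 2  # subsets containing d2
        for a, _, rank in top_combinations(ranking, n_with // 2):
            assert 2 in a.members and a.levels[a.members.index(2)] == 2

    def test_all_zero_coefficients_keep_enumeration_order(self):
        panel = make_panel(4)
        surface = QuadraticSurface(panel=panel, beta0=0.7, beta_lin=np.zeros(4),
                                   beta_quad=np.zeros(4), beta_int=np.zeros(6))
        ranking = rank_combinations(surface, 2)
        assert list(ranking.order) == list(range(len(ranking)))
        assert np.all(ranking.scores == 0.7)
        assert ranking.tie_rule_id == "enumeration-order"

    def test_full_size_properties(self, truth11):
        ranking = rank_combinations(truth11, 5)
        assert len(ranking) == 14784
        ranks = [rank for _, _, rank in ranking.entries()]
        assert sorted(ranks) == list(range(1, 14785))
        scores = [s for _, s, _ in ranking.entries()]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    def test_relabeling_invariance(self, rng):
        panel = make_panel(5)
        surface = random_surface(panel, rng)
        ranking = rank_combinations(surface, 2)

        perm = [4, 2, 0, 3, 1]
        from qpop import DrugPanel

        ppanel = DrugPanel(tuple(panel.drugs[i] for i in perm))
        inv = np.argsort(perm)
        coefs = surface.coefficients
        plin = coefs[1:6][perm]
        pquad = coefs[6:11][perm]
        pairs = list(itertools.combinations(range(5), 2))
        pint = np.zeros(10)
        for pos, (i, j) in enumerate(pairs):
            oi, oj = sorted((perm[i], perm[j]))
            pint[pos] = coefs[11 + pairs.index((oi, oj))]
        psurface = QuadraticSurface(panel=ppanel, beta0=coefs[0], beta_lin=plin,
                                    beta_quad=pquad, beta_int=pint)
        pranking = rank_combinations(psurface, 2)

        def as_named(r, panel):
            return [
                (frozenset(zip((panel.names[i] for i in a.members), a.levels)), round(s, 10))
                for a, s, _ in r.entries()
            ]

        # same multiset of (named combo, score) at each score level
        ours = sorted(as_named(ranking, panel), key=lambda t: (t[1], sorted(t[0])))
        theirs = sorted(as_named(pranking, ppanel), key=lambda t: (t[1], sorted(t[0])))
        assert ours == theirs

    def test_more_synergy_never_worsens_best_pair_rank(self, rng):
        panel = make_panel(5)
        surface = random_surface(panel, rng)
        pairs = list(itertools.combinations(range(5), 2))
        target = pairs.index((1, 3))

        def best_rank(s):
            ranking = rank_combinations(s, 2)
            return locate_regimen(ranking, Regimen("probe", ("d1", "d3")))[0]

        prev = None
        for delta in (0.0, -0.1, -0.3, -0.8):
            b = surface.beta_int.copy()
            b[target] += delta
            s = QuadraticSurface(panel=panel, beta0=surface.beta0,
                                 beta_lin=surface.beta_lin,
                                 beta_quad=surface.beta_quad, beta_int=b)
            r = best_rank(s)
            if prev is not None:
                assert r <= prev
            prev = r


class TestLocateRegimen:
    def test_rank_one_assignment(self, rng):
        panel = make_panel(4)
        surface = random_surface(panel, rng)
        ranking = rank_combinations(surface, 2)
        best, _, _ = ranking.entry(1)
        reg = Regimen(
            name="best",
            members=tuple(panel.names[i] for i in best.members),
            levels=best.levels,
        )
        rank, matched = locate_regimen(ranking, reg)
        assert rank == 1
        assert len(matched) == 1

    def test_best_over_levels_equals_brute_min(self, rng):
        panel = make_panel(5)
        surface = random_surface(panel, rng)
        ranking = rank_combinations(surface, 3)
        reg = Regimen(name="trip", members=("d0", "d2", "d4"))
        rank, matched = locate_regimen(ranking, reg)
        # brute force: every level assignment looked up individually
        explicit = []
        for levels in itertools.product((1, 2), repeat=3):
            a = CombinationAssignment((0, 2, 4), levels)
            explicit.append(ranking.rank_of_assignment(a))
        assert rank == min(explicit)
        assert len(matched) == 8
        assert [m[2] for m in matched] == sorted(explicit)

    def test_unknown_drug_named_in_error(self, rng):
        panel = make_panel(4)
        ranking = rank_combinations(random_surface(panel, rng), 2)
        with pytest.raises(ValidationError, match="nosuchdrug"):
            locate_regimen(ranking, Regimen(name="x", members=("d0", "nosuchdrug")))

    def test_size_mismatch(self, rng):
        panel = make_panel(4)
        ranking = rank_combinations(random_surface(panel, rng), 2)
        with pytest.raises(ValidationError, match="k="):
            locate_regimen(ranking, Regimen(name="x", members=("d0", "d1", "d2")))


class TestTopCombinations:
    def test_full_length(self, rng):
        panel = make_panel(4)
        ranking = rank_combinations(random_surface(panel, rng), 2)
        assert len(top_combinations(ranking, len(ranking))) == len(ranking)

    def test_m_zero(self, rng):
        panel = make_panel(4)
        ranking = rank_combinations(random_surface(panel, rng), 2)
        with pytest.raises(ValidationError):
            top_combinations(ranking, 0)

    def test_m_too_large(self, rng):
        panel = make_panel(4)
        ranking = rank_combinations(random_surface(panel, rng), 2)
        with pytest.raises(ValidationError):
            top_combinations(ranking, len(ranking) + 1)

    def test_top_one_contains_strong_drug(self):
        panel = make_panel(4)
        beta_lin = np.zeros(4)
        beta_lin[1] = -2.0
        surface = QuadraticSurface(panel=panel, beta0=1.0, beta_lin=beta_lin,
                                   beta_quad=np.zeros(4), beta_int=np.zeros(6))
        ranking = rank_combinations(surface, 2)
        (a, _, _), = top_combinations(ranking, 1)
        assert 1 in a.members
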