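"""Unit and property tests for the group-structured simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import groupsel as gs
from groupsel.analytics import DegenerateWeightsError
from groupsel.model import (
    GroupState,
    ModelParams,
    PopulationState,
    allocate_daughters,
    death_probs,
    init_heterogeneous,
    init_homogeneous,
    reproduction_probs,
    simulate,
    step_death,
    step_reproduction,
    step_split,
)


def pop(pairs):
    a, b = zip(*pairs)
    return PopulationState(np.array(a), np.array(b))


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(b=5.0),
            dict(b=0.5),
            dict(a=-0.1),
            dict(a=1.5),
            dict(mu=1.2),
            dict(K=1),
            dict(mode="bogus"),
        ],
    )
    def test_rejects_out_of_range(self, kw):
        base = dict(K=10, K_g=50, mu=0.5)
        with pytest.raises(ValueError):
            ModelParams(**{**base, **kw})


class TestReproduction:
    def test_probability_examples(self):
        p = ModelParams(K=10, K_g=10, mu=0.0, b=2.0)
        assert reproduction_probs(GroupState(2, 3), p) == pytest.approx((0.1, 0.3))
        # no resources left at the splitting threshold
        assert reproduction_probs(GroupState(5, 5), p) == (0.0, 0.0)
        # maximizing composition saturates the step exactly at b = 4
        p4 = ModelParams(K=10, K_g=10, mu=0.0, b=4.0)
        pA, pB = reproduction_probs(GroupState(0, 5), p4)
        assert (pA, pB) == pytest.approx((0.0, 1.0))

    def test_sum_bounded_by_one(self):
        p = ModelParams(K=12, K_g=10, mu=0.0, b=4.0)
        for nA in range(13):
            for nB in range(13 - nA):
                pA, pB = reproduction_probs(GroupState(nA, nB), p)
                assert pA + pB <= 1.0 + 1e-12

    def test_step_empirical_frequency(self, rng):
        # lone group (0,3), K=10, b=1: birth probability 0.21
        p = ModelParams(K=10, K_g=10, mu=0.0, b=1.0)
        n_reps, hits = 20000, 0
        for _ in range(n_reps):
            new = step_reproduction(pop([(0, 3)]), p, rng)
            hits += int(new.n_B[0] == 4)
        se = np.sqrt(0.21 * 0.79 / n_reps)
        assert hits / n_reps == pytest.approx(0.21, abs=3 * se)

    def test_full_group_never_reproduces(self, rng):
        p = ModelParams(K=10, K_g=10, mu=0.0, b=4.0)
        s = pop([(10, 0)])
        for _ in range(100):
            s = step_reproduction(s, p, rng)
        assert (int(s.n_A[0]), int(s.n_B[0])) == (10, 0)

    def test_parallel_update_order_invariant(self, rng):
        # birth marginals per group depend only on the entry composition,
        # not on the group's position in the population array
        p = ModelParams(K=10, K_g=10, mu=0.0, b=2.0)
        n_reps = 20000
        counts = {"fwd": [0, 0], "rev": [0, 0]}
        for _ in range(n_reps):
            f = step_reproduction(pop([(2, 2), (0, 4)]), p, rng)
            counts["fwd"][0] += int(f.n_A[0] + f.n_B[0] == 5)
            counts["fwd"][1] += int(f.n_A[1] + f.n_B[1] == 5)
            r = step_reproduction(pop([(0, 4), (2, 2)]), p, rng)
            counts["rev"][0] += int(r.n_A[1] + r.n_B[1] == 5)
            counts["rev"][1] += int(r.n_A[0] + r.n_B[0] == 5)
        for k in range(2):
            diff = abs(counts["fwd"][k] - counts["rev"][k]) / n_reps
            assert diff < 4 * np.sqrt(0.5 / n_reps)


class TestDeath:
    def test_prob_examples(self):
        groups = pop([(5, 0), (0, 5)])
        rel = ModelParams(K=10, K_g=10, mu=0.6, a=0.5, mode="relative")
        np.testing.assert_allclose(death_probs(groups, rel), [0.2, 0.4])
        ab = ModelParams(K=10, K_g=10, mu=0.6, a=0.5, mode="absolute")
        np.testing.assert_allclose(death_probs(groups, ab), [0.15, 0.3])

    def test_normalization(self):
        groups = pop([(3, 1), (1, 7), (5, 0)])
        rel = ModelParams(K=10, K_g=10, mu=0.37, a=0.8, mode="relative")
        assert death_probs(groups, rel).sum() == pytest.approx(0.37)
        ab = ModelParams(K=10, K_g=10, mu=0.37, a=0.8, mode="absolute")
        assert death_probs(groups, ab).sum() <= 0.37 + 1e-12
        neutral = ModelParams(K=10, K_g=10, mu=0.37, mode="neutral")
        np.testing.assert_allclose(death_probs(groups, neutral), 0.37 / 3)

    def test_neutral_reduction_exact(self):
        # a = 0 in either mode is identical to the neutral distribution
        groups = pop([(4, 2), (0, 9), (7, 0), (1, 1)])
        neutral = death_probs(groups, ModelParams(K=10, K_g=10, mu=0.41))
        for mode in ("relative", "absolute"):
            p = ModelParams(K=10, K_g=10, mu=0.41, a=0.0, mode=mode)
            np.testing.assert_array_equal(death_probs(groups, p), neutral)

    def test_degenerate_weights(self):
        groups = pop([(5, 0), (9, 0)])
        p = ModelParams(K=10, K_g=10, mu=0.5, a=1.0, mode="relative")
        with pytest.raises(DegenerateWeightsError):
            death_probs(groups, p)

    def test_step_marginals_match_probs(self, rng):
        groups = [(5, 0), (2, 6), (0, 5)]
        n_reps = 30000
        for mode in ("neutral", "relative", "absolute"):
            p = ModelParams(K=10, K_g=10, mu=0.6, a=0.5, mode=mode)
            expected = death_probs(pop(groups), p)
            removed = np.zeros(3)
            for _ in range(n_reps):
                new = step_death(pop(groups), p, rng)
                if new.n_groups == 2:
                    # identify the removed group by composition
                    remaining = {(int(a), int(b)) for a, b in zip(new.n_A, new.n_B)}
                    for j, g in enumerate(groups):
                        if g not in remaining:
                            removed[j] += 1
            freq = removed / n_reps
            se = np.sqrt(expected * (1 - expected) / n_reps)
            assert np.all(np.abs(freq - expected) < 4 * se)

    def test_certain_death_single_group(self, rng):
        p = ModelParams(K=10, K_g=10, mu=1.0, mode="neutral")
        new = step_death(pop([(3, 3)]), p, rng)
        assert new.n_groups == 0

    def test_protected_groups(self, rng):
        # a=1: all-A groups can never be selected (relative) or killed (absolute)
        rel = ModelParams(K=10, K_g=10, mu=0.5, a=1.0, mode="relative")
        survivors_all_A = True
        for _ in range(2000):
            new = step_death(pop([(5, 0), (0, 5)]), rel, rng)
            if new.n_groups == 1:
                survivors_all_A &= int(new.n_B[0]) == 0
        assert survivors_all_A
        ab = ModelParams(K=10, K_g=10, mu=1.0, a=1.0, mode="absolute")
        for _ in range(200):
            assert step_death(pop([(7, 0)]), ab, rng).n_groups == 1


class TestSplitting:
    def test_allocation_enumeration(self, rng):
        # (1,1) parent: four allocations, each with probability 1/4
        counts = {}
        n_reps = 40000
        for _ in range(n_reps):
            d1, _ = allocate_daughters(1, 1, rng)
            counts[(d1.n_A, d1.n_B)] = counts.get((d1.n_A, d1.n_B), 0) + 1
        assert set(counts) == {(0, 0), (0, 1), (1, 0), (1, 1)}
        for v in counts.values():
            assert v / n_reps == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / n_reps))

    def test_allocation_conservation(self, rng):
        for _ in range(2000):
            nA = int(rng.integers(0, 11))
            nB = 10 - nA
            d1, d2 = allocate_daughters(nA, nB, rng)
            assert d1.n_A + d2.n_A == nA
            assert d1.n_B + d2.n_B == nB
            assert min(d1.n_A, d1.n_B, d2.n_A, d2.n_B) >= 0

    def test_no_A_parent_gives_no_A_daughters(self, rng):
        for _ in range(50):
            d1, d2 = allocate_daughters(0, 10, rng)
            assert d1.n_A == 0 and d2.n_A == 0

    def test_split_conserves_individuals(self, rng):
        p = ModelParams(K=10, K_g=50, mu=0.0)
        s = pop([(4, 6), (2, 3)])
        new = step_split(s, p, rng)
        assert new.n_A.sum() == s.n_A.sum()
        assert new.n_B.sum() == s.n_B.sum()

    def test_uniform_choice_among_full_groups(self, rng):
        # distinguishable full parents: (10,0) and (0,10); each splits ~1/2
        p = ModelParams(K=10, K_g=50, mu=0.0)
        split_A = 0
        n_reps = 20000
        for _ in range(n_reps):
            new = step_split(pop([(10, 0), (0, 10)]), p, rng)
            if new.n_groups == 3:
                # which parent split: count groups of each pure type
                a_groups = int(np.sum((new.n_B == 0)))
                split_A += int(a_groups == 2)
        frac = split_A / n_reps
        # each parent chosen w.p. 1/2; a pure parent splits abortively when
        # its single uniform draw hits 0 or K (2 of 11 outcomes)
        assert frac == pytest.approx(0.5 * (9 / 11), abs=0.015)

    def test_no_split_at_capacity(self, rng):
        p = ModelParams(K=10, K_g=2, mu=0.0)
        s = pop([(10, 0), (0, 10)])
        new = step_split(s, p, rng)
        assert new.n_groups == 2
        np.testing.assert_array_equal(np.sort(new.n_A + new.n_B), [10, 10])

    def test_abortive_probability_by_enumeration(self, rng):
        # parent (1, K-1), K=10: exact abortive probability from exhaustive
        # enumeration of the (n_A+1)(n_B+1) equally likely allocations
        nA, nB = 1, 9
        total = (nA + 1) * (nB + 1)
        abortive = sum(
            1
            for mA in range(nA + 1)
            for mB in range(nB + 1)
            if mA + mB == 0 or (nA - mA) + (nB - mB) == 0
        )
        expected = abortive / total  # = 2/20 = 0.1
        p = ModelParams(K=10, K_g=50, mu=0.0)
        n_reps, no_change = 20000, 0
        for _ in range(n_reps):
            new = step_split(pop([(1, 9)]), p, rng)
            no_change += int(new.n_groups == 1)
        se = np.sqrt(expected * (1 - expected) / n_reps)
        assert no_change / n_reps == pytest.approx(expected, abs=3 * se)


class TestInit:
    def test_homogeneous_composition(self, rng):
        s = init_homogeneous(10, 10, 10, rng)
        assert s.n_groups == 20
        assert int(np.sum(s.n_B == 0)) == 10
        assert int(np.sum(s.n_A == 0)) == 10
        sizes = s.n_A + s.n_B
        assert sizes.min() >= 1 and sizes.max() <= 9

    def test_homogeneous_no_social(self, rng):
        s = init_homogeneous(0, 12, 10, rng)
        assert s.n_A.sum() == 0

    def test_homogeneous_size_distribution(self, rng):
        from scipy.stats import chisquare

        draws = np.concatenate(
            [init_homogeneous(0, 500, 10, rng).n_B for _ in range(50)]
        )
        observed = np.bincount(draws, minlength=10)[1:10]
        assert chisquare(observed).pvalue > 1e-4

    def test_heterogeneous_ranges_and_symmetry(self, rng):
        tot_A = tot_B = 0
        for _ in range(200):
            s = init_heterogeneous(20, 10, rng)
            assert s.n_groups == 20
            assert s.n_A.max() <= 5 and s.n_B.max() <= 5
            assert (s.n_A + s.n_B).min() >= 1
            tot_A += s.n_A.sum()
            tot_B += s.n_B.sum()
        # symmetric sampling: totals agree within a few percent
        assert abs(tot_A - tot_B) / (tot_A + tot_B) < 0.02


class TestSimulate:
    def test_no_death_never_extinct(self):
        p = ModelParams(K=10, K_g=500, mu=0.0, b=1.0)
        init = pop([(1, 0)])
        r = simulate(p, init, 2000, seed=5)
        assert r.outcome == "survived"
        assert np.all(np.diff(r.n_groups) >= 0)

    def test_determinism(self):
        p = ModelParams(K=10, K_g=70, mu=0.7, a=0.5, b=3.0, mode="relative")
        init = init_homogeneous(10, 10, 10, np.random.default_rng(7))
        r1 = simulate(p, init, 1500, seed=99)
        r2 = simulate(p, init, 1500, seed=99)
        for field in ("times", "n_groups", "n_groups_allA", "total_A", "total_B"):
            np.testing.assert_array_equal(getattr(r1, field), getattr(r2, field))
        assert r1.outcome == r2.outcome

    def test_extinction_truncates_trajectory(self):
        p = ModelParams(K=10, K_g=10, mu=1.0, mode="neutral")
        r = simulate(p, pop([(5, 0)]), 1000, seed=0)
        assert r.outcome == "extinct"
        assert r.n_groups[-1] == 0
        assert r.final_t < 1000
        assert r.final_state.n_A.size == 0

    def test_bounds_invariant(self):
        p = ModelParams(K=8, K_g=30, mu=0.4, a=0.6, b=2.0, mode="relative")
        init = init_homogeneous(5, 5, 8, np.random.default_rng(3))
        r = simulate(p, init, 2000, seed=11)
        assert np.all(r.n_groups <= max(10, 30))
        assert np.all(r.total_A + r.total_B <= r.n_groups * 8)
        assert np.all(r.total_A >= 0) and np.all(r.total_B >= 0)

    def test_kernel_degenerate_weights_raises(self):
        p = ModelParams(K=10, K_g=10, mu=1.0, a=1.0, mode="relative")
        with pytest.raises(DegenerateWeightsError):
            simulate(p, pop([(5, 0)]), 100, seed=2)

    def test_single_group_chain_matches_psi(self, rng):
        # single group with per-step death 1-delta and births from the step
        # operations, absorbed at the threshold: hit frequency must match
        # the analytic hitting probability
        from groupsel.analytics import SurvivalQuery, psi_exact

        delta, b, K, n0 = 0.98, 2.0, 8, 3
        p = ModelParams(K=K, K_g=1, mu=1 - delta, b=b, mode="neutral")
        n_reps, hit = 2000, 0
        for _ in range(n_reps):
            s = pop([(0, n0)])
            while True:
                s = step_death(s, p, rng)
                if s.n_groups == 0:
                    break
                s = step_reproduction(s, p, rng)
                if int(s.n_B[0]) == K:
                    hit += 1
                    break
        expected = psi_exact(n0, SurvivalQuery(delta, b, K))
        se = np.sqrt(expected * (1 - expected) / n_reps)
        assert hit / n_reps == pytest.approx(expected, abs=3.5 * se)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    comps=st.lists(
        st.tuples(st.integers(0, 10), st.integers(0, 10)).filter(lambda t: sum(t) > 0),
        min_size=1,
        max_size=12,
    ),
    seed=st.integers(0, 2**20),
)
def test_property_conservation_and_bounds(comps, seed):
    """Splitting conserves individuals; one step changes totals as allowed."""
    comps = [(a, min(b, 10 - a)) for a, b in comps if a + min(b, 10 - a) > 0]
    if not comps:
        comps = [(1, 0)]
    rng = np.random.default_rng(seed)
    p = ModelParams(K=10, K_g=len(comps) + 3, mu=0.3, a=0.5, b=2.0, mode="absolute")
    s = pop(comps)
    totals = (s.n_A.sum(), s.n_B.sum())
    after_split = step_split(s, p, rng)
    assert (after_split.n_A.sum(), after_split.n_B.sum()) == totals
    assert after_split.n_groups <= p.K_g
    after_repro = step_reproduction(s, p, rng)
    gained = (after_repro.n_A.sum() + after_repro.n_B.sum()) - sum(totals)
    assert 0 <= gained <= s.n_groups
    assert np.all(after_repro.n_A + after_repro.n_B <= 10)
    after_death = step_death(s, p, rng)
    assert after_death.n_groups in (s.n_groups, s.n_groups - 1)
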