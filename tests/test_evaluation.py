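"""Evaluation protocols: monotonicity, CCDF, SIR spreading, robustness."""

import math

import numpy as np
import pytest

from siwr import (
    Graph,
    Ranking,
    RankEntry,
    ScoreTable,
    SIRConfig,
    ccdf,
    default_beta,
    generate,
    monotonicity,
    propagation_curve,
    rank_from_scores,
    robustness_change_rate,
    sir_simulate,
    siwr_rank,
    toy_graph,
)


def ranking_from_scores(values: dict) -> Ranking:
    return rank_from_scores(ScoreTable("test", values))


class TestMonotonicity:
    def test_one_tied_pair_among_five(self):
        # orders: 1 > {2, 3 tied} > 4 > 5  ->  (1 - 1/10)^2
        r = ranking_from_scores({"a": 5.0, "b": 4.0, "c": 4.0, "d": 3.0, "e": 2.0})
        assert r.group_sizes == (1, 2, 1, 1)
        assert monotonicity(r) == pytest.approx(0.81)

    def test_all_distinct_is_one(self):
        r = ranking_from_scores({i: float(i) for i in range(20)})
        assert monotonicity(r) == 1.0

    def test_all_tied_is_zero(self):
        r = ranking_from_scores({i: 1.0 for i in range(7)})
        assert monotonicity(r) == 0.0

    def test_splitting_a_tie_strictly_increases(self):
        tied = ranking_from_scores({"a": 3.0, "b": 2.0, "c": 2.0, "d": 1.0})
        split = ranking_from_scores({"a": 3.0, "b": 2.5, "c": 2.0, "d": 1.0})
        assert monotonicity(split) > monotonicity(tied)

    def test_in_unit_interval(self):
        for sizes in [(3, 1), (2, 2, 2), (1, 5), (4,)]:
            scores = {}
            for order, s in enumerate(sizes):
                for k in range(s):
                    scores[f"{order}.{k}"] = -float(order)
            m = monotonicity(ranking_from_scores(scores))
            assert 0.0 <= m <= 1.0

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            monotonicity(ranking_from_scores({"a": 1.0}))


class TestCCDF:
    def test_toy_siwr_all_unique(self):
        curve = ccdf(siwr_rank(toy_graph()))
        assert curve == pytest.approx((5 / 6, 4 / 6, 3 / 6, 2 / 6, 1 / 6, 0.0))

    def test_single_group(self):
        assert ccdf(ranking_from_scores({i: 1.0 for i in range(4)})) == (0.0,)

    def test_non_increasing_and_terminal_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = {i: float(rng.integers(0, 6)) for i in range(12)}
            curve = ccdf(ranking_from_scores(scores))
            assert curve[-1] == 0.0
            assert all(a >= b for a, b in zip(curve, curve[1:]))


class TestDefaultBeta:
    def test_toy_average_degree_two(self):
        assert default_beta(toy_graph()) == pytest.approx(1.0)

    def test_clamped_below_average_degree_two(self, caplog):
        assert default_beta(generate("path", n=3)) == 1.0  # <d> = 4/3
        assert any("clamped" in r.message for r in caplog.records)

    def test_average_degree_at_most_one_errors(self):
        with pytest.raises(ValueError):
            default_beta(generate("path", n=2))  # <d> = 1


class TestSIR:
    def test_beta_zero_ability_is_seed_fraction(self):
        g = generate("erdos_renyi", n=20, p=0.2, rng_seed=3)
        res = sir_simulate(g, list(g.nodes)[:4], SIRConfig(beta=0.0, n_ite=50, rng_seed=1))
        assert res.propagation_ability == 4 / 20
        assert set(res.per_run_counts) == {4}

    def test_beta_one_connected_full_coverage(self):
        g = generate("barabasi_albert", n=25, m_attach=2, rng_seed=9)
        res = sir_simulate(g, [list(g.nodes)[0]], SIRConfig(beta=1.0, n_ite=20, rng_seed=1))
        assert res.propagation_ability == 1.0

    def test_star_closed_form_within_three_standard_errors(self):
        # center seed, one infectious step: ever = 1 + Binomial(n-1, beta)
        n, beta, n_ite = 11, 0.3, 10_000
        g = generate("star", n=n)
        res = sir_simulate(g, [0], SIRConfig(beta=beta, n_ite=n_ite, rng_seed=77))
        expected = (1 + (n - 1) * beta) / n
        se = math.sqrt((n - 1) * beta * (1 - beta)) / n / math.sqrt(n_ite)
        assert abs(res.propagation_ability - expected) < 3 * se

    def test_ability_bounds(self):
        g = generate("erdos_renyi", n=15, p=0.3, rng_seed=21)
        seeds = list(g.nodes)[:3]
        res = sir_simulate(g, seeds, SIRConfig(beta=0.4, n_ite=200, rng_seed=5))
        assert 3 / 15 <= res.propagation_ability <= 1.0

    def test_stochastically_monotone_in_beta(self):
        g = generate("erdos_renyi", n=20, p=0.25, rng_seed=13)
        seeds = [list(g.nodes)[0]]
        lo = sir_simulate(g, seeds, SIRConfig(beta=0.15, n_ite=2000, rng_seed=11))
        hi = sir_simulate(g, seeds, SIRConfig(beta=0.55, n_ite=2000, rng_seed=11))
        assert hi.propagation_ability >= lo.propagation_ability

    def test_deterministic_given_seed(self):
        g = generate("erdos_renyi", n=15, p=0.3, rng_seed=2)
        cfg = SIRConfig(beta=0.4, n_ite=100, rng_seed=42)
        a = sir_simulate(g, [list(g.nodes)[0]], cfg)
        b = sir_simulate(g, [list(g.nodes)[0]], cfg)
        assert a.per_run_counts == b.per_run_counts

    def test_invalid_inputs(self):
        g = generate("complete", n=4)
        with pytest.raises(ValueError, match="empty seed"):
            sir_simulate(g, [], SIRConfig(beta=0.5))
        with pytest.raises(ValueError, match="beta"):
            SIRConfig(beta=1.5)
        with pytest.raises(KeyError):
            sir_simulate(g, ["nope"], SIRConfig(beta=0.5, n_ite=1))


class TestPropagationCurve:
    def test_beta_zero_curve_is_seed_fractions(self):
        g = generate("erdos_renyi", n=20, p=0.2, rng_seed=3)
        r = siwr_rank(g)
        cfg = SIRConfig(beta=0.0, n_ite=20, rng_seed=1)
        results = propagation_curve(g, r, [2, 4, 6], cfg)
        assert [res.propagation_ability for res in results] == [2 / 20, 4 / 20, 6 / 20]

    def test_toy_top_seed_is_v2(self):
        r = siwr_rank(toy_graph())
        assert r.top(1) == ["v2"]

    def test_all_nodes_seeded_is_one(self):
        g = generate("complete", n=6)
        r = siwr_rank(g)
        results = propagation_curve(g, r, [6], SIRConfig(beta=0.3, n_ite=10, rng_seed=0))
        assert results[0].propagation_ability == 1.0

    def test_seed_count_exceeding_n_errors(self):
        g = generate("complete", n=4)
        with pytest.raises(ValueError):
            propagation_curve(g, siwr_rank(g), [5], SIRConfig(beta=0.5))

    def test_deterministic_given_seed(self):
        g = generate("erdos_renyi", n=15, p=0.3, rng_seed=8)
        r = siwr_rank(g)
        cfg = SIRConfig(beta=0.4, n_ite=50, rng_seed=9)
        a = propagation_curve(g, r, [2, 4], cfg)
        b = propagation_curve(g, r, [2, 4], cfg)
        assert [x.per_run_counts for x in a] == [x.per_run_counts for x in b]


# Hand-traced dense-order change rates for removing each single node of the
# worked-example graph under degree ranking (original groups {v1,v2} > {v3,v4}
# > {v5,v6}; each removal re-ranked by hand).
TOY_DC_SINGLE_REMOVAL_RATES = {
    "v1": 2 / 5,
    "v2": 2 / 5,
    "v3": 3 / 5,
    "v4": 2 / 5,
    "v5": 1 / 5,
    "v6": 1 / 5,
}


class TestRobustness:
    def test_complete_graph_rate_zero(self):
        g = generate("complete", n=6)
        rate = robustness_change_rate(g, "dc", 0.2, reps=10, rng_seed=1)
        assert rate == 0.0

    def test_toy_dc_matches_hand_trace_expectation(self):
        g = toy_graph()
        reps = 600
        rate = robustness_change_rate(g, "dc", 1 / 6, reps=reps, rng_seed=17)
        vals = np.array(list(TOY_DC_SINGLE_REMOVAL_RATES.values()))
        se = vals.std() / math.sqrt(reps)
        assert abs(rate - vals.mean()) < 4 * se

    def test_deterministic_given_seed(self):
        g = generate("erdos_renyi", n=20, p=0.3, rng_seed=4)
        a = robustness_change_rate(g, "dc", 0.1, reps=5, rng_seed=3)
        b = robustness_change_rate(g, "dc", 0.1, reps=5, rng_seed=3)
        assert a == b

    def test_rate_in_unit_interval(self):
        g = generate("erdos_renyi", n=18, p=0.25, rng_seed=6)
        for method in ["siwr", "dc", "iks"]:
            rate = robustness_change_rate(g, method, 0.15, reps=10, rng_seed=2)
            assert 0.0 <= rate <= 1.0

    def test_position_compare_mode(self):
        g = generate("erdos_renyi", n=12, p=0.4, rng_seed=10)
        rate = robustness_change_rate(
            g, "dc", 0.1, reps=10, rng_seed=2, compare="position"
        )
        assert 0.0 <= rate <= 1.0

    def test_callable_method_accepted(self):
        g = generate("complete", n=5)
        rate = robustness_change_rate(g, siwr_rank, 0.2, reps=5, rng_seed=1)
        assert rate == 0.0

    def test_invalid_fraction_errors(self):
        g = generate("complete", n=5)
        with pytest.raises(ValueError):
            robustness_change_rate(g, "dc", 0.0, reps=5)
        with pytest.raises(ValueError):
            robustness_change_rate(g, "dc", 0.99, reps=5)  # removes all 5
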