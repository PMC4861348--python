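"""The two-layer probabilistic model and its rewiring rules."""

import numpy as np
import pytest

from spikepid.feedforward_model import (
    DEGREE_RULE_PARAMS,
    FIRING_RATE_RULE_PARAMS,
    agreement_matrix,
    connection_mi_analysis,
    current_for_probability,
    initialize_model,
    lattice_search,
    model_synergy_degree_analysis,
    rewire_model,
    rewiring_score,
    run_network,
    signal_currents,
    solve_sigmoid_constants,
)


class TestSigmoidConstants:
    def test_printed_values_at_default_size(self):
        p = solve_sigmoid_constants(20, 10)
        assert p.alpha_gain == pytest.approx(0.023, abs=5e-4)
        assert p.beta_offset == pytest.approx(4.6, abs=0.01)

    def test_doubling_layer_size_halves_gain(self):
        p20 = solve_sigmoid_constants(20, 10)
        p40 = solve_sigmoid_constants(40, 10)
        assert p40.beta_offset == pytest.approx(p20.beta_offset)
        assert p40.alpha_gain == pytest.approx(p20.alpha_gain / 2)

    def test_boundary_conditions_exact(self):
        p = solve_sigmoid_constants(20, 10)
        assert p.probability(0.0) == pytest.approx(0.01, abs=1e-9)
        assert p.probability(200.0) == pytest.approx(0.5, abs=1e-9)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            solve_sigmoid_constants(20, 10, p_zero=0.5, p_full=0.5)


class TestSignalCurrents:
    def test_first_neuron_uncorrelated_with_signal(self):
        p = solve_sigmoid_constants(20, 10)
        c0, c1 = signal_currents("input", 1, p)
        assert c0 == pytest.approx(c1)
        assert c0 == pytest.approx(p.beta_offset / p.alpha_gain)  # = 200
        assert p.probability(c0) == pytest.approx(0.5)

    def test_last_input_neuron_strongly_modulated(self):
        p = solve_sigmoid_constants(20, 10)
        c0, c1 = signal_currents("input", 20, p)
        assert p.probability(c0) == pytest.approx(0.1, abs=1e-9)
        assert p.probability(c1) == pytest.approx(0.9, abs=1e-9)

    def test_last_output_neuron_weakly_modulated(self):
        p = solve_sigmoid_constants(20, 10)
        c0, c1 = signal_currents("output", 20, p)
        assert p.probability(c0) == pytest.approx(0.3, abs=1e-9)
        assert p.probability(c1) == pytest.approx(0.7, abs=1e-9)

    def test_index_bounds(self):
        p = solve_sigmoid_constants(20, 10)
        with pytest.raises(ValueError):
            signal_currents("input", 0, p)
        with pytest.raises(ValueError):
            signal_currents("output", 21, p)


class TestRunNetwork:
    def test_isolated_zero_current_neuron_fires_at_p_zero(self):
        state = initialize_model(20, seed=0)
        state.connectivity[:] = False
        state.output_currents[:] = 0.0
        log = run_network(state, 100_000, seed=1)
        freq = log.output_states.mean(axis=0)
        se = np.sqrt(0.01 * 0.99 / 100_000)
        assert np.all(np.abs(freq - 0.01) < 5 * se)

    def test_unconnected_first_input_fires_half_the_time(self):
        state = initialize_model(20, seed=0)
        state.connectivity[:] = False
        log = run_network(state, 10_000, seed=2)
        assert log.input_states[:, 0].mean() == pytest.approx(0.5, abs=0.02)

    def test_signal_modulates_last_input(self):
        state = initialize_model(20, seed=0)
        log = run_network(state, 20_000, seed=3)
        hi = log.input_states[log.b == 1, 19].mean()
        lo = log.input_states[log.b == 0, 19].mean()
        assert hi == pytest.approx(0.9, abs=0.02)
        assert lo == pytest.approx(0.1, abs=0.02)

    def test_seeded_repeat_identical(self):
        state = initialize_model(20, seed=4)
        a = run_network(state, 500, seed=5)
        b = run_network(state, 500, seed=5)
        assert np.array_equal(a.output_states, b.output_states)
        assert np.array_equal(a.b, b.b)

    def test_sigmoid_monotone_and_strictly_inside_unit_interval(self):
        state = initialize_model(20, seed=6)
        currents = np.linspace(-100, 500, 200)
        p = state.sigmoid.probability(currents)
        assert np.all((p > 0) & (p < 1))
        assert np.all(np.diff(p) > 0)


class TestRewiring:
    def test_connection_count_invariant(self):
        state = initialize_model(20, rule="hebbian", seed=8)
        assert state.n_connections == 80
        rewired = rewire_model(state, seed=9, n_stat_runs=50, n_rewirings=10)
        assert rewired.n_connections == 80

    def test_random_rule_is_noop(self):
        state = initialize_model(20, rule="random", seed=10)
        rewired = rewire_model(state, seed=11)
        assert np.array_equal(state.connectivity, rewired.connectivity)

    def test_hebbian_rule_pools_signal_correlated_inputs(self):
        moved_up = 0
        for seed in range(5):
            state = initialize_model(20, rule="hebbian", seed=20 + seed)
            before = np.argwhere(state.connectivity)[:, 0].mean()
            rewired = rewire_model(state, seed=30 + seed, n_stat_runs=200)
            after = np.argwhere(rewired.connectivity)[:, 0].mean()
            moved_up += after > before
        assert moved_up >= 4

    def test_degree_rule_spreads_inputs_more_uniformly_than_hebbian(self):
        heb = rewire_model(initialize_model(20, rule="hebbian", seed=40),
                           seed=41, n_stat_runs=200)
        deg = rewire_model(initialize_model(20, rule="degree", seed=40),
                           seed=42, n_stat_runs=200)
        spread = lambda s: np.ptp(s.connectivity.sum(axis=1))
        assert spread(deg) < spread(heb)

    def test_score_reduces_to_agreement_for_pure_hebbian(self):
        state = initialize_model(20, rule="hebbian", seed=12)
        log = run_network(state, 500, seed=13)
        assert np.allclose(rewiring_score(state, log), agreement_matrix(log))

    def test_degree_coefficients_shift_scores_linearly(self):
        state = initialize_model(20, rule="degree",
                                 score_params=DEGREE_RULE_PARAMS, seed=14)
        log = run_network(state, 500, seed=15)
        s0 = rewiring_score(state, log)
        bumped = state.copy()
        # give input 3 one more outgoing connection
        free = np.flatnonzero(~bumped.connectivity[3])[0]
        bumped.connectivity[3, free] = True
        s1 = rewiring_score(bumped, log)
        delta = s1[3] - s0[3]
        # a2 = -1.75 per added out-degree unit; the new connection's column
        # also gains a1 = +0.05 from the output's in-degree
        assert np.allclose(np.delete(delta, free), -1.75)
        assert delta[free] == pytest.approx(-1.75 + 0.05)

    def test_firing_rate_rule_rewards_active_inputs(self):
        state = initialize_model(20, rule="firing_rate",
                                 score_params=FIRING_RATE_RULE_PARAMS, seed=16)
        log = run_network(state, 500, seed=17)
        s = rewiring_score(state, log)
        fr_in = log.input_states.mean(axis=0)
        hi, lo = np.argmax(fr_in), np.argmin(fr_in)
        assert s[hi].mean() > s[lo].mean()


class TestModelAnalyses:
    def test_synergy_degree_analysis_deterministic(self):
        state = rewire_model(initialize_model(20, rule="hebbian", seed=50),
                             seed=51, n_stat_runs=100)
        a = model_synergy_degree_analysis(state, 1000, seed=52)
        b = model_synergy_degree_analysis(state, 1000, seed=52)
        assert a == b

    def test_too_few_triads_rejected(self):
        state = initialize_model(20, seed=53)
        state.connectivity[:] = False
        state.connectivity[0, 0] = True
        with pytest.raises(ValueError, match="triads"):
            model_synergy_degree_analysis(state, 200, seed=54)

    def test_conditioning_removes_signal_driven_dependence(self):
        # with no connections all input/output dependence flows through b
        state = initialize_model(20, seed=55)
        state.connectivity[:] = False
        state.connectivity[19, 19] = True  # strongly b-correlated pair
        res = connection_mi_analysis({"x": [state]}, n_runs=20_000, seed=56)
        mi, cmi = res["mi"]["x"][0], res["cmi"]["x"][0]
        # the single connection carries little; MI is dominated by b
        assert mi > 5 * cmi

    def test_mi_analysis_runs_pairwise_tests_with_fdr(self):
        states = {
            r: [rewire_model(initialize_model(20, rule=r, seed=60 + i),
                             seed=70 + i, n_stat_runs=50, n_rewirings=10)
                for i in range(3)]
            for r in ("random", "hebbian")
        }
        res = connection_mi_analysis(states, n_runs=1000, seed=80)
        assert set(res["tests"]["metric"]) == {"mi", "cmi"}
        assert (res["tests"]["p_fdr"] >= res["tests"]["p_raw"] - 1e-12).all()


class TestLatticeSearch:
    def test_known_quadratic_minimum_recovered(self):
        target = (1.2, -0.7)
        evaluated = []

        def objective(point):
            evaluated.append(point)
            return (point[0] - target[0]) ** 2 + (point[1] - target[1]) ** 2

        best, trace = lattice_search(
            "degree", (0, 0), stages=3, grid_points=7, objective=objective
        )
        # final-stage grid spacing: 6 / 9 / 6 within each refinement
        final_cell = (6.0 / 3 / 3) / 6
        assert abs(best[0] - target[0]) <= 2 * final_cell
        assert abs(best[1] - target[1]) <= 2 * final_cell

    def test_bounds_respected_and_trace_non_increasing(self):
        evaluated = []

        def objective(point):
            evaluated.append(point)
            return point[0] ** 2 + point[1] ** 2

        _, trace = lattice_search("firing_rate", (0, 0), stages=3,
                                  objective=objective)
        pts = np.array(evaluated)
        assert pts.min() >= -4.0 and pts.max() <= 4.0
        assert all(trace[i + 1] <= trace[i] + 1e-12 for i in range(len(trace) - 1))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            lattice_search("resistance", (0, 0))
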