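"""Unit and property tests of the integrate-and-fire networks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from posnersim.lif_network import (
    LIF_DEFAULT,
    OUTCOME_CODES,
    Architecture,
    NeuronParams,
    TaskSpec,
    TrialProtocol,
    evaluate_population,
    evaluate_task,
    fitness_of_trial,
    individual_median_rts,
    run_trial,
    split_genome,
    step_network,
    step_neuron,
    trial_list,
)

SRT = Architecture.for_task("SRT")
CRT = Architecture.for_task("CRT")


class TestArchitecture:
    def test_sizes(self):
        assert SRT.n_neurons == 6 and SRT.n_synapses == 30 and SRT.genome_length == 36
        assert CRT.n_neurons == 7 and CRT.n_synapses == 42 and CRT.genome_length == 49

    def test_genome_split_round_trip(self, rng):
        genome = rng.uniform(-3, 3, SRT.genome_length)
        biases, weights = split_genome(genome, SRT)
        assert np.array_equal(biases, genome[:6])
        assert np.all(np.diag(weights) == 0)
        assert np.array_equal(weights[~np.eye(6, dtype=bool)], genome[6:])

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            split_genome(np.zeros(10), SRT)


class TestStepNeuron:
    def test_rest_is_fixed_point(self):
        v, spiked = step_neuron(-65.0, 0.0)
        assert v == -65.0 and not spiked

    def test_exponential_decay_toward_rest(self):
        v, spiked = step_neuron(-55.0, 0.0)
        assert v == pytest.approx(-65.0 + 10.0 * math.exp(-0.1))
        assert not spiked

    def test_spike_and_reset(self):
        # -65 + 20 e^{-0.1} + 10 = -36.90 >= -40 -> spike, reset to -65
        v, spiked = step_neuron(-45.0, 10.0)
        assert spiked and v == -65.0

    @given(v=st.floats(-80, -40.001), i=st.floats(-30, 30))
    def test_stored_potential_never_exceeds_threshold(self, v, i):
        v_next, spiked = step_neuron(v, i)
        assert v_next < LIF_DEFAULT.v_threshold

    @given(v=st.floats(-80, -41))
    def test_decay_is_a_contraction(self, v):
        v_next, _ = step_neuron(v, 0.0)
        if v != LIF_DEFAULT.v_rest:
            assert abs(v_next - LIF_DEFAULT.v_rest) < abs(v - LIF_DEFAULT.v_rest)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            NeuronParams(v_rest=-65, v_reset=-60, v_threshold=-40)
        with pytest.raises(ValueError):
            NeuronParams(tau=0)


class TestStepNetwork:
    def test_all_zero_genome_never_spikes(self):
        genome = np.zeros(SRT.genome_length)
        v = np.full(6, -65.0)
        prev = np.zeros(6, dtype=bool)
        for _ in range(100):
            v, spiked = step_network(v, prev, genome, SRT, np.zeros(6))
            prev = spiked
            assert not spiked.any()

    def test_synapse_delivers_weight_one_step_later(self):
        # weight w from neuron 0 to neuron 5 contributes exactly w to
        # neuron 5's input on the step after neuron 0 fires
        genome = np.zeros(SRT.genome_length)
        _, weights = split_genome(genome, SRT)
        w = 1.7
        genome_w = genome.copy()
        # row-major off-diagonal order: (0,1),(0,2),...,(0,5) -> index 4 is 0->5
        genome_w[6 + 4] = w
        v = np.full(6, -65.0)
        prev = np.zeros(6, dtype=bool)
        prev[0] = True
        v_next, _ = step_network(v, prev, genome_w, SRT, np.zeros(6))
        assert v_next[5] == pytest.approx(-65.0 + w)
        assert v_next[1] == pytest.approx(-65.0)

    def test_constant_bias_first_spike_matches_geometric_series(self):
        # with only a bias b on the output neuron, V accumulates as
        # V(t) = rest + b (1 - d^t) / (1 - d); the first spike lands at
        # the smallest t with b (1 - d^t) / (1 - d) >= threshold gap
        b = 2.5
        d = LIF_DEFAULT.decay
        gap = LIF_DEFAULT.v_threshold - LIF_DEFAULT.v_rest
        t_pred = math.ceil(math.log(1.0 - gap * (1.0 - d) / b) / math.log(d))
        genome = np.zeros(SRT.genome_length)
        genome[5] = b
        v = np.full(6, -65.0)
        prev = np.zeros(6, dtype=bool)
        first = None
        for t in range(1, 100):
            v, spiked = step_network(v, prev, genome, SRT, np.zeros(6))
            prev = spiked
            if spiked[5]:
                first = t
                break
        assert first == t_pred

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            step_network(np.zeros(5), np.zeros(6, bool), np.zeros(36), SRT, np.zeros(6))


class TestRunTrial:
    def test_inhibited_genome_is_slow(self):
        genome = np.full(SRT.genome_length, -3.0)
        res = run_trial(genome, SRT, TrialProtocol("neutral", "left"), 1)
        assert res.outcome == "slow" and res.responding_output == "none"
        assert res.rt is None

    @staticmethod
    def _set_weight(genome, arch, pre, post, w):
        n = arch.n_neurons
        off = np.flatnonzero(~np.eye(n, dtype=bool).ravel())
        genome[n + np.where(off == pre * n + post)[0][0]] = w

    def test_optimal_noiseless_genome_responds_at_rt_one(self):
        # target and output neurons parked just below threshold by their
        # bias (steady depolarization 2.3/(1-e^{-0.1}) ~ 24.2 mV of the
        # 25 mV gap): the target neuron fires on the first target step,
        # the max-weight synapse fires the output one step later ->
        # rt = 1, the discrete-time floor
        genome = np.zeros(SRT.genome_length)
        genome[[3, 4, 5]] = 2.3
        for pre in (3, 4):
            self._set_weight(genome, SRT, pre, 5, 2.9)
        for side in ("left", "right"):
            res = run_trial(genome, SRT, TrialProtocol("neutral", side), 2)
            assert res.outcome == "correct" and res.rt == 1

    def test_cue_driven_spike_is_anticipated(self):
        # a spontaneously firing cue neuron plus a strong cue->output
        # weight makes the output fire before target onset
        genome = np.zeros(CRT.genome_length)
        genome[1] = 2.9  # cue_neutral fires on its own
        genome[5] = 2.3  # output_left near threshold
        self._set_weight(genome, CRT, 1, 5, 2.9)
        res = run_trial(genome, CRT, TrialProtocol("neutral", "left"), 3)
        assert res.outcome == "anticipated" and res.rt < 0

    def test_crt_wrong_output_is_incorrect(self):
        genome = np.zeros(CRT.genome_length)
        genome[[3, 4, 5]] = 2.3  # targets + LEFT output near threshold
        for pre in (3, 4):  # both targets excite only the left output
            self._set_weight(genome, CRT, pre, 5, 2.9)
        res = run_trial(genome, CRT, TrialProtocol("neutral", "right"), 4)
        assert res.outcome == "incorrect" and res.rt == 1


class TestFitness:
    @pytest.mark.parametrize(
        "rt, outcome, expected",
        [
            (-5, "anticipated", 0.0),
            (0, "correct", 1000.0),
            (100, "correct", 1000.0 * math.exp(-1.0)),
            (None, "slow", 0.0),
            (10, "incorrect", 0.0),
        ],
    )
    def test_values(self, rt, outcome, expected):
        assert fitness_of_trial(rt, outcome) == pytest.approx(expected)


class TestEvaluateTask:
    @pytest.mark.parametrize("ratio, expected", [((8, 5, 2), 30), ((8, 8, 2), 36)])
    def test_trial_counts(self, ratio, expected):
        task = TaskSpec(ratio, 0.0)
        assert task.n_trials == expected
        assert len(trial_list(task)) == expected

    def test_trial_composition_balanced_over_sides(self):
        trials = trial_list(TaskSpec((8, 5, 2), 0.0))
        from collections import Counter
        counts = Counter((ct, side) for _, side, ct in trials)
        for side in ("left", "right"):
            assert counts[("valid", side)] == 8
            assert counts[("neutral", side)] == 5
            assert counts[("invalid", side)] == 2

    def test_all_slow_genome_scores_zero(self):
        genome = np.full(SRT.genome_length, -3.0)
        fitness, results = evaluate_task(genome, SRT, TaskSpec((8, 5, 2), 0.0), 1)
        assert fitness == 0.0
        assert all(r.outcome == "slow" for r in results)

    def test_vectorized_matches_scalar_noiseless(self):
        task = TaskSpec((8, 5, 2), 0.0)
        rng = np.random.default_rng(42)
        genomes = rng.uniform(-3, 3, (5, SRT.genome_length))
        ev = evaluate_population(genomes, SRT, task, np.random.default_rng(99))
        durations = np.random.default_rng(99).integers(100, 201, size=30)
        code_names = {v: k for k, v in OUTCOME_CODES.items()}
        for g in range(5):
            total = 0.0
            for j, (cue, side, _) in enumerate(trial_list(task)):
                res = run_trial(
                    genomes[g], SRT, TrialProtocol(cue, side),
                    np.random.default_rng(0), cue_duration=int(durations[j]),
                )
                assert code_names[ev.outcome[g, j]] == res.outcome
                if res.rt is None:
                    assert np.isnan(ev.rt[g, j])
                else:
                    assert ev.rt[g, j] == res.rt
                total += fitness_of_trial(res.rt, res.outcome)
            assert ev.fitness[g] == pytest.approx(total)

    def test_noiseless_trials_are_seed_independent_given_durations(self):
        task = TaskSpec((8, 5, 2), 0.0)
        genome = np.random.default_rng(0).uniform(-3, 3, (1, SRT.genome_length))
        ev1 = evaluate_population(genome, SRT, task, np.random.default_rng(1))
        ev2 = evaluate_population(genome, SRT, task, np.random.default_rng(1))
        assert np.array_equal(ev1.fitness, ev2.fitness)
        assert np.array_equal(ev1.outcome, ev2.outcome)


class TestMedianRTs:
    def test_median_over_correct_trials(self):
        rt = np.array([[3.0, 5.0, 100.0, -2.0]])
        outcome = np.array([[0, 0, 0, 1]], dtype=np.int8)
        cue_types = np.array(["valid"] * 4)
        med = individual_median_rts(rt, outcome, cue_types)
        assert med[0, 0] == 5.0

    def test_no_correct_response_yields_null(self):
        rt = np.array([[-1.0, -2.0]])
        outcome = np.array([[1, 1]], dtype=np.int8)
        cue_types = np.array(["neutral", "neutral"])
        med = individual_median_rts(rt, outcome, cue_types)
        assert np.isnan(med[0, 1])
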