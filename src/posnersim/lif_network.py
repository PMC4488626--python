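"""Leaky integrate-and-fire motor networks for the Posner task.

A network is fully connected (all ordered pairs of distinct neurons) and
has three central input neurons (left / neutral / right cue), two
peripheral input neurons (left / right target) and one output neuron
(SRT) or two side-specific output neurons (CRT).  Each neuron follows the
discrete-time leaky integrator

    V(t+1) = V_rest + (V(t) - V_rest) * exp(-1/tau) + I(t)

and emits a spike when the updated potential reaches ``V_threshold``, at
which point it is reset to ``V_reset``.  The input ``I`` is the sum of
the neuron's bias, an external current of 5 mV on stimulated input
neurons, the weights of the synapses whose presynaptic neuron spiked on
the previous step, and (optionally) per-step Gaussian membrane noise.

A trial runs 50 silent time units, then cue stimulation for a uniform
random 100–200 time units, then target stimulation on top of the still-on
cue; it ends at the first output spike (at any time) or 1000 time units
after target onset.  Correct responses earn a fitness of
``1000 * exp(-0.01 * rt)``; anticipated, wrong-side and slow responses
earn nothing.

:func:`evaluate_population` evaluates a whole genome population on a task
in one vectorized simulation; :func:`run_trial` is the single-network
reference path and the two agree exactly in the noiseless case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "Architecture",
    "TrialProtocol",
    "TaskSpec",
    "MotorTrialResult",
    "PopulationEvaluation",
    "split_genome",
    "step_neuron",
    "step_network",
    "run_trial",
    "fitness_of_trial",
    "trial_list",
    "evaluate_task",
    "evaluate_population",
    "individual_error_rates",
    "individual_median_rts",
    "OUTCOME_CODES",
    "CUE_TYPES",
]

STIM_CURRENT = 5.0  # mV, cue and target input current
GENE_LOW, GENE_HIGH = -3.0, 3.0

CUE_TYPES = ("valid", "neutral", "invalid")

#: integer outcome codes used by the vectorized evaluator
OUTCOME_CODES = {"correct": 0, "anticipated": 1, "incorrect": 2, "slow": 3}


@dataclass(frozen=True)
class NeuronParams:
    """Integrate-and-fire constants (mV / time units)."""

    v_rest: float = -65.0
    v_reset: float = -65.0
    v_threshold: float = -40.0
    tau: float = 10.0

    def __post_init__(self) -> None:
        if not self.v_reset <= self.v_rest < self.v_threshold:
            raise ValueError("need v_reset <= v_rest < v_threshold")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @property
    def decay(self) -> float:
        """Per-step decay factor exp(-1/tau)."""
        return math.exp(-1.0 / self.tau)


LIF_DEFAULT = NeuronParams()

_SRT_ROLES = (
    "cue_left", "cue_neutral", "cue_right",
    "target_left", "target_right",
    "output",
)
_CRT_ROLES = (
    "cue_left", "cue_neutral", "cue_right",
    "target_left", "target_right",
    "output_left", "output_right",
)


@dataclass(frozen=True)
class Architecture:
    """Network layout for one task kind.

    All ordered pairs of distinct neurons are connected, so a genome has
    ``N`` biases followed by ``N*(N-1)`` weights (36 genes for SRT, 49
    for CRT).
    """

    task_kind: str
    roles: tuple[str, ...]

    @classmethod
    def for_task(cls, task_kind: str) -> "Architecture":
        task_kind = task_kind.upper()
        if task_kind == "SRT":
            return cls("SRT", _SRT_ROLES)
        if task_kind == "CRT":
            return cls("CRT", _CRT_ROLES)
        raise ValueError(f"task_kind must be 'SRT' or 'CRT', got {task_kind!r}")

    @property
    def n_neurons(self) -> int:
        return len(self.roles)

    @property
    def n_synapses(self) -> int:
        n = self.n_neurons
        return n * (n - 1)

    @property
    def genome_length(self) -> int:
        return self.n_neurons + self.n_synapses

    def cue_index(self, cue: str) -> int:
        return self.roles.index(f"cue_{cue}")

    def target_index(self, side: str) -> int:
        return self.roles.index(f"target_{side}")

    @property
    def output_indices(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.roles) if r.startswith("output"))


def split_genome(
    genome: np.ndarray, architecture: Architecture
) -> tuple[np.ndarray, np.ndarray]:
    """Split a flat genome into ``(biases, weight_matrix)``.

    ``weight_matrix[i, j]`` is the synapse from neuron ``i`` to neuron
    ``j``; the diagonal is zero (no self-connections).  Off-diagonal
    entries are filled row-major from the weight genes.
    """
    genome = np.asarray(genome, dtype=float)
    n = architecture.n_neurons
    if genome.shape != (architecture.genome_length,):
        raise ValueError(
            f"genome must have length {architecture.genome_length}, got {genome.shape}"
        )
    biases = genome[:n].copy()
    weights = np.zeros((n, n))
    weights[~np.eye(n, dtype=bool)] = genome[n:]
    return biases, weights


@dataclass(frozen=True)
class TrialProtocol:
    """Stimulation schedule and noise level of one trial."""

    cue_type: str  # cue direction: left / neutral / right
    target_side: str  # left / right
    noise_sigma: float = 0.0
    pre_cue: int = 50
    cue_min: int = 100
    cue_max: int = 200
    stim_current: float = STIM_CURRENT
    post_target_limit: int = 1000

    def __post_init__(self) -> None:
        if self.stim_current <= 0:
            raise ValueError("stim_current must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class MotorTrialResult:
    """Classified outcome of one network trial.  ``rt`` is the response
    instant minus target onset (``None`` if the network never responded)."""

    rt: int | None
    responding_output: str  # single / left / right / none
    outcome: str  # correct / anticipated / incorrect / slow
    cue_type: str
    target_side: str


@dataclass(frozen=True)
class TaskSpec:
    """A reaction-time task: cue-type mix and internal noise level.

    ``cue_ratio`` gives the (valid, neutral, invalid) counts per target
    side; each (cue, target-side) combination appears that many times, so
    the 8:5:2 ratio yields 30 trials and 8:8:2 yields 36.
    """

    cue_ratio: tuple[int, int, int] = (8, 5, 2)
    noise_sigma: float = 0.0

    @property
    def n_trials(self) -> int:
        return 2 * sum(self.cue_ratio)


def trial_list(task: TaskSpec) -> list[tuple[str, str, str]]:
    """Expand a task into ``(cue_direction, target_side, cue_type)``
    tuples, balanced over target sides."""
    valid, neutral, invalid = task.cue_ratio
    trials = []
    for side, other in (("left", "right"), ("right", "left")):
        trials += [(side, side, "valid")] * valid
        trials += [("neutral", side, "neutral")] * neutral
        trials += [(other, side, "invalid")] * invalid
    return trials


def step_neuron(
    v: float | np.ndarray,
    i_input: float | np.ndarray,
    params: NeuronParams = LIF_DEFAULT,
):
    """One integrate-and-fire step.  Returns ``(v_next, spiked)``; on a
    spike the stored potential is the reset value."""
    v_next = params.v_rest + (np.asarray(v) - params.v_rest) * params.decay + i_input
    spiked = v_next >= params.v_threshold
    v_next = np.where(spiked, params.v_reset, v_next)
    if np.ndim(v) == 0 and np.ndim(i_input) == 0:
        return float(v_next), bool(spiked)
    return v_next, spiked


def step_network(
    v: np.ndarray,
    prev_spikes: np.ndarray,
    genome: np.ndarray,
    architecture: Architecture,
    external: np.ndarray,
    noise: np.ndarray | None = None,
    params: NeuronParams = LIF_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance all neurons synchronously by one step.

    ``prev_spikes`` flags the neurons that spiked on the previous step;
    their outgoing weights are delivered as synaptic current now.
    """
    n = architecture.n_neurons
    if v.shape != (n,) or prev_spikes.shape != (n,) or external.shape != (n,):
        raise ValueError(f"state arrays must have shape ({n},)")
    biases, weights = split_genome(genome, architecture)
    current = biases + external + prev_spikes.astype(float) @ weights
    if noise is not None:
        if np.shape(noise) != (n,):
            raise ValueError(f"noise must have shape ({n},)")
        current = current + noise
    return step_neuron(v, current, params)


def run_trial(
    genome: np.ndarray,
    architecture: Architecture,
    protocol: TrialProtocol,
    rng: np.random.Generator | int | None = None,
    params: NeuronParams = LIF_DEFAULT,
    cue_duration: int | None = None,
) -> MotorTrialResult:
    """Run one trial of a single network.

    Potentials start at rest; after ``pre_cue`` silent steps the cue
    input neuron receives the stimulation current, and after the cue
    interval the target input neuron is stimulated as well (the cue stays
    on).  The trial ends at the first output spike — whenever it happens
    — or ``post_target_limit`` steps after target onset.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = architecture.n_neurons
    if cue_duration is None:
        cue_duration = int(rng.integers(protocol.cue_min, protocol.cue_max + 1))
    cue_idx = architecture.cue_index(protocol.cue_type)
    target_idx = architecture.target_index(protocol.target_side)
    outputs = architecture.output_indices
    t_on = protocol.pre_cue + cue_duration + 1  # first step with target current
    t_end = t_on + protocol.post_target_limit

    v = np.full(n, params.v_rest)
    prev = np.zeros(n, dtype=bool)
    external = np.zeros(n)
    for t in range(1, t_end + 1):
        if t == protocol.pre_cue + 1:
            external[cue_idx] += protocol.stim_current
        if t == t_on:
            external[target_idx] += protocol.stim_current
        noise = (
            rng.normal(0.0, protocol.noise_sigma, size=n)
            if protocol.noise_sigma > 0
            else None
        )
        v, spiked = step_network(
            v, prev, genome, architecture, external, noise, params
        )
        prev = spiked
        fired = [k for k in outputs if spiked[k]]
        if fired:
            if architecture.task_kind == "SRT":
                responding = "single"
            elif len(fired) == 2:
                responding = "left" if rng.random() < 0.5 else "right"
            else:
                responding = architecture.roles[fired[0]].removeprefix("output_")
            rt = t - t_on
            if rt < 0:
                outcome = "anticipated"
            elif architecture.task_kind == "SRT" or responding == protocol.target_side:
                outcome = "correct"
            else:
                outcome = "incorrect"
            return MotorTrialResult(
                rt, responding, outcome, protocol.cue_type, protocol.target_side
            )
    return MotorTrialResult(
        None, "none", "slow", protocol.cue_type, protocol.target_side
    )


def fitness_of_trial(rt: int | None, outcome: str) -> float:
    """Fitness of a classified trial: ``1000 * exp(-0.01 * rt)`` for a
    correct response, zero for anticipated, incorrect and slow ones."""
    if outcome != "correct":
        return 0.0
    return 1000.0 * math.exp(-0.01 * rt)


def evaluate_task(
    genome: np.ndarray,
    architecture: Architecture,
    task: TaskSpec,
    rng: np.random.Generator | int | None = None,
    params: NeuronParams = LIF_DEFAULT,
) -> tuple[float, list[MotorTrialResult]]:
    """Evaluate one genome on a full task, trial by trial.  Total fitness
    is the sum of the per-trial fitness values."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    results = []
    total = 0.0
    for cue, side, _ in trial_list(task):
        protocol = TrialProtocol(
            cue_type=cue, target_side=side, noise_sigma=task.noise_sigma
        )
        res = run_trial(genome, architecture, protocol, rng, params)
        results.append(res)
        total += fitness_of_trial(res.rt, res.outcome)
    return total, results


@dataclass(frozen=True)
class PopulationEvaluation:
    """Vectorized evaluation of ``G`` genomes on ``T`` trials."""

    fitness: np.ndarray  # (G,)
    rt: np.ndarray  # (G, T) float, NaN where no response
    outcome: np.ndarray  # (G, T) int8, see OUTCOME_CODES
    cue_types: np.ndarray  # (T,) valid/neutral/invalid
    cue_durations: np.ndarray  # (T,)


def evaluate_population(
    genomes: np.ndarray,
    architecture: Architecture,
    task: TaskSpec,
    rng: np.random.Generator | int | None = None,
    params: NeuronParams = LIF_DEFAULT,
) -> PopulationEvaluation:
    """Evaluate every genome on every trial of a task in one simulation.

    All genomes see the same trial list and the same per-trial cue
    durations (a fair comparison within a generation); membrane noise is
    drawn independently per genome, trial, neuron and time unit.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    genomes = np.atleast_2d(np.asarray(genomes, dtype=float))
    n = architecture.n_neurons
    g_count, length = genomes.shape
    if length != architecture.genome_length:
        raise ValueError(
            f"genomes must have length {architecture.genome_length}, got {length}"
        )
    trials = trial_list(task)
    t_count = len(trials)
    cue_idx = np.array([architecture.cue_index(c) for c, _, _ in trials])
    target_idx = np.array([architecture.target_index(s) for _, s, _ in trials])
    target_left = np.array([s == "left" for _, s, _ in trials])
    cue_types = np.array([ct for _, _, ct in trials])
    outputs = np.array(architecture.output_indices)
    proto = TrialProtocol(cue_type="neutral", target_side="left",
                          noise_sigma=task.noise_sigma)

    durations = rng.integers(proto.cue_min, proto.cue_max + 1, size=t_count)
    t_on = proto.pre_cue + durations + 1
    t_end = t_on + proto.post_target_limit

    biases = genomes[:, :n]
    weights = np.zeros((g_count, n, n))
    weights[:, ~np.eye(n, dtype=bool)] = genomes[:, n:]

    v = np.full((g_count, t_count, n), params.v_rest)
    prev = np.zeros((g_count, t_count, n))
    external = np.zeros((t_count, n))
    done = np.zeros((g_count, t_count), dtype=bool)
    resp_step = np.zeros((g_count, t_count), dtype=np.int64)
    resp_out = np.zeros((g_count, t_count), dtype=np.int8)  # 0 none,1 left/single,2 right
    sigma = task.noise_sigma
    decay = params.decay

    for t in range(1, int(t_end.max()) + 1):
        if t == proto.pre_cue + 1:
            external[np.arange(t_count), cue_idx] += proto.stim_current
        starting = t == t_on
        if starting.any():
            external[np.flatnonzero(starting), target_idx[starting]] += proto.stim_current
        current = biases[:, None, :] + external[None, :, :]
        current += np.einsum("gij,gti->gtj", weights, prev)
        if sigma > 0:
            current += rng.normal(0.0, sigma, size=(g_count, t_count, n))
        v_new = params.v_rest + (v - params.v_rest) * decay + current
        spiked = v_new >= params.v_threshold
        v_new = np.where(spiked, params.v_reset, v_new)
        alive = ~done
        v = np.where(alive[:, :, None], v_new, v)
        spiked &= alive[:, :, None]
        prev = spiked.astype(float)
        out_spikes = spiked[:, :, outputs]
        fired = out_spikes.any(axis=2)
        if fired.any():
            if architecture.task_kind == "SRT":
                resp_out[fired] = 1
            else:
                left = out_spikes[:, :, 0]
                right = out_spikes[:, :, 1]
                both = left & right
                resp_out[fired & left & ~right] = 1
                resp_out[fired & right & ~left] = 2
                if both.any():
                    resp_out[both] = rng.integers(
                        1, 3, size=int(both.sum()), dtype=np.int8
                    )
            resp_step[fired] = t
            done |= fired
        done |= (t >= t_end)[None, :]
        if done.all():
            break

    responded = resp_step > 0
    rt = np.where(responded, resp_step - t_on[None, :], 0).astype(float)
    rt[~responded] = np.nan
    outcome = np.full((g_count, t_count), OUTCOME_CODES["slow"], dtype=np.int8)
    ant = responded & (rt < 0)
    outcome[ant] = OUTCOME_CODES["anticipated"]
    on_time = responded & (rt >= 0)
    if architecture.task_kind == "SRT":
        outcome[on_time] = OUTCOME_CODES["correct"]
    else:
        match = (resp_out == 1) == target_left[None, :]
        outcome[on_time & match] = OUTCOME_CODES["correct"]
        outcome[on_time & ~match] = OUTCOME_CODES["incorrect"]
    correct = outcome == OUTCOME_CODES["correct"]
    fitness = np.where(correct, 1000.0 * np.exp(-0.01 * np.where(correct, rt, 0.0)), 0.0)
    return PopulationEvaluation(
        fitness=fitness.sum(axis=1),
        rt=rt,
        outcome=outcome,
        cue_types=cue_types,
        cue_durations=durations,
    )


def individual_error_rates(outcome: np.ndarray) -> np.ndarray:
    """Per-individual fraction of trials that were not correct
    (anticipated + incorrect + slow)."""
    return (outcome != OUTCOME_CODES["correct"]).mean(axis=1)


def individual_median_rts(
    rt: np.ndarray, outcome: np.ndarray, cue_types: np.ndarray
) -> np.ndarray:
    """Per-individual median RT over correct trials, per cue type.

    Returns a ``(G, 3)`` array ordered (valid, neutral, invalid); an
    individual with no correct response for a cue type gets NaN (its
    median is "null" and is excluded from population statistics).
    """
    g_count = rt.shape[0]
    out = np.full((g_count, len(CUE_TYPES)), np.nan)
    correct = outcome == OUTCOME_CODES["correct"]
    for k, cue in enumerate(CUE_TYPES):
        cols = cue_types == cue
        if not cols.any():
            continue
        vals = np.where(correct[:, cols], rt[:, cols], np.nan)
        counts = np.sum(~np.isnan(vals), axis=1)
        med = np.full(g_count, np.nan)
        has = counts > 0
        if has.any():
            med[has] = np.nanmedian(vals[has], axis=1)
        out[:, k] = med
    return out
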