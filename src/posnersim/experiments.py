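"""Experiment runners and population statistics.

Experiment 1 sweeps the Bayesian observer over tasks (SRT/CRT), signal
intensities and response thresholds, and tabulates accuracy, correct-trial
mean RT and the error-type proportions per cue type.  Experiment 2
evolves the integrate-and-fire networks under one of three conditions:

========= ==================== ==============
condition cue ratio (v:n:i)    noise sigma
========= ==================== ==============
A         8:5:2                0
B         8:8:2                0
C         8:8:2                2
========= ==================== ==============

Population RT statistics follow the convention of the motor experiment:
for every individual the median RT over its correct trials is computed
per cue type ("null", i.e. excluded, if it has none), and the mean, SD
and 95% confidence interval are taken over the non-null medians.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from posnersim.bayes_observer import BayesConfig, simulate_trials, summarize_trials
from posnersim.genetic_optimizer import EvolutionHistory, GAConfig, evolve
from posnersim.lif_network import CUE_TYPES, Architecture, TaskSpec

__all__ = [
    "ConditionSpec",
    "CONDITIONS",
    "condition",
    "exp1_cue_mix",
    "run_exp1",
    "run_exp2",
    "population_rt_summary",
    "rt_summary_by_generation",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One of the motor-experiment conditions (or a custom variant)."""

    label: str
    cue_ratio: tuple[int, int, int]
    noise_sigma: float
    task_kind: str

    @property
    def task_spec(self) -> TaskSpec:
        return TaskSpec(cue_ratio=self.cue_ratio, noise_sigma=self.noise_sigma)

    @property
    def architecture(self) -> Architecture:
        return Architecture.for_task(self.task_kind)


CONDITIONS = {
    "A": ((8, 5, 2), 0.0),
    "B": ((8, 8, 2), 0.0),
    "C": ((8, 8, 2), 2.0),
}


def condition(label: str, task_kind: str) -> ConditionSpec:
    """Build the ConditionSpec for a label A/B/C and a task kind."""
    label = label.upper()
    if label not in CONDITIONS:
        raise ValueError(f"unknown condition {label!r}; expected one of A, B, C")
    ratio, sigma = CONDITIONS[label]
    return ConditionSpec(label, ratio, sigma, task_kind.upper())


def exp1_cue_mix(n_trials: int) -> list[str]:
    """Cue directions for an observer block: half lateral cues (split
    evenly left/right), half neutral."""
    n_left = n_trials // 4
    n_right = n_trials // 4
    n_neutral = n_trials - n_left - n_right
    return ["left"] * n_left + ["right"] * n_right + ["neutral"] * n_neutral


def run_exp1(
    tasks=("SRT", "CRT"),
    s_values=(5.0, 0.5),
    gammas=(0.8, 0.95),
    n_trials: int = 100_000,
    sigma: float = 2.0,
    rng: np.random.Generator | int | None = None,
    trials_out: dict | None = None,
) -> pd.DataFrame:
    """Monte-Carlo sweep of the Bayesian observer.

    Returns a summary DataFrame with one row per (task, s, gamma,
    cue_type) plus a pooled row per configuration (cue_type ``pooled``).
    If ``trials_out`` is a dict, the per-trial DataFrames are stored in
    it keyed by (task, s, gamma).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    frames = []
    for task in tasks:
        for s in s_values:
            for gamma in gammas:
                cfg = BayesConfig(s=s, gamma=gamma, sigma=sigma, task_kind=task)
                if n_trials == 0:
                    continue
                trials = simulate_trials(cfg, exp1_cue_mix(n_trials), rng)
                if trials_out is not None:
                    trials_out[(task, s, gamma)] = trials
                summary = summarize_trials(trials)
                pooled = pd.DataFrame(
                    [
                        {
                            "cue_type": "pooled",
                            "n": len(trials),
                            "accuracy": (trials["outcome"] == "correct").mean(),
                            "mean_rt": trials.loc[
                                trials["outcome"] == "correct", "rt"
                            ].mean(),
                            "sd_rt": trials.loc[
                                trials["outcome"] == "correct", "rt"
                            ].std(ddof=1),
                            "prop_anticipated": (trials["outcome"] == "anticipated").mean(),
                            "prop_incorrect": (trials["outcome"] == "incorrect").mean(),
                            "prop_slow": (trials["outcome"] == "slow").mean(),
                        }
                    ]
                )
                summary = pd.concat([summary, pooled], ignore_index=True)
                summary.insert(0, "gamma", gamma)
                summary.insert(0, "s", s)
                summary.insert(0, "task", task)
                frames.append(summary)
    if not frames:
        return pd.DataFrame(
            columns=[
                "task", "s", "gamma", "cue_type", "n", "accuracy", "mean_rt",
                "sd_rt", "prop_anticipated", "prop_incorrect", "prop_slow",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def population_rt_summary(median_rts: np.ndarray) -> pd.DataFrame:
    """Population statistics over per-individual median RTs.

    ``median_rts`` is ``(G, 3)`` ordered (valid, neutral, invalid) with
    NaN for null medians.  Returns one row per cue type with the mean,
    SD, normal-approximation 95% CI half-width and the number of
    individuals that contributed; a cue type with no non-null individuals
    is marked unavailable (NaN statistics, n = 0).
    """
    median_rts = np.asarray(median_rts, dtype=float)
    if median_rts.ndim == 1:
        median_rts = median_rts[:, None]
    rows = []
    for k, cue in enumerate(CUE_TYPES[: median_rts.shape[1]]):
        vals = median_rts[:, k]
        vals = vals[~np.isnan(vals)]
        n = vals.size
        mean = float(vals.mean()) if n else np.nan
        sd = float(vals.std(ddof=1)) if n > 1 else np.nan
        ci = 1.96 * sd / np.sqrt(n) if n > 1 else np.nan
        rows.append(
            {"cue_type": cue, "n": n, "mean_median_rt": mean, "sd": sd, "ci95": ci}
        )
    return pd.DataFrame(rows)


def rt_summary_by_generation(history: EvolutionHistory) -> pd.DataFrame:
    """Population RT summary for every recorded generation."""
    frames = []
    for gen in range(history.n_generations):
        df = population_rt_summary(history.median_rts[gen])
        df.insert(0, "generation", gen)
        df["mean_error_rate"] = history.error_rates[gen].mean()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_exp2(
    cond: ConditionSpec | str,
    task_kind: str | None = None,
    ga: GAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    generations: int | None = None,
    progress: bool = False,
) -> tuple[EvolutionHistory, pd.DataFrame]:
    """Evolve networks under a condition and attach per-generation
    population RT summaries.  ``cond`` may be a label (then ``task_kind``
    is required) or a full :class:`ConditionSpec`."""
    if isinstance(cond, str):
        if task_kind is None:
            raise ValueError("task_kind is required when passing a condition label")
        cond = condition(cond, task_kind)
    ga = ga or GAConfig()
    history = evolve(
        ga,
        cond.architecture,
        cond.task_spec,
        rng=rng,
        generations=generations,
        progress=progress,
    )
    return history, rt_summary_by_generation(history)


def write_exp2_outputs(
    history: EvolutionHistory,
    summary: pd.DataFrame,
    out_dir: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write the history CSVs, a final-populations JSON checkpoint and a
    run-metadata sidecar into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    history.populations_df.to_csv(out / "history.csv", index=False)
    summary.to_csv(out / "rt_summary.csv", index=False)
    with open(out / "final_populations.json", "w") as fh:
        json.dump(history.final_populations.tolist(), fh)
    if metadata is not None:
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(metadata, fh, indent=2, default=str)
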