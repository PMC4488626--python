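"""Bayesian sequential detector for the Posner cueing task (sensory model).

The observer monitors two channels, *left* and *right*.  On every trial a
target of intensity ``s`` appears on one side at a time drawn uniformly
from ``{1, ..., t_max}`` and stays on until the trial ends.  At each time
unit the observer receives a stimulus pair ``(S_l, S_r)``: independent
Gaussian noise of standard deviation ``sigma`` around 0, shifted to mean
``s`` on the target side once the target is present.  The central cue sets
the prior probability ``rho`` that the target will appear on the left
(0.8 for a left cue, 0.5 neutral, 0.2 for a right cue).

After each stimulus the observer updates the posterior probabilities that
the target has *already* appeared on the left and on the right.  In a
simple reaction-time (SRT) task it responds when the sum of the two
posteriors reaches the threshold ``gamma``; in a choice reaction-time
(CRT) task it responds to whichever side's posterior reaches ``gamma``
first (ties broken by a fair coin).  Because the appearance prior is
exhausted at ``t_max``, the SRT observer always responds by ``t_max``;
the CRT observer may keep accumulating evidence afterwards and is scored
"slow" if it has not responded before the absolute deadline
``t_deadline``.

The running posteriors are maintained with a constant-cost recurrence on
three scaled accumulators (target-already-left, target-already-right, and
the running no-target likelihood product).  :func:`naive_posterior`
evaluates the defining sums over the full stimulus history directly and
serves as the reference implementation for testing the recurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RHO_BY_CUE",
    "BayesConfig",
    "StimulusPair",
    "PosteriorState",
    "BayesTrialResult",
    "prior_appearance",
    "step_likelihoods",
    "init_state",
    "update",
    "naive_posterior",
    "simulate_trial",
    "simulate_trials",
    "summarize_trials",
]

#: Prior probability that the target appears on the LEFT, by cue direction.
RHO_BY_CUE = {"left": 0.8, "neutral": 0.5, "right": 0.2}

# naive_posterior is an O(n^2) test oracle; refuse silly history lengths.
_NAIVE_MAX_LEN = 64


@dataclass(frozen=True)
class BayesConfig:
    """Task parameters of the Bayesian observer.

    Parameters
    ----------
    s:
        Signal intensity added to the target-side stimulus mean.
    gamma:
        Posterior-probability response threshold, in ``[0, 1]``.
    rho:
        Cue-implied prior probability that the target appears on the left
        (0.8 left cue, 0.5 neutral, 0.2 right cue).
    sigma:
        Stimulus noise standard deviation.
    t_max:
        Length of the appearance window; the target onset is uniform on
        ``{1, ..., t_max}``.
    task_kind:
        ``"SRT"`` or ``"CRT"``.
    t_deadline:
        Absolute time index; a CRT trial without a response before this
        instant is scored slow.
    """

    s: float
    gamma: float
    rho: float = 0.5
    sigma: float = 2.0
    t_max: int = 100
    task_kind: str = "SRT"
    t_deadline: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be > 0")
        if self.task_kind not in ("SRT", "CRT"):
            raise ValueError(f"task_kind must be 'SRT' or 'CRT', got {self.task_kind!r}")
        if self.t_deadline < self.t_max:
            raise ValueError("t_deadline must be >= t_max")


@dataclass(frozen=True)
class StimulusPair:
    """One time-step of left/right input.  Negative values are ordinary
    draws below the noise mean, not errors."""

    S_l: float
    S_r: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.S_l) and math.isfinite(self.S_r)):
            raise ValueError("stimuli must be finite")


@dataclass(frozen=True)
class PosteriorState:
    """Running posterior accumulators after ``t_now`` stimulus pairs.

    ``acc_l``/``acc_r`` are the likelihood-weighted prior sums for "target
    already appeared left/right"; ``acc_nbar`` is the running likelihood
    product under "no target yet".  All three share an arbitrary common
    scale (they are rescaled every step to avoid underflow); posteriors
    are recovered by :meth:`posteriors`.
    """

    t_now: int = 0
    acc_l: float = 0.0
    acc_r: float = 0.0
    acc_nbar: float = 1.0

    def posteriors(self, config: BayesConfig) -> tuple[float, float, float]:
        """Return ``(posterior_l, posterior_r, posterior_none)``."""
        remaining = max(0.0, 1.0 - self.t_now / config.t_max)
        g_n = self.acc_nbar * remaining
        total = self.acc_l + self.acc_r + g_n
        return self.acc_l / total, self.acc_r / total, g_n / total


@dataclass(frozen=True)
class BayesTrialResult:
    """Outcome of one observer trial.

    ``rt`` is the response time minus the target onset time (negative for
    anticipated responses, ``None`` for slow trials).  ``response_side``
    is ``"left"``/``"right"`` for CRT responses, ``"single"`` for the
    undirected SRT response and ``"none"`` when no response occurred.
    """

    rt: int | None
    response_side: str
    outcome: str
    target_side: str
    target_time: int
    cue_type: str


def prior_appearance(t: int, config: BayesConfig) -> tuple[float, float]:
    """Prior probability that the target appears exactly at time ``t``,
    per side: ``(rho/t_max, (1-rho)/t_max)`` inside the appearance window
    and ``(0, 0)`` after it."""
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if t > config.t_max:
        return 0.0, 0.0
    return config.rho / config.t_max, (1.0 - config.rho) / config.t_max


def step_likelihoods(
    pair: StimulusPair, config: BayesConfig
) -> tuple[float, float, float]:
    """Per-step likelihood factors of a stimulus pair under the three
    hypotheses (target already left / already right / not yet), with the
    Gaussian normalizing constant dropped; each lies in ``(0, 1]``."""
    inv = 1.0 / (2.0 * config.sigma**2)
    s = config.s
    f_l = math.exp(-((pair.S_l - s) ** 2 + pair.S_r**2) * inv)
    f_r = math.exp(-(pair.S_l**2 + (pair.S_r - s) ** 2) * inv)
    f_nbar = math.exp(-(pair.S_l**2 + pair.S_r**2) * inv)
    return f_l, f_r, f_nbar


def init_state(config: BayesConfig) -> PosteriorState:
    """Fresh state: at ``t_now = 0`` both side posteriors are zero and the
    no-target posterior is one."""
    return PosteriorState()


def update(
    state: PosteriorState, pair: StimulusPair, config: BayesConfig
) -> PosteriorState:
    """Advance the posterior by one stimulus pair.

    Constant-cost recurrence: with per-step factors ``f_side`` and
    ``f_nbar`` and appearance prior ``p_side(t)``,

    .. code-block:: text

        acc_side' = f_side * (acc_side + p_side(t) * acc_nbar)
        acc_nbar' = acc_nbar * f_nbar

    after which the three accumulators are rescaled by their sum.  The
    result matches :func:`naive_posterior` on the full history.
    """
    t = state.t_now + 1
    f_l, f_r, f_nbar = step_likelihoods(pair, config)
    p_l, p_r = prior_appearance(t, config)
    acc_l = f_l * (state.acc_l + p_l * state.acc_nbar)
    acc_r = f_r * (state.acc_r + p_r * state.acc_nbar)
    acc_nbar = state.acc_nbar * f_nbar
    scale = acc_l + acc_r + acc_nbar
    if scale > 0.0:
        acc_l, acc_r, acc_nbar = acc_l / scale, acc_r / scale, acc_nbar / scale
    return PosteriorState(t, acc_l, acc_r, acc_nbar)


def naive_posterior(
    history: Sequence[StimulusPair], config: BayesConfig
) -> np.ndarray:
    """Literal evaluation of the posterior over the full stimulus history.

    For each prefix length ``t'`` the appearance hypotheses ``t = 1..t'``
    are enumerated and their sequence likelihoods computed as explicit
    products.  Returns an ``(len(history), 2)`` array of
    ``(posterior_l, posterior_r)`` per step.  Test oracle only —
    quadratic cost, so the history length is capped.
    """
    n = len(history)
    if n > _NAIVE_MAX_LEN:
        raise ValueError(f"naive_posterior is an oracle; max length {_NAIVE_MAX_LEN}")
    factors = [step_likelihoods(pair, config) for pair in history]
    out = np.empty((n, 2))
    for tp in range(1, n + 1):
        g_l = 0.0
        g_r = 0.0
        for t in range(1, tp + 1):
            p_l, p_r = prior_appearance(t, config)
            lik_l = 1.0
            lik_r = 1.0
            for i in range(1, tp + 1):
                f_l_i, f_r_i, f_n_i = factors[i - 1]
                lik_l *= f_n_i if i < t else f_l_i
                lik_r *= f_n_i if i < t else f_r_i
            g_l += lik_l * p_l
            g_r += lik_r * p_r
        lik_none = 1.0
        for i in range(1, tp + 1):
            lik_none *= factors[i - 1][2]
        g_n = lik_none * max(0.0, 1.0 - min(tp, config.t_max) / config.t_max)
        total = g_l + g_r + g_n
        out[tp - 1] = g_l / total, g_r / total
    return out


def _cue_rho(cue: str) -> float:
    try:
        return RHO_BY_CUE[cue]
    except KeyError:
        raise ValueError(f"cue must be one of {sorted(RHO_BY_CUE)}, got {cue!r}")


def _cue_type(cue: str, target_side: str) -> str:
    if cue == "neutral":
        return "neutral"
    return "valid" if cue == target_side else "invalid"


def simulate_trial(
    config: BayesConfig,
    cue: str,
    rng: np.random.Generator | int | None = None,
) -> BayesTrialResult:
    """Run a single trial of the observer.

    The cue fixes ``rho``; target onset is uniform on ``{1..t_max}`` and
    the target side is drawn with probability ``rho`` (left).  Stimuli
    are streamed and posteriors updated until the task's decision rule
    fires; the stream stops at the first response.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rho = _cue_rho(cue)
    cfg = BayesConfig(
        s=config.s,
        gamma=config.gamma,
        rho=rho,
        sigma=config.sigma,
        t_max=config.t_max,
        task_kind=config.task_kind,
        t_deadline=config.t_deadline,
    )
    target_time = int(rng.integers(1, cfg.t_max + 1))
    target_side = "left" if rng.random() < rho else "right"
    cue_type = _cue_type(cue, target_side)
    state = init_state(cfg)
    t_limit = cfg.t_max if cfg.task_kind == "SRT" else cfg.t_deadline - 1
    for t in range(1, t_limit + 1):
        mean_l = cfg.s if (target_side == "left" and t >= target_time) else 0.0
        mean_r = cfg.s if (target_side == "right" and t >= target_time) else 0.0
        pair = StimulusPair(
            mean_l + cfg.sigma * rng.standard_normal(),
            mean_r + cfg.sigma * rng.standard_normal(),
        )
        state = update(state, pair, cfg)
        p_l, p_r, p_none = state.posteriors(cfg)
        if cfg.task_kind == "SRT":
            # 1 - p_none rather than p_l + p_r: identical in exact
            # arithmetic, and exactly 1 once the prior mass is exhausted
            if 1.0 - p_none >= cfg.gamma:
                rt = t - target_time
                outcome = "anticipated" if rt < 0 else "correct"
                return BayesTrialResult(rt, "single", outcome, target_side, target_time, cue_type)
        else:
            hit_l = p_l >= cfg.gamma
            hit_r = p_r >= cfg.gamma
            if hit_l or hit_r:
                if hit_l and hit_r:
                    side = "left" if rng.random() < 0.5 else "right"
                else:
                    side = "left" if hit_l else "right"
                rt = t - target_time
                if rt < 0:
                    outcome = "anticipated"
                elif side == target_side:
                    outcome = "correct"
                else:
                    outcome = "incorrect"
                return BayesTrialResult(rt, side, outcome, target_side, target_time, cue_type)
    # only reachable for CRT: no side posterior crossed gamma before the deadline
    return BayesTrialResult(None, "none", "slow", target_side, target_time, cue_type)


def simulate_trials(
    config: BayesConfig,
    cues: Iterable[str],
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Vectorized Monte-Carlo over many trials.

    ``cues`` gives the cue direction (``left``/``neutral``/``right``) per
    trial.  Returns a per-trial DataFrame with columns ``trial``,
    ``cue_type``, ``target_side``, ``target_time``, ``response_side``,
    ``rt`` and ``outcome``; ``rt`` is NaN for slow trials.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cues = np.asarray(list(cues), dtype=object)
    n = cues.size
    if n == 0:
        return pd.DataFrame(
            columns=[
                "trial", "cue_type", "target_side", "target_time",
                "response_side", "rt", "outcome",
            ]
        )
    rho = np.array([_cue_rho(c) for c in cues])
    t_max = config.t_max
    srt = config.task_kind == "SRT"
    target_time = rng.integers(1, t_max + 1, size=n)
    target_left = rng.random(n) < rho

    acc_l = np.zeros(n)
    acc_r = np.zeros(n)
    acc_nbar = np.ones(n)
    resp_t = np.zeros(n, dtype=np.int64)
    resp_side = np.zeros(n, dtype=np.int8)  # 0 none, 1 left, 2 right, 3 single
    active = np.ones(n, dtype=bool)

    inv = 1.0 / (2.0 * config.sigma**2)
    s = config.s
    t_limit = t_max if srt else config.t_deadline - 1
    for t in range(1, t_limit + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        noise = rng.normal(0.0, config.sigma, size=(idx.size, 2))
        on = t >= target_time[idx]
        s_l = noise[:, 0] + np.where(on & target_left[idx], s, 0.0)
        s_r = noise[:, 1] + np.where(on & ~target_left[idx], s, 0.0)
        f_l = np.exp(-((s_l - s) ** 2 + s_r**2) * inv)
        f_r = np.exp(-(s_l**2 + (s_r - s) ** 2) * inv)
        f_n = np.exp(-(s_l**2 + s_r**2) * inv)
        if t <= t_max:
            p_l = rho[idx] / t_max
            p_r = (1.0 - rho[idx]) / t_max
        else:
            p_l = p_r = 0.0
        g_l = f_l * (acc_l[idx] + p_l * acc_nbar[idx])
        g_r = f_r * (acc_r[idx] + p_r * acc_nbar[idx])
        g_nbar = acc_nbar[idx] * f_n
        scale = g_l + g_r + g_nbar
        g_l /= scale
        g_r /= scale
        g_nbar /= scale
        acc_l[idx] = g_l
        acc_r[idx] = g_r
        acc_nbar[idx] = g_nbar
        remaining = max(0.0, 1.0 - t / t_max)
        denom = g_l + g_r + g_nbar * remaining
        post_l = g_l / denom
        post_r = g_r / denom
        if srt:
            # exactly 1 at t_max, where the no-target mass vanishes
            fired = 1.0 - g_nbar * remaining / denom >= config.gamma
            side = np.full(fired.sum(), 3, dtype=np.int8)
        else:
            hit_l = post_l >= config.gamma
            hit_r = post_r >= config.gamma
            fired = hit_l | hit_r
            side = np.where(hit_l[fired], 1, 2).astype(np.int8)
            both = (hit_l & hit_r)[fired]
            if both.any():
                side[both] = rng.integers(1, 3, size=int(both.sum()), dtype=np.int8)
        j = idx[fired]
        resp_t[j] = t
        resp_side[j] = side
        active[j] = False

    responded = resp_t > 0
    rt = np.where(responded, resp_t - target_time, 0).astype(float)
    rt[~responded] = np.nan
    target_side = np.where(target_left, "left", "right")
    outcome = np.full(n, "slow", dtype=object)
    ant = responded & (rt < 0)
    outcome[ant] = "anticipated"
    if srt:
        outcome[responded & (rt >= 0)] = "correct"
    else:
        resp_left = resp_side == 1
        match = responded & (resp_left == target_left)
        outcome[responded & (rt >= 0) & match] = "correct"
        outcome[responded & (rt >= 0) & ~match] = "incorrect"
    side_names = np.array(["none", "left", "right", "single"], dtype=object)
    cue_type = np.where(
        cues == "neutral",
        "neutral",
        np.where(cues == target_side, "valid", "invalid"),
    )
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "cue_type": cue_type,
            "target_side": target_side,
            "target_time": target_time,
            "response_side": side_names[resp_side],
            "rt": rt,
            "outcome": outcome,
        }
    )


def summarize_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cue-type summary: trial count, accuracy, correct-trial mean/SD
    RT, and the anticipated/incorrect/slow proportions."""
    rows = []
    for cue_type, grp in trials.groupby("cue_type", sort=False):
        correct = grp[grp["outcome"] == "correct"]
        n = len(grp)
        rows.append(
            {
                "cue_type": cue_type,
                "n": n,
                "accuracy": len(correct) / n,
                "mean_rt": correct["rt"].mean() if len(correct) else np.nan,
                "sd_rt": correct["rt"].std(ddof=1) if len(correct) > 1 else np.nan,
                "prop_anticipated": (grp["outcome"] == "anticipated").mean(),
                "prop_incorrect": (grp["outcome"] == "incorrect").mean(),
                "prop_slow": (grp["outcome"] == "slow").mean(),
            }
        )
    return pd.DataFrame(rows)
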