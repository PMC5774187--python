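"""Synthetic trial generator for the censored behavioral model.

Generates realizations of the latent AR(1) inattention state together with
log-normal reaction times, optional binary decisions, and right censoring at
a per-trial response window.  Defaults reproduce the reference study
conditions: 100 trials per realization, stationary start, thresholds swept
over 0.2-2 s.  Decisions are simulated only on observed trials (joint
censoring: when the reaction time exceeds the window, neither the time nor
the choice is recorded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special

from .model import ModelParameters, TrialObservation, steady_state_moments

__all__ = [
    "Realization",
    "simulate_states",
    "simulate_trials",
    "simulate_realization",
    "expected_censoring_fraction",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class Realization:
    """One simulated session: true states plus the (censored) trial record.

    Regenerable bit-for-bit from ``seed`` with the same settings.
    """

    states: np.ndarray
    trials: tuple[TrialObservation, ...]
    seed: int
    threshold: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def censored_fraction(self) -> float:
        return sum(not t.observed for t in self.trials) / len(self.trials)


def simulate_states(
    params: ModelParameters,
    n_trials: int,
    rng: np.random.Generator,
    x0: Optional[float] = None,
) -> np.ndarray:
    """AR(1) state sequence x_1..x_n.

    ``x0=None`` draws x_1 from the stationary distribution (requires
    |a1| < 1); a float starts the recursion from that fixed value, in which
    case x_1 = a1*x0 + a0 + noise.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    x = np.empty(n_trials)
    if x0 is None:
        mean, sd = steady_state_moments(params)
        x[0] = mean + sd * rng.standard_normal()
    else:
        x[0] = params.a1 * x0 + params.a0 + params.sigma_eps * rng.standard_normal()
    eps = params.sigma_eps * rng.standard_normal(n_trials - 1)
    for k in range(1, n_trials):
        x[k] = params.a1 * x[k - 1] + params.a0 + eps[k - 1]
    return x


def simulate_trials(
    states: Sequence[float],
    params: ModelParameters,
    threshold: float,
    rng: np.random.Generator,
    with_decision: bool = True,
) -> tuple[TrialObservation, ...]:
    """Reaction times, censoring and (optionally) decisions for given states.

    Per trial: y = exp(b1*x + b0 + v).  If y exceeds the threshold the trial
    is censored with no recorded data; otherwise the reaction time is kept
    and, when ``with_decision``, a Bernoulli decision is drawn with
    probability logistic(c2*x + c1*y + c0).
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    states = np.asarray(states, dtype=float)
    n = states.size
    rts = np.exp(
        params.b1 * states + params.b0 + params.sigma_v * rng.standard_normal(n)
    )
    # decision uniforms are always drawn so the stream is threshold-invariant:
    # the same seed yields the same underlying session under any window
    dec_u = rng.random(n) if with_decision else None
    trials = []
    for k in range(n):
        if rts[k] > threshold:
            trials.append(
                TrialObservation(index=k + 1, threshold=threshold, status="censored")
            )
            continue
        decision = None
        if with_decision:
            p = special.expit(
                params.c2 * states[k] + params.c1 * rts[k] + params.c0
            )
            decision = int(dec_u[k] < p)
        trials.append(
            TrialObservation(
                index=k + 1,
                threshold=threshold,
                status="observed",
                rt=float(rts[k]),
                decision=decision,
            )
        )
    return tuple(trials)


def simulate_realization(
    params: ModelParameters,
    n_trials: int,
    threshold: float,
    seed: int,
    with_decision: bool = True,
    x0: Optional[float] = None,
) -> Realization:
    """One fully reproducible session from a single integer seed."""
    rng = np.random.default_rng(seed)
    states = simulate_states(params, n_trials, rng, x0=x0)
    trials = simulate_trials(states, params, threshold, rng, with_decision)
    return Realization(states=states, trials=trials, seed=seed, threshold=threshold)


def expected_censoring_fraction(threshold: float, params: ModelParameters) -> float:
    """Pr(y > T) under the stationary state law.

    Marginally, log y ~ N(b1*mu_ss + b0, b1^2*sigma_ss^2 + sigma_v^2), so the
    expected censored fraction is the normal upper-tail mass of log T.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    mu, sd = steady_state_moments(params)
    scale = math.hypot(params.b1 * sd, params.sigma_v)
    z = (math.log(threshold) - params.b1 * mu - params.b0) / scale
    return float(0.5 * special.erfc(z / _SQRT2))
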