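"""Generative model and per-trial likelihoods.

The model describes a trial-structured behavioral experiment in which a scalar
latent "inattention" state evolves as a stationary AR(1) process and drives two
observations per trial: a log-normally distributed reaction time and,
optionally, a binary decision whose log-odds depend on both the state and the
realized reaction time.  Each trial has a response window ``T_k``; whenever the
reaction time exceeds it the trial is *right-censored* and both the reaction
time and the decision are missing.  Because the censoring probability depends
on the latent state itself, the missingness is NMAR (missing not at random)
and censored trials still carry information through their survival probability.

State equation
    x_k = a1 * x_{k-1} + a0 + eps_k,          eps_k ~ N(0, sigma_eps^2)

Reaction-time equation
    log y_k = b1 * x_k + b0 + v_k,            v_k ~ N(0, sigma_v^2)

Decision equation
    logit Pr(z_k = 1) = c2 * x_k + c1 * y_k + c0

All likelihood evaluations here are vectorized over the state value ``x`` so
that grid-based filters can evaluate them on a whole state grid at once.  The
observed-trial likelihood is taken as the Gaussian density of ``log y`` (the
1/y Jacobian is independent of the state and cancels in every posterior
normalization, so filters are unaffected by the convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import special

__all__ = [
    "ModelParameters",
    "TrialObservation",
    "steady_state_moments",
    "state_transition_density",
    "rt_log_density",
    "rt_survival",
    "decision_probability",
    "trial_log_likelihood",
    "interval_censored_log_likelihood",
]

logger = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)

Scheme = Literal["full", "deletion"]


@dataclass(frozen=True)
class ModelParameters:
    """All nine scalars of the generative model.

    Defaults reproduce the reference simulation settings: a stationary AR(1)
    state with steady-state mean 0.5 and SD 0.25, a median reaction time of
    exp(-0.6) ~ 0.55 s at state zero, and a decision process in which longer
    reaction times raise and higher inattention lowers the probability of a
    correct response.
    """

    a0: float = 0.025
    a1: float = 0.95
    sigma_eps: float = 0.078
    b0: float = -0.6
    b1: float = 1.0
    sigma_v: float = 0.141
    c0: float = -3.5
    c1: float = 10.0
    c2: float = -8.5

    def __post_init__(self) -> None:
        if not self.sigma_eps > 0:
            raise ValueError(f"sigma_eps must be > 0, got {self.sigma_eps}")
        if not self.sigma_v > 0:
            raise ValueError(f"sigma_v must be > 0, got {self.sigma_v}")


@dataclass(frozen=True)
class TrialObservation:
    """One trial: censoring threshold plus the observed data, if any.

    Censoring is encoded by the explicit ``status`` field, never by sentinel
    numeric values.  ``rt`` (seconds) is present iff the trial was observed;
    ``decision`` is present only on observed trials of experiments that record
    a binary choice.
    """

    index: int
    threshold: float
    status: Literal["observed", "censored"]
    rt: Optional[float] = None
    decision: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status not in ("observed", "censored"):
            raise ValueError(f"trial {self.index}: bad status {self.status!r}")
        if not self.threshold > 0:
            raise ValueError(f"trial {self.index}: threshold must be > 0")
        if self.status == "observed":
            if self.rt is None:
                raise ValueError(f"trial {self.index}: observed trial missing rt")
            if not 0 < self.rt <= self.threshold:
                raise ValueError(
                    f"trial {self.index}: rt {self.rt} outside (0, {self.threshold}]"
                )
            if self.decision is not None and self.decision not in (0, 1):
                raise ValueError(f"trial {self.index}: decision must be 0 or 1")
        else:
            if self.rt is not None or self.decision is not None:
                raise ValueError(
                    f"trial {self.index}: censored trial cannot carry rt/decision"
                )

    @property
    def observed(self) -> bool:
        return self.status == "observed"


def steady_state_moments(params: ModelParameters) -> tuple[float, float]:
    """Stationary mean and SD of the AR(1) state.

    Returns ``(a0 / (1 - a1), sqrt(sigma_eps^2 / (1 - a1^2)))``.  Requires
    ``|a1| < 1``; a non-stationary state has no steady-state distribution.
    """
    if abs(params.a1) >= 1:
        raise ValueError(f"stationarity requires |a1| < 1, got a1={params.a1}")
    mean = params.a0 / (1.0 - params.a1)
    sd = math.sqrt(params.sigma_eps**2 / (1.0 - params.a1**2))
    return mean, sd


def state_transition_density(x_prev, x, params: ModelParameters):
    """Gaussian transition density f(x | x_prev): N(a1*x_prev + a0, sigma_eps^2)."""
    x_prev = np.asarray(x_prev, dtype=float)
    x = np.asarray(x, dtype=float)
    mu = params.a1 * x_prev + params.a0
    z = (x - mu) / params.sigma_eps
    return np.exp(-0.5 * z * z) / (params.sigma_eps * math.sqrt(2 * math.pi))


def rt_log_density(rt: float, x, params: ModelParameters):
    """Log Gaussian density of log(rt) given the state.

    log y | x ~ N(b1*x + b0, sigma_v^2).  This is the density over log-RT;
    see the module docstring for the Jacobian convention.
    """
    if not rt > 0:
        raise ValueError(f"rt must be > 0, got {rt}")
    x = np.asarray(x, dtype=float)
    mu = params.b1 * x + params.b0
    z = (math.log(rt) - mu) / params.sigma_v
    return -0.5 * z * z - math.log(params.sigma_v) - 0.5 * math.log(2 * math.pi)


def rt_survival(threshold: float, x, params: ModelParameters):
    """Pr(y > threshold | x) = 1 - Phi((log T - b1*x - b0) / sigma_v).

    Computed through erfc for tail accuracy; strictly increasing in ``x``
    when ``b1 > 0`` (higher inattention makes censoring more likely).
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    x = np.asarray(x, dtype=float)
    z = (math.log(threshold) - params.b1 * x - params.b0) / params.sigma_v
    return 0.5 * special.erfc(z / _SQRT2)


def _log_rt_survival(threshold: float, x, params: ModelParameters):
    """log Pr(y > T | x), stable deep in the censoring tail (via log-erfc)."""
    x = np.asarray(x, dtype=float)
    z = (math.log(threshold) - params.b1 * x - params.b0) / params.sigma_v
    # log(0.5*erfc(t)) = log(0.5) + log(erfcx(t)) - t^2, stable for large t
    t = z / _SQRT2
    return math.log(0.5) + np.log(special.erfcx(t)) - t * t


def decision_probability(x, rt: float, params: ModelParameters):
    """Probability of a correct decision: logistic(c2*x + c1*rt + c0)."""
    x = np.asarray(x, dtype=float)
    return special.expit(params.c2 * x + params.c1 * rt + params.c0)


def trial_log_likelihood(
    obs: TrialObservation,
    x,
    params: ModelParameters,
    scheme: Scheme = "full",
    include_decision: bool = True,
):
    """Log-likelihood of one trial's data as a function of the state.

    scheme="full"
        observed trial: Gaussian log-density of log-RT, plus the Bernoulli
        log-mass of the decision when present and ``include_decision``;
        censored trial: log survival probability of the response window.
    scheme="deletion"
        observed trial: as above; censored trial: 0 (likelihood set to one,
        so the update step leaves the prediction untouched).
    """
    if scheme not in ("full", "deletion"):
        raise ValueError(f"unknown scheme {scheme!r}")
    x = np.asarray(x, dtype=float)
    if obs.observed:
        ll = rt_log_density(obs.rt, x, params)
        if obs.decision is not None:
            if include_decision:
                eta = params.c2 * x + params.c1 * obs.rt + params.c0
                # z*log(p) + (1-z)*log(1-p) via the logit, stable for extreme eta
                ll = ll + obs.decision * eta - np.logaddexp(0.0, eta)
            else:
                logger.warning(
                    "trial %d: decision present but include_decision=False; ignored",
                    obs.index,
                )
        return ll
    if scheme == "deletion":
        return np.zeros_like(x)
    return _log_rt_survival(obs.threshold, x, params)


def interval_censored_log_likelihood(
    lower: float, upper: float, x, params: ModelParameters
):
    """Log-probability that the reaction time falls in (lower, upper].

    Two-sided censoring: ``log[Phi((log u - mu)/sv) - Phi((log l - mu)/sv)]``
    with ``mu = b1*x + b0``.  Right censoring is the special case
    ``upper = inf``; left censoring is ``lower = 0``.  This interval form is a
    reconstruction from the one-sided model (synthetic construction, not a
    transcribed formula) and reduces exactly to :func:`rt_survival` when
    ``(lower, upper) = (T, inf)``.
    """
    if not (0 <= lower < upper):
        raise ValueError(f"empty or invalid interval ({lower}, {upper})")
    x = np.asarray(x, dtype=float)
    mu = params.b1 * x + params.b0
    if math.isinf(upper):
        if lower == 0:
            return np.zeros_like(x)
        return _log_rt_survival(lower, x, params)
    zu = (math.log(upper) - mu) / params.sigma_v
    if lower == 0:
        prob = special.ndtr(zu)
    else:
        zl = (math.log(lower) - mu) / params.sigma_v
        prob = special.ndtr(zu) - special.ndtr(zl)
    with np.errstate(divide="ignore"):
        return np.log(prob)
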