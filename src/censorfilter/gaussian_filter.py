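"""Approximate Gaussian (Kalman-like) filter with censored-data corrections.

Each trial's posterior is summarized by a mean and variance.  Prediction is
the standard AR(1) moment map; the update is a second-order Taylor (Laplace)
step of the exact log-posterior about the prediction mean.  For an observed
trial this reduces to the scalar Kalman update on log-RT (plus a logistic
information term when a decision is present); for a censored trial the
correction is built from the inverse Mills ratio of the standardized
censoring residual, computed through the scaled complementary error function
so the ratio stays accurate arbitrarily deep in the censoring tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from scipy import special

from .model import ModelParameters, TrialObservation, steady_state_moments

__all__ = [
    "GaussianBelief",
    "CensoredUpdateTerms",
    "g_predict",
    "censored_terms",
    "g_update_rt",
    "g_update_mixed",
    "run_gaussian_filter",
]

_SQRT2 = math.sqrt(2.0)
_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)

Mode = Literal["rt_only", "mixed"]


@dataclass(frozen=True)
class GaussianBelief:
    """Mean/variance summary of a filtering belief."""

    mean: float
    variance: float
    trial_index: int = 0

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be > 0, got {self.variance}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class CensoredUpdateTerms:
    """Intermediate quantities of the censoring-aware update.

    y_hat : predicted log-RT, b1*mean + b0
    e     : residual, (log y if observed else log T) - y_hat (log-seconds)
    phi   : Gaussian density of e at scale sigma_v
    L     : survival mass Pr(residual > e), in (0, 1]
    U     : inverse Mills ratio phi / L (per log-second)
    q, d  : predicted decision probability and residual z - q (observed
            trials of the mixed model only)
    """

    y_hat: float
    e: float
    phi: float
    L: float
    U: float
    q: Optional[float] = None
    d: Optional[float] = None


def _std_mills(t: float) -> float:
    """Standard-normal inverse Mills ratio pdf(t)/sf(t), stable for all t."""
    return _SQRT_2_OVER_PI / special.erfcx(t / _SQRT2)


def g_predict(belief: GaussianBelief, params: ModelParameters) -> GaussianBelief:
    """AR(1) one-step prediction: mean' = a0 + a1*mean, var' = a1^2*var + sigma_eps^2."""
    return GaussianBelief(
        mean=params.a0 + params.a1 * belief.mean,
        variance=params.a1**2 * belief.variance + params.sigma_eps**2,
        trial_index=belief.trial_index + 1,
    )


def censored_terms(
    belief: GaussianBelief, obs: TrialObservation, params: ModelParameters
) -> CensoredUpdateTerms:
    """Residual, tail mass and inverse Mills ratio at the prediction mean."""
    y_hat = params.b1 * belief.mean + params.b0
    log_obs = math.log(obs.rt) if obs.observed else math.log(obs.threshold)
    e = log_obs - y_hat
    t = e / params.sigma_v
    phi = math.exp(-0.5 * t * t) / (params.sigma_v * math.sqrt(2 * math.pi))
    L = 0.5 * special.erfc(t / _SQRT2)
    U = _std_mills(t) / params.sigma_v
    q = d = None
    if obs.observed and obs.decision is not None:
        q = float(special.expit(params.c2 * belief.mean + params.c1 * obs.rt + params.c0))
        d = obs.decision - q
    return CensoredUpdateTerms(y_hat=y_hat, e=e, phi=phi, L=float(L), U=U, q=q, d=d)


def _laplace_update(
    belief: GaussianBelief,
    score: float,
    information: float,
    trial_index: int,
) -> GaussianBelief:
    """Gaussian posterior from a Laplace step: given the likelihood score and
    observed information evaluated at the prediction mean."""
    precision = 1.0 / belief.variance + information
    if not precision > 0:
        raise RuntimeError(
            f"non-positive posterior precision at trial {trial_index}"
        )
    variance = 1.0 / precision
    return GaussianBelief(
        mean=belief.mean + variance * score,
        variance=variance,
        trial_index=trial_index,
    )


def g_update_rt(
    belief: GaussianBelief, obs: TrialObservation, params: ModelParameters
) -> GaussianBelief:
    """Censoring-aware update from the reaction time alone.

    Observed:  precision' = 1/var + b1^2/sigma_v^2,
               mean' = mean + var' * b1 * e / sigma_v^2   (scalar Kalman step).
    Censored:  precision' = 1/var + b1^2 * U * (U - e/sigma_v^2),
               mean' = mean + var' * b1 * U.
    The censored information term U*(U - e/sigma_v^2) lies in (0, 1/sigma_v^2)
    (Mills inequality), so a censored trial always adds positive but bounded
    information and the update can never destroy positivity of the precision.
    """
    terms = censored_terms(belief, obs, params)
    sv2 = params.sigma_v**2
    if obs.observed:
        score = params.b1 * terms.e / sv2
        information = params.b1**2 / sv2
    else:
        score = params.b1 * terms.U
        information = params.b1**2 * terms.U * (terms.U - terms.e / sv2)
    return _laplace_update(belief, score, information, obs.index)


def g_update_mixed(
    belief: GaussianBelief, obs: TrialObservation, params: ModelParameters
) -> GaussianBelief:
    """Update from reaction time plus binary decision.

    Observed trials add the logistic score c2*d and information
    c2^2*q*(1-q) to the RT update; censored trials are identical to
    :func:`g_update_rt` (a censored decision carries no state information).
    """
    if not obs.observed or obs.decision is None:
        return g_update_rt(belief, obs, params)
    terms = censored_terms(belief, obs, params)
    sv2 = params.sigma_v**2
    score = params.b1 * terms.e / sv2 + params.c2 * terms.d
    information = params.b1**2 / sv2 + params.c2**2 * terms.q * (1.0 - terms.q)
    return _laplace_update(belief, score, information, obs.index)


def run_gaussian_filter(
    trials: Sequence[TrialObservation],
    params: ModelParameters,
    prior: Optional[GaussianBelief] = None,
    mode: Mode = "mixed",
) -> tuple[list[GaussianBelief], list[GaussianBelief]]:
    """Alternate prediction with the mode's update over an ordered trial sequence.

    Returns ``(predictions, posteriors)``.  The default prior is the
    stationary distribution of the state.
    """
    if mode not in ("rt_only", "mixed"):
        raise ValueError(f"unknown mode {mode!r}")
    if prior is None:
        mean, sd = steady_state_moments(params)
        prior = GaussianBelief(mean=mean, variance=sd**2, trial_index=0)
    update_fn = g_update_rt if mode == "rt_only" else g_update_mixed
    predictions: list[GaussianBelief] = []
    posteriors: list[GaussianBelief] = []
    belief = prior
    for obs in trials:
        pred = GaussianBelief(
            mean=params.a0 + params.a1 * belief.mean,
            variance=params.a1**2 * belief.variance + params.sigma_eps**2,
            trial_index=obs.index,
        )
        belief = update_fn(pred, obs, params)
        predictions.append(pred)
        posteriors.append(belief)
    return predictions, posteriors
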