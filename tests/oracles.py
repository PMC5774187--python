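"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the Kalman recursion is
written out longhand, and the Laplace-step oracle differentiates the trial
log-likelihood by central finite differences instead of using the analytic
score/information expressions inside the Gaussian filter.
"""

import numpy as np

from censorfilter.model import trial_log_likelihood


def kalman_log_rt(trials, params, prior_mean, prior_var):
    """Scalar Kalman filter for the uncensored linear-Gaussian log-RT model.

    Observation: log y_k = b1 x_k + b0 + v_k. Returns per-trial posterior
    (means, variances).
    """
    m, v = prior_mean, prior_var
    means, variances = [], []
    for obs in trials:
        assert obs.observed, "oracle is for uncensored data only"
        m = params.a0 + params.a1 * m
        v = params.a1**2 * v + params.sigma_eps**2
        gain = v * params.b1 / (params.b1**2 * v + params.sigma_v**2)
        m = m + gain * (np.log(obs.rt) - params.b1 * m - params.b0)
        v = (1.0 - gain * params.b1) * v
        means.append(m)
        variances.append(v)
    return np.array(means), np.array(variances)


def laplace_fd_update(pred_mean, pred_var, obs, params, include_decision, h=1e-4):
    """Laplace (second-order Taylor) update computed by finite differences.

    Differentiates the exact trial log-likelihood about the prediction mean
    and returns the implied Gaussian posterior (mean, variance).
    """

    def ll(x):
        return float(
            trial_log_likelihood(
                obs, np.array([x]), params, scheme="full",
                include_decision=include_decision,
            )[0]
        )

    f0 = ll(pred_mean)
    fp = ll(pred_mean + h)
    fm = ll(pred_mean - h)
    score = (fp - fm) / (2 * h)
    information = -(fp - 2 * f0 + fm) / h**2
    precision = 1.0 / pred_var + information
    var = 1.0 / precision
    return pred_mean + var * score, var


def riccati_by_iteration(params, tol=1e-14, max_iter=100_000):
    """Fixed point of the prediction/observed-update variance recursion."""
    v = params.sigma_eps**2
    for _ in range(max_iter):
        v_pred = params.a1**2 * v + params.sigma_eps**2
        v_new = 1.0 / (1.0 / v_pred + params.b1**2 / params.sigma_v**2)
        if abs(v_new - v) < tol:
            return v_new
        v = v_new
    return v
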