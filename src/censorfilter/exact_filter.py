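"""Exact recursive Bayes filter on a fixed state grid.

The posterior over the scalar latent state is represented as probability mass
on a uniform grid (Riemann summation).  Each trial alternates a
Chapman-Kolmogorov prediction step (dense transition-matrix product,
precomputed once per parameter/grid pair) with a Bayes update against any of
the per-trial likelihood schemes from :mod:`censorfilter.model`.  Posterior
moments and numeric highest-posterior-density (HPD) regions are read off the
grid directly, so the filter captures the skew that develops during runs of
censored trials — the feature a Gaussian approximation cannot represent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .model import (
    ModelParameters,
    Scheme,
    TrialObservation,
    state_transition_density,
    steady_state_moments,
    trial_log_likelihood,
)

__all__ = [
    "GridPosterior",
    "HPDRegion",
    "make_grid",
    "gaussian_grid_posterior",
    "transition_matrix",
    "predict",
    "update",
    "run_filter",
    "posterior_moments",
    "hpd_region",
]

logger = logging.getLogger(__name__)

#: prediction mass allowed to leak off the grid before a warning is logged
LEAK_TOLERANCE = 1e-6


@dataclass(frozen=True)
class GridPosterior:
    """Discretized belief: probability mass per cell on a uniform grid."""

    grid: np.ndarray
    mass: np.ndarray
    trial_index: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if grid.ndim != 1 or grid.size < 3:
            raise ValueError("grid must be 1-D with at least 3 points")
        if mass.shape != grid.shape:
            raise ValueError("mass and grid shapes differ")
        steps = np.diff(grid)
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=0):
            raise ValueError("grid spacing must be uniform")
        if np.any(mass < 0):
            raise ValueError("mass must be nonnegative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mass", mass)

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass(frozen=True)
class HPDRegion:
    """Highest-posterior-density region on the grid.

    ``cells`` holds the indices of the included grid cells (density above the
    selected cutoff, ties included), which may form several disjoint
    intervals for multimodal beliefs.
    """

    level: float
    cells: np.ndarray
    attained_mass: float

    def contains(self, belief: GridPosterior, value: float) -> bool:
        """Whether ``value`` falls in a cell of the region (cell = point +- spacing/2)."""
        half = belief.spacing / 2.0
        pts = belief.grid[self.cells]
        return bool(np.any(np.abs(pts - value) <= half))

    def intervals(self, belief: GridPosterior) -> list[tuple[float, float]]:
        """The region as a list of closed intervals in state units."""
        if self.cells.size == 0:
            return []
        half = belief.spacing / 2.0
        out = []
        cells = np.sort(self.cells)
        start = prev = cells[0]
        for c in cells[1:]:
            if c != prev + 1:
                out.append((belief.grid[start] - half, belief.grid[prev] + half))
                start = c
            prev = c
        out.append((belief.grid[start] - half, belief.grid[prev] + half))
        return out


def make_grid(
    params: ModelParameters,
    m_sd: float = 8.0,
    n_points: int = 1001,
    bounds: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Uniform state grid covering the stationary mean +- ``m_sd`` stationary SDs.

    For a non-stationary state explicit ``bounds`` must be supplied.  The
    default +-8 SD range keeps off-grid stationary mass below 1e-14.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if bounds is None:
        if abs(params.a1) >= 1:
            raise ValueError(
                "non-stationary state: supply explicit grid bounds"
            )
        mean, sd = steady_state_moments(params)
        bounds = (mean - m_sd * sd, mean + m_sd * sd)
    lo, hi = bounds
    if not hi > lo:
        raise ValueError(f"invalid grid bounds ({lo}, {hi})")
    return np.linspace(lo, hi, n_points)


def gaussian_grid_posterior(
    grid: np.ndarray, mean: float, sd: float, trial_index: int = 0
) -> GridPosterior:
    """Discretized Gaussian belief (the default initial prior)."""
    z = (np.asarray(grid, dtype=float) - mean) / sd
    mass = np.exp(-0.5 * z * z)
    mass /= mass.sum()
    return GridPosterior(grid=grid, mass=mass, trial_index=trial_index)


def transition_matrix(grid: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Dense one-step transition kernel K[i, j] = f(grid_i | grid_j) * dx.

    Column j holds the (discretized) predictive mass of x_k given
    x_{k-1} = grid_j, so prediction is the matrix-vector product ``K @ mass``.
    """
    grid = np.asarray(grid, dtype=float)
    dx = grid[1] - grid[0]
    return state_transition_density(grid[None, :], grid[:, None], params) * dx


def predict(
    belief: GridPosterior,
    params: ModelParameters,
    kernel: Optional[np.ndarray] = None,
    leak_tolerance: float = LEAK_TOLERANCE,
) -> GridPosterior:
    """Chapman-Kolmogorov one-step prediction on the grid, renormalized.

    Truncation to the grid is monitored: if more than ``leak_tolerance`` of
    the predicted mass falls off-grid a warning is logged.
    """
    if kernel is None:
        kernel = transition_matrix(belief.grid, params)
    raw = kernel @ belief.mass
    total = raw.sum()
    if total <= 0:
        raise RuntimeError(
            f"prediction after trial {belief.trial_index} lost all mass"
        )
    if 1.0 - total > leak_tolerance:
        logger.warning(
            "prediction after trial %d leaks %.3g mass off-grid",
            belief.trial_index,
            1.0 - total,
        )
    return GridPosterior(
        grid=belief.grid, mass=raw / total, trial_index=belief.trial_index + 1
    )


def update(
    pred: GridPosterior,
    obs: TrialObservation,
    params: ModelParameters,
    scheme: Scheme = "full",
    include_decision: bool = True,
) -> GridPosterior:
    """Bayes update: posterior mass proportional to likelihood x prediction mass.

    With ``scheme="deletion"`` a censored trial returns the prediction
    unchanged (its likelihood is identically one).
    """
    if scheme == "deletion" and not obs.observed:
        return replace(pred, trial_index=obs.index)
    ll = trial_log_likelihood(
        obs, pred.grid, params, scheme=scheme, include_decision=include_decision
    )
    ll = ll - ll.max()
    raw = pred.mass * np.exp(ll)
    total = raw.sum()
    if total <= 0 or not np.isfinite(total):
        raise RuntimeError(f"update underflow at trial {obs.index}")
    return GridPosterior(grid=pred.grid, mass=raw / total, trial_index=obs.index)


def run_filter(
    trials: Sequence[TrialObservation],
    params: ModelParameters,
    prior: Optional[GridPosterior] = None,
    scheme: Scheme = "full",
    include_decision: bool = True,
    grid: Optional[np.ndarray] = None,
    kernel: Optional[np.ndarray] = None,
) -> tuple[list[GridPosterior], list[GridPosterior]]:
    """Run the predict/update recursion over an ordered trial sequence.

    Returns ``(predictions, posteriors)``, one belief of each kind per trial.
    The default prior is the discretized stationary distribution of the state
    on the default grid.
    """
    if prior is None:
        if grid is None:
            grid = make_grid(params)
        mean, sd = steady_state_moments(params)
        prior = gaussian_grid_posterior(grid, mean, sd, trial_index=0)
    if kernel is None:
        kernel = transition_matrix(prior.grid, params)
    predictions: list[GridPosterior] = []
    posteriors: list[GridPosterior] = []
    belief = prior
    for obs in trials:
        pred = predict(belief, params, kernel=kernel)
        pred = replace(pred, trial_index=obs.index)
        belief = update(
            pred, obs, params, scheme=scheme, include_decision=include_decision
        )
        predictions.append(pred)
        posteriors.append(belief)
    return predictions, posteriors


def posterior_moments(belief: GridPosterior) -> tuple[float, float]:
    """Grid-weighted mean and variance of a normalized belief."""
    w = belief.mass / belief.mass.sum()
    mean = float(w @ belief.grid)
    var = float(w @ (belief.grid - mean) ** 2)
    return mean, var


def posterior_skewness(belief: GridPosterior) -> float:
    """Third standardized moment of the belief (positive under right skew)."""
    mean, var = posterior_moments(belief)
    w = belief.mass / belief.mass.sum()
    return float(w @ (belief.grid - mean) ** 3) / var**1.5


def hpd_region(belief: GridPosterior, level: float = 0.95) -> HPDRegion:
    """Numeric HPD region: highest-density cells until mass >= ``level``.

    Cells are added in decreasing density order; all cells tied at the cutoff
    density are included, so the attained mass is deterministically >= level.
    The region may be a union of disjoint intervals for multimodal beliefs.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    w = belief.mass / belief.mass.sum()
    order = np.argsort(w)[::-1]
    csum = np.cumsum(w[order])
    k = int(np.searchsorted(csum, level)) + 1
    cutoff = w[order[k - 1]]
    cells = np.flatnonzero(w >= cutoff)
    return HPDRegion(
        level=level, cells=cells, attained_mass=float(w[cells].sum())
    )
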