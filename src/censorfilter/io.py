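"""Trial-table CSV formats, run configuration, and artifact manifests.

The trial table encodes censoring with an explicit ``status`` column —
``observed`` or ``censored`` — and empty cells for the missing fields of
censored rows; sentinel numeric values are never used, so the NMAR structure
of the data survives a round trip through disk unambiguously.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .exact_filter import GridPosterior, hpd_region, posterior_moments
from .gaussian_filter import GaussianBelief
from .model import ModelParameters, TrialObservation

__all__ = [
    "read_trials",
    "write_trials",
    "write_truth",
    "read_truth",
    "beliefs_to_frame",
    "RunConfig",
    "write_manifest",
]

TRIAL_COLUMNS = ["trial", "threshold_s", "status", "rt_s", "decision"]


def write_trials(trials: Sequence[TrialObservation], path: Union[str, Path]) -> None:
    rows = [
        {
            "trial": t.index,
            "threshold_s": t.threshold,
            "status": t.status,
            "rt_s": t.rt if t.rt is not None else "",
            "decision": t.decision if t.decision is not None else "",
        }
        for t in trials
    ]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials(path: Union[str, Path]) -> tuple[TrialObservation, ...]:
    """Read and validate a trial table; malformed rows are reported by line.

    An observed row must carry a reaction time and a censored row must not;
    violations raise with the offending line number (header = line 1).
    """
    df = pd.read_csv(path, dtype={"status": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    trials = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2
        status = row.status
        rt = None if pd.isna(row.rt_s) else float(row.rt_s)
        decision = None if pd.isna(row.decision) else int(row.decision)
        if status == "observed" and rt is None:
            raise ValueError(f"{path}:{line}: observed row with empty rt_s")
        if status == "censored" and rt is not None:
            raise ValueError(f"{path}:{line}: censored row with non-empty rt_s")
        try:
            trials.append(
                TrialObservation(
                    index=int(row.trial),
                    threshold=float(row.threshold_s),
                    status=status,
                    rt=rt,
                    decision=decision,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{line}: {exc}") from exc
    return tuple(trials)


def write_truth(states: Sequence[float], path: Union[str, Path]) -> None:
    """Sidecar file with the simulated true state per trial."""
    pd.DataFrame(
        {"trial": np.arange(1, len(states) + 1), "true_state": np.asarray(states)}
    ).to_csv(path, index=False)


def read_truth(path: Union[str, Path]) -> np.ndarray:
    return pd.read_csv(path)["true_state"].to_numpy()


def beliefs_to_frame(
    predictions: Sequence[Union[GridPosterior, GaussianBelief]],
    posteriors: Sequence[Union[GridPosterior, GaussianBelief]],
    level: float = 0.95,
    truth: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-trial belief table: prediction/posterior moments and HPD bounds.

    For grid beliefs the bounds are the hull of the numeric HPD region (which
    may span disjoint intervals); for Gaussian beliefs they are mean +- z*sd.
    With ``truth`` supplied a coverage flag per trial is included.
    """
    from scipy import stats

    rows = []
    for k, (pred, post) in enumerate(zip(predictions, posteriors)):
        if isinstance(post, GridPosterior):
            pm, pv = posterior_moments(pred)
            m, v = posterior_moments(post)
            region = hpd_region(post, level)
            intervals = region.intervals(post)
            lo, hi = intervals[0][0], intervals[-1][1]
            covered = (
                region.contains(post, float(truth[k])) if truth is not None else None
            )
        else:
            pm, pv = pred.mean, pred.variance
            m, v = post.mean, post.variance
            z = stats.norm.ppf(0.5 + level / 2.0)
            lo, hi = m - z * post.sd, m + z * post.sd
            covered = (lo <= float(truth[k]) <= hi) if truth is not None else None
        row = {
            "trial": post.trial_index if post.trial_index else k + 1,
            "pred_mean": pm,
            "pred_var": pv,
            "post_mean": m,
            "post_var": v,
            "hpd_low": lo,
            "hpd_high": hi,
        }
        if truth is not None:
            row["true_state"] = float(truth[k])
            row["covered"] = bool(covered)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Experiment settings; defaults reproduce the reference study conditions."""

    params: ModelParameters = field(default_factory=ModelParameters)
    # filter block
    grid_points: int = 1001
    grid_m_sd: float = 8.0
    prior: str = "stationary"  # or "mean,sd"
    # imputation block
    m: int = 10
    max_rejections: int = 1000
    # sweep block
    thresholds: tuple[float, ...] = (0.2, 0.3, 0.45, 0.65, 0.9, 1.3, 2.0)
    n_realizations: int = 500
    n_trials: int = 100
    base_seed: int = 0
    mode: str = "mixed"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = ModelParameters(**d["params"])
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        """Load YAML (JSON is a subset of YAML, so either format parses)."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def write_manifest(
    path: Union[str, Path], config: RunConfig, seed: Optional[int], command: str
) -> None:
    """Record provenance of an artifact: config hash, seed, library versions."""
    import scipy

    manifest = {
        "command": command,
        "config_hash": config.digest(),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
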