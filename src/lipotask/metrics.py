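"""Regression metrics with percentile-bootstrap CIs, and matched-pair shifts.

R², RMSE, MAE and Spearman ρ are reported with 95% percentile-bootstrap
confidence intervals over paired resamples (obs/pred resampled together).
``pair_shift`` computes the signed property difference between two named
compounds — used to check whether a model reproduces the experimental
logP shift of a chemical transformation (e.g. phenyl → N-dimethyl) even
when its absolute predictions are off.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def _check(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty input")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ValueError("missing values are not allowed in metric inputs")
    return obs, pred


def rmse(obs, pred) -> float:
    obs, pred = _check(obs, pred)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mae(obs, pred) -> float:
    obs, pred = _check(obs, pred)
    return float(np.mean(np.abs(obs - pred)))


def r_squared(obs, pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative."""
    obs, pred = _check(obs, pred)
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in observations")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def spearman_rho(obs, pred) -> float:
    """Pearson correlation of mid-ranks (average ranks on ties)."""
    obs, pred = _check(obs, pred)
    if obs.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(obs == obs[0]) or np.all(pred == pred[0]):
        raise ValueError("spearman undefined for a constant vector")
    ra = stats.rankdata(obs)
    rb = stats.rankdata(pred)
    return float(np.corrcoef(ra, rb)[0, 1])


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    obs,
    pred,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile CI over seeded paired resamples with replacement.

    Resamples on which the metric is undefined (e.g. zero variance) are
    redrawn (count logged); if more than half of attempts fail, an error
    is raised.
    """
    obs, pred = _check(obs, pred)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    n = obs.size
    n_redrawn = attempts = 0
    for b in range(n_boot):
        while True:
            attempts += 1
            if attempts > 2 * n_boot and n_redrawn > attempts // 2:
                raise ValueError("metric undefined on more than half of the resamples")
            idx = rng.integers(0, n, size=n)
            try:
                vals[b] = metric(obs[idx], pred[idx])
                break
            except (ValueError, ZeroDivisionError):
                n_redrawn += 1
    if n_redrawn:
        logger.info("bootstrap: redrew %d degenerate resamples", n_redrawn)
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(vals, alpha)),
        float(np.quantile(vals, 1.0 - alpha)),
    )


@dataclass
class MetricReport:
    """Point estimates with bootstrap 95% CI bounds for one obs/pred set."""

    r2: float
    r2_ci: tuple[float, float]
    rmse: float
    rmse_ci: tuple[float, float]
    mae: float
    mae_ci: tuple[float, float]
    spearman: float
    spearman_ci: tuple[float, float]
    n: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "r2_ci": list(self.r2_ci),
            "rmse": self.rmse, "rmse_ci": list(self.rmse_ci),
            "mae": self.mae, "mae_ci": list(self.mae_ci),
            "spearman": self.spearman, "spearman_ci": list(self.spearman_ci),
            "n": self.n, "n_boot": self.n_boot, "seed": self.seed,
        }

    def format_table(self, label: str = "model") -> str:
        """One-line challenge-style table row: estimate [lower,upper]."""
        def cell(v, ci):
            return f"{v:.2f} [{ci[0]:.2f},{ci[1]:.2f}]"

        header = f"{'Model':<12}{'R^2':<20}{'RMSE':<20}{'MAE':<20}{'Spearman rho':<20}"
        row = (
            f"{label:<12}{cell(self.r2, self.r2_ci):<20}"
            f"{cell(self.rmse, self.rmse_ci):<20}{cell(self.mae, self.mae_ci):<20}"
            f"{cell(self.spearman, self.spearman_ci):<20}"
        )
        return header + "\n" + row


def evaluate(obs, pred, n_boot: int = 1000, seed: int = 0) -> MetricReport:
    """All four metrics with bootstrap 95% CIs on one obs/pred pairing."""
    obs, pred = _check(obs, pred)
    return MetricReport(
        r2=r_squared(obs, pred),
        r2_ci=bootstrap_ci(r_squared, obs, pred, n_boot=n_boot, seed=seed),
        rmse=rmse(obs, pred),
        rmse_ci=bootstrap_ci(rmse, obs, pred, n_boot=n_boot, seed=seed + 1),
        mae=mae(obs, pred),
        mae_ci=bootstrap_ci(mae, obs, pred, n_boot=n_boot, seed=seed + 2),
        spearman=spearman_rho(obs, pred),
        spearman_ci=bootstrap_ci(spearman_rho, obs, pred, n_boot=n_boot, seed=seed + 3),
        n=int(obs.size),
        n_boot=n_boot,
        seed=seed,
    )


def pair_shift(values: Mapping[str, float], id_a: str, id_b: str) -> float:
    """Signed difference value(a) - value(b) between two named compounds."""
    for key in (id_a, id_b):
        if key not in values:
            raise KeyError(f"compound {key!r} not present")
    return float(values[id_a] - values[id_b])


# Blind-challenge compound table used in the worked matched-pair examples:
# experimental logP and final-ensemble predictions for the three best and
# three worst predicted compounds (values as printed, with SEMs dropped).
SAMPL7_TABLE3_EXPERIMENTAL: dict[str, float] = {
    "SM43": 0.85, "SM42": 1.76, "SM36": 0.76,
    "SM37": 1.45, "SM26": 1.04, "SM28": 1.18,
}
SAMPL7_TABLE3_PREDICTED: dict[str, float] = {
    "SM43": 2.51, "SM42": 3.16, "SM36": 2.05,
    "SM37": 1.36, "SM26": 1.11, "SM28": 1.03,
}


def shift_analysis(
    experimental: Mapping[str, float],
    predicted: Mapping[str, float],
    pairs: Sequence[tuple[str, str]],
) -> list[dict]:
    """Experimental vs predicted shifts for matched compound pairs."""
    rows = []
    for a, b in pairs:
        rows.append(
            {
                "pair": f"{a}-{b}",
                "experimental_shift": pair_shift(experimental, a, b),
                "predicted_shift": pair_shift(predicted, a, b),
            }
        )
    return rows
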