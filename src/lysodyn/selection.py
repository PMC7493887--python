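"""Model-data agreement statistics for growth-curve model comparison.

Residuals are taken on log10-transformed densities because the data span
decades and both growth and death are multiplicative.  Two statistics are
computed on the pooled residuals of each candidate model:

* ``AIC = 2*M + N*log(RSS/N)`` with M free parameters, residual sum of
  squares RSS and sample size N (natural log by statistical convention;
  the base is configurable and does not affect preference ordering at
  fixed N);
* ``MAE = sum(|residual|)/N``, a robustness check that penalizes residual
  amplitude rather than its square, useful because the residuals are
  typically not normally distributed.

The comparison convention is ``delta = statistic(model_a) -
statistic(model_b)``; passing the temperate model as ``a`` and the virulent
model as ``b`` makes negative deltas mean "temperate fits better despite
the extra-parameter penalty".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import PER_ML, Trajectory

__all__ = [
    "ResidualSet",
    "FitComparison",
    "interp_log_density",
    "log_residuals",
    "pool_residuals",
    "aic",
    "mae",
    "compare_models",
    "parameter_count",
]


@dataclass
class ResidualSet:
    """Pooled log10(model) - log10(observation) residuals."""

    residuals: np.ndarray
    floor_applied: int = 0

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.size and not np.isfinite(self.residuals).all():
            raise ValueError("residuals must be finite")

    @property
    def N(self) -> int:
        return len(self.residuals)

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals ** 2))


@dataclass
class FitComparison:
    """AIC/MAE for two models on one pooled data set, with delta statistics."""

    M_a: int
    M_b: int
    N: int
    RSS_a: float
    RSS_b: float
    AIC_a: float
    AIC_b: float
    MAE_a: float
    MAE_b: float

    @property
    def delta_AIC(self) -> float:
        return self.AIC_a - self.AIC_b

    @property
    def delta_MAE(self) -> float:
        return self.MAE_a - self.MAE_b

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("M_a", "M_b", "N", "RSS_a", "RSS_b",
              "AIC_a", "AIC_b", "MAE_a", "MAE_b")}
        d["delta_AIC"] = self.delta_AIC
        d["delta_MAE"] = self.delta_MAE
        return d


def interp_log_density(traj_times: np.ndarray, traj_values: np.ndarray,
                       obs_times: np.ndarray, floor: float) -> np.ndarray:
    """Interpolate a model curve onto observation times, linear in log10.

    Densities span decades, so interpolation in (t, log10 value) space;
    values are floored before the transform.
    """
    logv = np.log10(np.maximum(traj_values, floor))
    return 10.0 ** np.interp(obs_times, traj_times, logv)


def log_residuals(model: Trajectory, obs, floor: float,
                  variable: str = "host_density") -> ResidualSet:
    """Residuals of a model trajectory against one observation series.

    ``obs`` is an ObservationSeries with per-mL values; model concentrations
    are converted to per-mL before comparison.  Censored or invalid
    observation points are excluded; both model and data are clamped at the
    detection ``floor`` (per mL) before the log10 transform, and the number
    of clamped comparisons is reported.
    """
    keep = (~np.asarray(obs.censored)) & np.asarray(obs.valid)
    t = np.asarray(obs.times)[keep]
    values = np.asarray(obs.values)[keep]
    if t.size == 0:
        raise ValueError("no comparable time points (all censored/invalid)")
    if t.min() < model.times[0] - 1e-9 or t.max() > model.times[-1] + 1e-9:
        raise ValueError("observation times fall outside the model time range")
    if variable == "host_density":
        curve = model.total_host / PER_ML
    elif variable == "virus_density":
        curve = model.V / PER_ML
    else:
        raise ValueError(f"unsupported variable {variable!r}")
    model_at_obs = interp_log_density(model.times, curve, t, floor)
    floored = int(np.sum(values < floor) + np.sum(model_at_obs <= floor))
    res = np.log10(np.maximum(model_at_obs, floor)) - np.log10(np.maximum(values, floor))
    return ResidualSet(residuals=res, floor_applied=floored)


def pool_residuals(sets: Sequence[ResidualSet]) -> ResidualSet:
    """Concatenate residual sets (pooling replicates within one cell)."""
    if not sets:
        raise ValueError("nothing to pool")
    return ResidualSet(
        residuals=np.concatenate([s.residuals for s in sets]),
        floor_applied=sum(s.floor_applied for s in sets))


def aic(res: ResidualSet, M: int, log_base: float = math.e) -> float:
    """Akaike information criterion, 2*M + N*log(RSS/N)."""
    if res.N < 1:
        raise ValueError("AIC requires at least one residual")
    rss = res.rss
    if rss == 0:
        raise ValueError("RSS is zero (perfect fit); AIC undefined")
    return 2.0 * M + res.N * math.log(rss / res.N) / math.log(log_base)


def mae(res: ResidualSet) -> float:
    """Mean absolute (log10) error, sum(|residual|)/N."""
    if res.N < 1:
        raise ValueError("MAE requires at least one residual")
    return float(np.mean(np.abs(res.residuals)))


def parameter_count(mode: str, n_density_bins: int = 1) -> int:
    """Free dynamical parameter count M for the AIC penalty.

    The shared dynamical core has 9 free parameters (mu_max, mu_min, t_mu,
    K, k, B, k_L, d_V, d_H).  The phenomenological temperate model adds one
    induction time t_s per initial-density bin; the self-regulated model
    adds the single stress_fraction threshold.
    """
    base = 9
    if mode == "virulent":
        return base
    if mode == "temperate_phenomenological":
        return base + n_density_bins
    if mode == "temperate_self_regulated":
        return base + 1
    raise ValueError(f"unknown mode {mode!r}")


def compare_models(obs_pool, model_a: Sequence[Trajectory],
                   model_b: Sequence[Trajectory], M_a: int, M_b: int,
                   floor: float = 10.0, variable: str = "host_density",
                   log_base: float = math.e) -> FitComparison:
    """AIC/MAE comparison of two models on a pooled observation set.

    ``obs_pool`` is a sequence of observation series (replicates and
    experiments pooled within one treatment x initial-density cell and one
    medium); ``model_a``/``model_b`` supply the matching trajectory for each
    series.  Pass the temperate model as ``a`` and virulent as ``b`` for the
    convention that negative deltas favor temperateness.
    """
    if not (len(obs_pool) == len(model_a) == len(model_b)):
        raise ValueError("obs_pool, model_a and model_b must align one-to-one")
    res_a = pool_residuals([log_residuals(m, o, floor, variable)
                            for m, o in zip(model_a, obs_pool)])
    res_b = pool_residuals([log_residuals(m, o, floor, variable)
                            for m, o in zip(model_b, obs_pool)])
    return FitComparison(
        M_a=M_a, M_b=M_b, N=res_a.N,
        RSS_a=res_a.rss, RSS_b=res_b.rss,
        AIC_a=aic(res_a, M_a, log_base), AIC_b=aic(res_b, M_b, log_base),
        MAE_a=mae(res_a), MAE_b=mae(res_b))
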