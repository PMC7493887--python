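"""Host-virus population dynamics for virulent and temperate infection.

The model tracks uninfected hosts ``H``, free infective viruses ``V`` and
infected hosts ``I`` (all individuals per liter) in a batch culture.  Free
viruses adsorb to hosts at rate ``k``; infected hosts either lyse
immediately (virulent mode) releasing ``B`` virions at lytic rate ``k_L``,
or persist and keep replicating with their hosts (temperate mode) until an
induction switch ``r_s`` flips from 0 to 1:

    dH/dt = mu*H - d_H*H - k*H*V + mu_I*I
    dV/dt = r_s*B*k_L*I - k*(H + superinfection*I)*V - d_V*V
    dI/dt = k*H*V - r_s*k_L*I - d_H*I

Host growth follows a time-varying logistic rate,
``mu = mu_eff(t) * (1 - (H + (1-r_s)*I)/K)``, where the effective rate
``mu_eff`` stays at a maximum for two days and then declines linearly to a
minimum at ``t_mu``, emulating batch-culture aging.  Infected hosts grow at
``mu_I = (1 - r_s) * mu``: like healthy hosts while the resident virus is
dormant, not at all once it replicates.

Induction can be imposed at a fixed time ``t_s`` (phenomenological temperate
mode), triggered by physiological stress when the realized per-capita growth
rate falls below a fraction of its maximum (self-regulated mode), or on from
the outset (virulent mode, the ``t_s = 0`` limit of the temperate model).
The switch latches: once lytic, the virus never reverts within a run.

Concentrations are individuals per liter internally; I/O layers convert
to/from the laboratory convention of per-milliliter values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PER_ML",
    "VIRULENT",
    "TEMPERATE_PHENOMENOLOGICAL",
    "TEMPERATE_SELF_REGULATED",
    "GrowthSchedule",
    "InductionRule",
    "ModelParameters",
    "SimulationState",
    "Trajectory",
    "effective_growth_rate",
    "realized_growth_rates",
    "induction_state",
    "derivatives",
    "simulate",
    "simulate_delayed_virulent",
    "preinfection_fraction",
    "default_adsorption_rate",
]

#: multiply a per-mL concentration by this to get the internal per-L value
PER_ML = 1.0e3

VIRULENT = "virulent"
TEMPERATE_PHENOMENOLOGICAL = "temperate_phenomenological"
TEMPERATE_SELF_REGULATED = "temperate_self_regulated"

_MODES = (VIRULENT, TEMPERATE_PHENOMENOLOGICAL, TEMPERATE_SELF_REGULATED)

#: plateau length of the effective growth rate (days)
GROWTH_PLATEAU_DAYS = 2.0

# integration tolerances: relative 1e-8, absolute 1e-3 individuals per liter
RTOL = 1.0e-8
ATOL = 1.0e-3


class ConfigurationError(ValueError):
    """Invalid model configuration (inconsistent schedule, missing t_s, ...)."""


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the solver diagnostics."""

    def __init__(self, message: str, last_time: float | None = None,
                 last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


def default_adsorption_rate(
    virus_per_ml: float = 1.0e7, exposure_hours: float = 2.0,
    target_fraction: float = 0.99,
) -> float:
    """Adsorption rate k (L ind^-1 d^-1) calibrated to a coincubation anchor.

    Solves ``1 - exp(-k * V * t) = target_fraction`` for the standard
    pre-infection protocol (~1e7 viruses/mL coincubated for 2 h yielding
    ~99% infection).  Default comes out to ~5.5e-9 L ind^-1 d^-1,
    equivalently ~2.3e-7 mL h^-1.
    """
    v_per_l = virus_per_ml * PER_ML
    t_days = exposure_hours / 24.0
    return -math.log(1.0 - target_fraction) / (v_per_l * t_days)


@dataclass(frozen=True)
class GrowthSchedule:
    """Time-varying logistic growth: plateau, linear decline, floor.

    ``mu_eff(t)`` equals ``mu_max`` for ``t < 2`` d, declines linearly to
    ``mu_min`` at ``t_mu``, and stays there.  The linear slope/intercept
    (``s_mu``, ``n_mu``) are derived from the continuity conditions at the
    two breakpoints, so continuity holds by construction.
    """

    mu_max: float = 1.0  # d^-1
    mu_min: float = 0.1  # d^-1
    t_mu: float = 12.0   # d
    K: float = 6.6e9     # individuals per liter (6.6e6 cells/mL)

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ConfigurationError(f"carrying capacity K must be > 0, got {self.K}")
        if self.mu_min > self.mu_max:
            raise ConfigurationError(
                f"mu_min ({self.mu_min}) must not exceed mu_max ({self.mu_max})")
        if self.t_mu <= GROWTH_PLATEAU_DAYS:
            raise ConfigurationError(
                f"t_mu must exceed the {GROWTH_PLATEAU_DAYS} d plateau, got {self.t_mu}")

    @property
    def s_mu(self) -> float:
        """Slope of the linear segment (d^-2)."""
        return (self.mu_min - self.mu_max) / (self.t_mu - GROWTH_PLATEAU_DAYS)

    @property
    def n_mu(self) -> float:
        """Intercept of the linear segment (d^-1)."""
        return self.mu_max - self.s_mu * GROWTH_PLATEAU_DAYS


@dataclass
class InductionRule:
    """Lysis switch: how and when ``r_s`` flips from temperate (0) to lytic (1).

    ``t_s`` (phenomenological mode) imposes induction at a fixed time,
    typically matched to the onset of photochemical stress in the paired
    F_v/F_m curve.  ``stress_fraction`` (self-regulated mode) latches
    induction the first time the realized per-capita growth rate drops below
    ``stress_fraction * mu_max``.  ``r_s_state`` holds the latched value.
    """

    mode: str = TEMPERATE_SELF_REGULATED
    t_s: float | None = None
    stress_fraction: float = 0.5
    r_s_state: int = field(default=0)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigurationError(f"unknown induction mode {self.mode!r}")
        if self.mode == TEMPERATE_PHENOMENOLOGICAL and self.t_s is None:
            raise ConfigurationError("phenomenological temperate mode requires t_s")
        if self.mode == TEMPERATE_SELF_REGULATED and not 0 < self.stress_fraction < 1:
            raise ConfigurationError(
                f"stress_fraction must be in (0, 1), got {self.stress_fraction}")
        if self.mode == VIRULENT:
            self.r_s_state = 1
        if self.r_s_state not in (0, 1):
            raise ConfigurationError(f"r_s_state must be 0 or 1, got {self.r_s_state}")


@dataclass
class ModelParameters:
    """All dynamical rates and constants of the host-virus model.

    Units: rates per day, ``k`` in liters per individual per day,
    concentrations per liter.  ``superinfection`` controls whether free
    viruses are also lost to adsorption on already-infected hosts; the
    exclusive-infection variant (off) loses them only to uninfected hosts.
    ``extinction_floor`` is the concentration below which the host
    population is reported extinct (default 1 cell/mL = 1000 per liter).
    """

    growth: GrowthSchedule = field(default_factory=GrowthSchedule)
    induction: InductionRule = field(default_factory=InductionRule)
    k: float = field(default_factory=default_adsorption_rate)  # L ind^-1 d^-1
    B: float = 500.0      # virions per lysed host
    k_L: float = 1.0 / 1.5  # d^-1 (latent period L = 1.5 d)
    d_V: float = 1.0      # d^-1 extracellular viral decay
    d_H: float = 0.05     # d^-1 host natural mortality
    superinfection: bool = True
    extinction_floor: float = 1.0 * PER_ML  # per liter

    def __post_init__(self) -> None:
        for name in ("k", "B", "k_L", "d_V", "d_H", "extinction_floor"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.B < 1:
            raise ConfigurationError(f"burst size B must be >= 1, got {self.B}")
        if self.k_L <= 0:
            raise ConfigurationError("lytic rate k_L must be > 0")

    @property
    def latent_period(self) -> float:
        """Mean latent period L = 1/k_L (days)."""
        return 1.0 / self.k_L

    def with_mode(self, mode: str, t_s: float | None = None,
                  stress_fraction: float | None = None) -> "ModelParameters":
        """Copy with a different induction rule (other parameters shared)."""
        rule = InductionRule(
            mode=mode, t_s=t_s,
            stress_fraction=(stress_fraction if stress_fraction is not None
                             else self.induction.stress_fraction))
        return replace(self, induction=rule)


@dataclass(frozen=True)
class SimulationState:
    """Instantaneous model state (all concentrations per liter)."""

    H: float
    V: float
    I: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if min(self.H, self.V, self.I) < 0:
            raise ValueError("state concentrations must be non-negative")

    @classmethod
    def from_per_ml(cls, H_per_ml: float, V_per_ml: float = 0.0,
                    I_per_ml: float = 0.0, t: float = 0.0) -> "SimulationState":
        return cls(H=H_per_ml * PER_ML, V=V_per_ml * PER_ML,
                   I=I_per_ml * PER_ML, t=t)


@dataclass
class Trajectory:
    """Deterministic model solution on a time grid (concentrations per liter)."""

    times: np.ndarray
    H: np.ndarray
    V: np.ndarray
    I: np.ndarray
    r_s: np.ndarray
    induction_time: float | None = None
    extinct: bool = False
    extinction_time: float | None = None
    #: exact (H, V, I) at the induction switch, straight from the integrator
    state_at_induction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.H) == len(self.V)
                == len(self.I) == len(self.r_s)):
            raise ValueError("trajectory arrays must share one length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def total_host(self) -> np.ndarray:
        return self.H + self.I

    @property
    def host_at_induction(self) -> float | None:
        """Total host concentration (per L) at the moment of induction."""
        if self.state_at_induction is None:
            return None
        return float(self.state_at_induction[0] + self.state_at_induction[2])

    def to_frame(self):
        """Tidy per-mL export (time_d, H_per_mL, V_per_mL, I_per_mL, r_s, extinct_flag)."""
        import pandas as pd

        extinct_flag = np.zeros(len(self.times), dtype=bool)
        if self.extinct and self.extinction_time is not None:
            extinct_flag = self.times >= self.extinction_time
        return pd.DataFrame({
            "time_d": self.times,
            "H_per_mL": self.H / PER_ML,
            "V_per_mL": self.V / PER_ML,
            "I_per_mL": self.I / PER_ML,
            "r_s": self.r_s.astype(int),
            "extinct_flag": extinct_flag,
        })


def effective_growth_rate(t: float, sched: GrowthSchedule) -> float:
    """Piecewise-linear effective growth rate mu_eff(t) (d^-1).

    Plateau at ``mu_max`` until 2 d, linear decline, floor at ``mu_min``
    from ``t_mu`` on.  Breakpoints return the continuous shared value.
    """
    if t <= GROWTH_PLATEAU_DAYS:
        return sched.mu_max
    if t >= sched.t_mu:
        return sched.mu_min
    return sched.s_mu * t + sched.n_mu


def realized_growth_rates(t: float, state: SimulationState,
                          params: ModelParameters,
                          r_s: int | None = None) -> tuple[float, float]:
    """Per-capita growth rates (mu, mu_I) of uninfected and infected hosts.

    ``mu = mu_eff(t) * (1 - (H + (1-r_s)*I)/K)``; dormant infected hosts
    count toward the density feedback and grow at the same rate, induced or
    virulent ones do neither.  May be negative above carrying capacity.
    """
    if r_s is None:
        r_s = induction_state(t, state, params)
    mu_eff = effective_growth_rate(t, params.growth)
    mu = mu_eff * (1.0 - (state.H + (1 - r_s) * state.I) / params.growth.K)
    return mu, (1 - r_s) * mu


def induction_state(t: float, state: SimulationState,
                    params: ModelParameters) -> int:
    """Evaluate (and latch) the induction switch r_s at time t.

    Virulent: always 1.  Phenomenological: 1 iff ``t >= t_s``.
    Self-regulated: latches to 1 the first time the realized per-capita
    growth rate falls below ``stress_fraction * mu_max`` and stays 1
    (the latch is stored on ``params.induction.r_s_state``).
    """
    rule = params.induction
    if rule.mode == VIRULENT:
        return 1
    if rule.mode == TEMPERATE_PHENOMENOLOGICAL:
        return 1 if t >= rule.t_s else 0
    if rule.r_s_state == 1:
        return 1
    mu_eff = effective_growth_rate(t, params.growth)
    mu = mu_eff * (1.0 - (state.H + state.I) / params.growth.K)
    if mu < rule.stress_fraction * params.growth.mu_max:
        rule.r_s_state = 1
        return 1
    return 0


def _rhs(t: float, y: np.ndarray, params: ModelParameters,
         r_s: int) -> np.ndarray:
    """Right-hand side of the H/V/I system for a fixed switch value.

    This is the single reconstruction point for the dynamical equations;
    every simulate variant routes through it (or its Erlang extension).
    """
    H, V, I = np.maximum(y, 0.0)
    g = params.growth
    mu_eff = effective_growth_rate(t, g)
    mu = mu_eff * (1.0 - (H + (1 - r_s) * I) / g.K)
    mu_I = (1 - r_s) * mu
    adsorbing = H + (I if params.superinfection else 0.0)
    infection = params.k * H * V
    dH = mu * H - params.d_H * H - infection + mu_I * I
    dV = r_s * params.B * params.k_L * I - params.k * adsorbing * V - params.d_V * V
    dI = infection - r_s * params.k_L * I - params.d_H * I
    return np.array([dH, dV, dI])


def derivatives(t: float, state: SimulationState,
                params: ModelParameters) -> tuple[float, float, float]:
    """d(H, V, I)/dt at the given state, with r_s from the induction rule."""
    r_s = induction_state(t, state, params)
    d = _rhs(t, np.array([state.H, state.V, state.I]), params, r_s)
    return float(d[0]), float(d[1]), float(d[2])


def _solve_segment(rhs, t_span, y0, t_eval, events=None):
    sol = solve_ivp(rhs, t_span, y0, method="LSODA", rtol=RTOL, atol=ATOL,
                    t_eval=t_eval if len(t_eval) else None,
                    events=events, dense_output=True)
    if not sol.success:
        raise IntegrationError(
            f"integrator failed on [{t_span[0]}, {t_span[1]}]: {sol.message}",
            last_time=sol.t[-1] if len(sol.t) else t_span[0],
            last_state=sol.y[:, -1] if sol.y.size else np.asarray(y0))
    return sol

def _self_regulated_switch_time(params: ModelParameters, y0: np.ndarray,
                                t0: float, t_end: float) -> float | None:
    """First time the per-capita growth rate crosses the stress threshold."""
    rule = params.induction
    threshold = rule.stress_fraction * params.growth.mu_max

    def stress_margin(t, y):
        H, V, I = np.maximum(y, 0.0)
        mu_eff = effective_growth_rate(t, params.growth)
        mu = mu_eff * (1.0 - (H + I) / params.growth.K)
        return mu - threshold

    if stress_margin(t0, y0) <= 0:
        return t0
    stress_margin.terminal = True
    stress_margin.direction = -1
    sol = _solve_segment(lambda t, y: _rhs(t, y, params, 0),
                         (t0, t_end), y0, np.empty(0), events=[stress_margin])
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return None


def _assemble(times: np.ndarray, params: ModelParameters, y0: np.ndarray,
              switch_time: float | None, rhs_factory
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Integrate piecewise around an (optional) switch.

    Returns the state matrix, the reported r_s per time point, and the
    exact state at the switch (None if the switch never happens within the
    grid).
    """
    t0, t_end = times[0], times[-1]
    out = np.empty((len(times), len(y0)))
    if switch_time is None or switch_time >= t_end:
        sol = _solve_segment(rhs_factory(0), (t0, t_end), y0, times)
        out[:] = sol.y.T
        r_s = np.zeros(len(times), dtype=int)
        y_switch = None
        if switch_time is not None:
            r_s[times >= switch_time] = 1
            if switch_time <= t_end:
                y_switch = sol.sol(switch_time)
        return out, r_s, y_switch
    if switch_time <= t0:
        sol = _solve_segment(rhs_factory(1), (t0, t_end), y0, times)
        out[:] = sol.y.T
        return out, np.ones(len(times), dtype=int), y0.copy()
    pre = times <= switch_time
    sol1 = _solve_segment(rhs_factory(0), (t0, switch_time), y0, times[pre])
    y_switch = sol1.sol(switch_time)
    sol2 = _solve_segment(rhs_factory(1), (switch_time, t_end), y_switch,
                          times[~pre])
    out[pre] = sol1.y.T
    out[~pre] = sol2.y.T
    r_s = np.where(times >= switch_time, 1, 0)
    return out, r_s, y_switch


def _extinction(times: np.ndarray, total_host: np.ndarray,
                floor: float) -> tuple[bool, float | None]:
    """Host extinction: first time H+I falls to the floor and stays there."""
    below = total_host <= floor
    if not below[-1]:
        return False, None
    # first index of the trailing run below the floor (no later recovery)
    rev = below[::-1]
    run = len(rev) if rev.all() else int(np.argmin(rev))
    return True, float(times[len(below) - run])


def simulate(params: ModelParameters, init: SimulationState,
             times: Sequence[float]) -> Trajectory:
    """Integrate the model over a time grid, resolving the induction switch.

    The switch time is located exactly (imposed ``t_s`` or a root of the
    stress-threshold crossing for self-regulated induction) and the system
    is integrated piecewise with the switch value constant on each side,
    so the discontinuous forcing never degrades solver accuracy.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing grid")
    y0 = np.array([init.H, init.V, init.I], dtype=float)
    t0, t_end = times[0], times[-1]

    mode = params.induction.mode
    if mode == VIRULENT:
        switch_time: float | None = t0
    elif mode == TEMPERATE_PHENOMENOLOGICAL:
        switch_time = float(params.induction.t_s)
    else:
        switch_time = _self_regulated_switch_time(params, y0, t0, t_end)

    def rhs_factory(r_s):
        return lambda t, y: _rhs(t, y, params, r_s)

    Y, r_s, y_switch = _assemble(times, params, y0, switch_time, rhs_factory)
    Y = np.maximum(Y, 0.0)
    induction_time = None
    if switch_time is not None and switch_time <= t_end:
        induction_time = max(float(switch_time), float(t0))
    extinct, t_ext = _extinction(times, Y[:, 0] + Y[:, 2],
                                 params.extinction_floor)
    if y_switch is not None:
        y_switch = np.maximum(np.asarray(y_switch, dtype=float), 0.0)
    return Trajectory(times=times, H=Y[:, 0], V=Y[:, 1], I=Y[:, 2], r_s=r_s,
                      induction_time=induction_time,
                      extinct=extinct, extinction_time=t_ext,
                      state_at_induction=y_switch)


def simulate_delayed_virulent(params: ModelParameters, init: SimulationState,
                              times: Sequence[float],
                              n_stages: int = 10) -> Trajectory:
    """Virulent dynamics with an explicit latent period before lysis.

    The delay between infection and lysis is realized as an Erlang chain of
    ``n_stages`` infected compartments, each leaving at rate
    ``n_stages * k_L``, so the mean delay equals the latent period
    ``L = 1/k_L`` and the delay distribution sharpens with ``n_stages``.
    ``n_stages = 1`` recovers the classic (exponential-latency) virulent
    model exactly.
    """
    if n_stages < 1:
        raise ConfigurationError(f"n_stages must be >= 1, got {n_stages}")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing grid")
    g = params.growth
    stage_rate = n_stages * params.k_L

    def rhs(t, y):
        y = np.maximum(y, 0.0)
        H, V = y[0], y[1]
        stages = y[2:]
        I_tot = stages.sum()
        mu_eff = effective_growth_rate(t, g)
        mu = mu_eff * (1.0 - H / g.K)  # r_s = 1: infected hosts inert
        adsorbing = H + (I_tot if params.superinfection else 0.0)
        infection = params.k * H * V
        dH = mu * H - params.d_H * H - infection
        dV = (params.B * stage_rate * stages[-1]
              - params.k * adsorbing * V - params.d_V * V)
        dstages = np.empty(n_stages)
        dstages[0] = infection - stage_rate * stages[0] - params.d_H * stages[0]
        for j in range(1, n_stages):
            dstages[j] = (stage_rate * stages[j - 1] - stage_rate * stages[j]
                          - params.d_H * stages[j])
        return np.concatenate(([dH, dV], dstages))

    y0 = np.zeros(2 + n_stages)
    y0[0], y0[1] = init.H, init.V
    y0[2] = init.I  # pre-infected cells start the chain at stage 1
    sol = _solve_segment(rhs, (times[0], times[-1]), y0, times)
    Y = np.maximum(sol.y.T, 0.0)
    H, V = Y[:, 0], Y[:, 1]
    I = Y[:, 2:].sum(axis=1)
    extinct, t_ext = _extinction(times, H + I, params.extinction_floor)
    return Trajectory(times=times, H=H, V=V, I=I,
                      r_s=np.ones(len(times), dtype=int),
                      induction_time=float(times[0]),
                      extinct=extinct, extinction_time=t_ext,
                      state_at_induction=np.array([init.H, init.V, init.I]))


def preinfection_fraction(k: float, V: float, t_exposure: float) -> float:
    """Probability a host adsorbs at least one virus during coincubation.

    ``1 - exp(-k*V*t)``; the product must be dimensionless, so pass ``k``,
    ``V`` and ``t_exposure`` in any one consistent unit system (e.g. k in
    L ind^-1 d^-1, V per liter, t in days).  Saturates at 1.
    """
    if min(k, V, t_exposure) < 0:
        raise ValueError("k, V and t_exposure must be non-negative")
    return 1.0 - math.exp(-k * V * t_exposure)
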