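"""Spatially explicit virus-host encounter rates in the ocean.

The volumetric encounter rate between free virions and host cells is
``E = beta * C_V * C_H``, with an additive encounter kernel

    beta = beta_b + beta_s + beta_t

decomposed into Brownian motion, differential sinking (Stokes terminal
velocity of the host; viral sinking is negligible) and turbulent shear:

    beta_b = (2/3) * (k_B*T/eta) * (r_V + r_H)^2 / (r_V * r_H)
    beta_s = pi * w_H * (r_V + r_H)^2
    beta_t = 1.3 * sqrt(epsilon/nu) * (r_V + r_H)^3

The reciprocal ``1/(beta * C_H)`` is the expected time for one virion to
encounter a host.  Additive kernels slightly overestimate encounter rates
relative to Sherwood-number (advection-diffusion) formulations, so the
resulting encounter times are conservative (short) estimates.

All quantities SI: radii m, kernels m^3/s, concentrations m^-3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EncounterParameters",
    "KernelBreakdown",
    "HOST_SPECS",
    "CALM_EPSILON",
    "TURBULENT_EPSILON",
    "stokes_velocity",
    "encounter_kernels",
    "encounter_time",
    "scenario_table",
]

BOLTZMANN = 1.380649e-23  # J/K
SECONDS_PER_DAY = 86400.0

#: dissipation rates for the two reference regimes (m^2 s^-3)
CALM_EPSILON = 1.0e-8
TURBULENT_EPSILON = 1.0e-4

#: reference host cell specs: (diameter m, cell density kg/m^3)
HOST_SPECS = {
    "naked": (5.0e-6, 1050.0),
    "calcified": (6.0e-6, 1190.0),
}


@dataclass(frozen=True)
class EncounterParameters:
    """Physical constants and particle properties for the kernel calculation.

    Defaults describe an EhV-like virion (capsid radius 90 nm) and
    temperate-culture seawater (18 degC).  The virus radius is much smaller
    than the host radius, so the sinking and turbulence kernels are
    insensitive to its exact value.
    """

    r_V: float = 90.0e-9          # virus radius (m)
    r_H: float = 2.5e-6           # host radius (m)
    rho_cell: float = 1050.0      # host cell density (kg/m^3)
    rho_sw: float = 1025.0        # seawater density (kg/m^3)
    T: float = 291.0              # absolute temperature (K)
    eta: float = 1.07e-3          # dynamic viscosity (Pa s)
    nu: float = 1.05e-6           # kinematic viscosity (m^2/s)
    epsilon: float = CALM_EPSILON  # turbulent dissipation rate (m^2/s^3)
    g: float = 9.81               # gravitational acceleration (m/s^2)
    k_B: float = BOLTZMANN        # J/K
    C_V: float = 0.0              # virus concentration (m^-3)
    C_H: float = 1.0e9            # host concentration (m^-3) = 1e3 per mL

    def __post_init__(self) -> None:
        for name in ("r_V", "r_H", "rho_cell", "rho_sw", "T", "eta", "nu", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    @classmethod
    def for_host(cls, host: str, **overrides) -> "EncounterParameters":
        """Parameters for a reference host type ('naked' or 'calcified')."""
        diameter, density = HOST_SPECS[host]
        return cls(r_H=diameter / 2.0, rho_cell=density, **overrides)


@dataclass(frozen=True)
class KernelBreakdown:
    """Encounter-kernel decomposition (m^3/s) with sinking speed and timing."""

    beta_b: float
    beta_s: float
    beta_t: float
    w_H: float
    encounter_time_s: float | None = None

    @property
    def beta_total(self) -> float:
        return self.beta_b + self.beta_s + self.beta_t

    @property
    def dominant(self) -> str:
        parts = {"beta_b": self.beta_b, "beta_s": self.beta_s,
                 "beta_t": self.beta_t}
        return max(parts, key=parts.get)

    @property
    def encounter_time_d(self) -> float | None:
        if self.encounter_time_s is None:
            return None
        return self.encounter_time_s / SECONDS_PER_DAY


def stokes_velocity(p: EncounterParameters) -> float:
    """Stokes terminal sinking velocity of the host cell (m/s).

    ``w_H = (2/9) * (rho_cell - rho_sw) * g * r_H^2 / eta``.  A buoyant
    cell (negative excess density) returns 0: upward motion is not an
    encounter mechanism in this additive kernel.
    """
    if p.eta <= 0:
        raise ValueError("dynamic viscosity must be > 0")
    excess = p.rho_cell - p.rho_sw
    if excess <= 0:
        return 0.0
    return (2.0 / 9.0) * excess * p.g * p.r_H ** 2 / p.eta


def encounter_kernels(p: EncounterParameters) -> KernelBreakdown:
    """Brownian, sinking and turbulence kernels and their sum (m^3/s)."""
    if p.r_V <= 0 or p.r_H <= 0:
        raise ValueError("particle radii must be > 0")
    r_sum = p.r_V + p.r_H
    beta_b = (2.0 / 3.0) * (p.k_B * p.T / p.eta) * r_sum ** 2 / (p.r_V * p.r_H)
    w_H = stokes_velocity(p)
    beta_s = np.pi * w_H * r_sum ** 2
    beta_t = 1.3 * np.sqrt(p.epsilon / p.nu) * r_sum ** 3
    t_enc = None
    if p.C_H > 0:
        t_enc = encounter_time(beta_b + beta_s + beta_t, p.C_H)
    return KernelBreakdown(beta_b=beta_b, beta_s=beta_s, beta_t=beta_t,
                           w_H=w_H, encounter_time_s=t_enc)


def encounter_time(beta_total: float, C_H: float) -> float:
    """Expected time (seconds) for one virion to encounter a host cell."""
    if beta_total <= 0 or C_H <= 0:
        raise ValueError("infinite encounter time: kernel and host density "
                         "must both be > 0")
    return 1.0 / (beta_total * C_H)


def scenario_table(hosts: Sequence[str] = ("naked", "calcified"),
                   regimes: Sequence[float] = (CALM_EPSILON, TURBULENT_EPSILON),
                   C_H: float = 1.0e9, **overrides) -> pd.DataFrame:
    """Kernel breakdown over the host-type x turbulence-regime grid.

    One row per (host, epsilon) combination, annotated with the dominant
    kernel component and the encounter time at host density ``C_H``
    (default 1e9 m^-3 = 1e3 cells/mL, the upper end of natural densities).
    """
    if not hosts or not len(regimes):
        raise ValueError("hosts and regimes must be non-empty")
    rows = []
    for host in hosts:
        for eps in regimes:
            p = EncounterParameters.for_host(host, epsilon=eps, C_H=C_H,
                                             **overrides)
            kb = encounter_kernels(p)
            rows.append({
                "host": host, "epsilon_m2_s3": eps,
                "w_H_m_s": kb.w_H,
                "beta_b_m3_s": kb.beta_b, "beta_s_m3_s": kb.beta_s,
                "beta_t_m3_s": kb.beta_t, "beta_total_m3_s": kb.beta_total,
                "dominant": kb.dominant,
                "C_H_per_m3": C_H,
                "encounter_time_s": kb.encounter_time_s,
                "encounter_time_d": kb.encounter_time_d,
            })
    return pd.DataFrame(rows)
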