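"""Synthetic infection experiments with the laboratory design's structure.

Generates observation sets shaped like the coincubation/pre-infection
growth-curve experiments: four treatments (uninfected control; 10:1 MOI
coincubation; pre-infected, washed free of extracellular virus;
pre-infected plus 1e6 added viruses/mL), initial host densities in decade
bins from 1e1 to 1e6 cells/mL, roughly daily sampling for one to three
weeks, flow-cytometry counting noise, a 1e3 cells/mL validity floor for
stain-based percentages and F_v/F_m, and a 1e5 viruses/mL qPCR detection
limit.  The latent model trajectories and parameters are returned alongside
the noisy observations so downstream extractors can be validated against
ground truth.

The observation model is instrument emulation, not biology: stain-positive
percentages are saturating functions of the induced-infected fraction with
a sub-1% false-positive baseline, and F_v/F_m holds a healthy plateau of
0.6 and declines linearly to 0.1 over three days after induction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import dynamics
from .dynamics import (
    PER_ML,
    GrowthSchedule,
    InductionRule,
    ModelParameters,
    SimulationState,
    Trajectory,
    preinfection_fraction,
    simulate,
)

__all__ = [
    "TREATMENTS",
    "UNINFECTED",
    "COINCUBATION_MOI10",
    "PREINFECTED",
    "PREINFECTED_PLUS_VIRUS",
    "ObservationSeries",
    "ExperimentDesign",
    "NoiseModel",
    "CultureTruth",
    "SyntheticExperiment",
    "schedule_for_inoculum",
    "uninfected_stress_time",
    "initial_state",
    "generate_experiment",
    "apply_observation_model",
    "qpcr_dilution_series",
]

UNINFECTED = "uninfected"
COINCUBATION_MOI10 = "coincubation_moi10"
PREINFECTED = "preinfected"
PREINFECTED_PLUS_VIRUS = "preinfected_plus_virus"
TREATMENTS = (UNINFECTED, COINCUBATION_MOI10, PREINFECTED,
              PREINFECTED_PLUS_VIRUS)

#: pre-infection protocol: ~1e7 viruses/mL coincubated for 2 h
PREINFECTION_VIRUS_PER_ML = 1.0e7
PREINFECTION_HOURS = 2.0
#: extracellular virus added back to the "plus virus" treatment (per mL)
ADDED_VIRUS_PER_ML = 1.0e6

_MODEL_ALIASES = {
    "virulent": dynamics.VIRULENT,
    "temperate": dynamics.TEMPERATE_PHENOMENOLOGICAL,
    "temperate_phenomenological": dynamics.TEMPERATE_PHENOMENOLOGICAL,
    "self-regulated": dynamics.TEMPERATE_SELF_REGULATED,
    "temperate_self_regulated": dynamics.TEMPERATE_SELF_REGULATED,
}

VARIABLES = ("host_density", "virus_density", "pct_dead", "pct_autophagy",
             "pct_uv", "fvfm")


@dataclass
class ObservationSeries:
    """Noisy, censored measurements of one variable in one culture.

    Densities are per mL; percentages in [0, 100]; F_v/F_m in [0, 0.8].
    ``censored`` marks points reported at a detection floor; ``valid``
    marks points whose host density supported the measurement (stains and
    F_v/F_m need >= 1e3 cells/mL).  ``meta`` carries the design cell
    (experiment, treatment, density_bin, replicate) and generator
    provenance.
    """

    variable: str
    times: np.ndarray
    values: np.ndarray
    censored: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.times)
        if not (len(self.values) == len(self.censored) == len(self.valid) == n):
            raise ValueError("series arrays must share one length")
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")


@dataclass
class ExperimentDesign:
    """Layout of one synthetic experiment.

    ``density_bins`` are initial host densities (cells/mL), by default the
    decade midpoints of the 1e1-1e6 design range.  ``medium`` sets the
    carrying capacity: nutrient-replete f/2 at 6.6e6 cells/mL, or
    unamended seawater at a ``seawater_K_factor``-fold lower capacity with
    per-experiment jitter.
    """

    treatments: tuple[str, ...] = TREATMENTS
    density_bins: tuple[float, ...] = tuple(10.0 ** e for e in
                                            (1.5, 2.5, 3.5, 4.5, 5.5))
    medium: str = "f2"
    K_per_ml: float = 6.6e6
    seawater_K_factor: float = 100.0
    seawater_K_jitter_sd: float = 0.15  # lognormal sigma on ln K
    duration: float = 14.0        # days
    sampling_interval: float = 1.0  # days
    replicates: int = 3
    name: str = "synthetic"

    def __post_init__(self) -> None:
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments: {sorted(unknown)}")
        if not 7.0 <= self.duration <= 21.0:
            raise ValueError("duration must be within the 7-21 day design range")
        for b in self.density_bins:
            if not 10.0 <= b <= 1.0e6:
                raise ValueError("density bins must lie within 1e1-1e6 cells/mL")
        if self.medium not in ("f2", "seawater"):
            raise ValueError(f"unknown medium {self.medium!r}")

    @property
    def sampling_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 1e-9, self.sampling_interval)


@dataclass
class NoiseModel:
    """Instrument emulation: counting noise, floors and validity rules."""

    count_cv: float = 0.15            # multiplicative lognormal CV
    analyzed_volume_ul: float = 100.0  # flow-cytometry analyzed volume
    host_floor: float = 10.0          # cells/mL
    stain_validity_floor: float = 1.0e3  # cells/mL
    qpcr_floor: float = 1.0e5         # viruses/mL
    pct_baseline: float = 0.5         # % false positives in healthy cultures
    pct_cv: float = 0.15
    pct_half_fraction: float = 0.2    # induced fraction at half-saturation
    pct_max: dict = field(default_factory=lambda: {
        "pct_dead": 95.0, "pct_autophagy": 90.0, "pct_uv": 80.0})
    fvfm_plateau: float = 0.6
    fvfm_floor: float = 0.1
    fvfm_decline_days: float = 3.0
    fvfm_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.count_cv < 0 or self.pct_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        for name in ("host_floor", "stain_validity_floor", "qpcr_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.analyzed_volume_ul > 0 or
                math.isinf(self.analyzed_volume_ul)):
            raise ValueError("analyzed volume must be positive (inf disables "
                             "Poisson counting)")


@dataclass
class CultureTruth:
    """Generator-side ground truth for one culture."""

    trajectory: Trajectory
    K_per_ml: float
    induction_time: float | None
    t_mu: float
    lytic_density_per_ml: float | None  # total host density at induction


@dataclass
class SyntheticExperiment:
    """Generated observations plus latent truth, keyed by design cell."""

    design: ExperimentDesign
    model: str
    seed: int | None
    observations: list
    truth: dict  # (treatment, density_bin, replicate) -> CultureTruth

    def series(self, treatment: str, density_bin: float, replicate: int,
               variable: str) -> ObservationSeries:
        for obs in self.observations:
            m = obs.meta
            if (m.get("treatment") == treatment
                    and m.get("density_bin") == density_bin
                    and m.get("replicate") == replicate
                    and obs.variable == variable):
                return obs
        raise KeyError((treatment, density_bin, replicate, variable))


def schedule_for_inoculum(H0_per_l: float, base: GrowthSchedule,
                          approach_fraction: float = 0.95) -> GrowthSchedule:
    """Growth schedule emulating a per-bin fit to uninfected growth data.

    The decline breakpoint ``t_mu`` is set so the cumulative effective
    growth carries the inoculum to ``approach_fraction`` of the carrying
    capacity before batch-culture aging takes over: sparser inocula keep
    growing longer, as their fitted uninfected curves do.  The logistic
    equation with a time-varying rate has the exact solution
    ``H(t) = K / (1 + ((K - H0)/H0) * exp(-G(t)))`` with ``G`` the
    cumulative effective growth, so reaching fraction ``f`` of K requires
    ``G = ln((K - H0)/H0) + ln(f/(1 - f))``.
    """
    if H0_per_l <= 0:
        raise ValueError("inoculum must be > 0")
    if not 0 < approach_fraction < 1:
        raise ValueError("approach_fraction must be in (0, 1)")
    f = approach_fraction
    ratio = max((base.K - H0_per_l) / H0_per_l, 1e-12)
    needed = math.log(ratio) + math.log(f / (1.0 - f))
    plateau_growth = dynamics.GROWTH_PLATEAU_DAYS * base.mu_max
    mean_decline_rate = 0.5 * (base.mu_max + base.mu_min)
    t_mu = (dynamics.GROWTH_PLATEAU_DAYS
            + max(needed - plateau_growth, 0.0) / mean_decline_rate)
    t_mu = max(t_mu, dynamics.GROWTH_PLATEAU_DAYS + 0.1)
    return replace(base, t_mu=t_mu)


def uninfected_stress_time(H0_per_l: float, params: ModelParameters,
                           duration: float,
                           stress_fraction: float | None = None) -> float | None:
    """Time the uninfected control's growth rate crosses the stress threshold.

    Used to place the imposed induction time t_s of the phenomenological
    temperate model at the onset of stress in the matching control, per
    initial-density bin.
    """
    p = params.with_mode(dynamics.TEMPERATE_SELF_REGULATED,
                         stress_fraction=stress_fraction)
    traj = simulate(p, SimulationState(H=H0_per_l, V=0.0, I=0.0),
                    np.array([0.0, duration]))
    return traj.induction_time


def initial_state(treatment: str, H0_per_ml: float,
                  params: ModelParameters) -> SimulationState:
    """Initial (H, V, I) per liter for one treatment at one density bin.

    Coincubation starts with free virus at 10:1 MOI.  Pre-infection moves
    the adsorbed fraction (from the 2 h, 1e7/mL protocol) into I and washes
    all free virus away; the "plus virus" variant adds back 1e6 viruses/mL.
    """
    H0 = H0_per_ml * PER_ML
    if treatment == UNINFECTED:
        return SimulationState(H=H0, V=0.0, I=0.0)
    if treatment == COINCUBATION_MOI10:
        return SimulationState(H=H0, V=10.0 * H0, I=0.0)
    if treatment in (PREINFECTED, PREINFECTED_PLUS_VIRUS):
        frac = preinfection_fraction(params.k,
                                     PREINFECTION_VIRUS_PER_ML * PER_ML,
                                     PREINFECTION_HOURS / 24.0)
        if frac == 0.0:
            raise ValueError("pre-infected treatment requires a non-zero "
                             "adsorption rate k")
        V0 = ADDED_VIRUS_PER_ML * PER_ML if treatment == PREINFECTED_PLUS_VIRUS else 0.0
        return SimulationState(H=(1.0 - frac) * H0, V=V0, I=frac * H0)
    raise ValueError(f"unknown treatment {treatment!r}")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int
                      ) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def _count_densities(latent: np.ndarray, noise: NoiseModel,
                     rng: np.random.Generator) -> np.ndarray:
    """Lognormal pipetting/gating noise, then Poisson counting."""
    values = latent * _lognormal_factor(rng, noise.count_cv, len(latent))
    if math.isinf(noise.analyzed_volume_ul):
        return values
    vol_ml = noise.analyzed_volume_ul / 1000.0
    counts = rng.poisson(np.maximum(values * vol_ml, 0.0))
    return counts / vol_ml


def apply_observation_model(traj: Trajectory, noise: NoiseModel,
                            rng: np.random.Generator | int | None = None,
                            meta: dict | None = None) -> list[ObservationSeries]:
    """Turn a latent trajectory into the six measured series.

    Host and virus densities get multiplicative lognormal noise and Poisson
    counting noise, then floor censoring (censored points carry the floor
    value).  Stain percentages saturate with the induced-infected fraction
    above a sub-1% false-positive baseline; F_v/F_m declines linearly after
    induction.  Stain/F_v/F_m points where the observed host density is
    below 1e3 cells/mL are flagged invalid.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    meta = dict(meta or {})
    t = traj.times
    n = len(t)
    host_latent = traj.total_host / PER_ML
    virus_latent = traj.V / PER_ML

    host_obs = _count_densities(host_latent, noise, rng)
    host_cens = host_obs < noise.host_floor
    host_vals = np.where(host_cens, noise.host_floor, host_obs)

    virus_obs = _count_densities(virus_latent, noise, rng)
    virus_cens = virus_obs < noise.qpcr_floor
    virus_vals = np.where(virus_cens, noise.qpcr_floor, virus_obs)

    stain_valid = host_vals >= noise.stain_validity_floor

    # induced-infected fraction drives the stress/infection markers
    total = np.maximum(traj.total_host, 1e-300)
    induced_frac = np.where(traj.r_s == 1, traj.I / total, 0.0)

    out = [
        ObservationSeries("host_density", t, host_vals, host_cens,
                          np.ones(n, bool), meta),
        ObservationSeries("virus_density", t, virus_vals, virus_cens,
                          np.ones(n, bool), meta),
    ]
    f50 = noise.pct_half_fraction
    for var, pmax in noise.pct_max.items():
        latent = (noise.pct_baseline
                  + (pmax - noise.pct_baseline)
                  * induced_frac ** 2 / (induced_frac ** 2 + f50 ** 2))
        vals = latent * _lognormal_factor(rng, noise.pct_cv, n)
        vals = np.clip(vals, 0.0, 100.0)
        out.append(ObservationSeries(var, t, vals, np.zeros(n, bool),
                                     stain_valid.copy(), meta))

    fv_latent = np.full(n, noise.fvfm_plateau)
    if traj.induction_time is not None:
        decline_rate = ((noise.fvfm_plateau - noise.fvfm_floor)
                        / noise.fvfm_decline_days)
        after = t >= traj.induction_time
        fv_latent[after] = np.maximum(
            noise.fvfm_plateau - decline_rate * (t[after] - traj.induction_time),
            noise.fvfm_floor)
    fv_vals = np.clip(fv_latent + rng.normal(0.0, noise.fvfm_sd, n), 0.0, 0.8)
    out.append(ObservationSeries("fvfm", t, fv_vals, np.zeros(n, bool),
                                 stain_valid.copy(), meta))
    return out


def generate_experiment(design: ExperimentDesign,
                        params: ModelParameters | None = None,
                        noise: NoiseModel | None = None,
                        model: str = "temperate_self_regulated",
                        seed: int | None = 0) -> SyntheticExperiment:
    """Simulate one full experiment and observe it through the instruments.

    For every treatment x density-bin x replicate the initial conditions
    are built per protocol, the chosen model variant is integrated over the
    sampling horizon with a per-bin growth schedule (emulating the per-bin
    uninfected fits), and the observation model is applied.  The latent
    trajectories and the induction/lytic-density truth are retained.

    The same seed reproduces the output bitwise.
    """
    if model not in _MODEL_ALIASES:
        raise ValueError(f"unknown model {model!r}")
    mode = _MODEL_ALIASES[model]
    params = params if params is not None else ModelParameters(
        induction=InductionRule(mode=dynamics.TEMPERATE_SELF_REGULATED))
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    K_per_ml = design.K_per_ml
    if design.medium == "seawater":
        K_per_ml = K_per_ml / design.seawater_K_factor
        K_per_ml *= math.exp(rng.normal(0.0, design.seawater_K_jitter_sd))
    base_growth = replace(params.growth, K=K_per_ml * PER_ML)
    times = design.sampling_times

    observations: list[ObservationSeries] = []
    truth: dict = {}
    for treatment in design.treatments:
        for bin_density in design.density_bins:
            sched = schedule_for_inoculum(bin_density * PER_ML, base_growth)
            p_bin = replace(params, growth=sched)
            if mode == dynamics.TEMPERATE_PHENOMENOLOGICAL:
                t_s = uninfected_stress_time(bin_density * PER_ML, p_bin,
                                             design.duration)
                p_run = p_bin.with_mode(mode, t_s=(t_s if t_s is not None
                                                   else design.duration + 1.0))
            else:
                p_run = p_bin.with_mode(mode)
            init = initial_state(treatment, bin_density, p_run)
            for rep in range(design.replicates):
                # re-resolve the latch per replicate
                p_rep = p_run.with_mode(p_run.induction.mode,
                                        t_s=p_run.induction.t_s)
                traj = simulate(p_rep, init, times)
                meta = {"experiment": design.name, "treatment": treatment,
                        "density_bin": bin_density, "replicate": rep,
                        "medium": design.medium, "model": model, "seed": seed}
                observations.extend(
                    apply_observation_model(traj, noise, rng, meta))
                lytic = None
                if traj.host_at_induction is not None and treatment != UNINFECTED:
                    lytic = traj.host_at_induction / PER_ML
                truth[(treatment, bin_density, rep)] = CultureTruth(
                    trajectory=traj, K_per_ml=K_per_ml,
                    induction_time=traj.induction_time,
                    t_mu=sched.t_mu, lytic_density_per_ml=lytic)
    return SyntheticExperiment(design=design, model=model, seed=seed,
                               observations=observations, truth=truth)


def qpcr_dilution_series(start: float = 3000.0, halvings: int = 8,
                         cutoff_copies: float = 10.0,
                         template_dilution: float = 10.0,
                         template_volume_ul: float = 1.0
                         ) -> tuple[np.ndarray, float]:
    """qPCR standard-curve levels and the implied detection limit.

    Returns the ``halvings + 1`` standard-curve levels ``start / 2**i``
    (copies per reaction) and the detection limit in viruses per mL of
    original sample: samples at or below ``cutoff_copies`` per reaction are
    discarded, and each reaction received ``template_volume_ul`` of
    template diluted ``template_dilution``-fold.
    """
    if start <= 0:
        raise ValueError("start must be > 0")
    if halvings < 0:
        raise ValueError("halvings must be >= 0")
    levels = start / 2.0 ** np.arange(halvings + 1)
    limit = cutoff_copies * template_dilution * 1000.0 / template_volume_ul
    return levels, limit
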