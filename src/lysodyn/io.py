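"""Tidy-table I/O, run configuration and end-to-end pipeline orchestration.

Observation tables are long-format CSV/TSV with columns
``experiment, treatment, density_bin, replicate, time_d, variable, value,
censored, valid`` — densities in cells (or viruses) per mL, times in days.
Internally the dynamical models work in individuals per liter; conversion
happens only at this boundary.

``run_full_pipeline`` chains the stages of the analysis: synthetic
generation (or a user table), per-culture feature extraction, stress-onset
informed induction times, virulent vs temperate model simulation, pooled
AIC/MAE comparison per initial-density bin, and the encounter-rate
scenario table, into one JSON-serializable report.  A run is reproducible
from its configuration and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics, encounter, features, selection, synthetic
from .dynamics import (PER_ML, GrowthSchedule, InductionRule, ModelParameters,
                       simulate)
from .synthetic import (ExperimentDesign, NoiseModel, ObservationSeries,
                        UNINFECTED, generate_experiment, initial_state,
                        schedule_for_inoculum, uninfected_stress_time)

__all__ = [
    "OBS_COLUMNS",
    "observations_to_frame",
    "frame_to_observations",
    "read_observations",
    "write_observations",
    "RunConfig",
    "run_full_pipeline",
    "run_scaling_survey",
]

OBS_COLUMNS = ["experiment", "treatment", "density_bin", "replicate",
               "time_d", "variable", "value", "censored", "valid"]
_KEY_COLUMNS = ["experiment", "treatment", "density_bin", "replicate",
                "time_d", "variable"]


def observations_to_frame(observations) -> pd.DataFrame:
    """Flatten observation series into the tidy long-format table."""
    rows = []
    for obs in observations:
        m = obs.meta
        for i in range(len(obs.times)):
            rows.append((m.get("experiment", ""), m.get("treatment", ""),
                         m.get("density_bin", float("nan")),
                         m.get("replicate", 0), float(obs.times[i]),
                         obs.variable, float(obs.values[i]),
                         bool(obs.censored[i]), bool(obs.valid[i])))
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def frame_to_observations(df: pd.DataFrame) -> list[ObservationSeries]:
    """Group a tidy table back into per-culture, per-variable series."""
    out = []
    keys = ["experiment", "treatment", "density_bin", "replicate", "variable"]
    for (exp, treat, dbin, rep, var), g in df.groupby(keys, sort=True):
        g = g.sort_values("time_d")
        out.append(ObservationSeries(
            variable=var, times=g["time_d"].to_numpy(),
            values=g["value"].to_numpy(),
            censored=g["censored"].to_numpy(dtype=bool),
            valid=g["valid"].to_numpy(dtype=bool),
            meta={"experiment": exp, "treatment": treat,
                  "density_bin": float(dbin), "replicate": int(rep)}))
    return out


def read_observations(path) -> pd.DataFrame:
    """Read and validate a tidy observation table (CSV or TSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("density_bin", "time_d", "value"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} near line {row}"
            ) from exc
    df["censored"] = df["censored"].astype(bool)
    df["valid"] = df["valid"].astype(bool)
    dup = df.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate observation key at line {row}")
    return df[OBS_COLUMNS]


def write_observations(obj, path) -> None:
    """Write observation series or a tidy frame to CSV/TSV."""
    path = Path(path)
    df = obj if isinstance(obj, pd.DataFrame) else observations_to_frame(obj)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# configuration


def _build(cls, data: dict | None):
    data = dict(data or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    return cls(**data)


def _params_from_dict(data: dict | None) -> ModelParameters:
    data = dict(data or {})
    growth = _build(GrowthSchedule, data.pop("growth", None))
    induction = _build(InductionRule, data.pop("induction", None)
                       or {"mode": dynamics.TEMPERATE_SELF_REGULATED})
    base = _build(ModelParameters, data)
    return replace(base, growth=growth, induction=induction)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    model: str = "temperate_self_regulated"   # generating model for synth
    synth: bool = True
    observations: str | None = None           # tidy table path (alternative input)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    params: ModelParameters = field(default_factory=lambda: _params_from_dict(None))
    noise: NoiseModel = field(default_factory=NoiseModel)
    residual_floor: float = 10.0              # cells/mL clamp for log residuals
    log_base: float = math.e
    compare_variable: str = "host_density"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        design = _build(ExperimentDesign, data.pop("design", None))
        params = _params_from_dict(data.pop("params", None))
        noise = _build(NoiseModel, data.pop("noise", None))
        cfg = _build(cls, data)
        return replace(cfg, design=design, params=params, noise=noise)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = (json.load(fh) if path.suffix.lower() == ".json"
                    else yaml.safe_load(fh))
        return cls.from_dict(data or {})


# ---------------------------------------------------------------------------
# pipeline


def _cultures(observations) -> dict:
    """Index series by (treatment, density_bin, replicate) -> {variable: series}."""
    cultures: dict = {}
    for obs in observations:
        m = obs.meta
        key = (m["treatment"], float(m["density_bin"]), int(m["replicate"]))
        cultures.setdefault(key, {})[obs.variable] = obs
    return cultures


def _infected_treatments(cultures) -> list[str]:
    return sorted({t for (t, _, _) in cultures if t != UNINFECTED})


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute synth -> features -> t_s -> models -> comparison -> encounter.

    Returns a JSON-serializable report.  Model comparison pools all
    infected cultures (treatments and replicates) within each
    initial-density bin of one medium, comparing the phenomenological
    temperate model (induction at the extracted stress onset) against the
    virulent model on log10 host densities.
    """
    if config.observations is not None:
        obs_list = frame_to_observations(read_observations(config.observations))
        truth = None
    elif config.synth:
        exp = generate_experiment(config.design, config.params, config.noise,
                                  model=config.model, seed=config.seed)
        obs_list = exp.observations
        truth = exp.truth
    else:
        raise ValueError("no input stage: enable synth or provide observations")

    cultures = _cultures(obs_list)
    bins = sorted({b for (_, b, _) in cultures})

    # per-culture features
    feature_rows = []
    onsets: dict[float, list[float]] = {b: [] for b in bins}
    capacity_by_bin: dict[float, list[float]] = {b: [] for b in bins}
    for (treat, dbin, rep), series in sorted(cultures.items()):
        control = None
        ctrl_key = (UNINFECTED, dbin, rep)
        if ctrl_key in cultures:
            control = cultures[ctrl_key].get("host_density")
        summary = {"treatment": treat, "density_bin": dbin, "replicate": rep,
                   "carrying_capacity": None, "lytic_density": None,
                   "stress_onset": None, "flags": []}
        host = series.get("host_density")
        if treat == UNINFECTED and host is not None:
            r = features.carrying_capacity(host)
            summary["carrying_capacity"] = r.value
            summary["flags"].extend(r.flags)
            if r.value is not None:
                capacity_by_bin[dbin].append(r.value)
        elif host is not None:
            r = features.lytic_density(host, control=control)
            summary["lytic_density"] = r.value
            summary["flags"].extend(r.flags)
        fv = series.get("fvfm")
        if fv is not None and treat != UNINFECTED:
            try:
                r = features.stress_onset(fv)
            except ValueError:
                r = features.FeatureResult(None, flags=("too few valid points",))
            summary["stress_onset"] = r.value
            if r.value is not None:
                onsets[dbin].append(r.value)
        feature_rows.append(summary)

    # stress-onset informed induction times per bin
    duration = max(max(o.times) for o in obs_list)
    times = np.arange(0.0, duration + 1e-9,
                      config.design.sampling_interval / 4.0)
    t_s_by_bin = {}
    for dbin in bins:
        if onsets[dbin]:
            t_s_by_bin[dbin] = float(np.median(onsets[dbin]))
        else:
            t_s = uninfected_stress_time(
                dbin * PER_ML,
                replace(config.params,
                        growth=schedule_for_inoculum(dbin * PER_ML,
                                                     config.params.growth)),
                duration)
            t_s_by_bin[dbin] = float(t_s) if t_s is not None else duration + 1.0

    # model simulations and pooled comparison per density bin
    infected = _infected_treatments(cultures)
    M_temp = selection.parameter_count("temperate_phenomenological",
                                      n_density_bins=len(bins))
    M_vir = selection.parameter_count("virulent")
    comparisons = []
    for dbin in bins:
        obs_pool, temp_traj, vir_traj = [], [], []
        sched = schedule_for_inoculum(dbin * PER_ML, config.params.growth)
        p_bin = replace(config.params, growth=sched)
        for treat in infected:
            init = initial_state(treat, dbin, p_bin)
            p_temp = p_bin.with_mode(dynamics.TEMPERATE_PHENOMENOLOGICAL,
                                     t_s=t_s_by_bin[dbin])
            p_vir = p_bin.with_mode(dynamics.VIRULENT)
            traj_t = simulate(p_temp, init, times)
            traj_v = simulate(p_vir, init, times)
            for rep in sorted(r for (t, b, r) in cultures
                              if t == treat and b == dbin):
                host = cultures[(treat, dbin, rep)].get("host_density")
                if host is None:
                    continue
                obs_pool.append(host)
                temp_traj.append(traj_t)
                vir_traj.append(traj_v)
        if not obs_pool:
            continue
        cmp = selection.compare_models(obs_pool, temp_traj, vir_traj,
                                       M_temp, M_vir,
                                       floor=config.residual_floor,
                                       variable=config.compare_variable,
                                       log_base=config.log_base)
        row = cmp.to_dict()
        row["density_bin"] = dbin
        row["t_s"] = t_s_by_bin[dbin]
        comparisons.append(row)

    # lytic density vs carrying capacity scaling, where identifiable
    pairs = []
    for row in feature_rows:
        if row["lytic_density"] is None:
            continue
        caps = capacity_by_bin.get(row["density_bin"], [])
        if caps:
            pairs.append((float(np.median(caps)), row["lytic_density"]))
    scaling = None
    if len(pairs) >= 3 and np.ptp(np.log10([k for k, _ in pairs])) > 0:
        fit = features.lytic_capacity_scaling(pairs)
        scaling = dataclasses.asdict(fit)

    enc = encounter.scenario_table()
    report = {
        "seed": config.seed,
        "model": config.model,
        "n_cultures": len(cultures),
        "features": feature_rows,
        "t_s_by_bin": {str(k): v for k, v in t_s_by_bin.items()},
        "comparisons": comparisons,
        "scaling": scaling,
        "encounter": enc.to_dict(orient="records"),
        "truth_available": truth is not None,
    }
    return report


def run_scaling_survey(K_values_per_ml=None, inoculum_fraction: float = 1e-3,
                       params: ModelParameters | None = None,
                       duration: float = 21.0,
                       sampling_interval: float = 1.0,
                       treatment: str = synthetic.COINCUBATION_MOI10) -> dict:
    """Lytic density vs carrying capacity across media of different richness.

    For each carrying capacity K, an infected culture under self-regulated
    induction and its uninfected control are simulated from an inoculum at
    a fixed fraction of K and sampled daily.  The model's lytic density is
    the total host density at realized induction; the carrying capacity is
    extracted from the noiseless control end-to-end.  Returns the pairs,
    the log-log OLS fit (physiology-triggered induction drives the slope
    to 1), and the decline-based extractor's lytic call for reference —
    at low K it returns None because the few induced cells lyse without
    a population-level decline (released virions are encounter-limited),
    which is the sparse-survival phenomenon itself.
    """
    if K_values_per_ml is None:
        K_values_per_ml = np.logspace(3.0, 6.8, 9)
    params = params or ModelParameters()
    noiseless = NoiseModel(count_cv=0.0, analyzed_volume_ul=float("inf"),
                           fvfm_sd=0.0, pct_cv=0.0)
    times = np.arange(0.0, duration + 1e-9, sampling_interval)
    pairs, extracted = [], []
    for K in K_values_per_ml:
        H0 = K * inoculum_fraction
        sched = schedule_for_inoculum(H0 * PER_ML,
                                      replace(params.growth, K=K * PER_ML))
        p_run = replace(params, growth=sched).with_mode(
            dynamics.TEMPERATE_SELF_REGULATED)
        control = simulate(p_run.with_mode(dynamics.TEMPERATE_SELF_REGULATED),
                           dynamics.SimulationState(H=H0 * PER_ML, V=0, I=0),
                           times)
        traj = simulate(p_run.with_mode(dynamics.TEMPERATE_SELF_REGULATED),
                        initial_state(treatment, H0, p_run), times)
        ctrl_obs = apply_noiseless(control, noiseless)
        inf_obs = apply_noiseless(traj, noiseless)
        cap = features.carrying_capacity(ctrl_obs).value
        lytic_model = None
        if traj.host_at_induction is not None:
            lytic_model = traj.host_at_induction / PER_ML
        pairs.append((cap, lytic_model))
        extracted.append((cap, features.lytic_density(
            inf_obs, control=ctrl_obs).value))
    fit = features.lytic_capacity_scaling(pairs)
    return {"pairs": pairs, "extracted_pairs": extracted, "fit": fit}


def apply_noiseless(traj, noise: NoiseModel) -> ObservationSeries:
    """Host-density series read off a trajectory without noise."""
    series = synthetic.apply_observation_model(traj, noise, rng=0)
    return next(s for s in series if s.variable == "host_density")
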