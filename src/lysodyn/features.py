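"""Empirical summaries of batch-culture growth curves.

Extracts the quantities used to characterize temperate vs virulent
behavior in infection experiments:

* carrying capacity — maximum density of an uninfected culture that
  reached stationary phase;
* lytic density — the highest host density observed in an infected culture
  before the first sustained viral-mediated decline, or before it first
  diverged sustainedly below its uninfected control;
* stress onset — the time the photochemical quantum yield (F_v/F_m) curve
  begins its decline, used to set the induction time of the
  phenomenological temperate model;
* the log-log scaling of lytic density on carrying capacity, whose slope
  near 1 (densities tracking the 1:1 line) is the signature of
  physiology-triggered induction;
* the dilution-assay estimate of the infected cell fraction.

Decline/divergence calls use simple rule-based scans (two consecutive
decreasing samples with a total two-fold drop; two consecutive samples
two-fold below control) chosen to be robust to ~15% counting noise.  All
densities are per mL (laboratory convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "FeatureResult",
    "FeatureSummary",
    "ScalingFit",
    "carrying_capacity",
    "lytic_density",
    "stress_onset",
    "lytic_capacity_scaling",
    "infected_fraction_dilution",
    "extract_features",
]

STATIONARY_GROWTH_CUTOFF = 0.1   # d^-1; an order below the default mu_max
DECLINE_FOLD = 2.0
DECLINE_CONSECUTIVE = 2
FVFM_PLATEAU_FRACTION = 0.95


@dataclass(frozen=True)
class FeatureResult:
    """A single extracted feature with quality flags."""

    value: float | None
    flags: tuple[str, ...] = ()
    time: float | None = None  # event time where meaningful (onset, decline)


@dataclass
class FeatureSummary:
    """Per-culture empirical features (densities per mL, times in days)."""

    carrying_capacity: float | None = None
    lytic_density: float | None = None
    stress_onset_t: float | None = None
    flags: tuple[str, ...] = ()


@dataclass
class ScalingFit:
    """OLS of log10(lytic density) on log10(carrying capacity)."""

    slope: float
    intercept: float
    n_points: int
    slope_ci: tuple[float, float]
    offset_from_identity: float  # mean log10(lytic/carrying), distance to 1:1 line


def _valid_points(series) -> tuple[np.ndarray, np.ndarray]:
    keep = (~np.asarray(series.censored, dtype=bool)) & np.asarray(series.valid, dtype=bool)
    return np.asarray(series.times, dtype=float)[keep], np.asarray(series.values, dtype=float)[keep]


def _median3(values: np.ndarray) -> np.ndarray:
    """3-point running median with edge passthrough."""
    if len(values) < 3:
        return values.copy()
    out = values.copy()
    out[1:-1] = np.median(
        np.column_stack([values[:-2], values[1:-1], values[2:]]), axis=1)
    return out


def carrying_capacity(uninfected,
                      growth_cutoff: float = STATIONARY_GROWTH_CUTOFF,
                      ) -> FeatureResult:
    """Stationary-phase density of an uninfected culture.

    Stationary phase is called when at least two consecutive sampling
    intervals show per-capita growth below ``growth_cutoff`` (d^-1).  The
    reported value is the median of the stationary-phase samples, which
    equals the maximum observed density for a clean saturating curve while
    staying robust to the upward bias a running maximum acquires under
    multiplicative counting noise.  Returns None with a "no stationary
    phase" flag if growth never slows.
    """
    t, v = _valid_points(uninfected)
    if t.size == 0:
        raise ValueError("all observations censored or invalid")
    if t.size < 4:
        raise ValueError("carrying capacity needs at least 4 valid time points")
    smooth = _median3(v)
    rates = np.diff(np.log(np.maximum(smooth, 1e-300))) / np.diff(t)
    slow = rates < growth_cutoff
    pairs = slow[:-1] & slow[1:]
    if not pairs.any():
        return FeatureResult(None, flags=("no stationary phase",))
    start = int(np.argmax(pairs))  # first sample of the stationary segment
    return FeatureResult(float(np.median(v[start:])),
                         time=float(t[start]))


def _control_at(control, times: np.ndarray) -> np.ndarray:
    ct, cv = _valid_points(control)
    if ct.size < 2:
        raise ValueError("control series has fewer than 2 valid points")
    return 10.0 ** np.interp(times, ct, np.log10(np.maximum(cv, 1e-300)))


def _first_decline(t: np.ndarray, v: np.ndarray,
                   fold: float, consecutive: int) -> int | None:
    """Index where the first sustained decline begins, else None."""
    for i in range(len(v) - consecutive):
        window = v[i:i + consecutive + 1]
        if np.all(np.diff(window) < 0) and window[0] / window[-1] >= fold:
            return i
    return None


def lytic_density(infected, control=None, fold: float = DECLINE_FOLD,
                  consecutive: int = DECLINE_CONSECUTIVE) -> FeatureResult:
    """Highest observed density before viral-mediated decline or divergence.

    Two events are scanned for: (a) a sustained decline — ``consecutive``
    successive decreases totalling at least ``fold``-fold; (b) a sustained
    divergence — ``consecutive`` successive samples at least ``fold``-fold
    below the paired uninfected control.  The value is the maximum density
    at or before whichever event occurs first; None if neither occurs.  A
    decline visible only at the final sample cannot be confirmed and yields
    a "single-point decline" flag.
    """
    t, v = _valid_points(infected)
    if t.size < 2:
        raise ValueError("need at least 2 valid points")
    flags: list[str] = []

    decline_idx = _first_decline(t, v, fold, consecutive)
    diverge_idx: int | None = None
    if control is not None:
        ctrl = _control_at(control, t)
        below = ctrl / np.maximum(v, 1e-300) >= fold
        for i in range(len(below) - consecutive + 1):
            if below[i:i + consecutive].all():
                diverge_idx = i
                break
    else:
        flags.append("no control; decline rule only")

    candidates = [i for i in (decline_idx, diverge_idx) if i is not None]
    if not candidates:
        if len(v) >= 2 and v[-1] < v[-2]:
            flags.append("single-point decline")
        return FeatureResult(None, flags=tuple(flags))
    event = min(candidates)
    return FeatureResult(float(v[:event + 1].max()), flags=tuple(flags),
                         time=float(t[event]))


def stress_onset(fvfm, plateau_fraction: float = FVFM_PLATEAU_FRACTION
                 ) -> FeatureResult:
    """Time the F_v/F_m curve begins a persistent decline.

    The series is 3-point median smoothed; the plateau reference is the
    median of the first (up to) five valid smoothed samples.  Onset is the
    first time the smoothed curve falls below ``plateau_fraction`` of the
    plateau and stays below for every subsequent sample — a transient dip
    that later recovers is not an onset.  The crossing is back-interpolated
    between samples so the onset is not quantized to the sampling grid; a
    curve already below threshold throughout reports the first valid time.
    Returns None if the curve never settles below threshold.
    """
    t, v = _valid_points(fvfm)
    if t.size < 3:
        raise ValueError("stress onset needs at least 3 valid points")
    smooth = _median3(v)
    plateau = float(np.median(smooth[:min(5, len(smooth))]))
    threshold = plateau_fraction * plateau
    below = smooth < threshold
    # first index from which the curve never recovers above threshold
    if not below[-1]:
        return FeatureResult(None)
    rev = below[::-1]
    run = len(rev) if rev.all() else int(np.argmin(rev))
    i = len(below) - run  # first persistently-below sample
    if i == 0:
        return FeatureResult(float(t[0]), time=float(t[0]))
    # the curve fell below the threshold between samples i-1 and i;
    # back-interpolate the crossing so the onset is not quantized to the
    # sampling grid
    drop = smooth[i - 1] - smooth[i]
    if drop > 0:
        frac = float(np.clip((smooth[i - 1] - threshold) / drop, 0.0, 1.0))
        onset = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    else:
        onset = float(t[i])
    return FeatureResult(onset, time=onset)


def lytic_capacity_scaling(pairs) -> ScalingFit:
    """OLS of log10 lytic density on log10 carrying capacity.

    ``pairs`` is a sequence of (carrying_capacity, lytic_density) tuples;
    incomplete pairs (either value None) are dropped.  Reports the slope
    with its 95% CI and the mean vertical offset from the 1:1 line.
    """
    clean = [(k, l) for k, l in pairs if k is not None and l is not None]
    if len(clean) < 3:
        raise ValueError("need at least 3 complete pairs")
    x = np.log10([k for k, _ in clean])
    y = np.log10([l for _, l in clean])
    if np.ptp(x) == 0:
        raise ValueError("degenerate carrying-capacity variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return ScalingFit(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                      n_points=len(clean), slope_ci=(float(lo), float(hi)),
                      offset_from_identity=float(np.mean(y - x)))


def infected_fraction_dilution(before: float, after_24h: float,
                               dilution: float, g: float) -> float:
    """Infected-cell percentage from the dilution assay.

    Cells are diluted ``dilution``-fold to preclude new infection and
    counted 24 h later; uninfected cells would have multiplied by ``g``.
    The shortfall ``1 - after / ((before/dilution)*g)`` estimates the
    fraction of cells that were infected (assumed neither to divide nor to
    be counted after lysis).  Clamped to [0, 100] percent.
    """
    if before < 0 or after_24h < 0:
        raise ValueError("densities must be non-negative")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    if g <= 0:
        raise ValueError("expected growth factor g must be > 0")
    expected = (before / dilution) * g
    if expected == 0:
        raise ValueError("no cells expected after dilution")
    return float(np.clip(100.0 * (1.0 - after_24h / expected), 0.0, 100.0))


def extract_features(uninfected=None, infected=None, fvfm=None) -> FeatureSummary:
    """Convenience bundle of the per-culture features."""
    flags: list[str] = []
    K = ld = onset = None
    if uninfected is not None:
        r = carrying_capacity(uninfected)
        K, _f = r.value, r.flags
        flags.extend(_f)
    if infected is not None:
        r = lytic_density(infected, control=uninfected)
        ld = r.value
        flags.extend(r.flags)
    if fvfm is not None:
        r = stress_onset(fvfm)
        onset = r.value
    return FeatureSummary(carrying_capacity=K, lytic_density=ld,
                          stress_onset_t=onset, flags=tuple(flags))
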