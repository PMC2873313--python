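"""Comparison analytics across the three solution frameworks.

Half-steady-state times, stochastic-vs-deterministic significance curves
(in units of the ensemble standard error), first-arrival transport speeds,
and across-run variability summaries with their square-root-of-n scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import layout
from .asymptotic import agar_half_time, M_PER_S_TO_CM_PER_H
from .ode import OdeSolution
from .parameters import ModelParameters
from .stochastic import EnsembleResult, Trajectory, ssa_run, derive_seeds

__all__ = [
    "HalfTimeResult", "SignificanceCurve", "VelocityEstimate",
    "VariabilitySummary", "SteadyStateError",
    "half_time", "half_time_asymptotic", "ensemble_half_times",
    "se_difference", "transport_speed", "variability_summary",
    "noise_scaling_check",
]


class SteadyStateError(RuntimeError):
    """Raised when a record is too short to identify a steady-state level."""


@dataclass(frozen=True)
class HalfTimeResult:
    compartment: str
    steady_level: float
    half_level: float
    crossing_time_s: float

    @property
    def crossing_time_min(self) -> float:
        return self.crossing_time_s / 60.0


@dataclass(frozen=True)
class SignificanceCurve:
    """z(t) = (stochastic mean - deterministic prediction) / SE.

    Masked (NaN) wherever the ensemble SE vanishes; ``significant`` flags
    |z| > 2, the two-standard-error criterion.
    """

    times: np.ndarray
    z: np.ndarray
    significant: np.ndarray


@dataclass(frozen=True)
class VelocityEstimate:
    mean_arrival_s: float
    sd_arrival_s: float
    speed_m_per_s: float
    sd_speed_m_per_s: float
    n: int

    @property
    def speed_cm_per_h(self) -> float:
        return self.speed_m_per_s * M_PER_S_TO_CM_PER_H

    @property
    def sd_speed_cm_per_h(self) -> float:
        return self.sd_speed_m_per_s * M_PER_S_TO_CM_PER_H


@dataclass(frozen=True)
class VariabilitySummary:
    """Time-averaged across-run SD of relative concentration, by
    compartment type (+/- its SD over time points)."""

    mean: dict
    sd_over_time: dict


def _resolve_compartment(compartment, N: int) -> int:
    if isinstance(compartment, str):
        labs = layout.labels(N)
        if compartment == "sink":
            return layout.idx_sink(N)
        if compartment == "source":
            return layout.idx_source(N)
        return labs.index(compartment)
    return int(compartment)


def estimate_steady_level(times: np.ndarray, values: np.ndarray,
                          plateau_tol: float = 2e-3) -> float:
    """Steady-state level estimate: mean over the last 10% of the record.

    The record is accepted as plateaued when the means of the last two 5%
    windows differ by less than ``plateau_tol`` of the overall excursion;
    otherwise :class:`SteadyStateError` is raised.  The windowed mean (rather
    than the endpoint value) makes the estimator robust to counting noise in
    stochastic trajectories.
    """
    n = len(times)
    if n < 40:
        raise SteadyStateError("record too short for a plateau estimate")
    w = max(n // 20, 2)
    last = float(np.mean(values[-w:]))
    prev = float(np.mean(values[-2 * w:-w]))
    scale = float(np.max(np.abs(values)))
    if scale == 0.0:
        return 0.0
    if abs(last - prev) > plateau_tol * scale:
        raise SteadyStateError(
            f"no plateau: last two 5% windows differ by "
            f"{abs(last - prev) / scale:.2%} of the excursion "
            f"(tolerance {plateau_tol:.2%}); extend t_end")
    return float(np.mean(values[-max(n // 10, 2):]))


def first_crossing(times: np.ndarray, values: np.ndarray,
                   level: float, rising: bool) -> float:
    """First crossing of ``level``, linearly interpolated between the
    bracketing samples."""
    v = values - level
    if not rising:
        v = -v
    above = v >= 0
    if above[0]:
        return float(times[0])
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        raise SteadyStateError("level never crossed within the record")
    i = idx[0]
    f = v[i - 1] / (v[i - 1] - v[i])
    return float(times[i - 1] + f * (times[i] - times[i - 1]))


def half_time(solution, compartment, steady: float = None,
              plateau_tol: float = 2e-3) -> HalfTimeResult:
    """Time for a compartment to reach halfway between its initial and
    steady-state levels.

    ``solution`` may be an :class:`OdeSolution` or a stochastic
    :class:`Trajectory`.  The half level is the midpoint of the initial and
    steady values (for a compartment starting empty this is half the steady
    level); ``steady`` may be supplied to bypass the plateau estimator.
    """
    if isinstance(solution, OdeSolution):
        N = solution.params.geometry.N
        idx = _resolve_compartment(compartment, N)
        times = solution.times
        series = solution.values[:, idx]
    elif isinstance(solution, Trajectory):
        N = solution.N
        idx = _resolve_compartment(compartment, N)
        times = solution.times
        series = solution.counts[:, idx].astype(float)
    else:
        raise TypeError(f"unsupported solution type {type(solution).__name__}")
    if steady is None:
        steady = estimate_steady_level(times, series, plateau_tol)
    initial = float(series[0])
    half = 0.5 * (initial + steady)
    t = first_crossing(times, series, half, rising=steady > initial)
    name = compartment if isinstance(compartment, str) else layout.labels(N)[idx]
    return HalfTimeResult(compartment=str(name), steady_level=float(steady),
                          half_level=float(half), crossing_time_s=t)


def half_time_asymptotic(params: ModelParameters,
                         compartment: str = "source") -> HalfTimeResult:
    """Half-time from the long-time agar-block formulas (source and sink
    coincide by construction)."""
    S0 = params.initial_source_concentration
    t = agar_half_time(params)
    if compartment == "source":
        return HalfTimeResult("source", steady_level=0.0,
                              half_level=0.5 * S0, crossing_time_s=t)
    if compartment == "sink":
        return HalfTimeResult("sink", steady_level=S0,
                              half_level=0.5 * S0, crossing_time_s=t)
    raise ValueError("asymptotic half-times exist for 'source' and 'sink'")


def ensemble_half_times(params: ModelParameters, n_runs: int, t_end: float,
                        dt_record: float = 60.0, base_seed: int = 0,
                        include_pin_backflux: bool = False,
                        steady: dict = None) -> dict:
    """Per-run agar-block half-times over an ensemble.

    Returns ``{"source": array_s, "sink": array_s}`` of per-run crossing
    times (seconds).  ``steady`` may map compartment name to a known steady
    level; otherwise each run uses its own plateau estimate.
    """
    seeds = derive_seeds(base_seed, n_runs)
    out = {"source": np.empty(n_runs), "sink": np.empty(n_runs)}
    for i, sd in enumerate(seeds):
        traj = ssa_run(params, t_end=t_end, seed=int(sd), dt_record=dt_record,
                       include_pin_backflux=include_pin_backflux)
        for name in ("source", "sink"):
            known = None if steady is None else steady.get(name)
            out[name][i] = half_time(traj, name, steady=known).crossing_time_s
    return out


def _deterministic_counts(det, times: np.ndarray, idx: int,
                          params: ModelParameters) -> np.ndarray:
    areas = layout.compartment_areas(params.geometry)
    if isinstance(det, OdeSolution):
        return det.at(times)[:, idx] * areas[idx]
    if callable(det):  # e.g. an asymptotic formula t -> molecule count
        return np.array([det(t) for t in times])
    raise TypeError("deterministic comparator must be an OdeSolution or callable")


def se_difference(ens: EnsembleResult, det, compartment,
                  params: ModelParameters) -> SignificanceCurve:
    """Significance curve of the stochastic-deterministic difference.

    z(t) is the ensemble-mean count minus the deterministic count, divided
    by the ensemble standard error (sign convention: positive when the
    stochastic model predicts more).  Grid points with zero SE are masked.
    """
    idx = _resolve_compartment(compartment, ens.N)
    detc = _deterministic_counts(det, ens.times, idx, params)
    se = ens.se[:, idx]
    z = np.full_like(detc, np.nan, dtype=float)
    ok = se > 0
    z[ok] = (ens.mean[ok, idx] - detc[ok]) / se[ok]
    return SignificanceCurve(times=ens.times, z=z,
                             significant=np.abs(z) > 2.0)


def transport_speed(arrival_times: np.ndarray, L: float) -> VelocityEstimate:
    """Transport speed L / mean(first-arrival time), with the first-order
    propagated SD."""
    at = np.asarray(arrival_times, dtype=float)
    at = at[np.isfinite(at)]
    if at.size < 2:
        raise ValueError("need at least 2 finite arrival times")
    mean = float(at.mean())
    sd = float(at.std(ddof=1))
    speed = L / mean
    return VelocityEstimate(mean_arrival_s=mean, sd_arrival_s=sd,
                            speed_m_per_s=speed,
                            sd_speed_m_per_s=speed * sd / mean, n=at.size)


def variability_summary(ens: EnsembleResult,
                        params: ModelParameters) -> VariabilitySummary:
    """Across-run variability by compartment type.

    The statistic per type is the across-run SD of the per-run type-averaged
    molecule count relative to the total load C, time-averaged over the
    record (+/- its SD over time points).  Averaging over the compartments
    of a type before taking the run-to-run spread is what makes the many
    small stem compartments far quieter than the two agar blocks.
    """
    from .stochastic import TYPE_ORDER
    if params.C == 0:
        zeros = {typ: 0.0 for typ in TYPE_ORDER}
        return VariabilitySummary(mean=dict(zeros), sd_over_time=dict(zeros))
    rel_sd = ens.type_sd / params.C
    mean, spread = {}, {}
    for j, typ in enumerate(TYPE_ORDER):
        mean[typ] = float(rel_sd[:, j].mean())
        spread[typ] = float(rel_sd[:, j].std(ddof=1))
    return VariabilitySummary(mean=mean, sd_over_time=spread)


def noise_scaling_check(ens_low: EnsembleResult, ens_high: EnsembleResult,
                        params_low: ModelParameters,
                        params_high: ModelParameters) -> dict:
    """Observed vs theoretical noise reduction between two initial loads.

    For initial counts differing by a factor r, relative-concentration noise
    scales as 1/sqrt(n), so the expected reduction is 1 - r**-0.5 (about 69%
    for r = 10).  Returns percentages.
    """
    if ens_low.times.shape != ens_high.times.shape or \
            not np.allclose(ens_low.times, ens_high.times):
        raise ValueError("ensembles must share a common time grid")
    r = params_high.C / params_low.C
    v_low = variability_summary(ens_low, params_low).mean
    v_high = variability_summary(ens_high, params_high).mean
    per_type = {t: 100.0 * (1.0 - v_high[t] / v_low[t]) for t in v_low}
    observed = float(np.mean(list(per_type.values())))
    theoretical = 100.0 * (1.0 - r ** -0.5)
    return {"observed_percent": observed,
            "theoretical_percent": theoretical,
            "per_type_percent": per_type,
            "concentration_ratio": r}
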