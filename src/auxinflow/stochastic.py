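"""Exact stochastic simulation of the multi-compartment rule system.

A single run is a statistically exact realisation of the continuous-time
Markov jump process defined by the rules (Gillespie direct method over the
flattened rule union).  Ensembles of independent runs provide per-compartment
means, standard deviations, standard errors and 95% confidence intervals on
a common time grid, plus empirical probability curves for trajectory
predicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import layout
from ._kernel import ssa_core
from .parameters import ModelParameters
from .rules import build_rule_set, rule_arrays

__all__ = [
    "Trajectory",
    "EnsembleResult",
    "ProbabilityCurve",
    "ssa_run",
    "ensemble",
    "first_arrival_time",
    "first_arrival_times",
    "sink_counts_at_time",
    "empirical_probability",
    "derive_seeds",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Independent per-run seeds (each < 2^31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


@dataclass(frozen=True)
class Trajectory:
    """One SSA realisation sampled on a uniform grid.

    ``counts`` has shape (n_times, n_compartments) in the canonical state
    order; ``first_arrival`` is the exact jump time of the first molecule
    entering the collecting block (inf if none fired before ``t_end``).
    """

    times: np.ndarray
    counts: np.ndarray
    seed: int
    n_firings: int
    first_arrival: float
    N: int

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def compartment(self, index: int) -> np.ndarray:
        return self.counts[:, index]


#: order of the coarse compartment types in the aggregated statistics
TYPE_ORDER = ("source", "sink", "cytoplasm", "apoplast")


@dataclass(frozen=True)
class EnsembleResult:
    """Across-run summary statistics on a common time grid (counts).

    ``type_mean``/``type_sd`` hold the statistics of the per-run
    *type-averaged* counts (mean count over all compartments of each coarse
    type, in ``TYPE_ORDER``), the aggregation used for the concentration
    variability summaries.
    """

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    type_mean: np.ndarray
    type_sd: np.ndarray
    n_runs: int
    base_seed: int
    N: int

    @property
    def se(self) -> np.ndarray:
        return self.sd / np.sqrt(self.n_runs)

    @property
    def ci_low(self) -> np.ndarray:
        return self.mean - _Z95 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.mean + _Z95 * self.se

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: time_s, compartment, statistic, value."""
        labs = layout.labels(self.N)
        frames = []
        for stat, arr in (("mean", self.mean), ("sd", self.sd),
                          ("se", self.se), ("ci_low", self.ci_low),
                          ("ci_high", self.ci_high)):
            df = pd.DataFrame(arr, columns=labs)
            df.insert(0, "time_s", self.times)
            df = df.melt(id_vars="time_s", var_name="compartment",
                         value_name="value")
            df.insert(2, "statistic", stat)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ProbabilityCurve:
    """Empirical probability that a per-run event has occurred by time t."""

    times: np.ndarray
    p_hat: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_runs: int


def _arrays_for(params, rules, include_pin_backflux):
    if rules is None:
        rules = build_rule_set(params, include_pin_backflux=include_pin_backflux)
    return rule_arrays(rules)


def ssa_run(params: ModelParameters, t_end: float, seed: int,
            dt_record: float = 10.0, rules=None,
            include_pin_backflux: bool = False,
            stop_at_first_arrival: bool = False) -> Trajectory:
    """Run one exact realisation with all C molecules initially in the
    source block."""
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    N = params.geometry.N
    src, dst, kk = _arrays_for(params, rules, include_pin_backflux)
    counts0 = np.zeros(layout.n_compartments(N), dtype=np.int64)
    counts0[layout.idx_source(N)] = params.C
    out, first, nev = ssa_core(counts0, src, dst, kk, float(t_end),
                               float(dt_record), int(seed),
                               layout.idx_sink(N), stop_at_first_arrival)
    times = np.arange(out.shape[0]) * dt_record
    return Trajectory(times=times, counts=out, seed=int(seed),
                      n_firings=int(nev), first_arrival=float(first), N=N)


def first_arrival_time(trajectory: Trajectory) -> float:
    """Exact time of the first molecule entering the collecting block
    (inf sentinel if none arrived before t_end)."""
    return trajectory.first_arrival


def ensemble(params: ModelParameters, n_runs: int, t_end: float,
             dt_record: float = 10.0, base_seed: int = 0, rules=None,
             include_pin_backflux: bool = False) -> EnsembleResult:
    """Across-run statistics over ``n_runs`` independent realisations.

    Accumulates mean and variance in one pass (Welford) so the per-run grids
    are never all held in memory.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 for ensemble statistics")
    N = params.geometry.N
    src, dst, kk = _arrays_for(params, rules, include_pin_backflux)
    counts0 = np.zeros(layout.n_compartments(N), dtype=np.int64)
    counts0[layout.idx_source(N)] = params.C
    seeds = derive_seeds(base_seed, n_runs)
    types = np.array(layout.compartment_types(N))
    masks = [types == typ for typ in TYPE_ORDER]
    mean = m2 = tmean = tm2 = times = None
    for i, sd_i in enumerate(seeds):
        out, _, _ = ssa_core(counts0, src, dst, kk, float(t_end),
                             float(dt_record), int(sd_i),
                             layout.idx_sink(N), False)
        x = out.astype(np.float64)
        xa = np.stack([x[:, m].mean(axis=1) for m in masks], axis=1)
        if mean is None:
            times = np.arange(out.shape[0]) * dt_record
            mean, m2 = np.zeros_like(x), np.zeros_like(x)
            tmean, tm2 = np.zeros_like(xa), np.zeros_like(xa)
        delta = x - mean
        mean += delta / (i + 1)
        m2 += delta * (x - mean)
        tdelta = xa - tmean
        tmean += tdelta / (i + 1)
        tm2 += tdelta * (xa - tmean)
    sd = np.sqrt(m2 / (n_runs - 1))
    type_sd = np.sqrt(tm2 / (n_runs - 1))
    return EnsembleResult(times=times, mean=mean, sd=sd, type_mean=tmean,
                          type_sd=type_sd, n_runs=n_runs,
                          base_seed=base_seed, N=N)


def first_arrival_times(params: ModelParameters, n_runs: int,
                        base_seed: int = 0, t_end: float = 3600.0,
                        rules=None,
                        include_pin_backflux: bool = False) -> np.ndarray:
    """Exact first-arrival times over ``n_runs`` early-stopped runs."""
    N = params.geometry.N
    src, dst, kk = _arrays_for(params, rules, include_pin_backflux)
    counts0 = np.zeros(layout.n_compartments(N), dtype=np.int64)
    counts0[layout.idx_source(N)] = params.C
    seeds = derive_seeds(base_seed, n_runs)
    out = np.empty(n_runs)
    for i, sd_i in enumerate(seeds):
        _, first, _ = ssa_core(counts0, src, dst, kk, float(t_end), float(t_end),
                               int(sd_i), layout.idx_sink(N), True)
        out[i] = first
    return out


def sink_counts_at_time(params: ModelParameters, n_runs: int, t: float,
                        base_seed: int = 0, rules=None,
                        include_pin_backflux: bool = False) -> np.ndarray:
    """Collecting-block molecule count at time ``t`` across runs."""
    N = params.geometry.N
    src, dst, kk = _arrays_for(params, rules, include_pin_backflux)
    counts0 = np.zeros(layout.n_compartments(N), dtype=np.int64)
    counts0[layout.idx_source(N)] = params.C
    seeds = derive_seeds(base_seed, n_runs)
    out = np.empty(n_runs)
    for i, sd_i in enumerate(seeds):
        grid, _, _ = ssa_core(counts0, src, dst, kk, float(t), float(t),
                              int(sd_i), layout.idx_sink(N), False)
        out[i] = grid[-1, layout.idx_sink(N)]
    return out


def empirical_probability(event_times: np.ndarray,
                          time_grid: np.ndarray) -> ProbabilityCurve:
    """P(event by time t) across runs, with a binomial 95% band.

    ``event_times`` holds one per-run event time (inf if the event never
    occurred); the estimate at t is the fraction of runs with event time
    <= t, which is non-decreasing by construction.
    """
    et = np.asarray(event_times, dtype=float)
    n = et.size
    p = np.array([(et <= t).mean() for t in np.asarray(time_grid)])
    half = _Z95 * np.sqrt(p * (1.0 - p) / n)
    return ProbabilityCurve(times=np.asarray(time_grid), p_hat=p,
                            ci_low=np.clip(p - half, 0.0, 1.0),
                            ci_high=np.clip(p + half, 0.0, 1.0), n_runs=n)
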