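"""Deterministic solution of the coupled compartment ODE system.

The per-area concentrations of the 2N+3 compartments obey a closed linear
system: diffusive exchange between each agar block and its terminal apoplast
(velocity 2D/L_s), passive transmembrane diffusion of protonated auxin at
every cytoplasm/apoplast interface, and the polar GHK carrier flux from each
cytoplasm into its downstream apoplast.  Every flux is divided by the length
of the compartment whose concentration it changes.

The system is integrated numerically with an adaptive Dormand-Prince scheme
(the analytic fixed point is also available in closed form for half-level
conventions and conservation checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import layout
from .parameters import ModelParameters, membrane_rates, agar_exchange_velocity

__all__ = ["OdeSolution", "rate_matrix", "rhs", "integrate",
           "steady_state", "sink_molecule_count"]


def rate_matrix(params: ModelParameters,
                include_pin_backflux: bool = True,
                include_passive_efflux: bool = True) -> np.ndarray:
    """Coefficient matrix A of the concentration system dy/dt = A y.

    The two optional terms mirror the stochastic solver's switches: the GHK
    backflux through PIN (kept by default here) and the passive protonated
    efflux out of the cytoplasm (part of the full two-way membrane flux law).
    """
    geom = params.geometry
    N = geom.N
    m = membrane_rates(params.physiology)
    pump, uptake = m["pump"], m["uptake"]
    back = m["backflux"] if include_pin_backflux else 0.0
    eff = m["efflux"] if include_passive_efflux else 0.0
    q = agar_exchange_velocity(geom, params.physiology)
    l, lam, Ls = geom.l, geom.lambda_, geom.L_s

    n = layout.n_compartments(N)
    ia = lambda j: layout.idx_apoplast(j, N)
    ic = lambda i: layout.idx_cytoplasm(i, N)
    iS, iF = layout.idx_source(N), layout.idx_sink(N)

    A = np.zeros((n, n))

    def move(src, dst, vel, src_len, dst_len):
        # one-way flux vel * y_src across the shared interface
        A[src, src] -= vel / src_len
        A[dst, src] += vel / dst_len

    move(iS, ia(0), q, Ls, lam)
    move(ia(0), iS, q, lam, Ls)
    move(iF, ia(N), q, Ls, lam)
    move(ia(N), iF, q, lam, Ls)
    for i in range(1, N + 1):
        move(ic(i), ia(i), pump, l, lam)       # PIN efflux, downstream face
        move(ia(i), ic(i), back, lam, l)       # GHK backflux through PIN
        move(ia(i), ic(i), uptake, lam, l)     # passive uptake, both faces
        move(ia(i - 1), ic(i), uptake, lam, l)
        move(ic(i), ia(i), eff, l, lam)        # passive protonated efflux
        move(ic(i), ia(i - 1), eff, l, lam)
    return A


def rhs(state: np.ndarray, params: ModelParameters, **matrix_kw) -> np.ndarray:
    """Time derivative of the concentration state vector."""
    state = np.asarray(state, dtype=float)
    n = layout.n_compartments(params.geometry.N)
    if state.shape != (n,):
        raise ValueError(f"state must have shape ({n},) for N={params.geometry.N}")
    return rate_matrix(params, **matrix_kw) @ state


@dataclass(frozen=True)
class OdeSolution:
    """Concentration trajectories on a fine uniform grid.

    ``values`` has shape (n_times, 2N+3) in the canonical state order
    (per-area concentrations).  Evaluation between grid points uses linear
    interpolation; the grid is chosen fine enough that the interpolation
    error is far below the reported precision of any derived quantity.
    """

    times: np.ndarray
    values: np.ndarray
    params: ModelParameters
    rtol: float
    atol: float

    def at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if t.min() < self.times[0] or t.max() > self.times[-1]:
            raise ValueError("evaluation time outside the solution range")
        out = np.empty((t.size, self.values.shape[1]))
        for j in range(self.values.shape[1]):
            out[:, j] = np.interp(t, self.times, self.values[:, j])
        return out[0] if out.shape[0] == 1 else out

    def compartment(self, index: int) -> np.ndarray:
        return self.values[:, index]

    @property
    def total_molecules(self) -> np.ndarray:
        areas = layout.compartment_areas(self.params.geometry)
        return self.values @ areas

    def to_frame(self) -> pd.DataFrame:
        labs = layout.labels(self.params.geometry.N)
        df = pd.DataFrame(self.values, columns=labs)
        df.insert(0, "time_s", self.times)
        df = df.melt(id_vars="time_s", var_name="compartment",
                     value_name="value")
        df.insert(2, "statistic", "deterministic")
        return df


def integrate(params: ModelParameters, t_end: float, rtol: float = 1e-8,
              atol: float = None, n_grid: int = 4000, method: str = "RK45",
              include_pin_backflux: bool = True,
              include_passive_efflux: bool = True) -> OdeSolution:
    """Integrate from the all-in-source initial condition to ``t_end``.

    ``method="RK45"`` (Dormand-Prince) is the default; ``"LSODA"`` is the
    stiff fallback.  ``atol`` defaults to 1e-12 times the initial source
    concentration.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    N = params.geometry.N
    S0 = params.initial_source_concentration
    if atol is None:
        atol = 1e-12 * max(S0, 1.0)
    A = rate_matrix(params, include_pin_backflux=include_pin_backflux,
                    include_passive_efflux=include_passive_efflux)
    y0 = np.zeros(layout.n_compartments(N))
    y0[layout.idx_source(N)] = S0
    t_eval = np.linspace(0.0, t_end, n_grid + 1)
    sol = solve_ivp(lambda t, y: A @ y, (0.0, t_end), y0, method=method,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:  # pragma: no cover - solver failure path
        raise RuntimeError(f"ODE integration failed at t={sol.t[-1]:.3g} s: "
                           f"{sol.message}")
    return OdeSolution(times=sol.t, values=sol.y.T, params=params,
                       rtol=rtol, atol=atol)


def steady_state(params: ModelParameters,
                 include_pin_backflux: bool = True,
                 include_passive_efflux: bool = True) -> np.ndarray:
    """Long-time fixed point of the closed system (concentrations).

    With the polar carrier active, essentially all auxin accumulates in the
    collecting block: the fixed point has F = a_N, a small recirculating
    cytoplasm-N level set by the uptake/pump balance, and zero elsewhere
    upstream.  Computed as the conservation-normalised null vector of the
    coefficient matrix, which also covers the non-polar (P_PIN = 0) case.
    """
    A = rate_matrix(params, include_pin_backflux=include_pin_backflux,
                    include_passive_efflux=include_passive_efflux)
    areas = layout.compartment_areas(params.geometry)
    w, v = np.linalg.eig(A)
    null = np.real(v[:, np.argmin(np.abs(w))])
    null = np.abs(null)
    return null * (params.C / float(areas @ null))


def sink_molecule_count(sol: OdeSolution, t: float) -> float:
    """Collecting-block content at time t, in molecules (continuous).

    F(t) * L_s * w -- the deterministic analogue of the stochastic
    collecting-block count.
    """
    geom = sol.params.geometry
    F = sol.at(float(t))[layout.idx_sink(geom.N)]
    return float(F) * geom.L_s * geom.w
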