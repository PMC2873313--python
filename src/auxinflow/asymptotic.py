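"""Closed-form continuum-limit (asymptotic) solution.

In the limit in which the tissue length L greatly exceeds the cell period
l + lambda (small parameter epsilon = (l+lambda)/L), the cell-scale dynamics
reduce to two regimes:

* **Transport time scale** (order L/P_PIN): the source barely depletes and
  auxin moves through the file as a sharp front obeying a wave equation with
  effective velocity

      v_eff = uptake * pump / (2*uptake + backflux),

  where ``pump = P_PIN g(phi) f_cA`` and ``uptake = P_diff f_aH`` are the
  one-way membrane velocities (the apoplast is in quasi-steady balance,
  losing to both neighbouring cells passively and to the upstream cell
  through the carrier's GHK backflux).  Behind the front the collecting
  block fills linearly.

* **Diffusive (long) time scale** (order 1/(epsilon) longer): the stem is a
  quasi-steady conveyor and agar-block diffusion limits the exchange.  The
  agar blocks evolve as S(t) = S0 exp(-k t), F(t) = S0 (1 - exp(-k t)) with
  the transfer rate

      k = (1/L_s) * q*uptake/(q + uptake),      q = 2 D / L_s,

  i.e. the series resistance of block diffusion and membrane uptake.  Both
  agar-block half-times equal ln(2)/k in this regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import ModelParameters, membrane_rates, agar_exchange_velocity

__all__ = [
    "DimensionlessParameters",
    "dimensionless_parameters",
    "effective_velocity",
    "transfer_rate",
    "front_arrival_time",
    "early_time_sink",
    "early_time_sink_molecules",
    "long_time_agar",
    "agar_half_time",
    "regime_timescales",
    "composite_solution",
    "M_PER_S_TO_CM_PER_H",
]

M_PER_S_TO_CM_PER_H = 3.6e5


@dataclass(frozen=True)
class DimensionlessParameters:
    """Small parameters and O(1) groups of the continuum limit.

    ``epsilon`` is the cell-to-tissue length ratio; ``uptake_hat`` and
    ``backflux_hat`` are the membrane velocities relative to P_PIN (both of
    order epsilon for the published estimates, hence the rescaled
    ``uptake_tilde``/``backflux_tilde`` which stay O(1) as epsilon -> 0).
    """

    epsilon: float
    Ls_bar: float
    lambda_bar: float
    phi: float
    pump_hat: float
    uptake_hat: float
    backflux_hat: float
    uptake_tilde: float
    backflux_tilde: float
    agar_hat: float


def dimensionless_parameters(params: ModelParameters) -> DimensionlessParameters:
    """Nondimensional groups for the cell file, with x = epsilon * i mapping
    cell index to the scaled tissue coordinate."""
    g = params.geometry
    phys = params.physiology
    eps = (g.l + g.lambda_) / g.L
    m = membrane_rates(phys)
    P = phys.P_PIN
    return DimensionlessParameters(
        epsilon=eps,
        Ls_bar=g.L_s / g.L,
        lambda_bar=g.lambda_ / g.l,
        phi=phys.phi,
        pump_hat=m["pump"] / P,
        uptake_hat=m["uptake"] / P,
        backflux_hat=m["backflux"] / P,
        uptake_tilde=m["uptake"] / P / eps,
        backflux_tilde=m["backflux"] / P / eps,
        agar_hat=agar_exchange_velocity(g, phys) / P,
    )


def effective_velocity(params: ModelParameters) -> float:
    """Leading-order front velocity through the cell file (m/s).

    v_eff = uptake * pump / (2*uptake + backflux); strictly increasing in
    P_PIN and independent of the initial load.  Multiply by
    ``M_PER_S_TO_CM_PER_H`` for cm/h.
    """
    m = membrane_rates(params.physiology)
    denom = 2.0 * m["uptake"] + m["backflux"]
    if denom == 0.0:
        return 0.0
    return m["uptake"] * m["pump"] / denom


def transfer_rate(params: ModelParameters) -> float:
    """Long-time agar-block transfer rate k (1/s): series conductance of
    block diffusion (2D/L_s) and membrane uptake, per block length."""
    g = params.geometry
    q = agar_exchange_velocity(g, params.physiology)
    p = membrane_rates(params.physiology)["uptake"]
    if q + p == 0.0:
        return 0.0
    return (q * p / (q + p)) / g.L_s


def front_arrival_time(params: ModelParameters) -> float:
    """Time L/v_eff at which the leading-order front reaches the collecting
    block (s)."""
    return params.geometry.L / effective_velocity(params)


def early_time_sink(t: float, params: ModelParameters) -> float:
    """Collecting-block concentration on the transport time scale.

    Zero until the front arrives at L/v_eff, then linear filling at the
    undepleted-source rate: F(t) = S0 * k * (t - L/v_eff).
    """
    t0 = front_arrival_time(params)
    if t <= t0:
        return 0.0
    return params.initial_source_concentration * transfer_rate(params) * (t - t0)


def early_time_sink_molecules(t: float, params: ModelParameters) -> float:
    """Early-time collecting-block content in molecules: C*k*(t - L/v_eff)+."""
    g = params.geometry
    return early_time_sink(t, params) * g.L_s * g.w


def long_time_agar(t: float, params: ModelParameters) -> tuple:
    """Agar-block concentrations (source, sink) on the diffusive time scale.

    S(t) = S0 exp(-k t) and F(t) = S0 (1 - exp(-k t)); the stem content is
    negligible at leading order, so the two half-times coincide exactly.
    """
    k = transfer_rate(params)
    S0 = params.initial_source_concentration
    decay = math.exp(-k * t)
    return S0 * decay, S0 * (1.0 - decay)


def agar_half_time(params: ModelParameters) -> float:
    """Common half-steady-state time ln(2)/k of both agar blocks (s)."""
    return math.log(2.0) / transfer_rate(params)


def regime_timescales(params: ModelParameters) -> dict:
    """Crossover markers between the two regimes (s): the transport scale
    L/v_eff on which the front traverses the file, and the much longer
    diffusive scale 1/k on which the agar blocks equilibrate."""
    return {"transport_s": front_arrival_time(params),
            "diffusive_s": 1.0 / transfer_rate(params)}


def composite_solution(x: float, t: float, params: ModelParameters,
                       compartment: str = "cytoplasm") -> float:
    """Leading-order stem-segment concentration profile at scaled position
    ``x`` in [0, 1] and time ``t``.

    Ahead of the front (x > v_eff*t/L) the concentration vanishes; behind
    it, flux continuity with the source gives a spatially uniform level
    a = (q/(q+uptake)) * S(t) in the apoplasts and c = a * (2*uptake +
    backflux)/pump in the cytoplasms, with S(t) following the long-time
    source formula (S(t) ~ S0 on the transport scale).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"scaled coordinate x must lie in [0, 1], got {x}")
    if t < 0:
        raise ValueError("time must be non-negative")
    g = params.geometry
    if effective_velocity(params) * t < x * g.L:
        return 0.0
    q = agar_exchange_velocity(g, params.physiology)
    m = membrane_rates(params.physiology)
    S, _ = long_time_agar(t, params)
    a = q / (q + m["uptake"]) * S
    if compartment == "apoplast":
        return a
    if compartment == "cytoplasm":
        return a * (2.0 * m["uptake"] + m["backflux"]) / m["pump"]
    raise ValueError("compartment must be 'cytoplasm' or 'apoplast'")
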