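"""Biophysical parameters, derived constants and flux laws.

The model describes the classic agar-block auxin-transport assay: a source
agar block loaded with auxin, a single file of ``N`` cells (each a cytoplasm
of length ``l`` separated from its neighbours by apoplast layers of thickness
``lambda_``), and a collecting agar block.  Auxin exists in a protonated
(membrane-permeant) and an anionic (carrier-dependent) form, partitioned by
the Henderson-Hasselbalch equilibrium at the local pH.  Anionic auxin leaves
each cytoplasm through PIN efflux carriers on the downstream cell face; the
electrodiffusive carrier flux follows Goldman-Hodgkin-Katz (GHK) theory with
the dimensionless membrane-energy parameter ``phi = -F_D V / (R T)``.

Everything downstream (stochastic rules, ODE right-hand side, asymptotic
formulas) is derived from the quantities defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.constants import N_A as AVOGADRO

__all__ = [
    "Geometry",
    "Physiology",
    "ProtonationFractions",
    "RateConstants",
    "ModelParameters",
    "proton_fractions",
    "phi_value",
    "ghk_factor",
    "flux_components",
    "rate_constants",
    "molecules_from_molar",
    "molar_from_molecules",
    "default_parameters",
]

#: Threshold below which the removable singularity of the GHK factor at
#: phi = 0 is replaced by its limit value.
_PHI_SINGULARITY_GUARD = 1e-12


@dataclass(frozen=True)
class Geometry:
    """Tissue and agar-block geometry (metres).

    The stem segment is a single two-dimensional file of ``N`` cells; its
    total length is the derived quantity ``L = N*l + (N+1)*lambda_``.
    ``L_s`` is the length of each (rectangular) agar block; both blocks and
    the tissue share the width ``w``.
    """

    N: int = 20
    l: float = 100e-6
    w: float = 10e-6
    lambda_: float = 0.5e-6
    L_s: float = 2e-3

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"cell count N must be >= 1, got {self.N}")
        for name in ("l", "w", "lambda_", "L_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry length {name!r} must be positive")

    @property
    def L(self) -> float:
        """Tissue length N*l + (N+1)*lambda_ (m)."""
        return self.N * self.l + (self.N + 1) * self.lambda_

    @property
    def source_volume(self) -> float:
        """Agar-block volume L_s*w*w used for molar conversions (m^3).

        The model is two-dimensional; the out-of-plane depth is taken equal
        to the cell width ``w``.
        """
        return self.L_s * self.w * self.w


@dataclass(frozen=True)
class Physiology:
    """Membrane, diffusion and electrochemical parameters (SI units)."""

    P_diff: float = 5.6e-7   # membrane permeability of protonated auxin, m/s
    P_PIN: float = 3.3e-6    # PIN permeability of anionic auxin, m/s
    D: float = 6.7e-10       # diffusion coefficient in agar, m^2/s
    pH_c: float = 7.2        # cytoplasm pH
    pH_a: float = 5.3        # apoplast pH
    pK: float = 4.8          # auxin dissociation constant
    V: float = -0.120        # membrane voltage, V (inside relative to outside)
    T: float = 295.15        # temperature, K
    F_D: float = 96485.3399  # Faraday constant, C/mol
    R: float = 8.314472      # gas constant, J/(K mol)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        for name in ("P_diff", "P_PIN", "D"):
            if getattr(self, name) < 0:
                raise ValueError(f"permeability {name!r} must be non-negative")

    @property
    def phi(self) -> float:
        """Dimensionless membrane-energy parameter -F_D*V/(R*T)."""
        return phi_value(self.V, self.T, self.F_D, self.R)

    @property
    def fractions_cytoplasm(self) -> "ProtonationFractions":
        return proton_fractions(self.pH_c, self.pK)

    @property
    def fractions_apoplast(self) -> "ProtonationFractions":
        return proton_fractions(self.pH_a, self.pK)


@dataclass(frozen=True)
class ProtonationFractions:
    """Equilibrium partition of auxin into protonated and anionic form."""

    f_H: float
    f_A: float


@dataclass(frozen=True)
class RateConstants:
    """Per-molecule stochastic reaction constants of the eight rule types (1/s).

    ``k1``/``k2``: agar-block -> terminal-apoplast diffusion (source, sink);
    ``k3``: PIN efflux cytoplasm -> downstream apoplast;
    ``k4``/``k5``: passive membrane diffusion apoplast -> upstream / downstream
    cytoplasm; ``k6``: GHK backflux through PIN, apoplast -> upstream
    cytoplasm (the smallest transport rate; the stochastic solver zeroes it by
    default); ``k7``/``k8``: terminal-apoplast -> agar-block diffusion.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float

    def as_tuple(self) -> tuple:
        return (self.k1, self.k2, self.k3, self.k4,
                self.k5, self.k6, self.k7, self.k8)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set: geometry, physiology and initial load.

    ``C`` is the initial number of auxin molecules, all placed in the source
    agar block at t = 0 (the system is closed thereafter).
    """

    geometry: Geometry = field(default_factory=Geometry)
    physiology: Physiology = field(default_factory=Physiology)
    C: int = 12044

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError(f"initial molecule count C must be >= 0, got {self.C}")

    @property
    def initial_source_concentration(self) -> float:
        """Initial source-block concentration C/(L_s*w), number per unit area."""
        g = self.geometry
        return self.C / (g.L_s * g.w)

    @property
    def rate_constants(self) -> RateConstants:
        return rate_constants(self.geometry, self.physiology)


def proton_fractions(pH: float, pK: float) -> ProtonationFractions:
    """Henderson-Hasselbalch partition of auxin at equilibrium.

    The protonated fraction is ``1 / (1 + 10**(pH - pK))``; the anionic
    fraction is its complement.  At pH = pK the two forms are equally
    abundant; the protonated fraction decreases strictly with pH.
    """
    if not (math.isfinite(pH) and math.isfinite(pK)):
        raise ValueError("pH and pK must be finite")
    f_H = 1.0 / (1.0 + 10.0 ** (pH - pK))
    return ProtonationFractions(f_H=f_H, f_A=1.0 - f_H)


def phi_value(V: float, T: float,
              F_D: float = 96485.3399, R: float = 8.314472) -> float:
    """Dimensionless membrane-energy parameter phi = -F_D*V/(R*T)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return -F_D * V / (R * T)


def ghk_factor(phi: float) -> float:
    """GHK rectification factor phi / (1 - exp(-phi)).

    This multiplies the carrier-mediated anionic flux; its reverse (uptake)
    counterpart carries an extra factor exp(-phi).  The removable singularity
    at phi = 0 is replaced by the limit value 1.
    """
    if abs(phi) < _PHI_SINGULARITY_GUARD:
        return 1.0
    if phi < -700.0:  # exp(-phi) would overflow; factor vanishes
        return 0.0
    return phi / -math.expm1(-phi)


def flux_components(c: float, a: float, phys: Physiology) -> tuple:
    """Flux components from a cytoplasm (concentration ``c``) to the
    adjacent downstream apoplast (concentration ``a``).

    Returns ``(J_diff, J_PIN)``:

    * ``J_diff = P_diff * (f_cH * c - f_aH * a)`` -- passive transmembrane
      diffusion of the protonated (neutral) pool, present on every face;
    * ``J_PIN = P_PIN * g(phi) * (f_cA * c - exp(-phi) * f_aA * a)`` with
      ``g(phi) = phi/(1 - exp(-phi))`` -- GHK electrodiffusion of the anionic
      pool through PIN carriers, present on the downstream face only.

    Units are concentration * m/s (flux per unit membrane width).
    """
    if c < 0 or a < 0:
        raise ValueError("concentrations must be non-negative")
    fc = phys.fractions_cytoplasm
    fa = phys.fractions_apoplast
    phi = phys.phi
    J_diff = phys.P_diff * (fc.f_H * c - fa.f_H * a)
    g = ghk_factor(phi)
    J_PIN = phys.P_PIN * g * (fc.f_A * c - math.exp(-phi) * fa.f_A * a)
    return J_diff, J_PIN


def membrane_rates(phys: Physiology) -> dict:
    """Elementary one-way membrane/agar exchange velocities (m/s).

    ``pump``:    P_PIN * g(phi) * f_cA      (cytoplasm -> downstream apoplast)
    ``backflux``: P_PIN * g(phi) * e^-phi * f_aA (apoplast -> upstream cytoplasm)
    ``uptake``:  P_diff * f_aH              (apoplast -> either cytoplasm)
    ``efflux``:  P_diff * f_cH              (cytoplasm -> either apoplast)
    ``agar``:    2 D / L_s                  (agar block <-> terminal apoplast)
    """
    fc = phys.fractions_cytoplasm
    fa = phys.fractions_apoplast
    g = ghk_factor(phys.phi)
    return {
        "pump": phys.P_PIN * g * fc.f_A,
        "backflux": phys.P_PIN * g * math.exp(-phys.phi) * fa.f_A,
        "uptake": phys.P_diff * fa.f_H,
        "efflux": phys.P_diff * fc.f_H,
    }


def agar_exchange_velocity(geom: Geometry, phys: Physiology) -> float:
    """Diffusive exchange velocity 2*D/L_s between a well-mixed agar block
    and the adjacent terminal apoplast (m/s).

    The factor 2/L_s is the inverse of the mean diffusion distance from the
    interior of a well-mixed block of length L_s to its face.
    """
    return 2.0 * phys.D / geom.L_s


def rate_constants(geom: Geometry, phys: Physiology) -> RateConstants:
    """Stochastic reaction constants of rules R1-R8.

    Each constant is the per-molecule jump rate: the one-way exchange
    velocity divided by the length of the donating compartment, so that in
    the large-count limit the mean of the rule system obeys the deterministic
    flux laws exactly.
    """
    if min(geom.l, geom.w, geom.lambda_, geom.L_s) <= 0:
        raise ValueError("degenerate geometry: all lengths must be positive")
    m = membrane_rates(phys)
    q = agar_exchange_velocity(geom, phys)
    return RateConstants(
        k1=q / geom.L_s,            # source block -> apoplast 0
        k2=q / geom.L_s,            # collecting block -> apoplast N
        k3=m["pump"] / geom.l,      # cytoplasm i -> apoplast i (PIN)
        k4=m["uptake"] / geom.lambda_,   # apoplast j -> cytoplasm j
        k5=m["uptake"] / geom.lambda_,   # apoplast j -> cytoplasm j+1
        k6=m["backflux"] / geom.lambda_,  # apoplast i -> cytoplasm i (PIN, reverse)
        k7=q / geom.lambda_,        # apoplast 0 -> source block
        k8=q / geom.lambda_,        # apoplast N -> collecting block
    )


def molecules_from_molar(conc_molar: float, geom: Geometry) -> int:
    """Convert a molar concentration (mol/L) in the source agar block to a
    molecule count, using the block volume L_s*w*w.

    0.1 nM in the default geometry gives 12044 molecules.
    """
    if conc_molar < 0:
        raise ValueError("concentration must be non-negative")
    conc_per_m3 = conc_molar * 1e3
    return int(round(conc_per_m3 * AVOGADRO * geom.source_volume))


def molar_from_molecules(count: float, geom: Geometry) -> float:
    """Inverse of :func:`molecules_from_molar` (continuous-valued)."""
    return count / (AVOGADRO * geom.source_volume) / 1e3


def default_parameters(C: int = 12044, N: int = 20) -> ModelParameters:
    """Parameter set of the reference experiment (published estimates,
    N = 20 cells, 0.1 nM initial load)."""
    return ModelParameters(geometry=Geometry(N=N), physiology=Physiology(), C=C)
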