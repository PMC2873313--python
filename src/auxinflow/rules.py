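"""Instantiation of the stochastic rewriting-rule system.

Each rule moves one molecule from a source compartment to a target
compartment at a per-molecule rate ``k`` (propensity = k * current count in
the source compartment).  The eight canonical rule types are:

====  =======================================  ==================
R1    source block -> apoplast 0               diffusion
R2    collecting block -> apoplast N           diffusion
R3    cytoplasm i -> apoplast i                PIN transport
R4    apoplast j -> cytoplasm j   (j >= 1)     membrane diffusion
R5    apoplast j -> cytoplasm j+1 (j <= N-1)   membrane diffusion
R6    apoplast i -> cytoplasm i   (i >= 1)     PIN transport (reverse)
R7    apoplast 0 -> source block               diffusion
R8    apoplast N -> collecting block           diffusion
====  =======================================  ==================

R6 carries the GHK reverse factor exp(-phi) and is by far the smallest
carrier rate; the stochastic solver zeroes it by default
(``include_pin_backflux=False``) while the deterministic equations keep it.
The passive protonated efflux out of the cytoplasm (smaller still) is absent
from the canonical rule table; ``include_passive_efflux=True`` adds the
corresponding rule pair so the rule system can mirror the full flux law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import layout
from .parameters import ModelParameters, membrane_rates

__all__ = ["Rule", "build_rule_set", "rule_arrays", "drift_matrix"]


@dataclass(frozen=True)
class Rule:
    id: str
    source_compartment: int
    target_compartment: int
    k: float
    process: str


def build_rule_set(params: ModelParameters,
                   include_pin_backflux: bool = False,
                   include_passive_efflux: bool = False) -> list:
    """Instantiate the full rule list for an N-cell file.

    Rule count is 4N + 4 for the canonical table, plus N for the PIN
    backflux rules and 2N for the passive-efflux rules when enabled.
    """
    geom, N = params.geometry, params.geometry.N
    k = params.rate_constants
    ia = lambda j: layout.idx_apoplast(j, N)
    ic = lambda i: layout.idx_cytoplasm(i, N)
    iS, iF = layout.idx_source(N), layout.idx_sink(N)

    rules = [
        Rule("R1", iS, ia(0), k.k1, "diffusion"),
        Rule("R2", iF, ia(N), k.k2, "diffusion"),
        Rule("R7", ia(0), iS, k.k7, "diffusion"),
        Rule("R8", ia(N), iF, k.k8, "diffusion"),
    ]
    for i in range(1, N + 1):
        rules.append(Rule("R3", ic(i), ia(i), k.k3, "PIN transport"))
        rules.append(Rule("R4", ia(i), ic(i), k.k4, "membrane diffusion"))
        rules.append(Rule("R5", ia(i - 1), ic(i), k.k5, "membrane diffusion"))
        if include_pin_backflux:
            rules.append(Rule("R6", ia(i), ic(i), k.k6, "PIN transport"))
    if include_passive_efflux:
        ke = membrane_rates(params.physiology)["efflux"] / geom.l
        for i in range(1, N + 1):
            rules.append(Rule("RD", ic(i), ia(i), ke, "membrane diffusion"))
            rules.append(Rule("RU", ic(i), ia(i - 1), ke, "membrane diffusion"))
    return rules


def rule_arrays(rules: list) -> tuple:
    """Flatten a rule list to (source, target, rate) arrays for the SSA."""
    src = np.array([r.source_compartment for r in rules], dtype=np.int64)
    dst = np.array([r.target_compartment for r in rules], dtype=np.int64)
    kk = np.array([r.k for r in rules], dtype=np.float64)
    return src, dst, kk


def drift_matrix(rules: list, params: ModelParameters) -> np.ndarray:
    """Expected drift of the rule system, expressed on concentrations.

    For counts n, E[dn/dt] = sum_r k_r n_src (e_dst - e_src).  Dividing each
    compartment by its area converts this to the concentration drift matrix;
    for a mean-field-consistent model it equals the ODE coefficient matrix.
    """
    n = layout.n_compartments(params.geometry.N)
    areas = layout.compartment_areas(params.geometry)
    A = np.zeros((n, n))
    for r in rules:
        s, d = r.source_compartment, r.target_compartment
        A[s, s] -= r.k
        A[d, s] += r.k * areas[s] / areas[d]
    return A
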