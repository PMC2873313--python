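"""State-vector layout shared by all solvers.

Compartments are ordered ``[S, a_0, c_1, a_1, ..., c_N, a_N, F]``:
index 0 is the source agar block, odd indices ``1+2j`` are apoplasts
``a_j`` (j = 0..N), even indices ``2i`` are cytoplasms ``c_i`` (i = 1..N),
and the last index is the collecting agar block.
"""

from __future__ import annotations

import numpy as np

from .parameters import Geometry

__all__ = [
    "n_compartments", "idx_source", "idx_sink", "idx_apoplast",
    "idx_cytoplasm", "labels", "compartment_lengths", "compartment_areas",
    "compartment_types",
]


def n_compartments(N: int) -> int:
    return 2 * N + 3


def idx_source(N: int) -> int:
    return 0


def idx_sink(N: int) -> int:
    return 2 * N + 2


def idx_apoplast(j: int, N: int) -> int:
    if not 0 <= j <= N:
        raise IndexError(f"apoplast index {j} out of range 0..{N}")
    return 1 + 2 * j


def idx_cytoplasm(i: int, N: int) -> int:
    if not 1 <= i <= N:
        raise IndexError(f"cytoplasm index {i} out of range 1..{N}")
    return 2 * i


def labels(N: int) -> list:
    out = ["source"]
    for j in range(N):
        out.append(f"apoplast_{j}")
        out.append(f"cytoplasm_{j + 1}")
    out.append(f"apoplast_{N}")
    out.append("sink")
    return out


def compartment_types(N: int) -> list:
    """Coarse type of each compartment: source/sink/cytoplasm/apoplast."""
    return [lab.split("_")[0] for lab in labels(N)]


def compartment_lengths(geom: Geometry) -> np.ndarray:
    """In-file length of each compartment (m), in state order."""
    N = geom.N
    out = np.empty(n_compartments(N))
    out[idx_source(N)] = geom.L_s
    out[idx_sink(N)] = geom.L_s
    for j in range(N + 1):
        out[idx_apoplast(j, N)] = geom.lambda_
    for i in range(1, N + 1):
        out[idx_cytoplasm(i, N)] = geom.l
    return out


def compartment_areas(geom: Geometry) -> np.ndarray:
    """2-D area of each compartment (m^2): length * width.

    Molecule count = per-area concentration * area.
    """
    return compartment_lengths(geom) * geom.w
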