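"""Inner loop of the direct-method stochastic simulation algorithm.

Compiled with numba when available; the pure-Python path is identical and
is exercised automatically if compilation is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - environment dependent
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f
        return wrap


@njit(cache=True)
def ssa_core(counts0, src, dst, kk, t_end, dt_record, seed, sink_idx,
             stop_at_first):
    """Direct-method SSA over the flattened rule union.

    Records the state on the uniform grid ``i * dt_record`` (snapshot of the
    state holding at that instant) and returns the exact jump time of the
    first firing that increments ``sink_idx`` (inf if none).  Propensities
    are refreshed only for rules touching the two compartments changed by a
    firing.
    """
    np.random.seed(seed)
    n = counts0.copy()
    nr = kk.shape[0]
    a = np.empty(nr)
    for r in range(nr):
        a[r] = kk[r] * n[src[r]]
    atot = a.sum()

    nrec = int(t_end / dt_record) + 1
    out = np.zeros((nrec, n.shape[0]), dtype=np.int64)
    out[0] = n
    irec = 1
    t = 0.0
    first = np.inf
    nev = 0
    while True:
        if atot <= 0.0:
            break
        t += -np.log(np.random.random()) / atot
        while irec < nrec and irec * dt_record <= t:
            out[irec] = n
            irec += 1
        if t >= t_end:
            break
        u = np.random.random() * atot
        s = 0.0
        r = 0
        for r in range(nr):
            s += a[r]
            if s >= u:
                break
        n[src[r]] -= 1
        n[dst[r]] += 1
        nev += 1
        cs = src[r]
        cd = dst[r]
        for r2 in range(nr):
            if src[r2] == cs or src[r2] == cd:
                a[r2] = kk[r2] * n[src[r2]]
        atot = a.sum()
        if cd == sink_idx and first == np.inf:
            first = t
            if stop_at_first:
                break
    while irec < nrec:
        out[irec] = n
        irec += 1
    return out, first, nev
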