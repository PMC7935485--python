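"""Numba kernel for chaining per-sample propagator matrices.

Kept in its own module so the jit compile happens only when the fast
grid-propagation path is first used.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def step_chain(props, idx, w, p0, zero, prop_zero):
    """Sequentially apply interpolated propagators to an occupancy vector.

    props : (G, 13, 13) propagator grid
    idx   : (n-1,) lower grid index per step
    w     : (n-1,) interpolation weight per step
    p0    : (13,) initial occupancy
    zero  : (n-1,) bool, step has exactly zero concentration
    prop_zero : (13, 13) propagator at zero concentration

    Returns the (n, 13) occupancy trajectory.
    """
    nstep = idx.shape[0]
    ns = p0.shape[0]
    out = np.empty((nstep + 1, ns))
    p = p0.copy()
    out[0] = p
    pn = np.empty(ns)
    for i in range(nstep):
        if zero[i]:
            for r in range(ns):
                acc = 0.0
                for c in range(ns):
                    acc += prop_zero[r, c] * p[c]
                pn[r] = acc
        else:
            m0 = props[idx[i]]
            m1 = props[idx[i] + 1]
            wi = w[i]
            for r in range(ns):
                acc = 0.0
                for c in range(ns):
                    acc += ((1.0 - wi) * m0[r, c] + wi * m1[r, c]) * p[c]
                pn[r] = acc
        for r in range(ns):
            p[r] = pn[r]
        out[i + 1] = p
    return out
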