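"""Numba kernels for the Glauber dynamics inner loop."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def count_triplet_tables(bits, trip, lag, counts):  # pragma: no cover
    """Accumulate 16-cell lagged joint counts for each (target, j, k) triplet.

    ``bits`` is the (T, n) 0/1 spin array, ``trip`` an (M, 3) index array,
    ``counts`` an (M, 16) int64 accumulator updated in place.
    """
    T = bits.shape[0]
    m = trip.shape[0]
    for a in range(m):
        tgt = trip[a, 0]
        j = trip[a, 1]
        k = trip[a, 2]
        for t in range(T - lag):
            code = (
                bits[t + lag, tgt] * 8
                + bits[t, tgt] * 4
                + bits[t, j] * 2
                + bits[t, k]
            )
            counts[a, code] += 1


@njit(cache=True)
def glauber_run(J, state, beta, n_discard, n_collect, seed, out):  # pragma: no cover
    """Run Glauber sweeps in place; record one row per sweep after discard.

    ``J`` is the (n, n) float64 coupling matrix, ``state`` an int8 vector of
    +/-1 updated in place, ``out`` an (n_collect, n) int8 buffer.  Within a
    sweep every spin is visited exactly once, in a fresh random permutation,
    and flips with the Glauber probability 1 / (1 + exp(beta * dE)) evaluated
    on the current (sequentially updated) configuration.
    """
    np.random.seed(seed)
    n = state.shape[0]
    total = n_discard + n_collect
    for sweep in range(total):
        order = np.random.permutation(n)
        for idx in range(n):
            i = order[idx]
            h = 0.0
            for j in range(n):
                h += J[i, j] * state[j]
            d_e = 2.0 * state[i] * h
            x = beta * d_e
            if x > 500.0:
                p = 0.0
            elif x < -500.0:
                p = 1.0
            else:
                p = 1.0 / (1.0 + np.exp(x))
            if np.random.random() < p:
                state[i] = -state[i]
        if sweep >= n_discard:
            out[sweep - n_discard, :] = state
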