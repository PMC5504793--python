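"""Numba kernel for the single-site Gibbs sweep over marker effects.

The sweep updates each marker effect from its full conditional given the
current residual vector, with an optional spike-and-slab indicator step
(Bayes B / Bayes Cpi). All random numbers are pre-drawn by the caller from
a seeded numpy Generator, so chains are reproducible and the kernel is
draw-order deterministic.
"""

import numpy as np
from numba import njit

__all__ = ["marker_sweep"]


@njit(cache=True)
def marker_sweep(Z, zsq, m, e, incl, s2m, s2e, log_odds_excl, ssvs,
                 zdraw, udraw):
    """One Gibbs sweep over all marker effects, updating ``m``, ``e`` and
    ``incl`` in place.

    Z          : (n, p) centered dosage matrix, Fortran order
    zsq        : (p,) column sums of squares
    m          : (p,) current effects
    e          : (n,) residual y - Xb - Zm
    incl       : (p,) inclusion indicators (int8)
    s2m        : (p,) per-marker prior variance of the effect
    s2e        : residual variance
    log_odds_excl : log(pi / (1 - pi)) with pi = prior exclusion probability
    ssvs       : 1 for point-mass-at-zero methods, else 0
    zdraw, udraw : (p,) standard normal / uniform draws for this sweep
    """
    n, p = Z.shape
    for j in range(p):
        old = m[j]
        if zsq[j] == 0.0:
            m[j] = 0.0
            incl[j] = 0 if ssvs == 1 else 1
            continue
        rhs = 0.0
        for i in range(n):
            rhs += Z[i, j] * e[i]
        rhs += zsq[j] * old
        c = zsq[j] + s2e / s2m[j]
        mean = rhs / c
        if ssvs == 1:
            # log Bayes factor of inclusion vs the point mass at zero
            logbf = 0.5 * np.log(s2e / (s2m[j] * c)) \
                + rhs * rhs / (2.0 * s2e * c)
            t = log_odds_excl - logbf
            if t > 35.0:
                p_in = 0.0
            elif t < -35.0:
                p_in = 1.0
            else:
                p_in = 1.0 / (1.0 + np.exp(t))
            if udraw[j] < p_in:
                new = mean + np.sqrt(s2e / c) * zdraw[j]
                incl[j] = 1
            else:
                new = 0.0
                incl[j] = 0
        else:
            new = mean + np.sqrt(s2e / c) * zdraw[j]
            incl[j] = 1
        diff = old - new
        if diff != 0.0:
            for i in range(n):
                e[i] += Z[i, j] * diff
        m[j] = new
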