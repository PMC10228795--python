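"""Compiled inner loop for the packed RHS.

The pure-numpy implementation in :mod:`.model` is the readable reference;
this kernel exists because parameter-space scans call the RHS millions of
times.  A property test pins the two implementations to each other.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco(args[0]) if args and callable(args[0]) else deco


@njit(cache=True)
def rhs_packed(y, t, p, wound, inv_dx2, mutual, reflect):  # pragma: no cover - exercised via wrapper
    """dy/dt for the interleaved state vector [EIG0, JNK0, JAK0, UPD0, EIG1, ...].

    ``p`` follows PARAM_NAMES order.  States are clipped at 0 inside Hill
    powers so fractional exponents stay defined on solver undershoots.
    """
    n = wound.size
    out = np.empty(4 * n)
    gamma = p[0]
    kd_jnk = p[1]; kd_jak = p[2]; kd_upd = p[3]
    ka_eig = p[4]; ka_jnk = p[5]; ka_jak = p[6]; ka_upd = p[7]
    n1 = p[15]; n2 = p[16]; n3 = p[17]; n4 = p[18]; ni1 = p[19]; ni2 = p[20]
    km_eig_n = p[8] ** n1; km_jnk_n = p[9] ** n2; km_jak_n = p[10] ** n3; km_upd_n = p[11] ** n4
    ki_jak_by_jnk = p[12] ** ni2
    ki_jnk_by_jak = p[13] ** ni1
    d = p[14]
    for i in range(n):
        eig = max(y[4 * i], 0.0)
        jnk = max(y[4 * i + 1], 0.0)
        jak = max(y[4 * i + 2], 0.0)
        upd = max(y[4 * i + 3], 0.0)

        h1 = jnk ** n1
        d_eig = gamma * (wound[i] - eig + ka_eig * h1 / (km_eig_n + h1))
        h2 = eig ** n2
        d_jnk = gamma * (1.0 - kd_jnk * jnk
                         + ka_jnk * h2 / ((km_jnk_n + h2) * (1.0 + ki_jnk_by_jak * jak ** ni1)))
        h3 = jak ** n3
        den = km_jak_n + h3
        if mutual:
            den = den * (1.0 + ki_jak_by_jnk * jnk ** ni2)
        d_jak = gamma * (1.0 - kd_jak * jak + ka_jak * upd * h3 / den)
        h4 = jnk ** n4
        d_upd = gamma * (1.0 - kd_upd * upd + ka_upd * h4 / (km_upd_n + h4))

        # diffusion of EIG and UPD only
        if i > 0:
            left_e = max(y[4 * (i - 1)], 0.0)
            left_u = max(y[4 * (i - 1) + 3], 0.0)
        else:
            left_e = eig if reflect else 0.0
            left_u = upd if reflect else 0.0
        if i < n - 1:
            right_e = max(y[4 * (i + 1)], 0.0)
            right_u = max(y[4 * (i + 1) + 3], 0.0)
        else:
            right_e = eig if reflect else 0.0
            right_u = upd if reflect else 0.0
        d_eig += (left_e - 2.0 * eig + right_e) * inv_dx2
        d_upd += d * (left_u - 2.0 * upd + right_u) * inv_dx2

        out[4 * i] = d_eig
        out[4 * i + 1] = d_jnk
        out[4 * i + 2] = d_jak
        out[4 * i + 3] = d_upd
    return out
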