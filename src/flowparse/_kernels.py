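"""Fused elementwise update kernels.

The shunting Euler updates and the synaptic-depression update touch multi-
million-element float32 tensors every ~3 ms model step; fusing them into
single-pass numba kernels keeps the integration memory-bound rather than
temporary-bound.  Pure-numpy fallbacks keep the package importable without a
working numba.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _shunt0_flat(A, E, decay, bound, dt):
        out = np.empty_like(A)
        for k in range(A.size):
            a = A[k]
            out[k] = a + dt * (-decay * a + (bound - a) * E[k])
        return out

    @njit(cache=True, fastmath=True)
    def _shunt_clip_flat(A, E, I, decay, bound, dt):
        out = np.empty_like(A)
        for k in range(A.size):
            a = A[k]
            v = a + dt * (-decay * a + (bound - a) * E[k] - a * I[k])
            if v < 0.0:
                v = 0.0
            elif v > bound:
                v = bound
            out[k] = v
        return out

    @njit(cache=True, fastmath=True)
    def _shunt_clip2_flat(A, E, I, F, fscale, decay, bound, dt):
        """As _shunt_clip_flat with inhibition I + fscale * F."""
        out = np.empty_like(A)
        for k in range(A.size):
            a = A[k]
            inh = I[k] + fscale * F[k]
            v = a + dt * (-decay * a + (bound - a) * E[k] - a * inh)
            if v < 0.0:
                v = 0.0
            elif v > bound:
                v = bound
            out[k] = v
        return out

    @njit(cache=True, fastmath=True)
    def _depress_flat(eff, N, tau, rate, dt):
        trans = np.empty_like(eff)
        new = np.empty_like(eff)
        for k in range(eff.size):
            e = eff[k]
            trans[k] = e * N[k]
            v = e + dt * ((1.0 - e) / tau - rate * e * N[k])
            if v < 0.0:
                v = 0.0
            elif v > 1.0:
                v = 1.0
            new[k] = v
        return trans, new


def _flat32(x):
    return np.ascontiguousarray(x, dtype=np.float32).reshape(-1)


def shunt_leaky(A, E, decay, bound, dt):
    """A + dt*(-decay*A + (bound-A)*E), fused."""
    if _HAVE_NUMBA:
        out = _shunt0_flat(_flat32(A), _flat32(E),
                           np.float32(decay), np.float32(bound),
                           np.float32(dt))
        return out.reshape(np.shape(A))
    return A + dt * (-decay * A + (bound - A) * E)


def shunt_inhibited(A, E, I, decay, bound, dt, F=None, fscale=1.0):
    """Shunting on-center/off-surround Euler step, clipped to [0, bound].

    Total inhibition is I (+ fscale * F when F is given).
    """
    if _HAVE_NUMBA:
        if F is None:
            out = _shunt_clip_flat(_flat32(A), _flat32(E), _flat32(I),
                                   np.float32(decay), np.float32(bound),
                                   np.float32(dt))
        else:
            out = _shunt_clip2_flat(_flat32(A), _flat32(E), _flat32(I),
                                    _flat32(F), np.float32(fscale),
                                    np.float32(decay), np.float32(bound),
                                    np.float32(dt))
        return out.reshape(np.shape(A))
    inh = I if F is None else I + fscale * F
    out = A + dt * (-decay * A + (bound - A) * E - A * inh)
    return np.clip(out, 0.0, bound)


def depress_fused(efficacy, N, tau, rate, dt):
    """Depressing-synapse transmission + efficacy update, fused."""
    if _HAVE_NUMBA:
        trans, new = _depress_flat(_flat32(efficacy), _flat32(N),
                                   np.float32(tau), np.float32(rate),
                                   np.float32(dt))
        shape = np.shape(efficacy)
        return trans.reshape(shape), new.reshape(shape)
    trans = efficacy * N
    new = efficacy + dt * ((1.0 - efficacy) / tau - rate * efficacy * N)
    return trans, np.clip(new, 0.0, 1.0)
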