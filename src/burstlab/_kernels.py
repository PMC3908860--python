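"""Compiled right-hand sides for the single cell, the frozen fast subsystem
and the synaptically coupled chain.

The kernels consume the flat parameter vector produced by
:meth:`burstlab.model.NeuronParams.pack`; its layout is fixed here and in
that method.  If numba is unavailable the pure-Python definitions are used
unchanged (they are written in scalar numpy-free style so both paths give
bit-identical results).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

# indices into the packed parameter vector
(G_NA, G_K2, G_H, G_LEAK, E_NA, E_K, E_H, E_LEAK, CAP, I_POL,
 K_MNA, TH_MNA, K_HNA, TH_HNA, TAU_HNA, K_MK2, TH_K2, TAU_MK2,
 K_MH, TH_H, TMH0, TMH1, TMHK, TMHT, K_MH2) = range(25)


@njit(cache=True)
def cell_rhs(y, p, i_ext, out):
    """dy/dt of the 4-D single cell; y = (V, h_Na, m_K2, m_h)."""
    v, h_na, m_k2, m_h = y[0], y[1], y[2], y[3]
    m_na = 1.0 / (1.0 + math.exp(-p[K_MNA] * (v + p[TH_MNA])))
    i_na = p[G_NA] * m_na * m_na * m_na * h_na * (v - p[E_NA])
    i_k2 = p[G_K2] * m_k2 * m_k2 * (v - p[E_K])
    i_h = p[G_H] * m_h * m_h * (v - p[E_H])
    i_leak = p[G_LEAK] * (v - p[E_LEAK])
    out[0] = (-i_na - i_k2 - i_h - i_leak + p[I_POL] + i_ext) / p[CAP]
    hinf = 1.0 / (1.0 + math.exp(p[K_HNA] * (v + p[TH_HNA])))
    out[1] = (hinf - h_na) / p[TAU_HNA]
    minf = 1.0 / (1.0 + math.exp(-p[K_MK2] * (v + p[TH_K2])))
    out[2] = (minf - m_k2) / p[TAU_MK2]
    x_h = v + p[TH_H]
    mhinf = 1.0 / (1.0 + 2.0 * math.exp(p[K_MH] * x_h) + math.exp(p[K_MH2] * x_h))
    tau_mh = p[TMH0] + p[TMH1] / (1.0 + math.exp(-p[TMHK] * (v + p[TMHT])))
    out[3] = (mhinf - m_h) / tau_mh
    return out


@njit(cache=True)
def fast_rhs(y, p, m_k2, out):
    """dy/dt of the 3-D fast subsystem (V, h_Na, m_h) with m_K2 frozen."""
    v, h_na, m_h = y[0], y[1], y[2]
    m_na = 1.0 / (1.0 + math.exp(-p[K_MNA] * (v + p[TH_MNA])))
    i_na = p[G_NA] * m_na * m_na * m_na * h_na * (v - p[E_NA])
    i_k2 = p[G_K2] * m_k2 * m_k2 * (v - p[E_K])
    i_h = p[G_H] * m_h * m_h * (v - p[E_H])
    i_leak = p[G_LEAK] * (v - p[E_LEAK])
    out[0] = (-i_na - i_k2 - i_h - i_leak + p[I_POL]) / p[CAP]
    hinf = 1.0 / (1.0 + math.exp(p[K_HNA] * (v + p[TH_HNA])))
    out[1] = (hinf - h_na) / p[TAU_HNA]
    x_h = v + p[TH_H]
    mhinf = 1.0 / (1.0 + 2.0 * math.exp(p[K_MH] * x_h) + math.exp(p[K_MH2] * x_h))
    tau_mh = p[TMH0] + p[TMH1] / (1.0 + math.exp(-p[TMHK] * (v + p[TMHT])))
    out[2] = (mhinf - m_h) / tau_mh
    return out


@njit(cache=True)
def chain_rhs(y, p, w, e_syn, k_s, th_s, tau_s, out):
    """dy/dt of an N-cell chain with graded inhibitory synapses.

    Layout: y[4*i : 4*i+4] = (V, h_Na, m_K2, m_h) of cell i, followed by the
    N synaptic activations s_i.  w[j, i] is the conductance (nS) of the
    synapse from presynaptic cell j onto postsynaptic cell i.
    """
    n = w.shape[0]
    for i in range(n):
        b = 4 * i
        v, h_na, m_k2, m_h = y[b], y[b + 1], y[b + 2], y[b + 3]
        m_na = 1.0 / (1.0 + math.exp(-p[K_MNA] * (v + p[TH_MNA])))
        i_na = p[G_NA] * m_na * m_na * m_na * h_na * (v - p[E_NA])
        i_k2 = p[G_K2] * m_k2 * m_k2 * (v - p[E_K])
        i_h = p[G_H] * m_h * m_h * (v - p[E_H])
        i_leak = p[G_LEAK] * (v - p[E_LEAK])
        i_syn = 0.0
        for j in range(n):
            if w[j, i] != 0.0:
                i_syn += w[j, i] * y[4 * n + j] * (v - e_syn)
        out[b] = (-i_na - i_k2 - i_h - i_leak - i_syn + p[I_POL]) / p[CAP]
        hinf = 1.0 / (1.0 + math.exp(p[K_HNA] * (v + p[TH_HNA])))
        out[b + 1] = (hinf - h_na) / p[TAU_HNA]
        minf = 1.0 / (1.0 + math.exp(-p[K_MK2] * (v + p[TH_K2])))
        out[b + 2] = (minf - m_k2) / p[TAU_MK2]
        x_h = v + p[TH_H]
        mhinf = 1.0 / (1.0 + 2.0 * math.exp(p[K_MH] * x_h) + math.exp(p[K_MH2] * x_h))
        tau_mh = p[TMH0] + p[TMH1] / (1.0 + math.exp(-p[TMHK] * (v + p[TMHT])))
        out[b + 3] = (mhinf - m_h) / tau_mh
    for j in range(n):
        v_pre = y[4 * j]
        s_inf = 1.0 / (1.0 + math.exp(-k_s * (v_pre + th_s)))
        out[4 * n + j] = (s_inf - y[4 * n + j]) / tau_s
    return out


def warmup() -> None:
    """Trigger JIT compilation of all kernels (cheap no-op afterwards)."""
    p = np.zeros(25)
    p[CAP] = 1.0
    p[TAU_HNA] = p[TAU_MK2] = p[TMH0] = 1.0
    cell_rhs(np.zeros(4), p, 0.0, np.zeros(4))
    fast_rhs(np.zeros(3), p, 0.0, np.zeros(3))
    w = np.zeros((2, 2))
    chain_rhs(np.zeros(10), p, w, 0.0, 1.0, 0.0, 1.0, np.zeros(10))
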