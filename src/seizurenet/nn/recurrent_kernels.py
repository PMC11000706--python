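"""Numba-compiled recurrent cores (forward and BPTT) for LSTM and GRU.

Arrays are time-major, ``(T, B, ...)``, float32.  Input projections
(``x @ Wx + b``) are precomputed outside the time loop as one large matrix
product; the kernels carry only the hidden-state recurrence: one BLAS ``dot``
per step plus a fused elementwise pass (sigmoid/tanh written via ``exp`` —
markedly faster than numba's scalar ``tanh``).  The forward kernels store
every activation the backward pass needs, so BPTT is transcendental-free.

Gate order: LSTM (input, forget, cell, output); GRU (reset, update) with a
separate candidate projection, reset applied to the previous hidden state
before the candidate's recurrent product (the classic formulation).
"""
from __future__ import annotations

import numpy as np
from numba import njit

F1 = np.float32(1.0)
F2 = np.float32(2.0)


@njit(cache=False, fastmath=True)
def lstm_forward(xg, wh):
    """Run an LSTM over precomputed input projections.

    Parameters
    ----------
    xg : (T, B, 4H) float32
        ``x_t @ Wx + b`` for every step.
    wh : (H, 4H) float32
        Recurrent weights.

    Returns
    -------
    gates : (T, B, 4H) post-activation gate values (i, f, g, o)
    cells : (T, B, H) cell states
    tanhc : (T, B, H) tanh of the cell states
    hs : (T, B, H) hidden states (the layer output)
    """
    T, B, G = xg.shape
    H = G // 4
    gates = np.empty((T, B, G), dtype=np.float32)
    cells = np.empty((T, B, H), dtype=np.float32)
    tanhc = np.empty((T, B, H), dtype=np.float32)
    hs = np.empty((T, B, H), dtype=np.float32)
    h = np.zeros((B, H), dtype=np.float32)
    c = np.zeros((B, H), dtype=np.float32)
    for t in range(T):
        pre = xg[t] + np.dot(h, wh)
        for b in range(B):
            for k in range(H):
                i = F1 / (F1 + np.exp(-pre[b, k]))
                f = F1 / (F1 + np.exp(-pre[b, H + k]))
                g = F1 - F2 / (np.exp(F2 * pre[b, 2 * H + k]) + F1)
                o = F1 / (F1 + np.exp(-pre[b, 3 * H + k]))
                cv = f * c[b, k] + i * g
                tc = F1 - F2 / (np.exp(F2 * cv) + F1)
                c[b, k] = cv
                h[b, k] = o * tc
                gates[t, b, k] = i
                gates[t, b, H + k] = f
                gates[t, b, 2 * H + k] = g
                gates[t, b, 3 * H + k] = o
                cells[t, b, k] = cv
                tanhc[t, b, k] = tc
                hs[t, b, k] = h[b, k]
    return gates, cells, tanhc, hs


@njit(cache=False, fastmath=True)
def lstm_backward(dh_out, gates, cells, tanhc, hs, wh):
    """BPTT for :func:`lstm_forward`.

    Parameters
    ----------
    dh_out : (T, B, H) gradient w.r.t. the hidden-state outputs.

    Returns
    -------
    dxg : (T, B, 4H) gradient w.r.t. the precomputed input projections
    dwh : (H, 4H) gradient w.r.t. the recurrent weights
    """
    T, B, H = dh_out.shape
    dxg = np.empty((T, B, 4 * H), dtype=np.float32)
    dwh = np.zeros(wh.shape, dtype=np.float32)
    whT = wh.T.copy()
    dh = np.zeros((B, H), dtype=np.float32)
    dc = np.zeros((B, H), dtype=np.float32)
    dpre = np.empty((B, 4 * H), dtype=np.float32)
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for k in range(H):
                i = gates[t, b, k]
                f = gates[t, b, H + k]
                g = gates[t, b, 2 * H + k]
                o = gates[t, b, 3 * H + k]
                tc = tanhc[t, b, k]
                dhv = dh[b, k] + dh_out[t, b, k]
                dcv = dc[b, k] + dhv * o * (F1 - tc * tc)
                c_prev = cells[t - 1, b, k] if t > 0 else np.float32(0.0)
                dpre[b, k] = dcv * g * i * (F1 - i)
                dpre[b, H + k] = dcv * c_prev * f * (F1 - f)
                dpre[b, 2 * H + k] = dcv * i * (F1 - g * g)
                dpre[b, 3 * H + k] = dhv * tc * o * (F1 - o)
                dc[b, k] = dcv * f
        dxg[t] = dpre
        dh = np.dot(dpre, whT)
        if t > 0:
            dwh += np.dot(hs[t - 1].T, dpre)
    return dxg, dwh


@njit(cache=False, fastmath=True)
def gru_forward(xrz, xn, urz, un):
    """Run a GRU over precomputed input projections.

    ``xrz`` holds ``x @ Wrz + brz`` (reset/update gates, (T, B, 2H)); ``xn``
    holds ``x @ Wn + bn`` (candidate, (T, B, H)).

    Returns
    -------
    rz : (T, B, 2H) post-activation reset/update gates
    ns : (T, B, H) candidate activations
    hs : (T, B, H) hidden states (the layer output)
    """
    T, B, H = xn.shape
    rz = np.empty((T, B, 2 * H), dtype=np.float32)
    ns = np.empty((T, B, H), dtype=np.float32)
    hs = np.empty((T, B, H), dtype=np.float32)
    h = np.zeros((B, H), dtype=np.float32)
    rh = np.empty((B, H), dtype=np.float32)
    for t in range(T):
        prerz = xrz[t] + np.dot(h, urz)
        for b in range(B):
            for k in range(H):
                r = F1 / (F1 + np.exp(-prerz[b, k]))
                rz[t, b, k] = r
                rz[t, b, H + k] = F1 / (F1 + np.exp(-prerz[b, H + k]))
                rh[b, k] = r * h[b, k]
        pren = xn[t] + np.dot(rh, un)
        for b in range(B):
            for k in range(H):
                n = F1 - F2 / (np.exp(F2 * pren[b, k]) + F1)
                z = rz[t, b, H + k]
                h[b, k] = z * h[b, k] + (F1 - z) * n
                ns[t, b, k] = n
                hs[t, b, k] = h[b, k]
    return rz, ns, hs


@njit(cache=False, fastmath=True)
def gru_backward(dh_out, rz, ns, hs, urz, un):
    """BPTT for :func:`gru_forward`.

    Returns
    -------
    dxrz : (T, B, 2H) gradient w.r.t. the gate input projections
    dxn : (T, B, H) gradient w.r.t. the candidate input projection
    durz : (H, 2H) gradient w.r.t. the gate recurrent weights
    dun : (H, H) gradient w.r.t. the candidate recurrent weights
    """
    T, B, H = dh_out.shape
    dxrz = np.empty((T, B, 2 * H), dtype=np.float32)
    dxn = np.empty((T, B, H), dtype=np.float32)
    durz = np.zeros(urz.shape, dtype=np.float32)
    dun = np.zeros(un.shape, dtype=np.float32)
    urzT = urz.T.copy()
    unT = un.T.copy()
    dh = np.zeros((B, H), dtype=np.float32)
    dn = np.empty((B, H), dtype=np.float32)
    drz_pre = np.empty((B, 2 * H), dtype=np.float32)
    rh = np.empty((B, H), dtype=np.float32)
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for k in range(H):
                z = rz[t, b, H + k]
                n = ns[t, b, k]
                h_prev = hs[t - 1, b, k] if t > 0 else np.float32(0.0)
                dhv = dh[b, k] + dh_out[t, b, k]
                drz_pre[b, H + k] = dhv * (h_prev - n) * z * (F1 - z)
                dn[b, k] = dhv * (F1 - z) * (F1 - n * n)
                dh[b, k] = dhv * z
        drh = np.dot(dn, unT)
        for b in range(B):
            for k in range(H):
                r = rz[t, b, k]
                h_prev = hs[t - 1, b, k] if t > 0 else np.float32(0.0)
                drz_pre[b, k] = drh[b, k] * h_prev * r * (F1 - r)
                dh[b, k] += drh[b, k] * r
                rh[b, k] = r * h_prev
        dxrz[t] = drz_pre
        dxn[t] = dn
        dh += np.dot(drz_pre, urzT)
        if t > 0:
            durz += np.dot(hs[t - 1].T, drz_pre)
            dun += np.dot(rh.T, dn)
    return dxrz, dxn, durz, dun
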