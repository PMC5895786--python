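"""Compiled inner loop for single-entry SGD updates.

The update math mirrors the block-level :func:`epitensor.training.adam_nag_step`
exactly (same Nadam formulation, same schedule); it is specialized here to
row-at-a-time updates over flattened training entries so that millions of
updates run in compiled code. All gradients for one entry are evaluated at
the pre-update parameter values.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _row_vec_update(row, grad, m, v, t, p,
                    eta, beta1, phi_eta, phi_b1, beta2, eps):
    """In-place Nadam update of one factor row; returns (t_new, p_new)."""
    t_new = t + 1.0
    eta_t = eta * phi_eta ** (t_new - 1.0)
    b1_t = beta1 * phi_b1 ** (t_new - 1.0)
    b1_next = beta1 * phi_b1 ** t_new
    p_new = p * b1_t
    denom = 1.0 - p_new
    if denom <= 0.0:
        denom = eps
    bc2 = 1.0 - beta2 ** t_new
    for l in range(row.shape[0]):
        gl = grad[l]
        m[l] = b1_t * m[l] + (1.0 - b1_t) * gl
        v[l] = beta2 * v[l] + (1.0 - beta2) * gl * gl
        m_hat = m[l] / denom
        g_hat = gl / denom
        v_hat = v[l] / bc2
        row[l] -= eta_t * (b1_next * m_hat + (1.0 - b1_t) * g_hat) / (np.sqrt(v_hat) + eps)
    return t_new, p_new


@njit(cache=True)
def _scalar_update(x, grad, m, v, t, p,
                   eta, beta1, phi_eta, phi_b1, beta2, eps):
    """Nadam update of one bias entry; returns (x_new, m, v, t_new, p_new)."""
    t_new = t + 1.0
    eta_t = eta * phi_eta ** (t_new - 1.0)
    b1_t = beta1 * phi_b1 ** (t_new - 1.0)
    b1_next = beta1 * phi_b1 ** t_new
    p_new = p * b1_t
    denom = 1.0 - p_new
    if denom <= 0.0:
        denom = eps
    m = b1_t * m + (1.0 - b1_t) * grad
    v = beta2 * v + (1.0 - beta2) * grad * grad
    m_hat = m / denom
    g_hat = grad / denom
    v_hat = v / (1.0 - beta2 ** t_new)
    x -= eta_t * (b1_next * m_hat + (1.0 - b1_t) * g_hat) / (np.sqrt(v_hat) + eps)
    return x, m, v, t_new, p_new


@njit(cache=True)
def sgd_entry_updates(
    C, A, G, c, a, g,
    mC, vC, tC, pC, mA, vA, tA, pA, mG, vG, tG, pG,
    mc, vc, tc, pc, ma, va, ta, pa, mg, vg, tg, pg,
    reg_C, reg_A, reg_G,
    jj, kk, ii, dd, order,
    eta, beta1, phi_eta, phi_b1, beta2, eps,
    update_ca, update_g,
):
    """Visit entries in the given order, applying single-entry updates."""
    L = C.shape[1]
    gradC = np.empty(L)
    gradA = np.empty(L)
    gradG = np.empty(L)
    for n in order:
        j = jj[n]
        k = kk[n]
        i = ii[n]
        pred = c[j] + a[k] + g[i]
        for l in range(L):
            pred += C[j, l] * A[k, l] * G[i, l]
        e2 = 2.0 * (pred - dd[n])
        # all gradients at the pre-update point
        if update_ca:
            for l in range(L):
                gradC[l] = e2 * A[k, l] * G[i, l] + reg_C[j] * C[j, l]
                gradA[l] = e2 * C[j, l] * G[i, l] + reg_A[k] * A[k, l]
        if update_g:
            for l in range(L):
                gradG[l] = e2 * C[j, l] * A[k, l] + reg_G[i] * G[i, l]
        if update_ca:
            tC[j], pC[j] = _row_vec_update(
                C[j], gradC, mC[j], vC[j], tC[j], pC[j],
                eta, beta1, phi_eta, phi_b1, beta2, eps)
            c[j], mc[j], vc[j], tc[j], pc[j] = _scalar_update(
                c[j], e2, mc[j], vc[j], tc[j], pc[j],
                eta, beta1, phi_eta, phi_b1, beta2, eps)
            tA[k], pA[k] = _row_vec_update(
                A[k], gradA, mA[k], vA[k], tA[k], pA[k],
                eta, beta1, phi_eta, phi_b1, beta2, eps)
            a[k], ma[k], va[k], ta[k], pa[k] = _scalar_update(
                a[k], e2, ma[k], va[k], ta[k], pa[k],
                eta, beta1, phi_eta, phi_b1, beta2, eps)
        if update_g:
            tG[i], pG[i] = _row_vec_update(
                G[i], gradG, mG[i], vG[i], tG[i], pG[i],
                eta, beta1, phi_eta, phi_b1, beta2, eps)
            g[i], mg[i], vg[i], tg[i], pg[i] = _scalar_update(
                g[i], e2, mg[i], vg[i], tg[i], pg[i],
                eta, beta1, phi_eta, phi_b1, beta2, eps)
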