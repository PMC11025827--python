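"""JIT-compiled fixed-step Euler drivers for the coupled model.

This module is the fast inner loop only.  The readable, vectorized
reference formulas live in :mod:`cell_model`, :mod:`lv_geometry` and
:mod:`circulation`; the test suite asserts that one kernel step equals the
composition of those reference operations.

State vector layout (10,):
    0 [TSCa3]  1 [TSCa3~]  2 [TSCa3*]  3 [TS*]  4 [TS~]   (uM)
    5 X_p      6 X_w                                       (um)
    7 [Ca2+]                                               (uM)
    8 V_lv     9 V_a                                       (mL)
"""

from __future__ import annotations

import numpy as np
from numba import njit

# state indices
(S_TSCA3, S_TSCA3W, S_TSCA3P, S_TSP, S_TSW, S_XP, S_XW, S_CA, S_VLV, S_VA) = range(10)

# parameter vector layout
(
    IA_P, IA_W, IH_PR, IH_WR, IB, IY_B, IY_C, IY_D, IY_P, IY_Q, IY_R, IY_V,
    IY_VD, IZ_A, IZ_B, IZ_P, IZ_Q, IZ_R, IL_C, IK_GAMMA, IGAMMA, IF,
    IR_GAUSS, IL_A, ITS_TOT, ICA_STOICH, IQ_M, IT_1, IQ_PUMP_REST, IK_P,
    IK_M, IK_PE, IK_PL, ID_PAS, IL_0, IK_R, IK_V, IK_L, IL_B, IK_S, IK_U,
    IH_LV, IP_E1, IP_E2, IR_PV, IR_LO, IR_OUT, IC_A, ICLAMP_EN, ICLAMP_P,
    ICLAMP_VA, ICLAMP_HOLD,
) = range(52)
N_PARAMS = 52


def pack_params(mp) -> np.ndarray:
    """Flatten a ModelParams bundle into the kernel parameter vector."""
    c, ca, pp, g, ci = mp.cell, mp.ca, mp.passive, mp.geometry, mp.circulation
    P = np.empty(N_PARAMS)
    P[IA_P], P[IA_W], P[IH_PR], P[IH_WR], P[IB] = c.A_p, c.A_w, c.h_pr, c.h_wr, c.B
    P[IY_B], P[IY_C], P[IY_D], P[IY_P], P[IY_Q] = c.Y_b, c.Y_c, c.Y_d, c.Y_p, c.Y_q
    P[IY_R], P[IY_V], P[IY_VD], P[IZ_A], P[IZ_B] = c.Y_r, c.Y_v, c.Y_vd, c.Z_a, c.Z_b
    P[IZ_P], P[IZ_Q], P[IZ_R], P[IL_C] = c.Z_p, c.Z_q, c.Z_r, c.L_c
    P[IK_GAMMA], P[IGAMMA], P[IF] = c.K_gamma, c.gamma, c.f
    P[IR_GAUSS], P[IL_A], P[ITS_TOT] = c.R_gauss, c.L_a, c.TS_tot
    P[ICA_STOICH] = c.ca_stoich
    P[IQ_M], P[IT_1], P[IQ_PUMP_REST] = ca.Q_m, ca.t_1, ca.Q_pump_rest
    P[IK_P], P[IK_M] = ca.K_p, ca.K_m
    P[IK_PE], P[IK_PL], P[ID_PAS], P[IL_0] = pp.K_PE, pp.K_PL, pp.D, pp.L_0
    P[IK_R], P[IK_V], P[IK_L], P[IL_B] = g.K_R, g.K_V, g.K_L, g.L_b
    P[IK_S], P[IK_U], P[IH_LV] = g.K_S, g.K_u, g.h_lvED
    P[IP_E1], P[IP_E2], P[IR_PV], P[IR_LO], P[IR_OUT] = (
        ci.P_E1, ci.P_E2, ci.R_pv, ci.R_lo, ci.R_out)
    P[IC_A] = ci.C_a
    P[ICLAMP_EN] = 1.0 if ci.clamp_enabled else 0.0
    P[ICLAMP_P], P[ICLAMP_VA] = ci.clamp_P, ci.clamp_Va
    P[ICLAMP_HOLD] = 1.0 if ci.clamp_hold else 0.0
    return P


@njit(cache=True)
def _cell_dy(y, L, t_cycle, P, dy):
    """Cell-state derivatives into dy[0:8]; returns (F_b, F_p)."""
    hp = L - y[S_XP]
    hw = L - y[S_XW]
    dXp = P[IB] * (hp - P[IH_PR])
    dXw = P[IB] * (hw - P[IH_WR])
    gm = P[IGAMMA] / P[IK_GAMMA] if dXw > 0.0 else P[IGAMMA]
    ex = np.exp(-gm * (hw - P[IH_WR]) ** 2)
    g = P[IZ_A] + P[IY_V] * (1.0 - ex)
    gd = P[IY_D] + P[IY_C] * (L - P[IL_C]) ** 2 + P[IY_VD] * (1.0 - ex)

    ca3 = y[S_CA] ** 3
    ts_free = P[ITS_TOT] - (y[S_TSCA3] + y[S_TSCA3W] + y[S_TSCA3P] + y[S_TSP] + y[S_TSW])
    att = P[IF] * np.exp(-P[IR_GAUSS] * (L - P[IL_A]) ** 2)

    d0 = P[IY_B] * ts_free * ca3 - P[IZ_B] * y[S_TSCA3] + g * y[S_TSCA3W] - att * y[S_TSCA3]
    d1 = att * y[S_TSCA3] - g * y[S_TSCA3W] + P[IZ_P] * y[S_TSCA3P] - P[IY_P] * y[S_TSCA3W]
    d2 = P[IY_P] * y[S_TSCA3W] - P[IZ_P] * y[S_TSCA3P] + P[IZ_R] * y[S_TSP] * ca3 - P[IY_R] * y[S_TSCA3P]
    d3 = P[IY_R] * y[S_TSCA3P] - P[IZ_R] * y[S_TSP] * ca3 + P[IZ_Q] * y[S_TSW] - P[IY_Q] * y[S_TSP]
    d4 = P[IY_Q] * y[S_TSP] - P[IZ_Q] * y[S_TSW] - gd * y[S_TSW]

    x = t_cycle / P[IT_1]
    q_rel = P[IQ_M] * x ** 4 * np.exp(4.0 * (1.0 - x)) + P[IQ_PUMP_REST]
    if y[S_CA] > 0.0:
        q_pump = P[IK_P] / (1.0 + (P[IK_M] / y[S_CA]) ** 2)
    else:
        q_pump = 0.0
    i_trop = P[ICA_STOICH] * (d0 + d1 + d2)

    dy[S_TSCA3] = d0
    dy[S_TSCA3W] = d1
    dy[S_TSCA3P] = d2
    dy[S_TSP] = d3
    dy[S_TSW] = d4
    dy[S_XP] = dXp
    dy[S_XW] = dXw
    dy[S_CA] = q_rel - q_pump - i_trop

    f_b = P[IA_W] * (y[S_TSCA3W] + y[S_TSW]) * hw + P[IA_P] * (y[S_TSCA3P] + y[S_TSP]) * hp
    if L < P[IL_0]:
        f_p = -P[IK_PL] * (1.0 - L / P[IL_0])
    else:
        f_p = P[IK_PE] * (np.exp(P[ID_PAS] * (L / P[IL_0] - 1.0)) - 1.0)
    return f_b, f_p


@njit(cache=True)
def _eval(y, t_cycle, P, ej_clamped, dy):
    """Derivatives of the full coupled state from pre-step values.

    Applies the ejection-onset clamp in place (V_a reset) at the first
    upward crossing of clamp_P per cycle.  Returns
    (clamped_now, P_lv, P_a, q0, q_in, q_out).
    """
    r_lv = P[IK_R] * y[S_VLV] + P[IK_V]
    L = P[IK_L] * r_lv + P[IL_B]
    f_b, f_p = _cell_dy(y, L, t_cycle, P, dy)
    f_ext = P[IK_S] * f_b + f_p
    p_lv = 2.0 * P[IK_U] * f_ext * P[IH_LV] / r_lv

    clamped_now = False
    if P[ICLAMP_EN] != 0.0 and (not ej_clamped) and p_lv >= P[ICLAMP_P]:
        y[S_VA] = P[ICLAMP_VA]
        clamped_now = True

    if P[ICLAMP_HOLD] != 0.0 and (ej_clamped or clamped_now):
        p_a = P[ICLAMP_P]
    else:
        p_a = y[S_VA] / P[IC_A]

    q0 = (P[IP_E1] - p_lv) / P[IR_PV]
    if q0 < 0.0:
        q0 = 0.0
    q_in = (p_lv - p_a) / P[IR_LO]
    if q_in < 0.0:
        q_in = 0.0
    q_out = (p_a - P[IP_E2]) / P[IR_OUT]

    dy[S_VLV] = q0 - q_in
    dy[S_VA] = q_in - q_out
    return clamped_now, p_lv, p_a, q0, q_in, q_out


@njit(cache=True)
def run_cycles(y, P, dt, steps_per_cycle, max_cycles, tol):
    """Integrate whole cardiac cycles until the end-diastolic volume settles.

    Mutates y in place; on exit y sits at a cycle start.  Returns
    (edv_history, t_ej_per_cycle, n_cycles_run, converged, n_clip, ierr).
    ierr: 0 ok, 1 non-finite state, 2 negative volume.
    """
    edv = np.empty(max_cycles)
    t_ej = np.full(max_cycles, -1.0)
    dy = np.empty(10)
    n_clip = 0
    converged = False
    n_run = 0
    ierr = 0
    for c in range(max_cycles):
        edv[c] = y[S_VLV]
        n_run = c + 1
        if c > 0 and abs(edv[c] - edv[c - 1]) < tol:
            converged = True
            break
        ej = False
        for s in range(steps_per_cycle):
            clamped_now, p_lv, p_a, q0, q_in, q_out = _eval(y, s * dt, P, ej, dy)
            if clamped_now:
                ej = True
                t_ej[c] = s * dt
            for k in range(10):
                y[k] += dt * dy[k]
            for k in range(8):
                if k <= S_TSW or k == S_CA:
                    if y[k] < 0.0:
                        y[k] = 0.0
                        n_clip += 1
        if not np.isfinite(y[S_VLV]):
            ierr = 1
            n_run = c + 1
            break
        if y[S_VLV] <= 0.0 or y[S_VA] <= 0.0:
            ierr = 2
            n_run = c + 1
            break
        n_run = c + 1
    return edv[: max(n_run, 1)], t_ej[: max(n_run, 1)], n_run, converged, n_clip, ierr


@njit(cache=True)
def run_trace(y, P, dt, n_steps, t0_cycle, ej0):
    """Integrate n_steps recording the state at every step.

    Sample s is the state at time t0_cycle + s*dt after any clamp reset at
    that instant (so the recorded aortic volume reflects the protocol).
    Returns (states (n_steps+1, 10), t_ej_index, n_clip).
    """
    ys = np.empty((n_steps + 1, 10))
    dy = np.empty(10)
    ej = ej0
    t_ej_idx = -1
    n_clip = 0
    for s in range(n_steps):
        clamped_now, p_lv, p_a, q0, q_in, q_out = _eval(y, t0_cycle + s * dt, P, ej, dy)
        if clamped_now:
            ej = True
            t_ej_idx = s
        for k in range(10):
            ys[s, k] = y[k]
        for k in range(10):
            y[k] += dt * dy[k]
        for k in range(8):
            if k <= S_TSW or k == S_CA:
                if y[k] < 0.0:
                    y[k] = 0.0
                    n_clip += 1
    for k in range(10):
        ys[n_steps, k] = y[k]
    return ys, t_ej_idx, n_clip


@njit(cache=True)
def run_cell_clamped(y8, P, dt, n_steps, hold_steps, ca_clamp, v_um_per_ms, l_init):
    """Cell-only isovelocity protocol: [Ca2+] clamped, L prescribed.

    L is held at l_init for hold_steps, then shortens at constant velocity.
    Returns (states (n_steps+1, 8), L (n_steps+1,)).
    """
    ys = np.empty((n_steps + 1, 8))
    ls = np.empty(n_steps + 1)
    dy = np.empty(10)
    y = np.zeros(10)
    for k in range(8):
        y[k] = y8[k]
    y[S_CA] = ca_clamp
    for s in range(n_steps + 1):
        if s <= hold_steps:
            L = l_init
        else:
            L = l_init - v_um_per_ms * (s - hold_steps) * dt
        if L <= 0.0:
            raise ValueError("isovelocity shortening drove L below zero")
        ls[s] = L
        for k in range(8):
            ys[s, k] = y[k]
        if s == n_steps:
            break
        _cell_dy(y, L, 1e9, P, dy)  # t_cycle large: release pulse long over
        for k in range(8):
            if k != S_CA:  # [Ca2+] clamped
                y[k] += dt * dy[k]
    return ys, ls


# ---------------------------------------------------------------------------
# Time-varying elastance comparator: state (V_lv, V_a) only.
# Parameter vector: [E_d, E_s, T_s, V_0, P_E1, P_E2, R_pv, R_lo, R_out,
#                    C_a, clamp_en, clamp_P, clamp_Va]
(JE_D, JE_S, JT_S, JV_0, JP_E1, JP_E2, JR_PV, JR_LO, JR_OUT, JC_A,
 JCLAMP_EN, JCLAMP_P, JCLAMP_VA) = range(13)
N_TVEM_PARAMS = 13


def pack_tvem_params(tvem, circ) -> np.ndarray:
    Q = np.empty(N_TVEM_PARAMS)
    Q[JE_D], Q[JE_S], Q[JT_S], Q[JV_0] = tvem.E_d, tvem.E_s, tvem.T_s, tvem.V_0_tvem
    Q[JP_E1], Q[JP_E2] = circ.P_E1, circ.P_E2
    Q[JR_PV], Q[JR_LO], Q[JR_OUT], Q[JC_A] = circ.R_pv, circ.R_lo, circ.R_out, circ.C_a
    Q[JCLAMP_EN] = 1.0 if circ.clamp_enabled else 0.0
    Q[JCLAMP_P], Q[JCLAMP_VA] = circ.clamp_P, circ.clamp_Va
    return Q


@njit(cache=True)
def tvem_E(t_cycle, E_d, E_s, T_s):
    """Three-branch cosine elastance waveform [mmHg/mL]."""
    if t_cycle <= T_s:
        return E_d + 0.5 * (E_s - E_d) * (1.0 - np.cos(np.pi * t_cycle / T_s))
    elif t_cycle <= 1.5 * T_s:
        return E_d + 0.5 * (E_s - E_d) * (1.0 + np.cos(2.0 * np.pi * (t_cycle - T_s) / T_s))
    else:
        return E_d


@njit(cache=True)
def _tvem_eval(v, t_cycle, Q, ej_clamped, dv):
    p_lv = tvem_E(t_cycle, Q[JE_D], Q[JE_S], Q[JT_S]) * (v[0] - Q[JV_0])
    clamped_now = False
    if Q[JCLAMP_EN] != 0.0 and (not ej_clamped) and p_lv >= Q[JCLAMP_P]:
        v[1] = Q[JCLAMP_VA]
        clamped_now = True
    p_a = v[1] / Q[JC_A]
    q0 = (Q[JP_E1] - p_lv) / Q[JR_PV]
    if q0 < 0.0:
        q0 = 0.0
    q_in = (p_lv - p_a) / Q[JR_LO]
    if q_in < 0.0:
        q_in = 0.0
    q_out = (p_a - Q[JP_E2]) / Q[JR_OUT]
    dv[0] = q0 - q_in
    dv[1] = q_in - q_out
    return clamped_now


@njit(cache=True)
def run_tvem_cycles(v, Q, dt, steps_per_cycle, max_cycles, tol):
    edv = np.empty(max_cycles)
    dv = np.empty(2)
    converged = False
    n_run = 0
    for c in range(max_cycles):
        edv[c] = v[0]
        if c > 0 and abs(edv[c] - edv[c - 1]) < tol:
            converged = True
            break
        ej = False
        for s in range(steps_per_cycle):
            clamped_now = _tvem_eval(v, s * dt, Q, ej, dv)
            if clamped_now:
                ej = True
            v[0] += dt * dv[0]
            v[1] += dt * dv[1]
        n_run = c + 1
    return edv[: max(n_run, 1)], n_run, converged


@njit(cache=True)
def run_tvem_trace(v, Q, dt, n_steps, t0_cycle, ej0):
    vs = np.empty((n_steps + 1, 2))
    dv = np.empty(2)
    ej = ej0
    t_ej_idx = -1
    for s in range(n_steps):
        clamped_now = _tvem_eval(v, t0_cycle + s * dt, Q, ej, dv)
        if clamped_now:
            ej = True
            t_ej_idx = s
        vs[s, 0] = v[0]
        vs[s, 1] = v[1]
        v[0] += dt * dv[0]
        v[1] += dt * dv[1]
    vs[n_steps, 0] = v[0]
    vs[n_steps, 1] = v[1]
    return vs, t_ej_idx
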