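"""Numba-compiled right-hand side and fixed-step integrators.

The state is the volume vector only; pressures are algebraic:

    P_i = P0 + (V_i - V0_i)/C_i + lung_i * P_lung + med_i * P_M + plr_i * P_PLR

Edge flows are ΔP/R, rectified to max(0, ·) on valve edges; gated edges
(the coronary path) additionally carry zero flow whenever the compression
force exceeds the gate threshold.  Volume is conserved exactly because
every edge flow enters the divergence once with each sign.

Both integrators (classic RK4 and explicit Euler) take the diode
discontinuities head-on at a 1 ms step; no event detection.
"""

import numba
import numpy as np

__all__ = ["force_at", "plr_at", "rhs", "integrate_fixed_step"]


@numba.njit(fastmath=False)
def force_at(t, amplitude, period, duty_cycle):
    if amplitude == 0.0:
        return 0.0
    tau = t % period
    t_comp = duty_cycle * period
    if tau < t_comp:
        return amplitude * np.sin(np.pi * tau / t_comp)
    return 0.0


@numba.njit(fastmath=False)
def plr_at(t, p_full, start, ramp):
    if t < start:
        return 0.0
    if ramp > 0.0 and t < start + ramp:
        return p_full * (t - start) / ramp
    return p_full


@numba.njit(fastmath=False)
def pressures(V, C, V0, lung, med, plr, P0, p_lung, p_m, p_plr, P):
    n = V.shape[0]
    for i in range(n):
        P[i] = (
            P0 + (V[i] - V0[i]) / C[i]
            + lung[i] * p_lung + med[i] * p_m + plr[i] * p_plr
        )


@numba.njit(fastmath=False)
def edge_flows(P, src, dst, R, valve, gated, force, gate_thr, q):
    m = src.shape[0]
    for e in range(m):
        if gated[e] == 1 and force > gate_thr:
            q[e] = 0.0
            continue
        f = (P[src[e]] - P[dst[e]]) / R[e]
        if valve[e] == 1 and f < 0.0:
            f = 0.0
        q[e] = f


@numba.njit(fastmath=False)
def rhs(
    t, V, dV,
    C, V0, lung, med, plr, P0,
    src, dst, R, valve, gated,
    amplitude, period, duty, k_lung, k_med, gate_thr,
    p_plr_full, plr_start, plr_ramp,
    P, q,
):
    force = force_at(t, amplitude, period, duty)
    p_plr = plr_at(t, p_plr_full, plr_start, plr_ramp)
    pressures(V, C, V0, lung, med, plr, P0, k_lung * force, k_med * force,
              p_plr, P)
    edge_flows(P, src, dst, R, valve, gated, force, gate_thr, q)
    n = V.shape[0]
    for i in range(n):
        dV[i] = 0.0
    m = src.shape[0]
    for e in range(m):
        dV[src[e]] -= q[e]
        dV[dst[e]] += q[e]


@numba.njit(fastmath=False)
def integrate_fixed_step(
    V_init, dt, n_steps, record_every, use_euler,
    C, V0, lung, med, plr, P0,
    src, dst, R, valve, gated,
    amplitude, period, duty, k_lung, k_med, gate_thr,
    p_plr_full, plr_start, plr_ramp,
):
    """Fixed-step RK4 (or explicit Euler) over ``n_steps`` steps of ``dt``.

    Returns (V_record, bad_step, bad_comp): the decimated volume history
    including the initial state, and the first step/compartment at which a
    non-finite volume appeared ((-1, -1) if none; integration stops there).
    """
    n = V_init.shape[0]
    m = src.shape[0]
    n_rec = n_steps // record_every + 1
    V_rec = np.empty((n_rec, n))

    V = V_init.copy()
    Vtmp = np.empty(n)
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    P = np.empty(n)
    q = np.empty(m)

    V_rec[0] = V
    bad_step = -1
    bad_comp = -1
    rec = 1
    for step in range(n_steps):
        t = step * dt
        if use_euler == 1:
            rhs(t, V, k1, C, V0, lung, med, plr, P0, src, dst, R, valve,
                gated, amplitude, period, duty, k_lung, k_med, gate_thr,
                p_plr_full, plr_start, plr_ramp, P, q)
            for i in range(n):
                V[i] += dt * k1[i]
        else:
            rhs(t, V, k1, C, V0, lung, med, plr, P0, src, dst, R, valve,
                gated, amplitude, period, duty, k_lung, k_med, gate_thr,
                p_plr_full, plr_start, plr_ramp, P, q)
            for i in range(n):
                Vtmp[i] = V[i] + 0.5 * dt * k1[i]
            rhs(t + 0.5 * dt, Vtmp, k2, C, V0, lung, med, plr, P0, src, dst,
                R, valve, gated, amplitude, period, duty, k_lung, k_med,
                gate_thr, p_plr_full, plr_start, plr_ramp, P, q)
            for i in range(n):
                Vtmp[i] = V[i] + 0.5 * dt * k2[i]
            rhs(t + 0.5 * dt, Vtmp, k3, C, V0, lung, med, plr, P0, src, dst,
                R, valve, gated, amplitude, period, duty, k_lung, k_med,
                gate_thr, p_plr_full, plr_start, plr_ramp, P, q)
            for i in range(n):
                Vtmp[i] = V[i] + dt * k3[i]
            rhs(t + dt, Vtmp, k4, C, V0, lung, med, plr, P0, src, dst, R,
                valve, gated, amplitude, period, duty, k_lung, k_med,
                gate_thr, p_plr_full, plr_start, plr_ramp, P, q)
            for i in range(n):
                V[i] += (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

        if (step + 1) % record_every == 0:
            for i in range(n):
                if not np.isfinite(V[i]):
                    bad_step = step + 1
                    bad_comp = i
                    break
            if bad_step >= 0:
                break
            V_rec[rec] = V
            rec += 1

    if bad_step >= 0:
        V_rec = V_rec[:rec]
    return V_rec, bad_step, bad_comp
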