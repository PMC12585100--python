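"""Numba-compiled inner loops for the neural and hemodynamic integrators.

These kernels are the performance-critical Euler loops; all validation,
configuration handling and unit bookkeeping lives in the public modules.
Each kernel seeds numba's own RNG so trajectories are bitwise reproducible
for a given (arguments, seed) pair.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def wilson_cowan_euler(
    coupling_in,  # (n, n) row i = incoming weights C[j, i]
    g_vec,
    sigma_e_vec,
    r_e,
    r_i,
    tau_e,
    tau_i,
    a_ee,
    a_ei,
    p_ext,
    noise_d,
    rho_e,
    mu,
    sigma_i,
    dt,
    sqrt_dt_noise,  # 0 -> noise enters as D*eps; 1 -> D*eps/sqrt(dt) (Euler-Maruyama)
    n_transient,
    tau_ip_transient,
    n_settle,
    n_main,
    tau_ip_main,
    record_stride,
    aux_stride,
    seed,
    e_init,
    i_init,
    a_init,
):
    n = coupling_in.shape[0]
    np.random.seed(seed)
    E = np.full(n, e_init)
    I = np.full(n, i_init)
    a = np.full(n, a_init)

    noise_scale = noise_d
    if sqrt_dt_noise == 1:
        noise_scale = noise_d / np.sqrt(dt)

    n_rec = n_main // record_stride
    n_aux = n_main // aux_stride
    e_rec = np.empty((n, n_rec), dtype=np.float32)
    i_rec = np.empty((n, n_aux), dtype=np.float32)
    a_rec = np.empty((n, n_aux), dtype=np.float32)

    # phase 0: fast-plasticity transient; phase 1: settling at the main
    # plasticity time constant; phase 2: recorded analysis window
    for phase in range(3):
        if phase == 0:
            steps = n_transient
            tau_ip = tau_ip_transient
        elif phase == 1:
            steps = n_settle
            tau_ip = tau_ip_main
        else:
            steps = n_main
            tau_ip = tau_ip_main
        for t in range(steps):
            eps = np.random.standard_normal(n)
            net = np.dot(coupling_in, E)
            for i in range(n):
                x = a_ee * E[i] - a[i] * I[i] + g_vec[i] * net[i] + p_ext + noise_scale * eps[i]
                s_e = 1.0 / (1.0 + np.exp(-(x - mu) / sigma_e_vec[i]))
                s_i = 1.0 / (1.0 + np.exp(-(a_ei * E[i] - mu) / sigma_i))
                d_e = dt / tau_e * (-E[i] + (1.0 - r_e * E[i]) * s_e)
                d_i = dt / tau_i * (-I[i] + (1.0 - r_i * I[i]) * s_i)
                d_a = dt / tau_ip * (I[i] * (E[i] - rho_e))
                E[i] += d_e
                I[i] += d_i
                a[i] = max(a[i] + d_a, 0.0)
            if phase == 2:
                if t % record_stride == record_stride - 1:
                    e_rec[:, t // record_stride] = E
                if t % aux_stride == aux_stride - 1:
                    i_rec[:, t // aux_stride] = I
                    a_rec[:, t // aux_stride] = a
            if t % 10000 == 0:
                ok = True
                for i in range(n):
                    if not np.isfinite(E[i]) or not np.isfinite(I[i]) or not np.isfinite(a[i]):
                        ok = False
                if not ok:
                    return e_rec, i_rec, a_rec, phase, t
    return e_rec, i_rec, a_rec, -1, -1


@njit(cache=True)
def balloon_windkessel_euler(
    e_series,  # (n, T) neural drive at spacing dt
    dt,
    tau_s,
    tau_f,
    tau_v,
    tau_q,
    kappa,
    e0,
    v0,
    k1,
    k2,
    k3,
):
    n, T = e_series.shape
    bold = np.empty((n, T))
    inv_kappa = 1.0 / kappa
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            drive = e_series[i, t]
            v_pow = v ** inv_kappa
            ds = drive - s / tau_s - (f - 1.0) / tau_f
            df = s
            dv = (f - v_pow) / tau_v
            dq = (f * (1.0 - (1.0 - e0) ** (1.0 / f)) / e0 - q * v_pow / v) / tau_q
            s += dt * ds
            f += dt * df
            v += dt * dv
            q += dt * dq
            if v <= 0.0 or q <= 0.0 or not np.isfinite(q):
                return bold, i, t
            bold[i, t] = v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return bold, -1, -1
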