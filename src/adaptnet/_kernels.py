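"""Numba kernels: the model right-hand side and fixed-step RK4 integrators.

One rhs implementation backs everything — the public ``dynamics.rhs`` API,
plain simulation, fixed-point relaxation, and the two-trajectory Benettin
loop — so there is a single source of truth for the flow.

State packing (flat vector of length N*(K+2)):
    y[0:N]              x   dendritic potentials
    y[N + k*N + i]      a_ik  SFA state of neuron i at timescale k
    y[N*(K+1) + i]      b_i   available vesicle fraction

Non-adapting neurons (and disabled mechanisms) keep a = 0, b = 1 with zero
derivatives, so the packed flow restricted to the active coordinates equals
the reduced system.

Step stimuli are evaluated inside the kernels from (amplitudes, t_on, t_off);
time is recomputed from the integer step count, never accumulated.
"""

import numpy as np
from numba import njit

DIVERGENCE_BOUND = 1e6

# status codes returned by the loops
OK = 0
DIVERGED = 1
DEGENERATE = 2


@njit(cache=True)
def phi_scalar(h, w):
    """Hard sigmoid with quadratic (C^1) corners of half-width w, range [0,1]."""
    if h <= -w:
        return 0.0
    if h <= w:
        return (h + w) * (h + w) / (4.0 * w)
    if h <= 1.0 - w:
        return h
    if h <= 1.0 + w:
        return 1.0 - (1.0 - h + w) * (1.0 - h + w) / (4.0 * w)
    return 1.0


@njit(cache=True)
def phi_prime_scalar(h, w):
    if h <= -w:
        return 0.0
    if h <= w:
        return min(1.0, max(0.0, (h + w) / (2.0 * w)))
    if h <= 1.0 - w:
        return 1.0
    if h <= 1.0 + w:
        return min(1.0, max(0.0, (1.0 - h + w) / (2.0 * w)))
    return 0.0


@njit(cache=True)
def rhs_flat(
    y,
    u,
    W,
    adapt,
    sfa_on,
    std_on,
    a0,
    c,
    tau_d,
    tau_k,
    tau_rec,
    tau_rel,
    w_corner,
    dy,
    r_buf,
    br_buf,
):
    """dy/dt of the packed state; rates and b*r are left in the buffers."""
    N = W.shape[0]
    K = tau_k.size
    boff = N * (K + 1)
    for i in range(N):
        h = y[i] - a0[i]
        if sfa_on and adapt[i]:
            s = 0.0
            for k in range(K):
                s += y[N + k * N + i]
            h -= c * s
        r = phi_scalar(h, w_corner)
        r_buf[i] = r
        if std_on and adapt[i]:
            br_buf[i] = y[boff + i] * r
        else:
            br_buf[i] = r
    syn = np.dot(W, br_buf)
    for i in range(N):
        dy[i] = (-y[i] + u[i] + syn[i]) / tau_d
    for k in range(K):
        base = N + k * N
        for i in range(N):
            if sfa_on and adapt[i]:
                dy[base + i] = (-y[base + i] + r_buf[i]) / tau_k[k]
            else:
                dy[base + i] = 0.0
    for i in range(N):
        if std_on and adapt[i]:
            bi = y[boff + i]
            dy[boff + i] = (1.0 - bi) / tau_rec - bi * r_buf[i] / tau_rel
        else:
            dy[boff + i] = 0.0


@njit(cache=True)
def _fill_u(t, amp, t_on, t_off, u):
    if t_on <= t < t_off:
        for i in range(amp.size):
            u[i] = amp[i]
    else:
        for i in range(amp.size):
            u[i] = 0.0


@njit(cache=True)
def rk4_step(
    y,
    t,
    dt,
    amp,
    t_on,
    t_off,
    W,
    adapt,
    sfa_on,
    std_on,
    a0,
    c,
    tau_d,
    tau_k,
    tau_rec,
    tau_rel,
    w_corner,
    k1,
    k2,
    k3,
    k4,
    ytmp,
    u_buf,
    r_buf,
    br_buf,
):
    n = y.size
    _fill_u(t, amp, t_on, t_off, u_buf)
    rhs_flat(y, u_buf, W, adapt, sfa_on, std_on, a0, c, tau_d, tau_k,
             tau_rec, tau_rel, w_corner, k1, r_buf, br_buf)
    for i in range(n):
        ytmp[i] = y[i] + 0.5 * dt * k1[i]
    _fill_u(t + 0.5 * dt, amp, t_on, t_off, u_buf)
    rhs_flat(ytmp, u_buf, W, adapt, sfa_on, std_on, a0, c, tau_d, tau_k,
             tau_rec, tau_rel, w_corner, k2, r_buf, br_buf)
    for i in range(n):
        ytmp[i] = y[i] + 0.5 * dt * k2[i]
    rhs_flat(ytmp, u_buf, W, adapt, sfa_on, std_on, a0, c, tau_d, tau_k,
             tau_rec, tau_rel, w_corner, k3, r_buf, br_buf)
    for i in range(n):
        ytmp[i] = y[i] + dt * k3[i]
    _fill_u(t + dt, amp, t_on, t_off, u_buf)
    rhs_flat(ytmp, u_buf, W, adapt, sfa_on, std_on, a0, c, tau_d, tau_k,
             tau_rec, tau_rel, w_corner, k4, r_buf, br_buf)
    for i in range(n):
        y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def _alloc(n):
    return (
        np.empty(n), np.empty(n), np.empty(n), np.empty(n),
        np.empty(n),
    )


@njit(cache=True)
def _x_diverged(y, N):
    for i in range(N):
        if not np.isfinite(y[i]) or abs(y[i]) > DIVERGENCE_BOUND:
            return True
    return False


@njit(cache=True)
def simulate_loop(
    y0,
    n_steps,
    sample_every,
    dt,
    amp,
    t_on,
    t_off,
    W,
    adapt,
    sfa_on,
    std_on,
    a0,
    c,
    tau_d,
    tau_k,
    tau_rec,
    tau_rel,
    w_corner,
):
    """Integrate and record every ``sample_every`` steps (including t=0).

    Returns (samples, status, step_of_blowup).
    """
    N = W.shape[0]
    n = y0.size
    k1, k2, k3, k4, ytmp = _alloc(n)
    u_buf = np.empty(N)
    r_buf = np.empty(N)
    br_buf = np.empty(N)
    n_samples = n_steps // sample_every + 1
    out = np.empty((n_samples, n))
    y = y0.copy()
    out[0] = y
    isamp = 1
    for step in range(n_steps):
        t = step * dt
        rk4_step(y, t, dt, amp, t_on, t_off, W, adapt, sfa_on, std_on, a0, c,
                 tau_d, tau_k, tau_rec, tau_rel, w_corner,
                 k1, k2, k3, k4, ytmp, u_buf, r_buf, br_buf)
        if (step + 1) % sample_every == 0:
            if _x_diverged(y, N):
                return out[:isamp], DIVERGED, step + 1
            out[isamp] = y
            isamp += 1
    return out, OK, -1


@njit(cache=True)
def relax_loop(
    y0,
    max_steps,
    check_every,
    tol,
    dt,
    u_const,
    W,
    adapt,
    sfa_on,
    std_on,
    a0,
    c,
    tau_d,
    tau_k,
    tau_rec,
    tau_rel,
    w_corner,
):
    """Integrate under constant input until |dy/dt|_inf < tol or max_steps.

    Returns (y, steps_taken, converged_flag, status).
    """
    N = W.shape[0]
    n = y0.size
    k1, k2, k3, k4, ytmp = _alloc(n)
    u_buf = np.empty(N)
    r_buf = np.empty(N)
    br_buf = np.empty(N)
    y = y0.copy()
    t_off = 1e30
    for step in range(max_steps):
        rk4_step(y, step * dt, dt, u_const, 0.0, t_off, W, adapt, sfa_on,
                 std_on, a0, c, tau_d, tau_k, tau_rec, tau_rel, w_corner,
                 k1, k2, k3, k4, ytmp, u_buf, r_buf, br_buf)
        if (step + 1) % check_every == 0:
            if _x_diverged(y, N):
                return y, step + 1, False, DIVERGED
            rhs_flat(y, u_const, W, adapt, sfa_on, std_on, a0, c, tau_d,
                     tau_k, tau_rec, tau_rel, w_corner, k1, r_buf, br_buf)
            m = 0.0
            for i in range(n):
                ai = abs(k1[i])
                if ai > m:
                    m = ai
            if m < tol:
                return y, step + 1, True, OK
    return y, max_steps, False, OK


@njit(cache=True)
def benettin_loop(
    y0,
    direction,
    delta0,
    n_renorm,
    renorm_every,
    dt,
    amp,
    t_on,
    t_off,
    W,
    adapt,
    sfa_on,
    std_on,
    a0,
    c,
    tau_d,
    tau_k,
    tau_rec,
    tau_rel,
    w_corner,
):
    """Two-trajectory Benettin rescaling.

    The shadow starts at ``y0 + delta0 * direction`` (direction must be unit
    norm and supported on the dynamically active coordinates).  Every
    ``renorm_every`` steps the log expansion ln(d/delta0) is recorded and the
    shadow is pulled back to distance delta0 along the current separation.

    Returns (log_expansions, status, renorm_index_of_failure, y_final).
    """
    N = W.shape[0]
    n = y0.size
    k1, k2, k3, k4, ytmp = _alloc(n)
    u_buf = np.empty(N)
    r_buf = np.empty(N)
    br_buf = np.empty(N)
    y = y0.copy()
    ys = np.empty(n)
    for i in range(n):
        ys[i] = y0[i] + delta0 * direction[i]
    logexp = np.zeros(n_renorm)
    step = 0
    for m in range(n_renorm):
        for _ in range(renorm_every):
            t = step * dt
            rk4_step(y, t, dt, amp, t_on, t_off, W, adapt, sfa_on, std_on,
                     a0, c, tau_d, tau_k, tau_rec, tau_rel, w_corner,
                     k1, k2, k3, k4, ytmp, u_buf, r_buf, br_buf)
            rk4_step(ys, t, dt, amp, t_on, t_off, W, adapt, sfa_on, std_on,
                     a0, c, tau_d, tau_k, tau_rec, tau_rel, w_corner,
                     k1, k2, k3, k4, ytmp, u_buf, r_buf, br_buf)
            step += 1
        if _x_diverged(y, N) or _x_diverged(ys, N):
            return logexp, DIVERGED, m, y
        d2 = 0.0
        for i in range(n):
            di = y[i] - ys[i]
            d2 += di * di
        d = np.sqrt(d2)
        if d == 0.0:
            return logexp, DEGENERATE, m, y
        logexp[m] = np.log(d / delta0)
        fac = delta0 / d
        for i in range(n):
            ys[i] = y[i] + (ys[i] - y[i]) * fac
    return logexp, OK, -1, y
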