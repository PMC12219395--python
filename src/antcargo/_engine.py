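"""Compiled hot loop for the microscopic simulator.

The simulation couples a Gillespie event process (attach / detach / forget /
reorient / role-switch) to deterministic overdamped motion advanced on a
fixed ``dt`` grid: a waiting time is drawn from the total event rate, the
cargo angle is stepped in ``dt`` increments until that time has elapsed,
the event executes, and rates are rebuilt.  Pulse edges also rebuild rates
(the role-switch exponents depend on the local force, which jumps there).

Everything here is `numba`-nopython compatible; :data:`SIM_LOOP_JIT` is the
compiled entry point used by :func:`antcargo.microsim.run_trial`.  The RNG
is the MT19937 behind ``np.random`` seeded per call, which draws the exact
same sequence as ``numpy.random.RandomState`` — the pure-Python reference
engine relies on this for bit-level comparisons.

Channel codes in the event log: 0 attach, 1 detach, 2 forget, 3 reorient,
4 role-switch.
"""

import math

import numpy as np
from numba import njit

__all__ = ["SIM_LOOP_JIT", "sim_loop_py"]


@njit(cache=True)
def _wrap(x):
    """Wrap an angle to (-pi, pi]."""
    y = (x + math.pi) % (2.0 * math.pi) - math.pi
    return y


@njit(cache=True)
def _clip_phi(x, phi_max):
    if x > phi_max:
        return phi_max
    if x < -phi_max:
        return -phi_max
    return x


@njit(cache=True)
def _forces(theta, occ, pul, inf, phi, alpha, f0, phi_max, nest_angle):
    """Total puller force vector and its tangential component.

    Informed pullers steer toward the nest: their body-axis deviation is
    re-clipped toward the nest direction at the current cargo angle, so
    ``phi`` is refreshed in place for informed ants.
    """
    Fx = 0.0
    Fy = 0.0
    n = occ.shape[0]
    for i in range(n):
        if occ[i] == 0:
            continue
        nu = theta + alpha[i]
        if inf[i] == 1:
            phi[i] = _clip_phi(_wrap(nest_angle - nu), phi_max)
        if pul[i] == 1:
            pa = nu + phi[i]
            Fx += f0 * math.cos(pa)
            Fy += f0 * math.sin(pa)
    Ftan = -math.sin(theta) * Fx + math.cos(theta) * Fy
    return Fx, Fy, Ftan


@njit(cache=True)
def _floc(Fx, Fy, Ftan, Fext, theta, planar):
    """Local force vector felt by the ants.

    ``planar``: full centre-of-mass force (ant vector sum plus the
    tangential external force).  Otherwise the rod-constrained reading:
    only the net tangential force (= gamma*v) is transmitted.
    """
    if planar:
        return Fx - math.sin(theta) * Fext, Fy + math.cos(theta) * Fext
    Ft = Ftan + Fext
    return -math.sin(theta) * Ft, math.cos(theta) * Ft


@njit(cache=True)
def _rates(occ, pul, inf, phi, alpha, theta, flx, fly,
           k_on_eff, k_off, k_forget, k_c, k_ori, F_ind, rates):
    """Fill the flat rate table and return (R_total, n_empty).

    Layout: entry 0 is the attach channel (k_on_eff per empty site);
    entries 1+4i .. 4+4i are detach / forget / reorient / role-switch for
    site i.  The role-switch rate is k_c * exp(-/+ f_loc . p_hat / F_ind)
    for pullers/lifters, so the two directions multiply to k_c**2.
    """
    n = occ.shape[0]
    n_empty = 0
    for i in range(n):
        if occ[i] == 0:
            n_empty += 1
    rates[0] = k_on_eff * n_empty
    R = rates[0]
    for i in range(n):
        base = 1 + 4 * i
        if occ[i] == 0:
            rates[base] = 0.0
            rates[base + 1] = 0.0
            rates[base + 2] = 0.0
            rates[base + 3] = 0.0
            continue
        rates[base] = k_off
        rates[base + 1] = k_forget if inf[i] == 1 else 0.0
        rates[base + 2] = k_ori
        pa = theta + alpha[i] + phi[i]
        d = (flx * math.cos(pa) + fly * math.sin(pa)) / F_ind
        if pul[i] == 1:
            rates[base + 3] = k_c * math.exp(-d)
        else:
            rates[base + 3] = k_c * math.exp(d)
        R += rates[base] + rates[base + 1] + rates[base + 2] + rates[base + 3]
    return R, n_empty


@njit(cache=True)
def _pick_channel(rates, R, u):
    """Inverse-CDF channel selection; u is uniform on [0, 1)."""
    target = u * R
    acc = 0.0
    chosen = -1
    for j in range(rates.shape[0]):
        if rates[j] <= 0.0:
            continue
        acc += rates[j]
        if target < acc:
            chosen = j
            break
    if chosen < 0:
        # float round-off pushed the target past the last positive entry
        for j in range(rates.shape[0] - 1, -1, -1):
            if rates[j] > 0.0:
                chosen = j
                break
    return chosen


@njit(cache=True)
def _nth_empty(occ, k):
    cnt = -1
    n = occ.shape[0]
    for i in range(n):
        if occ[i] == 0:
            cnt += 1
            if cnt == k:
                return i
    return -1


def sim_loop_py(
    occ, pul, inf, phi,
    f0, F_ind, k_on_eff, k_off, k_forget, k_c, k_ori,
    gamma, l_rod, phi_max, dt, nest_angle,
    pulse_on, F_pulse, dur_max, trig, refractory, start_after, max_pulses,
    oppose, fixed_sign, end_on_switch, switch_hold,
    n_steps, seed, stride, theta0, log_events, ev_cap,
    stop_after_pulse, t_stop_abs, floc_planar,
):
    """Single-source simulation loop (compiled as :data:`SIM_LOOP_JIT`).

    Mutates the state arrays in place and returns sampled series, the
    event log, and the pulse log.

    ``stop_after_pulse`` > 0 ends the run that many seconds after the
    first pulse's maximum duration has elapsed (for single-pulse ensemble
    runs); ``t_stop_abs`` > 0 ends the run at that absolute time.  Either
    truncates the sampled series.
    """
    np.random.seed(seed)
    n = occ.shape[0]
    alpha = np.empty(n)
    for i in range(n):
        alpha[i] = 2.0 * math.pi * i / n
    rates = np.zeros(1 + 4 * n)

    n_rec = n_steps // stride + 1
    rec_t = np.empty(n_rec)
    rec_theta = np.empty(n_rec)
    rec_v = np.empty(n_rec)
    rec_Ftan = np.empty(n_rec)
    rec_Fext = np.empty(n_rec)
    rec_nf = np.empty(n_rec, np.int32)
    rec_nr = np.empty(n_rec, np.int32)
    rec_N = np.empty(n_rec, np.int32)
    rec_G = np.empty(n_rec, np.int32)

    cap = ev_cap if log_events else 1
    ev_t = np.empty(cap)
    ev_ch = np.empty(cap, np.int32)
    ev_site = np.empty(cap, np.int32)
    n_ev = 0
    ev_overflow = False

    pl_cap = 1024
    pl_begin = np.empty(pl_cap)
    pl_end = np.empty(pl_cap)
    pl_sign = np.empty(pl_cap, np.int32)
    n_pl = 0

    theta = theta0
    t = 0.0
    Fext = 0.0
    pulse_active = False
    pulse_t0 = 0.0
    last_end = -1.0e18
    pulses_done = 0
    align_run = 0.0
    vsign = 1.0

    Fx, Fy, Ftan = _forces(theta, occ, pul, inf, phi, alpha, f0, phi_max, nest_angle)
    v = (Ftan + Fext) / gamma
    if v > 0.0:
        vsign = 1.0
    elif v < 0.0:
        vsign = -1.0
    flx, fly = _floc(Fx, Fy, Ftan, Fext, theta, floc_planar)
    R, n_empty = _rates(occ, pul, inf, phi, alpha, theta, flx, fly,
                        k_on_eff, k_off, k_forget, k_c, k_ori, F_ind, rates)
    if R > 0.0:
        tte = -math.log(np.random.random()) / R
    else:
        tte = np.inf

    # initial sample
    irec = 0
    nf = 0
    nr = 0
    Natt = 0
    G = 0
    for i in range(n):
        if occ[i] == 1:
            Natt += 1
            if inf[i] == 1:
                G += 1
            if pul[i] == 1:
                if math.cos(alpha[i] - vsign * math.pi / 2.0) > 0.0:
                    nf += 1
                else:
                    nr += 1
    rec_t[0] = 0.0
    rec_theta[0] = theta
    rec_v[0] = v
    rec_Ftan[0] = Ftan
    rec_Fext[0] = Fext
    rec_nf[0] = nf
    rec_nr[0] = nr
    rec_N[0] = Natt
    rec_G[0] = G
    irec = 1

    for step in range(1, n_steps + 1):
        Fx, Fy, Ftan = _forces(theta, occ, pul, inf, phi, alpha,
                               f0, phi_max, nest_angle)
        v = (Ftan + Fext) / gamma
        if v > 0.0:
            vsign = 1.0
        elif v < 0.0:
            vsign = -1.0
        flx, fly = _floc(Fx, Fy, Ftan, Fext, theta, floc_planar)
        theta_prev = theta
        theta = theta + (v / l_rod) * dt
        t = step * dt

        rates_dirty = False
        if pulse_on:
            if pulse_active:
                # clutch disengagement: velocity aligned with the force for
                # switch_hold seconds means the cargo switched and the
                # cantilever unloads
                if end_on_switch and v * Fext > 0.0:
                    align_run += dt
                else:
                    align_run = 0.0
                if ((t - pulse_t0) >= dur_max - 1e-12
                        or (end_on_switch and align_run >= switch_hold - 1e-12)):
                    pulse_active = False
                    if Fext != 0.0:
                        rates_dirty = True
                    Fext = 0.0
                    if n_pl > 0:
                        pl_end[n_pl - 1] = t
                    last_end = t
            if ((not pulse_active)
                    and (max_pulses < 0 or pulses_done < max_pulses)
                    and t >= start_after
                    and (t - last_end) >= refractory):
                # wrapped crossing: the cargo may wind past +/-2*pi, but the
                # nest passage is a crossing of the trigger angle mod 2*pi
                a = _wrap(theta_prev - trig)
                b = _wrap(theta - trig)
                if a * b < 0.0 and abs(a - b) < 1.5:
                    if oppose:
                        s = -vsign
                    else:
                        s = float(fixed_sign)
                    pulse_active = True
                    pulse_t0 = t
                    align_run = 0.0
                    Fext = s * F_pulse
                    if Fext != 0.0:
                        rates_dirty = True
                    if n_pl < pl_cap:
                        frac = a / (a - b)
                        pl_begin[n_pl] = (step - 1) * dt + frac * dt
                        pl_end[n_pl] = n_steps * dt
                        pl_sign[n_pl] = int(s)
                        n_pl += 1
                    pulses_done += 1

        tte -= dt
        while tte <= 0.0 and R > 0.0:
            te = t + tte
            u = np.random.random()
            chosen = _pick_channel(rates, R, u)
            if chosen == 0:
                u3 = np.random.random()
                k = int(u3 * n_empty)
                if k >= n_empty:
                    k = n_empty - 1
                site = _nth_empty(occ, k)
                occ[site] = 1
                pul[site] = 1
                inf[site] = 1
                phi[site] = _clip_phi(
                    _wrap(nest_angle - (theta + alpha[site])), phi_max)
                code = 0
            else:
                site = (chosen - 1) // 4
                kind = (chosen - 1) % 4
                if kind == 0:
                    occ[site] = 0
                    pul[site] = 0
                    inf[site] = 0
                    phi[site] = 0.0
                    code = 1
                elif kind == 1:
                    inf[site] = 0
                    code = 2
                elif kind == 2:
                    if inf[site] == 0:
                        fmag2 = flx * flx + fly * fly
                        if fmag2 > 1e-24:
                            phi[site] = _clip_phi(
                                _wrap(math.atan2(fly, flx)
                                      - (theta + alpha[site])), phi_max)
                    code = 3
                else:
                    pul[site] = 1 - pul[site]
                    code = 4
            if log_events:
                if n_ev < cap:
                    ev_t[n_ev] = te
                    ev_ch[n_ev] = code
                    ev_site[n_ev] = site
                    n_ev += 1
                else:
                    ev_overflow = True
            # refresh forces, local force and rates at the post-event state
            Fx, Fy, Ftan = _forces(theta, occ, pul, inf, phi, alpha,
                                   f0, phi_max, nest_angle)
            flx, fly = _floc(Fx, Fy, Ftan, Fext, theta, floc_planar)
            R, n_empty = _rates(occ, pul, inf, phi, alpha, theta, flx, fly,
                                k_on_eff, k_off, k_forget, k_c, k_ori,
                                F_ind, rates)
            rates_dirty = False
            if R > 0.0:
                tte = -math.log(np.random.random()) / R
            else:
                tte = np.inf

        if rates_dirty:
            flx, fly = _floc(Fx, Fy, Ftan, Fext, theta, floc_planar)
            R, n_empty = _rates(occ, pul, inf, phi, alpha, theta, flx, fly,
                                k_on_eff, k_off, k_forget, k_c, k_ori,
                                F_ind, rates)
            if R > 0.0:
                tte = -math.log(np.random.random()) / R
            else:
                tte = np.inf

        if step % stride == 0:
            nf = 0
            nr = 0
            Natt = 0
            G = 0
            for i in range(n):
                if occ[i] == 1:
                    Natt += 1
                    if inf[i] == 1:
                        G += 1
                    if pul[i] == 1:
                        if math.cos(alpha[i] - vsign * math.pi / 2.0) > 0.0:
                            nf += 1
                        else:
                            nr += 1
            rec_t[irec] = t
            rec_theta[irec] = theta
            rec_v[irec] = v
            rec_Ftan[irec] = Ftan
            rec_Fext[irec] = Fext
            rec_nf[irec] = nf
            rec_nr[irec] = nr
            rec_N[irec] = Natt
            rec_G[irec] = G
            irec += 1

        if stop_after_pulse > 0.0 and n_pl > 0 and not pulse_active:
            if t >= pl_end[0] + stop_after_pulse:
                break
        if t_stop_abs > 0.0 and t >= t_stop_abs:
            break

    if n_pl > 0 and pl_end[n_pl - 1] > t:
        pl_end[n_pl - 1] = t

    return (rec_t[:irec], rec_theta[:irec], rec_v[:irec], rec_Ftan[:irec],
            rec_Fext[:irec],
            rec_nf[:irec], rec_nr[:irec], rec_N[:irec], rec_G[:irec],
            ev_t[:n_ev], ev_ch[:n_ev], ev_site[:n_ev], ev_overflow,
            pl_begin[:n_pl], pl_end[:n_pl], pl_sign[:n_pl])


SIM_LOOP_JIT = njit(cache=True)(sim_loop_py)
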