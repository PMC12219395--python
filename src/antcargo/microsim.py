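"""Stochastic microscopic simulator of cooperative cargo transport.

A ring-shaped cargo with ``N_max`` equally spaced attachment sites is
hinged to a rigid rod, constraining its centre to a circular path of
radius ``l_rod``; the cargo's angular position ``theta`` is measured from
the nest direction.  Ants occupy sites as *pullers* or *lifters*; only
pullers exert force, ``f0`` along their body axis ``p_hat``.  A newly
attached ant is an *informed* puller steering toward the nest; it forgets
at ``k_forget``.  Role switching is force-coupled Ising-style:

    r_(p->l) = k_c * exp(- f_loc . p_hat / F_ind)
    r_(l->p) = k_c * exp(+ f_loc . p_hat / F_ind)

where ``f_loc`` is the (uniform) local force at the cargo's centre of
mass.  The rigid rod absorbs radial components, so ``f_loc`` is the net
*tangential* force — ant pull plus external force projected on the path
tangent — which by overdamped force balance equals ``gamma * v``.

Two engines share one loop implementation (:mod:`antcargo._engine`): the
compiled numba path (default) and the interpreted reference path; both
draw the identical random sequence and produce identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import SIM_LOOP_JIT, sim_loop_py
from .params import ModelParams, PulseEvent, PulseSpec, from_model_force

__all__ = [
    "SimState",
    "RateTable",
    "Trajectory",
    "PulseController",
    "site_angles",
    "role_switch_rates",
    "refresh_orientations",
    "total_ant_force",
    "local_force",
    "build_rate_table",
    "draw_next_event",
    "execute_event",
    "step_dynamics",
    "run_trial",
    "classify_outcome",
    "EVENT_NAMES",
]

EVENT_NAMES = {0: "attach", 1: "detach", 2: "forget", 3: "reorient", 4: "role_switch"}


def site_angles(N_max: int) -> np.ndarray:
    """Site angles alpha_i = 2*pi*i/N_max on the cargo ring."""
    return 2.0 * np.pi * np.arange(N_max) / N_max


def _wrap(x):
    return (x + np.pi) % (2.0 * np.pi) - np.pi


@dataclass
class SimState:
    """Instantaneous state of the ant-cargo system.

    ``theta`` is unwrapped; ``F_ext_now`` is the signed tangential external
    force in model units.  Per-site arrays have length ``N_max``.
    """

    theta: float = 0.0
    v: float = 0.0
    t: float = 0.0
    F_ext_now: float = 0.0
    occupied: np.ndarray = field(default=None)  # type: ignore[assignment]
    puller: np.ndarray = field(default=None)  # type: ignore[assignment]
    informed: np.ndarray = field(default=None)  # type: ignore[assignment]
    phi: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def empty(cls, params: ModelParams, theta: float = 0.0) -> "SimState":
        n = params.N_max
        return cls(
            theta=theta,
            occupied=np.zeros(n, np.int8),
            puller=np.zeros(n, np.int8),
            informed=np.zeros(n, np.int8),
            phi=np.zeros(n, float),
        )

    @property
    def N_attached(self) -> int:
        return int(self.occupied.sum())

    @property
    def G(self) -> int:
        return int((self.occupied & self.informed).sum())


def role_switch_rates(f_loc: np.ndarray, p_hat: np.ndarray, params: ModelParams):
    """Puller<->lifter transition rates for one ant.

    Returns ``(r_p_to_l, r_l_to_p)``; their product is exactly k_c**2.
    """
    f_loc = np.asarray(f_loc, float)
    p_hat = np.asarray(p_hat, float)
    if not np.all(np.isfinite(f_loc)):
        raise ValueError("local force must be finite")
    d = float(f_loc @ p_hat) / params.F_ind
    return params.k_c * math.exp(-d), params.k_c * math.exp(d)


def refresh_orientations(state: SimState, params: ModelParams) -> None:
    """Re-aim informed ants at the nest, clipped to +/- phi_max.

    Informed ants steer continuously, so their deviation from the site
    normal depends on the current cargo angle and is refreshed before any
    force evaluation.
    """
    alpha = site_angles(params.N_max)
    mask = (state.occupied == 1) & (state.informed == 1)
    nu = state.theta + alpha[mask]
    state.phi[mask] = np.clip(
        _wrap(params.nest_angle - nu), -params.phi_max, params.phi_max
    )


def pull_angles(state: SimState, params: ModelParams) -> np.ndarray:
    """Arena-frame pulling direction angle per site (only occupied sites
    are meaningful)."""
    return state.theta + site_angles(params.N_max) + state.phi


def total_ant_force(state: SimState, params: ModelParams) -> np.ndarray:
    """Vector sum f0 * p_hat_i over pullers (model units).

    Refreshes informed orientations first; lifters contribute nothing.
    """
    refresh_orientations(state, params)
    pa = pull_angles(state, params)
    mask = (state.occupied == 1) & (state.puller == 1)
    Fx = params.f0 * np.cos(pa[mask]).sum()
    Fy = params.f0 * np.sin(pa[mask]).sum()
    return np.array([Fx, Fy])


def tangent_unit(theta: float) -> np.ndarray:
    """Unit tangent of the circular path in the direction of increasing
    theta."""
    return np.array([-math.sin(theta), math.cos(theta)])


def local_force(state: SimState, params: ModelParams) -> np.ndarray:
    """Uniform local force felt by every ant (model units).

    Under the default ``"planar"`` model this is the full force at the
    cargo's centre of mass: the ants' vector sum plus the external
    tangential force.  Under ``"tangential"`` the rigid rod absorbs
    radial components and the ants feel only the net tangential force
    (= gamma * v) as a vector along the path tangent.
    """
    tvec = tangent_unit(state.theta)
    F_ant = total_ant_force(state, params)
    if params.local_force_model == "planar":
        return F_ant + state.F_ext_now * tvec
    Ftan = float(tvec @ F_ant)
    return (Ftan + state.F_ext_now) * tvec


@dataclass
class RateTable:
    """Flat Gillespie rate table.

    Entry 0 is the attach channel; entries ``1+4i .. 4+4i`` are detach,
    forget, reorient, role-switch for site ``i``.  ``R_total`` is the sum
    of all entries, accumulated in the same order as the compiled engine.
    """

    rates: np.ndarray
    R_total: float
    n_empty: int

    def channel_rate(self, kind: str, site: int | None = None) -> float:
        offsets = {"detach": 0, "forget": 1, "reorient": 2, "role_switch": 3}
        if kind == "attach":
            return float(self.rates[0])
        if site is None:
            k = offsets[kind]
            return float(self.rates[1 + k :: 4].sum())
        return float(self.rates[1 + 4 * site + offsets[kind]])


def build_rate_table(state: SimState, params: ModelParams) -> RateTable:
    """Event rates for the current state.

    attach: k_on_eff per empty site; detach: k_off per attached ant;
    forget: k_forget per informed ant; reorient: k_ori per attached ant;
    role-switch: from :func:`role_switch_rates` with the current local
    force.
    """
    n = params.N_max
    alpha = site_angles(n)
    refresh_orientations(state, params)
    floc = local_force(state, params)
    rates = np.zeros(1 + 4 * n)
    n_empty = int((state.occupied == 0).sum())
    rates[0] = params.k_on_eff * n_empty
    R = rates[0]
    for i in range(n):
        if state.occupied[i] == 0:
            continue
        base = 1 + 4 * i
        rates[base] = params.k_off
        rates[base + 1] = params.k_forget if state.informed[i] == 1 else 0.0
        rates[base + 2] = params.k_ori
        pa = state.theta + alpha[i] + state.phi[i]
        p_hat = np.array([math.cos(pa), math.sin(pa)])
        r_pl, r_lp = role_switch_rates(floc, p_hat, params)
        rates[base + 3] = r_pl if state.puller[i] == 1 else r_lp
        R += rates[base] + rates[base + 1] + rates[base + 2] + rates[base + 3]
    return RateTable(rates=rates, R_total=R, n_empty=n_empty)


def draw_next_event(table: RateTable, rng: np.random.RandomState):
    """Draw (waiting time, flat channel index) from the rate table.

    The waiting time is exponential with mean 1/R_total; the channel is
    chosen with probability rate/R_total.  R_total == 0 returns
    ``(inf, -1)`` — no event can ever occur.
    """
    if table.R_total <= 0.0:
        return np.inf, -1
    wait = -math.log(rng.random_sample()) / table.R_total
    u = rng.random_sample()
    target = u * table.R_total
    acc = 0.0
    chosen = -1
    for j, r in enumerate(table.rates):
        if r <= 0.0:
            continue
        acc += r
        if target < acc:
            chosen = j
            break
    if chosen < 0:
        positive = np.nonzero(table.rates > 0.0)[0]
        chosen = int(positive[-1])
    return wait, chosen


def decode_channel(channel: int) -> tuple[str, int | None]:
    """Map a flat channel index to (event name, site)."""
    if channel == 0:
        return "attach", None
    site, kind = divmod(channel - 1, 4)
    return EVENT_NAMES[1 + kind], site


def execute_event(
    state: SimState,
    channel: int,
    rng: np.random.RandomState,
    params: ModelParams,
) -> SimState:
    """Apply one stochastic event in place (and return the state).

    attach: a random empty site gains an informed puller aimed at the
    nest; detach empties the site; forget clears the informed flag;
    reorient re-aims an uninformed ant's body axis along the current local
    force; role-switch toggles puller/lifter.
    """
    alpha = site_angles(params.N_max)
    kind, site = decode_channel(channel)
    if kind == "attach":
        empties = np.nonzero(state.occupied == 0)[0]
        if empties.size == 0:
            raise ValueError("attach event on a fully occupied cargo")
        k = min(int(rng.random_sample() * empties.size), empties.size - 1)
        i = int(empties[k])
        state.occupied[i] = 1
        state.puller[i] = 1
        state.informed[i] = 1
        state.phi[i] = float(
            np.clip(
                _wrap(params.nest_angle - (state.theta + alpha[i])),
                -params.phi_max,
                params.phi_max,
            )
        )
        return state
    assert site is not None
    if state.occupied[site] == 0:
        raise ValueError(f"{kind} event on empty site {site}")
    if kind == "detach":
        state.occupied[site] = 0
        state.puller[site] = 0
        state.informed[site] = 0
        state.phi[site] = 0.0
    elif kind == "forget":
        state.informed[site] = 0
    elif kind == "reorient":
        if state.informed[site] == 0:
            floc = local_force(state, params)
            if floc @ floc > 1e-24:
                target = math.atan2(floc[1], floc[0])
                state.phi[site] = float(
                    np.clip(
                        _wrap(target - (state.theta + alpha[site])),
                        -params.phi_max,
                        params.phi_max,
                    )
                )
    elif kind == "role_switch":
        state.puller[site] = 1 - state.puller[site]
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {kind}")
    return state


def step_dynamics(
    state: SimState, params: ModelParams, F_ext_now: float, dt: float
) -> SimState:
    """Advance the overdamped motion by one step.

    v is slaved to the force: v = (tangential ant force + signed external
    tangential force) / gamma, and theta advances by (v / l_rod) * dt.
    """
    if not dt > 0.0:
        raise ValueError("dt must be > 0")
    state.F_ext_now = float(F_ext_now)
    F = total_ant_force(state, params)
    Ftan = float(tangent_unit(state.theta) @ F)
    state.v = (Ftan + state.F_ext_now) / params.gamma
    state.theta += (state.v / params.l_rod) * dt
    state.t += dt
    return state


class PulseController:
    """Robot-like rectangular pulse logic.

    Returns zero before any trigger; on an (unwrapped) crossing of the
    trigger angle — outside the refractory window and once armed — emits
    ``-sign(v) * F_ext`` (or a fixed sign) for up to ``duration_max``
    seconds.
    """

    def __init__(self, spec: PulseSpec, params: ModelParams, dt: float | None = None):
        self.spec = spec
        self.F_model = spec.F_ext * params.force_unit_per_mN
        self.dt = dt if dt is not None else params.dt
        self.active = False
        self.t_begin = -np.inf
        self.last_end = -np.inf
        self.pulses_done = 0
        self.align_run = 0.0
        self.sign = 0.0
        self.pulses: list[tuple[float, float, int]] = []

    def _end_pulse(self, t: float) -> None:
        self.active = False
        self.last_end = t
        if self.pulses:
            tb, _, s = self.pulses[-1]
            self.pulses[-1] = (tb, t, s)

    def update(self, t: float, theta_prev: float, theta: float, v: float) -> float:
        spec = self.spec
        if self.active:
            if spec.end_on_switch and v * self.sign > 0.0:
                self.align_run += self.dt
            else:
                self.align_run = 0.0
            if (t - self.t_begin) >= spec.duration_max - 1e-12 or (
                spec.end_on_switch and self.align_run >= spec.switch_hold - 1e-12
            ):
                self._end_pulse(t)
        armed = (
            not self.active
            and (spec.max_pulses < 0 or self.pulses_done < spec.max_pulses)
            and t >= spec.start_after
            and (t - self.last_end) >= spec.refractory
        )
        if armed:
            a = _wrap(theta_prev - spec.trigger_angle)
            b = _wrap(theta - spec.trigger_angle)
            if a * b < 0.0 and abs(a - b) < 1.5:
                if spec.direction_rule == "oppose-motion":
                    s = -1.0 if v >= 0.0 else 1.0
                else:
                    s = float(spec.fixed_sign)
                self.active = True
                self.t_begin = t
                self.align_run = 0.0
                self.sign = s
                self.pulses_done += 1
                self.pulses.append((t, np.inf, int(s)))
        return self.sign * self.F_model if self.active else 0.0


@dataclass
class Trajectory:
    """Sampled output of one simulated trial, plus event and pulse logs."""

    t: np.ndarray
    theta: np.ndarray
    v: np.ndarray
    F_ant_tang: np.ndarray
    F_ext: np.ndarray
    n_front: np.ndarray
    n_rear: np.ndarray
    N_attached: np.ndarray
    G: np.ndarray
    events: pd.DataFrame
    pulses: pd.DataFrame
    params: ModelParams
    spec: PulseSpec | None
    seed: int
    event_log_overflow: bool = False

    @property
    def omega(self) -> np.ndarray:
        """Angular velocity in rad/s."""
        return self.v / self.params.l_rod

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "theta_rad": self.theta,
                "omega_rad_s": self.omega,
                "v": self.v,
                "F_ant_tangential": self.F_ant_tang,
                "F_ext": self.F_ext,
                "n_front_pullers": self.n_front,
                "n_rear_pullers": self.n_rear,
                "N_attached": self.N_attached,
                "G": self.G,
            }
        )


def run_trial(
    params: ModelParams,
    spec: PulseSpec | None = None,
    T_total: float = 100.0,
    seed: int = 0,
    record_stride: int = 1,
    theta0: float = 0.0,
    initial_state: SimState | None = None,
    engine: str = "numba",
    log_events: bool = True,
    stop_after_pulse: float = 0.0,
    t_stop: float = 0.0,
) -> Trajectory:
    """Simulate one trial and return the sampled :class:`Trajectory`.

    Identical ``seed`` (and engine-independent: the two engines share one
    loop source and RNG stream) gives an identical trajectory.
    """
    if not T_total > 0.0:
        raise ValueError("T_total must be > 0")
    if engine not in ("numba", "python"):
        raise ValueError(f"unknown engine {engine!r}")
    n = params.N_max
    if initial_state is not None:
        occ = initial_state.occupied.astype(np.int8).copy()
        pul = initial_state.puller.astype(np.int8).copy()
        inf_ = initial_state.informed.astype(np.int8).copy()
        phi = initial_state.phi.astype(float).copy()
        theta0 = initial_state.theta
    else:
        occ = np.zeros(n, np.int8)
        pul = np.zeros(n, np.int8)
        inf_ = np.zeros(n, np.int8)
        phi = np.zeros(n, float)
    n_steps = int(round(T_total / params.dt))
    ev_cap = int(min(3_000_000, 40 * n * T_total + 20_000))
    if spec is None:
        pulse_args = (False, 0.0, 1.0, 0.0, 0.0, 0.0, 0, True, -1, False, 0.5)
    else:
        pulse_args = (
            True,
            spec.F_ext * params.force_unit_per_mN,
            spec.duration_max,
            spec.trigger_angle,
            spec.refractory,
            spec.start_after,
            spec.max_pulses,
            spec.direction_rule == "oppose-motion",
            spec.fixed_sign,
            spec.end_on_switch,
            spec.switch_hold,
        )
    loop = SIM_LOOP_JIT if engine == "numba" else sim_loop_py
    out = loop(
        occ, pul, inf_, phi,
        params.f0, params.F_ind, params.k_on_eff, params.k_off,
        params.k_forget, params.k_c, params.k_ori,
        params.gamma, params.l_rod, params.phi_max, params.dt,
        params.nest_angle,
        *pulse_args,
        n_steps, int(seed), int(record_stride), float(theta0),
        bool(log_events), ev_cap,
        float(stop_after_pulse), float(t_stop),
        params.local_force_model == "planar",
    )
    (rec_t, rec_theta, rec_v, rec_Ftan, rec_Fext,
     rec_nf, rec_nr, rec_N, rec_G,
     ev_t, ev_ch, ev_site, ev_overflow,
     pl_begin, pl_end, pl_sign) = out
    events = pd.DataFrame(
        {
            "t": ev_t,
            "channel": [EVENT_NAMES[int(c)] for c in ev_ch],
            "site_index": ev_site,
        }
    )
    pulses = pd.DataFrame(
        {"t_begin": pl_begin, "t_end": pl_end, "sign": pl_sign}
    )
    return Trajectory(
        t=rec_t, theta=rec_theta, v=rec_v, F_ant_tang=rec_Ftan,
        F_ext=rec_Fext, n_front=rec_nf, n_rear=rec_nr,
        N_attached=rec_N, G=rec_G,
        events=events, pulses=pulses,
        params=params, spec=spec, seed=int(seed),
        event_log_overflow=bool(ev_overflow),
    )


def classify_outcome(
    traj: Trajectory,
    pulse: int | tuple[float, float] = 0,
    min_hold: float = 0.5,
) -> PulseEvent:
    """Label one pulse window as switch or resist.

    A switch is the first angular-velocity sign reversal (relative to the
    direction of motion at pulse onset) inside the window that persists
    for at least ``min_hold`` seconds; otherwise the trial resists and the
    effective duration is the full window.
    """
    if isinstance(pulse, tuple):
        t_begin, t_end = pulse
    else:
        if len(traj.pulses) <= pulse:
            raise ValueError(f"trajectory has no pulse with index {pulse}")
        row = traj.pulses.iloc[pulse]
        t_begin, t_end = float(row.t_begin), float(row.t_end)
    if t_begin < traj.t[0] - 1e-9 or t_end > traj.t[-1] + 1e-9:
        raise ValueError("pulse window lies outside the trajectory")
    t = traj.t
    omega = traj.omega
    i0 = int(np.searchsorted(t, t_begin, side="left"))
    i1 = int(np.searchsorted(t, t_end, side="right"))
    pre = omega[max(i0 - 1, 0)]
    base_sign = 1.0 if pre >= 0.0 else -1.0
    dt_s = t[1] - t[0] if len(t) > 1 else np.inf
    hold_n = max(1, int(round(min_hold / dt_s)))
    reversed_ = omega * (-base_sign) > 0.0
    t_switch = None
    for i in range(i0, i1):
        if not reversed_[i]:
            continue
        j_end = i + hold_n
        if j_end > len(omega):
            break
        if np.all(reversed_[i:j_end]):
            t_switch = float(t[i])
            break
    mag_mask_end = t_switch if t_switch is not None else t_end
    sel = (t >= t_begin) & (t <= mag_mask_end)
    # the pulse engages on the step after the interpolated crossing, so
    # zero-force edge samples inside the window are quantisation artefacts
    applied = sel & (traj.F_ext != 0.0)
    if not applied.any():
        applied = sel
    magnitude = float(
        from_model_force(np.abs(traj.F_ext[applied]).mean() if applied.any()
                         else 0.0, traj.params)
    )
    if t_switch is not None and t_switch > t_begin:
        return PulseEvent(
            t_begin=t_begin, t_end=t_end, magnitude=magnitude,
            outcome="switch", t_switch=t_switch,
        )
    return PulseEvent(
        t_begin=t_begin, t_end=t_end, magnitude=magnitude, outcome="resist"
    )
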