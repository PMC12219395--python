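"""Mean-field theory of the ant-cargo pendulum and its force response.

When the cargo is saturated every ant feels the same collective force, and
the stochastic model reduces to deterministic equations for the cargo
angle ``theta`` and speed ``v``:

    d(theta)/dt = v / l_rod
    (1/k_c) dv/dt = (f0*N/gamma) * sinh(v / (F_ind/gamma))
                    - 2*(v + (f0*G/gamma)*sin(theta) + F(t)/gamma)
                      * cosh(v / (F_ind/gamma))
                    - (f0*G/gamma) * (1/k_c) * v*cos(theta)/l_rod

with a rectangular external pulse F(t); differentiating the overdamped
force balance F_tot = gamma*v turns the pulse edges into instantaneous
velocity jumps of magnitude F_ext/gamma.

Linearising around v = 0 exposes the pitchfork bifurcation governed by

    beta = f0*N / (2*F_ind) - 1,

negative in the disordered regime (v -> 0) and positive in the ordered
regime, where the spontaneous speed v0 solves
(f0*N/gamma)*tanh(gamma*v/F_ind) = 2*v.  Integrating the linearised flow
from v0 to rest under a constant opposing force yields the closed-form
switching boundary

    F_ext(dt) = gamma*v0*beta / (1 - exp(-2*beta*k_c*dt)),

which this module also fits to measured 50%-switching points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "MeanFieldParams",
    "MeanFieldState",
    "BoundaryFit",
    "beta",
    "critical_group_size",
    "meanfield_rhs",
    "integrate_meanfield",
    "spontaneous_speed",
    "force_response_curve",
    "fit_force_boundary",
]


def beta(N: float, f0: float = 2.8, F_ind: float = 28.0) -> float:
    """Order parameter coefficient beta = f0*N/(2*F_ind) - 1.

    Negative: disordered regime (the rest state is stable).  Positive:
    ordered regime (spontaneous motion).  Zero at the critical group size.
    """
    if not F_ind > 0:
        raise ValueError("F_ind must be > 0")
    return f0 * N / (2.0 * F_ind) - 1.0


def critical_group_size(f0: float = 2.8, F_ind: float = 28.0) -> float:
    """Group size at which beta changes sign: N* = 2*F_ind/f0."""
    return 2.0 * F_ind / f0


@dataclass
class MeanFieldParams:
    """Reduced parameter set of the deterministic model."""

    N: float = 60.0
    G: float = 0.0
    f0: float = 2.8
    F_ind: float = 28.0
    gamma: float | None = None
    k_c: float = 1.0
    l_rod: float = 10.0

    def __post_init__(self) -> None:
        if self.gamma is None:
            self.gamma = 3.0 * self.N
        if self.N < 0 or self.G < 0 or self.G > self.N:
            raise ValueError("need 0 <= G <= N")
        if self.F_ind <= 0 or self.gamma <= 0 or self.l_rod <= 0:
            raise ValueError("F_ind, gamma, l_rod must be > 0")

    @property
    def N_tilde(self) -> float:
        """Reduced drive f0*N/gamma (speed units)."""
        return self.f0 * self.N / self.gamma

    @property
    def F_ind_tilde(self) -> float:
        """Reduced individuality force F_ind/gamma (speed units)."""
        return self.F_ind / self.gamma

    @property
    def beta(self) -> float:
        return beta(self.N, self.f0, self.F_ind)


@dataclass
class MeanFieldState:
    t: float = 0.0
    theta: float = 0.0
    v: float = 0.0


@dataclass
class Pulse:
    """Rectangular external force: F(t) = F for t_start <= t < t_start + duration."""

    F: float                  # signed, model force units
    t_start: float
    duration: float


def meanfield_rhs(
    state: MeanFieldState, params: MeanFieldParams, F_now: float = 0.0
) -> tuple[float, float]:
    """Time derivatives (dtheta/dt, dv/dt) away from pulse edges.

    ``F_now`` is the current value of the piecewise-constant external
    force; the delta-function contributions at pulse edges are applied as
    velocity jumps by the integrator, not here.
    """
    p = params
    x = state.v / p.F_ind_tilde
    dtheta = state.v / p.l_rod
    restoring = (p.f0 * p.G / p.gamma) * math.sin(state.theta)
    dv = p.k_c * (
        p.N_tilde * math.sinh(x)
        - 2.0 * (state.v + restoring + F_now / p.gamma) * math.cosh(x)
    ) - (p.f0 * p.G / p.gamma) * state.v * math.cos(state.theta) / p.l_rod
    return dtheta, dv


def integrate_meanfield(
    initial: MeanFieldState,
    params: MeanFieldParams,
    pulse: Pulse | None = None,
    T: float = 100.0,
    step: float = 0.01,
) -> np.ndarray:
    """Fixed-step RK4 integration; returns an array of (t, theta, v).

    Velocity jumps -F/gamma and +F/gamma are applied at the pulse's rising
    and falling edge (the formal integral of the delta terms).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    n = int(round(T / step))
    out = np.empty((n + 1, 3))
    t, th, v = initial.t, initial.theta, initial.v
    out[0] = (t, th, v)
    jump_on = pulse.t_start if pulse is not None else math.inf
    jump_off = pulse.t_start + pulse.duration if pulse is not None else math.inf

    def f(th_, v_, F_now):
        s = MeanFieldState(t=0.0, theta=th_, v=v_)
        return meanfield_rhs(s, params, F_now)

    for i in range(1, n + 1):
        if pulse is not None:
            if jump_on is not None and t >= jump_on - 1e-12:
                v -= pulse.F / params.gamma
                jump_on = None
            if jump_off is not None and t >= jump_off - 1e-12 and jump_on is None:
                v += pulse.F / params.gamma
                jump_off = None
            F_now = pulse.F if (jump_on is None and jump_off is not None) else 0.0
        else:
            F_now = 0.0
        try:
            k1t, k1v = f(th, v, F_now)
            k2t, k2v = f(th + 0.5 * step * k1t, v + 0.5 * step * k1v, F_now)
            k3t, k3v = f(th + 0.5 * step * k2t, v + 0.5 * step * k2v, F_now)
            k4t, k4v = f(th + step * k3t, v + step * k3v, F_now)
        except OverflowError as err:
            raise FloatingPointError(
                f"mean-field state diverged at t={t:.3f}: theta={th}, v={v}"
            ) from err
        th += (step / 6.0) * (k1t + 2 * k2t + 2 * k3t + k4t)
        v += (step / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
        t += step
        if not (math.isfinite(th) and math.isfinite(v)):
            raise FloatingPointError(
                f"mean-field state diverged at t={t:.3f}: theta={th}, v={v}"
            )
        out[i] = (t, th, v)
    return out


def spontaneous_speed(params: MeanFieldParams) -> float:
    """Spontaneous steady speed v0 of the free, uninformed system.

    Zero for beta <= 0; for beta > 0 the positive root of
    (f0*N/gamma) * tanh(gamma*v/F_ind) = 2*v, isolated by bracketing on
    (0, f0*N/(2*gamma)] (tanh < 1 bounds the drive).
    """
    p = params
    if p.beta <= 0.0:
        return 0.0

    def h(v):
        return p.N_tilde * math.tanh(v / p.F_ind_tilde) - 2.0 * v

    hi = p.N_tilde / 2.0
    lo = 1e-12 * hi
    return float(brentq(h, lo, hi, xtol=1e-15, rtol=1e-15))


def force_response_curve(
    delta_t: float | np.ndarray,
    gamma: float,
    v0: float,
    beta_val: float,
    k_c: float,
) -> float | np.ndarray:
    """Minimal switching force for a pulse of duration ``delta_t``.

    F_ext = gamma*v0*beta / (1 - exp(-2*beta*k_c*delta_t)); the beta -> 0
    limit gamma*v0/(2*k_c*delta_t) is taken smoothly via expm1.
    """
    dt = np.asarray(delta_t, float)
    if np.any(dt <= 0.0):
        raise ValueError("delta_t must be > 0")
    if beta_val == 0.0:
        out = gamma * v0 / (2.0 * k_c * dt)
    else:
        out = gamma * v0 * beta_val / (-np.expm1(-2.0 * beta_val * k_c * dt))
    if np.isscalar(delta_t):
        return float(out)
    return out


@dataclass
class BoundaryFit:
    """Least-squares fit of the closed-form switching boundary."""

    v0: float
    beta: float
    k_c: float
    gamma: float
    residual_norm: float
    points: np.ndarray = field(repr=False)  # (n, 2) columns: F_ext, delta_t

    def predict(self, delta_t):
        return force_response_curve(delta_t, self.gamma, self.v0, self.beta, self.k_c)


def fit_force_boundary(
    points, gamma: float, k_c: float = 0.7
) -> BoundaryFit:
    """Fit (v0, beta) of the switching boundary to 50%-probability points.

    ``points`` is a sequence of (F_ext, delta_t) pairs; gamma and k_c are
    held fixed.  Least squares is performed over the independent variable
    delta_t, i.e. the residuals are in F.  For a fixed beta the model is
    linear in v0, so a 1-D profile over beta seeds the joint refinement.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (F_ext, delta_t) points")
    if np.unique(pts, axis=0).shape[0] < 3:
        raise ValueError("need at least 3 distinct boundary points")
    F_obs, dts = pts[:, 0], pts[:, 1]
    if np.any(dts <= 0.0):
        raise ValueError("delta_t must be > 0")
    if np.unique(dts).size < 2:
        raise ValueError("degenerate boundary: all points share one delta_t")

    def shape(beta_val):
        # F = gamma * v0 * g(beta, dt): profile out the linear amplitude
        if abs(beta_val) < 1e-12:
            return 1.0 / (2.0 * k_c * dts)
        return beta_val / (-np.expm1(-2.0 * beta_val * k_c * dts))

    best = None
    for b0 in np.concatenate([-np.geomspace(5, 0.01, 12), [0.0],
                              np.geomspace(0.01, 5, 12)]):
        g = gamma * shape(b0)
        v0_hat = float(g @ F_obs / (g @ g))
        r = float(np.linalg.norm(v0_hat * g - F_obs))
        if best is None or r < best[2]:
            best = (v0_hat, b0, r)
    v0_init, beta_init, _ = best

    def resid(x):
        v0_, b_ = x
        return gamma * v0_ * shape(b_) - F_obs

    sol = least_squares(
        resid, x0=[max(v0_init, 1e-9), beta_init],
        bounds=([0.0, -50.0], [np.inf, 50.0]), xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    v0_fit, beta_fit = map(float, sol.x)
    return BoundaryFit(
        v0=v0_fit, beta=beta_fit, k_c=k_c, gamma=gamma,
        residual_norm=float(np.linalg.norm(sol.fun)), points=pts,
    )
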