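"""Synthetic field recordings: noisy dual-angle tracks at fixed frame rate.

The field experiments track two angles per video frame: the cargo (rod)
angle and the robot blade angle.  The robot's soft cantilever acts as a
linear spring, so the angular difference maps to the applied force,
``F = kappa * (theta_blade - theta_cargo)``.  This module renders
simulated trajectories into that observable form — resampled to the
camera frame rate, with independent Gaussian tracking noise per frame —
so the downstream analysis runs without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .microsim import Trajectory, classify_outcome, run_trial
from .params import ModelParams, PulseSpec

__all__ = [
    "TrackedSeries",
    "render_tracked",
    "write_tracks",
    "read_tracks",
    "make_benchmark_suite",
    "DEFAULT_KAPPA",
    "DEFAULT_NOISE_SIGMA",
]

#: Cantilever stiffness, mN per radian of blade-cargo angle difference.
#: 40 mN/rad puts a 1 mN force at ~1.4 degrees of deflection.
DEFAULT_KAPPA = 40.0

#: Tracking noise standard deviation in radians (~0.2 degrees).
DEFAULT_NOISE_SIGMA = np.deg2rad(0.2)


@dataclass
class TrackedSeries:
    """Frame-by-frame angle tracks of cargo and robot blade.

    Frames are uniformly spaced at 1/fps; angles are radians, unwrapped.
    """

    fps: float
    t: np.ndarray
    theta_cargo: np.ndarray
    theta_blade: np.ndarray
    kappa: float = DEFAULT_KAPPA
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.t) != len(self.theta_cargo) or len(self.t) != len(self.theta_blade):
            raise ValueError("tracks must have equal length")
        if len(self.t) > 1:
            gaps = np.diff(self.t)
            if not np.allclose(gaps, 1.0 / self.fps, rtol=1e-6, atol=1e-9):
                raise ValueError("frames are not uniformly spaced at 1/fps")
        if not (np.all(np.isfinite(self.theta_cargo))
                and np.all(np.isfinite(self.theta_blade))):
            raise ValueError("angles must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.t)


def render_tracked(
    traj: Trajectory,
    fps: float = 25.0,
    kappa: float = DEFAULT_KAPPA,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> TrackedSeries:
    """Render a simulated trajectory as a camera-rate dual-angle track.

    The cargo angle is the simulated angle resampled to frame times plus
    Gaussian tracking noise; the blade angle adds the cantilever
    deflection F_ext(t)/kappa (zero-order hold of the simulated external
    force, converted to mN) plus its own independent noise.
    """
    dt_s = traj.t[1] - traj.t[0] if len(traj.t) > 1 else np.inf
    if 1.0 / fps < dt_s - 1e-12:
        raise ValueError(
            f"fps {fps} exceeds trajectory sampling resolution ({1.0 / dt_s:.1f}/s)"
        )
    rng = np.random.default_rng(seed)
    n = int(np.floor(traj.t[-1] * fps)) + 1
    t = np.arange(n) / fps
    theta = np.interp(t, traj.t, traj.theta)
    # zero-order hold keeps pulse edges rectangular at frame resolution
    idx = np.minimum(np.searchsorted(traj.t, t, side="right") - 1, len(traj.t) - 1)
    F_mN = traj.F_ext[idx] / traj.params.force_unit_per_mN
    theta_cargo = theta + noise_sigma * rng.standard_normal(n)
    theta_blade = theta + F_mN / kappa + noise_sigma * rng.standard_normal(n)
    return TrackedSeries(
        fps=fps, t=t, theta_cargo=theta_cargo, theta_blade=theta_blade,
        kappa=kappa, noise_sigma=noise_sigma, seed=seed,
    )


def write_tracks(path: str | Path, series: TrackedSeries) -> None:
    """Write a track as CSV with columns t_s, theta_cargo_rad, theta_blade_rad."""
    pd.DataFrame(
        {
            "t_s": series.t,
            "theta_cargo_rad": series.theta_cargo,
            "theta_blade_rad": series.theta_blade,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_tracks(
    path: str | Path,
    kappa: float = DEFAULT_KAPPA,
    spacing_rtol: float = 1e-4,
) -> TrackedSeries:
    """Read a track CSV; the frame rate is inferred and validated.

    Raises on missing columns or on timestamps whose spacing deviates from
    uniform by more than ``spacing_rtol`` (relative).
    """
    df = pd.read_csv(path)
    required = ["t_s", "theta_cargo_rad", "theta_blade_rad"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"track file {path} lacks columns {missing}")
    t = df["t_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("track needs at least two frames")
    gaps = np.diff(t)
    med = float(np.median(gaps))
    if med <= 0 or np.any(np.abs(gaps - med) > spacing_rtol * med):
        raise ValueError("non-uniform frame timestamps")
    return TrackedSeries(
        fps=1.0 / med,
        t=t,
        theta_cargo=df["theta_cargo_rad"].to_numpy(float),
        theta_blade=df["theta_blade_rad"].to_numpy(float),
        kappa=kappa,
    )


#: Representative site counts for the four experimental cargo sizes
#: (small 2-4, intermediate 15-20, large 30-40, very large 50-60 ants).
SIZE_BANDS = {
    "small": (2, 4),
    "intermediate": (15, 20),
    "large": (30, 40),
    "very_large": (50, 60),
}


def make_benchmark_suite(
    out_dir: str | Path,
    group_sizes=(3, 18, 35, 55),
    forces_mN=(0.2, 0.4),
    durations_s=(2.0, 5.0),
    seeds=(0, 1, 2),
    params: ModelParams | None = None,
    fps: float = 25.0,
    kappa: float = DEFAULT_KAPPA,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    warmup: float = 40.0,
    trigger_window: float = 250.0,
) -> pd.DataFrame:
    """Generate a grid of tracked recordings plus a ground-truth manifest.

    For each (group size, F_ext, duration, seed) cell one single-pulse
    trial is simulated, rendered to a track CSV, and entered in
    ``manifest.csv`` with the simulation parameters and the ground-truth
    pulse timing/outcome from :func:`classify_outcome`.  Trials whose
    trigger never fires are recorded with outcome ``none``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = params if params is not None else ModelParams()
    rows = []
    for N in group_sizes:
        p = base.with_group_size(int(N))
        for F in forces_mN:
            for dur in durations_s:
                for seed in seeds:
                    spec = PulseSpec(
                        F_ext=float(F), duration_max=float(dur),
                        max_pulses=1, start_after=warmup,
                    )
                    T = warmup + trigger_window + dur + 10.0
                    traj = run_trial(
                        p, spec, T_total=T, seed=int(seed),
                        log_events=False, stop_after_pulse=8.0,
                    )
                    name = f"tracks_N{N}_F{F:g}_dt{dur:g}_s{seed}.csv"
                    series = render_tracked(
                        traj, fps=fps, kappa=kappa,
                        noise_sigma=noise_sigma, seed=int(seed) + 10_000,
                    )
                    write_tracks(out_dir / name, series)
                    if len(traj.pulses) > 0:
                        ev = classify_outcome(traj)
                        row = dict(
                            file=name, N_max=N, F_ext_mN=F, duration_s=dur,
                            seed=seed, outcome=ev.outcome,
                            t_begin=ev.t_begin, t_end=ev.t_end,
                            t_switch=ev.t_switch if ev.t_switch is not None else np.nan,
                            magnitude_mN=ev.magnitude,
                        )
                    else:
                        row = dict(
                            file=name, N_max=N, F_ext_mN=F, duration_s=dur,
                            seed=seed, outcome="none",
                            t_begin=np.nan, t_end=np.nan, t_switch=np.nan,
                            magnitude_mN=np.nan,
                        )
                    rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
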