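"""Analysis of angular time series: pulses, switches, and switching maps.

This is the measurement side of the pipeline.  From a dual-angle track it
recovers the force timeline (cantilever calibration), approximates it by
rectangular pulses, finds direction switches as sustained angular-velocity
reversals, and aggregates trials into the switching-probability-per-time-
bin statistic — a discrete-time hazard of reversal during force
application — binned over force magnitude and duration, smoothed with
k-nearest neighbours plus a moving window, and reduced to the 50%
switching boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .params import PulseEvent
from .synthexp import TrackedSeries

__all__ = [
    "angular_velocity",
    "force_from_tracks",
    "rectangularize_pulses",
    "cluster_event_times",
    "detect_switch",
    "switching_prob_per_bin",
    "SwitchHeatmap",
    "knn_smooth_heatmap",
    "extract_boundary",
]


def angular_velocity(theta_frames: np.ndarray, fps: float) -> np.ndarray:
    """Angular velocity by central differences, rad/s.

    omega_i = (theta_{i+1} - theta_{i-1}) / 2 * fps at interior frames;
    one-sided differences at the two endpoints keep the length equal to
    the input.
    """
    theta = np.asarray(theta_frames, float)
    if theta.size < 3:
        raise ValueError("need at least 3 frames for a central difference")
    omega = np.empty_like(theta)
    omega[1:-1] = (theta[2:] - theta[:-2]) * 0.5 * fps
    omega[0] = (theta[1] - theta[0]) * fps
    omega[-1] = (theta[-1] - theta[-2]) * fps
    return omega


def force_from_tracks(series: TrackedSeries, kappa: float | None = None) -> np.ndarray:
    """Signed force timeline in mN: F(t) = kappa * (theta_blade - theta_cargo)."""
    k = series.kappa if kappa is None else kappa
    return k * (series.theta_blade - series.theta_cargo)


def rectangularize_pulses(
    force_mN: np.ndarray,
    t: np.ndarray,
    threshold: float = 0.05,
    min_gap: float = 0.5,
) -> list[PulseEvent]:
    """Reduce a force timeline to rectangular pulse events.

    Maximal runs with |F| > threshold, merged across sub-``min_gap``
    dropouts, each summarised by (t_begin, t_end, mean |F|).  The outcome
    field is filled with "resist" as a placeholder; switch detection is a
    separate step (:func:`detect_switch`).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    F = np.asarray(force_mN, float)
    t = np.asarray(t, float)
    above = np.abs(F) > threshold
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1  # inclusive frame indices
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if t[s] - t[pe] < min_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        if e <= s:
            continue  # single-frame blips carry no duration
        events.append(
            PulseEvent(
                t_begin=float(t[s]),
                t_end=float(t[e]),
                magnitude=float(np.abs(F[s : e + 1]).mean()),
                outcome="resist",
            )
        )
    return events


def cluster_event_times(timestamps, expected_k: int, seed: int = 0):
    """Group candidate event timestamps with 1-D k-means.

    Returns (sorted cluster centers, membership labels aligned to the
    input order, labelled by sorted-center index).
    """
    ts = np.asarray(timestamps, float).reshape(-1, 1)
    if ts.size == 0:
        raise ValueError("no timestamps to cluster")
    if expected_k < 1 or expected_k > ts.size:
        raise ValueError(f"expected_k must be in [1, {ts.size}]")
    km = KMeans(n_clusters=expected_k, n_init=10, random_state=seed).fit(ts)
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty_like(order)
    remap[order] = np.arange(expected_k)
    return km.cluster_centers_.ravel()[order], remap[km.labels_]


def detect_switch(
    omega: np.ndarray,
    t: np.ndarray,
    pulse: PulseEvent,
    min_hold: float = 0.5,
) -> float | None:
    """First sustained direction reversal inside a pulse window, or None.

    The reference direction is the motion just before ``t_begin``; a
    reversal counts if the opposite sign persists for at least
    ``min_hold`` seconds, which rejects single-frame tracking flickers.
    """
    omega = np.asarray(omega, float)
    t = np.asarray(t, float)
    if pulse.t_begin < t[0] - 1e-9 or pulse.t_end > t[-1] + 1e-9:
        raise ValueError("pulse window lies outside the series")
    i0 = int(np.searchsorted(t, pulse.t_begin, side="left"))
    i1 = int(np.searchsorted(t, pulse.t_end, side="right"))
    base = omega[max(i0 - 1, 0)]
    base_sign = 1.0 if base >= 0 else -1.0
    dt_s = t[1] - t[0] if len(t) > 1 else np.inf
    hold_n = max(1, int(round(min_hold / dt_s)))
    reversed_ = omega * (-base_sign) > 0
    for i in range(i0, i1):
        if not reversed_[i]:
            continue
        j = i + hold_n
        if j > len(omega):
            break
        if np.all(reversed_[i:j]):
            return float(t[i])
    return None


def switching_prob_per_bin(
    events: list[PulseEvent], bin_width: float
) -> pd.DataFrame:
    """Discrete-time switching hazard over pulse duration.

    The time axis from 0 to the longest effective duration is split into
    even ``bin_width`` bins.  A resisting trial of duration d contributes
    a "no switch" count to every bin it covers; a switching trial counts
    "no switch" in the bins before its switch and one "switch" in the bin
    containing d = t_switch - t_begin.  Returns a frame with bin edges,
    counts and probability switch/(switch + no_switch) (NaN where empty).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not events:
        raise ValueError("no pulse events supplied")
    durations = [ev.duration for ev in events]
    n_bins = max(1, int(np.ceil(max(durations) / bin_width - 1e-9)))
    switch = np.zeros(n_bins, int)
    no_switch = np.zeros(n_bins, int)
    for ev in events:
        d = ev.duration
        if ev.outcome == "switch":
            k = min(int(d / bin_width), n_bins - 1)
            switch[k] += 1
            no_switch[:k] += 1
        else:
            covered = max(1, int(np.ceil(d / bin_width - 1e-9)))
            no_switch[:covered] += 1
    total = switch + no_switch
    with np.errstate(invalid="ignore"):
        prob = np.where(total > 0, switch / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_left_s": np.arange(n_bins) * bin_width,
            "bin_right_s": (np.arange(n_bins) + 1) * bin_width,
            "n_switch": switch,
            "n_no_switch": no_switch,
            "p_switch": prob,
        }
    )


@dataclass
class SwitchHeatmap:
    """Smoothed switching probability over (F_ext, delta_t).

    ``prob[i, j]`` is the probability at force bin i (rows, ``F_grid``)
    and duration bin j (columns, ``dt_grid``); ``counts`` holds the number
    of switch records among the k neighbours that entered each cell.
    """

    F_grid: np.ndarray
    dt_grid: np.ndarray
    prob: np.ndarray
    counts: np.ndarray
    k: int
    window: int


def knn_smooth_heatmap(
    records: pd.DataFrame,
    k: int = 15,
    window: int = 3,
    grid_shape: tuple[int, int] = (20, 20),
    F_range: tuple[float, float] | None = None,
    dt_range: tuple[float, float] | None = None,
) -> SwitchHeatmap:
    """Bin outcome records into a smoothed (F_ext, delta_t) heatmap.

    ``records`` needs columns F_ext_mN, dt_s and outcome (1 = switch
    bin, 0 = no-switch bin).  Each grid cell averages its k nearest
    records (Euclidean distance in z-scored axes), then a ``window`` x
    ``window`` moving average is applied.  Probabilities stay in [0, 1].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    req = {"F_ext_mN", "dt_s", "outcome"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    n = len(records)
    if n == 0:
        raise ValueError("no records")
    if n < k:
        warnings.warn(f"only {n} records; clipping k from {k}", stacklevel=2)
        k = n
    X = records[["F_ext_mN", "dt_s"]].to_numpy(float)
    y = records["outcome"].to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    Fr = F_range if F_range is not None else (X[:, 0].min(), X[:, 0].max())
    Dr = dt_range if dt_range is not None else (X[:, 1].min(), X[:, 1].max())
    F_grid = np.linspace(Fr[0], Fr[1], grid_shape[0])
    dt_grid = np.linspace(Dr[0], Dr[1], grid_shape[1])
    cells = np.array(
        [[f, d] for f in F_grid for d in dt_grid], float
    )
    cells_z = (cells - mu) / sd
    nn = NearestNeighbors(n_neighbors=k).fit(Z)
    _, idx = nn.kneighbors(cells_z)
    prob = y[idx].mean(axis=1).reshape(grid_shape)
    counts = y[idx].sum(axis=1).reshape(grid_shape).astype(int)
    if window > 1:
        prob = uniform_filter(prob, size=window, mode="nearest")
    return SwitchHeatmap(
        F_grid=F_grid, dt_grid=dt_grid, prob=prob, counts=counts,
        k=k, window=window,
    )


def extract_boundary(heatmap: SwitchHeatmap, level: float = 0.5) -> np.ndarray:
    """Level crossings of the switching probability, per force row.

    For each F row the first crossing of ``level`` along the duration
    axis is located by linear interpolation; returns an (m, 2) array of
    (F_ext, delta_t) points (empty, with a warning, if no row crosses).
    """
    pts = []
    for i, F in enumerate(heatmap.F_grid):
        row = heatmap.prob[i]
        for j in range(len(row) - 1):
            a, b = row[j], row[j + 1]
            if np.isnan(a) or np.isnan(b):
                continue
            if (a - level) * (b - level) < 0 or a == level:
                if a == level:
                    dt_c = heatmap.dt_grid[j]
                else:
                    frac = (level - a) / (b - a)
                    dt_c = heatmap.dt_grid[j] + frac * (
                        heatmap.dt_grid[j + 1] - heatmap.dt_grid[j]
                    )
                pts.append((F, dt_c))
                break
    if not pts:
        warnings.warn("no 50% crossing found in any heatmap row", stacklevel=2)
        return np.empty((0, 2))
    return np.asarray(pts)
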