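"""Parameter sets, unit conventions, and config serialization.

The simulation runs in dimensionless *model force units*.  A single puller
ant exerts ``f0`` model units, and field measurements put a single leader
ant's pull at roughly 0.1 mN, so the default conversion is
``force_unit_per_mN = f0 / 0.1 = 28`` model units per millinewton.  All
user-facing forces (pulse magnitudes, calibrated forces from tracked
angles) are expressed in mN and converted at the boundary.

Angles are radians, unwrapped (no 2*pi jumps); the nest sits at
``nest_angle = 0`` by convention.  Rates are 1/s, times are seconds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ModelParams",
    "PulseSpec",
    "PulseEvent",
    "to_model_force",
    "from_model_force",
    "read_config",
    "write_config",
]


@dataclass
class ModelParams:
    """All microscopic rates, forces, geometry and integration constants.

    Defaults are the ordered-regime parameter set used for the largest
    cargo (60 attachment sites).  ``gamma`` may be left ``None``, in which
    case it is set to ``3 * N_max`` — the damping coefficient scales
    linearly with the number of attachment sites because every attached
    ant adds drag.
    """

    N_max: int = 60                 # attachment sites on the cargo ring
    f0: float = 2.8                 # single-ant pull force (model units)
    F_ind: float = 28.0             # individuality (inverse coupling) force scale
    k_on: float = 0.021             # attachment rate per empty site (1/s)
    k_off: float = 0.015            # detachment rate per attached ant (1/s)
    k_forget: float = 0.09          # informed -> uninformed rate (1/s)
    k_c: float = 1.0                # basal puller<->lifter conversion rate (1/s)
    k_ori: float = 0.7              # reorientation rate per attached ant (1/s)
    gamma: float | None = None      # damping (model force units * s / length)
    l_rod: float = 10.0             # rod length (length units)
    phi_max_deg: float = 52.0       # max body-axis deviation from site normal
    dt: float = 0.01                # integration step (s)
    force_unit_per_mN: float = 28.0 # model force units per mN
    nest_angle: float = 0.0         # nest direction (radians)
    # Effective attachment multiplier.  The default keeps the cargo close to
    # saturation (stationary occupancy 0.9, i.e. <N> = 54 of 60 sites) as in
    # the field recordings; set to 1.0 for bare per-empty-site kinetics.
    attach_boost: float = 6.43
    # What force the ants feel for role switching/reorientation:
    # "tangential" = the rod-transmitted net tangential force (= gamma * v),
    # matching the mean-field rate equations; "planar" = the full planar
    # force at the cargo centre of mass, radial components included.
    local_force_model: str = "tangential"

    def __post_init__(self) -> None:
        if self.gamma is None:
            self.gamma = 3.0 * self.N_max
        self.validate()

    def validate(self) -> None:
        if int(self.N_max) != self.N_max or self.N_max < 1:
            raise ValueError(f"N_max must be an integer >= 1, got {self.N_max}")
        self.N_max = int(self.N_max)
        for name in ("k_on", "k_off", "k_forget", "k_c", "k_ori", "attach_boost"):
            v = getattr(self, name)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite rate >= 0, got {v}")
        if not (self.f0 > 0.0):
            raise ValueError(f"f0 must be > 0, got {self.f0}")
        if not (self.F_ind > 0.0):
            raise ValueError(f"F_ind must be > 0, got {self.F_ind}")
        if not (self.gamma > 0.0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (self.dt > 0.0):
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not (0.0 < self.phi_max_deg < 90.0):
            raise ValueError(f"phi_max_deg must lie in (0, 90), got {self.phi_max_deg}")
        if not (self.l_rod > 0.0):
            raise ValueError(f"l_rod must be > 0, got {self.l_rod}")
        if not (self.force_unit_per_mN > 0.0):
            raise ValueError(
                f"force_unit_per_mN must be > 0, got {self.force_unit_per_mN}"
            )
        if self.local_force_model not in ("planar", "tangential"):
            raise ValueError(
                f"local_force_model must be 'planar' or 'tangential', "
                f"got {self.local_force_model!r}"
            )

    @property
    def phi_max(self) -> float:
        """Maximum body-axis deviation in radians."""
        return math.radians(self.phi_max_deg)

    @property
    def k_on_eff(self) -> float:
        """Effective per-empty-site attachment rate (1/s)."""
        return self.k_on * self.attach_boost

    def with_group_size(self, N_max: int) -> "ModelParams":
        """Copy with a new site count and the matching gamma = 3 * N_max."""
        return dataclasses.replace(self, N_max=N_max, gamma=3.0 * N_max)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class PulseSpec:
    """One external-force protocol: rectangular opposing pulses at the nest.

    The pulse fires when the unwrapped cargo angle crosses
    ``trigger_angle`` (once armed), points against the instantaneous
    direction of motion under the default ``direction_rule``, and lasts at
    most ``duration_max`` seconds.
    """

    F_ext: float                    # magnitude in mN
    duration_max: float             # maximum application time (s)
    trigger_angle: float = 0.0      # radians
    direction_rule: str = "oppose-motion"   # or "fixed-sign"
    fixed_sign: int = -1            # used only under "fixed-sign"
    refractory: float = 10.0        # min time between pulses (s)
    max_pulses: int = -1            # -1 = unlimited
    start_after: float = 0.0        # arm pulses only after this time (s)
    # The robot's clutch disengages once the cargo moves with the force:
    # the pulse ends after the velocity has aligned with the applied force
    # for switch_hold seconds.  Set end_on_switch=False for a pulse that
    # always runs its full duration.
    end_on_switch: bool = True
    switch_hold: float = 0.5

    def __post_init__(self) -> None:
        if not (self.F_ext >= 0.0):
            raise ValueError(f"F_ext must be >= 0 mN, got {self.F_ext}")
        if not (self.duration_max > 0.0):
            raise ValueError(f"duration_max must be > 0 s, got {self.duration_max}")
        if self.direction_rule not in ("oppose-motion", "fixed-sign"):
            raise ValueError(f"unknown direction_rule {self.direction_rule!r}")
        if self.fixed_sign not in (-1, 1):
            raise ValueError("fixed_sign must be -1 or +1")
        if not (self.switch_hold >= 0.0):
            raise ValueError("switch_hold must be >= 0")


@dataclass
class PulseEvent:
    """One force application, as recovered from a trajectory or track."""

    t_begin: float
    t_end: float
    magnitude: float                # mean calibrated |force| over the effective duration (mN)
    outcome: str                    # "switch" | "resist"
    t_switch: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_begin < self.t_end):
            raise ValueError("t_begin must precede t_end")
        if self.outcome not in ("switch", "resist"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "switch":
            if self.t_switch is None or not (self.t_begin < self.t_switch <= self.t_end):
                raise ValueError("switch outcome requires t_begin < t_switch <= t_end")
        elif self.t_switch is not None:
            raise ValueError("resist outcome must not carry a t_switch")

    @property
    def duration(self) -> float:
        """Effective pulse duration: to the switch if one occurred, else full."""
        if self.outcome == "switch":
            assert self.t_switch is not None
            return self.t_switch - self.t_begin
        return self.t_end - self.t_begin


def to_model_force(F_mN: float, params: ModelParams) -> float:
    """Convert a force in mN to model force units."""
    if not (F_mN >= 0.0):
        raise ValueError(f"force in mN must be >= 0, got {F_mN}")
    return F_mN * params.force_unit_per_mN


def from_model_force(F_model: float, params: ModelParams) -> float:
    """Convert model force units to mN (signed values allowed)."""
    return F_model / params.force_unit_per_mN


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def write_config(path: str | Path, params: ModelParams) -> None:
    """Write a flat key-value YAML config (also valid JSON-ish mapping)."""
    d = params.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_config(path: str | Path) -> ModelParams:
    """Read a flat config file; missing keys fall back to defaults.

    Unknown keys are rejected with an explicit message and non-numeric
    values raise a :class:`ValueError`.  An empty file yields the full
    default parameter set.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    unknown = sorted(set(raw) - _PARAM_FIELDS)
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; valid keys are {sorted(_PARAM_FIELDS)}"
        )
    for key, val in raw.items():
        if val is None and key == "gamma":
            continue
        if key == "local_force_model":
            if not isinstance(val, str):
                raise ValueError(f"config key {key!r} must be a string, got {val!r}")
            continue
        if isinstance(val, bool) or not isinstance(val, (int, float)):
            raise ValueError(f"config key {key!r} must be numeric, got {val!r}")
    return ModelParams(**raw)
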