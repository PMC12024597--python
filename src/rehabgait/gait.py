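"""Joint range-of-motion checks and platform workspace sampling.

Angles are magnitudes in degrees per anatomical direction (the ROM table's
``0..X`` convention); mapping a signed recording onto per-direction
magnitudes is the caller's responsibility.  Normal gait uses only a small
subset of the physiological range, which is why angle classification is
three-valued: within the gait range, within the physiological range, or
exceeding it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, KinematicsError
from .kinematics import MechanismGeometry, Pose, inverse_kinematics

__all__ = [
    "RomEntry",
    "JointROMTable",
    "AngleSeries",
    "classify_angle",
    "discretize_series",
    "workspace_sample",
    "WorkspaceReport",
    "GAIT",
    "PHYSIOLOGICAL",
    "EXCEEDS",
    "NOT_APPLICABLE",
]

GAIT = "gait"
PHYSIOLOGICAL = "physiological"
EXCEEDS = "exceeds"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class RomEntry:
    """Physiological and gait angular limits for one (joint, plane,
    direction); ``applicable=False`` marks directions the joint lacks."""

    joint: str
    plane: str
    direction: str
    physiological: tuple[float, float] | None
    gait: tuple[float, float] | None
    applicable: bool = True


@dataclass
class JointROMTable:
    """Lookup of RomEntry by (joint, plane, direction)."""

    entries: dict[tuple[str, str, str], RomEntry]

    def get(self, joint: str, plane: str, direction: str) -> RomEntry:
        key = (joint, plane, direction)
        if key not in self.entries:
            raise ConfigError(f"no ROM entry for {key}")
        return self.entries[key]

    def __iter__(self):
        return iter(self.entries.values())


@dataclass
class AngleSeries:
    """A joint-angle recording: (t seconds, angle degrees) samples with
    strictly increasing times."""

    joint: str
    plane: str
    direction: str
    samples: list[tuple[float, float]]

    def __post_init__(self):
        times = [t for t, _ in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError("sample times must be strictly increasing")
        if any(not np.isfinite(a) for _, a in self.samples):
            raise ConfigError("angles must be finite")

    @property
    def angles(self) -> np.ndarray:
        return np.array([a for _, a in self.samples], dtype=float)


def classify_angle(rom: JointROMTable, joint: str, plane: str,
                   direction: str, angle: float) -> str:
    """Classify an angle magnitude against the gait and physiological limits.

    Boundaries are inclusive: ``gait`` if 0 <= angle <= gait limit,
    ``physiological`` if <= physiological limit, else ``exceeds``.
    """
    entry = rom.get(joint, plane, direction)
    if not entry.applicable:
        return NOT_APPLICABLE
    if angle < 0:
        raise ConfigError("angles are magnitudes; got a negative value")
    if entry.gait[0] <= angle <= entry.gait[1]:
        return GAIT
    if entry.physiological[0] <= angle <= entry.physiological[1]:
        return PHYSIOLOGICAL
    return EXCEEDS


@dataclass
class DiscretizationReport:
    state: int
    gait_fraction: float
    threshold: float
    n_samples: int


def discretize_series(rom: JointROMTable, series: AngleSeries,
                      good_fraction: float = 0.8) -> DiscretizationReport:
    """Collapse an angle series to a binary node state (0 good / 1 poor).

    State 0 iff the fraction of samples classified ``gait`` is at least
    ``good_fraction`` (boundary inclusive; default 0.8).  The report feeds
    evidence construction for the rehabilitation network.
    """
    if not series.samples:
        raise ConfigError("cannot discretize an empty series")
    if not 0.0 < good_fraction <= 1.0:
        raise ConfigError("good_fraction must lie in (0, 1]")
    labels = [classify_angle(rom, series.joint, series.plane,
                             series.direction, a) for a in series.angles]
    if labels and labels[0] == NOT_APPLICABLE:
        raise ConfigError(
            f"series targets a not-applicable ROM entry "
            f"({series.joint}, {series.plane}, {series.direction})")
    frac = sum(1 for c in labels if c == GAIT) / len(labels)
    state = 0 if frac >= good_fraction else 1
    return DiscretizationReport(state, frac, good_fraction, len(labels))


@dataclass
class WorkspaceReport:
    """Reachable fraction of a pose grid under per-branch stroke limits."""

    fraction: float
    n_grid: int
    n_reachable: int
    bounding_box: tuple[tuple[float, float], ...] | None  # per axis, or None


def workspace_sample(geometry: MechanismGeometry,
                     stroke: Sequence[tuple[float, float]],
                     box: Sequence[tuple[float, float]],
                     step: float) -> WorkspaceReport:
    """Grid-sample the pose box; a pose is reachable iff every rod length
    lies within its branch's stroke interval.  Deterministic for a fixed
    grid."""
    if step <= 0:
        raise ConfigError("grid step must be positive")
    if len(stroke) != 3 or len(box) != 3:
        raise ConfigError("stroke and box must have one entry per axis/branch")
    axes = []
    for lo, hi in box:
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ConfigError("pose box must be finite with lo <= hi")
        axes.append(np.arange(lo, hi + step / 2, step))
    if any(len(ax) == 0 for ax in axes):
        raise ConfigError("empty pose grid")
    n_grid = 0
    reach_pts = []
    for px, py, pz in itertools.product(*axes):
        n_grid += 1
        try:
            lengths = inverse_kinematics(geometry, Pose(px, py, pz))
        except KinematicsError:
            continue
        ok = all(lo <= L <= hi for (lo, hi), L in
                 zip(stroke, lengths.as_array()))
        if ok:
            reach_pts.append((px, py, pz))
    if reach_pts:
        arr = np.array(reach_pts)
        bbox = tuple((float(arr[:, i].min()), float(arr[:, i].max()))
                     for i in range(3))
    else:
        bbox = None
    return WorkspaceReport(len(reach_pts) / n_grid, n_grid, len(reach_pts),
                           bbox)
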