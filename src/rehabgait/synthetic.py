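"""Synthetic inputs at desk scale: patient cohorts, joint-angle recordings,
platform trajectories, and calibration rows.

The generators emulate the study conditions the toolkit is built around — a
surveyed cohort of rehabilitation patients whose discretized joint states
follow the network's probability tables, gait-lab style angle recordings, and
the CAD-verification platform motion (vertical rise of 300 mm over 5 s from
(0, 485, -1225), sampled every 0.5 s).  Every generator takes an explicit
seed and is bit-reproducible; no hidden random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gait import AngleSeries, JointROMTable
from .kinematics import (
    CalibrationRow,
    MechanismGeometry,
    Pose,
    TrajectorySample,
    inverse_kinematics,
)
from .network import NetworkModel

__all__ = [
    "CohortConfig",
    "AngleChannelConfig",
    "AngleGenConfig",
    "gen_cohort",
    "gen_state_sequence",
    "gen_angle_series",
    "gen_trajectory",
    "gen_calibration_rows",
]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sampling configuration.

    ``root_priors`` overrides P(state 1) per observation root (default: the
    model's own priors); ``slices`` requests per-subject state sequences for
    dynamic updating, generated from ``transition`` (row-stochastic).
    """

    n: int = 200
    root_priors: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    slices: int | None = None
    transition: Sequence[Sequence[float]] | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("cohort size must be at least 1")
        for node, p in self.root_priors.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ConfigError(f"root prior for {node} outside [0, 1]")


def gen_cohort(model: NetworkModel, cfg: CohortConfig) -> pd.DataFrame:
    """Ancestral sampling of subject node states (root to leaf).

    Returns a DataFrame of shape (n, n_nodes) with one sampled state index
    per node per subject, columns in topological order.
    """
    rng = np.random.default_rng(cfg.seed)
    order = model.topological_order()
    cards = {n: model.card(n) for n in order}
    data: dict[str, np.ndarray] = {}
    for node in order:
        if model.is_root(node):
            prior = model.priors[node].copy()
            if node in cfg.root_priors:
                p1 = float(cfg.root_priors[node])
                prior = np.array([1.0 - p1, p1])
            u = rng.random(cfg.n)
            data[node] = (u >= prior[0]).astype(int)
        else:
            tab = model.tables[node]
            arr = tab.to_array([cards[p] for p in tab.parent_order])
            cfgs = tuple(data[p] for p in tab.parent_order)
            probs = arr[cfgs]                      # (n, k)
            u = rng.random(cfg.n)
            cdf = np.cumsum(probs, axis=1)
            data[node] = (u[:, None] >= cdf).sum(axis=1)
    return pd.DataFrame(data, columns=order)


def gen_state_sequence(transition: Sequence[Sequence[float]], n_slices: int,
                       seed: int, init_state: int = 0) -> list[int]:
    """Markov-chain state sequence from a row-stochastic transition matrix;
    the ground truth for sliding-window transition recovery tests."""
    T = np.asarray(transition, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ConfigError("transition must be a square matrix")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigError("transition rows must be probability vectors")
    rng = np.random.default_rng(seed)
    state = int(init_state)
    out = [state]
    for _ in range(n_slices - 1):
        state = int(rng.choice(T.shape[0], p=T[state]))
        out.append(state)
    return out


@dataclass(frozen=True)
class AngleChannelConfig:
    """Rectified-sinusoid channel: amplitude/period of the gait cycle,
    Gaussian measurement noise, and a per-cycle rate of out-of-range
    episodes (cycles whose peak is pushed beyond the gait limit)."""

    amplitude_deg: float
    period_s: float = 1.1
    phase_rad: float = 0.0
    noise_sd_deg: float = 0.0
    episode_rate: float = 0.0
    episode_scale: float = 1.3   # episode peak = max(A, scale * gait limit)

    def __post_init__(self):
        if self.amplitude_deg < 0:
            raise ConfigError("amplitude must be nonnegative")
        if self.period_s <= 0:
            raise ConfigError("period must be positive")
        if not 0.0 <= self.episode_rate <= 1.0:
            raise ConfigError("episode_rate is a per-cycle probability")


@dataclass(frozen=True)
class AngleGenConfig:
    channels: Mapping[tuple[str, str, str], AngleChannelConfig]
    duration_s: float = 11.0
    dt_s: float = 0.05
    seed: int = 0


def gen_angle_series(rom: JointROMTable, cfg: AngleGenConfig
                     ) -> list[AngleSeries]:
    """Generate angle-magnitude recordings for the configured channels.

    Angles are ``|A sin(2 pi t / T + phase)|`` plus truncated-at-zero
    Gaussian noise; in an episode cycle the amplitude is raised beyond the
    channel's gait limit.  Seed-deterministic.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.dt_s, cfg.duration_s + cfg.dt_s / 2, cfg.dt_s)
    out = []
    for key in sorted(cfg.channels):
        ch = cfg.channels[key]
        joint, plane, direction = key
        entry = rom.get(joint, plane, direction)
        cycle = np.floor((t / ch.period_s) + 1e-12).astype(int)
        n_cycles = int(cycle.max()) + 1
        episodes = rng.random(n_cycles) < ch.episode_rate
        amp = np.full(t.shape, ch.amplitude_deg)
        if entry.applicable and entry.gait is not None:
            boosted = max(ch.amplitude_deg,
                          ch.episode_scale * entry.gait[1])
            amp[episodes[cycle]] = boosted
        base = np.abs(amp * np.sin(2 * np.pi * t / ch.period_s
                                   + ch.phase_rad))
        noise = rng.normal(0.0, ch.noise_sd_deg, size=t.shape) \
            if ch.noise_sd_deg > 0 else 0.0
        angles = np.clip(base + noise, 0.0, None)
        out.append(AngleSeries(joint, plane, direction,
                               list(zip(t.tolist(), angles.tolist()))))
    return out


#: Defaults of the CAD cross-check motion: vertical rise at constant speed.
ADAMS_VERTICAL_DEFAULTS = {
    "start": (0.0, 485.0, -1225.0),
    "rise_mm": 300.0,
    "duration_s": 5.0,
    "dt_s": 0.5,
}


def gen_trajectory(kind: str, params: Mapping | None = None,
                   seed: int | None = None) -> list[TrajectorySample]:
    """Generate a platform trajectory.

    Kinds:

    * ``"adams_vertical"`` — the verification motion: start (0, 485, -1225)
      mm, rise 300 mm in Z at constant speed over 5 s, sampled at t = 0.5,
      1.0, ..., 5.0 (10 points; t = 0 excluded by convention).
    * ``"circle_xz"`` — circle of given radius in the XZ plane around a
      center pose, one revolution per ``period_s``.
    * ``"gait_ellipse"`` — foot-path-like ellipse in the XZ plane (stride
      semi-axis ``ax_mm``, lift semi-axis ``az_mm``) with optional Gaussian
      jitter (seeded).
    """
    p = dict(params or {})
    if kind == "adams_vertical":
        d = {**ADAMS_VERTICAL_DEFAULTS, **p}
        x0, y0, z0 = d["start"]
        speed = d["rise_mm"] / d["duration_s"]
        n = round(d["duration_s"] / d["dt_s"])
        return [TrajectorySample(t, Pose(x0, y0, z0 + speed * t))
                for t in (d["dt_s"] * (i + 1) for i in range(n))]
    if kind == "circle_xz":
        center = p.get("center", (0.0, 485.0, -1075.0))
        radius = float(p.get("radius_mm", 100.0))
        period = float(p.get("period_s", 4.0))
        n = int(p.get("n_samples", 16))
        dt = period / n
        out = []
        for i in range(1, n + 1):
            t = i * dt
            ang = 2 * np.pi * t / period
            out.append(TrajectorySample(
                t, Pose(center[0] + radius * np.cos(ang), center[1],
                        center[2] + radius * np.sin(ang))))
        return out
    if kind == "gait_ellipse":
        center = p.get("center", (0.0, 485.0, -1075.0))
        ax = float(p.get("ax_mm", 150.0))
        az = float(p.get("az_mm", 50.0))
        period = float(p.get("period_s", 1.1))
        n = int(p.get("n_samples", 22))
        jitter = float(p.get("jitter_mm", 0.0))
        rng = np.random.default_rng(0 if seed is None else seed)
        dt = period / n
        out = []
        for i in range(1, n + 1):
            t = i * dt
            ang = 2 * np.pi * t / period
            dx, dz = (rng.normal(0.0, jitter, size=2) if jitter > 0
                      else (0.0, 0.0))
            out.append(TrajectorySample(
                t, Pose(center[0] + ax * np.cos(ang) + dx, center[1],
                        center[2] + az * np.sin(ang) + dz)))
        return out
    raise ConfigError(f"unknown trajectory kind {kind!r}")


def gen_calibration_rows(true_geometry: MechanismGeometry,
                         poses: Sequence[Pose], noise_sd_mm: float = 0.0,
                         seed: int = 0) -> list[CalibrationRow]:
    """Closed-form rod lengths at the given poses plus i.i.d. Gaussian
    noise; ground truth for calibration-recovery tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for pose in poses:
        lengths = inverse_kinematics(true_geometry, pose)
        noise = (rng.normal(0.0, noise_sd_mm, size=3)
                 if noise_sd_mm > 0 else np.zeros(3))
        rows.append(CalibrationRow(pose,
                                   lengths.L1 + noise[0],
                                   lengths.L2 + noise[1],
                                   lengths.L3 + noise[2]))
    return rows
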