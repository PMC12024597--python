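"""Kinematics of the 3-branch PRPR translational parallel platform.

The rehabilitation actuator couples a fixed frame to an ankle-mounted moving
platform through three prismatic-revolute-prismatic-revolute branches.  The
mechanism has three purely translational degrees of freedom, so the moving
platform pose reduces to the position ``(Px, Py, Pz)`` of its origin in the
fixed frame (mm; Z up, X along the fixed platform's horizontal bar, Y
right-handed; the device operates hanging below the rails, Pz < 0).

Closed-form relations (all lengths mm):

* passive first-prismatic displacements: ``d1 = d2 = Py``, ``d3 = Px``;
* push-rod (second prismatic) lengths, with lumped offsets
  ``m = L/2 - a - c`` and ``q = b + c``::

      L1 = sqrt((Px + m)^2 + Pz^2)
      L2 = sqrt((Px - m)^2 + Pz^2)
      L3 = sqrt((q - Py)^2 + Pz^2)

Individual link dimensions a, b, c, L enter the length model only through m
and q, so geometry may be supplied lumped; full parameters are needed only
for the branch-point construction and its right-triangle constraint
residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    CalibrationError,
    CapabilityError,
    ConfigError,
    InfeasiblePoseError,
    SingularGeometryError,
)

__all__ = [
    "MechanismTopology",
    "MechanismGeometry",
    "Pose",
    "ActuatorLengths",
    "PassiveDisplacements",
    "BranchPoints",
    "TrajectorySample",
    "CommandSample",
    "CalibrationRow",
    "CalibrationReport",
    "mobility",
    "passive_displacements",
    "inverse_kinematics",
    "forward_kinematics",
    "branch_points",
    "constraint_residuals",
    "calibrate_lumped_offsets",
    "trajectory_commands",
]


@dataclass(frozen=True)
class MechanismTopology:
    """Component/pair counts for the modified Gruebler-Kutzbach criterion."""

    n: int = 11          # components, frame included
    g: int = 12          # kinematic pairs
    sum_fi: int = 12     # total pair freedoms
    mu: int = 3          # redundant constraints


def mobility(topology: MechanismTopology = MechanismTopology()) -> int:
    """Degrees of freedom ``M = 6(n - g - 1) + sum_fi + mu`` (exact ints)."""
    t = topology
    for name in ("n", "g", "sum_fi", "mu"):
        v = getattr(t, name)
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ConfigError(f"topology count {name}={v!r} must be a "
                              "nonnegative integer")
    return 6 * (t.n - t.g - 1) + t.sum_fi + t.mu


@dataclass(frozen=True)
class Pose:
    """Moving-platform origin in the fixed frame (mm); working poses have
    ``pz < 0``."""

    px: float
    py: float
    pz: float

    def as_array(self) -> np.ndarray:
        return np.array([self.px, self.py, self.pz], dtype=float)


@dataclass(frozen=True)
class ActuatorLengths:
    """Push-rod lengths C1B1, C2B2, C3B3 (mm, strictly positive)."""

    L1: float
    L2: float
    L3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L1, self.L2, self.L3], dtype=float)


@dataclass(frozen=True)
class PassiveDisplacements:
    """First prismatic displacements d1, d2, d3 (mm); d1 = d2 structurally."""

    d1: float
    d2: float
    d3: float


@dataclass(frozen=True)
class MechanismGeometry:
    """Platform geometry, either full link dimensions or lumped offsets.

    Full mode: moving platform horizontal bars 2b and vertical bar 2a, fixed
    vertical bar L, branch offset c (= AiCi).  Lumped mode keeps only the
    identifiable combinations ``m = L/2 - a - c`` and ``q = b + c``.
    """

    m: float | None = None
    q: float | None = None
    a: float | None = None
    b: float | None = None
    c: float | None = None
    L: float | None = None
    mode: str = "lumped"

    @classmethod
    def lumped(cls, m: float, q: float | None = None) -> "MechanismGeometry":
        if m is not None and not math.isfinite(m):
            raise ConfigError("lumped offset m must be finite")
        if q is not None and not math.isfinite(q):
            raise ConfigError("lumped offset q must be finite")
        return cls(m=float(m), q=None if q is None else float(q),
                   mode="lumped")

    @classmethod
    def full(cls, a: float, b: float, c: float, L: float
             ) -> "MechanismGeometry":
        if min(a, b, c, L) <= 0:
            raise ConfigError("link dimensions must be positive")
        return cls(m=L / 2.0 - a - c, q=b + c, a=float(a), b=float(b),
                   c=float(c), L=float(L), mode="full")

    @property
    def is_full(self) -> bool:
        return self.mode == "full"

    def require_m(self) -> float:
        if self.m is None:
            raise ConfigError("geometry has no lumped offset m")
        return float(self.m)

    def require_q(self) -> float:
        if self.q is None:
            raise ConfigError("geometry has no lumped offset q "
                              "(branch 3 uncalibrated)")
        return float(self.q)


def passive_displacements(pose: Pose) -> PassiveDisplacements:
    """Structural coupling of the first prismatic joints: (Py, Py, Px)."""
    return PassiveDisplacements(pose.py, pose.py, pose.px)


def inverse_kinematics(geometry: MechanismGeometry, pose: Pose
                       ) -> ActuatorLengths:
    """Closed-form push-rod lengths for a platform pose.

    A zero length (pose at a branch's pivot line) is a degenerate pose.
    """
    m = geometry.require_m()
    q = geometry.require_q()
    d = passive_displacements(pose)
    # The (Py - d1) and (Px - d3) terms of the general expressions vanish
    # identically through the passive coupling; they are kept here so the
    # computation follows the constraint structure, not a shortcut.
    l1 = math.sqrt((pose.px + m) ** 2 + pose.pz ** 2
                   + (pose.py - d.d1) ** 2)
    l2 = math.sqrt((pose.px - m) ** 2 + pose.pz ** 2
                   + (pose.py - d.d2) ** 2)
    l3 = math.sqrt((q - pose.py) ** 2 + pose.pz ** 2
                   + (pose.px - d.d3) ** 2)
    if min(l1, l2, l3) <= 0.0:
        raise InfeasiblePoseError(f"degenerate pose {pose}: zero rod length")
    return ActuatorLengths(l1, l2, l3)


#: Tolerance (mm^2) below which a slightly negative FK radicand is clipped.
_FK_RADICAND_TOL = 1e-6


def forward_kinematics(geometry: MechanismGeometry, lengths: ActuatorLengths,
                       py_box: tuple[float, float] | None = None) -> Pose:
    """Invert the closed-form length model.

    ``Px = (L1^2 - L2^2) / (4 m)``; ``Pz`` takes the working-configuration
    root (negative, platform hanging below the rails); ``Py = q +/- r`` with
    the root chosen inside ``py_box`` (default ``[0, q]``; the lower root is
    preferred when both fall inside).
    """
    m = geometry.require_m()
    q = geometry.require_q()
    if m == 0.0:
        raise SingularGeometryError("m = 0 makes Px unobservable from "
                                    "branch lengths")
    if min(lengths.L1, lengths.L2, lengths.L3) <= 0:
        raise InfeasiblePoseError("actuator lengths must be positive")
    # Factored difference-of-squares forms limit cancellation error when the
    # radicand is small relative to the squared lengths.
    px = ((lengths.L1 - lengths.L2) * (lengths.L1 + lengths.L2)) / (4.0 * m)
    rad_z = (lengths.L1 - (px + m)) * (lengths.L1 + (px + m))
    if rad_z < -_FK_RADICAND_TOL:
        raise InfeasiblePoseError(
            f"lengths inconsistent: Pz radicand {rad_z:.3g} mm^2 < 0")
    pz = -math.sqrt(max(rad_z, 0.0))
    rad_y = (lengths.L3 - pz) * (lengths.L3 + pz)
    if rad_y < -_FK_RADICAND_TOL:
        raise InfeasiblePoseError(
            f"lengths inconsistent: Py radicand {rad_y:.3g} mm^2 < 0")
    r = math.sqrt(max(rad_y, 0.0))
    lo, hi = py_box if py_box is not None else (0.0, q)
    candidates = [py for py in (q - r, q + r) if lo <= py <= hi]
    if not candidates:
        raise InfeasiblePoseError(
            f"neither Py root ({q - r:.3f}, {q + r:.3f}) lies in the "
            f"workspace box [{lo}, {hi}]")
    return Pose(px, candidates[0], pz)


# ---------------------------------------------------------------------------
# Branch-point construction and constraint residuals (full geometry)


@dataclass(frozen=True)
class BranchPoints:
    """Positions of Ai, Ci, Mi, Bi (i = 1..3) in the fixed frame (mm)."""

    A: tuple[np.ndarray, np.ndarray, np.ndarray]
    C: tuple[np.ndarray, np.ndarray, np.ndarray]
    M: tuple[np.ndarray, np.ndarray, np.ndarray]
    B: tuple[np.ndarray, np.ndarray, np.ndarray]


def branch_points(geometry: MechanismGeometry, pose: Pose) -> BranchPoints:
    """Construct all branch points by vector addition from the pose."""
    if not geometry.is_full:
        raise CapabilityError("branch-point construction needs full link "
                              "dimensions a, b, c, L")
    a, b, c, L = geometry.a, geometry.b, geometry.c, geometry.L
    d = passive_displacements(pose)
    P = pose.as_array()
    B1 = P + np.array([-a, 0.0, 0.0])
    B2 = P + np.array([a, 0.0, 0.0])
    B3 = P + np.array([0.0, -b, 0.0])
    C1 = np.array([-L / 2 + c, d.d1, 0.0])
    C2 = np.array([L / 2 - c, d.d2, 0.0])
    C3 = np.array([d.d3, c, 0.0])
    M1 = np.array([-L / 2 + c, c, 0.0])
    M2 = np.array([L / 2 - c, c, 0.0])
    M3 = np.array([0.0, c, 0.0])
    A1 = np.array([-L / 2, d.d1, 0.0])
    A2 = np.array([L / 2, d.d2, 0.0])
    A3 = np.array([d.d3, 0.0, 0.0])
    return BranchPoints((A1, A2, A3), (C1, C2, C3), (M1, M2, M3),
                        (B1, B2, B3))


def constraint_residuals(geometry: MechanismGeometry, pose: Pose,
                         lengths: ActuatorLengths | None = None
                         ) -> tuple[float, float, float]:
    """Right-triangle residuals ``|MiCi|^2 + |CiBi|^2 - |MiBi|^2`` (mm^2).

    Zero for any consistent configuration, including the degenerate
    coincidence cases (Ci on Mi).  Passing explicit ``lengths`` substitutes
    them for the |CiBi| legs, so perturbed rod lengths show up directly.
    """
    pts = branch_points(geometry, pose)
    if lengths is None:
        legs = [float(np.dot(bb - cc, bb - cc))
                for cc, bb in zip(pts.C, pts.B)]
    else:
        legs = [lengths.L1 ** 2, lengths.L2 ** 2, lengths.L3 ** 2]
    out = []
    for i in range(3):
        mc = pts.C[i] - pts.M[i]
        mb = pts.B[i] - pts.M[i]
        out.append(float(np.dot(mc, mc) + legs[i] - np.dot(mb, mb)))
    return tuple(out)


# ---------------------------------------------------------------------------
# Calibration of lumped offsets from measured rows


@dataclass(frozen=True)
class CalibrationRow:
    """One calibration observation: a pose and its measured rod lengths
    (mm); branches without a measurement carry ``None``."""

    pose: Pose
    L1: float | None = None
    L2: float | None = None
    L3: float | None = None


@dataclass
class CalibrationReport:
    """Fit diagnostics for one lumped parameter."""

    parameter: str                      # "m" or "q"
    estimate: float
    rms_residual: float                 # mm, over rows kept
    row_residuals: list[tuple[int, int, float]]   # (row idx, branch, mm)
    outliers: list[tuple[int, int]]     # (row idx, branch) excluded
    solutions: list[tuple[float, float]]  # distinct (estimate, rms) by rms
    ambiguous: bool


@dataclass
class CalibrationResult:
    geometry: MechanismGeometry
    reports: dict[str, CalibrationReport] = field(default_factory=dict)


def _length_residuals(param, obs: list[tuple[str, float, float, float]]
                      ) -> np.ndarray:
    param = float(np.atleast_1d(param)[0])
    out = []
    for kind, u, pz, meas in obs:
        if kind == "b1":
            pred = math.sqrt((u + param) ** 2 + pz ** 2)
        elif kind == "b2":
            pred = math.sqrt((u - param) ** 2 + pz ** 2)
        else:  # b3: u is Py
            pred = math.sqrt((param - u) ** 2 + pz ** 2)
        out.append(pred - meas)
    return np.asarray(out)


def _candidate_values(obs) -> list[float]:
    """Both algebraic sign roots of the length equation per observation."""
    cands = []
    for kind, u, pz, meas in obs:
        rad = meas ** 2 - pz ** 2
        r = math.sqrt(max(rad, 0.0))
        if kind == "b1":
            cands += [-u + r, -u - r]
        elif kind == "b2":
            cands += [u + r, u - r]
        else:
            cands += [u + r, u - r]
    return cands


def _fit_offset(obs: list[tuple[str, float, float, float]],
                parameter: str, outlier_tol: float, tol: float
                ) -> CalibrationReport:
    """Consensus-then-refine 1D fit over the enumerated sign roots.

    Every algebraic root of every observation seeds a least-squares polish;
    the distinct converged solutions are ranked by RMS length residual.  Rows
    whose residual under the best solution exceeds ``outlier_tol`` are
    excluded and the fit repeated on the survivors.
    """
    if not obs:
        raise CalibrationError(f"no observations constrain {parameter}")
    seeds: list[float] = []
    for c in _candidate_values(obs):
        if not any(abs(c - s) < 0.25 for s in seeds):
            seeds.append(c)
    # Consensus: refine every seed against all observations, then score each
    # refined estimate by its inlier set; refit on the inliers.
    refined: list[tuple[int, float, float, list[int]]] = []
    for c0 in seeds:
        fit = least_squares(_length_residuals, x0=c0, args=(obs,))
        for est0 in (float(fit.x[0]), c0):
            res = _length_residuals(est0, obs)
            inliers = [i for i, r in enumerate(res) if abs(r) <= outlier_tol]
            if not inliers:
                continue
            sub = [obs[i] for i in inliers]
            refit = least_squares(_length_residuals, x0=est0, args=(sub,))
            est = float(refit.x[0])
            rms = float(np.sqrt(np.mean(refit.fun ** 2)))
            if not any(abs(est - r[1]) < 0.25 for r in refined):
                refined.append((len(inliers), est, rms, inliers))
    if not refined:
        raise CalibrationError(
            f"no calibration row is consistent with the {parameter} length "
            f"model within {outlier_tol} mm; rows: "
            f"{[(kind, i) for i, (kind, *_rest) in enumerate(obs)]}")
    refined.sort(key=lambda r: (-r[0], r[2], r[1]))
    n_in, best, best_rms, keep = refined[0]
    outl = [i for i in range(len(obs)) if i not in keep]
    if len(obs) > 1 and 2 * len(keep) <= len(obs):
        raise CalibrationError(
            f"irreconcilable calibration rows for {parameter}: no estimate "
            f"explains a majority of the observations (best covers "
            f"{len(keep)}/{len(obs)}); outlier rows: "
            f"{[(obs[i][0], i) for i in outl]}")
    if best_rms > tol:
        raise CalibrationError(
            f"irreconcilable calibration rows for {parameter}: minimal rms "
            f"residual {best_rms:.3f} mm exceeds {tol} mm")

    row_res = _length_residuals(best, obs)
    solutions = [(est, rms) for _, est, rms, _ in refined]
    rivals = [r for r in refined[1:] if r[0] == n_in]
    ambiguous = any(r[2] <= max(2.0 * best_rms, 1e-9) for r in rivals)
    return CalibrationReport(
        parameter=parameter,
        estimate=best,
        rms_residual=best_rms,
        row_residuals=[(i, 0, float(r)) for i, r in enumerate(row_res)],
        outliers=[(i, 0) for i in outl],
        solutions=solutions,
        ambiguous=ambiguous,
    )


def calibrate_lumped_offsets(rows: Sequence[CalibrationRow],
                             use_branches: Iterable[int] = (1, 2, 3),
                             outlier_tol: float = 1.0,
                             tol: float = 0.5) -> CalibrationResult:
    """Estimate lumped offsets (m from branches 1-2, q from branch 3).

    The length equations are sign-symmetric in the offsets, so each
    observation admits two algebraic roots.  All roots seed a least-squares
    fit; the minimal-residual solution wins, and the report flags ambiguity
    when a second distinct solution fits comparably well (within a factor of
    two).  Rows irreconcilable with the best solution (residual beyond
    ``outlier_tol`` mm) are excluded and listed.
    """
    branches = set(use_branches)
    obs_m: list[tuple[str, float, float, float]] = []
    obs_q: list[tuple[str, float, float, float]] = []
    m_rows: list[int] = []
    q_rows: list[int] = []
    for idx, row in enumerate(rows):
        if 1 in branches and row.L1 is not None:
            obs_m.append(("b1", row.pose.px, row.pose.pz, float(row.L1)))
            m_rows.append(idx)
        if 2 in branches and row.L2 is not None:
            obs_m.append(("b2", row.pose.px, row.pose.pz, float(row.L2)))
            m_rows.append(idx)
        if 3 in branches and row.L3 is not None:
            obs_q.append(("b3", row.pose.py, row.pose.pz, float(row.L3)))
            q_rows.append(idx)

    reports: dict[str, CalibrationReport] = {}
    m_val = q_val = None
    if obs_m:
        rep = _fit_offset(obs_m, "m", outlier_tol, tol)
        rep.row_residuals = [(m_rows[i], 1 if obs_m[i][0] == "b1" else 2, r)
                             for i, _, r in rep.row_residuals]
        rep.outliers = [(m_rows[i], 1 if obs_m[i][0] == "b1" else 2)
                        for i, _ in rep.outliers]
        reports["m"] = rep
        m_val = rep.estimate
    if obs_q:
        rep = _fit_offset(obs_q, "q", outlier_tol, tol)
        rep.row_residuals = [(q_rows[i], 3, r)
                             for i, _, r in rep.row_residuals]
        rep.outliers = [(q_rows[i], 3) for i, _ in rep.outliers]
        reports["q"] = rep
        q_val = rep.estimate
    if m_val is None and q_val is None:
        raise CalibrationError("no usable observations in calibration rows")
    geom = MechanismGeometry(m=m_val, q=q_val, mode="lumped")
    return CalibrationResult(geom, reports)


# ---------------------------------------------------------------------------
# Trajectory-to-actuator planning


@dataclass(frozen=True)
class TrajectorySample:
    """Time-stamped platform pose (s, mm)."""

    t: float
    pose: Pose


@dataclass(frozen=True)
class CommandSample:
    """Actuator command: lengths plus per-axis rod components (mm).

    Branches 1-2 stay parallel to the XO1Z plane (zero Y component) and
    branch 3 to the YO1Z plane (zero X component); the zero components are
    computed from the passive coupling, not asserted.
    """

    t: float
    lengths: ActuatorLengths
    b1: tuple[float, float, float]   # (x, y, z) components of rod C1B1
    b2: tuple[float, float, float]
    b3: tuple[float, float, float]


def trajectory_commands(geometry: MechanismGeometry,
                        trajectory: Sequence[TrajectorySample]
                        ) -> list[CommandSample]:
    """Inverse kinematics along a trajectory, with rod axis components."""
    m = geometry.require_m()
    q = geometry.require_q()
    out = []
    for sample in trajectory:
        pose = sample.pose
        try:
            lengths = inverse_kinematics(geometry, pose)
        except InfeasiblePoseError as exc:
            raise InfeasiblePoseError(
                f"trajectory sample at t={sample.t}: {exc}") from exc
        d = passive_displacements(pose)
        b1 = (pose.px + m, pose.py - d.d1, pose.pz)
        b2 = (pose.px - m, pose.py - d.d2, pose.pz)
        b3 = (pose.px - d.d3, pose.py - q, pose.pz)
        out.append(CommandSample(sample.t, lengths, b1, b2, b3))
    return out
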