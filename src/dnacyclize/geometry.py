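"""Rigid-basepair geometry.

A DNA molecule of ``N`` basepairs is a chain of rigid frames, one per
basepair, numbered ``i = 1..N`` (plus a fictitious frame ``N+1`` used to
phrase cyclization as the coincidence of frames 1 and N+1).  Each frame has
an origin ``r`` (angstroms) and an orthonormal director triad collected in a
rotation matrix ``R = [d1 d2 d3]``; frame 1 sits at the origin with the
identity orientation.

The step between frames ``i`` and ``i+1`` is described by six internal
coordinates: a Cayley rotation vector ``theta`` (components conventionally
called roll, tilt and twist; magnitude ``2 tan(phi/2)`` for rotation angle
``phi``) and a translation ``a`` (shift, slide, rise) expressed in the
"midframe", i.e. frame ``i`` rotated by half the step rotation.  This is the
symmetric basepair-step convention of Lankas-style rigid-basepair models:
renumbering the chain backwards simply flips the signs of the coordinates.

Intrinsic (minimum-energy) shapes are concatenations of helical, circular-arc
and straight segments with constant intrinsic twist.  A helical segment is
controlled by three angles: ``psi`` (half the bend per bp), ``beta`` (twist
per bp, ``2 pi / helical repeat``) and ``alpha`` (helicity; zero for a planar
arc).  Closed forms for the per-step intrinsic coordinates and for the frame
origins they generate are provided, and pin the Cayley/midframe convention
used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._quat import (
    quat_from_cayley,
    quat_half,
    quat_identity,
    quat_multiply,
    quat_rotate,
    quat_to_matrix,
)

__all__ = [
    "DEFAULT_RISE",
    "BasePairFrame",
    "StepCoords",
    "HelixParams",
    "SegmentSpec",
    "cayley_rotation",
    "compose_step",
    "intrinsic_step",
    "intrinsic_segment_steps",
    "solve_helix_params",
    "pitch_over_circumference",
    "bend_per_bp",
    "helix_origins",
    "build_intrinsic_shape",
    "intrinsic_shape_arrays",
    "frames_from_steps",
]

#: Intrinsic basepair spacing along the helix, in angstroms.
DEFAULT_RISE = 3.4

_ORTHO_TOL = 1e-10


@dataclass
class BasePairFrame:
    """Origin (angstrom) and director triad of one basepair."""

    origin: np.ndarray
    directors: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.directors = np.asarray(self.directors, dtype=float)
        if self.origin.shape != (3,) or self.directors.shape != (3, 3):
            raise ValueError("frame needs a 3-vector origin and a 3x3 triad")
        err = np.abs(self.directors @ self.directors.T - np.eye(3)).max()
        if err > 1e-8 or np.linalg.det(self.directors) < 0:
            raise ValueError("directors must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "BasePairFrame":
        return cls(np.zeros(3), np.eye(3))

    @property
    def d3(self) -> np.ndarray:
        return self.directors[:, 2]


@dataclass
class StepCoords:
    """Six internal coordinates of one basepair step.

    ``theta``: Cayley rotation vector (dimensionless; |theta| = 2 tan(phi/2)).
    ``trans``: midframe translation (angstrom).
    """

    theta: np.ndarray
    trans: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if self.theta.shape != (3,) or self.trans.shape != (3,):
            raise ValueError("step coordinates are two 3-vectors")
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.trans))):
            raise ValueError("step coordinates must be finite")


@dataclass
class HelixParams:
    """Parameters of an intrinsically helical segment.

    alpha : helicity angle (radians); sign sets handedness, 0 = planar arc.
    psi : half the intrinsic bend per bp (radians).
    beta_twist : intrinsic twist per bp (radians) = 2 pi / helical repeat.
    ell : basepair spacing (angstrom).
    """

    alpha: float
    psi: float
    beta_twist: float
    ell: float = DEFAULT_RISE

    def __post_init__(self):
        if not self.ell > 0:
            raise ValueError("ell must be positive")
        if not (abs(self.psi) < np.pi / 2 and abs(self.alpha) < np.pi / 2):
            raise ValueError("|psi| and |alpha| must be < pi/2 (chart domain)")


@dataclass
class SegmentSpec:
    """One piece of an intrinsic shape: helix, circular arc, or straight."""

    kind: str
    n_bp: int
    bend_total_deg: float = 0.0
    pitch_over_circumf: float = 0.0

    def __post_init__(self):
        if self.kind not in ("helix", "arc", "straight"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.n_bp < 1:
            raise ValueError("segments need n_bp >= 1")
        if self.kind == "straight" and (
            self.bend_total_deg != 0.0 or self.pitch_over_circumf != 0.0
        ):
            raise ValueError("straight segments have no bend and no pitch")
        if self.kind == "arc" and self.pitch_over_circumf != 0.0:
            raise ValueError("arc segments are planar (pitch_over_circumf = 0)")


def cayley_rotation(theta):
    """Rotation matrix of a Cayley vector (vectorized over leading axes).

    The axis is ``theta/|theta|`` and the rotation angle ``phi`` satisfies
    ``|theta| = 2 tan(phi/2)``, so the chart covers angles below pi.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != 3:
        raise ValueError("theta must have 3 components")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return quat_to_matrix(quat_from_cayley(theta))


def compose_step(frame: BasePairFrame, step: StepCoords) -> BasePairFrame:
    """Advance one basepair frame by one step (midframe translation rule)."""
    q = quat_from_cayley(step.theta)
    mid = frame.directors @ quat_to_matrix(quat_half(q))
    return BasePairFrame(
        frame.origin + mid @ step.trans,
        frame.directors @ quat_to_matrix(q),
    )


def _helix_step_arrays(helix: HelixParams, idx: np.ndarray):
    """Intrinsic (theta, a) of a helical segment at step indices ``idx``."""
    al, ps, be, ell = helix.alpha, helix.psi, helix.beta_twist, helix.ell
    D = 1.0 + np.cos(ps) * np.cos(be / 2) + np.sin(ps) * np.sin(be / 2) * np.sin(al)
    # D > 1 is the Cayley chart condition: the step rotation angle stays
    # below pi.  D - 1 -> 0 means a ~180-degree step; beyond it the printed
    # closed forms change branch.
    if D - 1.0 <= 1e-12:
        raise ValueError(
            "helix parameters outside the Cayley chart (D - 1 <= 0): "
            "step rotation angle would reach pi"
        )
    phase = (2 * idx - 1) * be / 2.0
    sphase, cphase = np.sin(phase), np.cos(phase)
    bracket = 1.0 + np.tan(ps / 2) * np.tan(be / 4) * np.sin(al)
    amp_a = -(ell / D) * np.cos(al) * np.sin(ps) * np.sin(be / 2) * bracket
    a = np.empty((idx.size, 3))
    a[:, 0] = amp_a * sphase
    a[:, 1] = amp_a * cphase
    a[:, 2] = (ell / D) * (
        np.cos(al) ** 2 * (np.cos(ps) + np.cos(be / 2))
        + np.sin(al)
        * (
            np.sin(ps) * np.sin(be / 2)
            + np.sin(al)
            + np.sin(al) * np.cos(ps) * np.cos(be / 2)
        )
    )
    theta = np.empty((idx.size, 3))
    amp_t = -(2.0 / (D - 1.0)) * np.sin(ps) * np.cos(al)
    theta[:, 0] = amp_t * sphase
    theta[:, 1] = amp_t * cphase
    theta[:, 2] = (2.0 / (D - 1.0)) * (
        np.cos(ps) * np.sin(be / 2) - np.sin(ps) * np.cos(be / 2) * np.sin(al)
    )
    return theta, a


def intrinsic_step(helix: HelixParams, i: int) -> StepCoords:
    """Intrinsic step coordinates between frames ``i`` and ``i+1`` (i >= 1)."""
    if i < 1:
        raise ValueError("step index starts at 1")
    if helix.psi == 0.0 and helix.alpha == 0.0:
        # straight limit, taken in closed form (theta3 = 2 tan(beta/2))
        return StepCoords(
            np.array([0.0, 0.0, 2.0 * np.tan(helix.beta_twist / 2)]),
            np.array([0.0, 0.0, helix.ell]),
        )
    theta, a = _helix_step_arrays(helix, np.array([i]))
    return StepCoords(theta[0], a[0])


def intrinsic_segment_steps(helix: HelixParams, n_bp: int):
    """Intrinsic ``(theta, a)`` arrays for local steps ``i = 1..n_bp``."""
    if helix.psi == 0.0 and helix.alpha == 0.0:
        theta = np.zeros((n_bp, 3))
        theta[:, 2] = 2.0 * np.tan(helix.beta_twist / 2)
        a = np.zeros((n_bp, 3))
        a[:, 2] = helix.ell
        return theta, a
    return _helix_step_arrays(helix, np.arange(1, n_bp + 1))


def pitch_over_circumference(alpha: float, psi: float) -> float:
    """Nonplanarity measure of the intrinsic helix: tan(alpha) sin(psi)/psi."""
    if psi == 0.0:
        return np.tan(alpha)
    return np.tan(alpha) * np.sin(psi) / psi


def bend_per_bp(alpha: float, psi: float) -> float:
    """Bend angle per bp between successive tangents of the intrinsic helix."""
    c = np.cos(alpha) ** 2 * np.cos(2 * psi) + np.sin(alpha) ** 2
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def solve_helix_params(
    bend_per_bp_rad: float,
    pitch_over_circumf: float,
    helical_repeat: float,
    ell: float = DEFAULT_RISE,
) -> HelixParams:
    """Invert (bend per bp, pitch/circumference) for the angles (alpha, psi).

    The bend per bp fixes ``sin(psi) = sin(bend/2)/cos(alpha)``; substituting
    into the pitch ratio leaves a single monotone equation for ``alpha``,
    solved by bracketed root finding.  ``alpha`` carries the sign of the
    pitch ratio (positive = left-handed in this package's convention).
    """
    b = float(bend_per_bp_rad)
    rho = float(pitch_over_circumf)
    if not (0.0 < b < np.pi):
        raise ValueError("bend per bp must lie in (0, pi)")
    if not np.isfinite(rho):
        raise ValueError("pitch_over_circumf must be finite")
    beta = 2 * np.pi / helical_repeat
    s = np.sin(b / 2)
    if rho == 0.0:
        return HelixParams(0.0, b / 2, beta, ell)

    def psi_of(alpha):
        return np.arcsin(min(s / np.cos(alpha), 1.0))

    def ratio_of(alpha):
        ps = psi_of(alpha)
        return np.tan(alpha) * np.sin(ps) / ps

    # alpha is limited by sin(psi) <= 1 and psi < pi/2
    alpha_max = np.arccos(s) - 1e-12
    target = abs(rho)
    if ratio_of(alpha_max) < target:
        raise ValueError(
            f"no helix in the chart with bend/bp {b:.4g} rad and "
            f"|pitch/circumference| {target:.4g}"
        )
    alpha = brentq(lambda a_: ratio_of(a_) - target, 0.0, alpha_max, xtol=1e-15)
    alpha = float(np.copysign(alpha, rho))
    psi = float(psi_of(abs(alpha)))
    # verify both defining relations
    res = max(
        abs(bend_per_bp(alpha, psi) - b),
        abs(pitch_over_circumference(alpha, psi) - rho),
    )
    if res > 1e-9:
        raise ValueError(f"helix parameter solve did not converge (residual {res:g})")
    return HelixParams(alpha, psi, beta, ell)


def helix_origins(helix: HelixParams, n_frames: int) -> np.ndarray:
    """Closed-form origins of frames ``1..n_frames`` of the intrinsic helix.

    The origins lie on a helix of radius ``(ell/2) cos(alpha)/sin(psi)``
    advancing by ``ell sin(alpha)`` per bp along its axis.  With frame 1 held
    at the identity the helix axis is the y-axis rotated by ``alpha`` about
    x; for a planar arc (alpha = 0) the curve is a circle in the x-z plane.
    """
    al, ps, ell = helix.alpha, helix.psi, helix.ell
    i = np.arange(n_frames, dtype=float)  # i = frame index - 1
    if ps == 0.0:
        out = np.zeros((n_frames, 3))
        out[:, 2] = i * ell
        return out
    r = 0.5 * ell * np.cos(al) / np.sin(ps)
    pts = np.stack(
        [-r + r * np.cos(2 * i * ps), i * ell * np.sin(al), r * np.sin(2 * i * ps)],
        axis=1,
    )
    ca, sa = np.cos(al), np.sin(al)
    rot_x = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    return pts @ rot_x.T


def intrinsic_shape_arrays(spec) -> tuple[np.ndarray, np.ndarray]:
    """Per-step intrinsic ``(theta_hat, a_hat)`` arrays, shape (N, 3) each.

    ``spec`` needs attributes ``segments``, ``N``, ``helical_repeat`` and
    ``ell``.  Segment bp counts may undershoot N; the remainder is filled
    with straight steps.  Step N (to the fictitious frame N+1) is included.
    Each segment restarts its local phase index at 1, so a bend is always
    oriented the same way relative to the local material frame.
    """
    N = int(spec.N)
    ell = getattr(spec, "ell", DEFAULT_RISE)
    beta = 2 * np.pi / spec.helical_repeat
    total = sum(seg.n_bp for seg in spec.segments)
    if total > N:
        raise ValueError(f"segments cover {total} steps but N = {N}")
    segments = list(spec.segments)
    if total < N:
        segments.append(SegmentSpec("straight", N - total))
    thetas, trans = [], []
    for seg in segments:
        if seg.kind == "straight":
            hp = HelixParams(0.0, 0.0, beta, ell)
        else:
            per_bp = np.deg2rad(seg.bend_total_deg) / seg.n_bp
            if seg.kind == "arc" or seg.pitch_over_circumf == 0.0:
                hp = HelixParams(0.0, per_bp / 2, beta, ell)
            else:
                hp = solve_helix_params(
                    per_bp, seg.pitch_over_circumf, spec.helical_repeat, ell
                )
        th, a = intrinsic_segment_steps(hp, seg.n_bp)
        thetas.append(th)
        trans.append(a)
    return np.concatenate(thetas), np.concatenate(trans)


def build_intrinsic_shape(spec) -> list[StepCoords]:
    """Intrinsic shape of a molecule as a list of N StepCoords."""
    theta, a = intrinsic_shape_arrays(spec)
    return [StepCoords(t, v) for t, v in zip(theta, a)]


def frames_from_steps(theta: np.ndarray, trans: np.ndarray):
    """Compose a chain of steps from the identity frame.

    Returns ``(origins, quats)`` of the ``n+1`` frames: origins with shape
    ``(n+1, 3)`` and orientations as quaternions with shape ``(n+1, 4)``.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    trans = np.atleast_2d(np.asarray(trans, dtype=float))
    if theta.shape != trans.shape:
        raise ValueError("theta and trans must have matching shapes")
    n = theta.shape[0]
    origins = np.zeros((n + 1, 3))
    quats = np.zeros((n + 1, 4))
    quats[0] = quat_identity()
    q = quat_identity()
    r = np.zeros(3)
    for i in range(n):
        step_q = quat_from_cayley(theta[i])
        r = r + quat_rotate(quat_multiply(q, quat_half(step_q)), trans[i])
        q = quat_multiply(q, step_q)
        origins[i + 1] = r
        quats[i + 1] = q
    return origins, quats
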