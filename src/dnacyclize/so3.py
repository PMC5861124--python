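"""Rotation-group distance, Haar ball volumes, and Haar sampling.

Chain closure needs a tolerance region around the identity in SO(3) and its
volume under the normalized Haar (rotation-invariant) measure.  The distance
adopted here is ``d(R1, R2) = sin(phi/2)`` where ``phi`` is the angle of the
relative rotation ``R1^T R2``.  It is rotation invariant, ranges over
[0, 1], and its metric balls have the closed-form normalized Haar volume

    V(delta) = (2/pi) (arcsin(delta) - delta sqrt(1 - delta^2)),

which follows from the Haar density ``(1 - cos(phi))/pi`` of the rotation
angle by substituting ``delta = sin(phi/2)``.  For small tolerances this
closure region agrees (to leading order in volume) with the older
Flory-style convention of separate tolerances on the tangent-bending angle
``nu_eps`` and the torsion angle ``tau_eps``, whose Haar volume is
``nu_eps * tau_eps / (2 pi)``.
"""

from __future__ import annotations

import numpy as np

from ._quat import quat_to_matrix

__all__ = [
    "ClosureTolerances",
    "rotation_distance",
    "rotation_distance_quat",
    "haar_ball_volume",
    "haar_sample",
    "haar_sample_quat",
    "czapla_region_volume",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class ClosureTolerances:
    """Closure region: Euclidean radius eps (angstrom), SO(3) radius delta."""

    eps: float = 30.0
    delta: float = 0.3

    def __post_init__(self):
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must lie in (0, 1]")

    @property
    def volume_trans(self) -> float:
        """Translational region volume (4/3) pi eps^3, in cubic angstrom."""
        return 4.0 / 3.0 * np.pi * self.eps**3

    @property
    def volume_rot(self) -> float:
        """Normalized Haar volume of the SO(3) ball of radius delta."""
        return haar_ball_volume(self.delta)

    def halved(self) -> "ClosureTolerances":
        return ClosureTolerances(self.eps / 2.0, self.delta / 2.0)


def _check_rotation(R):
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError("expected 3x3 rotation matrices")
    err = np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)).max()
    if err > 1e-8 or np.any(np.linalg.det(R) < 0):
        raise ValueError("input is not a rotation matrix")
    return R


def rotation_distance(R1, R2) -> float | np.ndarray:
    """sin(phi/2) for the angle phi of the relative rotation R1^T R2."""
    R1 = _check_rotation(R1)
    R2 = _check_rotation(R2)
    tr = np.einsum("...ij,...ij->...", R1, R2)  # trace(R1^T R2)
    cos_phi = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    d = np.sqrt(0.5 * (1.0 - cos_phi))  # sin(phi/2)
    return float(d) if d.ndim == 0 else d


def rotation_distance_quat(q1, q2) -> np.ndarray:
    """Same distance from scalar-first quaternions: sqrt(1 - (q1 . q2)^2)."""
    dot = np.einsum("...i,...i->...", np.asarray(q1), np.asarray(q2))
    return np.sqrt(np.clip(1.0 - dot * dot, 0.0, 1.0))


def haar_ball_volume(delta) -> float | np.ndarray:
    """Normalized Haar volume of {R : sin(angle(R)/2) <= delta}."""
    delta = np.asarray(delta, dtype=float)
    if np.any((delta < 0) | (delta > 1)):
        raise ValueError("delta must lie in [0, 1]")
    v = (2.0 / np.pi) * (np.arcsin(delta) - delta * np.sqrt(1.0 - delta * delta))
    return float(v) if v.ndim == 0 else v


def haar_sample_quat(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Haar-uniform rotations as scalar-first unit quaternions."""
    shape = (4,) if n is None else (n, 4)
    q = rng.standard_normal(shape)
    q /= np.sqrt(np.einsum("...i,...i->...", q, q))[..., None]
    return q


def haar_sample(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Haar-uniform rotation matrices (via uniform unit quaternions)."""
    return quat_to_matrix(haar_sample_quat(rng, n))


def czapla_region_volume(
    nu_eps: float,
    tau_eps: float,
    n_samples: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Haar volume of the Flory-style closure region (tangent + torsion cut).

    The region is ``{R : angle(R e3, e3) < arccos(1 - nu_eps) and |torsion| <
    tau_eps}`` where the torsion is the residual rotation about e3 after the
    minimal rotation aligning the tangents.  Returns the leading-order value
    ``nu_eps tau_eps / (2 pi)`` when ``n_samples == 0``, otherwise a Haar
    Monte Carlo estimate (useful as a cross-check of the equivalence).
    """
    if nu_eps < 0 or tau_eps < 0:
        raise ValueError("tolerances must be nonnegative")
    leading = nu_eps * tau_eps / (2.0 * np.pi)
    if n_samples <= 0:
        return leading
    if nu_eps == 0 or tau_eps == 0:
        return 0.0
    rng = np.random.default_rng(0) if rng is None else rng
    hits = 0
    chunk = 1 << 20
    remaining = int(n_samples)
    cos_cut = 1.0 - nu_eps
    while remaining > 0:
        m = min(chunk, remaining)
        q = haar_sample_quat(rng, m)
        w, x, y, z = q.T
        r33 = 1.0 - 2.0 * (x * x + y * y)  # e3 . (R e3)
        # torsion = twist of the swing-twist decomposition about e3
        torsion = 2.0 * np.arctan2(z, w)
        torsion = (torsion + np.pi) % (2.0 * np.pi) - np.pi
        hits += int(np.sum((r33 > cos_cut) & (np.abs(torsion) < tau_eps)))
        remaining -= m
    return hits / float(n_samples)
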