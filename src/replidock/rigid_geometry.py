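"""Rigid-body pose algebra and the docking movers.

A :class:`RigidPose` carries the six rigid-body degrees of freedom of the
mobile partner as a unit quaternion plus a translation (Å).  The pose maps
a mobile-partner point ``x`` to ``R (x - c) + c + t`` where ``c`` is the
model's fixed rotation center (the mobile partner's center of mass).  With
this convention a perturbation applied about the *current* center of mass
composes as a left rotation product and a translation sum, which keeps
Monte-Carlo moves cheap and exactly invertible.

Provides uniform (Haar) rotations on SO(3) via the z-y-z Euler
construction, the random initial placement with slide-into-contact, and a
symmetric-proposal rigid-body perturbation mover suitable for Metropolis
sampling (density of a move equals the density of its reverse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_io import CentroidModel, ValidationError


class ContactSearchError(RuntimeError):
    """slide_into_contact exhausted its travel budget without finding contact."""


# ---------------------------------------------------------------------------
# Quaternion helpers (scalar-first convention, w >= 0 not enforced)
# ---------------------------------------------------------------------------

def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 * q2 (apply q2 first, then q1)."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    h = 0.5 * angle
    return np.concatenate([[math.cos(h)], math.sin(h) * axis])


def quat_from_euler_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Quaternion of R_z(alpha) R_y(beta) R_z(gamma)."""
    qa = np.array([math.cos(alpha / 2), 0.0, 0.0, math.sin(alpha / 2)])
    qb = np.array([math.cos(beta / 2), 0.0, math.sin(beta / 2), 0.0])
    qg = np.array([math.cos(gamma / 2), 0.0, 0.0, math.sin(gamma / 2)])
    return quat_multiply(qa, quat_multiply(qb, qg))


def quat_rotation_angle(q: np.ndarray) -> float:
    """Net rotation angle in [0, pi] represented by unit quaternion q."""
    return 2.0 * math.acos(min(1.0, abs(float(q[0]))))


# ---------------------------------------------------------------------------
# RigidPose
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidPose:
    """Rotation (unit quaternion, scalar first) + translation (Å) of the
    mobile partner about the model's fixed rotation center."""

    quat: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "quat", np.asarray(self.quat, dtype=float))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )
        n = np.linalg.norm(self.quat)
        if abs(n - 1.0) > 1e-6:
            raise ValidationError(f"quaternion norm {n} is not 1")
        if abs(n - 1.0) > 1e-12:
            object.__setattr__(self, "quat", self.quat / n)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(quat=quat_identity(), translation=np.zeros(3))

    def apply(self, coords: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Map coordinates (..., 3): x -> R (x - center) + center + t."""
        R = quat_to_matrix(self.quat)
        return (coords - center) @ R.T + center + self.translation

    def compose_left(self, dq: np.ndarray, dt: np.ndarray) -> "RigidPose":
        """Perturb about the current (posed) mobile center: rotation dq then
        translation dt.  Exact because the posed center is ``c + t``."""
        return RigidPose(
            quat=quat_normalize(quat_multiply(dq, self.quat)),
            translation=self.translation + dt,
        )

    def translated(self, dt: np.ndarray) -> "RigidPose":
        return RigidPose(quat=self.quat.copy(), translation=self.translation + dt)

    def inverse(self) -> "RigidPose":
        """Inverse map in the same fixed-center convention."""
        qi = quat_conjugate(self.quat)
        Ri = quat_to_matrix(qi)
        return RigidPose(quat=qi, translation=-(Ri @ self.translation))

    def as_array7(self) -> np.ndarray:
        return np.concatenate([self.quat, self.translation])

    def mobile_center_position(self, center: np.ndarray) -> np.ndarray:
        """Posed position of the rotation center itself (= center + t)."""
        return np.asarray(center, dtype=float) + self.translation


def pose_distance(p1: RigidPose, p2: RigidPose) -> tuple[float, float]:
    """(translation distance in Å, rotation angle in rad) between two poses."""
    dq = quat_multiply(p1.quat, quat_conjugate(p2.quat))
    return (
        float(np.linalg.norm(p1.translation - p2.translation)),
        quat_rotation_angle(dq),
    )


# ---------------------------------------------------------------------------
# Random rotations
# ---------------------------------------------------------------------------

def random_uniform_rotation(rng: np.random.Generator, n: int | None = None):
    """Draw rotations from the Haar (uniform) measure on SO(3).

    Uses the z-y-z Euler construction: alpha, gamma uniform on [0, 2pi),
    beta = arccos(z) with z uniform on [-1, 1].  Returns a single
    quaternion for ``n is None``, else an (n, 4) array.
    """
    m = 1 if n is None else n
    alpha = rng.uniform(0.0, 2.0 * math.pi, m)
    z = rng.uniform(-1.0, 1.0, m)
    gamma = rng.uniform(0.0, 2.0 * math.pi, m)
    beta = np.arccos(z)
    quats = np.array(
        [quat_from_euler_zyz(a, b, g) for a, b, g in zip(alpha, beta, gamma)]
    )
    return quats[0] if n is None else quats


def random_unit_axis(rng: np.random.Generator) -> np.ndarray:
    """Unbiased rotation axis via the (x, y)-uniform disc construction
    (Marsaglia): x, y uniform on [-1, 1] accepted when x^2 + y^2 < 1."""
    while True:
        x, y = rng.uniform(-1.0, 1.0, 2)
        s = x * x + y * y
        if s < 1.0:
            r = math.sqrt(1.0 - s)
            return np.array([2.0 * x * r, 2.0 * y * r, 1.0 - 2.0 * s])


# ---------------------------------------------------------------------------
# Movers
# ---------------------------------------------------------------------------

@dataclass
class MoveParams:
    """Perturbation step sizes: per-axis Gaussian translation sd (Å) and
    Gaussian Euler-angle magnitude (degrees)."""

    translation_sigma: float = 0.7
    rotation_magnitude: float = 5.0

    def __post_init__(self):
        if self.translation_sigma < 0 or self.rotation_magnitude < 0:
            raise ValidationError("move magnitudes must be >= 0")

    def copy(self) -> "MoveParams":
        return MoveParams(self.translation_sigma, self.rotation_magnitude)


def perturb_rigid_body(
    pose: RigidPose, params: MoveParams, rng: np.random.Generator
) -> RigidPose:
    """Unbiased rigid-body proposal with a symmetric density.

    Translation increment: independent Gaussian (mean 0, sd
    ``translation_sigma``) per axis.  Rotation increment: draw three z-y-z
    Euler angles from a Gaussian of magnitude ``rotation_magnitude``,
    convert to axis-angle, keep only the angle, and apply it about a fresh
    unbiased random axis.  Axis uniformity over the full sphere makes the
    proposal symmetric (reverse move has the same density).
    """
    if params.translation_sigma > 0:
        dt = rng.normal(0.0, params.translation_sigma, 3)
    else:
        dt = np.zeros(3)
    if params.rotation_magnitude > 0:
        sigma = math.radians(params.rotation_magnitude)
        a, b, g = rng.normal(0.0, sigma, 3)
        angle = quat_rotation_angle(quat_from_euler_zyz(a, b, g))
        axis = random_unit_axis(rng)
        dq = quat_from_axis_angle(axis, angle)
    else:
        dq = quat_identity()
    return pose.compose_left(dq, dt)


# ---------------------------------------------------------------------------
# Initial placement
# ---------------------------------------------------------------------------

def random_initial_placement(
    model: CentroidModel,
    rng: np.random.Generator,
    clash_fn=None,
    slide_step: float = 1.0,
    clash_threshold: float = 0.1,
    max_travel: float = 500.0,
) -> RigidPose:
    """Random relative orientation of both partners, slid into contact.

    Both partners receive independent uniform rotations about their own
    centers of mass; the two are composed into a single relative pose of
    the mobile partner in the receptor frame, then
    :func:`slide_into_contact` is applied.  ``clash_fn`` maps a pose to the
    soft clash score (REU); if omitted, a default is built from the model.
    """
    if clash_fn is None:
        from .centroid_energy import interchain_vdw

        clash_fn = lambda p: interchain_vdw(model, p)  # noqa: E731
    qA = random_uniform_rotation(rng)
    qB = random_uniform_rotation(rng)
    cA, cB = model.com_A, model.com_B
    qA_inv = quat_conjugate(qA)
    # receptor rotated about cA, ligand about cB, then the whole system
    # mapped back into the receptor frame; the net ligand map is
    # x -> RA^-1 RB (x - cB) + RA^-1 (cB - cA) + cA
    q_rel = quat_normalize(quat_multiply(qA_inv, qB))
    RAi = quat_to_matrix(qA_inv)
    t_rel = RAi @ (cB - cA) + cA - cB
    pose = RigidPose(quat=q_rel, translation=t_rel)
    return slide_into_contact(
        pose, model, clash_fn,
        step=slide_step, threshold=clash_threshold, max_travel=max_travel,
    )


def slide_into_contact(
    pose: RigidPose,
    model: CentroidModel,
    clash_fn,
    step: float = 1.0,
    threshold: float = 0.1,
    max_travel: float = 500.0,
) -> RigidPose:
    """Slide the mobile partner along the partner center-center axis in
    fixed steps until the partners just touch.

    First-touch contract: the returned pose has ``clash_fn > threshold``
    while the pose one step further out has ``clash_fn <= threshold``.  If
    the input already satisfies ``clash_fn < threshold`` the outward phase
    is skipped.  Raises :class:`ContactSearchError` if no contact is found
    within ``max_travel`` Å.
    """
    center_B = pose.mobile_center_position(model.mobile_center)
    axis = center_B - model.com_A
    norm = np.linalg.norm(axis)
    # degenerate coincident centers: pick a fixed axis for determinism
    u = axis / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    travel = 0.0
    # outward: increase separation until the clash score drops below threshold
    while clash_fn(pose) >= threshold:
        pose = pose.translated(step * u)
        travel += step
        if travel > max_travel:
            raise ContactSearchError(
                f"no clash-free separation within {max_travel} Å of outward travel"
            )
    # inward: decrease separation until the clash score exceeds threshold
    while clash_fn(pose) <= threshold:
        pose = pose.translated(-step * u)
        travel += step
        if travel > max_travel:
            raise ContactSearchError(
                f"no contact found within {max_travel} Å of travel"
            )
    return pose
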