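"""Rigid-body geometry primitives.

Provides the :class:`RigidTransform` carrier used for the docking jump and
all superpositions, weighted Kabsch alignment, per-residue orthonormal
frames, the 6-D residue-pair transform (translation + rotation vector of
one backbone frame expressed in the other), and the backrub rotation
operator (whole-segment rotation about the axis through two pivot CA
atoms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


class DegeneratePointSetError(ValueError):
    """Raised when a superposition target is rank-deficient or too small."""


class DegenerateFrameError(ValueError):
    """Raised when N, CA, C are (near-)collinear and no frame exists."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` in Cartesian angstrom space."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point (3,) or a stack of points (N, 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation component in degrees."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_rotvec(rotvec: np.ndarray, center: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by a rotation vector (radians) about ``center`` (default origin)."""
        rv = np.asarray(rotvec, dtype=float)
        theta = float(np.linalg.norm(rv))
        if theta < 1e-12:
            rot = np.eye(3)
        else:
            # Rodrigues: cheaper than scipy Rotation on the MC hot path
            kx, ky, kz = rv / theta
            K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
            rot = np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)
        if center is None:
            return RigidTransform(rot, np.zeros(3))
        c = np.asarray(center, dtype=float)
        return RigidTransform(rot, c - rot @ c)

    @staticmethod
    def from_translation(t: np.ndarray) -> "RigidTransform":
        return RigidTransform(np.eye(3), np.asarray(t, dtype=float))


@dataclass(frozen=True)
class PairTransform:
    """Relative placement of residue B's frame expressed in residue A's frame.

    ``translation`` is in angstroms along A's local axes; ``rotation`` is a
    rotation vector in radians.  Both are invariant under any global rigid
    motion of the complex.
    """

    translation: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.translation))

    @property
    def angle(self) -> float:
        """Rotation magnitude in radians."""
        return float(np.linalg.norm(self.rotation))


def kabsch(
    X: np.ndarray,
    Y: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal weighted superposition of ``X`` onto ``Y``.

    Returns the proper rigid transform ``T`` minimizing the weighted RMSD of
    ``T(X)`` against ``Y`` (reflections corrected) and that minimal RMSD.

    Raises
    ------
    DegeneratePointSetError
        If fewer than 3 points are given or either point set is collinear.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matching (N, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise DegeneratePointSetError("degenerate point set: need at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    cx = w @ X
    cy = w @ Y
    Xc = X - cx
    Yc = Y - cy
    # collinear point sets have no unique rotation
    for Z in (Xc, Yc):
        s = np.linalg.svd(Z, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise DegeneratePointSetError("degenerate point set: points are collinear")

    H = Xc.T @ (Yc * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cy - R @ cx
    diff = Xc @ R.T - Yc
    rmsd = float(np.sqrt(np.sum(w * np.sum(diff * diff, axis=1))))
    return RigidTransform(R, t), rmsd


def rmsd_fixed(X: np.ndarray, Y: np.ndarray) -> float:
    """Plain coordinate RMSD with no superposition."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    return float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1))))


def residue_frame(res) -> RigidTransform:
    """Right-handed orthonormal backbone frame of a residue.

    Origin at CA; x-axis along CA->N; z-axis along (CA->N) x (CA->C);
    y completes the right-handed set.  The returned transform maps local
    frame coordinates to global coordinates.
    """
    n, ca, c = np.asarray(res.N, float), np.asarray(res.CA, float), np.asarray(res.C, float)
    x = n - ca
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateFrameError("degenerate frame: N coincides with CA")
    x = x / nx
    v = c - ca
    z = np.cross(x, v)
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise DegenerateFrameError("degenerate frame: N, CA, C collinear")
    z = z / nz
    y = np.cross(z, x)
    rot = np.column_stack([x, y, z])
    return RigidTransform(rot, ca)


def pair_transform(res_a, res_b) -> PairTransform:
    """6-D transform of residue B's backbone frame expressed in A's frame."""
    fa = residue_frame(res_a)
    fb = residue_frame(res_b)
    rel = fa.invert().compose(fb)
    rotvec = Rotation.from_matrix(rel.rotation).as_rotvec()
    return PairTransform(rel.translation, rotvec)


class FragmentTooShortError(ValueError):
    pass


_BACKRUB_ATOMS = ("N", "CA", "C", "O", "CB", "centroid")


def backrub_rotate(residues, pivot_first: int, pivot_last: int, angle: float):
    """Rotate the residues strictly between two pivots about the pivot-CA axis.

    ``residues`` is an ordered residue list; ``pivot_first``/``pivot_last``
    are indices into it with ``pivot_last - pivot_first >= 2``.  All atoms of
    the interior residues are rotated by ``angle`` degrees about the axis
    through the two pivot CA atoms; the pivots themselves do not move, so
    internal bond geometry of the rotated segment is preserved exactly.

    Returns a new residue list (input is not mutated).
    """
    if pivot_last - pivot_first < 2:
        raise FragmentTooShortError("fragment too short for backrub")
    if pivot_first < 0 or pivot_last >= len(residues):
        raise IndexError("pivot index out of range")
    p0 = np.asarray(residues[pivot_first].CA, dtype=float)
    p1 = np.asarray(residues[pivot_last].CA, dtype=float)
    axis = p1 - p0
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise DegenerateFrameError("degenerate backrub axis: pivot CAs coincide")
    axis = axis / norm
    T = RigidTransform.from_rotvec(np.radians(angle) * axis, center=p0)

    out = list(residues)
    for i in range(pivot_first + 1, pivot_last):
        res = residues[i]
        updates = {}
        for name in _BACKRUB_ATOMS:
            coord = getattr(res, name, None)
            if coord is not None:
                updates[name] = T.apply(np.asarray(coord, dtype=float))
        out[i] = res.replace(**updates)
    return out


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def random_axis(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit vector on the sphere."""
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
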