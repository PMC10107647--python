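"""Rotation parameterization, coordinate transforms and the registration cost.

All geometry is done on physical coordinates (micrometres).  Voxel-index to
physical conversion happens at I/O time (``lmreg3d.fileio``) or in
``lmreg3d.imageops``; nothing in this module knows about voxel sizes.

The rotation convention used throughout the package is the intrinsic
Z-Y-X (yaw-pitch-roll) composition

    R = Rz(phi) @ Ry(theta) @ Rx(psi)

centralised in :func:`rotation_matrix`.  Any proper-rotation
parameterization spans SO(3), so the choice affects only the reported
angle triple, never the fitted matrix or cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointSet",
    "EulerAngles",
    "AxisScales",
    "rotation_matrix",
    "apply_scale",
    "transform_points",
    "landmark_cost",
    "PairingMismatchError",
]


class PairingMismatchError(ValueError):
    """Raised when two landmark sets that must be row-paired differ in size."""


def _as_coords(coords) -> np.ndarray:
    a = np.asarray(coords, dtype=float)
    if a.ndim == 1 and a.size == 3:
        a = a.reshape(1, 3)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinates must be an (N, 3) array, got shape {a.shape}")
    if a.shape[0] < 1:
        raise ValueError("a PointSet needs at least one point")
    if not np.all(np.isfinite(a)):
        raise ValueError("coordinates must be finite")
    return a


@dataclass(frozen=True)
class PointSet:
    """Identified 3D points: integer object ids + xyz coordinates in um.

    Used both for landmarks (row-paired across two images) and for
    unpaired objects of interest (e.g. nucleus centroids).
    """

    ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        coords = _as_coords(self.coords)
        ids = np.asarray(self.ids, dtype=int)
        if ids.ndim != 1 or ids.shape[0] != coords.shape[0]:
            raise ValueError("ids must be a 1D array matching the number of points")
        if np.unique(ids).size != ids.size:
            raise ValueError("object ids must be unique within a point set")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "coords", coords)

    @classmethod
    def from_coords(cls, coords, ids=None) -> "PointSet":
        coords = _as_coords(coords)
        if ids is None:
            ids = np.arange(1, coords.shape[0] + 1)
        return cls(ids=np.asarray(ids), coords=coords)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def select(self, indices) -> "PointSet":
        """Row subset (positional indices), ids carried along."""
        idx = np.asarray(indices, dtype=int)
        return PointSet(ids=self.ids[idx], coords=self.coords[idx])

    def with_coords(self, coords) -> "PointSet":
        return PointSet(ids=self.ids.copy(), coords=coords)


@dataclass(frozen=True)
class EulerAngles:
    """Three rotation angles (radians), intrinsic Z-Y-X order."""

    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0

    def __post_init__(self):
        for name in ("phi", "theta", "psi"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"angle {name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        return np.array([self.phi, self.theta, self.psi])

    def normalized(self) -> "EulerAngles":
        """Wrap each angle into the canonical range [-pi, pi)."""
        wrapped = (self.as_array() + np.pi) % (2 * np.pi) - np.pi
        return EulerAngles(*wrapped)

    @classmethod
    def from_array(cls, a) -> "EulerAngles":
        a = np.asarray(a, dtype=float).ravel()
        if a.size != 3:
            raise ValueError("expected exactly three angles")
        return cls(a[0], a[1], a[2])


@dataclass(frozen=True)
class AxisScales:
    """Per-axis multiplicative scale factors (unitless, > 0).

    Used to correct shrinkage (<1) or elongation (>1) of coordinates,
    typically along z where voxel spacing miscalibration and refractive
    index mismatch distort stacks.
    """

    sx: float = 1.0
    sy: float = 1.0
    sz: float = 1.0

    def __post_init__(self):
        for name in ("sx", "sy", "sz"):
            v = float(getattr(self, name))
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"scale {name} must be strictly positive, got {v!r}")
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        # xyz order, matching PointSet columns
        return np.array([self.sx, self.sy, self.sz])


def rotation_matrix(angles: EulerAngles) -> np.ndarray:
    """Proper rotation matrix for three Euler angles.

    Composition is intrinsic Z-Y-X: ``Rz(phi) @ Ry(theta) @ Rx(psi)``.
    The result is orthonormal with determinant +1 for any finite input.
    """
    if not isinstance(angles, EulerAngles):
        angles = EulerAngles.from_array(angles)
    cph, sph = math.cos(angles.phi), math.sin(angles.phi)
    cth, sth = math.cos(angles.theta), math.sin(angles.theta)
    cps, sps = math.cos(angles.psi), math.sin(angles.psi)
    return np.array(
        [
            [cph * cth, cph * sth * sps - sph * cps, cph * sth * cps + sph * sps],
            [sph * cth, sph * sth * sps + cph * cps, sph * sth * cps - cph * sps],
            [-sth, cth * sps, cth * cps],
        ]
    )


def apply_scale(points: PointSet, scales: AxisScales) -> PointSet:
    """Component-wise scale correction of coordinates; ids preserved."""
    if not isinstance(scales, AxisScales):
        scales = AxisScales(*np.asarray(scales, dtype=float))
    return points.with_coords(points.coords * scales.as_array())


def transform_points(
    points: PointSet,
    angles: EulerAngles,
    center_from,
    center_to,
) -> PointSet:
    """Rigidly map points: ``p -> R (p - center_from) + center_to``.

    ``center_from``/``center_to`` are the rotation centers in the source and
    destination frames; in the registration workflow these are the landmark
    centroids of the second and first image respectively.
    """
    center_from = np.asarray(center_from, dtype=float).ravel()
    center_to = np.asarray(center_to, dtype=float).ravel()
    if center_from.size != 3 or center_to.size != 3:
        raise ValueError("rotation centers must be 3-vectors")
    if not (np.all(np.isfinite(center_from)) and np.all(np.isfinite(center_to))):
        raise ValueError("rotation centers must be finite")
    R = rotation_matrix(angles)
    moved = (points.coords - center_from) @ R.T + center_to
    return points.with_coords(moved)


def _paired_coords(landmarks1: PointSet, landmarks2: PointSet):
    if len(landmarks1) != len(landmarks2):
        raise PairingMismatchError(
            f"landmark sets must be row-paired with equal counts "
            f"({len(landmarks1)} vs {len(landmarks2)})"
        )
    return landmarks1.coords, landmarks2.coords


def landmark_cost(
    landmarks1: PointSet,
    landmarks2: PointSet,
    angles: EulerAngles,
    squared: bool = False,
) -> float:
    """Registration cost: sum of distances between paired landmarks.

    The second set is rotated about its own centroid and translated onto the
    centroid of the first set, then the per-pair Euclidean distances are
    summed:

        cost = sum_i || R (q_i - c2) + c1 - p_i ||

    Centroid centering removes translation analytically, so the cost has
    exactly the three angles as free parameters.  ``squared=True`` sums the
    squared distances instead; that variant has a closed-form optimum
    (orthogonal Procrustes) and exists for cross-checking, not as the
    method's cost.
    """
    p, q = _paired_coords(landmarks1, landmarks2)
    R = rotation_matrix(angles)
    moved = (q - q.mean(axis=0)) @ R.T + p.mean(axis=0)
    d2 = np.sum((moved - p) ** 2, axis=1)
    if squared:
        return float(np.sum(d2))
    return float(np.sum(np.sqrt(d2)))
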