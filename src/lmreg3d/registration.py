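"""Multi-start minimization of the landmark cost over three rotation angles.

The cost surface over the Euler angles has local minima, so a single local
minimization can be trapped.  Following the tool's protocol, the local
minimizer is launched from a deterministic grid of initial angle triples —
three values per angle, hence 27 starts at the defaults — and the fraction
of starts reaching the global (best-found) minimum is reported as a
convergence-robustness diagnostic.

The local minimizer is derivative-free (Nelder-Mead simplex): the
sum-of-distances cost is non-smooth wherever a pair distance hits zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    EulerAngles,
    PairingMismatchError,
    PointSet,
    landmark_cost,
    rotation_matrix,
)

__all__ = [
    "RigidFit",
    "MultiStartResult",
    "fit_rotation",
    "global_min_probability",
    "subsample_landmarks",
    "InsufficientLandmarksError",
    "DegenerateGeometryError",
    "DEFAULT_START_VALUES",
]

# Three initial values per angle, evenly covering the circle -> 27 starts.
DEFAULT_START_VALUES = (-2 * np.pi / 3, 0.0, 2 * np.pi / 3)


class InsufficientLandmarksError(ValueError):
    """Fewer than three landmark pairs: the rotation is not determined."""


class DegenerateGeometryError(ValueError):
    """Landmarks are (near-)collinear: rotation about their axis is free."""


@dataclass(frozen=True)
class RigidFit:
    """One fitted rigid transform: angles, matrix, centers and cost (um)."""

    angles: EulerAngles
    rotation: np.ndarray
    center_from: np.ndarray
    center_to: np.ndarray
    cost: float

    def transform(self, points: PointSet) -> PointSet:
        """Map points from the second image's frame into the first's."""
        from .geometry import transform_points

        return transform_points(points, self.angles, self.center_from, self.center_to)

    def inverse(self) -> "RigidFit":
        """The fit mapping frame 1 back onto frame 2 (transpose rotation)."""
        Rt = self.rotation.T
        # recover angles of the transposed matrix from its entries
        theta = float(np.arcsin(np.clip(-Rt[2, 0], -1.0, 1.0)))
        phi = float(np.arctan2(Rt[1, 0], Rt[0, 0]))
        psi = float(np.arctan2(Rt[2, 1], Rt[2, 2]))
        ang = EulerAngles(phi, theta, psi)
        return RigidFit(
            angles=ang,
            rotation=rotation_matrix(ang),
            center_from=self.center_to.copy(),
            center_to=self.center_from.copy(),
            cost=self.cost,
        )


@dataclass(frozen=True)
class MultiStartResult:
    """All local-minimization outcomes of one multi-start run."""

    fits: tuple
    best_index: int
    tol_cost: float
    start_angles: tuple
    start_costs: np.ndarray

    @property
    def best(self) -> RigidFit:
        return self.fits[self.best_index]

    @property
    def n_starts(self) -> int:
        return len(self.fits)

    @property
    def n_global(self) -> int:
        """Number of starts whose final cost is within tol of the best."""
        costs = np.array([f.cost for f in self.fits])
        return int(np.sum(costs <= self.best.cost + self.tol_cost))

    @property
    def probability(self) -> float:
        return self.n_global / self.n_starts


def _check_landmarks(landmarks1: PointSet, landmarks2: PointSet) -> None:
    if len(landmarks1) != len(landmarks2):
        raise PairingMismatchError(
            f"landmark counts differ: {len(landmarks1)} vs {len(landmarks2)}"
        )
    if len(landmarks1) < 3:
        raise InsufficientLandmarksError(
            "at least three landmark pairs are required to determine a 3D rotation"
        )
    for name, lm in (("first", landmarks1), ("second", landmarks2)):
        centered = lm.coords - lm.coords.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        # rank < 2 <=> points lie on a line; a planar triangle is fine
        if s[1] < 1e-9 * max(s[0], 1e-300):
            raise DegenerateGeometryError(
                f"landmarks in the {name} image are collinear; they must span "
                "at least a triangle to pin down the rotation"
            )


def _make_fit(landmarks1, landmarks2, angles: EulerAngles, squared: bool) -> RigidFit:
    angles = angles.normalized()
    return RigidFit(
        angles=angles,
        rotation=rotation_matrix(angles),
        center_from=landmarks2.centroid,
        center_to=landmarks1.centroid,
        cost=landmark_cost(landmarks1, landmarks2, angles, squared=squared),
    )


def fit_rotation(
    landmarks1: PointSet,
    landmarks2: PointSet,
    starts_per_angle: int = 3,
    tol_cost: Optional[float] = None,
    seed=None,
    squared: bool = False,
    n_random_starts: int = 0,
    maxfev: int = 10_000,
) -> MultiStartResult:
    """Fit the rotation aligning landmarks2 onto landmarks1 by multi-start
    local minimization of the sum-of-distances cost.

    Parameters
    ----------
    landmarks1, landmarks2
        Row-paired landmark sets (same count, same order) in um.  The
        rotation centers are fixed at the two centroids, so only the three
        Euler angles are free.
    starts_per_angle
        Number of initial values per angle; the start grid is the Cartesian
        product, ``starts_per_angle ** 3`` local minimizations (27 at the
        default, with initial values evenly spaced on the circle).
    tol_cost
        A start "reached the global minimum" if its final cost is within
        ``tol_cost`` of the best.  Default:
        ``max(1e-6, 1e-4 * bounding-box diagonal of landmarks1)``.
    seed
        Consulted only when ``n_random_starts > 0``; the deterministic grid
        needs no randomness.
    squared
        Minimize the sum of *squared* distances instead (cross-check mode;
        its optimum has a closed form).
    n_random_starts
        Extra uniformly drawn initial triples appended to the grid.

    Returns
    -------
    MultiStartResult
        All per-start fits, the best fit, and the global-minimum fraction.
    """
    _check_landmarks(landmarks1, landmarks2)

    if starts_per_angle < 1:
        raise ValueError("starts_per_angle must be >= 1")
    if starts_per_angle == 3:
        values = np.asarray(DEFAULT_START_VALUES)
    else:
        values = -np.pi + (np.arange(starts_per_angle) + 0.5) * 2 * np.pi / starts_per_angle
    grid = [
        np.array([a, b, c]) for a in values for b in values for c in values
    ]
    if n_random_starts:
        rng = np.random.default_rng(seed)
        grid.extend(rng.uniform(-np.pi, np.pi, size=(n_random_starts, 3)))

    if tol_cost is None:
        extent = landmarks1.coords.max(axis=0) - landmarks1.coords.min(axis=0)
        tol_cost = max(1e-6, 1e-4 * float(np.linalg.norm(extent)))

    def cost(x: np.ndarray) -> float:
        return landmark_cost(
            landmarks1, landmarks2, EulerAngles(*x), squared=squared
        )

    fits = []
    start_costs = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        start_costs[i] = cost(x0)
        res = minimize(
            cost,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxfev": maxfev},
        )
        # simplex never accepts an uphill final point, but guard anyway
        if res.fun <= start_costs[i]:
            final = res.x
        else:  # pragma: no cover
            final = x0
        fits.append(_make_fit(landmarks1, landmarks2, EulerAngles(*final), squared))

    costs = np.array([f.cost for f in fits])
    best_index = int(np.argmin(costs))  # argmin -> lowest start index on ties
    return MultiStartResult(
        fits=tuple(fits),
        best_index=best_index,
        tol_cost=float(tol_cost),
        start_angles=tuple(tuple(x) for x in grid),
        start_costs=start_costs,
    )


def global_min_probability(result: MultiStartResult) -> float:
    """Fraction of starts that reached the global (best-found) minimum.

    1.0 means every local minimization converged to the same best cost
    within the result's recorded tolerance.
    """
    if result.n_starts < 1:
        raise ValueError("result contains no fits")
    return result.probability


def subsample_landmarks(
    landmarks1: PointSet,
    landmarks2: PointSet,
    k: int,
    n_sets: int = 4,
    seed=None,
) -> list:
    """Draw ``n_sets`` random k-subsets of the paired landmarks.

    The same positional indices are drawn from both sets so that pairing is
    preserved.  Used to probe how the number of landmarks affects fit
    robustness and pairing accuracy.
    """
    if len(landmarks1) != len(landmarks2):
        raise PairingMismatchError(
            f"landmark counts differ: {len(landmarks1)} vs {len(landmarks2)}"
        )
    n = len(landmarks1)
    if k < 3:
        raise InsufficientLandmarksError("subsets must keep at least three landmarks")
    if k > n:
        raise ValueError(f"cannot draw {k} landmarks from {n}")
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_sets):
        idx = np.sort(rng.choice(n, size=k, replace=False))
        subsets.append((landmarks1.select(idx), landmarks2.select(idx)))
    return subsets
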