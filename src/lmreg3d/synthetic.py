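"""Synthetic deformation/noise benchmark for the registration pipeline.

Real two-image data differ from an exact rigid rotation in three ways this
generator emulates:

* **z-scaling** — apparent shrinkage (<100%) or elongation (>100%) of the
  stack along z, as caused by refractive-index mismatch or fixation;
* **trapezoid deformation** — xy planes expanded near the top of the volume
  and contracted near the bottom, linearly interpolated in between
  (rate ``epsilon`` in percent), a depth-dependent optical distortion;
* **positional noise** — i.i.d. uniform perturbations of every coordinate,
  amplitude ``xi`` expressed in percent of the z extent, applied
  *independently* to both point sets.

A benchmark replicate draws ~50 objects uniformly in a box
(default x 0-200, y 0-150, z 0-100 um), deforms and randomly rotates them
into a "second image", picks a shared subset as landmarks, runs the full
registration-and-pairing pipeline, and scores the percentage of objects
paired back to their true counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import EulerAngles, PointSet, transform_points
from .pairing import pair_objects, pairing_accuracy
from .registration import DegenerateGeometryError, fit_rotation

__all__ = [
    "Scenario",
    "DEFAULT_BOUNDS",
    "random_pointset",
    "apply_z_scaling",
    "apply_trapezoid",
    "apply_noise",
    "make_pair",
    "run_benchmark",
]

# benchmark box in um: x 0-200, y 0-150, z 0-100
DEFAULT_BOUNDS = ((0.0, 200.0), (0.0, 150.0), (0.0, 100.0))


@dataclass(frozen=True)
class Scenario:
    """One benchmark condition.

    Percent conventions: ``z_scale=100`` is no z deformation, ``epsilon=0``
    no trapezoid deformation, ``xi=0`` no positional noise (xi is relative
    to the z extent of the box).
    """

    n_objects: int = 50
    bounds: Tuple = DEFAULT_BOUNDS
    z_scale: float = 100.0
    epsilon: float = 0.0
    xi: float = 0.0
    n_landmarks: int = 3
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self):
        b = tuple(tuple(float(v) for v in ax) for ax in self.bounds)
        if len(b) != 3 or any(hi <= lo for lo, hi in b):
            raise ValueError("bounds must be three non-degenerate (lo, hi) ranges")
        if not (self.n_objects >= self.n_landmarks >= 3):
            raise ValueError("need n_objects >= n_landmarks >= 3")
        if self.z_scale <= 0:
            raise ValueError("z_scale percent must be positive")
        if self.epsilon < 0 or self.xi < 0:
            raise ValueError("epsilon and xi percents must be >= 0")
        object.__setattr__(self, "bounds", b)

    @property
    def z_length(self) -> float:
        return self.bounds[2][1] - self.bounds[2][0]


def random_pointset(n: int, bounds=DEFAULT_BOUNDS, seed=None) -> PointSet:
    """n points i.i.d. uniform in the box; ids 1..n; reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.array([ax[0] for ax in bounds])
    hi = np.array([ax[1] for ax in bounds])
    coords = rng.uniform(lo, hi, size=(n, 3))
    return PointSet.from_coords(coords)


def apply_z_scaling(points: PointSet, z_scale_percent: float) -> PointSet:
    """Shrink (<100) or elongate (>100) z coordinates; x, y untouched.

    Scaling is about z = 0, mimicking a voxel-spacing miscalibration; the
    difference from scaling about the centroid is a pure translation, which
    centroid-centered registration removes anyway.
    """
    if z_scale_percent <= 0:
        raise ValueError("z_scale_percent must be positive")
    coords = points.coords.copy()
    coords[:, 2] *= z_scale_percent / 100.0
    return points.with_coords(coords)


def apply_trapezoid(points: PointSet, epsilon_percent: float, bounds=DEFAULT_BOUNDS) -> PointSet:
    """z-dependent xy expansion/contraction about the xy box center.

    The xy offsets from the box center are scaled by
    ``1 + (epsilon/100) * (2 z / z_max - 1)``: expanded by epsilon percent
    at the top plane, contracted at the bottom, untouched exactly at
    mid-height.  epsilon >= 100 would collapse or invert the bottom plane
    and is rejected.
    """
    if epsilon_percent < 0:
        raise ValueError("epsilon_percent must be >= 0")
    if epsilon_percent >= 100:
        raise ValueError("epsilon_percent >= 100 inverts the bottom plane")
    if epsilon_percent == 0:
        return points.with_coords(points.coords.copy())
    (x0, x1), (y0, y1), (z0, z1) = bounds
    center = np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])
    coords = points.coords.copy()
    rel_z = (coords[:, 2] - z0) / (z1 - z0)
    factor = 1.0 + (epsilon_percent / 100.0) * (2.0 * rel_z - 1.0)
    coords[:, :2] = center + (coords[:, :2] - center) * factor[:, None]
    return points.with_coords(coords)


def apply_noise(points: PointSet, xi_percent: float, z_length: float, seed=None) -> PointSet:
    """Perturb every coordinate by i.i.d. uniform(-xi, +xi) noise.

    The amplitude is ``xi = xi_percent / 100 * z_length`` um on each of the
    three axes.
    """
    if xi_percent < 0:
        raise ValueError("xi_percent must be >= 0")
    if xi_percent == 0:
        return points.with_coords(points.coords.copy())
    rng = np.random.default_rng(seed)
    xi = xi_percent / 100.0 * z_length
    return points.with_coords(points.coords + rng.uniform(-xi, xi, size=points.coords.shape))


def _random_rotation_angles(rng) -> EulerAngles:
    # uniform over SO(3); report as the package's Euler convention
    R = Rotation.random(rng=rng)
    phi, theta, psi = R.as_euler("ZYX")
    return EulerAngles(phi, theta, psi)


def make_pair(scenario: Scenario):
    """Generate one (first, second) point-set pair plus ground truth.

    The second set is ``noise(rotate(deform(first)))`` with a uniformly
    random proper rotation about the box center; when ``xi > 0``
    independent noise is also added to the first set.  Returns
    ``(first, second, truth, landmark_indices)`` where ``truth`` is the
    identity map on the shared ids and ``landmark_indices`` are the
    positional indices of the landmark subset (shared by construction).
    """
    rng = np.random.default_rng(scenario.seed)
    clean = random_pointset(scenario.n_objects, scenario.bounds, seed=rng.integers(2**31))

    second = apply_z_scaling(clean, scenario.z_scale)
    second = apply_trapezoid(second, scenario.epsilon, scenario.bounds)
    angles = _random_rotation_angles(rng)
    box_center = np.array([(lo + hi) / 2.0 for lo, hi in scenario.bounds])
    second = transform_points(second, angles, box_center, box_center)

    first = apply_noise(clean, scenario.xi, scenario.z_length, seed=rng.integers(2**31))
    second = apply_noise(second, scenario.xi, scenario.z_length, seed=rng.integers(2**31))

    # landmarks: shared random subset, re-drawn in the (measure-zero) event
    # that the clean positions are collinear
    for _ in range(100):
        idx = np.sort(rng.choice(scenario.n_objects, size=scenario.n_landmarks, replace=False))
        centered = clean.coords[idx] - clean.coords[idx].mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] > 1e-9 * s[0]:
            break
    else:  # pragma: no cover
        raise DegenerateGeometryError("could not draw a non-collinear landmark subset")

    truth = {int(i): int(i) for i in first.ids}
    return first, second, truth, idx


def _replicate_accuracy(scenario: Scenario) -> float:
    first, second, truth, lm_idx = make_pair(scenario)
    result = fit_rotation(first.select(lm_idx), second.select(lm_idx))
    second_in_first = result.best.transform(second)
    table = pair_objects(first, second_in_first, k=3)
    return pairing_accuracy(table, truth)


def run_benchmark(scenarios: Sequence[Scenario]) -> pd.DataFrame:
    """Run the full pipeline on every scenario and tabulate mean accuracy.

    For each scenario, ``n_replicates`` independent pairs are generated
    (seeds derived from the scenario seed), registered from the landmark
    subset, and scored; the table holds one row per scenario with the mean
    and per-replicate accuracies in percent.
    """
    rows = []
    for sc in scenarios:
        child_seeds = np.random.SeedSequence(sc.seed).generate_state(sc.n_replicates) % (2**31)
        accs = [
            _replicate_accuracy(replace(sc, seed=int(s), n_replicates=1))
            for s in child_seeds
        ]
        rows.append(
            {
                "n_objects": sc.n_objects,
                "z_scale": sc.z_scale,
                "epsilon": sc.epsilon,
                "xi": sc.xi,
                "n_landmarks": sc.n_landmarks,
                "n_replicates": sc.n_replicates,
                "seed": sc.seed,
                "mean_accuracy": float(np.mean(accs)),
                "replicate_accuracies": accs,
            }
        )
    return pd.DataFrame(rows)
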