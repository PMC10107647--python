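"""Voxel-based 3D rotation, rescaling, particle rendering and channel merging.

Conventions, used everywhere in this module:

* Arrays are indexed ``(z, y, x)``; ``voxel_size`` is ``(dz, dy, dx)`` in
  um/voxel.  Physical coordinates are ``(x, y, z)`` in um, matching
  :class:`~lmreg3d.geometry.PointSet` columns.
* Voxel index i (0-based) sits at physical coordinate ``i * d`` — index
  times voxel size at the voxel center.
* Resampling is inverse mapping (pull) with linear interpolation by
  default; voxels that map outside the source volume read 0.

Stacks are resampled to isotropic physical sampling before rotation, to
avoid the shear artifacts a rotation in anisotropic index space produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import AxisScales, PointSet
from .registration import RigidFit

__all__ = [
    "ImageStack",
    "rescale_stack",
    "rotate_stack",
    "render_particles",
    "merge_channels",
]


@dataclass(frozen=True)
class ImageStack:
    """3D intensity array (z, y, x) with per-axis voxel size in um/voxel."""

    voxels: np.ndarray
    voxel_size: Tuple[float, float, float]  # (dz, dy, dx)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("voxels must be a non-empty 3D (z, y, x) array")
        vs = tuple(float(s) for s in self.voxel_size)
        if len(vs) != 3 or any(s <= 0 for s in vs):
            raise ValueError("voxel_size must be three positive values (dz, dy, dx)")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def physical_extent(self) -> Tuple[float, float, float]:
        """(z, y, x) extent in um."""
        return tuple(n * d for n, d in zip(self.voxels.shape, self.voxel_size))


def rescale_stack(stack: ImageStack, scales: AxisScales, order: int = 1) -> ImageStack:
    """Resample so the physical extent is multiplied per axis.

    The voxel size is kept and the voxel counts change, so downstream code
    sees the corrected geometry at the same sampling.  Linear interpolation
    by default.
    """
    if not isinstance(scales, AxisScales):
        scales = AxisScales(*np.asarray(scales, dtype=float))
    zoom = (scales.sz, scales.sy, scales.sx)  # array order z, y, x
    new_shape = tuple(int(round(n * z)) for n, z in zip(stack.shape, zoom))
    if any(n < 1 for n in new_shape):
        raise ValueError(f"rescaling to shape {new_shape} leaves an empty axis")
    out = ndimage.zoom(stack.voxels.astype(float), zoom, order=order, grid_mode=False)
    # zoom rounds shapes itself; trust its output shape
    return ImageStack(out.astype(stack.voxels.dtype, copy=False), stack.voxel_size)


def _isotropize(stack: ImageStack, order: int = 1) -> ImageStack:
    d = min(stack.voxel_size)
    if all(abs(s - d) < 1e-12 for s in stack.voxel_size):
        return stack
    zoom = tuple(s / d for s in stack.voxel_size)
    out = ndimage.zoom(stack.voxels.astype(float), zoom, order=order, grid_mode=False)
    return ImageStack(out, (d, d, d))


def rotate_stack(
    stack2: ImageStack,
    fit: RigidFit,
    output_shape: Optional[Tuple[int, int, int]] = None,
    output_voxel_size: Optional[Tuple[float, float, float]] = None,
    order: int = 1,
    isotropize: bool = True,
) -> ImageStack:
    """Reconstruct the second image in the first image's frame.

    Each output voxel at physical position q samples the source stack at
    ``R^T (q - center_to) + center_from`` (inverse mapping through the
    fitted rigid transform); positions outside the source read 0.

    ``output_shape``/``output_voxel_size`` default to the (isotropized)
    source geometry; pass the first image's geometry to reconstruct on its
    grid.
    """
    src = _isotropize(stack2, order=order) if isotropize else stack2
    if output_voxel_size is None:
        output_voxel_size = src.voxel_size
    if output_shape is None:
        output_shape = src.shape

    dz, dy, dx = output_voxel_size
    iz, iy, ix = np.meshgrid(
        np.arange(output_shape[0]),
        np.arange(output_shape[1]),
        np.arange(output_shape[2]),
        indexing="ij",
    )
    # physical xyz positions of the output voxels (first image's frame)
    q = np.stack([ix * dx, iy * dy, iz * dz], axis=-1).reshape(-1, 3)
    p = (q - fit.center_to) @ fit.rotation + fit.center_from  # (q-c)@R == R.T@(q-c)

    sdz, sdy, sdx = src.voxel_size
    coords = np.stack(
        [p[:, 2] / sdz, p[:, 1] / sdy, p[:, 0] / sdx], axis=0
    ).reshape(3, *output_shape)
    out = ndimage.map_coordinates(
        src.voxels.astype(float), coords, order=order, mode="constant", cval=0.0
    )
    return ImageStack(out, tuple(float(s) for s in output_voxel_size))


def render_particles(
    points: PointSet,
    shape: Tuple[int, int, int],
    voxel_size: Tuple[float, float, float],
    radius_vox: float = 2.0,
    dtype=np.uint8,
) -> ImageStack:
    """Draw each point as a sphere whose voxel value is the object id.

    With the id-as-intensity contract an ImageJ lookup table (e.g.
    3-3-2-RGB) colors corresponding particles of two images identically.
    Later-drawn ids win on overlap.  8-bit output restricts ids to 1..255;
    pass ``dtype=np.uint16`` to lift the limit.
    """
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ValueError("rendered stacks are 8- or 16-bit unsigned")
    limit = np.iinfo(dtype).max
    if np.any(points.ids < 0) or np.any(points.ids > limit):
        raise ValueError(f"object ids must fit {dtype.name} intensities (0..{limit})")

    vol = np.zeros(shape, dtype=dtype)
    dz, dy, dx = (float(s) for s in voxel_size)
    r = int(np.ceil(radius_vox))
    for oid, (x, y, z) in zip(points.ids, points.coords):
        cz, cy, cx = z / dz, y / dy, x / dx
        z0, z1 = max(0, int(np.floor(cz)) - r), min(shape[0], int(np.ceil(cz)) + r + 1)
        y0, y1 = max(0, int(np.floor(cy)) - r), min(shape[1], int(np.ceil(cy)) + r + 1)
        x0, x1 = max(0, int(np.floor(cx)) - r), min(shape[2], int(np.ceil(cx)) + r + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue  # particle entirely out of field
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
        )
        mask = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_vox**2
        vol[z0:z1, y0:y1, x0:x1][mask] = oid
    return ImageStack(vol, (dz, dy, dx))


def merge_channels(stacks: Sequence[ImageStack]) -> np.ndarray:
    """Stack same-shape images into a (channel, z, y, x) composite.

    Lossless: each input channel is recoverable bit-exactly by indexing the
    first axis.  Used to overlay e.g. the first image and the rotated
    second image for visual inspection of the registration.
    """
    if not stacks:
        raise ValueError("need at least one channel")
    shape = stacks[0].shape
    for s in stacks[1:]:
        if s.shape != shape:
            raise ValueError(f"channel shapes differ: {s.shape} vs {shape}")
    return np.stack([s.voxels for s in stacks], axis=0)
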