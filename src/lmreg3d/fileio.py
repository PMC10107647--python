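"""File formats: coordinate tables, fit reports, pairing tables, TIFF stacks.

Coordinate tables are CSV or TSV (dialect auto-detected) with a header and
columns ``id, x, y, z``; coordinates may be voxel indices if per-axis voxel
sizes are supplied, in which case they are converted to um on read.  Fit
reports are JSON; pairing and benchmark tables are TSV with units in the
headers.  Image stacks are multi-page TIFF with the voxel size recorded in
a side-car YAML (and ImageJ-style resolution tags where possible).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import AxisScales, PointSet
from .imageops import ImageStack
from .pairing import PairingTable
from .registration import MultiStartResult

__all__ = [
    "read_points",
    "write_points",
    "read_stack",
    "write_stack",
    "fit_report",
    "write_fit_report",
    "write_pairing_table",
    "write_benchmark_table",
]


class TableFormatError(ValueError):
    """A coordinate table violates the documented schema."""


def read_points(path, voxel_size: Optional[AxisScales] = None, role: Optional[str] = None) -> PointSet:
    """Read a coordinate table into a PointSet (coordinates in um).

    ``voxel_size`` (sx, sy, sz in um/voxel) converts voxel-index columns to
    physical um.  If the table has no ``id`` column, ids 1..N are assigned
    with a warning.  ``role`` filters on an optional ``role`` column
    (``landmark`` / ``object``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path.name}: missing required column(s) {missing}")
    if role is not None and "role" in df.columns:
        df = df[df["role"].str.strip().str.lower() == role.lower()]
        if df.empty:
            raise TableFormatError(f"{path.name}: no rows with role {role!r}")

    coords = np.empty((len(df), 3))
    for j, c in enumerate(("x", "y", "z")):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            raise TableFormatError(
                f"{path.name}: non-numeric {c!r} value in data row {bad[0] + 1}"
            )
        coords[:, j] = col.to_numpy(dtype=float)

    if "id" in df.columns:
        ids = pd.to_numeric(df["id"], errors="coerce")
        bad = np.nonzero(ids.isna().to_numpy())[0]
        if bad.size:
            raise TableFormatError(
                f"{path.name}: non-numeric 'id' value in data row {bad[0] + 1}"
            )
        ids = ids.to_numpy(dtype=int)
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
        if dup.size:
            raise TableFormatError(f"{path.name}: duplicate id(s) {dup.tolist()}")
    else:
        warnings.warn(f"{path.name}: no 'id' column; assigning ids 1..{len(df)}")
        ids = np.arange(1, len(df) + 1)

    if voxel_size is not None:
        if not isinstance(voxel_size, AxisScales):
            voxel_size = AxisScales(*np.asarray(voxel_size, dtype=float))
        coords = coords * voxel_size.as_array()
    return PointSet(ids=ids, coords=coords)


def write_points(points: PointSet, path, sep: str = ",") -> None:
    """Write a PointSet as a coordinate table (um)."""
    df = pd.DataFrame(
        {
            "id": points.ids,
            "x": points.coords[:, 0],
            "y": points.coords[:, 1],
            "z": points.coords[:, 2],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def write_stack(stack: ImageStack, path) -> None:
    """Write a multi-page TIFF plus a voxel-size side-car YAML."""
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        stack.voxels,
        imagej=stack.voxels.dtype in (np.dtype(np.uint8), np.dtype(np.uint16)),
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(
        yaml.safe_dump({"voxel_size_um": {"dz": dz, "dy": dy, "dx": dx}})
    )


def read_stack(path, voxel_size=None) -> ImageStack:
    """Read a multi-page TIFF; voxel size from argument or side-car YAML."""
    path = Path(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None]
    if voxel_size is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())["voxel_size_um"]
            voxel_size = (meta["dz"], meta["dy"], meta["dx"])
        else:
            warnings.warn(f"{path.name}: no voxel size available; assuming 1 um/voxel")
            voxel_size = (1.0, 1.0, 1.0)
    return ImageStack(voxels, tuple(float(s) for s in voxel_size))


def fit_report(result: MultiStartResult) -> dict:
    """JSON-serializable report of a multi-start registration run."""
    best = result.best
    return {
        "cost_um": best.cost,
        "angles_rad": {"phi": best.angles.phi, "theta": best.angles.theta, "psi": best.angles.psi},
        "angles_deg": {
            "phi": float(np.degrees(best.angles.phi)),
            "theta": float(np.degrees(best.angles.theta)),
            "psi": float(np.degrees(best.angles.psi)),
        },
        "rotation_matrix": best.rotation.tolist(),
        "center_from_um": best.center_from.tolist(),
        "center_to_um": best.center_to.tolist(),
        "n_starts": result.n_starts,
        "n_reaching_global_minimum": result.n_global,
        "global_minimum_probability": result.probability,
        "tolerance_um": result.tol_cost,
        "starts": [
            {
                "initial_angles_rad": list(result.start_angles[i]),
                "initial_cost_um": float(result.start_costs[i]),
                "final_cost_um": f.cost,
                "final_angles_rad": [f.angles.phi, f.angles.theta, f.angles.psi],
                "reached_global_minimum": bool(f.cost <= best.cost + result.tol_cost),
            }
            for i, f in enumerate(result.fits)
        ],
    }


def write_fit_report(result: MultiStartResult, path) -> None:
    Path(path).write_text(json.dumps(fit_report(result), indent=2) + "\n")


def write_pairing_table(table: PairingTable, path) -> None:
    """TSV pairing table plus the multiply-assigned id listing.

    Columns: image-1 id, then (image-2 candidate id, distance in um) for
    each rank; ambiguous rows are flagged.  Multiply-assigned image-2 ids
    are appended as comment lines so one file carries the full output.
    """
    path = Path(path)
    df = table.to_frame()
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        ids = sorted(table.multiply_assigned)
        fh.write(f"# multiply_assigned_image2_ids\t{','.join(map(str, ids)) if ids else 'none'}\n")


def write_benchmark_table(df: pd.DataFrame, path) -> None:
    """TSV accuracy table (accuracies in percent)."""
    out = df.copy()
    if "replicate_accuracies" in out.columns:
        out["replicate_accuracies"] = out["replicate_accuracies"].map(
            lambda accs: ",".join(f"{a:g}" for a in accs)
        )
    out.to_csv(path, sep="\t", index=False)
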