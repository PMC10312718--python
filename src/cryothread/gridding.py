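"""Division of maps into fixed-size overlapping sub-grids and stitching of
per-sub-grid predictions back into a full-map volume.

Full maps are too large for one model pass, so they are cut into cubes of
``cube_size`` voxels (default 32) whose faces overlap by ``border`` voxels
(default 6).  Adjacent cubes share ``2 * border`` voxels, so the stride is
the core size ``cube_size - 2 * border`` (20 by default) and every original
voxel lies in exactly one cube's central core.  Stitching copies only those
cores back, which avoids boundary artifacts in per-cube predictions.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError
from .mrc_io import DensityMap

__all__ = ["SubGridSet", "divide_map", "stitch_predictions",
           "save_archive", "load_archive"]

ARCHIVE_VERSION = 1


@dataclass
class SubGridSet:
    """Cubes tiling a zero-padded copy of the original grid.

    ``items`` holds ``(offset, cube)`` pairs where ``offset`` is the cube's
    low corner (z, y, x) in padded space; offsets advance with stride
    ``core`` so cube cores partition the padded volume.
    """

    cube_size: int
    border: int
    original_shape: tuple[int, int, int]
    items: list[tuple[tuple[int, int, int], np.ndarray]] = field(
        default_factory=list)

    @property
    def core(self) -> int:
        return self.cube_size - 2 * self.border

    @property
    def n_cubes_per_axis(self) -> tuple[int, int, int]:
        return tuple(-(-d // self.core) for d in self.original_shape)

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        return tuple(n * self.core + 2 * self.border
                     for n in self.n_cubes_per_axis)


def _as_array(volume) -> np.ndarray:
    if isinstance(volume, DensityMap):
        return np.asarray(volume.values)
    if hasattr(volume, "values"):  # LabelVolume
        return np.asarray(volume.values)
    return np.asarray(volume)


def divide_map(volume, cube_size: int = 32, border: int = 6) -> SubGridSet:
    """Cut a map, mask or bare array into overlapping ``cube_size`` cubes.

    The grid is zero-padded by ``border`` on the low side of each axis and
    up to the next core multiple plus ``border`` on the high side, then
    cubes are extracted at stride ``core = cube_size - 2 * border``; the
    cube count per axis is ``ceil(dim / core)``.
    """
    if border < 0 or cube_size <= 2 * border:
        raise ValueError("need cube_size > 2 * border >= 0")
    values = _as_array(volume)
    if values.ndim != 3:
        raise DimensionError("expected a 3D grid")
    if min(values.shape) < 1:
        raise DimensionError(f"non-positive grid dimensions {values.shape}")

    grid_set = SubGridSet(cube_size=cube_size, border=border,
                          original_shape=values.shape)
    core = grid_set.core
    padded = np.zeros(grid_set.padded_shape, dtype=values.dtype)
    padded[border:border + values.shape[0],
           border:border + values.shape[1],
           border:border + values.shape[2]] = values
    for a in range(grid_set.n_cubes_per_axis[0]):
        for b in range(grid_set.n_cubes_per_axis[1]):
            for c in range(grid_set.n_cubes_per_axis[2]):
                off = (a * core, b * core, c * core)
                cube = padded[off[0]:off[0] + cube_size,
                              off[1]:off[1] + cube_size,
                              off[2]:off[2] + cube_size].copy()
                grid_set.items.append((off, cube))
    return grid_set


def stitch_predictions(grid_set: SubGridSet) -> np.ndarray:
    """Reassemble a full-map volume from per-cube values or predictions.

    Only each cube's central core is copied into the output at its
    position; padding is trimmed so the result has the original grid shape.
    Cubes may carry trailing channel dimensions (e.g. class probabilities);
    the output then has shape ``original_shape + channels``.
    """
    core = grid_set.core
    if core <= 0:
        raise ValueError("core size must be positive")
    expected = {(a * core, b * core, c * core)
                for a in range(grid_set.n_cubes_per_axis[0])
                for b in range(grid_set.n_cubes_per_axis[1])
                for c in range(grid_set.n_cubes_per_axis[2])}
    present = {tuple(off) for off, _ in grid_set.items}
    missing = expected - present
    if missing:
        raise ValueError(f"missing sub-grid at offset {sorted(missing)[0]}")

    first_cube = np.asarray(grid_set.items[0][1])
    channels = first_cube.shape[3:]
    b = grid_set.border
    core_shape = tuple(n * core for n in grid_set.n_cubes_per_axis)
    out = np.zeros(core_shape + channels, dtype=first_cube.dtype)
    for off, cube in grid_set.items:
        cube = np.asarray(cube)
        if cube.shape[:3] != (grid_set.cube_size,) * 3:
            raise ValueError(
                f"cube at {off} has shape {cube.shape[:3]}, "
                f"expected {(grid_set.cube_size,) * 3}")
        out[off[0]:off[0] + core, off[1]:off[1] + core, off[2]:off[2] + core]\
            = cube[b:b + core, b:b + core, b:b + core]
    sz, sy, sx = grid_set.original_shape
    return out[:sz, :sy, :sx]


# ---------------------------------------------------------------------------
# archive container: named arrays + JSON metadata in one .npz

def save_archive(path: str | os.PathLike,
                 grid_sets: dict[str, SubGridSet]) -> str:
    """Save several aligned sub-grid sets (map + masks) as one archive.

    The archive is an ``.npz`` of stacked cube arrays, one entry per named
    set, with offsets and a versioned JSON metadata entry.
    """
    if not grid_sets:
        raise ValueError("nothing to save")
    ref = next(iter(grid_sets.values()))
    meta = {"version": ARCHIVE_VERSION, "cube_size": ref.cube_size,
            "border": ref.border, "original_shape": list(ref.original_shape),
            "names": list(grid_sets)}
    arrays = {"offsets": np.array([off for off, _ in ref.items], dtype=np.int64),
              "metadata": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for name, gs in grid_sets.items():
        if (gs.cube_size, gs.border, gs.original_shape) != (
                ref.cube_size, ref.border, ref.original_shape):
            raise ValueError(f"sub-grid set {name!r} is not aligned")
        arrays[f"cubes_{name}"] = np.stack([cube for _, cube in gs.items])
    np.savez_compressed(str(path), **arrays)
    return str(path)


def load_archive(path: str | os.PathLike) -> dict[str, SubGridSet]:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["metadata"]).decode())
        if meta["version"] != ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {meta['version']}")
        offsets = [tuple(int(v) for v in off) for off in data["offsets"]]
        out = {}
        for name in meta["names"]:
            cubes = data[f"cubes_{name}"]
            out[name] = SubGridSet(
                cube_size=meta["cube_size"], border=meta["border"],
                original_shape=tuple(meta["original_shape"]),
                items=list(zip(offsets, list(cubes))))
    return out
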