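"""Map standardization: resampling to a uniform voxel grid and percentile
normalization of densities to [0, 1].

Raw cryo-EM maps come with heterogeneous voxel sizes and density scales
(one map may span [-2.32, 3.91], another [-0.553, 0.762]).  Two steps make
them comparable: trilinear resampling to a uniform 1 Å voxel grid, and
division by the 95th percentile of the strictly positive density values
followed by clipping to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DimensionError
from .mrc_io import DensityMap

__all__ = ["ResampleSpec", "NormalizeSpec", "resample_map", "normalize_map"]


@dataclass
class ResampleSpec:
    """Target voxel size (Å per axis) and interpolation method."""
    target_voxel: float = 1.0
    interpolation: str = "trilinear"

    def __post_init__(self):
        if self.target_voxel <= 0:
            raise ValueError("target_voxel must be positive")
        if self.interpolation != "trilinear":
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


@dataclass
class NormalizeSpec:
    """Percentile of the positive values used as the division constant."""
    percentile: float = 95.0
    clip_low: float = 0.0
    clip_high: float = 1.0

    def __post_init__(self):
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")


def resample_map(density_map: DensityMap,
                 spec: ResampleSpec | None = None) -> DensityMap:
    """Resample a map onto a uniform grid of ``spec.target_voxel`` Å voxels.

    The output grid starts at the input origin and extends far enough to
    cover the input's physical extent; values are obtained by trilinear
    interpolation, with points outside the input support filled with 0.
    Trilinear interpolation reproduces any linear density field exactly,
    and resampling a map already at the target voxel size is the identity.
    """
    spec = spec or ResampleSpec()
    vx, vy, vz = density_map.voxel_size
    if min(vx, vy, vz) <= 0:
        raise ValueError("input voxel sizes must be positive")
    nz, ny, nx = density_map.values.shape
    if min(nz, ny, nx) < 2:
        raise DimensionError(
            f"cannot resample a degenerate axis (shape {(nz, ny, nx)})")

    t = spec.target_voxel
    in_voxel = (vz, vy, vx)
    # number of sample points covering the physical extent per axis
    out_shape = tuple(
        int(math.ceil((n - 1) * v / t)) + 1 for n, v in zip((nz, ny, nx), in_voxel))
    coords = np.meshgrid(
        *(np.arange(m) * t / v for m, v in zip(out_shape, in_voxel)),
        indexing="ij")
    values = map_coordinates(
        np.asarray(density_map.values, dtype=np.float64),
        np.stack([c.ravel() for c in coords]),
        order=1, mode="constant", cval=0.0).reshape(out_shape)
    return DensityMap.from_values(values.astype(np.float32),
                                  voxel_size=t, origin=density_map.origin)


def normalize_map(density_map: DensityMap,
                  spec: NormalizeSpec | None = None) -> DensityMap:
    """Normalize densities to [0, 1] by the positive-percentile rule.

    The division constant is the ``spec.percentile``-th percentile of the
    strictly positive values (linear interpolation between order
    statistics); every value is divided by it, then values below 0 are set
    to 0 and values above 1 to 1.  A map with no strictly positive voxel is
    returned as all zeros with a warning (divide-by guard).
    """
    spec = spec or NormalizeSpec()
    values = np.asarray(density_map.values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("grid contains non-finite values")
    positives = values[values > 0]
    if positives.size == 0:
        warnings.warn("map has no strictly positive density values; "
                      "returning an all-zero map", stacklevel=2)
        out = np.zeros_like(values, dtype=np.float32)
        return DensityMap.from_values(out, voxel_size=density_map.voxel_size,
                                      origin=density_map.origin)
    scale = float(np.percentile(positives, spec.percentile))
    out = np.clip(values / scale, spec.clip_low, spec.clip_high)
    return DensityMap.from_values(out.astype(np.float32),
                                  voxel_size=density_map.voxel_size,
                                  origin=density_map.origin)
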