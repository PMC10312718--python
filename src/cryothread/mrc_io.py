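"""Reading, writing and validating MRC2014 volumetric files.

The MRC2014 format stores a 3D grid behind a fixed 1024-byte header.  The
toolkit keeps every volume in a canonical logical order ``(z, y, x)`` =
(section, row, column): files whose ``mapc/mapr/maps`` fields permute the
crystallographic axes are de-permuted on read, and files are always written
back with the canonical ``1, 2, 3`` mapping.  This pins the grid-index
convention used by the labeling formulas — index ``i`` always runs along z,
``j`` along y and ``k`` along x.

:func:`validate_mrc` runs a 12-point compliance battery (format ID string,
machine stamp, mode, map dimensions, cell dimensions, axis mapping, volume
stack divisibility, header labels, format version, extended-header type,
data statistics, file size) and reports each check individually.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import MRCFormatError, UnsupportedModeError

__all__ = [
    "MapHeader",
    "DensityMap",
    "ValidationReport",
    "CheckResult",
    "read_mrc",
    "write_mrc",
    "validate_mrc",
    "SUPPORTED_MODES",
]

#: MRC mode code -> numpy dtype (little-endian on disk).
SUPPORTED_MODES = {
    0: np.dtype("<i1"),   # 8-bit signed integer
    1: np.dtype("<i2"),   # 16-bit signed integer
    2: np.dtype("<f4"),   # 32-bit signed real
    4: np.dtype("<c8"),   # transform: complex 32-bit reals
    6: np.dtype("<u2"),   # 16-bit unsigned integer
    12: np.dtype("<f2"),  # 16-bit float
}

HEADER_SIZE = 1024
MAP_ID = b"MAP "
#: Accepted machine stamps: little-endian, little-endian (old), big-endian.
MACHINE_STAMPS = (b"\x44\x44\x00\x00", b"\x44\x41\x00\x00", b"\x11\x11\x00\x00")
VALID_NVERSIONS = (20140, 20141)
#: Registered extended-header type tags.
EXTTYPES = ("CCP4", "MRCO", "SERI", "AGAR", "FEI1", "FEI2", "HDF5")


@dataclass
class MapHeader:
    """Spatial and bookkeeping metadata of an MRC2014 volume.

    ``nx/ny/nz`` count voxels along the crystallographic x/y/z axes (in the
    canonical mapping these equal columns/rows/sections), ``mx/my/mz`` are
    the sampling counts used to derive voxel sizes from the cell dimensions
    ``cella_*`` (Å): ``voxel_x = cella_x / mx`` and likewise per axis.
    """

    nx: int
    ny: int
    nz: int
    mode: int = 2
    mx: int = 0
    my: int = 0
    mz: int = 0
    cella_x: float = 0.0
    cella_y: float = 0.0
    cella_z: float = 0.0
    mapc: int = 1
    mapr: int = 2
    maps: int = 3
    origin_x: float = 0.0
    origin_y: float = 0.0
    origin_z: float = 0.0
    nversion: int = 20140
    map_id: bytes = MAP_ID
    machine_stamp: bytes = MACHINE_STAMPS[0]
    nlabl: int = 0
    labels: list[bytes] = field(default_factory=list)
    exttyp: bytes = b"\x00\x00\x00\x00"
    ispg: int = 1
    nsymbt: int = 0
    dmin: float = 0.0
    dmax: float = 0.0
    dmean: float = 0.0
    rms: float = -1.0
    nxstart: int = 0
    nystart: int = 0
    nzstart: int = 0

    def __post_init__(self):
        if self.mx == 0:
            self.mx, self.my, self.mz = self.nx, self.ny, self.nz
        if self.cella_x == 0.0:
            # default to 1 Å voxels
            self.cella_x, self.cella_y, self.cella_z = (
                float(self.mx), float(self.my), float(self.mz))

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """(voxel_x, voxel_y, voxel_z) in Å, derived as cella / m-count."""
        return (self.cella_x / self.mx, self.cella_y / self.my,
                self.cella_z / self.mz)

    @property
    def origin(self) -> tuple[float, float, float]:
        return (self.origin_x, self.origin_y, self.origin_z)


@dataclass
class DensityMap:
    """A 3D value grid plus its spatial header.

    ``values`` is indexed ``(i, j, k)`` = (section, row, column) = (z, y, x).
    """

    header: MapHeader
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3-dimensional")
        nz, ny, nx = self.values.shape
        if (nz, ny, nx) != (self.header.nz, self.header.ny, self.header.nx):
            raise ValueError(
                f"grid shape {self.values.shape} does not match header "
                f"(nz={self.header.nz}, ny={self.header.ny}, nx={self.header.nx})")

    @classmethod
    def from_values(cls, values: np.ndarray,
                    voxel_size: float | tuple[float, float, float] = 1.0,
                    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
                    ) -> "DensityMap":
        """Build a map with a fresh canonical header around a (z, y, x) grid."""
        values = np.asarray(values)
        nz, ny, nx = values.shape
        if np.isscalar(voxel_size):
            voxel_size = (float(voxel_size),) * 3
        vx, vy, vz = voxel_size
        header = MapHeader(
            nx=nx, ny=ny, nz=nz, mx=nx, my=ny, mz=nz,
            cella_x=nx * vx, cella_y=ny * vy, cella_z=nz * vz,
            origin_x=origin[0], origin_y=origin[1], origin_z=origin[2])
        return cls(header=header, values=values)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.header.voxel_size

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.header.origin


# ---------------------------------------------------------------------------
# raw header packing

_HDR = struct.Struct("<10i 6f 3i 3f 2i 8x 4s i 84x 3f 4s 4s f i")
# fields: nx ny nz mode nxstart nystart nzstart mx my mz | cella(3) cellb(3)
#         mapc mapr maps | dmin dmax dmean | ispg nsymbt | extra(8B)
#         exttyp nversion | extra(84B) | origin(3) | map machst | rms nlabl


def _parse_header(raw: bytes) -> MapHeader:
    if len(raw) < HEADER_SIZE:
        raise MRCFormatError(
            f"file too short for an MRC header ({len(raw)} < {HEADER_SIZE} bytes)")
    (nx, ny, nz, mode, nxstart, nystart, nzstart, mx, my, mz,
     ca, cb, cc, _, _, _, mapc, mapr, maps_, dmin, dmax, dmean,
     ispg, nsymbt, exttyp, nversion, ox, oy, oz, map_id, machst,
     rms, nlabl) = _HDR.unpack(raw[:_HDR.size])
    labels = [raw[224 + 80 * i:224 + 80 * (i + 1)] for i in range(10)]
    return MapHeader(
        nx=nx, ny=ny, nz=nz, mode=mode, mx=mx, my=my, mz=mz,
        cella_x=ca, cella_y=cb, cella_z=cc,
        mapc=mapc, mapr=mapr, maps=maps_,
        origin_x=ox, origin_y=oy, origin_z=oz,
        nversion=nversion, map_id=map_id, machine_stamp=machst,
        nlabl=nlabl, labels=labels, exttyp=exttyp,
        ispg=ispg, nsymbt=nsymbt, dmin=dmin, dmax=dmax, dmean=dmean,
        rms=rms, nxstart=nxstart, nystart=nystart, nzstart=nzstart)


def _pack_header(h: MapHeader) -> bytes:
    body = _HDR.pack(
        h.nx, h.ny, h.nz, h.mode, h.nxstart, h.nystart, h.nzstart,
        h.mx, h.my, h.mz, h.cella_x, h.cella_y, h.cella_z,
        90.0, 90.0, 90.0, h.mapc, h.mapr, h.maps,
        h.dmin, h.dmax, h.dmean, h.ispg, h.nsymbt,
        h.exttyp, h.nversion, h.origin_x, h.origin_y, h.origin_z,
        h.map_id, h.machine_stamp, h.rms, h.nlabl)
    labels = bytearray(800)
    for i, lab in enumerate(h.labels[:10]):
        lab = lab[:80].ljust(80, b" " if lab.strip() else b"\x00")
        labels[80 * i:80 * (i + 1)] = lab
    return body + bytes(labels)


# ---------------------------------------------------------------------------
# read / write

def read_mrc(path: str | os.PathLike) -> DensityMap:
    """Read an MRC2014 file into canonical (z, y, x) logical order.

    Files stored with a permuted ``mapc/mapr/maps`` axis mapping are
    transposed so that ``values[i, j, k]`` always indexes (z, y, x),
    and the header is rewritten to the canonical 1,2,3 mapping.

    Raises
    ------
    MRCFormatError
        Truncated file or malformed header.
    UnsupportedModeError
        Mode code outside {0, 1, 2, 4, 6, 12}.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    header = _parse_header(raw)
    if header.mode not in SUPPORTED_MODES:
        raise UnsupportedModeError(f"unsupported MRC mode {header.mode}")
    mapping = (header.mapc, header.mapr, header.maps)
    if sorted(mapping) != [1, 2, 3]:
        raise MRCFormatError(f"axis mapping {mapping} is not a permutation of 1..3")
    dtype = SUPPORTED_MODES[header.mode]
    n_voxels = header.nx * header.ny * header.nz
    start = HEADER_SIZE + header.nsymbt
    data = np.frombuffer(raw, dtype=dtype, count=-1, offset=start)
    if data.size < n_voxels:
        raise MRCFormatError(
            f"truncated data block: expected {n_voxels} voxels, found {data.size}")
    # on-disk array is (sections, rows, columns); header nx counts columns
    grid = data[:n_voxels].reshape(header.nz, header.ny, header.nx)

    # data dims (0,1,2) carry crystal axes (maps, mapr, mapc); re-order so
    # dims carry (3, 2, 1) = (z, y, x)
    axes_on_dims = (header.maps, header.mapr, header.mapc)
    order = [axes_on_dims.index(a) for a in (3, 2, 1)]
    grid = np.ascontiguousarray(np.transpose(grid, order))

    # per-crystal-axis voxel counts and start indices
    n_along = {axes_on_dims[0]: header.nz, axes_on_dims[1]: header.ny,
               axes_on_dims[2]: header.nx}
    start_along = {header.mapc: header.nxstart, header.mapr: header.nystart,
                   header.maps: header.nzstart}
    header.nx, header.ny, header.nz = n_along[1], n_along[2], n_along[3]
    header.nxstart = start_along[1]
    header.nystart = start_along[2]
    header.nzstart = start_along[3]
    header.mapc, header.mapr, header.maps = 1, 2, 3
    return DensityMap(header=header, values=grid)


def write_mrc(density_map: DensityMap, path: str | os.PathLike,
              mode: int = 2) -> str:
    """Write a map as a compliant MRC2014 file.

    Header statistics (dmin, dmax, dmean, rms) are recomputed from the data,
    the axis mapping is written canonically and ``nversion``/``map_id``/
    machine stamp are set to MRC2014 values, so the output passes
    :func:`validate_mrc` by construction.
    """
    if mode not in SUPPORTED_MODES:
        raise UnsupportedModeError(f"unsupported MRC mode {mode}")
    values = np.asarray(density_map.values)
    if not np.all(np.isfinite(values)):
        raise ValueError("grid contains non-finite values")
    h = density_map.header
    dtype = SUPPORTED_MODES[mode]
    data = np.ascontiguousarray(values.astype(dtype))
    out = MapHeader(
        nx=h.nx, ny=h.ny, nz=h.nz, mode=mode,
        mx=h.mx, my=h.my, mz=h.mz,
        cella_x=h.cella_x, cella_y=h.cella_y, cella_z=h.cella_z,
        mapc=1, mapr=2, maps=3,
        origin_x=h.origin_x, origin_y=h.origin_y, origin_z=h.origin_z,
        nversion=20140, map_id=MAP_ID, machine_stamp=MACHINE_STAMPS[0],
        ispg=h.ispg if 0 <= h.ispg else 1, nsymbt=0,
        nxstart=h.nxstart, nystart=h.nystart, nzstart=h.nzstart,
        nlabl=1, labels=[b"cryothread".ljust(80)],
        dmin=float(np.min(data.real)), dmax=float(np.max(data.real)),
        dmean=float(np.mean(data.real, dtype=np.float64)),
        rms=float(np.std(data.real.astype(np.float64))))
    with open(path, "wb") as fh:
        fh.write(_pack_header(out))
        fh.write(data.tobytes())
    return str(path)


# ---------------------------------------------------------------------------
# validation

@dataclass
class CheckResult:
    name: str
    passed: bool
    message: str = ""


@dataclass
class ValidationReport:
    path: str
    checks: list[CheckResult]

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]

    def __str__(self) -> str:
        lines = [f"{self.path}:"]
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            msg = f"  [{status}] {c.name}"
            if c.message:
                msg += f" — {c.message}"
            lines.append(msg)
        return "\n".join(lines)


def _label_in_use(label: bytes) -> bool:
    return bool(label.strip(b"\x00 "))


def validate_mrc(path: str | os.PathLike) -> ValidationReport:
    """Run the 12-point MRC2014 compliance battery on a file.

    Each check is reported individually with a pass/fail flag and a message;
    an unreadable file raises an I/O / format error rather than reporting a
    failed check.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    h = _parse_header(raw)
    checks: list[CheckResult] = []

    def add(name: str, passed: bool, message: str = ""):
        checks.append(CheckResult(name, bool(passed), "" if passed else message))

    add("map_id", h.map_id[:3] == b"MAP",
        f"map field is {h.map_id!r}, expected 'MAP '")
    add("machine_stamp", h.machine_stamp in MACHINE_STAMPS,
        f"machine stamp {h.machine_stamp.hex()} not in the allowed set")
    mode_ok = h.mode in SUPPORTED_MODES
    add("mode", mode_ok, f"mode {h.mode} is not a supported mode number")
    add("map_dimensions",
        all(v > 0 for v in (h.nx, h.ny, h.nz, h.mx, h.my, h.mz)),
        "nx, ny, nz, mx, my, mz must all be positive")
    add("cell_dimensions",
        all(v > 0 for v in (h.cella_x, h.cella_y, h.cella_z)),
        "cella.x, cella.y, cella.z must all be positive")
    add("axis_mapping", sorted((h.mapc, h.mapr, h.maps)) == [1, 2, 3],
        f"mapc/mapr/maps = {(h.mapc, h.mapr, h.maps)} is not a permutation of 1..3")
    if 401 <= h.ispg <= 630:
        add("volume_stack", h.mz > 0 and h.nz % h.mz == 0,
            f"volume stack: nz={h.nz} not divisible by mz={h.mz}")
    else:
        add("volume_stack", True)
    in_use = [_label_in_use(lab) for lab in h.labels]
    n_used = sum(in_use)
    labels_ok = (0 <= h.nlabl <= 10 and n_used == h.nlabl
                 and all(i < h.nlabl for i, u in enumerate(in_use) if u))
    add("header_labels", labels_ok,
        f"nlabl={h.nlabl} but {n_used} labels in use (used labels must come first)")
    add("nversion", h.nversion in VALID_NVERSIONS,
        f"nversion={h.nversion}, expected 20140 or 20141")
    if h.nsymbt > 0:
        add("exttyp", h.exttyp.decode("ascii", "replace") in EXTTYPES,
            f"extended header present but exttyp {h.exttyp!r} is not a known tag")
    else:
        add("exttyp", True)

    # data-dependent checks need a parseable data block
    if mode_ok and h.nx > 0 and h.ny > 0 and h.nz > 0:
        dtype = SUPPORTED_MODES[h.mode]
        n_voxels = h.nx * h.ny * h.nz
        expected_size = HEADER_SIZE + h.nsymbt + n_voxels * dtype.itemsize
        size_ok = len(raw) == expected_size
        add("file_size", size_ok,
            f"file is {len(raw)} bytes, header implies {expected_size}")
        if size_ok and h.mode != 4:
            data = np.frombuffer(raw, dtype=dtype, count=n_voxels,
                                 offset=HEADER_SIZE + h.nsymbt)
            amin = float(np.min(data))
            amax = float(np.max(data))
            amean = float(np.mean(data, dtype=np.float64))
            scale = max(abs(amin), abs(amax), 1.0)
            tol = 1e-4 * scale
            undet_min_max = h.dmin > h.dmax
            undet_mean = h.dmean < min(h.dmin, h.dmax)
            ok = ((undet_min_max or (abs(h.dmin - amin) <= tol
                                     and abs(h.dmax - amax) <= tol))
                  and (undet_mean or undet_min_max or abs(h.dmean - amean) <= tol))
            add("data_statistics", ok,
                f"header stats (min={h.dmin}, max={h.dmax}, mean={h.dmean}) "
                f"disagree with data (min={amin}, max={amax}, mean={amean:.6g})")
        else:
            add("data_statistics", True)
    else:
        add("file_size", False, "header invalid; expected size undefined")
        add("data_statistics", False, "header invalid; cannot locate data")

    return ValidationReport(path=str(path), checks=checks)
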