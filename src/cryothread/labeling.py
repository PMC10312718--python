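"""Voxel labeling of density maps from atomic structures.

Given an atomic model in the same physical frame as a (resampled,
normalized) density map, four integer masks are produced on the map's grid:

* ``atom``   — backbone atoms: Cα voxels = 1, N = 2, carbonyl C = 3
* ``calpha`` — Cα voxels only (0/1)
* ``amino``  — amino-acid type at Cα voxels, codes 1..20 (alphabetical by
  three-letter code, ALA=1 … VAL=20), 0 = absent or unknown
* ``ss``     — secondary structure at Cα voxels: 1 coil, 2 α-helix,
  3 β-strand

An atom at physical coordinate (x, y, z) maps to grid index
``(i, j, k) = round((z - origin_z)/voxel_z), round((y - origin_y)/voxel_y),
round((x - origin_x)/voxel_x)`` with round-to-nearest (half away from
zero); the inverse conversion recovers the voxel-center coordinate, so
every in-bounds atom round-trips to within half a voxel per axis.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import OutOfBoundsError
from .mrc_io import DensityMap, MapHeader

__all__ = [
    "Coordinate", "GridIndex", "Atom", "Residue", "Chain", "Structure",
    "LabelVolume", "AMINO_CODES", "SS_CODES",
    "coord_to_index", "index_to_coord",
    "make_atom_labels", "make_amino_labels", "make_ss_labels",
    "extract_sequence", "verify_labels", "read_pdb", "write_pdb",
    "write_fasta",
]

#: Amino-acid integer codes, alphabetical by three-letter code.
AMINO_CODES = {name: i + 1 for i, name in enumerate([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"])}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

SS_CODES = {"coil": 1, "helix": 2, "strand": 3}

_LABEL_RANGES = {"atom": 3, "calpha": 1, "amino": 20, "ss": 3}


@dataclass(frozen=True)
class Coordinate:
    """A physical position in Å in the map's frame."""
    x: float
    y: float
    z: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("coordinate components must be finite")


@dataclass(frozen=True)
class GridIndex:
    """(section, row, column) = (z, y, x) voxel index."""
    i: int
    j: int
    k: int


@dataclass
class Atom:
    name: str
    coord: Coordinate


@dataclass
class Residue:
    seqnum: int
    name: str                      # three-letter code, upper case
    atoms: dict[str, Atom] = field(default_factory=dict)
    ss: str | None = None          # "coil" | "helix" | "strand" | None

    @property
    def calpha(self) -> Atom | None:
        return self.atoms.get("CA")

    @property
    def amino_code(self) -> int:
        """1..20 for standard residues, 0 for unknown."""
        return AMINO_CODES.get(self.name, 0)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


@dataclass
class LabelVolume:
    """Integer codes per voxel, sharing shape and header with its map."""
    kind: str
    values: np.ndarray
    header: MapHeader
    collisions: int = 0
    skipped: int = 0

    def __post_init__(self):
        if self.kind not in _LABEL_RANGES:
            raise ValueError(f"unknown label kind {self.kind!r}")
        self.values = np.asarray(self.values)
        hi = _LABEL_RANGES[self.kind]
        if self.values.size and (self.values.min() < 0 or self.values.max() > hi):
            raise ValueError(
                f"{self.kind} labels must lie in 0..{hi}")

    def as_map(self) -> DensityMap:
        return DensityMap(header=self.header,
                          values=self.values.astype(np.float32))


# ---------------------------------------------------------------------------
# coordinate <-> index

def _round_half_away(v: float) -> int:
    return int(math.floor(abs(v) + 0.5) * (1 if v >= 0 else -1))


def coord_to_index(c: Coordinate, header: MapHeader) -> GridIndex:
    """Map a physical coordinate to its voxel index (nearest voxel center).

    ``i`` comes from z, ``j`` from y and ``k`` from x; each is the nearest
    integer of ``(coordinate - origin) / voxel`` for its axis.  Indices
    outside the grid raise :class:`OutOfBoundsError` naming the axis.
    """
    vx, vy, vz = header.voxel_size
    i = _round_half_away((c.z - header.origin_z) / vz)
    j = _round_half_away((c.y - header.origin_y) / vy)
    k = _round_half_away((c.x - header.origin_x) / vx)
    for value, bound, axis in ((i, header.nz, "z"), (j, header.ny, "y"),
                               (k, header.nx, "x")):
        if not 0 <= value < bound:
            raise OutOfBoundsError(
                f"index {value} outside [0, {bound}) on axis {axis}", axis=axis)
    return GridIndex(i=i, j=j, k=k)


def index_to_coord(g: GridIndex, header: MapHeader) -> Coordinate:
    """Voxel-center physical coordinate of a grid index (inverse conversion)."""
    vx, vy, vz = header.voxel_size
    return Coordinate(x=g.k * vx + header.origin_x,
                      y=g.j * vy + header.origin_y,
                      z=g.i * vz + header.origin_z)


# ---------------------------------------------------------------------------
# masks

_ATOM_CODES = {"CA": 1, "N": 2, "C": 3}


def make_atom_labels(structure: Structure, header: MapHeader
                     ) -> tuple[LabelVolume, LabelVolume]:
    """Backbone-atom and Cα-only masks on the map grid.

    Each residue's Cα voxel is set to 1, N to 2 and carbonyl C to 3 in the
    ``atom`` mask; the ``calpha`` mask is 1 at Cα voxels only.  Atoms whose
    index falls outside the grid are skipped and counted; a voxel written
    twice counts as a collision (last atom wins).
    """
    shape = (header.nz, header.ny, header.nx)
    atom_mask = np.zeros(shape, dtype=np.int16)
    collisions = skipped = 0
    for residue in structure.residues():
        for name, code in _ATOM_CODES.items():
            atom = residue.atoms.get(name)
            if atom is None:
                continue
            try:
                g = coord_to_index(atom.coord, header)
            except OutOfBoundsError:
                skipped += 1
                continue
            if atom_mask[g.i, g.j, g.k]:
                collisions += 1
            atom_mask[g.i, g.j, g.k] = code
    if skipped and not atom_mask.any():
        warnings.warn("all atoms fell outside the grid; masks are empty",
                      stacklevel=2)
    calpha_mask = (atom_mask == 1).astype(np.int16)
    return (LabelVolume("atom", atom_mask, header, collisions, skipped),
            LabelVolume("calpha", calpha_mask, header, collisions, skipped))


def make_amino_labels(structure: Structure, header: MapHeader) -> LabelVolume:
    """Amino-acid-type mask: each Cα voxel carries its residue's code 1..20.

    Non-standard residues are written as 0 (unknown) and counted in
    ``skipped`` alongside out-of-grid atoms.
    """
    mask = np.zeros((header.nz, header.ny, header.nx), dtype=np.int16)
    collisions = skipped = 0
    for residue in structure.residues():
        atom = residue.calpha
        if atom is None:
            continue
        try:
            g = coord_to_index(atom.coord, header)
        except OutOfBoundsError:
            skipped += 1
            continue
        code = residue.amino_code
        if code == 0:
            skipped += 1
        if mask[g.i, g.j, g.k]:
            collisions += 1
        mask[g.i, g.j, g.k] = code
    return LabelVolume("amino", mask, header, collisions, skipped)


def make_ss_labels(structure: Structure, header: MapHeader) -> LabelVolume:
    """Secondary-structure mask: 1 coil, 2 helix, 3 strand at Cα voxels.

    Residues without an annotation default to coil.
    """
    mask = np.zeros((header.nz, header.ny, header.nx), dtype=np.int16)
    collisions = skipped = 0
    for residue in structure.residues():
        atom = residue.calpha
        if atom is None:
            continue
        try:
            g = coord_to_index(atom.coord, header)
        except OutOfBoundsError:
            skipped += 1
            continue
        if mask[g.i, g.j, g.k]:
            collisions += 1
        mask[g.i, g.j, g.k] = SS_CODES.get(residue.ss or "coil", 1)
    return LabelVolume("ss", mask, header, collisions, skipped)


# ---------------------------------------------------------------------------
# sequences

def extract_sequence(structure: Structure) -> dict[str, str]:
    """One-letter sequence per chain, ordered by residue number.

    Unknown residues are emitted as ``X``; empty chains are omitted.
    """
    sequences: dict[str, str] = {}
    for chain in structure.chains:
        residues = sorted(chain.residues, key=lambda r: r.seqnum)
        seq = "".join(THREE_TO_ONE.get(r.name, "X") for r in residues)
        if seq:
            sequences[chain.chain_id] = seq
    return sequences


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> str:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chain_id, description="")
               for chain_id, seq in sequences.items()]
    seqio_write(records, str(path), "fasta")
    return str(path)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio.SeqIO import parse
    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# verification

def verify_labels(calpha_mask: LabelVolume, structure: Structure,
                  header: MapHeader) -> tuple[float, list]:
    """Round-trip check of the Cα mask against the source structure.

    For every in-bounds Cα atom the mask voxel is converted back to a
    coordinate; the atom matches when the mask voxel is set and the
    recovered coordinate deviates by at most half a voxel per axis.
    Returns the match fraction (1.0 for an empty structure) and the list of
    deviating atoms as (chain_id, seqnum, deviation-per-axis) tuples.
    """
    if calpha_mask.values.shape != (header.nz, header.ny, header.nx):
        raise ValueError("mask shape does not match header")
    vx, vy, vz = header.voxel_size
    half = (0.5 * vx + 1e-9, 0.5 * vy + 1e-9, 0.5 * vz + 1e-9)
    total = matched = 0
    deviating = []
    for chain in structure.chains:
        for residue in chain.residues:
            atom = residue.calpha
            if atom is None:
                continue
            try:
                g = coord_to_index(atom.coord, header)
            except OutOfBoundsError:
                continue
            total += 1
            back = index_to_coord(g, header)
            dev = (abs(back.x - atom.coord.x), abs(back.y - atom.coord.y),
                   abs(back.z - atom.coord.z))
            ok = (calpha_mask.values[g.i, g.j, g.k] == 1
                  and all(d <= h for d, h in zip(dev, half)))
            if ok:
                matched += 1
            else:
                deviating.append((chain.chain_id, residue.seqnum, dev))
    if total == 0:
        return 1.0, []
    return matched / total, deviating


# ---------------------------------------------------------------------------
# PDB input

def read_pdb(path: str | os.PathLike) -> Structure:
    """Read a PDB file into the toolkit's structure type.

    Backbone atoms (CA, N, C) and any others are kept per residue;
    secondary-structure tags come from HELIX/SHEET records, with untagged
    residues left unannotated (they label as coil).
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    model = st[0]

    helix_ranges: list[tuple[str, int, int]] = []
    for helix in st.helices:
        helix_ranges.append((helix.start.chain_name, helix.start.res_id.seqid.num,
                             helix.end.res_id.seqid.num))
    strand_ranges: list[tuple[str, int, int]] = []
    for sheet in st.sheets:
        for strand in sheet.strands:
            strand_ranges.append((strand.start.chain_name,
                                  strand.start.res_id.seqid.num,
                                  strand.end.res_id.seqid.num))

    def ss_tag(chain_id: str, seqnum: int) -> str | None:
        for cid, lo, hi in helix_ranges:
            if cid == chain_id and lo <= seqnum <= hi:
                return "helix"
        for cid, lo, hi in strand_ranges:
            if cid == chain_id and lo <= seqnum <= hi:
                return "strand"
        return None

    structure = Structure()
    for chain in model:
        out_chain = Chain(chain_id=chain.name)
        for res in chain:
            if not any(a.name in _ATOM_CODES for a in res):
                continue
            residue = Residue(seqnum=res.seqid.num, name=res.name.upper(),
                              ss=ss_tag(chain.name, res.seqid.num))
            for a in res:
                residue.atoms[a.name] = Atom(
                    name=a.name,
                    coord=Coordinate(x=a.pos.x, y=a.pos.y, z=a.pos.z))
            out_chain.residues.append(residue)
        if out_chain.residues:
            structure.chains.append(out_chain)
    return structure


def _ss_runs(chain: Chain, tag: str):
    """Contiguous (start_seqnum, end_seqnum) runs of one ss tag in a chain."""
    runs = []
    run_start = prev = None
    for residue in chain.residues:
        if residue.ss == tag:
            if run_start is None:
                run_start = residue.seqnum
            prev = residue.seqnum
        elif run_start is not None:
            runs.append((run_start, prev))
            run_start = None
    if run_start is not None:
        runs.append((run_start, prev))
    return runs


def write_pdb(structure: Structure, path: str | os.PathLike) -> str:
    """Write a structure as a PDB file.

    Secondary-structure tags are emitted as HELIX/SHEET records over
    contiguous runs, so :func:`read_pdb` recovers them.
    """
    st = gemmi.Structure()
    st.name = "structure"
    model = gemmi.Model("1")
    resname_of = {}
    for chain in structure.chains:
        out = gemmi.Chain(chain.chain_id)
        for residue in chain.residues:
            res = gemmi.Residue()
            res.name = residue.name
            res.seqid = gemmi.SeqId(residue.seqnum, " ")
            resname_of[(chain.chain_id, residue.seqnum)] = residue.name
            for atom in residue.atoms.values():
                a = gemmi.Atom()
                a.name = atom.name
                a.element = gemmi.Element(atom.name[:1])
                a.pos = gemmi.Position(atom.coord.x, atom.coord.y, atom.coord.z)
                a.occ = 1.0
                a.b_iso = 0.0
                res.add_atom(a)
            out.add_residue(res)
        model.add_chain(out)
    st.add_model(model)

    def address(chain_id: str, seqnum: int) -> gemmi.AtomAddress:
        return gemmi.AtomAddress(chain_id, gemmi.SeqId(seqnum, " "),
                                 resname_of[(chain_id, seqnum)], "CA")

    n_sheet = 0
    for chain in structure.chains:
        for lo, hi in _ss_runs(chain, "helix"):
            helix = gemmi.Helix()
            helix.start = address(chain.chain_id, lo)
            helix.end = address(chain.chain_id, hi)
            helix.pdb_helix_class = 1
            helix.length = hi - lo + 1
            st.helices.append(helix)
        for lo, hi in _ss_runs(chain, "strand"):
            n_sheet += 1
            sheet = gemmi.Sheet(f"S{n_sheet}")
            strand = gemmi.Sheet.Strand()
            strand.start = address(chain.chain_id, lo)
            strand.end = address(chain.chain_id, hi)
            strand.name = "1"
            strand.sense = 0
            sheet.strands.append(strand)
            st.sheets.append(sheet)

    st.setup_entities()
    st.write_pdb(str(path))
    return str(path)
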