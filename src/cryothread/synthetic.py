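"""Synthetic fixtures: toy backbones, simulated maps, masks and corrupted
"prediction" volumes.

The generator produces every input the pipeline consumes, with the
statistical structure the method assumes, so each stage is testable
without downloads or trained networks:

* Backbones are seeded self-avoiding random walks whose consecutive Cα–Cα
  distances are drawn from N(3.8047 Å, 0.036 Å) — the geometry the HMM's
  transition law models.
* Density is a sum of isotropic Gaussian blobs around atoms on a 1 Å grid
  plus additive Gaussian noise, then percentile-normalized; the analytic
  kernel gives an exact oracle for the noise-free values.
* "Predictions" are the ground-truth label masks corrupted at a
  controllable error rate ε: the true class keeps probability 1 − ε, and
  with probability ε the top class is flipped to a random wrong one.

One global seed drives all draws; sub-streams for the walk, the noise, the
residue types and the corruption are spawned deterministically from it.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .hmm_threading import (AMINO_CLASSES, ATOM_CLASSES, PredictionVolume,
                            write_prediction_volume)
from .labeling import (AMINO_CODES, Atom, Chain, Coordinate, LabelVolume,
                       Residue, Structure, extract_sequence, make_amino_labels,
                       make_atom_labels, make_ss_labels, write_fasta, write_pdb)
from .mrc_io import DensityMap, write_mrc
from .preprocess import normalize_map

__all__ = ["SyntheticConfig", "SyntheticFixture", "generate_backbone",
           "simulate_density", "corrupt_to_predictions", "make_fixture"]

_AMINO_NAMES = tuple(sorted(AMINO_CODES, key=AMINO_CODES.get))
#: Fractional positions of the carbonyl C and the next residue's N on the
#: virtual Cα(t) -> Cα(t+1) segment.
_C_FRACTION = 0.35
_N_FRACTION = 0.65
_BOX_MARGIN = 6.0  # Å of padding around the structure's bounding box


@dataclass
class SyntheticConfig:
    """Study conditions for fixture generation.

    ``bond_mu``/``bond_sigma`` match the backbone Cα–Cα distance law the
    threading model assumes; ``min_separation`` is the self-avoidance
    radius between non-consecutive Cα atoms; ``blob_sigma`` the density
    kernel width; ``label_error_rate`` the corruption probability ε.
    """

    n_residues: int = 30
    n_chains: int = 1
    bond_mu: float = 3.8047
    bond_sigma: float = 0.036
    min_separation: float = 3.5
    blob_sigma: float = 1.0
    noise_sigma: float = 0.05
    label_error_rate: float = 0.0
    seed: int = 7

    def __post_init__(self):
        if min(self.n_residues, self.n_chains) < 1:
            raise ValueError("n_residues and n_chains must be positive")
        if min(self.bond_mu, self.bond_sigma, self.min_separation,
               self.blob_sigma) <= 0:
            raise ValueError("geometric parameters must be positive")
        if not 0 <= self.label_error_rate < 1:
            raise ValueError("label_error_rate must lie in [0, 1)")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named per-component generators spawned from the global seed."""
        names = ("walk", "types", "noise", "corrupt")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {name: np.random.default_rng(child)
                for name, child in zip(names, children)}


@dataclass
class SyntheticFixture:
    structure: Structure
    density: DensityMap                      # normalized
    masks: dict[str, LabelVolume]            # atom / calpha / amino / ss
    atom_pred: PredictionVolume
    amino_pred: PredictionVolume
    sequences: dict[str, str]
    paths: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# backbone generation

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _ss_tag(position: int) -> str:
    # alternate coil / helix / strand in runs of five residues
    return ("coil", "helix", "strand")[(position // 5) % 3]


def generate_backbone(config: SyntheticConfig) -> Structure:
    """Seeded self-avoiding random walk over Cα positions.

    Consecutive Cα distances are drawn from N(bond_mu, bond_sigma); every
    pair of non-consecutive Cα atoms (within and across chains) stays at
    least ``min_separation`` apart.  The carbonyl C and the next N are
    placed at fixed fractions of the virtual Cα–Cα segment.  Deterministic
    given the seed.
    """
    streams = config.streams()
    rng, type_rng = streams["walk"], streams["types"]
    placed: list[np.ndarray] = []       # all Cα across chains
    chains: list[list[np.ndarray]] = []

    for c in range(config.n_chains):
        for _attempt in range(50):
            chain_ca = _walk_chain(config, rng, placed)
            if chain_ca is not None:
                break
        else:
            raise GenerationError(
                f"could not place chain {c} after bounded retries; "
                "reduce n_residues or min_separation")
        chains.append(chain_ca)
        placed.extend(chain_ca)

    structure = Structure()
    for c, chain_ca in enumerate(chains):
        chain = Chain(chain_id=chr(ord("A") + c))
        for t, ca in enumerate(chain_ca):
            name = _AMINO_NAMES[type_rng.integers(0, 20)]
            residue = Residue(seqnum=t + 1, name=name, ss=_ss_tag(t))
            residue.atoms["CA"] = Atom("CA", Coordinate(*ca))
            if t + 1 < len(chain_ca):
                seg = chain_ca[t + 1] - ca
            else:
                seg = ca - chain_ca[t - 1] if t > 0 else np.array([1.0, 0, 0])
            c_pos = ca + _C_FRACTION * seg
            residue.atoms["C"] = Atom("C", Coordinate(*c_pos))
            if t == 0:
                n_pos = ca - _C_FRACTION * seg
            else:
                n_pos = chain_ca[t - 1] + _N_FRACTION * (ca - chain_ca[t - 1])
            residue.atoms["N"] = Atom("N", Coordinate(*n_pos))
            chain.residues.append(residue)
        structure.chains.append(chain)
    return structure


def _walk_chain(config: SyntheticConfig, rng: np.random.Generator,
                placed: list[np.ndarray]) -> list[np.ndarray] | None:
    """One chain's Cα walk; None when the walk dead-ends."""
    # start away from already-placed chains
    for _ in range(200):
        start = rng.uniform(-5, 5, size=3) + np.array(
            [12.0 * len(placed) / max(config.n_residues, 1), 0, 0])
        if all(np.linalg.norm(start - q) >= config.min_separation
               for q in placed):
            break
    else:
        return None
    chain = [start]
    direction = _random_unit(rng)
    for _t in range(1, config.n_residues):
        for _retry in range(200):
            # persistent direction keeps the walk extended, like a backbone
            proposal = direction + 0.9 * _random_unit(rng)
            proposal /= np.linalg.norm(proposal)
            step = rng.normal(config.bond_mu, config.bond_sigma)
            nxt = chain[-1] + step * proposal
            others = chain[:-1] + placed
            if all(np.linalg.norm(nxt - q) >= config.min_separation
                   for q in others):
                chain.append(nxt)
                direction = proposal
                break
        else:
            return None
    return chain


# ---------------------------------------------------------------------------
# density simulation

def simulate_density(structure: Structure, config: SyntheticConfig,
                     normalize: bool = True) -> DensityMap:
    """Gaussian-blob density for a structure on a 1 Å grid.

    Each atom contributes ``exp(-r^2 / (2 * blob_sigma^2))``; seeded
    Gaussian noise of scale ``noise_sigma`` is added, and the map is
    percentile-normalized unless ``normalize`` is False.  The grid starts
    ``6 Å`` below the structure's bounding box on every axis.
    """
    coords = np.array([(a.coord.x, a.coord.y, a.coord.z)
                       for r in structure.residues()
                       for a in r.atoms.values()])
    if coords.size == 0:
        raise ValueError("structure has no atoms")
    low = np.floor(coords.min(axis=0) - _BOX_MARGIN)
    high = np.ceil(coords.max(axis=0) + _BOX_MARGIN)
    nx, ny, nz = (int(high[d] - low[d]) + 1 for d in range(3))
    values = np.zeros((nz, ny, nx), dtype=np.float64)

    reach = int(math.ceil(4 * config.blob_sigma))
    two_s2 = 2.0 * config.blob_sigma ** 2
    for x, y, z in coords:
        ck, cj, ci = x - low[0], y - low[1], z - low[2]
        k0, k1 = max(0, int(ck) - reach), min(nx, int(ck) + reach + 2)
        j0, j1 = max(0, int(cj) - reach), min(ny, int(cj) + reach + 2)
        i0, i1 = max(0, int(ci) - reach), min(nz, int(ci) + reach + 2)
        kk, jj, ii = np.meshgrid(np.arange(k0, k1), np.arange(j0, j1),
                                 np.arange(i0, i1), indexing="ij")
        r2 = (kk - ck) ** 2 + (jj - cj) ** 2 + (ii - ci) ** 2
        values[i0:i1, j0:j1, k0:k1] += np.exp(-r2 / two_s2).transpose(2, 1, 0)

    if config.noise_sigma > 0:
        noise_rng = config.streams()["noise"]
        values += noise_rng.normal(0.0, config.noise_sigma, size=values.shape)
    density = DensityMap.from_values(values.astype(np.float32), voxel_size=1.0,
                                     origin=tuple(low))
    return normalize_map(density) if normalize else density


# ---------------------------------------------------------------------------
# prediction corruption

def _corrupt(mask: np.ndarray, class_names: tuple[str, ...],
             label_to_channel, epsilon: float,
             rng: np.random.Generator, header) -> PredictionVolume:
    n_classes = len(class_names)
    background = np.full(n_classes, 1e-3 / (n_classes - 1))
    background[0] = 1.0 - 1e-3
    probs = np.tile(background, mask.shape + (1,))

    labeled = np.argwhere(mask > 0)
    off = epsilon / (n_classes - 1)
    flip = rng.random(len(labeled)) < epsilon
    wrong_draw = rng.integers(0, n_classes - 1, size=len(labeled))
    for row, (i, j, k) in enumerate(labeled):
        true_channel = label_to_channel(mask[i, j, k])
        top = true_channel
        if flip[row]:
            top = int(wrong_draw[row])
            if top >= true_channel:
                top += 1
        probs[i, j, k, :] = off
        probs[i, j, k, top] = 1.0 - epsilon
    return PredictionVolume(class_names=class_names, probs=probs, header=header)


def corrupt_to_predictions(atom_mask: LabelVolume, amino_mask: LabelVolume,
                           epsilon: float, seed: int | np.random.Generator
                           ) -> tuple[PredictionVolume, PredictionVolume]:
    """Ground-truth masks corrupted into soft "prediction" volumes.

    Each labeled voxel's true class receives probability 1 − ε with ε
    spread evenly over the other classes; with probability ε the top class
    is flipped to a random wrong class.  Unlabeled voxels get near-one
    background probability.  Rows sum to 1; deterministic given the seed.
    """
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must lie in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    atom_pred = _corrupt(np.asarray(atom_mask.values), ATOM_CLASSES,
                         lambda code: int(code), epsilon, rng,
                         atom_mask.header)
    amino_pred = _corrupt(np.asarray(amino_mask.values), AMINO_CLASSES,
                          lambda code: int(code), epsilon, rng,
                          amino_mask.header)
    return atom_pred, amino_pred


# ---------------------------------------------------------------------------
# fixture assembly

MASK_FILENAMES = {
    "atom": "atom_emd_normalized_map.mrc",
    "calpha": "atom_ca_emd_normalized_map.mrc",
    "amino": "amino_emd_normalized_map.mrc",
    "ss": "sec_struc_emd_normalized_map.mrc",
}


def make_fixture(config: SyntheticConfig | None = None,
                 out_dir: str | os.PathLike | None = None) -> SyntheticFixture:
    """Generate a full fixture and optionally write it in the standard
    per-map directory layout.

    The directory receives ``emd_normalized_map.mrc``, the four mask files,
    the model PDB, the FASTA sequences, and the prediction volumes as
    per-channel MRC files; every MRC written passes the validation battery.
    """
    config = config or SyntheticConfig()
    structure = generate_backbone(config)
    density = simulate_density(structure, config)
    header = density.header
    atom_mask, calpha_mask = make_atom_labels(structure, header)
    amino_mask = make_amino_labels(structure, header)
    ss_mask = make_ss_labels(structure, header)
    masks = {"atom": atom_mask, "calpha": calpha_mask,
             "amino": amino_mask, "ss": ss_mask}
    atom_pred, amino_pred = corrupt_to_predictions(
        atom_mask, amino_mask, config.label_error_rate,
        config.streams()["corrupt"])
    sequences = extract_sequence(structure)
    fixture = SyntheticFixture(structure=structure, density=density,
                               masks=masks, atom_pred=atom_pred,
                               amino_pred=amino_pred, sequences=sequences)
    if out_dir is not None:
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        paths = {"map": write_mrc(density,
                                  os.path.join(out_dir, "emd_normalized_map.mrc"))}
        for kind, mask in masks.items():
            paths[kind] = write_mrc(mask.as_map(),
                                    os.path.join(out_dir, MASK_FILENAMES[kind]))
        paths["pdb"] = write_pdb(structure, os.path.join(out_dir, "model.pdb"))
        paths["fasta"] = write_fasta(sequences,
                                     os.path.join(out_dir, "sequence.fasta"))
        paths["atom_pred"] = write_prediction_volume(
            atom_pred, out_dir, "atom_pred")
        paths["amino_pred"] = write_prediction_volume(
            amino_pred, out_dir, "amino_pred")
        fixture.paths = paths
    return fixture
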