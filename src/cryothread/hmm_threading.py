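"""HMM-guided threading of protein sequences through predicted Cα voxels.

Voxels predicted to hold a Cα atom become the hidden states of an HMM whose
observations are the amino acids of the known protein sequence:

* **Emissions** — for each state, the normalized geometric mean
  ``sqrt(a_t * b_t) / sum_u sqrt(a_u * b_u)`` of the per-voxel predicted
  amino-acid probability ``a_t`` and the background frequency ``b_t``.
* **Transitions** — a Gaussian density over the Euclidean distance between
  two states' coordinates, mean 3.8047 Å (the consecutive Cα–Cα distance in
  protein backbones) and standard deviation 0.036 Å times a scaling factor
  Λ = 10, truncated to zero beyond a neighbor cutoff.
* **Initial distribution** — any state may start a chain, with probability
  proportional to its emission of the chain's first amino acid.

Decoding uses a Viterbi search constrained so that every hidden state is
used at most once across all chains (a Cα position can hold only one
residue).  The constraint makes exact decoding combinatorial, so the
search keeps a beam of partial paths, each carrying its used-state set;
with an unbounded beam the search is exhaustive and exact.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.stats import norm

from .errors import EmptyModelError, PartialThreadError
from .labeling import (AMINO_CODES, ONE_TO_THREE, Coordinate, GridIndex,
                       index_to_coord)
from .mrc_io import DensityMap, MapHeader, read_mrc, write_mrc

__all__ = [
    "ATOM_CLASSES", "AMINO_CLASSES",
    "PredictionVolume", "CandidateState", "HMMParams", "HMMModel",
    "BackboneModel", "select_calpha_candidates", "build_emissions",
    "transition_prob", "initial_probs", "build_hmm", "viterbi_thread",
    "write_backbone", "write_prediction_volume", "read_prediction_volume",
]

#: Channel order of atom-type prediction volumes.
ATOM_CLASSES = ("none", "CA", "N", "C")
#: Channel order of amino-acid prediction volumes: unknown/absent + 20 types.
AMINO_CLASSES = ("UNK",) + tuple(sorted(AMINO_CODES, key=AMINO_CODES.get))

NEG_INF = float("-inf")


@dataclass
class PredictionVolume:
    """Per-voxel class probabilities on a map grid (channel-last layout)."""

    class_names: tuple[str, ...]
    probs: np.ndarray            # (nz, ny, nx, n_classes)
    header: MapHeader

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 4 or self.probs.shape[3] != len(self.class_names):
            raise ValueError("probs must be (nz, ny, nx, n_classes)")
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=3)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-voxel probabilities must sum to 1")

    def channel(self, name: str) -> np.ndarray:
        return self.probs[..., self.class_names.index(name)]


@dataclass
class CandidateState:
    """One candidate Cα position (a voxel), a hidden state of the HMM."""
    index: GridIndex
    coord: Coordinate
    calpha_prob: float
    emission: np.ndarray | None = None   # 20-vector over amino types


@dataclass
class HMMParams:
    """Model geometry and search-control parameters.

    ``mu``/``sigma`` are the mean and standard deviation (Å) of the
    consecutive Cα–Cα distance; the transition Gaussian uses standard
    deviation ``sigma * lambda_scale``.  ``neighbor_cutoff`` truncates
    transitions (default ``mu + 10 * sigma * lambda_scale``), and
    ``beam_width`` bounds the number of partial paths kept per step
    (``None`` = unbounded, exact).
    """

    mu: float = 3.8047
    sigma: float = 0.036
    lambda_scale: float = 10.0
    background: np.ndarray | None = None
    neighbor_cutoff: float | None = None
    beam_width: int | None = 50
    detection_threshold: float = 0.5
    normalize_transitions: bool = False

    def __post_init__(self):
        if min(self.mu, self.sigma, self.lambda_scale) <= 0:
            raise ValueError("mu, sigma and lambda_scale must be positive")
        if self.background is None:
            self.background = np.full(20, 1.0 / 20)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.background.shape != (20,) or not math.isclose(
                float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background must be a 20-vector summing to 1")
        if self.neighbor_cutoff is None:
            self.neighbor_cutoff = self.mu + 10 * self.sigma * self.lambda_scale

    @property
    def transition_sd(self) -> float:
        return self.sigma * self.lambda_scale


@dataclass
class HMMModel:
    """Candidate states plus the distance-based transition law."""
    states: list[CandidateState]
    params: HMMParams
    log_transitions: np.ndarray = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class BackboneModel:
    """Ordered, typed Cα trace per chain.

    ``chains`` maps chain id to a list of ``(residue number, three-letter
    type, Coordinate)``; ``state_paths`` records the hidden-state indices
    each chain consumed (for the used-at-most-once invariant) and
    ``log_scores`` the per-chain path log-score.
    """
    chains: dict[str, list[tuple[int, str, Coordinate]]] = field(
        default_factory=dict)
    state_paths: dict[str, list[int]] = field(default_factory=dict)
    log_scores: dict[str, float] = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


# ---------------------------------------------------------------------------
# model construction

def select_calpha_candidates(atom_pred: PredictionVolume,
                             threshold: float = 0.5) -> list[CandidateState]:
    """Voxels whose Cα-channel probability reaches ``threshold``.

    States are ordered by (i, j, k) for determinism; an empty candidate set
    raises :class:`EmptyModelError`.
    """
    ca = atom_pred.channel("CA")
    picks = np.argwhere(ca >= threshold)
    if picks.size == 0:
        raise EmptyModelError(
            f"no voxel has Cα probability >= {threshold}; cannot build an HMM")
    states = []
    for i, j, k in picks:  # argwhere returns lexicographic (i, j, k) order
        g = GridIndex(int(i), int(j), int(k))
        states.append(CandidateState(
            index=g, coord=index_to_coord(g, atom_pred.header),
            calpha_prob=float(ca[i, j, k])))
    return states


def build_emissions(states: list[CandidateState],
                    amino_pred: PredictionVolume,
                    background: np.ndarray | None = None
                    ) -> list[CandidateState]:
    """Attach normalized geometric-mean emission vectors to states.

    ``raw_t = sqrt(a_t * b_t)`` with ``a_t`` the predicted probability of
    amino type t at the state's voxel and ``b_t`` its background frequency;
    the emission is ``raw / raw.sum()``.  An all-zero raw vector falls back
    to the uniform emission with a warning.
    """
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=np.float64)
    amino_channels = [amino_pred.class_names.index(name)
                      for name in AMINO_CLASSES[1:]]
    for state in states:
        g = state.index
        a = amino_pred.probs[g.i, g.j, g.k, amino_channels]
        raw = np.sqrt(a * background)
        total = raw.sum()
        if total <= 0:
            warnings.warn(f"state at {g} has an all-zero emission vector; "
                          "using the uniform emission", stacklevel=2)
            state.emission = np.full(20, 1.0 / 20)
        else:
            state.emission = raw / total
    return states


def transition_prob(s1: CandidateState, s2: CandidateState,
                    params: HMMParams) -> float:
    """Gaussian transition weight between two states.

    The density of N(mu, (sigma * lambda_scale)^2) evaluated at the
    Euclidean distance between the states; zero beyond the neighbor cutoff
    and zero for a self-transition (states are used at most once).
    """
    if s1 is s2 or s1.index == s2.index:
        return 0.0
    d = math.dist((s1.coord.x, s1.coord.y, s1.coord.z),
                  (s2.coord.x, s2.coord.y, s2.coord.z))
    if d > params.neighbor_cutoff:
        return 0.0
    return float(norm.pdf(d, loc=params.mu, scale=params.transition_sd))


def initial_probs(states: list[CandidateState],
                  first_residue: str) -> np.ndarray:
    """Distribution over states for the first residue of a chain.

    Each state's probability is its emission of the first amino acid
    divided by the sum over all states; if every state emits it with
    probability zero, the distribution falls back to uniform.
    """
    aa = _aa_index(first_residue)
    if aa is None:
        return np.full(len(states), 1.0 / len(states))
    weights = np.array([s.emission[aa] for s in states], dtype=np.float64)
    total = weights.sum()
    if total <= 0:
        warnings.warn("no state emits the first residue; "
                      "using the uniform initial distribution", stacklevel=2)
        return np.full(len(states), 1.0 / len(states))
    return weights / total


def build_hmm(atom_pred: PredictionVolume, amino_pred: PredictionVolume,
              params: HMMParams | None = None) -> HMMModel:
    """Full model construction: candidates, emissions, transition table."""
    params = params or HMMParams()
    states = select_calpha_candidates(atom_pred, params.detection_threshold)
    build_emissions(states, amino_pred, params.background)
    return HMMModel(states=states, params=params,
                    log_transitions=_log_transition_matrix(states, params))


def _log_transition_matrix(states: list[CandidateState],
                           params: HMMParams) -> np.ndarray:
    coords = np.array([(s.coord.x, s.coord.y, s.coord.z) for s in states])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    with np.errstate(divide="ignore"):
        logw = norm.logpdf(dist, loc=params.mu, scale=params.transition_sd)
        logw[dist > params.neighbor_cutoff] = NEG_INF
        np.fill_diagonal(logw, NEG_INF)
        if params.normalize_transitions:
            row = np.logaddexp.reduce(np.where(np.isneginf(logw), NEG_INF, logw),
                                      axis=1, keepdims=True)
            logw = logw - np.where(np.isneginf(row), 0.0, row)
    return logw


# ---------------------------------------------------------------------------
# constrained Viterbi (beam search over used-state sets)

def _aa_index(letter: str) -> int | None:
    """0-based amino index of a one-letter code, None for unknowns."""
    three = ONE_TO_THREE.get(letter.upper())
    if three is None:
        return None
    return AMINO_CODES[three] - 1


def _thread_chain(model: HMMModel, sequence: str, consumed: set[int],
                  beam_width: int | None, allow_partial: bool
                  ) -> tuple[list[int], float]:
    """Best at-most-once state path for one chain.

    Returns (path, log-score); raises :class:`PartialThreadError` when the
    full sequence cannot be placed and ``allow_partial`` is False.
    """
    n = model.n_states
    log_emis = np.full((n, 20), NEG_INF)
    with np.errstate(divide="ignore"):
        for s_idx, state in enumerate(model.states):
            log_emis[s_idx] = np.log(state.emission)
    available = [s for s in range(n) if s not in consumed]
    if not available:
        raise PartialThreadError("no unconsumed states left for this chain")

    init = initial_probs([model.states[s] for s in available], sequence[0])
    aa0 = _aa_index(sequence[0])
    with np.errstate(divide="ignore"):
        log_init = np.log(init)
    # hypothesis: (score, path tuple, used frozenset)
    beam = []
    for pos, s_idx in enumerate(available):
        e = 0.0 if aa0 is None else log_emis[s_idx, aa0]
        score = log_init[pos] + e
        if score > NEG_INF:
            beam.append((score, (s_idx,), frozenset((s_idx,))))
    beam.sort(key=lambda h: (-h[0], h[1]))
    if beam_width is not None:
        beam = beam[:beam_width]
    if not beam:
        raise PartialThreadError("no feasible starting state", prefix=[])

    logT = model.log_transitions
    for t in range(1, len(sequence)):
        aa = _aa_index(sequence[t])
        extended = []
        for score, path, used in beam:
            last = path[-1]
            for s_idx in available:
                if s_idx in used:
                    continue
                step = logT[last, s_idx]
                if step == NEG_INF:
                    continue
                if aa is not None:
                    e = log_emis[s_idx, aa]
                    if e == NEG_INF:
                        continue
                    step += e
                extended.append((score + step, path + (s_idx,),
                                 used | {s_idx}))
        if not extended:
            best = beam[0]
            if allow_partial:
                return list(best[1]), best[0]
            raise PartialThreadError(
                f"sequence of length {len(sequence)} stalls after "
                f"{t} residues", prefix=list(best[1]))
        extended.sort(key=lambda h: (-h[0], h[1]))
        beam = extended if beam_width is None else extended[:beam_width]

    best = beam[0]
    return list(best[1]), best[0]


def viterbi_thread(model: HMMModel, sequences: dict[str, str],
                   params: HMMParams | None = None,
                   allow_partial: bool = False) -> BackboneModel:
    """Thread per-chain sequences through the HMM's candidate states.

    Chains are threaded longest-first; states consumed by earlier chains
    are removed before later chains are threaded, so no state appears twice
    anywhere in the output.  Each chain's path maximizes
    ``log initial(s_1) + log e_{s_1}(aa_1) +
    sum_t [log transition(s_{t-1}, s_t) + log e_{s_t}(aa_t)]``
    over injective state assignments, searched with a beam of width
    ``params.beam_width`` (unbounded beam = exact).

    With ``allow_partial`` the longest achievable prefix of a chain is kept
    instead of raising :class:`PartialThreadError`.
    """
    params = params or model.params
    total = sum(len(s) for s in sequences.values())
    if model.n_states < total and not allow_partial:
        raise PartialThreadError(
            f"{model.n_states} candidate states cannot host {total} residues")
    if model.log_transitions is None:
        model.log_transitions = _log_transition_matrix(model.states, params)

    backbone = BackboneModel()
    consumed: set[int] = set()
    order = sorted(sequences, key=lambda c: (-len(sequences[c]), c))
    for chain_id in order:
        sequence = sequences[chain_id]
        if not sequence:
            continue
        path, score = _thread_chain(model, sequence, consumed,
                                    params.beam_width, allow_partial)
        residues = []
        for t, s_idx in enumerate(path):
            aa = sequence[t].upper()
            residues.append((t + 1, ONE_TO_THREE.get(aa, "UNK"),
                             model.states[s_idx].coord))
        backbone.chains[chain_id] = residues
        backbone.state_paths[chain_id] = path
        backbone.log_scores[chain_id] = score
        consumed.update(path)
    return backbone


# ---------------------------------------------------------------------------
# output

def write_backbone(model: BackboneModel, path: str | os.PathLike) -> str:
    """Write a backbone trace as a PDB file with one Cα ATOM per residue."""
    if model.n_residues == 0:
        raise ValueError("backbone model is empty")
    if model.n_residues > 99999:
        raise ValueError("more than 99999 atoms cannot be numbered in PDB")
    st = gemmi.Structure()
    st.name = "backbone"
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        chain = gemmi.Chain(chain_id)
        for resnum, resname, coord in residues:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(coord.x, coord.y, coord.z)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
    return str(path)


def write_prediction_volume(volume: PredictionVolume, directory: str | os.PathLike,
                            prefix: str) -> list[str]:
    """Serialize a prediction volume as one mode-2 MRC file per channel."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for c, name in enumerate(volume.class_names):
        channel_map = DensityMap(header=volume.header,
                                 values=volume.probs[..., c].astype(np.float32))
        out = os.path.join(str(directory), f"{prefix}_{name}.mrc")
        write_mrc(channel_map, out, mode=2)
        paths.append(out)
    return paths


def read_prediction_volume(directory: str | os.PathLike, prefix: str,
                           class_names: tuple[str, ...]) -> PredictionVolume:
    channels = []
    header = None
    for name in class_names:
        m = read_mrc(os.path.join(str(directory), f"{prefix}_{name}.mrc"))
        header = header or m.header
        channels.append(np.asarray(m.values, dtype=np.float64))
    probs = np.stack(channels, axis=-1)
    # float32 round-trip can leave sums a hair off 1
    probs /= probs.sum(axis=-1, keepdims=True)
    return PredictionVolume(class_names=tuple(class_names), probs=probs,
                            header=header)
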