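"""HMM construction and constrained Viterbi threading.

The beam search is checked against an independent brute-force oracle that
enumerates every injective assignment of residues to states and scores it
with direct evaluations of the Gaussian transition density.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from cryothread.errors import EmptyModelError, PartialThreadError
from cryothread.hmm_threading import (AMINO_CLASSES, ATOM_CLASSES,
                                      BackboneModel, CandidateState, HMMModel,
                                      HMMParams, PredictionVolume,
                                      build_emissions, initial_probs,
                                      select_calpha_candidates,
                                      transition_prob, viterbi_thread,
                                      write_backbone)
from cryothread.labeling import (AMINO_CODES, Coordinate, GridIndex,
                                 ONE_TO_THREE, read_pdb)
from cryothread.mrc_io import MapHeader

AA = sorted(AMINO_CODES, key=AMINO_CODES.get)  # three-letter codes, 1..20


def make_state(idx, coord, emission=None):
    return CandidateState(
        index=GridIndex(idx, 0, 0), coord=Coordinate(*coord),
        calpha_prob=1.0,
        emission=None if emission is None else np.asarray(emission, float))


def one_hot(aa_position, eps=0.0):
    e = np.full(20, eps / 19)
    e[aa_position] = 1.0 - eps
    return e


def header(n=8):
    return MapHeader(nx=n, ny=n, nz=n)


def atom_volume(ca_probs):
    """Atom PredictionVolume from a (nz,ny,nx) array of Cα probabilities."""
    ca = np.asarray(ca_probs, dtype=np.float64)
    probs = np.zeros(ca.shape + (4,))
    probs[..., 1] = ca
    rest = (1 - ca) / 3
    for c in (0, 2, 3):
        probs[..., c] = rest
    return PredictionVolume(ATOM_CLASSES, probs, header(ca.shape[0]))


class TestCandidateSelection:
    def test_three_voxels_above_threshold(self):
        ca = np.zeros((8, 8, 8))
        ca[1, 2, 3] = 0.9
        ca[4, 4, 4] = 0.8
        ca[7, 0, 1] = 0.6
        states = select_calpha_candidates(atom_volume(ca), threshold=0.5)
        assert len(states) == 3
        assert {(s.index.i, s.index.j, s.index.k) for s in states} == {
            (1, 2, 3), (4, 4, 4), (7, 0, 1)}
        # coordinates are the voxel centers (1 Å grid, origin 0)
        assert any((s.coord.x, s.coord.y, s.coord.z) == (3, 2, 1)
                   for s in states)

    def test_threshold_zero_selects_all(self):
        ca = np.full((3, 3, 3), 0.1)
        states = select_calpha_candidates(atom_volume(ca), threshold=0.0)
        assert len(states) == 27

    def test_candidate_count_monotone_in_threshold(self, rng):
        ca = rng.random((6, 6, 6))
        vol = atom_volume(ca)
        counts = []
        for t in np.linspace(0.05, 0.95, 10):
            try:
                counts.append(len(select_calpha_candidates(vol, t)))
            except EmptyModelError:
                counts.append(0)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_no_candidates_raises(self):
        with pytest.raises(EmptyModelError):
            select_calpha_candidates(atom_volume(np.zeros((3, 3, 3))), 0.5)


class TestEmissions:
    def amino_volume(self, a_vector):
        probs = np.zeros((1, 1, 1, 21))
        probs[0, 0, 0, 1:] = a_vector
        probs[0, 0, 0, 0] = 1.0 - np.sum(a_vector)
        return PredictionVolume(AMINO_CLASSES, probs, MapHeader(nx=1, ny=1, nz=1))

    def state(self):
        return make_state(0, (0, 0, 0))

    def test_uniform_times_uniform_is_uniform(self):
        vol = self.amino_volume(np.full(20, 0.05))
        (s,) = build_emissions([self.state()], vol, np.full(20, 0.05))
        np.testing.assert_allclose(s.emission, 0.05, atol=1e-12)

    def test_one_hot_annihilates(self):
        vol = self.amino_volume(one_hot(0))
        (s,) = build_emissions([self.state()], vol, np.full(20, 0.05))
        np.testing.assert_allclose(s.emission, one_hot(0), atol=1e-12)

    def test_hand_arithmetic(self):
        a = np.zeros(20)
        a[0], a[1] = 0.8, 0.2
        b = np.zeros(20)
        b[0], b[1] = 0.5, 0.5
        vol = self.amino_volume(a)
        (s,) = build_emissions([self.state()], vol, b)
        # raw = (sqrt(0.40), sqrt(0.10)); normalized = (2/3, 1/3)
        assert s.emission[0] == pytest.approx(2 / 3, abs=1e-9)
        assert s.emission[1] == pytest.approx(1 / 3, abs=1e-9)
        assert s.emission[2:].sum() == 0

    def test_all_zero_raw_falls_back_to_uniform(self):
        a = one_hot(0)
        b = np.zeros(20)
        b[1] = 1.0  # disjoint support -> all-zero geometric mean
        vol = self.amino_volume(a)
        with pytest.warns(UserWarning):
            (s,) = build_emissions([self.state()], vol, b)
        np.testing.assert_allclose(s.emission, 0.05)


class TestTransitions:
    def test_density_peak_at_mean(self):
        params = HMMParams()
        s1 = make_state(0, (0, 0, 0))
        s2 = make_state(1, (3.8047, 0, 0))
        w = transition_prob(s1, s2, params)
        assert w == pytest.approx(1 / (0.36 * math.sqrt(2 * math.pi)),
                                  rel=1e-9)
        assert w == pytest.approx(1.108, abs=1e-3)

    def test_symmetry_about_mean(self):
        params = HMMParams()
        s1 = make_state(0, (0, 0, 0))
        plus = make_state(1, (params.mu + 0.2, 0, 0))
        minus = make_state(2, (params.mu - 0.2, 0, 0))
        assert transition_prob(s1, plus, params) == pytest.approx(
            transition_prob(s1, minus, params), rel=1e-12)

    def test_cutoff_and_self_transition_are_zero(self):
        params = HMMParams(neighbor_cutoff=20.0)
        s1 = make_state(0, (0, 0, 0))
        far = make_state(1, (50, 0, 0))
        assert transition_prob(s1, far, params) == 0.0
        assert transition_prob(s1, s1, params) == 0.0


class TestInitialProbs:
    def test_two_state_normalization(self):
        e1, e2 = np.zeros(20), np.zeros(20)
        e1[0], e2[0] = 0.2, 0.3
        states = [make_state(0, (0, 0, 0), e1), make_state(1, (4, 0, 0), e2)]
        probs = initial_probs(states, "A")
        np.testing.assert_allclose(probs, [0.4, 0.6], atol=1e-9)

    def test_identical_states_uniform(self):
        states = [make_state(i, (4.0 * i, 0, 0), np.full(20, 0.05))
                  for i in range(4)]
        np.testing.assert_allclose(initial_probs(states, "G"), 0.25)

    def test_three_state_direct_normalization(self):
        emissions = [0.5, 0.25, 0.25]
        states = []
        for i, e in enumerate(emissions):
            em = np.zeros(20)
            em[0] = e
            em[1] = 1 - e
            states.append(make_state(i, (4.0 * i, 0, 0), em))
        np.testing.assert_allclose(initial_probs(states, "A"),
                                   [0.5, 0.25, 0.25], atol=1e-9)


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_best_score(states, sequence, params):
    """Exhaustive search over all injective residue->state assignments,
    scored by direct evaluation of the model densities."""
    n = len(states)
    aa_idx = [AMINO_CODES[ONE_TO_THREE[ch]] - 1 for ch in sequence]
    first = np.array([s.emission[aa_idx[0]] for s in states])
    init = first / first.sum() if first.sum() > 0 else np.full(n, 1 / n)
    coords = [(s.coord.x, s.coord.y, s.coord.z) for s in states]
    best = -math.inf
    best_path = None
    for perm in itertools.permutations(range(n), len(sequence)):
        score = (math.log(init[perm[0]]) if init[perm[0]] > 0 else -math.inf)
        e0 = states[perm[0]].emission[aa_idx[0]]
        score += math.log(e0) if e0 > 0 else -math.inf
        for t in range(1, len(sequence)):
            d = math.dist(coords[perm[t - 1]], coords[perm[t]])
            if d > params.neighbor_cutoff:
                score = -math.inf
                break
            score += norm.logpdf(d, loc=params.mu, scale=params.transition_sd)
            e = states[perm[t]].emission[aa_idx[t]]
            score += math.log(e) if e > 0 else -math.inf
        if score > best:
            best, best_path = score, perm
    return best, best_path


def random_instance(rng, n_states, box=8.0):
    states = []
    for i in range(n_states):
        emission = rng.dirichlet(np.full(20, 0.5))
        coord = tuple(rng.uniform(0, box, 3))
        states.append(make_state(i, coord, emission))
    return states


class TestViterbi:
    def test_single_state_single_residue(self):
        e = np.zeros(20)
        e[AMINO_CODES["GLY"] - 1] = 0.7
        e[AMINO_CODES["ALA"] - 1] = 0.3
        model = HMMModel(states=[make_state(0, (1, 1, 1), e)],
                         params=HMMParams(beam_width=None))
        backbone = viterbi_thread(model, {"A": "G"})
        assert backbone.state_paths["A"] == [0]
        assert backbone.log_scores["A"] == pytest.approx(math.log(0.7))

    def test_collinear_states_recover_spatial_order(self):
        seq = "AGV"
        positions = [(0.0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)]
        states = [make_state(i, pos, one_hot(AMINO_CODES[ONE_TO_THREE[aa]] - 1,
                                             eps=0.01))
                  for i, (pos, aa) in enumerate(zip(positions, seq))]
        params = HMMParams(beam_width=None)
        model = HMMModel(states=states, params=params)
        backbone = viterbi_thread(model, {"A": seq})
        assert backbone.state_paths["A"] == [0, 1, 2]
        oracle_score, oracle_path = brute_force_best_score(states, seq, params)
        assert list(oracle_path) == [0, 1, 2]
        assert backbone.log_scores["A"] == pytest.approx(oracle_score)

    @pytest.mark.parametrize("seed", range(20))
    def test_unbounded_beam_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        states = random_instance(rng, 6)
        seq = "".join(rng.choice(list(ONE_TO_THREE), 4))
        params = HMMParams(beam_width=None, neighbor_cutoff=1e6)
        model = HMMModel(states=states, params=params)
        backbone = viterbi_thread(model, {"A": seq})
        oracle_score, _ = brute_force_best_score(states, seq, params)
        assert backbone.log_scores["A"] == pytest.approx(oracle_score,
                                                         rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_score_monotone_in_beam_width(self, seed):
        rng = np.random.default_rng(100 + seed)
        states = random_instance(rng, 8)
        seq = "".join(rng.choice(list(ONE_TO_THREE), 5))
        scores = []
        for beam in (None, 20, 5, 1):
            params = HMMParams(beam_width=beam, neighbor_cutoff=1e6)
            model = HMMModel(states=states, params=params)
            backbone = viterbi_thread(model, {"A": seq})
            scores.append(backbone.log_scores["A"])
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_states_never_reused_across_chains(self, rng):
        states = random_instance(rng, 12)
        params = HMMParams(beam_width=None, neighbor_cutoff=1e6)
        model = HMMModel(states=states, params=params)
        backbone = viterbi_thread(model, {"A": "AGV", "B": "LK", "C": "WYFS"})
        used = [s for path in backbone.state_paths.values() for s in path]
        assert len(used) == len(set(used))

    def test_too_few_states_raises_partial_thread(self, rng):
        states = random_instance(rng, 3)
        model = HMMModel(states=states, params=HMMParams(beam_width=None))
        with pytest.raises(PartialThreadError):
            viterbi_thread(model, {"A": "AGVLK"})

    def test_allow_partial_returns_longest_prefix(self):
        # two reachable states, then a 100 Å gap beyond the cutoff
        positions = [(0, 0, 0), (3.8, 0, 0), (100, 0, 0)]
        states = [make_state(i, p, np.full(20, 0.05)) for i, p in
                  enumerate(positions)]
        model = HMMModel(states=states,
                         params=HMMParams(beam_width=None))
        backbone = viterbi_thread(model, {"A": "AGV"}, allow_partial=True)
        assert len(backbone.chains["A"]) == 2

    def test_perfect_one_hot_recovery_30_residues(self, rng):
        """With one-hot emissions at true backbone positions the full
        residue order is recovered."""
        from cryothread.labeling import THREE_TO_ONE
        from cryothread.synthetic import SyntheticConfig, generate_backbone
        structure = generate_backbone(SyntheticConfig(n_residues=30, seed=3))
        residues = structure.chains[0].residues
        sequence = "".join(THREE_TO_ONE[r.name] for r in residues)
        states = [make_state(t, (r.calpha.coord.x, r.calpha.coord.y,
                                 r.calpha.coord.z),
                             one_hot(AMINO_CODES[r.name] - 1))
                  for t, r in enumerate(residues)]
        model = HMMModel(states=states, params=HMMParams(beam_width=50))
        backbone = viterbi_thread(model, {"A": sequence})
        assert backbone.state_paths["A"] == list(range(30))


class TestWriteBackbone:
    def backbone(self):
        bb = BackboneModel()
        bb.chains["A"] = [(1, "ALA", Coordinate(1.0, 2.0, 3.0)),
                          (2, "GLY", Coordinate(4.8, 2.0, 3.0)),
                          (3, "VAL", Coordinate(8.6, 2.0, 3.0))]
        bb.state_paths["A"] = [0, 1, 2]
        return bb

    def test_three_atom_records(self, tmp_path):
        path = tmp_path / "bb.pdb"
        write_backbone(self.backbone(), path)
        lines = [ln for ln in path.read_text().splitlines()
                 if ln.startswith("ATOM")]
        assert len(lines) == 3
        assert all(" CA " in ln for ln in lines)

    def test_round_trip_through_pdb_reader(self, tmp_path):
        path = tmp_path / "bb.pdb"
        bb = self.backbone()
        write_backbone(bb, path)
        back = read_pdb(path)
        coords = [(r.calpha.coord.x, r.calpha.coord.y, r.calpha.coord.z)
                  for r in back.chains[0].residues]
        expected = [(c.x, c.y, c.z) for _, _, c in bb.chains["A"]]
        np.testing.assert_allclose(coords, expected, atol=1e-3)

    def test_two_chains_separated_by_ter(self, tmp_path):
        bb = self.backbone()
        bb.chains["B"] = [(1, "LEU", Coordinate(0.0, 8.0, 8.0)),
                          (2, "LYS", Coordinate(3.8, 8.0, 8.0))]
        path = tmp_path / "two.pdb"
        write_backbone(bb, path)
        text = path.read_text()
        assert text.count("TER") >= 2
        back = read_pdb(path)
        assert sorted(c.chain_id for c in back.chains) == ["A", "B"]

    def test_empty_model_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_backbone(BackboneModel(), tmp_path / "x.pdb")
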