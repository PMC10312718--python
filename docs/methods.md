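# Methods

This note records the models, conventions and numerical choices behind
`cryothread`, and what the synthetic test bed does and does not show.

## Coordinate conventions and labeling

All volumes are held in logical `(i, j, k) = (z, y, x)` order (section,
row, column). MRC files whose `mapc/mapr/maps` header fields permute the
crystallographic axes are de-permuted on read and written back with the
canonical 1,2,3 mapping, so the index formulas below hold for every map
the toolkit touches.

An atom at `(x, y, z)` Å maps to the voxel

```
i = round((z - origin_z) / voxel_z)
j = round((y - origin_y) / voxel_y)
k = round((x - origin_x) / voxel_x)
```

with round-to-nearest, half away from zero. Nearest rounding is the only
rule under which the inverse mapping (voxel-center coordinate
`k·voxel + origin`, etc.) recovers every atom to within half a voxel per
axis, which is the bound the labeling round-trip check enforces.

Label codes: backbone-atom mask Cα = 1, N = 2, carbonyl C = 3; amino-acid
mask 1–20 in alphabetical order of the three-letter codes (ALA = 1 …
VAL = 20), 0 for absence or non-standard residues (e.g. MSE); secondary
structure coil = 1, helix = 2, strand = 3, with untagged residues defaulting
to coil. The alphabetical amino mapping is a fixed, documented choice;
any other published mapping can be substituted via the code table. When
two atoms round to the same voxel the last-written atom wins and the
collision is counted, keeping masks single-valued while making the event
observable. Atoms outside the grid are skipped and counted rather than
treated as errors, since real models routinely extend past the map box.
Secondary structure is taken from HELIX/SHEET annotations of the input
structure file; no geometric reassignment is performed.

## Preprocessing

Resampling uses trilinear interpolation onto a grid of the target voxel
size (default 1 Å) starting at the input origin and covering the input
extent, with zero fill outside the input support. Trilinear interpolation
is the standard volume-resampling default and is exact on linear density
fields, which provides an analytic test oracle. Normalization divides by
the 95th percentile of the strictly positive density values (linear
interpolation between order statistics — the deterministic common
default), then clips below 0 and above 1. Zeros and negatives are
excluded from the percentile pool but still divided and clipped. A map
with no positive voxel is returned as all zeros with a warning rather
than dividing by zero.

## Grid division

Maps are cut into cubes of 32³ voxels overlapping by 6 voxels per face,
i.e. border 6 and stride `core = 32 − 2·6 = 20`; this is the only reading
of the overlap consistent with stitching predictions from 20³ cores. The
grid is zero-padded (normalized maps are ≥ 0 with 0 = background) by the
border on the low side and up to the next core multiple plus border on
the high side, so cube cores partition the padded volume and
divide → stitch is exactly the identity for any grid shape and any valid
(cube, border) pair. Sub-grids and their label cubes are stored together
in one versioned `.npz` archive of named arrays per map.

## MRC validation

The validator runs twelve independent checks per file: format ID string
(`MAP `), machine stamp, mode code (0, 1, 2, 4, 6, 12), positive map
dimensions, positive cell dimensions, axis-mapping permutation, volume-
stack divisibility (spacegroups 401–630), label-count consistency,
`nversion` ∈ {20140, 20141}, extended-header type tag, header statistics
consistent with the data (or marked undetermined by the `dmax < dmin`
convention), and on-disk size against the header-derived expectation.
Files written by the toolkit always recompute statistics, set version and
stamp, and use mode 2 (32-bit real) by default — masks included, stored
with integral values — so everything written passes by construction, and
the statistics check is genuinely exercised.

## The threading HMM

Candidate states are voxels whose predicted Cα probability reaches the
detection threshold (default 0.5); their coordinates are the voxel
centers. For state *s* and amino type *t* the emission is the normalized
geometric mean

```
e_s(t) = sqrt(a_t · b_t) / Σ_u sqrt(a_u · b_u)
```

of the voxel's predicted amino-type probability `a_t` and the background
frequency `b_t`. Background frequencies default to uniform 1/20 and can
be overridden with a frequency table; an all-zero geometric-mean vector
falls back to uniform with a warning. Transitions between states are the
Gaussian density N(µ, (σ·Λ)²) evaluated at their Euclidean distance, with
µ = 3.8047 Å and σ = 0.036 Å — the consecutive Cα–Cα distance law of
protein backbones — and scaling factor Λ = 10, which widens the effective
standard deviation to 0.36 Å so that voxel-quantized positions (each
coordinate off by up to 0.5 Å) are not over-penalized. Transitions are
zero beyond a neighbor cutoff of µ + 10·σ·Λ ≈ 7.4 Å (pruning the graph
while keeping far more than the density's effective support) and for
self-transitions. Transition weights enter the score as unnormalized
log-densities; per-state row normalization over in-cutoff neighbors is
available behind a flag. The initial distribution over states is each
state's emission of the chain's first residue divided by the sum over
states.

### Constrained Viterbi search

The decoding problem differs from standard Viterbi by a global
constraint: each state may be used at most once within and across chains
(one Cα position holds one residue). This makes exact decoding
combinatorial, so the search keeps a beam of partial paths, each carrying
its used-state set, scored by

```
log init(s_1) + log e_{s_1}(aa_1) + Σ_{t≥2} [log T(s_{t−1}, s_t) + log e_{s_t}(aa_t)]
```

With an unbounded beam the search enumerates all feasible injective
paths and is exact; the test suite verifies this equivalence against
brute-force enumeration on 100 random instances. The default beam width
is 50, a controllable accuracy/cost knob. Ties are broken toward the
lexicographically smallest path for determinism; probabilities are
handled in log space with −∞ for zeros. Chains are threaded longest
first (the most constrained chains get first pick of states), and states
consumed by earlier chains are removed. When too few reachable states
remain, the default behavior is a partial-thread error reporting the
longest achievable prefix; `allow_partial=True` keeps that prefix
instead, which is the intended mode for degraded predictions where the
candidate count can drop below the sequence length.

## Evaluation

F1 sweeps compare the Cα probability channel against the 0/1 truth mask
voxel-wise at each threshold, with F1 = 0 by convention when no voxel is
predicted positive. Backbone comparison matches model Cα atoms to
reference Cα atoms greedily, closest pairs first, one-to-one, within a
3 Å cutoff (configurable); matching % is relative to the reference
residue count, sequence identity is computed over matched pairs, and
RMSD is taken over matched pairs without superposition — both structures
live in the same map frame, so superposition would mask systematic
placement error. Greedy matching is deterministic and near-optimal at
backbone densities (≈ 3.8 Å spacing versus a 3 Å cutoff); an
optimal-assignment mode could be added without interface changes.

## Synthetic test bed

The generator emulates exactly the statistical structure the pipeline
assumes, with defaults fixed once: 30 residues, 1 chain, Cα–Cα bonds
drawn from N(3.8047, 0.036) Å, a 3.5 Å self-avoidance radius between
non-consecutive Cα atoms (just under the bond length, so compact folds
remain possible while voxel collisions stay rare at 1 Å sampling),
Gaussian density blobs of width 1 Å (comparable to the voxel size, giving
well-separated peaks at backbone resolution), additive noise of 0.05
density units (a visible but non-dominant perturbation relative to unit
peak height), corruption rate ε = 0, and seed 7. N and C atoms are placed
at fixed fractions (0.35 / 0.65) of the virtual Cα→Cα segment — adequate
for voxel labeling, though not stereochemically exact. The map box is the
structure's bounding box plus a 6 Å margin, so grid division always has
at least one cube. A single global seed drives all draws through named
sub-streams spawned deterministically from it.

Prediction corruption gives each labeled voxel's true class probability
1 − ε with ε spread over the other classes, flips the top class to a
random wrong one with probability ε, and assigns unlabeled voxels
near-one background probability (10⁻³ spread over non-background
classes). At ε = 0 the argmax reproduces the masks exactly, so the
end-to-end recovery test (30 residues, seed 7) demands matching and
sequence identity of 100% with RMSD below the √3/2 ≈ 0.87 Å
voxel-quantization bound.

What the synthetic bed does **not** emulate: experimental noise spectra,
missing or blurred density, resolution anisotropy, map sharpening
artifacts, side-chain density, or realistic secondary-structure geometry
(tags are assigned in fixed runs, not derived from conformation).
Passing tests therefore demonstrate correctness of the algorithms under
the stated model assumptions — not expected accuracy on experimental
maps with learned predictors.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
30-residue single-chain fixtures for end-to-end recovery, ≤ 7-state /
≤ 5-residue instances for exhaustive-search equivalence (the brute-force
oracle enumerates all injective assignments), 10,000 coordinate
round-trip samples, and a few dozen random maps and geometries for the
contract checks. These sizes exercise every code path while keeping the
whole suite in the tens of seconds.

## Known limitations

* Threading assumes candidate states at least equal in number to the
  residues being placed; heavily degraded predictions require
  `allow_partial`.
* The beam search is exact only in the unbounded limit; with the default
  beam of 50 the score is monotone in beam width but global optimality is
  not guaranteed (NP-hard in general under the once-only constraint).
* PDB output carries Cα atoms only; N/C placement from threading and
  full-atom building are out of scope.
* mmCIF input, extended MRC headers, compressed containers and EM image
  stacks are not supported.
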