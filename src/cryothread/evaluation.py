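"""Scoring of voxel-wise Cα predictions and reconstructed backbones.

Voxel predictions are scored with precision/recall/F1 swept over
probability thresholds (F1 is the right summary here: Cα voxels are a tiny
fraction of a map, so accuracy is uninformative).  Reconstructed backbones
are compared to the reference structure in the shared map frame — no
superposition — by greedy one-to-one nearest-neighbor matching of Cα atoms
under a distance cutoff, reporting the matched percentage of reference
residues, the sequence identity over matched pairs, and their RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .hmm_threading import BackboneModel
from .labeling import LabelVolume, Structure

__all__ = ["f1_sweep", "ChainCompareReport", "chain_compare"]


def f1_sweep(pred_calpha: np.ndarray, truth: LabelVolume | np.ndarray,
             thresholds) -> pd.DataFrame:
    """Precision/recall/F1 of the Cα channel against a 0/1 truth mask.

    At each threshold, predicted positives are voxels with probability
    ``>= threshold``.  Columns: threshold, tp, fp, fn, precision, recall,
    f1.  When no voxel is predicted positive, precision is undefined and F1
    is reported as 0 by convention.
    """
    probs = np.asarray(pred_calpha, dtype=np.float64)
    truth_values = np.asarray(
        truth.values if isinstance(truth, LabelVolume) else truth)
    if probs.shape != truth_values.shape:
        raise ValueError(
            f"shape mismatch: predictions {probs.shape} vs truth "
            f"{truth_values.shape}")
    positives = truth_values == 1
    n_pos = int(positives.sum())
    rows = []
    for t in thresholds:
        predicted = probs >= t
        tp = int(np.count_nonzero(predicted & positives))
        fp = int(np.count_nonzero(predicted & ~positives))
        fn = n_pos - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / n_pos if n_pos else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        rows.append({"threshold": float(t), "tp": tp, "fp": fp, "fn": fn,
                     "precision": precision, "recall": recall, "f1": f1})
    return pd.DataFrame(rows)


@dataclass
class ChainCompareReport:
    """Backbone-vs-reference comparison in the shared map frame."""
    n_matched: int
    n_reference: int
    n_model: int
    matching_pct: float        # % of reference residues matched
    sequence_id_pct: float     # % of matched residues with equal amino type
    rmsd: float | None         # Å over matched pairs; None when no matches
    cutoff: float

    def __str__(self) -> str:
        rmsd = "n/a" if self.rmsd is None else f"{self.rmsd:.3f} Å"
        return (f"matched {self.n_matched}/{self.n_reference} reference "
                f"residues ({self.matching_pct:.1f}%), sequence identity "
                f"{self.sequence_id_pct:.1f}%, RMSD {rmsd} "
                f"(cutoff {self.cutoff:.1f} Å)")


def _model_calphas(model: BackboneModel):
    coords, names = [], []
    for residues in model.chains.values():
        for _, resname, coord in residues:
            coords.append((coord.x, coord.y, coord.z))
            names.append(resname)
    return np.asarray(coords, dtype=np.float64), names


def _reference_calphas(reference: Structure):
    coords, names = [], []
    for residue in reference.residues():
        atom = residue.calpha
        if atom is None:
            continue
        coords.append((atom.coord.x, atom.coord.y, atom.coord.z))
        names.append(residue.name)
    return np.asarray(coords, dtype=np.float64), names


def chain_compare(model: BackboneModel, reference: Structure,
                  cutoff: float = 3.0) -> ChainCompareReport:
    """Match model Cα atoms to reference Cα atoms and score the backbone.

    Matching is greedy one-to-one, closest pairs first, restricted to pairs
    within ``cutoff`` Å.  ``matching_pct`` is matched / reference residues,
    ``sequence_id_pct`` the share of matched pairs with equal amino type,
    and ``rmsd`` the root mean squared distance over matched pairs (absent
    when nothing matches).  Both structures are assumed to live in the same
    map coordinate frame; no superposition is performed.
    """
    model_xyz, model_names = _model_calphas(model)
    ref_xyz, ref_names = _reference_calphas(reference)
    if len(model_xyz) == 0 or len(ref_xyz) == 0:
        raise ValueError("both model and reference must contain Cα atoms")

    distances = cdist(model_xyz, ref_xyz)
    candidates = np.argwhere(distances <= cutoff)
    order = np.argsort(distances[candidates[:, 0], candidates[:, 1]],
                       kind="stable")
    used_model: set[int] = set()
    used_ref: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for m, r in candidates[order]:
        if m in used_model or r in used_ref:
            continue
        used_model.add(int(m))
        used_ref.add(int(r))
        pairs.append((int(m), int(r)))

    n_matched = len(pairs)
    if n_matched == 0:
        return ChainCompareReport(0, len(ref_xyz), len(model_xyz),
                                  0.0, 0.0, None, cutoff)
    same_type = sum(model_names[m] == ref_names[r] for m, r in pairs)
    sq = [float(distances[m, r]) ** 2 for m, r in pairs]
    return ChainCompareReport(
        n_matched=n_matched, n_reference=len(ref_xyz), n_model=len(model_xyz),
        matching_pct=100.0 * n_matched / len(ref_xyz),
        sequence_id_pct=100.0 * same_type / n_matched,
        rmsd=float(np.sqrt(np.mean(sq))), cutoff=cutoff)
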