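"""Ensemble superposition and coordinate-precision statistics.

Two conventions are exposed: iterative fit-to-mean r.m.s.d. (the NMR-ensemble
precision statistic) and mean pairwise r.m.s.d. (the crystal-monomer spread
statistic). Superposition is least-squares optimal over proper rotations
(Kabsch, via scipy's align_vectors).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from hbondnmr.structio import Ensemble, Model

BACKBONE_ATOMS = frozenset({"N", "CA", "C"})


class AtomSet(enum.Enum):
    BACKBONE = "backbone"  # N, CA, C (carbonyl O excluded)
    HEAVY = "heavy"  # all non-hydrogen atoms
    SIDECHAIN_HEAVY = "sidechain_heavy"  # heavy atoms outside N/CA/C/O


@dataclass(frozen=True)
class SelectionSpec:
    """Residue window (inclusive, full-length numbering) and atom set."""

    residue_range: tuple[int, int]
    atom_set: AtomSet = AtomSet.BACKBONE

    def __post_init__(self):
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError(f"empty residue range {self.residue_range}")

    def matches(self, atom) -> bool:
        lo, hi = self.residue_range
        if not (lo <= atom.residue_number <= hi):
            return False
        if self.atom_set is AtomSet.BACKBONE:
            return atom.name in BACKBONE_ATOMS
        if self.atom_set is AtomSet.HEAVY:
            return atom.element != "H"
        return atom.element != "H" and atom.name not in ("N", "CA", "C", "O")


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired points (proper rotation only).

    Returns the transform mapping ``mobile`` onto ``reference`` and the
    post-fit r.m.s.d. Degenerate (collinear or fewer than 3) point sets are
    rejected because the rotation is then underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 paired 3D points")
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    mob_c = mobile - mob_center
    ref_c = reference - ref_center
    sing = np.linalg.svd(mob_c, compute_uv=False)
    if sing[1] <= 1e-9 * max(sing[0], 1.0):
        raise ValueError("degenerate (collinear) point set; rotation underdetermined")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    assert np.linalg.det(matrix) > 0, "superposition produced a reflection"
    transformed = mob_c @ matrix.T + ref_center
    rmsd = float(np.sqrt(np.mean(np.sum((transformed - reference) ** 2, axis=1))))
    translation = ref_center - matrix @ mob_center
    return SuperpositionResult(rotation=matrix, translation=translation, rmsd=rmsd)


def _selection_coords(ensemble: Ensemble, selection: SelectionSpec) -> np.ndarray:
    """(n_models, n_atoms, 3) coordinate array over the shared selection."""
    key_lists = []
    for m in ensemble.models:
        keys = sorted(a.key() for a in m.atoms if selection.matches(a))
        if not keys:
            raise ValueError(f"selection empty in model {m.model_id}")
        key_lists.append(keys)
    common = sorted(set.intersection(*(set(k) for k in key_lists)))
    if not common:
        raise ValueError("selection shares no atoms across models")
    coords = np.empty((len(ensemble.models), len(common), 3))
    for i, m in enumerate(ensemble.models):
        index = m.atom_index()
        coords[i] = [index[k].pos for k in common]
    return coords


def ensemble_precision(
    ensemble: Ensemble,
    selection: SelectionSpec,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float, float, list[float]]:
    """Iterative fit-to-mean precision: (mean r.m.s.d., sd, per-model r.m.s.d.).

    All models are superposed on the current mean coordinates, the mean is
    recomputed, and the loop repeats until the mean moves less than ``tol``
    Angstrom. Initialization is deterministic from model 1. The sd is the
    sample standard deviation over models.
    """
    if len(ensemble.models) < 2:
        raise ValueError("ensemble precision needs at least 2 models")
    coords = _selection_coords(ensemble, selection)
    mean = coords[0].copy()
    fitted = coords.copy()
    for _ in range(max_iter):
        for i in range(coords.shape[0]):
            res = superpose(coords[i], mean)
            fitted[i] = res.apply(coords[i])
        new_mean = fitted.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    rmsds = [
        float(np.sqrt(np.mean(np.sum((fitted[i] - mean) ** 2, axis=1))))
        for i in range(coords.shape[0])
    ]
    return float(np.mean(rmsds)), float(np.std(rmsds, ddof=1)), rmsds


def cross_monomer_rmsd(ensemble: Ensemble, selection: SelectionSpec) -> float:
    """Mean pairwise superposed r.m.s.d. over all unordered model pairs."""
    if len(ensemble.models) < 2:
        raise ValueError("pairwise r.m.s.d. needs at least 2 models")
    coords = _selection_coords(ensemble, selection)
    n = coords.shape[0]
    vals = [
        superpose(coords[i], coords[j]).rmsd
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def per_model_rmsd_to_reference(
    ensemble: Ensemble, selection: SelectionSpec, reference: Model
) -> list[float]:
    """R.m.s.d. of each model to a fixed reference over the selection."""
    ref_keys = sorted(a.key() for a in reference.atoms if selection.matches(a))
    ref_index = reference.atom_index()
    out = []
    for m in ensemble.models:
        index = m.atom_index()
        keys = [k for k in ref_keys if k in index]
        if len(keys) < 3:
            raise ValueError(f"model {m.model_id} shares too few atoms with reference")
        mob = np.array([index[k].pos for k in keys])
        ref = np.array([ref_index[k].pos for k in keys])
        out.append(superpose(mob, ref).rmsd)
    return out
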