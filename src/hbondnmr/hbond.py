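"""Geometric backbone hydrogen-bond detection, consensus, and restraint derivation.

Reference crystal monomers lack amide hydrogens, so they are rebuilt in the
peptide plane first. A backbone N-H...O=C contact counts as a hydrogen bond
under conventional geometric criteria (H...O and N...O distance cutoffs plus
a minimum N-H...O angle). Bonds recurring in at least a set fraction of
reference monomers become consensus partners; each CSTC-positive donor with a
consensus acceptor yields one hydrogen bond encoded as two upper and two
lower distance bounds (H-O and N-O), the conventional two-restraints-per-bond
encoding for structure calculation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from hbondnmr.cstc import HBClass
from hbondnmr.structio import (
    Atom,
    DistanceRestraint,
    Ensemble,
    Model,
    RestraintAtom,
)

logger = logging.getLogger(__name__)

N_H_BOND_LENGTH = 1.02  # Angstrom


@dataclass(frozen=True)
class HBGeometry:
    """Geometric acceptance criteria for a backbone N-H...O=C hydrogen bond."""

    max_HO: float = 2.5  # Angstrom
    max_NO: float = 3.5  # Angstrom
    min_NHO_angle: float = 120.0  # degrees

    def __post_init__(self):
        if min(self.max_HO, self.max_NO, self.min_NHO_angle) <= 0:
            raise ValueError("all geometric criteria must be positive")
        if self.max_HO >= self.max_NO:
            raise ValueError("max_HO must be smaller than max_NO")


@dataclass(frozen=True)
class HydrogenBond:
    donor_residue: int
    acceptor_residue: int
    d_NO: float
    d_HO: float
    angle_NHO: float


@dataclass(frozen=True)
class ConsensusHBond:
    """A donor->acceptor pair recurring across reference monomers."""

    donor_residue: int
    acceptor_residue: int
    support: int
    n_monomers: int
    donor_name: str = "XXX"  # 3-letter residue names from the reference models
    acceptor_name: str = "XXX"

    def __post_init__(self):
        if not (1 <= self.support <= self.n_monomers):
            raise ValueError("support must lie in [1, n_monomers]")


@dataclass(frozen=True)
class RestraintDefaults:
    """Distance bounds encoding one hydrogen bond as two restraint pairs."""

    upper_HO: float = 2.0
    lower_HO: float = 1.8
    upper_NO: float = 3.0
    lower_NO: float = 2.7

    def __post_init__(self):
        if not (self.lower_HO < self.upper_HO and self.lower_NO < self.upper_NO):
            raise ValueError("each lower bound must be below its upper bound")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_amide_hydrogens(model: Model, keep_existing: bool = True) -> Model:
    """Rebuild backbone amide hydrogens in the peptide plane.

    H sits 1.02 A from N along the direction opposing the bisector of the
    C(i-1)->N and CA(i)->N bonds, i.e. trans to both, coplanar with
    C(i-1), N, CA. The chain-initial residue and prolines get no amide H;
    residues missing a backbone atom are skipped with a warning.
    """
    index = model.atom_index()
    by_chain: dict[str, list[int]] = {}
    for a in model.atoms:
        if a.name == "N":
            by_chain.setdefault(a.chain_id, []).append(a.residue_number)
    new_atoms = list(model.atoms)
    existing = {a.key() for a in model.atoms}
    for chain_id, resnums in by_chain.items():
        resnums = sorted(set(resnums))
        for resnum in resnums:
            key = (chain_id, resnum, "H")
            if key in existing:
                if keep_existing:
                    continue
                new_atoms = [a for a in new_atoms if a.key() != key]
            n = index.get((chain_id, resnum, "N"))
            ca = index.get((chain_id, resnum, "CA"))
            c_prev = index.get((chain_id, resnum - 1, "C"))
            if n is None or n.residue_name == "PRO":
                continue
            if c_prev is None:  # chain-initial residue: no preceding carbonyl
                continue
            if ca is None:
                logger.warning(
                    "residue %s/%d missing CA; amide H not placed", chain_id, resnum
                )
                continue
            direction = -_unit(_unit(c_prev.pos - n.pos) + _unit(ca.pos - n.pos))
            h_xyz = n.pos + N_H_BOND_LENGTH * direction
            new_atoms.append(
                Atom(
                    name="H",
                    element="H",
                    residue_number=resnum,
                    residue_name=n.residue_name,
                    chain_id=chain_id,
                    xyz=tuple(h_xyz),
                )
            )
    return Model(model_id=model.model_id, atoms=new_atoms)


def detect_hbonds(
    model: Model, geometry: HBGeometry = HBGeometry(), multi_acceptor: bool = False
) -> list[HydrogenBond]:
    """Detect backbone N-H...O=C hydrogen bonds meeting all geometric criteria.

    Donors are backbone amides (H placed beforehand if absent), acceptors
    backbone carbonyl oxygens; pairs closer than two residues apart in the
    same chain are excluded. By default each donor keeps only its closest
    (smallest H...O) acceptor; ``multi_acceptor`` returns all qualifying pairs.
    """
    if not any(a.name == "H" for a in model.atoms):
        model = place_amide_hydrogens(model)
    donors = []  # (chain, resnum, N, H)
    index = model.atom_index()
    for a in model.atoms:
        if a.name == "H":
            n = index.get((a.chain_id, a.residue_number, "N"))
            if n is not None:
                donors.append((a.chain_id, a.residue_number, n, a))
    acceptors = [a for a in model.atoms if a.name == "O"]
    bonds: list[HydrogenBond] = []
    for chain_id, resnum, n_atom, h_atom in donors:
        candidates = []
        for o_atom in acceptors:
            if o_atom.chain_id == chain_id and abs(o_atom.residue_number - resnum) < 2:
                continue
            d_ho = float(np.linalg.norm(o_atom.pos - h_atom.pos))
            if d_ho > geometry.max_HO:
                continue
            d_no = float(np.linalg.norm(o_atom.pos - n_atom.pos))
            if d_no > geometry.max_NO:
                continue
            v1 = n_atom.pos - h_atom.pos
            v2 = o_atom.pos - h_atom.pos
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < geometry.min_NHO_angle:
                continue
            candidates.append(
                HydrogenBond(resnum, o_atom.residue_number, d_no, d_ho, angle)
            )
        if not candidates:
            continue
        if multi_acceptor:
            bonds.extend(sorted(candidates, key=lambda b: b.d_HO))
        else:
            bonds.append(min(candidates, key=lambda b: b.d_HO))
    return sorted(bonds, key=lambda b: (b.donor_residue, b.acceptor_residue))


def consensus_hbonds(
    ensemble: Ensemble,
    geometry: HBGeometry = HBGeometry(),
    min_fraction: float = 0.5,
) -> list[ConsensusHBond]:
    """Tally detected bonds across an ensemble of reference monomers.

    A (donor, acceptor) residue pair is retained iff it appears in at least
    ``min_fraction`` of the monomers. Residue names are taken from the first
    model exhibiting each pair.
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    n = len(ensemble.models)
    tally: Counter[tuple[int, int]] = Counter()
    names: dict[int, str] = {}
    for model in ensemble.models:
        for num, name in model.residue_names().items():
            names.setdefault(num, name)
        for bond in detect_hbonds(model, geometry):
            tally[(bond.donor_residue, bond.acceptor_residue)] += 1
    out = [
        ConsensusHBond(
            donor_residue=d,
            acceptor_residue=a,
            support=count,
            n_monomers=n,
            donor_name=names.get(d, "XXX"),
            acceptor_name=names.get(a, "XXX"),
        )
        for (d, a), count in sorted(tally.items())
        if count / n >= min_fraction
    ]
    return out


def derive_restraints(
    classes: Mapping[int, HBClass],
    consensus: Sequence[ConsensusHBond],
    defaults: RestraintDefaults = RestraintDefaults(),
) -> tuple[list[DistanceRestraint], list[int]]:
    """Pair CSTC-positive donors with consensus acceptors into distance bounds.

    Every residue classed HBONDED that has at least one consensus acceptor
    contributes one hydrogen bond (its best-supported acceptor; ties break to
    the lower acceptor number), encoded as two upper bounds (H-O, N-O) plus
    the two matching lower bounds. Returns (restraints, unmatched) where
    ``unmatched`` lists HBONDED residues without a consensus partner — the gap
    between CSTC-positive and restrainable residues.
    """
    hbonded = sorted(r for r, c in classes.items() if c == HBClass.HBONDED)
    if classes and consensus:
        class_frame = set(classes)
        consensus_frame = {c.donor_residue for c in consensus} | {
            c.acceptor_residue for c in consensus
        }
        if not class_frame & consensus_frame:
            raise ValueError(
                "classification and consensus residue numbering frames are disjoint; "
                "apply an offset map before deriving restraints"
            )
    by_donor: dict[int, list[ConsensusHBond]] = {}
    for c in consensus:
        by_donor.setdefault(c.donor_residue, []).append(c)
    restraints: list[DistanceRestraint] = []
    unmatched: list[int] = []
    for resnum in hbonded:
        options = by_donor.get(resnum)
        if not options:
            unmatched.append(resnum)
            continue
        best = min(options, key=lambda c: (-c.support, c.acceptor_residue))
        donor_h = RestraintAtom(resnum, best.donor_name, "H")
        donor_n = RestraintAtom(resnum, best.donor_name, "N")
        acceptor_o = RestraintAtom(best.acceptor_residue, best.acceptor_name, "O")
        restraints += [
            DistanceRestraint(donor_h, acceptor_o, defaults.upper_HO, "upper"),
            DistanceRestraint(donor_n, acceptor_o, defaults.upper_NO, "upper"),
            DistanceRestraint(donor_h, acceptor_o, defaults.lower_HO, "lower"),
            DistanceRestraint(donor_n, acceptor_o, defaults.lower_NO, "lower"),
        ]
    return restraints, unmatched
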