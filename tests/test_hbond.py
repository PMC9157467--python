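import numpy as np
import pytest

from hbondnmr import hbond
from hbondnmr.cstc import HBClass
from hbondnmr.hbond import ConsensusHBond, HBGeometry, RestraintDefaults
from hbondnmr.structio import Atom, Ensemble, Model
from hbondnmr.synthdata import make_ideal_helix, make_noisy_ensemble

from conftest import make_random_nho_model
from oracles import brute_force_hbonds


class TestPlaceHydrogens:
    def test_every_non_initial_residue_gains_one_h(self, helix12):
        model, _ = helix12
        placed = hbond.place_amide_hydrogens(model)
        assert sum(1 for a in placed.atoms if a.name == "H") == 11

    def test_h_geometry(self, helix12):
        placed = hbond.place_amide_hydrogens(helix12[0])
        idx = placed.atom_index()
        for resnum in range(2, 13):
            n = idx[("A", resnum, "N")].pos
            h = idx[("A", resnum, "H")].pos
            ca = idx[("A", resnum, "CA")].pos
            c_prev = idx[("A", resnum - 1, "C")].pos
            assert np.linalg.norm(h - n) == pytest.approx(1.02, abs=1e-3)
            normal = np.cross(c_prev - n, ca - n)
            normal /= np.linalg.norm(normal)
            assert abs(np.dot(h - n, normal)) < 1e-6  # coplanar with C(i-1), N, CA

    def test_missing_ca_skips_with_warning(self, helix12, caplog):
        model, _ = helix12
        atoms = [a for a in model.atoms if not (a.residue_number == 5 and a.name == "CA")]
        placed = hbond.place_amide_hydrogens(Model(1, atoms))
        assert ("A", 5, "H") not in {a.key() for a in placed.atoms}
        assert any("5" in rec.message for rec in caplog.records)

    def test_prolines_get_no_amide_h(self, helix12):
        model, _ = helix12
        atoms = [
            Atom(a.name, a.element, a.residue_number,
                 "PRO" if a.residue_number == 6 else a.residue_name,
                 a.chain_id, a.xyz)
            for a in model.atoms
        ]
        placed = hbond.place_amide_hydrogens(Model(1, atoms))
        assert ("A", 6, "H") not in {a.key() for a in placed.atoms}


class TestDetect:
    def test_ideal_helix_matches_truth_exactly(self, helix12):
        model, truth = helix12
        bonds = hbond.detect_hbonds(model)
        assert [(b.donor_residue, b.acceptor_residue) for b in bonds] == truth

    def test_distant_residues_no_bonds(self):
        atoms = [
            Atom("N", "N", 1, "ALA", "A", (0, 0, 0)),
            Atom("H", "H", 1, "ALA", "A", (1.02, 0, 0)),
            Atom("O", "O", 3, "ALA", "A", (50, 0, 0)),
        ]
        assert hbond.detect_hbonds(Model(1, atoms)) == []

    @pytest.mark.parametrize("d_ho,expected", [(2.6, 0), (1.9, 1)])
    def test_ho_cutoff_straddle(self, d_ho, expected):
        atoms = [
            Atom("N", "N", 1, "ALA", "A", (0, 0, 0)),
            Atom("H", "H", 1, "ALA", "A", (1.02, 0, 0)),
            Atom("O", "O", 3, "ALA", "A", (1.02 + d_ho, 0, 0)),  # angle 180 deg
        ]
        assert len(hbond.detect_hbonds(Model(1, atoms))) == expected

    def test_adjacent_residues_excluded(self):
        atoms = [
            Atom("N", "N", 1, "ALA", "A", (0, 0, 0)),
            Atom("H", "H", 1, "ALA", "A", (1.02, 0, 0)),
            Atom("O", "O", 2, "ALA", "A", (3.0, 0, 0)),
        ]
        assert hbond.detect_hbonds(Model(1, atoms)) == []

    def test_matches_brute_force_oracle_on_random_structures(self):
        geometry = HBGeometry()
        rng = np.random.default_rng(2024)
        for _ in range(50):
            model = make_random_nho_model(rng)
            oracle = brute_force_hbonds(
                model, geometry.max_HO, geometry.max_NO, geometry.min_NHO_angle
            )
            got = hbond.detect_hbonds(model, geometry, multi_acceptor=True)
            assert {(b.donor_residue, b.acceptor_residue) for b in got} == {
                (d[1], a[1]) for d, a, _ in oracle
            }
            # default mode keeps each donor's closest acceptor
            best = {}
            for d, a, d_ho in oracle:
                if d not in best or d_ho < best[d][1]:
                    best[d] = (a, d_ho)
            single = hbond.detect_hbonds(model, geometry)
            assert {(b.donor_residue, b.acceptor_residue) for b in single} == {
                (d[1], a[1]) for d, (a, _) in best.items()
            }


class TestConsensus:
    def _ensemble_with_broken_bond(self, n_models, n_broken):
        base, truth = make_ideal_helix(12)
        models = []
        for k in range(n_models):
            atoms = []
            for a in base.atoms:
                xyz = a.xyz
                if k < n_broken and a.residue_number == 1 and a.name == "O":
                    xyz = (a.xyz[0] + 50.0, a.xyz[1], a.xyz[2])
                atoms.append(Atom(a.name, a.element, a.residue_number,
                                  a.residue_name, a.chain_id, xyz))
            models.append(Model(k + 1, atoms))
        return Ensemble(models=models), truth

    def test_pair_present_in_all_monomers_retained(self):
        ens, truth = self._ensemble_with_broken_bond(11, 0)
        cons = hbond.consensus_hbonds(ens, min_fraction=0.5)
        pairs = {(c.donor_residue, c.acceptor_residue) for c in cons}
        assert pairs == set(truth)
        assert all(c.support == 11 and c.n_monomers == 11 for c in cons)

    def test_minority_pair_dropped(self):
        ens, _ = self._ensemble_with_broken_bond(11, 6)  # (5, 1) in only 5/11
        cons = hbond.consensus_hbonds(ens, min_fraction=0.5)
        assert (5, 1) not in {(c.donor_residue, c.acceptor_residue) for c in cons}

    def test_consensus_equals_counting_oracle(self):
        base, _ = make_ideal_helix(20)
        ens = make_noisy_ensemble(base, 7, noise_sd=0.15, seed=3)
        tally = {}
        for model in ens.models:
            for b in hbond.detect_hbonds(model):
                key = (b.donor_residue, b.acceptor_residue)
                tally[key] = tally.get(key, 0) + 1
        for min_fraction in (0.25, 0.5, 0.75, 1.0):
            cons = hbond.consensus_hbonds(ens, min_fraction=min_fraction)
            expected = {k for k, v in tally.items() if v / 7 >= min_fraction}
            assert {(c.donor_residue, c.acceptor_residue) for c in cons} == expected

    def test_retained_set_shrinks_as_fraction_rises(self):
        base, _ = make_ideal_helix(20)
        ens = make_noisy_ensemble(base, 7, noise_sd=0.25, seed=5)
        sizes = [
            len(hbond.consensus_hbonds(ens, min_fraction=f))
            for f in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


def consensus_pairs(pairs, support=11, n=11):
    return [
        ConsensusHBond(d, a, support, n, "ALA", "ALA") for d, a in pairs
    ]


class TestDeriveRestraints:
    def test_two_upper_two_lower_per_matched_donor(self):
        classes = {5: HBClass.HBONDED, 6: HBClass.HBONDED, 7: HBClass.HBONDED}
        cons = consensus_pairs([(5, 1), (6, 2)])
        restraints, unmatched = hbond.derive_restraints(classes, cons)
        uppers = [r for r in restraints if r.bound_kind == "upper"]
        lowers = [r for r in restraints if r.bound_kind == "lower"]
        assert len(uppers) == 4 and len(lowers) == 4
        assert unmatched == [7]
        assert all(
            lo.bound < up.bound
            for lo, up in zip(sorted(lowers, key=str), sorted(uppers, key=str))
        )

    def test_no_hbonded_residues_empty(self):
        restraints, unmatched = hbond.derive_restraints(
            {1: HBClass.NOT_HBONDED}, consensus_pairs([(5, 1)])
        )
        assert restraints == [] and unmatched == []

    def test_even_count_and_donor_arithmetic(self):
        classes = {r: HBClass.HBONDED for r in range(5, 57)}  # 52 donors
        cons = consensus_pairs([(r, r - 4) for r in range(5, 61)])
        restraints, unmatched = hbond.derive_restraints(classes, cons)
        uppers = [r for r in restraints if r.bound_kind == "upper"]
        assert len(uppers) == 104
        assert len(restraints) % 2 == 0
        assert len(uppers) // 2 == 52 and unmatched == []

    def test_disjoint_numbering_frames_rejected(self):
        classes = {500: HBClass.HBONDED}
        with pytest.raises(ValueError, match="disjoint"):
            hbond.derive_restraints(classes, consensus_pairs([(5, 1)]))

    def test_best_supported_acceptor_wins(self):
        cons = [
            ConsensusHBond(5, 1, 4, 11, "ALA", "ALA"),
            ConsensusHBond(5, 2, 9, 11, "ALA", "ALA"),
        ]
        restraints, _ = hbond.derive_restraints({5: HBClass.HBONDED}, cons)
        assert {r.acceptor.residue_number for r in restraints} == {2}

    def test_default_bounds_are_consistent(self):
        d = RestraintDefaults()
        assert d.lower_HO < d.upper_HO < d.lower_NO < d.upper_NO


def test_geometry_validation():
    with pytest.raises(ValueError):
        HBGeometry(max_HO=4.0, max_NO=3.5)
    with pytest.raises(ValueError):
        HBGeometry(max_HO=-1.0)
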