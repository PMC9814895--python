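"""RMSD (plain / symmetric / solvent-exposure-modified), CMS, fold splits."""

import numpy as np
import pytest

from hydrascore.pose_eval import (
    contact_mode_score,
    fragment_decompose,
    fragment_sasa,
    label_pose,
    modified_rmsd,
    rmsd,
    sasa,
    split_folds,
)
from hydrascore.structures import AtomRecord, MolecularStructure, BondGraph
from conftest import make_ligand


def _protein(coords, elements=None):
    coords = np.asarray(coords, float)
    elements = elements or ["C"] * len(coords)
    atoms = [AtomRecord(i, elements[i], coords[i]) for i in range(len(coords))]
    return MolecularStructure(atoms, BondGraph(), "protein")


class TestRMSD:
    def test_identical_pose_zero(self, hexagon_ligand):
        assert rmsd(hexagon_ligand, hexagon_ligand) == pytest.approx(0.0)

    def test_hand_case_two_displaced(self):
        ref = make_ligand([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]],
                          bonds=[(0, 1), (1, 2), (2, 3)])
        moved = np.array(ref.coords)
        moved[2] += [0, 2.0, 0]
        moved[3] += [0, 2.0, 0]
        pose = make_ligand(moved, bonds=[(0, 1), (1, 2), (2, 3)])
        assert rmsd(pose, ref, use_symmetry=False) == pytest.approx(np.sqrt(2))

    def test_ring_rotation_symmetry(self, hexagon_ligand):
        # rotate atom positions by one ring position
        coords = hexagon_ligand.coords
        rotated = make_ligand(np.roll(coords, 1, axis=0),
                              bonds=[(i, (i + 1) % 6) for i in range(6)],
                              types=["l_C_aro_hyd"] * 6)
        assert rmsd(rotated, hexagon_ligand, use_symmetry=True) == \
            pytest.approx(0.0, abs=1e-9)
        assert rmsd(rotated, hexagon_ligand, use_symmetry=False) > 0.5

    def test_symmetry_never_worse(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = np.linspace(0, 2 * np.pi, 7)[:-1]
            coords = np.stack([np.cos(theta), np.sin(theta), np.zeros(6)], 1)
            ref = make_ligand(coords, bonds=[(i, (i + 1) % 6) for i in range(6)])
            pose = make_ligand(coords + rng.normal(0, 1, coords.shape),
                               bonds=[(i, (i + 1) % 6) for i in range(6)])
            assert rmsd(pose, ref, True) <= rmsd(pose, ref, False) + 1e-12

    def test_multiple_references_take_minimum(self):
        ref1 = make_ligand([[0, 0, 0], [1.5, 0, 0]], bonds=[(0, 1)])
        ref2 = make_ligand([[5, 0, 0], [6.5, 0, 0]], bonds=[(0, 1)])
        pose = make_ligand([[5, 0, 0], [6.5, 0, 0]], bonds=[(0, 1)])
        assert rmsd(pose, [ref1, ref2]) == pytest.approx(0.0)

    def test_composition_mismatch_rejected(self):
        a = make_ligand([[0, 0, 0], [1.5, 0, 0]], ["C", "O"], [(0, 1)])
        b = make_ligand([[0, 0, 0], [1.5, 0, 0]], ["C", "N"], [(0, 1)])
        with pytest.raises(ValueError, match="composition"):
            rmsd(a, b)


class TestFragments:
    def test_biphenyl_like_two_fragments(self):
        theta = np.linspace(0, 2 * np.pi, 7)[:-1]
        ring1 = np.stack([1.4 * np.cos(theta), 1.4 * np.sin(theta),
                          np.zeros(6)], 1)
        ring2 = ring1 + [5.0, 0, 0]
        coords = np.vstack([ring1, ring2])
        bonds = [(i, (i + 1) % 6) for i in range(6)]
        bonds += [(6 + i, 6 + (i + 1) % 6) for i in range(6)]
        bonds += [(0, 6)]  # the biphenyl bridge
        lig = make_ligand(coords, bonds=bonds)
        assert len(fragment_decompose(lig)) == 2

    def test_single_ring_one_fragment(self, hexagon_ligand):
        assert len(fragment_decompose(hexagon_ligand)) == 1

    def test_terminal_bond_not_cut(self):
        lig = make_ligand([[0, 0, 0], [1.5, 0, 0]], bonds=[(0, 1)])
        assert len(fragment_decompose(lig)) == 1

    def test_double_bond_not_cut(self):
        # three atoms in a row; 0-1 double (kept), 1-2 single but terminal
        lig = make_ligand([[0, 0, 0], [1.3, 0, 0], [2.8, 0, 0], [4.3, 0, 0]],
                          bonds=[(0, 1), (1, 2), (2, 3)],
                          orders=[2.0, 1.0, 1.0])
        # only the 1-2 bond is acyclic+single+non-terminal
        assert len(fragment_decompose(lig)) == 2


class TestSASA:
    def test_isolated_atom_closed_form(self):
        a = AtomRecord(0, "C", (0, 0, 0), vdw_radius=1.9)
        area = sasa([a])[0]
        assert area == pytest.approx(4 * np.pi * (1.9 + 1.4) ** 2, rel=0.01)

    def test_buried_atom_near_zero(self):
        a = AtomRecord(0, "C", (0, 0, 0), vdw_radius=1.7)
        shell = [
            AtomRecord(i + 1, "C", 3.0 * p, vdw_radius=1.9)
            for i, p in enumerate(_sphere_points(60))
        ]
        assert sasa([a], shell)[0] == pytest.approx(0.0, abs=1.0)

    def test_deterministic(self):
        atoms = [AtomRecord(0, "C", (0, 0, 0)), AtomRecord(1, "O", (2.0, 0, 0))]
        np.testing.assert_array_equal(sasa(atoms), sasa(atoms))

    def test_occlusion_reduces_area(self):
        a = AtomRecord(0, "C", (0, 0, 0))
        b = AtomRecord(1, "C", (2.5, 0, 0))
        together = sasa([a, b]).sum()
        apart = sasa([a])[0] + sasa([b])[0]
        assert together < apart


def _sphere_points(n):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], 1)


def _buried_exposed_system():
    """4-atom chain: atoms 0,1 buried in a protein cage, atoms 2,3 exposed."""
    ref = make_ligand([[0, 0, 0], [1.5, 0, 0], [4.0, 0, 0], [5.5, 0, 0]],
                      bonds=[(0, 1), (1, 2), (2, 3)])
    mid = np.array([0.75, 0, 0])
    cage = [mid + 3.4 * p for p in _sphere_points(80)
            if np.linalg.norm(mid + 3.4 * p - [4.0, 0, 0]) > 2.8
            and np.linalg.norm(mid + 3.4 * p - [5.5, 0, 0]) > 2.8]
    # close the cage around the buried pair only
    protein = _protein(cage)
    return ref, protein


class TestModifiedRMSD:
    def test_identical_pose_zero(self):
        ref, protein = _buried_exposed_system()
        assert modified_rmsd(ref, ref, protein) == pytest.approx(0.0)

    def test_exposed_fragment_excluded(self):
        ref, protein = _buried_exposed_system()
        decomp = fragment_sasa(ref, protein)
        assert len(decomp.fragments) == 2
        assert list(decomp.excluded) == [False, True]
        moved = np.array(ref.coords)
        moved[2] += [0, 2.0, 0]
        moved[3] += [0, 2.0, 0]
        pose = make_ligand(moved, bonds=[(0, 1), (1, 2), (2, 3)])
        assert rmsd(pose, ref, use_symmetry=False) == pytest.approx(np.sqrt(2))
        assert modified_rmsd(pose, ref, protein) == pytest.approx(0.0)

    def test_fully_exposed_falls_back_with_warning(self):
        ref = make_ligand([[0, 0, 0], [1.5, 0, 0]], bonds=[(0, 1)])
        protein = _protein([[20.0, 0, 0]])
        pose = make_ligand([[0, 1.0, 0], [1.5, 1.0, 0]], bonds=[(0, 1)])
        with pytest.warns(UserWarning, match="solvent exposed"):
            m = modified_rmsd(pose, ref, protein)
        assert m == pytest.approx(1.0)


class TestCMS:
    def test_identical_pose_one(self):
        ref = make_ligand([[0, 0, 0], [1.5, 0, 0]], bonds=[(0, 1)])
        protein = _protein([[3.0, 0, 0]])
        assert contact_mode_score(ref, ref, protein) == pytest.approx(1.0)

    def test_disjoint_contacts_zero(self):
        protein = _protein([[0, 0, 0]])
        ref = make_ligand([[3.0, 0, 0]], bonds=None)
        pose = make_ligand([[30.0, 0, 0]], bonds=None)
        # pose has no contacts, ref has one -> Tanimoto 0
        assert contact_mode_score(pose, ref, protein) == pytest.approx(0.0)

    def test_hand_half(self):
        protein = _protein([[0, 0, 0]])
        ref = make_ligand([[3.0, 0, 0], [8.0, 0, 0]], bonds=[(0, 1)])
        pose = make_ligand([[3.0, 0, 0], [4.0, 0, 0]], bonds=[(0, 1)])
        # pose contacts {(p,l0),(p,l1)}, ref contacts {(p,l0)}
        assert contact_mode_score(pose, ref, protein) == pytest.approx(0.5)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        protein = _protein(rng.uniform(-4, 4, (10, 3)))
        a = make_ligand(rng.uniform(-3, 3, (4, 3)), bonds=[(0, 1), (1, 2), (2, 3)])
        b = make_ligand(rng.uniform(-3, 3, (4, 3)), bonds=[(0, 1), (1, 2), (2, 3)])
        assert contact_mode_score(a, b, protein) == pytest.approx(
            contact_mode_score(b, a, protein))

    def test_both_empty_is_one(self):
        protein = _protein([[50.0, 0, 0]])
        a = make_ligand([[0.0, 0, 0]])
        assert contact_mode_score(a, a, protein) == pytest.approx(1.0)


class TestLabels:
    @pytest.mark.parametrize("value,native", [(1.9, True), (2.0, False),
                                              (7.3, False)])
    def test_strict_two_angstrom_threshold(self, value, native):
        assert label_pose(value) is native


class TestSplitFolds:
    def _matrices(self, n, links):
        seq = np.ones((n, n))
        sim = np.zeros((n, n))
        for i, j in links:
            seq[i, j] = seq[j, i] = 0.1  # linked via sequence
        np.fill_diagonal(seq, 0.0)
        return seq, sim

    def test_two_pairs_balanced(self):
        seq, sim = self._matrices(6, [(0, 1), (2, 3)])
        folds = split_folds(seq, sim, 3)
        sizes = np.bincount(folds, minlength=3)
        assert sorted(sizes) == [2, 2, 2]
        assert folds[0] == folds[1] and folds[2] == folds[3]

    def test_nine_singletons_round_robin(self):
        seq, sim = self._matrices(9, [])
        folds = split_folds(seq, sim, 3)
        assert sorted(np.bincount(folds, minlength=3)) == [3, 3, 3]

    def test_large_group_imbalance_warned(self):
        links = [(i, i + 1) for i in range(4)]  # 5-chain + 1 singleton
        seq, sim = self._matrices(6, links)
        with pytest.warns(UserWarning, match="imbalance"):
            folds = split_folds(seq, sim, 3)
        assert sorted(np.bincount(folds, minlength=3)) == [0, 1, 5]

    def test_no_cross_fold_linked_pairs_random(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 20
            seq = rng.uniform(0, 1, (n, n))
            seq = (seq + seq.T) / 2
            sim = rng.uniform(0.5, 1.0, (n, n))
            sim = (sim + sim.T) / 2
            folds = split_folds(seq, sim, 3)
            linked = (seq < 0.5) | (sim > 0.9)
            np.fill_diagonal(linked, False)
            for i, j in zip(*np.where(linked)):
                assert folds[i] == folds[j]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            split_folds(np.ones((3, 3)), np.ones((4, 4)))
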