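"""Hand-computable metric scenarios used by the acceptance script."""

import numpy as np

from hydrascore.structures import AtomRecord, BondGraph, MolecularStructure


def _ligand(coords, bonds):
    atoms = [AtomRecord(i, "C", c) for i, c in enumerate(np.asarray(coords, float))]
    return MolecularStructure(atoms, BondGraph.from_pairs(bonds, len(atoms)),
                              "ligand")


def _protein(coords):
    atoms = [AtomRecord(i, "C", c) for i, c in enumerate(np.asarray(coords, float))]
    return MolecularStructure(atoms, BondGraph(), "protein")


def _sphere_points(n):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], 1)


def buried_exposed_system():
    """4-atom chain: atoms 0,1 buried in a cage (kept by the SASA rule),
    atoms 2,3 exposed (excluded) and displaced by 2 A in the pose.

    Standard RMSD sqrt(2); modified RMSD 0.
    """
    bonds = [(0, 1), (1, 2), (2, 3)]
    ref = _ligand([[0, 0, 0], [1.5, 0, 0], [4.0, 0, 0], [5.5, 0, 0]], bonds)
    mid = np.array([0.75, 0, 0])
    cage = [mid + 3.4 * p for p in _sphere_points(80)
            if np.linalg.norm(mid + 3.4 * p - [4.0, 0, 0]) > 2.8
            and np.linalg.norm(mid + 3.4 * p - [5.5, 0, 0]) > 2.8]
    moved = np.array(ref.coords)
    moved[2] += [0, 2.0, 0]
    moved[3] += [0, 2.0, 0]
    pose = _ligand(moved, bonds)
    return ref, _protein(cage), pose


def hand_cms_system():
    """One protein atom; reference makes 1 contact, pose makes 2 sharing
    one: Tanimoto contact similarity 1/2."""
    protein = _protein([[0, 0, 0]])
    ref = _ligand([[3.0, 0, 0], [8.0, 0, 0]], [(0, 1)])
    pose = _ligand([[3.0, 0, 0], [4.0, 0, 0]], [(0, 1)])
    return protein, ref, pose
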