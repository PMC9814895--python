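"""Shared fixtures: toy structures and file snippets, built in memory."""

import numpy as np
import pytest

from hydrascore.grids import GridSpec
from hydrascore.structures import (
    AtomRecord,
    BondGraph,
    LigandPose,
    MolecularStructure,
)


def _pdb_line(i, name, resname, chain, resid, xyz, element):
    return (
        f"ATOM  {i:>5} {name:<4} {resname:<3} {chain}{resid:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
        f"{element:>2}"
    )


@pytest.fixture
def water_pdb_text():
    return _pdb_line(1, "O", "HOH", "A", 1, (1.0, 2.0, 3.0), "O") + "\nEND\n"


@pytest.fixture
def two_chain_pdb_text():
    lines = []
    n = 0
    for chain in "AB":
        for k in range(5):
            n += 1
            elem = "N" if k == 0 else "C"
            lines.append(
                _pdb_line(n, elem, "ALA", chain, k + 1,
                          (float(n), 0.0, 0.0), elem)
            )
    return "\n".join(lines) + "\nEND\n"


@pytest.fixture
def bad_element_pdb_text():
    good = _pdb_line(1, "C", "LIG", "A", 1, (0.0, 0.0, 0.0), "C")
    bad = _pdb_line(2, "ZZ", "LIG", "A", 1, (1.0, 0.0, 0.0), "ZZ")
    return good + "\n" + bad + "\n"


def make_ligand(coords, elements=None, bonds=None, types=None,
                orders=None) -> MolecularStructure:
    coords = np.asarray(coords, float)
    n = len(coords)
    elements = elements or ["C"] * n
    atoms = [
        AtomRecord(i, elements[i], coords[i],
                   atom_type=(types[i] if types else None))
        for i in range(n)
    ]
    bg = (BondGraph.from_pairs(bonds, n, orders) if bonds else BondGraph())
    return MolecularStructure(atoms, bg, "ligand")


@pytest.fixture
def small_grid():
    return GridSpec(center=(0.0, 0.0, 0.0), extent=4.0, spacing=1.0)


@pytest.fixture
def hexagon_ligand():
    """Benzene-like ring: 6 identical carbons, 6 ring bonds."""
    theta = np.linspace(0, 2 * np.pi, 7)[:-1]
    coords = np.stack([1.4 * np.cos(theta), 1.4 * np.sin(theta),
                       np.zeros(6)], axis=1)
    bonds = [(i, (i + 1) % 6) for i in range(6)]
    return make_ligand(coords, bonds=bonds,
                       types=["l_C_aro_hyd"] * 6)


def sdf_block(coords, bonds, name="mol"):
    """Minimal V2000 molecule block."""
    lines = [name, "  synthetic", ""]
    lines.append(f"{len(coords):>3}{len(bonds):>3}  0  0  0  0  0  0  0  0999 V2000")
    for c in coords:
        lines.append(f"{c[0]:>10.4f}{c[1]:>10.4f}{c[2]:>10.4f} C   0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j in bonds:
        lines.append(f"{i + 1:>3}{j + 1:>3}  1  0")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"
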