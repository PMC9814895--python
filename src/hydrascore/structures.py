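"""Molecular structures: parsing, bond graphs, and atom typing.

Proteins arrive as PDB text, ligand pose sets as SDF V2000 (with a MOL2
MOLECULE/ATOM/BOND subset reader), and everything is normalized into
:class:`MolecularStructure` — an ordered list of typed atoms plus a bond
graph — which is what featurization and the pose metrics consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import atom_types as at

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "H2O"})


class ParseError(ValueError):
    """Malformed structure input."""


@dataclass
class AtomRecord:
    """One atom: element, coordinates (A), vdW radius R_i, charge, type."""

    index: int
    element: str
    coords: np.ndarray
    vdw_radius: float = 0.0
    partial_charge: float = 0.0
    atom_type: str | None = None
    name: str = ""
    resname: str = ""
    resid: int = 0
    chain: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        if self.vdw_radius == 0.0:
            self.vdw_radius = at.vdw_radius(self.element)
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.index}: vdw_radius must be > 0")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class BondGraph:
    """Undirected bond graph over atom indices with per-edge ring flags.

    ``orders`` optionally carries bond orders (1.0 when unknown); ring flags
    are always recomputed from cycle structure (an edge is in a ring iff it
    is not a bridge).
    """

    edges: frozenset = frozenset()
    ring_membership: dict = field(default_factory=dict)
    orders: dict = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs, n_atoms: int, orders=None) -> "BondGraph":
        edges = set()
        order_map = {}
        for k, (i, j) in enumerate(pairs):
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n_atoms and 0 <= j < n_atoms):
                raise ValueError(f"bond ({i},{j}) outside atom range 0..{n_atoms - 1}")
            e = frozenset((i, j))
            edges.add(e)
            order_map[e] = float(orders[k]) if orders is not None else 1.0
        g = nx.Graph(tuple(e) for e in edges)
        bridges = {frozenset(b) for b in nx.bridges(g)} if g.number_of_edges() else set()
        ring = {e: e not in bridges for e in edges}
        return cls(frozenset(edges), ring, order_map)

    def neighbors(self, n_atoms: int) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(n_atoms)]
        for e in self.edges:
            i, j = tuple(e)
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [sorted(v) for v in nbrs]

    def atom_in_ring(self, i: int) -> bool:
        return any(i in e and self.ring_membership[e] for e in self.edges)


@dataclass
class MolecularStructure:
    atoms: list
    bonds: BondGraph = field(default_factory=BondGraph)
    role: str = "protein"  # protein | ligand | water

    def __post_init__(self):
        n = len(self.atoms)
        for e in self.bonds.edges:
            i, j = tuple(e)
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond endpoint {max(i, j)} out of range")

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms])

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    @property
    def has_explicit_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        coords = np.asarray(coords, float)
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return MolecularStructure(atoms, self.bonds, self.role)


@dataclass
class LigandPose:
    structure: MolecularStructure
    pose_id: str = ""
    source: str = "docked"  # docked | native | reference

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords


# ---------------------------------------------------------------------------
# PDB

def _pdb_element(line: str, lineno: int) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if not elem:
        # atom-name heuristic: first alphabetic character(s) of the name field
        name = line[12:16].strip()
        stripped = name.lstrip("0123456789")
        if len(stripped) >= 2 and stripped[:2].capitalize() in at.SUPPORTED_ELEMENTS:
            elem = stripped[:2]
        elif stripped:
            elem = stripped[0]
        else:
            raise ParseError(f"line {lineno}: cannot infer element from {name!r}")
    elem = elem.capitalize() if len(elem) > 1 else elem.upper()
    if elem not in at.SUPPORTED_ELEMENTS:
        raise ParseError(f"line {lineno}: unknown element {elem!r}")
    return elem


def parse_structure(text: str, role: str = "protein") -> MolecularStructure:
    """Parse PDB-format text into a structure, preserving file atom order.

    Waters remain separable afterwards via :func:`split_waters` (residue
    names HOH/WAT/...). Raises :class:`ParseError` on empty input or on a
    record whose element cannot be resolved, naming the offending line.
    """
    atoms = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: bad coordinates") from exc
        elem = _pdb_element(line, lineno)
        resid_s = line[22:26].strip()
        atoms.append(
            AtomRecord(
                index=len(atoms),
                element=elem,
                coords=(x, y, z),
                name=line[12:16].strip(),
                resname=line[17:20].strip(),
                resid=int(resid_s) if resid_s else 0,
                chain=line[21:22].strip(),
            )
        )
    if not atoms:
        raise ParseError("no ATOM/HETATM records in input")
    return MolecularStructure(atoms, BondGraph(), role)


def split_waters(structure: MolecularStructure):
    """Split into (non-water structure, water structure) by residue name."""
    dry, wet = [], []
    for a in structure.atoms:
        (wet if a.resname in WATER_RESNAMES else dry).append(a)

    def rebuild(atom_list, role):
        return MolecularStructure(
            [replace(a, index=i) for i, a in enumerate(atom_list)], BondGraph(), role
        )

    return rebuild(dry, structure.role), rebuild(wet, "water")


def write_pdb(structure: MolecularStructure) -> str:
    lines = []
    for a in structure.atoms:
        rec = "HETATM" if structure.role in ("ligand", "water") else "ATOM"
        lines.append(
            f"{rec:<6}{a.index + 1:>5} {a.name[:4]:<4} {a.resname[:3]:<3} "
            f"{(a.chain or 'A')[:1]}{a.resid:>4}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SDF via RDKit

def _mol_to_structure(mol, conf_id: int = -1) -> MolecularStructure:
    conf = mol.GetConformer(conf_id)
    atoms = []
    for i, a in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        elem = a.GetSymbol()
        if elem not in at.SUPPORTED_ELEMENTS:
            warnings.warn(f"element {elem!r} outside vocabulary; typed as generic")
        atoms.append(
            AtomRecord(
                index=i,
                element=elem,
                coords=(pos.x, pos.y, pos.z),
                partial_charge=float(a.GetDoubleProp("_charge"))
                if a.HasProp("_charge")
                else 0.0,
                vdw_radius=at.vdw_radius(elem),
            )
        )
    pairs, orders = [], []
    for b in mol.GetBonds():
        pairs.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        orders.append(b.GetBondTypeAsDouble() or 1.0)
    bonds = BondGraph.from_pairs(pairs, len(atoms), orders)
    return MolecularStructure(atoms, bonds, "ligand")


def parse_ligand_poses(text: str) -> list[LigandPose]:
    """Parse an SDF into a pose set; all blocks must share one topology.

    One pose per molecule block, bonds from the bond block. Raises
    :class:`ParseError` for a malformed block or inconsistent atom counts
    across blocks.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=False, removeHs=False)
    poses: list[LigandPose] = []
    signature = None
    for k, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"malformed SDF molecule block #{k + 1}")
        s = _mol_to_structure(mol)
        sig = (len(s.atoms), tuple(a.element for a in s.atoms))
        if signature is None:
            signature = sig
        elif sig != signature:
            raise ParseError(
                f"SDF block #{k + 1}: atom count/ordering differs from first block "
                f"({sig[0]} vs {signature[0]} atoms)"
            )
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        poses.append(LigandPose(s, pose_id=name or f"pose_{k}"))
    if not poses:
        raise ParseError("no molecule blocks in SDF input")
    return poses


def write_sdf(poses: list[LigandPose]) -> str:
    """Serialize a pose set to SDF V2000 (coordinates + bond block)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    out = []
    for pose in poses:
        s = pose.structure
        rw = Chem.RWMol()
        for a in s.atoms:
            rw.AddAtom(Chem.Atom(a.element))
        for e in s.bonds.edges:
            i, j = sorted(e)
            order = s.bonds.orders.get(e, 1.0)
            bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                  3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}.get(
                      order, Chem.BondType.SINGLE)
            rw.AddBond(i, j, bt)
        conf = Chem.Conformer(len(s.atoms))
        for i, a in enumerate(s.atoms):
            conf.SetAtomPosition(i, Point3D(*map(float, a.coords)))
        mol = rw.GetMol()
        mol.AddConformer(conf)
        mol.SetProp("_Name", pose.pose_id)
        out.append(Chem.MolToMolBlock(mol, kekulize=False) + "$$$$\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# MOL2 subset (MOLECULE/ATOM/BOND record types only)

def parse_mol2(text: str) -> MolecularStructure:
    """Read the MOLECULE/ATOM/BOND subset of MOL2; other records are skipped
    with a warning. Partial charges are taken from the ATOM records."""
    section = None
    atoms, pairs, orders = [], [], []
    skipped: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            if section not in ("MOLECULE", "ATOM", "BOND"):
                skipped.add(section)
            continue
        if not line or line.startswith("#"):
            continue
        if section == "ATOM":
            f = line.split()
            elem = f[5].split(".")[0].capitalize()
            atoms.append(
                AtomRecord(
                    index=len(atoms),
                    element=elem if elem in at.SUPPORTED_ELEMENTS else elem,
                    coords=(float(f[2]), float(f[3]), float(f[4])),
                    name=f[1],
                    partial_charge=float(f[8]) if len(f) > 8 else 0.0,
                )
            )
        elif section == "BOND":
            f = line.split()
            pairs.append((int(f[1]) - 1, int(f[2]) - 1))
            orders.append({"1": 1.0, "2": 2.0, "3": 3.0, "ar": 1.5, "am": 1.0}
                          .get(f[3], 1.0))
    if skipped:
        warnings.warn(f"MOL2 record types ignored: {sorted(skipped)}")
    if not atoms:
        raise ParseError("no ATOM records in MOL2 input")
    return MolecularStructure(atoms, BondGraph.from_pairs(pairs, len(atoms), orders),
                              "ligand")


# ---------------------------------------------------------------------------
# bonds + typing

def infer_bonds(structure: MolecularStructure, tolerance: float = 0.45) -> BondGraph:
    """Distance-based bond perception: i-j bonded when
    d(i,j) <= r_cov(i) + r_cov(j) + tolerance. Used for proteins, where PDB
    input has no bond block."""
    coords = structure.coords
    if len(coords) < 2:
        return BondGraph()
    radii = np.array([at.COVALENT_RADII.get(a.element, 1.4) for a in structure.atoms])
    tree = cKDTree(coords)
    pairs = []
    for i, j in tree.query_pairs(r=2 * radii.max() + tolerance):
        if np.linalg.norm(coords[i] - coords[j]) <= radii[i] + radii[j] + tolerance:
            pairs.append((i, j))
    return BondGraph.from_pairs(pairs, len(coords))


def assign_atom_types(structure: MolecularStructure, role: str | None = None
                      ) -> MolecularStructure:
    """Assign exactly one vocabulary key to every heavy atom.

    Ligands must carry a bond graph (from the SDF/MOL2 bond block); proteins
    without bonds get distance-inferred ones. Hydrogens stay untyped. Elements
    outside the table land in the generic metal/other bucket with a warning.
    """
    role = role or structure.role
    if role not in ("protein", "ligand"):
        raise ValueError(f"cannot type role {role!r}")
    bonds = structure.bonds
    n = len(structure.atoms)
    if not bonds.edges and n > 1:
        if role == "ligand":
            raise ValueError("ligand typing requires a bond graph")
        bonds = infer_bonds(structure)
    nbrs = bonds.neighbors(n)
    explicit_h = structure.has_explicit_hydrogens

    def is_carbonyl_like(i: int) -> bool:
        # oxygen double-bonded to C/S/P, or (when orders are unknown) a
        # terminal oxygen whose carbon also binds another N/O
        # (carbonyl / amide / carboxyl(ate) / phosphate-like)
        for j in nbrs[i]:
            if bonds.orders.get(frozenset((i, j)), 1.0) >= 2.0:
                return True
            a = structure.atoms[j]
            if a.element in ("C", "S", "P"):
                for k in nbrs[j]:
                    ak = structure.atoms[k]
                    if k != i and ak.is_heavy and ak.element in ("O", "N"):
                        return True
        return False

    def is_amide_nitrogen(i: int) -> bool:
        for j in nbrs[i]:
            if structure.atoms[j].element == "C":
                for k in nbrs[j]:
                    ak = structure.atoms[k]
                    if ak.element == "O" and k != i and len(
                        [m for m in nbrs[k] if structure.atoms[m].is_heavy]
                    ) == 1 and not bonds.ring_membership.get(frozenset((j, k)), False):
                        return True
        return False

    typed = []
    for i, a in enumerate(structure.atoms):
        if not a.is_heavy:
            typed.append(replace(a))
            continue
        if a.element not in at.SUPPORTED_ELEMENTS:
            warnings.warn(
                f"atom {i} ({a.element!r}) outside the type vocabulary; "
                "assigned to the generic metal/other type"
            )
        key = at.type_atom(
            a.element,
            role,
            in_ring=bonds.atom_in_ring(i),
            neighbor_elements=tuple(structure.atoms[j].element for j in nbrs[i]),
            n_hydrogens=sum(
                1 for j in nbrs[i] if structure.atoms[j].element == "H"
            ),
            is_amide_n=a.element == "N" and is_amide_nitrogen(i),
            is_carbonyl_o=a.element == "O" and is_carbonyl_like(i),
            hydrogens_explicit=explicit_h,
        )
        typed.append(replace(a, atom_type=key))
    return MolecularStructure(typed, bonds, role)
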