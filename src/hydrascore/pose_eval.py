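"""Pose-quality metrics, labeling, and similarity-balanced fold splitting.

All RMSDs are computed in the shared docking frame (no re-superposition:
poses and references sit in the same receptor coordinates); the
symmetry-aware variant minimizes over bond-graph automorphisms so that,
e.g., a benzene ring rotated by one position scores 0. The
solvent-exposure-modified RMSD drops reference-pose fragments whose
bound/unbound SASA ratio exceeds 0.25 before averaging — solvent-exposed
tails in alternative positions should not fail a pose. The contact mode
score (CMS) is the Tanimoto similarity of the protein-ligand heavy-atom
contact sets (4.5 A cutoff) of pose and reference, in [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structures import LigandPose, MolecularStructure

NATIVE_RMSD_THRESHOLD = 2.0  # A, strict
CONTACT_CUTOFF = 4.5  # A
SASA_RATIO_CUTOFF = 0.25
SASA_PROBE = 1.4  # A
SASA_POINTS = 960
AUTOMORPHISM_CAP = 10_000


@dataclass
class FragmentDecomposition:
    fragments: list  # list of atom-index lists (heavy atoms)
    sasa_bound: np.ndarray
    sasa_unbound: np.ndarray
    sasa_ratio: np.ndarray
    excluded: np.ndarray  # bool per fragment


@dataclass
class ContactMap:
    contacts: frozenset  # {(protein heavy index, ligand heavy index)}
    cutoff: float = CONTACT_CUTOFF


@dataclass
class EvaluationResult:
    pose_id: str
    rmsd: float
    modified_rmsd: float
    cms: float
    is_native: bool
    references_used: int = 1


def _as_structure(pose) -> MolecularStructure:
    return pose.structure if isinstance(pose, LigandPose) else pose


def _heavy_graph(structure: MolecularStructure):
    heavy = structure.heavy_indices
    remap = {int(i): k for k, i in enumerate(heavy)}
    g = nx.Graph()
    for k, i in enumerate(heavy):
        g.add_node(k, element=structure.atoms[int(i)].element)
    for e in structure.bonds.edges:
        i, j = tuple(e)
        if i in remap and j in remap:
            g.add_edge(remap[i], remap[j])
    return g, heavy


def _automorphisms(structure: MolecularStructure, cap: int = AUTOMORPHISM_CAP):
    """Element-preserving bond-graph automorphisms over heavy atoms, as
    permutations of the heavy-atom subindex; capped (fallback: identity)."""
    g, heavy = _heavy_graph(structure)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"]
    )
    perms = []
    for mapping in gm.isomorphisms_iter():
        perms.append(np.array([mapping[k] for k in range(len(heavy))]))
        if len(perms) > cap:
            warnings.warn(
                f"more than {cap} automorphisms; falling back to identity"
            )
            return [np.arange(len(heavy))]
    return perms or [np.arange(len(heavy))]


def rmsd(pose, references, use_symmetry: bool = True) -> float:
    """Heavy-atom RMSD (A), minimum over references and (optionally) over
    bond-graph automorphisms; no superposition."""
    ps = _as_structure(pose)
    refs = references if isinstance(references, (list, tuple)) else [references]
    heavy = ps.heavy_indices
    coords = ps.coords[heavy]
    perms = _automorphisms(ps) if use_symmetry else [np.arange(len(heavy))]
    best = np.inf
    for ref in refs:
        rs = _as_structure(ref)
        rheavy = rs.heavy_indices
        if len(rheavy) != len(heavy) or any(
            ps.atoms[int(i)].element != rs.atoms[int(j)].element
            for i, j in zip(heavy, rheavy)
        ):
            raise ValueError("pose and reference heavy-atom compositions differ")
        ref_coords = rs.coords[rheavy]
        for perm in perms:
            d = coords[perm] - ref_coords
            best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return best


def _rmsd_subset(pose_coords, ref_coords, idx) -> float:
    d = pose_coords[idx] - ref_coords[idx]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


# ---------------------------------------------------------------------------
# fragments and SASA

def fragment_decompose(ligand) -> list:
    """Split the ligand into rigid fragments: cut every acyclic single bond
    between two non-terminal heavy atoms; the connected components of the
    cut graph are the fragments (heavy-atom index lists)."""
    s = _as_structure(ligand)
    g, heavy = _heavy_graph(s)
    heavy_degree = dict(g.degree())
    cut = nx.Graph(g)
    for e in s.bonds.edges:
        i, j = tuple(e)
        ai, aj = s.atoms[i], s.atoms[j]
        if not (ai.is_heavy and aj.is_heavy):
            continue
        hi = int(np.searchsorted(heavy, i))
        hj = int(np.searchsorted(heavy, j))
        if (
            not s.bonds.ring_membership.get(e, False)
            and s.bonds.orders.get(e, 1.0) == 1.0
            and heavy_degree[hi] >= 2
            and heavy_degree[hj] >= 2
        ):
            cut.remove_edge(hi, hj)
    comps = sorted(nx.connected_components(cut), key=min)
    return [sorted(int(heavy[k]) for k in comp) for comp in comps]


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


_SPHERE_POINTS = _fibonacci_sphere(SASA_POINTS)


def sasa(atoms, context_atoms=(), probe: float = SASA_PROBE,
         n_points: int = SASA_POINTS) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible surface area (A^2).

    ``atoms``/``context_atoms`` are AtomRecord sequences; the context
    occludes but receives no area. The point set is a fixed Fibonacci
    sphere, so results are deterministic.
    """
    pts = (_SPHERE_POINTS if n_points == SASA_POINTS
           else _fibonacci_sphere(n_points))
    all_atoms = list(atoms) + list(context_atoms)
    coords = np.array([a.coords for a in all_atoms])
    radii = np.array([a.vdw_radius for a in all_atoms]) + probe
    tree = cKDTree(coords)
    out = np.zeros(len(atoms))
    for k, a in enumerate(atoms):
        r = radii[k]
        surface = a.coords + r * pts
        nbrs = [j for j in tree.query_ball_point(a.coords, r + radii.max())
                if j != k]
        if nbrs:
            d = np.linalg.norm(
                surface[:, None, :] - coords[nbrs][None, :, :], axis=2
            )
            accessible = np.all(d >= radii[nbrs][None, :], axis=1)
        else:
            accessible = np.ones(len(pts), bool)
        out[k] = 4.0 * np.pi * r**2 * accessible.mean()
    return out


def fragment_sasa(reference, protein) -> FragmentDecomposition:
    """Per-fragment SASA of the reference pose, bound (protein context) and
    unbound (ligand alone); fragments with ratio > 0.25 are solvent exposed."""
    rs = _as_structure(reference)
    frags = fragment_decompose(rs)
    ref_atoms = [rs.atoms[i] for i in range(len(rs.atoms))]
    heavy = [a for a in ref_atoms if a.is_heavy]
    prot_heavy = [a for a in protein.atoms if a.is_heavy]
    per_atom_bound = sasa(heavy, prot_heavy)
    per_atom_unbound = sasa(heavy)
    heavy_pos = {a.index: k for k, a in enumerate(heavy)}
    sb, su = [], []
    for frag in frags:
        ks = [heavy_pos[i] for i in frag]
        sb.append(per_atom_bound[ks].sum())
        su.append(per_atom_unbound[ks].sum())
    sb = np.array(sb)
    su = np.array(su)
    ratio = np.divide(sb, su, out=np.zeros_like(sb), where=su > 0)
    return FragmentDecomposition(
        fragments=frags,
        sasa_bound=sb,
        sasa_unbound=su,
        sasa_ratio=ratio,
        excluded=ratio > SASA_RATIO_CUTOFF,
    )


def modified_rmsd(pose, reference, protein,
                  decomposition: FragmentDecomposition | None = None) -> float:
    """RMSD over the non-solvent-exposed fragments of the reference pose.

    Exposure is decided once on the reference (stable atom subset across a
    pose set). If every fragment is exposed, falls back to the standard
    RMSD with a warning.
    """
    ps = _as_structure(pose)
    rs = _as_structure(reference)
    if decomposition is None:
        decomposition = fragment_sasa(reference, protein)
    keep = [
        i
        for frag, excl in zip(decomposition.fragments, decomposition.excluded)
        if not excl
        for i in frag
    ]
    if not keep:
        warnings.warn(
            "all fragments solvent exposed; falling back to standard RMSD"
        )
        return rmsd(pose, reference, use_symmetry=False)
    heavy = ps.heavy_indices
    if len(heavy) != len(rs.heavy_indices):
        raise ValueError("pose and reference compositions differ")
    return _rmsd_subset(ps.coords, rs.coords, np.array(keep))


# ---------------------------------------------------------------------------
# contacts

def contact_map(pose, protein, cutoff: float = CONTACT_CUTOFF) -> ContactMap:
    ps = _as_structure(pose)
    lig_heavy = ps.heavy_indices
    prot_heavy = protein.heavy_indices
    if len(lig_heavy) == 0 or len(prot_heavy) == 0:
        return ContactMap(frozenset(), cutoff)
    tree = cKDTree(protein.coords[prot_heavy])
    contacts = set()
    for lk, li in enumerate(lig_heavy):
        for pk in tree.query_ball_point(ps.coords[li], cutoff):
            contacts.add((int(prot_heavy[pk]), int(li)))
    return ContactMap(frozenset(contacts), cutoff)


def contact_mode_score(pose, reference, protein,
                       cutoff: float = CONTACT_CUTOFF) -> float:
    """Tanimoto of pose vs reference contact sets; 1.0 when both empty."""
    cp = contact_map(pose, protein, cutoff).contacts
    cr = contact_map(reference, protein, cutoff).contacts
    union = cp | cr
    if not union:
        return 1.0
    return len(cp & cr) / len(union)


def label_pose(rmsd_value: float,
               threshold: float = NATIVE_RMSD_THRESHOLD) -> bool:
    """Native iff RMSD strictly below 2 A."""
    return bool(rmsd_value < threshold)


def evaluate_pose(pose, references, protein,
                  decomposition: FragmentDecomposition | None = None
                  ) -> EvaluationResult:
    refs = references if isinstance(references, (list, tuple)) else [references]
    r = rmsd(pose, refs, use_symmetry=True)
    m = min(modified_rmsd(pose, ref, protein, decomposition) for ref in refs)
    c = max(contact_mode_score(pose, ref, protein) for ref in refs)
    return EvaluationResult(
        pose_id=getattr(pose, "pose_id", ""),
        rmsd=r,
        modified_rmsd=m,
        cms=c,
        is_native=label_pose(min(r, m)),
        references_used=len(refs),
    )


# ---------------------------------------------------------------------------
# fold splitting

def split_folds(sequence_distance: np.ndarray, ligand_similarity: np.ndarray,
                n_folds: int = 3, seed=None) -> np.ndarray:
    """Similarity-balanced fold assignment.

    Systems i, j are linked when sequence distance < 0.5 OR ligand
    similarity > 0.9; single-linkage groups of linked systems are sorted by
    size (descending) and greedily assigned to the currently smallest fold
    (ties: lowest fold index), so no linked pair ever crosses folds.
    """
    seq = np.asarray(sequence_distance, float)
    sim = np.asarray(ligand_similarity, float)
    if seq.shape != sim.shape or seq.ndim != 2 or seq.shape[0] != seq.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    n = seq.shape[0]
    linked = (seq < 0.5) | (sim > 0.9)
    np.fill_diagonal(linked, False)
    g = nx.from_numpy_array(linked.astype(int))
    groups = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    folds = np.full(n, -1, dtype=int)
    sizes = np.zeros(n_folds, dtype=int)
    for grp in groups:
        target = int(np.argmin(sizes))  # argmin takes the lowest index on ties
        folds[grp] = target
        sizes[target] += len(grp)
    if sizes.max() - sizes.min() > 1:
        warnings.warn(f"fold imbalance: sizes {sizes.tolist()}")
    return folds
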