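"""Desk-scale synthetic complexes, decoy pose sets, and water trajectories.

Every generator is deterministic per (seed, system index) and reuses the
real atom-type vocabulary, so featurization and metrics run exactly as they
would on real data.

Pockets are built C2-symmetric (a two-fold rotation axis through the pocket
center, the classic HIV-protease-like geometry): every pocket atom has a
symmetry mate, and for each system the decoy set contains the C2 images of
the native-like poses. When ``hydration_dependent_labels`` is on, the label
of a pose is a deterministic function of its overlap with a planted
high-occupancy water hotspot placed on one side of the axis — geometrically
the native pose and its C2 image are indistinguishable, so only a model
that reads the water channels can tell them apart.

Decoy RMSDs are constructed exactly: a rotation about the ligand centroid
contributes r_rot, an orthogonal translation supplies the remainder, so the
recorded RMSD equals the recomputed one to float precision.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .grids import GridSpec, ScalarGrid
from .hydration import (
    BulkReference,
    HydrationThermoGrids,
    WaterTrajectory,
    accumulate_occupancy,
    encode_hydration_channels,
)
from .pose_eval import contact_mode_score, rmsd as compute_rmsd
from .structures import AtomRecord, BondGraph, LigandPose, MolecularStructure
from .voxelize import assemble_input, rasterize

PROTEIN_PALETTE = [
    ("C", "p_C_ali_hyd"), ("C", "p_C_aro_hyd"), ("C", "p_C_ali_pol"),
    ("N", "p_N_don"), ("O", "p_O_acc"), ("O", "p_O_donacc"), ("S", "p_S"),
]
LIGAND_PALETTE = [
    ("C", "l_C_ali_hyd"), ("C", "l_C_ali_pol"), ("N", "l_N_don"),
    ("N", "l_N_acc"), ("O", "l_O_acc"), ("O", "l_O_donacc"),
]
POLAR_LIGAND = {"l_N_don", "l_N_acc", "l_O_acc", "l_O_donacc"}

SITE_OFFSET = 3.5  # A, ligand site distance from the C2 axis
BOND_LENGTH = 1.5  # A
MIN_CONTACT, MAX_CONTACT = 2.5, 4.5  # A, native pose to pocket
OVERLAP_CUTOFF = 2.0  # A, ligand-hotspot overlap criterion for labels


@dataclass(frozen=True)
class HotspotSpec:
    position: tuple
    occupancy_fraction: float = 1.0
    mean_energy: float = -12.0  # kcal/mol
    sigma: float = 0.3  # A positional spread


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    n_systems: int = 20
    pocket_atoms: int = 32
    ligand_size: int = 8
    n_poses: int = 25
    decoy_scale: float = 4.0
    hotspots: tuple = ()
    hotspot_energy: float = -12.0
    hotspot_sigma: float = 0.3
    bulk_density: float = 0.0334  # waters / A^3
    bulk_energy: float = -10.0  # kcal/mol
    n_frames: int = 100
    hydration_dependent_labels: bool = False
    grid: GridSpec = field(default_factory=lambda: GridSpec((0.0, 0.0, 0.0), 16.0, 2.0))

    def __post_init__(self):
        if self.n_systems < 1 or self.ligand_size < 2 or self.n_poses < 1:
            raise ValueError("all counts must be >= 1")


def _system_rng(spec: SyntheticSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(index,)))


def _c2(points: np.ndarray) -> np.ndarray:
    """Two-fold rotation about the z axis."""
    out = np.array(points, float, copy=True)
    out[..., 0] *= -1
    out[..., 1] *= -1
    return out


def _random_ligand(rng, n_atoms: int) -> np.ndarray:
    """Self-avoiding random walk with 1.5 A bonds; returns local coords
    centered at the origin."""
    coords = [np.zeros(3)]
    while len(coords) < n_atoms:
        anchor = coords[rng.integers(len(coords))]
        for _ in range(50):
            d = rng.normal(size=3)
            cand = anchor + BOND_LENGTH * d / np.linalg.norm(d)
            if all(np.linalg.norm(cand - c) >= 1.2 for c in coords):
                coords.append(cand)
                break
        else:  # pathological draw: restart the walk
            coords = [np.zeros(3)]
    coords = np.array(coords)
    return coords - coords.mean(axis=0)


def _ligand_bonds(coords: np.ndarray) -> BondGraph:
    """Connect each atom to its nearest earlier atom (the walk's anchors are
    not recorded, but nearest-earlier reproduces a connected tree)."""
    pairs = []
    for i in range(1, len(coords)):
        d = np.linalg.norm(coords[:i] - coords[i], axis=1)
        pairs.append((int(np.argmin(d)), i))
    return BondGraph.from_pairs(pairs, len(coords))


def generate_complex(spec: SyntheticSpec, system_index: int):
    """One toy system: a C2-symmetric pocket of typed pseudo-atoms on a
    spherical shell, and a native ligand pose at +SITE_OFFSET from the axis
    with at least one polar contact at 2.8-3.5 A."""
    rng = _system_rng(spec, system_index)

    lig_local = _random_ligand(rng, spec.ligand_size)
    bonds = _ligand_bonds(lig_local)
    site = np.array([SITE_OFFSET, 0.0, 0.0]) + rng.normal(0, 0.3, 3)
    lig_coords = lig_local + site
    lig_atoms = []
    for i, c in enumerate(lig_coords):
        elem, typ = LIGAND_PALETTE[rng.integers(len(LIGAND_PALETTE))]
        lig_atoms.append(AtomRecord(i, elem, c, atom_type=typ))
    # guarantee a polar ligand atom for the contact
    if not any(a.atom_type in POLAR_LIGAND for a in lig_atoms):
        lig_atoms[0] = AtomRecord(0, "O", lig_coords[0], atom_type="l_O_acc")
    ligand = MolecularStructure(lig_atoms, bonds, "ligand")

    pocket_coords = []
    pocket_types = []
    half = max(1, (spec.pocket_atoms - 2) // 2)
    tries = 0
    while len(pocket_coords) < 2 * half and tries < 10_000:
        tries += 1
        d = rng.normal(size=3)
        p = (6.5 + rng.uniform(-0.5, 0.5)) * d / np.linalg.norm(d)
        pm = _c2(p)
        dmin = min(
            np.linalg.norm(lig_coords - p, axis=1).min(),
            np.linalg.norm(lig_coords - pm, axis=1).min(),
        )
        if dmin < 2.6:
            continue
        elem, typ = PROTEIN_PALETTE[rng.integers(len(PROTEIN_PALETTE))]
        pocket_coords.extend([p, pm])
        pocket_types.extend([(elem, typ), (elem, typ)])
    # polar contact atom: 3.0 A outward from a polar ligand atom (+ its mate)
    polar_idx = [i for i, a in enumerate(lig_atoms) if a.atom_type in POLAR_LIGAND]
    anchor = lig_coords[polar_idx[int(rng.integers(len(polar_idx)))]]
    for _ in range(200):
        d = rng.normal(size=3)
        contact = anchor + 3.0 * d / np.linalg.norm(d)
        if np.linalg.norm(lig_coords - contact, axis=1).min() >= MIN_CONTACT and \
           np.linalg.norm(lig_coords - _c2(contact), axis=1).min() >= MIN_CONTACT:
            break
    pocket_coords.extend([contact, _c2(contact)])
    pocket_types.extend([("O", "p_O_donacc"), ("O", "p_O_donacc")])

    prot_atoms = [
        AtomRecord(i, elem, c, atom_type=typ, resname="POC", resid=i + 1)
        for i, (c, (elem, typ)) in enumerate(zip(pocket_coords, pocket_types))
    ]
    protein = MolecularStructure(prot_atoms, BondGraph(), "protein")
    native = LigandPose(ligand, "pose_0", "native")
    return protein, native


def _perturbed_pose(native: LigandPose, target_rmsd: float, rng,
                    pose_id: str) -> LigandPose:
    """Rigid perturbation with exactly the requested heavy-atom RMSD."""
    coords = native.coords
    centroid = coords.mean(axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = rng.uniform(0.05, 0.5)
    while True:
        R = Rotation.from_rotvec(theta * axis).as_matrix()
        rotated = (coords - centroid) @ R.T + centroid
        r_rot = float(np.sqrt(np.mean(np.sum((rotated - coords) ** 2, axis=1))))
        if r_rot <= 0.95 * target_rmsd:
            break
        theta *= 0.5
    t_norm = np.sqrt(target_rmsd**2 - r_rot**2)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    out = rotated + t_norm * direction
    return LigandPose(native.structure.with_coords(out), pose_id, "docked")


def generate_decoys(native: LigandPose, n: int, scale: float, seed):
    """n rigid perturbations with stratified RMSDs: at least one native-like
    (< 2 A) and at least n/2 clear decoys (> 2 A); recorded RMSDs equal
    the metric module's output to 1e-6."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_low = max(1, n // 5)
    targets = np.concatenate([
        rng.uniform(0.3, 1.8, size=n_low),
        rng.uniform(2.2, 2.2 + max(scale, 0.1), size=n - n_low),
    ])
    poses, rmsds = [], []
    for k, t in enumerate(targets):
        if scale == 0:
            poses.append(LigandPose(native.structure.with_coords(
                native.coords.copy()), f"pose_{k + 1}", "docked"))
            rmsds.append(0.0)
        else:
            poses.append(_perturbed_pose(native, float(t), rng, f"pose_{k + 1}"))
            rmsds.append(float(t))
    return poses, np.array(rmsds)


def generate_water_trajectory(
    spec: SyntheticSpec,
    protein: MolecularStructure | None,
    grid: GridSpec,
    rng=None,
) -> WaterTrajectory:
    """Planted hotspots over uniform bulk.

    Per frame each hotspot is occupied with its stated fraction (oxygen
    drawn isotropically with its sigma, energy around its mean with
    sigma_E = 0.5 kcal/mol); bulk waters are uniform at the stated density
    outside the protein's 2 A envelope and outside a 2 A hard core around
    each hotspot (the site water occupies that volume), with energies
    around the bulk mean.
    """
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    lo = grid.origin_corner
    box = grid.extent
    for h in spec.hotspots:
        pos = np.asarray(h.position, float)
        if np.any(pos < lo) or np.any(pos > lo + box):
            raise ValueError(f"hotspot at {pos} lies outside the grid")
    n_bulk = int(round(spec.bulk_density * box**3))
    prot_tree = None
    if protein is not None and len(protein.atoms):
        prot_tree = cKDTree(protein.coords)
    frames, energies, ids = [], [], []
    hot_pos = np.array([h.position for h in spec.hotspots]).reshape(-1, 3)
    sigma_e = 0.5
    for _f in range(spec.n_frames):
        coords_f, en_f, id_f = [], [], []
        for k, h in enumerate(spec.hotspots):
            if h.occupancy_fraction >= 1.0 or rng.uniform() < h.occupancy_fraction:
                coords_f.append(np.asarray(h.position) +
                                rng.normal(0, h.sigma, 3))
                en_f.append(rng.normal(h.mean_energy, sigma_e))
                id_f.append(k)
        bulk = lo + rng.uniform(0, box, size=(n_bulk, 3))
        if prot_tree is not None:
            d, _ = prot_tree.query(bulk)
            bulk = bulk[d > 2.0]
        if len(hot_pos):
            # hard-core exclusion: the site water occupies its own volume
            d = np.linalg.norm(bulk[:, None, :] - hot_pos[None, :, :], axis=2)
            bulk = bulk[d.min(axis=1) > 2.0]
        coords_f.extend(bulk)
        en_f.extend(rng.normal(spec.bulk_energy, sigma_e, size=len(bulk)))
        id_f.extend(range(len(spec.hotspots),
                          len(spec.hotspots) + len(bulk)))
        frames.append(np.array(coords_f).reshape(-1, 3))
        energies.append(np.array(en_f))
        ids.append(np.array(id_f, dtype=int))
    return WaterTrajectory(frames, energies, ids)


# ---------------------------------------------------------------------------
# labeled datasets

@dataclass
class SyntheticSystem:
    protein: MolecularStructure
    poses: list  # LigandPose
    labels: dict  # pose_id -> bool
    rmsds: dict  # pose_id -> float (to the native pose)
    cms: dict  # pose_id -> float
    occupancy: ScalarGrid | None
    hotspot: HotspotSpec | None


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    systems: list

    def manifest_hash(self) -> str:
        h = hashlib.sha256()
        for sys in self.systems:
            h.update(np.ascontiguousarray(sys.protein.coords).tobytes())
            for p in sys.poses:
                h.update(p.pose_id.encode())
                h.update(np.ascontiguousarray(p.coords).tobytes())
                h.update(b"1" if sys.labels[p.pose_id] else b"0")
            if sys.occupancy is not None:
                h.update(np.ascontiguousarray(sys.occupancy.values).tobytes())
        return h.hexdigest()


def _hydration_label(pose: LigandPose, hotspot: HotspotSpec) -> bool:
    d = np.linalg.norm(pose.coords - np.asarray(hotspot.position), axis=1)
    return bool(d.min() < OVERLAP_CUTOFF)


def _hydration_pose_set(native: LigandPose, hotspot: HotspotSpec, n: int, rng):
    """Pose set for hotspot-dependent labels: native + jittered natives,
    their C2 images, and far decoys pushed off the hotspot."""
    poses = [native]
    n_nat = max(1, min(3, n // 3))
    for k in range(n_nat - 1):
        poses.append(_perturbed_pose(native, rng.uniform(0.5, 1.5), rng,
                                     f"pose_{len(poses)}"))
    for p in list(poses):
        img = LigandPose(p.structure.with_coords(_c2(p.coords)),
                         f"pose_{len(poses)}", "docked")
        poses.append(img)
    while len(poses) < n:
        cand = _perturbed_pose(native, rng.uniform(3.0, 6.0), rng,
                               f"pose_{len(poses)}")
        for _ in range(20):
            if not _hydration_label(cand, hotspot):
                break
            cand = _perturbed_pose(native, rng.uniform(3.0, 6.0), rng,
                                   cand.pose_id)
        poses.append(cand)
    return poses[:n]


def _choose_hotspot(native: LigandPose, spec: SyntheticSpec, rng) -> HotspotSpec:
    """Hotspot on a native ligand atom whose C2 image stays clear of it."""
    coords = native.coords
    order = np.argsort(-np.linalg.norm(coords[:, :2], axis=1))
    for i in order:
        pos = coords[i] + rng.normal(0, 0.2, 3)
        if np.linalg.norm(_c2(coords) - pos, axis=1).min() > 2.5:
            return HotspotSpec(tuple(pos), 1.0, spec.hotspot_energy,
                               spec.hotspot_sigma)
    raise RuntimeError("could not place a C2-separated hotspot")


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Fully labeled dataset: per system a protein, a pose set with RMSDs
    and contact scores, the hydration occupancy grid, and labels.

    Geometric mode: native iff RMSD < 2 A. Hydration mode: native iff any
    ligand atom lies within 2 A of the planted hotspot center (which sits
    on the native pose, so geometry alone cannot identify it against the
    C2 image).
    """
    systems = []
    for i in range(spec.n_systems):
        rng = _system_rng(spec, i)
        protein, native = generate_complex(spec, i)
        if spec.hydration_dependent_labels:
            hotspot = _choose_hotspot(native, spec, rng)
            poses = _hydration_pose_set(native, hotspot, spec.n_poses, rng)
            if rng.uniform() < 0.5:
                # flip the whole system through the C2 axis so the correct
                # side is unpredictable from pocket-frame geometry
                poses = [
                    LigandPose(p.structure.with_coords(_c2(p.coords)),
                               p.pose_id, p.source)
                    for p in poses
                ]
                hotspot = HotspotSpec(
                    tuple(_c2(np.asarray(hotspot.position))),
                    hotspot.occupancy_fraction, hotspot.mean_energy,
                    hotspot.sigma,
                )
            native = poses[0]
            labels = {p.pose_id: _hydration_label(p, hotspot) for p in poses}
        else:
            hotspot = None
            decoys, _r = generate_decoys(
                native, spec.n_poses - 1, spec.decoy_scale,
                rng.integers(2**31),
            )
            poses = [native] + decoys
            labels = None  # from RMSD below
        rmsds = {p.pose_id: compute_rmsd(p, native, use_symmetry=False)
                 for p in poses}
        if labels is None:
            labels = {pid: r < 2.0 for pid, r in rmsds.items()}
        cms = {p.pose_id: contact_mode_score(p, native, protein)
               for p in poses}
        sys_spec = dc_replace(spec, hotspots=(hotspot,) if hotspot else ())
        traj = generate_water_trajectory(
            sys_spec, protein, spec.grid, rng=rng
        )
        bulk = BulkReference(spec.bulk_energy,
                             spec.bulk_density * spec.grid.voxel_volume)
        occ = accumulate_occupancy(traj, spec.grid, bulk)
        assert any(labels.values()) and not all(labels.values()), (
            f"system {i}: both classes must be present"
        )
        systems.append(SyntheticSystem(protein, poses, labels, rmsds, cms,
                                       occ, hotspot))
    return SyntheticDataset(spec, systems)


def featurize_dataset(dataset: SyntheticDataset, mode: str = "occupancy"):
    """Rasterize every pose into a network input stack.

    Returns (X, y, cms, system_index, pose_ids) with X of shape
    (n_poses_total, C, D, D, D); C is 34 for mode='pl', 35 for 'occupancy'.
    """
    spec = dataset.spec.grid
    X, y, cms_v, sys_idx, pose_ids = [], [], [], [], []
    for si, system in enumerate(dataset.systems):
        prot_stack = rasterize(system.protein, spec)
        hydr = None
        if mode != "pl":
            zeros = ScalarGrid.zeros(spec)
            grids = HydrationThermoGrids(system.occupancy, zeros, zeros)
            hydr = encode_hydration_channels(grids, "occupancy")
        for p in system.poses:
            lig_stack = rasterize(p.structure, spec)
            stack = assemble_input(prot_stack, lig_stack, hydr,
                                   mode="occupancy" if mode != "pl" else "pl")
            X.append(stack.data.astype(np.float32))
            y.append(int(system.labels[p.pose_id]))
            cms_v.append(system.cms[p.pose_id])
            sys_idx.append(si)
            pose_ids.append(p.pose_id)
    return (np.array(X, dtype=np.float32), np.array(y), np.array(cms_v),
            np.array(sys_idx), pose_ids)
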