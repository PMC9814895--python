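"""Voxel featurization: atom-density channels and network input assembly.

Every typed heavy atom is rasterized onto the binding-site grid with a
piece-wise continuous density in its own atom-type channel:

    rho_i(r) = exp(-2 r^2 / R_i^2)                              0 <= r < R_i
             = (4/(e^2 R_i^2)) r^2 - (12/(e^2 R_i)) r + 9/e^2   R_i <= r < 1.5 R_i
             = 0                                                r >= 1.5 R_i

with R_i the van der Waals radius of the atom's type. Both branches equal
1/e^2 at r = R_i and the quadratic vanishes at 1.5 R_i, so the density is
continuous with compact support. Overlapping same-type atoms sum.

The assembled network input stacks 16 protein + 18 ligand channels (34),
plus 1 water-occupancy channel (35) or 3 thermodynamic channels (37), plus
optional probe-extremum channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .atom_types import LIGAND_TYPES, PROTEIN_TYPES
from .grids import GridSpec, ScalarGrid
from .structures import LigandPose, MolecularStructure


def density_kernel(r, R_i):
    """Atom density at distance ``r`` (A) for vdW radius ``R_i`` (A)."""
    if np.any(np.asarray(R_i) <= 0):
        raise ValueError("R_i must be > 0")
    r = np.asarray(r, dtype=float)
    e2 = np.e**2
    gauss = np.exp(-2.0 * r**2 / R_i**2)
    quad = 4.0 / (e2 * R_i**2) * r**2 - 12.0 / (e2 * R_i) * r + 9.0 / e2
    out = np.where(r < R_i, gauss, np.where(r < 1.5 * R_i, quad, 0.0))
    return out if out.shape else float(out)


@dataclass
class ChannelStack:
    """A named stack of scalar channels sharing one GridSpec."""

    spec: GridSpec
    data: np.ndarray  # (C, D, D, D)
    names: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.names), *self.spec.shape):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.names)} channels on {self.spec.shape}"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def channel(self, name: str) -> ScalarGrid:
        return ScalarGrid(self.spec, self.data[self.names.index(name)])


def rasterize(
    structure: MolecularStructure,
    spec: GridSpec,
    vocabulary: tuple | None = None,
) -> ChannelStack:
    """Sum per-type atom densities onto the grid.

    Channels for every vocabulary key are present (all-zero when unused).
    Hydrogens carry no density. Raises on an untyped heavy atom.
    """
    if vocabulary is None:
        vocabulary = PROTEIN_TYPES if structure.role == "protein" else LIGAND_TYPES
    index = {t: k for k, t in enumerate(vocabulary)}
    D = spec.dims
    data = np.zeros((len(vocabulary), D, D, D))
    ax = spec.axis_centers()  # (3, D)
    lo_corner = spec.origin_corner

    for a in structure.atoms:
        if not a.is_heavy:
            continue
        if a.atom_type is None:
            raise ValueError(f"heavy atom {a.index} has no atom type")
        if a.atom_type not in index:
            raise ValueError(
                f"atom type {a.atom_type!r} not in the {structure.role} vocabulary"
            )
        R = a.vdw_radius
        cut = 1.5 * R
        # voxel index window overlapping the kernel support
        lo = np.floor((a.coords - cut - lo_corner) / spec.spacing).astype(int)
        hi = np.ceil((a.coords + cut - lo_corner) / spec.spacing).astype(int)
        lo = np.clip(lo, 0, D)
        hi = np.clip(hi, 0, D)
        if np.any(lo >= hi):
            continue
        dx = ax[0][lo[0]:hi[0]] - a.coords[0]
        dy = ax[1][lo[1]:hi[1]] - a.coords[1]
        dz = ax[2][lo[2]:hi[2]] - a.coords[2]
        r = np.sqrt(
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        data[index[a.atom_type], lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            density_kernel(r, R)
        )
    return ChannelStack(spec, data, tuple(vocabulary))


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about ``center`` followed by translation."""

    rotation: np.ndarray  # (3,3)
    translation: np.ndarray  # (3,)
    center: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = (pts - self.center) @ self.rotation.T + self.center + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]


def random_rigid_transform(
    seed, center, max_translation: float = 2.0
) -> RigidTransform:
    """Uniform random SO(3) rotation about ``center`` plus a translation
    drawn uniformly from the ball of radius ``max_translation`` (A)."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = max_translation * rng.uniform() ** (1.0 / 3.0)
    return RigidTransform(rot, radius * direction, np.asarray(center, float))


def augment(
    protein: MolecularStructure,
    pose: LigandPose,
    seed,
    center=None,
    max_translation: float = 2.0,
):
    """Data augmentation: one rigid motion applied identically to protein and
    pose (and, via the returned transform, to any water coordinates).

    Images are re-rendered from the transformed coordinates, never
    interpolated. Deterministic per seed.
    """
    if center is None:
        heavy = pose.structure.heavy_indices
        center = pose.coords[heavy].mean(axis=0)
    t = random_rigid_transform(seed, center, max_translation)
    protein_t = protein.with_coords(t.apply(protein.coords))
    pose_t = LigandPose(
        pose.structure.with_coords(t.apply(pose.coords)), pose.pose_id, pose.source
    )
    return protein_t, pose_t, t


#: fixed channel order of the assembled input
HYDRATION_OCC_NAMES = ("water_occupancy",)
HYDRATION_THERMO_NAMES = ("dH_negative", "dH_positive", "TdS")


def assemble_input(
    protein_stack: ChannelStack,
    ligand_stack: ChannelStack,
    hydration: ChannelStack | None = None,
    probes: ChannelStack | None = None,
    mode: str = "pl",
) -> ChannelStack:
    """Concatenate channels in the documented order:
    16 protein types, 18 ligand types, then hydration (1 channel in
    ``occupancy`` mode, 3 in ``thermo`` mode), then optional probe channels.
    Totals 34 / 35 / 37 (+probes)."""
    if mode not in ("pl", "occupancy", "thermo"):
        raise ValueError(f"unknown mode {mode!r}")
    stacks = [protein_stack, ligand_stack]
    if mode == "pl":
        if hydration is not None:
            raise ValueError("mode='pl' takes no hydration channels")
    else:
        if hydration is None:
            raise ValueError(f"mode={mode!r} requires hydration channels")
        want = HYDRATION_OCC_NAMES if mode == "occupancy" else HYDRATION_THERMO_NAMES
        if hydration.names != want:
            raise ValueError(
                f"hydration channels {hydration.names} do not match mode "
                f"{mode!r} (expected {want})"
            )
        stacks.append(hydration)
    if probes is not None:
        stacks.append(probes)
    spec = protein_stack.spec
    for s in stacks[1:]:
        if s.spec != spec:
            raise ValueError("all channel stacks must share one GridSpec")
    names = tuple(n for s in stacks for n in s.names)
    data = np.concatenate([s.data for s in stacks], axis=0)
    return ChannelStack(spec, data, names)
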