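"""Grid-based hydration thermodynamics from explicit-water trajectories.

A water trajectory (oxygen positions plus per-water per-frame interaction
energies) is binned onto the binding-site grid. Voxels whose occupancy
exceeds twice the bulk expectation are "pseudo-hydration sites"; every
(water, frame) observation within a 1 A radius of the voxel center
contributes to the site's desolvation enthalpy

    dH = <E_contrib> - E_bulk          (kcal/mol)

and to a translational entropy term

    -T dS = T k_B KL(q || uniform)     (kcal/mol, T = 300 K)

where q is the empirical distribution of contributing oxygen positions over
a fixed 0.25 A sub-binning of the 1 A sphere. Classical hydration sites are
recovered by greedy quality-threshold clustering of occupancy peaks.

Grids are compared with the overlap coefficient

    OC = sum_i min(p_i^1 / sum_j p_j^1, p_i^2 / sum_j p_j^2)

which is 1 for identical and 0 for disjoint distributions.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import GridSpec, ScalarGrid
from .voxelize import (
    ChannelStack,
    HYDRATION_OCC_NAMES,
    HYDRATION_THERMO_NAMES,
)

KB = 0.0019872  # kcal/mol/K
DEFAULT_T = 300.0
#: bulk water number density, waters per A^3
BULK_NUMBER_DENSITY = 0.0334
SUBBIN = 0.25  # A, sub-binning of the 1 A site sphere
SITE_RADIUS = 1.0  # A


@dataclass
class WaterTrajectory:
    """Per-frame oxygen coordinates, energies (kcal/mol) and stable ids."""

    frames: list  # list of (n_i, 3) arrays
    energies: list  # list of (n_i,) arrays
    water_ids: list  # list of (n_i,) int arrays

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        for k, (c, e, w) in enumerate(zip(self.frames, self.energies, self.water_ids)):
            if not (len(c) == len(e) == len(w)):
                raise ValueError(f"frame {k}: coords/energies/ids misaligned")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def flat(self):
        """(coords (M,3), energies (M,), frame index (M,)) over all frames."""
        coords = np.concatenate([np.atleast_2d(f) for f in self.frames])
        energies = np.concatenate(self.energies)
        frames = np.concatenate(
            [np.full(len(f), k, dtype=int) for k, f in enumerate(self.frames)]
        )
        return coords, energies, frames


@dataclass
class BulkReference:
    bulk_energy: float  # kcal/mol, mean interaction energy of a bulk water
    bulk_occupancy: float  # expected waters per voxel per frame

    def __post_init__(self):
        if self.bulk_occupancy <= 0:
            raise ValueError("bulk_occupancy must be > 0")

    @classmethod
    def for_spec(cls, spec: GridSpec, bulk_energy: float = -9.5) -> "BulkReference":
        """Bulk occupancy from the standard water number density and the
        voxel volume. The default bulk energy is a documented configuration
        constant, not an asserted physical truth."""
        return cls(bulk_energy, BULK_NUMBER_DENSITY * spec.voxel_volume)


@dataclass
class PseudoHydrationSite:
    voxel_index: tuple
    position: np.ndarray  # voxel center, A
    occupancy_ratio: float
    n_contributing: int
    dH: float = np.nan
    minus_TdS: float = np.nan
    contributors: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


@dataclass
class HydrationSite:
    center: np.ndarray
    peak_occupancy: float
    radius: float = SITE_RADIUS
    dH: float = np.nan
    minus_TdS: float = np.nan


@dataclass
class HydrationThermoGrids:
    occupancy: ScalarGrid
    enthalpy: ScalarGrid
    entropy_term: ScalarGrid  # -T dS, kcal/mol


# ---------------------------------------------------------------------------

def accumulate_occupancy(
    traj: WaterTrajectory, spec: GridSpec, bulk: BulkReference
) -> ScalarGrid:
    """Occupancy ratio to bulk per voxel.

    Each oxygen visits exactly one voxel per frame (its containing cell);
    value = visits / (n_frames * bulk_occupancy). Conserves counts exactly:
    sum(ratio) * bulk_occupancy * n_frames equals total in-grid visits.
    """
    coords, _, _ = traj.flat()
    D = spec.dims
    lo = spec.origin_corner
    edges = [lo[k] + spec.spacing * np.arange(D + 1) for k in range(3)]
    counts, _ = np.histogramdd(coords, bins=edges)
    return ScalarGrid(spec, counts / (traj.n_frames * bulk.bulk_occupancy))


def detect_pseudo_sites(
    occupancy_grid: ScalarGrid, traj: WaterTrajectory, bulk: BulkReference
) -> list:
    """One pseudo-hydration site per voxel with occupancy ratio strictly > 2.

    Contributors are all (water, frame) observations with the oxygen within
    a closed 1 A ball of the voxel center, across the whole trajectory.
    """
    spec = occupancy_grid.spec
    hot = np.argwhere(occupancy_grid.values > 2.0)
    if len(hot) == 0:
        return []
    coords, _, _ = traj.flat()
    tree = cKDTree(coords)
    sites = []
    for idx in hot:
        center = spec.center_of(idx)
        contrib = np.asarray(
            sorted(tree.query_ball_point(center, SITE_RADIUS)), dtype=int
        )
        sites.append(
            PseudoHydrationSite(
                voxel_index=tuple(int(i) for i in idx),
                position=center,
                occupancy_ratio=float(occupancy_grid.values[tuple(idx)]),
                n_contributing=len(contrib),
                contributors=contrib,
            )
        )
    return sites


def _sphere_bins():
    """Centers of the 0.25 A sub-bins tiling [-1,1]^3 that intersect the
    unit sphere, as (m, 3) array; a point is assigned to its containing bin,
    clamped into range."""
    n = int(round(2 * SITE_RADIUS / SUBBIN))  # 8 per axis
    centers_1d = -SITE_RADIUS + SUBBIN * (np.arange(n) + 0.5)
    X, Y, Z = np.meshgrid(centers_1d, centers_1d, centers_1d, indexing="ij")
    centers = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    # a bin can receive points iff its nearest point to the origin is inside
    # the sphere
    nearest = np.maximum(np.abs(centers) - SUBBIN / 2.0, 0.0)
    keep = np.linalg.norm(nearest, axis=1) < SITE_RADIUS
    flat_of_full = -np.ones(len(centers), dtype=int)
    flat_of_full[keep] = np.arange(keep.sum())
    return centers[keep], flat_of_full, n


_SPHERE_BIN_CENTERS, _SPHERE_BIN_LOOKUP, _SPHERE_BIN_N = _sphere_bins()
N_SPHERE_BINS = len(_SPHERE_BIN_CENTERS)


def site_translational_entropy(
    rel_positions: np.ndarray, T: float = DEFAULT_T
) -> float:
    """-T dS = T k_B KL(q || uniform) over the sphere sub-bins (kcal/mol).

    Uniform occupation gives 0; a point mass gives T k_B ln(m).
    """
    rel = np.atleast_2d(rel_positions)
    idx3 = np.floor((rel + SITE_RADIUS) / SUBBIN).astype(int)
    idx3 = np.clip(idx3, 0, _SPHERE_BIN_N - 1)
    flat_full = (idx3[:, 0] * _SPHERE_BIN_N + idx3[:, 1]) * _SPHERE_BIN_N + idx3[:, 2]
    flat = _SPHERE_BIN_LOOKUP[flat_full]
    # numerical corner slivers: snap to the nearest valid bin
    bad = flat < 0
    if np.any(bad):
        d = np.linalg.norm(
            rel[bad][:, None, :] - _SPHERE_BIN_CENTERS[None, :, :], axis=2
        )
        flat[bad] = np.argmin(d, axis=1)
    q = np.bincount(flat, minlength=N_SPHERE_BINS).astype(float)
    q /= q.sum()
    nz = q > 0
    kl = float(np.sum(q[nz] * np.log(q[nz] * N_SPHERE_BINS)))
    return T * KB * kl


def site_thermodynamics(
    traj: WaterTrajectory,
    sites: list,
    bulk: BulkReference,
    T: float = DEFAULT_T,
) -> list:
    """Fill dH and -TdS of each pseudo-site from its contributors."""
    coords, energies, _ = traj.flat()
    out = []
    for s in sites:
        if s.n_contributing < 1:
            raise ValueError(
                f"pseudo-site at voxel {s.voxel_index} has no contributing waters"
            )
        e = energies[s.contributors]
        rel = coords[s.contributors] - s.position
        out.append(
            PseudoHydrationSite(
                voxel_index=s.voxel_index,
                position=s.position,
                occupancy_ratio=s.occupancy_ratio,
                n_contributing=s.n_contributing,
                dH=float(e.mean() - bulk.bulk_energy),
                minus_TdS=site_translational_entropy(rel, T),
                contributors=s.contributors,
            )
        )
    return out


def thermo_grids(
    traj: WaterTrajectory,
    spec: GridSpec,
    bulk: BulkReference,
    T: float = DEFAULT_T,
) -> HydrationThermoGrids:
    """Occupancy/enthalpy/entropy grids; dH and -TdS are defined only on
    pseudo-site voxels (occupancy ratio > 2) and zero elsewhere."""
    occ = accumulate_occupancy(traj, spec, bulk)
    sites = site_thermodynamics(traj, detect_pseudo_sites(occ, traj, bulk), bulk, T)
    dH = np.zeros(spec.shape)
    tds = np.zeros(spec.shape)
    for s in sites:
        dH[s.voxel_index] = s.dH
        tds[s.voxel_index] = s.minus_TdS
    return HydrationThermoGrids(occ, ScalarGrid(spec, dH), ScalarGrid(spec, tds))


def cluster_hydration_sites(
    occupancy_grid: ScalarGrid,
    threshold: float = 2.0,
    exclusion: float = 2.0,
) -> list:
    """Greedy quality-threshold clustering of occupancy peaks.

    Repeatedly take the maximum-occupancy voxel with ratio > threshold as a
    site (radius 1 A), remove all voxels within ``exclusion`` (2 A) of its
    center, until none qualifies. Sites ordered by decreasing peak occupancy;
    centers are therefore pairwise >= 2 A apart.
    """
    spec = occupancy_grid.spec
    work = occupancy_grid.values.copy()
    centers = spec.voxel_centers()
    sites = []
    while True:
        peak = np.unravel_index(np.argmax(work), work.shape)
        if work[peak] <= threshold:
            break
        center = centers[peak]
        sites.append(HydrationSite(center=center, peak_occupancy=float(work[peak])))
        d2 = np.sum((centers - center) ** 2, axis=-1)
        work[d2 <= exclusion**2] = -np.inf
    return sites


# ---------------------------------------------------------------------------

def encode_hydration_channels(
    grids: HydrationThermoGrids,
    mode: str,
    s_occ: float = 2.0,
    s_H: float = 2.0,
    s_S: float = 1.0,
) -> ChannelStack:
    """Scale hydration data into [0, 1) network channels with tanh.

    ``occupancy`` mode: one channel tanh(ratio / s_occ). ``thermo`` mode:
    negative enthalpy |dH|, positive enthalpy, and the entropy term each get
    their own channel (H-, H+, TS), all tanh-scaled; negative values are
    taken as absolute values before scaling.
    """
    spec = grids.occupancy.spec
    for g in (grids.occupancy, grids.enthalpy, grids.entropy_term):
        if not np.all(np.isfinite(g.values)):
            raise ValueError("hydration grids contain non-finite values")
    if mode == "occupancy":
        data = np.tanh(grids.occupancy.values / s_occ)[None]
        return ChannelStack(spec, data, HYDRATION_OCC_NAMES)
    if mode == "thermo":
        dh = grids.enthalpy.values
        h_neg = np.tanh(np.where(dh < 0, -dh, 0.0) / s_H)
        h_pos = np.tanh(np.where(dh > 0, dh, 0.0) / s_H)
        ts = np.tanh(np.abs(grids.entropy_term.values) / s_S)
        return ChannelStack(
            spec, np.stack([h_neg, h_pos, ts]), HYDRATION_THERMO_NAMES
        )
    raise ValueError(f"unknown hydration mode {mode!r}")


def overlap_coefficient(grid1: ScalarGrid, grid2: ScalarGrid) -> float:
    """OC of two non-negative grids on the same spec, in [0, 1]."""
    if grid1.spec != grid2.spec:
        raise ValueError("grids must share one GridSpec")
    p1 = grid1.values.ravel()
    p2 = grid2.values.ravel()
    if np.any(p1 < 0) or np.any(p2 < 0):
        raise ValueError(
            "overlap coefficient requires non-negative grids; apply a "
            "magnitude (abs) or sign-split pre-transform to signed grids"
        )
    s1, s2 = p1.sum(), p2.sum()
    if s1 == 0 or s2 == 0:
        raise ValueError("overlap coefficient undefined for a zero-total grid")
    return float(np.minimum(p1 / s1, p2 / s2).sum())


# ---------------------------------------------------------------------------
# trajectory / energy-table IO

def load_energy_table(text: str) -> tuple[pd.DataFrame, bool]:
    """TSV ``frame water_id energy_kcal`` with a ``# ww_halved: true|false``
    header flag; returns (table, ww_halved)."""
    ww_halved = None
    for line in text.splitlines():
        if line.startswith("#") and "ww_halved" in line:
            ww_halved = line.split(":", 1)[1].strip().lower() == "true"
        if not line.startswith("#"):
            break
    if ww_halved is None:
        warnings.warn("energy table lacks '# ww_halved:' header; assuming true")
        ww_halved = True
    df = pd.read_csv(
        io.StringIO(text), sep=r"\s+", comment="#",
        names=["frame", "water_id", "energy_kcal"],
    )
    return df, ww_halved


def load_water_trajectory(
    pdb_text: str, energy_text: str, ww_energy_text: str | None = None
) -> WaterTrajectory:
    """Multi-frame PDB (MODEL/ENDMDL) of water oxygens plus an energy table.

    If the table's water-water components were not pre-halved
    (``ww_halved: false``), a separate water-water energy table must be
    supplied and its half is subtracted from the totals.
    """
    from .structures import ParseError, parse_structure, split_waters

    frames_coords: list = []
    frames_ids: list = []
    current: list[str] = []
    in_model = False
    any_model = False
    for line in pdb_text.splitlines():
        if line.startswith("MODEL"):
            in_model, any_model, current = True, True, []
        elif line.startswith("ENDMDL"):
            in_model = False
            _append_frame(current, frames_coords, frames_ids)
        elif in_model or line.startswith(("ATOM", "HETATM")):
            current.append(line)
    if not any_model:
        _append_frame(current, frames_coords, frames_ids)
    if not frames_coords:
        raise ParseError("no frames in trajectory input")

    df, ww_halved = load_energy_table(energy_text)
    if not ww_halved:
        if ww_energy_text is None:
            raise ValueError(
                "ww_halved is false but no separate water-water table given"
            )
        ww, _ = load_energy_table(ww_energy_text)
        key = ["frame", "water_id"]
        df = df.merge(ww, on=key, suffixes=("", "_ww"))
        df["energy_kcal"] = df["energy_kcal"] - 0.5 * df["energy_kcal_ww"]
    lookup = df.set_index(["frame", "water_id"])["energy_kcal"]
    energies = [
        np.array([lookup.loc[(k, int(w))] for w in ids])
        for k, ids in enumerate(frames_ids)
    ]
    return WaterTrajectory(frames_coords, energies, frames_ids)


def _append_frame(lines, frames_coords, frames_ids):
    from .structures import parse_structure, split_waters

    if not lines:
        return
    s = parse_structure("\n".join(lines), role="water")
    _, wet = split_waters(s)
    oxy = [a for a in wet.atoms if a.element == "O"]
    if not oxy:
        return
    frames_coords.append(np.array([a.coords for a in oxy]))
    frames_ids.append(np.array([a.resid for a in oxy], dtype=int))
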