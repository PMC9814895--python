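"""Probe interaction fields and probe-extremum channels.

A unit positive or negative probe is swept over the grid; its Coulomb
interaction with the molecule's point charges gives an energy field whose
favorable extrema (strict 26-neighborhood minima) mark directional
interaction hot spots, e.g. sigma-holes. Each extremum is re-encoded as a
Gaussian channel with a width that grows with the interaction magnitude.

The charge model is pluggable: any callable mapping a structure to per-atom
charges can stand behind it; the default uses the charges carried on the
atoms themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridSpec, ScalarGrid
from .structures import MolecularStructure
from .voxelize import ChannelStack

COULOMB_K = 332.06  # kcal * A / (mol * e^2)
R_MIN = 0.5  # A, singularity clamp
DEFAULT_TAU = 5.0  # kcal/mol, extremum noise floor
DEFAULT_SIGMA0 = 1.0  # A
DEFAULT_E0 = 10.0  # kcal/mol

PROBE_CHANNEL_NAMES = (
    "probe_pos_protein",
    "probe_neg_protein",
    "probe_pos_ligand",
    "probe_neg_ligand",
)


@dataclass
class ProbeField:
    spec: GridSpec
    probe_sign: int  # +1 | -1
    values: np.ndarray  # kcal/mol per voxel
    target: str  # protein | ligand


@dataclass
class ProbeExtremum:
    position: np.ndarray
    magnitude: float  # favorable interaction strength, >= 0
    probe_sign: int
    target: str


def probe_interaction_field(
    structure: MolecularStructure,
    spec: GridSpec,
    probe_sign: int,
    charge_model=None,
) -> ProbeField:
    """Coulomb energy of a unit probe at every voxel center:
    sum over atoms of sign * q * K / max(r, 0.5 A). Linear in the charges."""
    if probe_sign not in (+1, -1):
        raise ValueError("probe_sign must be +1 or -1")
    charges = (
        np.asarray(charge_model(structure), float)
        if charge_model is not None
        else np.array([a.partial_charge for a in structure.atoms])
    )
    values = np.zeros(spec.shape)
    if np.any(charges != 0):
        centers = spec.voxel_centers()  # (D,D,D,3)
        coords = structure.coords
        for q, pos in zip(charges, coords):
            if q == 0:
                continue
            r = np.linalg.norm(centers - pos, axis=-1)
            values += probe_sign * q * COULOMB_K / np.maximum(r, R_MIN)
    return ProbeField(spec, probe_sign, values, structure.role)


def extract_extrema(field: ProbeField, tau: float = DEFAULT_TAU) -> list:
    """Favorable extrema: voxels that are strict minima of the energy within
    their 26-voxel neighborhood, negative (favorable), and at least ``tau``
    in magnitude. Sorted by magnitude, descending."""
    v = field.values
    footprint = np.ones((3, 3, 3), bool)
    footprint[1, 1, 1] = False
    neigh_min = ndimage.minimum_filter(
        v, footprint=footprint, mode="constant", cval=np.inf
    )
    mask = (v < neigh_min) & (v < 0) & (np.abs(v) >= tau)
    centers = field.spec.voxel_centers()
    extrema = [
        ProbeExtremum(
            position=centers[tuple(idx)],
            magnitude=float(-v[tuple(idx)]),
            probe_sign=field.probe_sign,
            target=field.target,
        )
        for idx in np.argwhere(mask)
    ]
    extrema.sort(key=lambda e: -e.magnitude)
    return extrema


def gaussian_width(magnitude: float, sigma0: float = DEFAULT_SIGMA0,
                   E0: float = DEFAULT_E0) -> float:
    """sigma = sigma0 * (0.5 + tanh(magnitude / E0)); monotone in magnitude."""
    return sigma0 * (0.5 + np.tanh(magnitude / E0))


def probe_channels(
    extrema: list,
    spec: GridSpec,
    sigma0: float = DEFAULT_SIGMA0,
    E0: float = DEFAULT_E0,
) -> ChannelStack:
    """Four Gaussian channels (probe sign x target); each extremum adds
    exp(-d^2 / 2 sigma^2) with amplitude 1 at its own center."""
    data = np.zeros((4, *spec.shape))
    centers = spec.voxel_centers()
    for e in extrema:
        name = f"probe_{'pos' if e.probe_sign > 0 else 'neg'}_{e.target}"
        k = PROBE_CHANNEL_NAMES.index(name)
        sigma = gaussian_width(e.magnitude, sigma0, E0)
        d2 = np.sum((centers - e.position) ** 2, axis=-1)
        data[k] += np.exp(-d2 / (2.0 * sigma**2))
    return ChannelStack(spec, data, PROBE_CHANNEL_NAMES)
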