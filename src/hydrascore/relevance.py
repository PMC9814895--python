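"""Deep-Taylor layer-wise relevance propagation (z+ rule).

Starting from the native-class output of the pose classifier, relevance is
propagated backward layer by layer. For a linear map with activations x_i,
weights w_ij and biases b_j:

    R_i = sum_j  z+_ij / sum_m z+_mj * R_j,     z+_ij = x_i * max(w_ij, 0)

and relevance flows only through positively activated nodes
(sum_i x_i w_ij + b_j >= 0; otherwise the node's relevance is dropped).
Convolutions are treated as shared-weight linear maps; max pooling routes
relevance winner-takes-all with equal tie splitting; ReLU is transparent
(the gating at the preceding linear map handles it).

Consequences used by the tests: relevance is non-negative everywhere, and
on zero-bias networks whose start node has a non-negative pre-activation
the per-layer relevance sums are conserved. With biases, or when a whole
column of z+ vanishes, relevance can be lost (the count of such degenerate
nodes is reported).

Voxel relevance is aggregated to atoms by each atom's share of its channel's
density, and water-channel voxels are classified by geometry into replaced /
interface-mediating / first-shell / other hydration categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Dense, MaxPool, Network, conv3d, conv3d_input_grad, softmax
from .voxelize import (
    ChannelStack,
    HYDRATION_OCC_NAMES,
    HYDRATION_THERMO_NAMES,
    rasterize,
)

WATER_CHANNELS = set(HYDRATION_OCC_NAMES) | set(HYDRATION_THERMO_NAMES)
#: geometric operationalization of the hydration categories (A)
REPLACED_CUTOFF = 2.0
INTERFACE_CUTOFF = 3.5
FIRST_SHELL_CUTOFF = 4.5
POLAR_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass
class RelevanceMap:
    input_relevance: np.ndarray  # (C, D, D, D), >= 0
    channel_names: tuple
    start_relevance: float
    layer_sums: list  # relevance totals from output to input
    n_zero_denominator: int = 0


@dataclass
class RelevanceSummary:
    per_atom_protein: np.ndarray
    per_atom_ligand: np.ndarray
    fractions: dict  # category -> fraction of total relevance
    totals: dict


def _check_nonneg(x: np.ndarray, what: str):
    if np.any(x < 0):
        raise ValueError(f"{what} must be non-negative for the z+ rule")


def relevance_backprop_linear(W, b, x, R_upper):
    """z+ backprop through one dense map. W: (out, in), x: (in,), R: (out,).

    Returns (R_lower, n_zero_denominator)."""
    W = np.asarray(W, float)
    b = np.asarray(b, float)
    x = np.asarray(x, float)
    R_upper = np.asarray(R_upper, float)
    _check_nonneg(x, "input activations")
    _check_nonneg(R_upper, "upper-layer relevance")
    pre = W @ x + b
    Rg = np.where(pre >= 0, R_upper, 0.0)
    Wp = np.maximum(W, 0.0)
    denom = Wp @ x
    dead = (denom == 0) & (Rg > 0)
    ratio = np.where(denom > 0, Rg / np.where(denom > 0, denom, 1.0), 0.0)
    return x * (Wp.T @ ratio), int(dead.sum())


def relevance_backprop_conv(W, b, x, R_upper):
    """z+ backprop through a 'same' 3^3 convolution.

    x: (C, D, D, D); R_upper: (F, D, D, D). Returns (R_lower, n_dead)."""
    x = np.asarray(x, float)
    R_upper = np.asarray(R_upper, float)
    _check_nonneg(x, "input activations")
    _check_nonneg(R_upper, "upper-layer relevance")
    W = np.asarray(W, float)
    Wp = np.maximum(W, 0.0)
    pre = conv3d(x[None], W, np.asarray(b, float))[0]
    Rg = np.where(pre >= 0, R_upper, 0.0)
    denom = conv3d(x[None], Wp)[0]
    dead = (denom == 0) & (Rg > 0)
    ratio = np.where(denom > 0, Rg / np.where(denom > 0, denom, 1.0), 0.0)
    R_lower = x * conv3d_input_grad(ratio[None], Wp, x[None].shape)[0]
    return R_lower, int(dead.sum())


def relevance_backprop_pool(x, R_upper):
    """Winner-takes-all routing through 2^3 max pooling; ties split equally."""
    _check_nonneg(np.asarray(R_upper), "upper-layer relevance")
    pool = MaxPool()
    pool.forward(np.asarray(x, float)[None])
    return pool.route(np.asarray(R_upper, float)[None])[0]


def explain(network: Network, stack, start: str = "softmax") -> RelevanceMap:
    """Backward relevance pass from the native-class output to the input.

    ``stack`` is a ChannelStack or a (C, D, D, D) array. ``start`` selects
    the start relevance: the native softmax output ("softmax", default) or
    the raw native logit clipped at zero ("logit")."""
    network.check_finite()
    if isinstance(stack, ChannelStack):
        names = stack.names
        x0 = np.asarray(stack.data, float)
    else:
        x0 = np.asarray(stack, float)
        names = tuple(f"channel_{k}" for k in range(x0.shape[0]))
    _check_nonneg(x0, "input channels")

    # forward trace in float64
    activations = [x0]
    x = x0
    for conv, _pool in network.blocks:
        pre = conv3d(x[None], conv.W.astype(float), conv.b.astype(float))[0]
        relu = np.maximum(pre, 0.0)
        pool = MaxPool()
        x = pool.forward(relu[None])[0]
        activations.append((relu, pool, x))
    feat = x.reshape(-1)
    logits = network.dense.W.astype(float) @ feat + network.dense.b.astype(float)
    p = softmax(logits[:2])
    r0 = float(p[1]) if start == "softmax" else float(max(logits[1], 0.0))

    R_out = np.zeros_like(logits)
    R_out[1] = r0
    layer_sums = [r0]
    n_dead = 0
    R, d = relevance_backprop_linear(
        network.dense.W.astype(float), network.dense.b.astype(float), feat, R_out
    )
    n_dead += d
    layer_sums.append(float(R.sum()))
    R = R.reshape(x.shape)
    for k in reversed(range(len(network.blocks))):
        _relu, pool, _pooled = activations[k + 1]
        R = pool.route(R[None])[0]
        lower_x = activations[k][2] if k > 0 else x0
        conv = network.blocks[k][0]
        R, d = relevance_backprop_conv(
            conv.W.astype(float), conv.b.astype(float), lower_x, R
        )
        n_dead += d
        layer_sums.append(float(R.sum()))
    return RelevanceMap(
        input_relevance=R,
        channel_names=names,
        start_relevance=r0,
        layer_sums=layer_sums,
        n_zero_denominator=n_dead,
    )


# ---------------------------------------------------------------------------
# aggregation

def _min_dist_to(points: np.ndarray, centers_flat: np.ndarray) -> np.ndarray:
    """Min distance from each grid voxel center to any of ``points``."""
    if len(points) == 0:
        return np.full(len(centers_flat), np.inf)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(points).query(centers_flat)
    return d


def aggregate_relevance(
    rmap: RelevanceMap,
    stack: ChannelStack,
    protein,
    pose,
    cutoffs=(REPLACED_CUTOFF, INTERFACE_CUTOFF, FIRST_SHELL_CUTOFF),
) -> RelevanceSummary:
    """Attribute voxel relevance to atoms and hydration categories.

    An atom receives, per voxel, its share of its channel's density times
    the voxel relevance. Water-channel voxels are classified: *replaced*
    (within 2 A of a ligand heavy atom), *interface-mediating* (within
    3.5 A of both a ligand heavy atom and a protein polar heavy atom),
    *first-shell* (within 4.5 A of the ligand), else *other*.
    """
    if stack.spec.shape != rmap.input_relevance.shape[1:]:
        raise ValueError("relevance map and stack grids differ")
    rep_c, interf_c, shell_c = cutoffs
    spec = stack.spec
    name_to_idx = {n: k for k, n in enumerate(stack.names)}

    def atom_relevance(structure):
        rel = np.zeros(len(structure.atoms))
        for a in structure.atoms:
            if not a.is_heavy or a.atom_type is None:
                continue
            if a.atom_type not in name_to_idx:
                continue
            k = name_to_idx[a.atom_type]
            single = rasterize(
                type(structure)([a], role=structure.role), spec,
                vocabulary=(a.atom_type,),
            ).data[0]
            total = stack.data[k]
            share = np.divide(single, total, out=np.zeros_like(single),
                              where=total > 0)
            rel[a.index] = float((share * rmap.input_relevance[k]).sum())
        return rel

    prot_rel = atom_relevance(protein)
    lig_struct = pose.structure if hasattr(pose, "structure") else pose
    lig_rel = atom_relevance(lig_struct)

    centers = spec.voxel_centers().reshape(-1, 3)
    lig_heavy = lig_struct.coords[lig_struct.heavy_indices]
    prot_polar = np.array(
        [a.coords for a in protein.atoms if a.is_heavy and a.element in POLAR_ELEMENTS]
    ).reshape(-1, 3)
    d_lig = _min_dist_to(lig_heavy, centers)
    d_pol = _min_dist_to(prot_polar, centers)
    replaced = d_lig <= rep_c
    interface = (~replaced) & (d_lig <= interf_c) & (d_pol <= interf_c)
    first_shell = (~replaced) & (~interface) & (d_lig <= shell_c)
    other = ~(replaced | interface | first_shell)

    totals = {
        "protein": float(prot_rel.sum()),
        "ligand": float(lig_rel.sum()),
        "water_replaced": 0.0,
        "water_interface": 0.0,
        "water_first_shell": 0.0,
        "water_other": 0.0,
        "probe": 0.0,
    }
    for k, name in enumerate(stack.names):
        if name in WATER_CHANNELS:
            r = rmap.input_relevance[k].reshape(-1)
            totals["water_replaced"] += float(r[replaced].sum())
            totals["water_interface"] += float(r[interface].sum())
            totals["water_first_shell"] += float(r[first_shell].sum())
            totals["water_other"] += float(r[other].sum())
        elif name.startswith("probe_"):
            totals["probe"] += float(rmap.input_relevance[k].sum())

    grand = sum(totals.values())
    fractions = {k: (v / grand if grand > 0 else 0.0) for k, v in totals.items()}
    return RelevanceSummary(
        per_atom_protein=prot_rel,
        per_atom_ligand=lig_rel,
        fractions=fractions,
        totals=totals,
    )
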