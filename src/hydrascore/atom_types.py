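"""Frozen atom-type vocabulary and typing rules.

The featurization uses 34 heavy-atom density channels: 16 protein types and
18 ligand types, in the Smina/AutoDock lineage (carbon split by aromaticity
and polarity of its neighborhood, N/O split by donor/acceptor status,
per-halogen ligand types, one generic metal/other type per role). The exact
published vocabulary is not enumerated anywhere, so this table is this
package's frozen, versioned operationalization: typing is a pure function of
element, ring membership, bonded neighbors and donor/acceptor status, and is
deterministic and order-independent.

Hydrogens carry no density channel; protonation is assumed done upstream.
"""

from __future__ import annotations

VOCABULARY_VERSION = "1.0"

# fmt: off
PROTEIN_TYPES: tuple[str, ...] = (
    "p_C_ali_hyd",   # aliphatic carbon, only C/H neighbors
    "p_C_ali_pol",   # aliphatic carbon with heteroatom neighbor
    "p_C_aro_hyd",   # ring carbon, only C/H neighbors
    "p_C_aro_pol",   # ring carbon with heteroatom neighbor
    "p_N_don",       # nitrogen, H-bond donor only (e.g. backbone amide N)
    "p_N_acc",       # nitrogen, acceptor only (e.g. deprotonated His N)
    "p_N_donacc",    # nitrogen, donor and acceptor
    "p_N_plain",     # nitrogen, neither (e.g. proline backbone N)
    "p_O_don",       # oxygen, donor only (rare; kept for vocabulary closure)
    "p_O_acc",       # oxygen, acceptor only (carbonyl, carboxylate, ether)
    "p_O_donacc",    # oxygen, donor and acceptor (hydroxyl, water)
    "p_S",           # sulfur (Cys/Met)
    "p_P",           # phosphorus (phosphorylated residues)
    "p_halogen",     # any halogen on the protein side (generic)
    "p_metal",       # structural/catalytic metals
    "p_other",       # anything outside the table (warned, never dropped)
)

LIGAND_TYPES: tuple[str, ...] = (
    "l_C_ali_hyd",
    "l_C_ali_pol",
    "l_C_aro_hyd",
    "l_C_aro_pol",
    "l_N_don",
    "l_N_acc",
    "l_N_donacc",
    "l_N_plain",
    "l_O_don",
    "l_O_acc",
    "l_O_donacc",
    "l_S",
    "l_P",
    "l_F",
    "l_Cl",
    "l_Br",
    "l_I",
    "l_metal_other",
)
# fmt: on

ALL_TYPES: tuple[str, ...] = PROTEIN_TYPES + LIGAND_TYPES
assert len(PROTEIN_TYPES) == 16 and len(LIGAND_TYPES) == 18

#: van der Waals radii (Angstrom) used as R_i in the density kernel,
#: Smina/X-score flavored values.
VDW_RADII: dict[str, float] = {
    "H": 1.0,
    "C": 1.9,
    "N": 1.8,
    "O": 1.7,
    "S": 2.0,
    "P": 2.1,
    "F": 1.5,
    "Cl": 1.8,
    "Br": 2.0,
    "I": 2.2,
    "B": 1.92,
    "Se": 1.9,
    # metals and ions: one compact radius
    "Na": 1.2, "K": 1.2, "Mg": 1.2, "Ca": 1.2, "Zn": 1.2, "Fe": 1.2,
    "Mn": 1.2, "Cu": 1.2, "Ni": 1.2, "Co": 1.2, "Cd": 1.2, "Hg": 1.2,
}

#: simple single-bond covalent radii for distance-based bond inference (A)
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
    "Na": 1.66, "K": 2.03, "Mg": 1.41, "Ca": 1.76, "Zn": 1.22, "Fe": 1.32,
    "Mn": 1.39, "Cu": 1.32, "Ni": 1.24, "Co": 1.26, "Cd": 1.44, "Hg": 1.32,
}

METALS = frozenset(
    {"Na", "K", "Mg", "Ca", "Zn", "Fe", "Mn", "Cu", "Ni", "Co", "Cd", "Hg"}
)
HALOGENS = frozenset({"F", "Cl", "Br", "I"})
HETERO = frozenset({"N", "O", "S", "P", "F", "Cl", "Br", "I", "Se", "B"})

SUPPORTED_ELEMENTS = frozenset(VDW_RADII)


def vdw_radius(element: str) -> float:
    """R_i for an element; unknown elements get the generic metal radius."""
    return VDW_RADII.get(element, 1.2)


def type_atom(
    element: str,
    role: str,
    *,
    in_ring: bool = False,
    neighbor_elements: tuple[str, ...] = (),
    n_hydrogens: int = 0,
    is_amide_n: bool = False,
    is_carbonyl_o: bool = False,
    hydrogens_explicit: bool = True,
) -> str:
    """Assign one vocabulary key to a heavy atom.

    ``role`` is "protein" or "ligand". When the parent structure carries no
    explicit hydrogens (typical for PDB input), ``hydrogens_explicit=False``
    lets implicit hydrogens be inferred from heavy-atom valence.
    """
    if role not in ("protein", "ligand"):
        raise ValueError(f"role must be protein or ligand, got {role!r}")
    p = role == "protein"
    heavy_degree = sum(1 for e in neighbor_elements if e != "H")

    if element == "C":
        polar = any(e in HETERO for e in neighbor_elements)
        aro = "aro" if in_ring else "ali"
        pol = "pol" if polar else "hyd"
        return f"{'p' if p else 'l'}_C_{aro}_{pol}"

    if element == "N":
        if hydrogens_explicit:
            donor = n_hydrogens > 0
        else:
            donor = heavy_degree < 3 and not (is_amide_n and heavy_degree >= 3)
            if is_amide_n and heavy_degree >= 3:
                donor = False
        # amide/aromatic-amide lone pair is delocalized: not an acceptor
        acceptor = (not is_amide_n) and heavy_degree <= 2
        key = {(True, True): "N_donacc", (True, False): "N_don",
               (False, True): "N_acc", (False, False): "N_plain"}[(donor, acceptor)]
        return f"{'p' if p else 'l'}_{key}"

    if element == "O":
        if hydrogens_explicit:
            donor = n_hydrogens > 0
        else:
            # terminal non-carbonyl oxygen presumed protonated (hydroxyl/water)
            donor = heavy_degree <= 1 and not is_carbonyl_o
        acceptor = True
        key = "O_donacc" if donor else "O_acc"
        return f"{'p' if p else 'l'}_{key}"

    if element == "S":
        return "p_S" if p else "l_S"
    if element == "P":
        return "p_P" if p else "l_P"
    if element in HALOGENS:
        return "p_halogen" if p else f"l_{element}"
    if element in METALS:
        return "p_metal" if p else "l_metal_other"
    # outside the table: generic bucket, caller warns
    return "p_other" if p else "l_metal_other"
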