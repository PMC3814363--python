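"""Per-element and per-residue chemical tables used across the package.

Radii are the Bondi (1964) van der Waals set, the table name travels with
every SASA result so area numbers stay traceable to a radius convention.
Donor/acceptor and apolar-carbon typing follows standard amino-acid
chemistry on heavy atoms only (crystal structures rarely carry hydrogens).
"""

from __future__ import annotations

VDW_TABLE_NAME = "bondi64"

# Bondi vdW radii, Å.  Elements missing here raise, by design.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "MG": 1.73,
    "ZN": 1.39,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "MN": 2.05,
    "FE": 2.04,
}


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Å; raises KeyError naming the element."""
    key = element.strip().upper()
    try:
        return VDW_RADII[key]
    except KeyError:
        raise KeyError(f"no van der Waals radius for element {element!r} "
                       f"in table {VDW_TABLE_NAME}") from None


STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",  # selenomethionine, treated as MET
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Hydrogen-bond donor heavy atoms (the attached H is implicit).
# Backbone N is always a donor, backbone O always an acceptor.
SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}

SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
    "MSE": {"SE"},
    "CYS": {"SG"},
}

# Basic-side-chain nitrogens and acidic-side-chain oxygens for salt bridges.
SALT_BRIDGE_BASIC: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
    "HIS": {"ND1", "NE2"},
}

SALT_BRIDGE_ACIDIC: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

# Side-chain carbons bonded to N/O/S (polar-adjacent, excluded from the
# apolar-carbon set used for hydrophobic contacts).  Backbone C (carbonyl)
# and CA (bonded to backbone N) are excluded for every residue.
POLARIZED_SIDECHAIN_CARBONS: dict[str, set[str]] = {
    "ARG": {"CZ"},
    "ASN": {"CG"},
    "ASP": {"CG"},
    "GLN": {"CD"},
    "GLU": {"CD"},
    "HIS": {"CG", "CD2", "CE1"},
    "LYS": {"CE"},
    "MET": {"CG", "CE"},
    "MSE": {"CG", "CE"},
    "CYS": {"CB"},
    "SER": {"CB"},
    "THR": {"CB"},
    "TRP": {"CD1", "CE2"},
    "TYR": {"CZ"},
    "PRO": {"CD"},
}


def is_hbond_donor(res_name: str, atom_name: str) -> bool:
    if atom_name == "N":
        return True
    return atom_name in SIDECHAIN_DONORS.get(res_name, set())


def is_hbond_acceptor(res_name: str, atom_name: str) -> bool:
    if atom_name in ("O", "OXT"):
        return True
    return atom_name in SIDECHAIN_ACCEPTORS.get(res_name, set())


def is_salt_bridge_basic(res_name: str, atom_name: str) -> bool:
    return atom_name in SALT_BRIDGE_BASIC.get(res_name, set())


def is_salt_bridge_acidic(res_name: str, atom_name: str) -> bool:
    return atom_name in SALT_BRIDGE_ACIDIC.get(res_name, set())


def is_apolar_carbon(res_name: str, atom_name: str, element: str) -> bool:
    if element.strip().upper() != "C":
        return False
    if atom_name in ("C", "CA"):
        return False
    return atom_name not in POLARIZED_SIDECHAIN_CARBONS.get(res_name, set())


def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name, for files lacking column 77–78.

    Follows the PDB convention that a two-character element (e.g. FE, CL)
    starts in the first column of the name field; names starting with a
    digit (e.g. 1HB) or with H/D plus digits are hydrogens/deuteriums.
    """
    name = atom_name.strip()
    if not name:
        raise ValueError("cannot infer element from empty atom name")
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in ("FE", "ZN", "MG", "SE", "CL", "BR", "NA", "MN") and len(name) <= 2:
        return two
    first = stripped[0].upper()
    if first in ("H", "D"):
        return "H"
    if first in ("C", "N", "O", "S", "P", "F", "I", "K"):
        return first
    return first
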