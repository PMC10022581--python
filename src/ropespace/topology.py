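"""Residue topology for the 20 standard amino acids.

Heavy-atom connectivity, one-letter codes and hybridisation classes used to
build atom trees and to generate the ideal-geometry table.  Ring-closing
bonds (proline CD-N, aromatic rings) are listed separately: the atom tree is
a spanning tree, so one bond per ring is left out of parent/child relations.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Side-chain spanning-tree bonds, parent first (parent is closer to CA).
SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

# Ring-closing bonds excluded from the spanning tree (kept for reference).
RING_CLOSURES: dict[str, list[tuple[str, str]]] = {
    "HIS": [("CE1", "NE2")],
    "PHE": [("CZ", "CE2")],
    "PRO": [("CD", "N")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "TYR": [("CZ", "CE2")],
}

# sp2 / aromatic centres (backbone carbonyl C is always sp2).
SP2_CENTERS: dict[str, set[str]] = {
    "ARG": {"NE", "CZ", "NH1", "NH2"},
    "ASN": {"CG"},
    "ASP": {"CG"},
    "GLN": {"CD"},
    "GLU": {"CD"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
}

# Members of 5-membered rings (narrower interior angles).
FIVE_RING: dict[str, set[str]] = {
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "PRO": {"N", "CA", "CB", "CG", "CD"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2"},
}


def heavy_atoms(residue_name: str) -> list[str]:
    """Ordered heavy-atom names of a standard residue (backbone then side chain)."""
    atoms = list(BACKBONE_ATOMS)
    for parent, child in SIDECHAIN_BONDS.get(residue_name, []):
        if child not in atoms:
            atoms.append(child)
    return atoms


def element_of(atom_name: str) -> str:
    # Heavy protein atoms all carry their element as the first character.
    return atom_name[0]


def is_sp2(residue_name: str, atom_name: str) -> bool:
    if atom_name == "C":
        return True
    return atom_name in SP2_CENTERS.get(residue_name, set())


def in_five_ring(residue_name: str, atom_name: str) -> bool:
    return atom_name in FIVE_RING.get(residue_name, set())
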