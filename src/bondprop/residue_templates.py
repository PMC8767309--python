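"""Heavy-atom connectivity templates for the 20 standard amino acids.

Each entry lists intra-residue heavy-atom bonds as (name_a, name_b,
order) with order 1, 2 or 1.5 (delocalised/aromatic), plus the number of
hydrogens expected on each heavy atom at physiological pH (charged Lys/
Arg/Asp/Glu side chains; neutral His in the NE2-H tautomer).  Aromatic
ring memberships are listed for pi-stacking detection.
"""

from __future__ import annotations

__all__ = [
    "BACKBONE_BONDS",
    "SIDECHAIN_BONDS",
    "HYDROGEN_COUNTS",
    "AROMATIC_RINGS",
    "template_bonds",
    "template_hydrogen_count",
]

#: Shared backbone connectivity (PRO's N-CD closure is in its side chain).
BACKBONE_BONDS: list[tuple[str, str, float]] = [
    ("N", "CA", 1),
    ("CA", "C", 1),
    ("C", "O", 2),
]

SIDECHAIN_BONDS: dict[str, list[tuple[str, str, float]]] = {
    "ALA": [("CA", "CB", 1)],
    "ARG": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1), ("CD", "NE", 1),
        ("NE", "CZ", 1.5), ("CZ", "NH1", 1.5), ("CZ", "NH2", 1.5),
    ],
    "ASN": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "ND2", 1)],
    "ASP": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "OD2", 1)],
    "CYS": [("CA", "CB", 1), ("CB", "SG", 1)],
    "GLN": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
        ("CD", "OE1", 2), ("CD", "NE2", 1),
    ],
    "GLU": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
        ("CD", "OE1", 2), ("CD", "OE2", 1),
    ],
    "GLY": [],
    "HIS": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "ND1", 1.5),
        ("ND1", "CE1", 1.5), ("CE1", "NE2", 1.5), ("NE2", "CD2", 1.5),
        ("CD2", "CG", 1.5),
    ],
    "ILE": [
        ("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1), ("CG1", "CD1", 1),
    ],
    "LEU": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 1), ("CG", "CD2", 1),
    ],
    "LYS": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1), ("CD", "CE", 1),
        ("CE", "NZ", 1),
    ],
    "MET": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "SD", 1), ("SD", "CE", 1),
    ],
    "PHE": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 1.5), ("CD1", "CE1", 1.5),
        ("CE1", "CZ", 1.5), ("CZ", "CE2", 1.5), ("CE2", "CD2", 1.5),
        ("CD2", "CG", 1.5),
    ],
    "PRO": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1), ("CD", "N", 1),
    ],
    "SER": [("CA", "CB", 1), ("CB", "OG", 1)],
    "THR": [("CA", "CB", 1), ("CB", "OG1", 1), ("CB", "CG2", 1)],
    "TRP": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 1.5), ("CD1", "NE1", 1.5),
        ("NE1", "CE2", 1.5), ("CE2", "CD2", 1.5), ("CD2", "CG", 1.5),
        ("CE2", "CZ2", 1.5), ("CZ2", "CH2", 1.5), ("CH2", "CZ3", 1.5),
        ("CZ3", "CE3", 1.5), ("CE3", "CD2", 1.5),
    ],
    "TYR": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 1.5), ("CD1", "CE1", 1.5),
        ("CE1", "CZ", 1.5), ("CZ", "CE2", 1.5), ("CE2", "CD2", 1.5),
        ("CD2", "CG", 1.5), ("CZ", "OH", 1),
    ],
    "VAL": [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1)],
}

#: Hydrogens on each heavy atom (backbone N:1 except PRO:0; CA:1 except GLY:2).
_SIDECHAIN_H: dict[str, dict[str, int]] = {
    "ALA": {"CB": 3},
    "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "NH1": 2, "NH2": 2},
    "ASN": {"CB": 2, "ND2": 2},
    "ASP": {"CB": 2},
    "CYS": {"CB": 2, "SG": 1},
    "GLN": {"CB": 2, "CG": 2, "NE2": 2},
    "GLU": {"CB": 2, "CG": 2},
    "GLY": {},
    "HIS": {"CB": 2, "CD2": 1, "CE1": 1, "NE2": 1},
    "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "MET": {"CB": 2, "CG": 2, "CE": 3},
    "PHE": {"CB": 2, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "PRO": {"CB": 2, "CG": 2, "CD": 2},
    "SER": {"CB": 2, "OG": 1},
    "THR": {"CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {"CB": 2, "CD1": 1, "NE1": 1, "CZ2": 1, "CH2": 1, "CZ3": 1, "CE3": 1},
    "TYR": {"CB": 2, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "OH": 1},
    "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
}

HYDROGEN_COUNTS: dict[str, dict[str, int]] = {}
for _res, _side in _SIDECHAIN_H.items():
    counts = {"N": 0 if _res == "PRO" else 1, "CA": 2 if _res == "GLY" else 1}
    counts.update(_side)
    HYDROGEN_COUNTS[_res] = counts

AROMATIC_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    ],
}


def template_bonds(res_name: str) -> list[tuple[str, str, float]] | None:
    """Heavy-atom bonds for a standard residue, or None if non-standard."""
    side = SIDECHAIN_BONDS.get(res_name)
    if side is None:
        return None
    return BACKBONE_BONDS + side


def template_hydrogen_count(res_name: str) -> int:
    """Total hydrogens expected on a (non-terminal) standard residue."""
    return sum(HYDROGEN_COUNTS[res_name].values())
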