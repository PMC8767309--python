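"""Build an energy-weighted atomistic graph from a cleaned structure.

Nodes are atoms; edges are typed bonds (covalent, hydrogen bond,
hydrophobic, electrostatic, pi-pi) weighted by interaction energies in
kJ/mol.  Attractive (negative) potential energies are mapped to positive
graph weights by absolute value, since the diffusion machinery
downstream requires nonnegative weights.  Detection cutoffs below are
*detection* criteria only — no distance cutoff is applied anywhere in
the propensity analysis itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.sparse import csc_matrix, diags
from scipy.spatial import cKDTree

from bondprop.residue_templates import (
    AROMATIC_RINGS,
    HYDROGEN_COUNTS,
    template_bonds,
)
from bondprop.structure_io import StructureModel

__all__ = [
    "Bond",
    "AtomisticGraph",
    "EnergyParameters",
    "detect_covalent",
    "detect_noncovalent",
    "assemble_graph",
    "incidence_and_weights",
]

BOND_KINDS = ("covalent", "hydrogen_bond", "hydrophobic", "electrostatic", "pi_pi")

#: Standard single/double/delocalised bond energies, kJ/mol, keyed by
#: (element pair sorted alphabetically, order).
STANDARD_BOND_ENERGIES: dict[tuple[str, str, float], float] = {
    ("C", "C", 1): 346.0,
    ("C", "C", 2): 602.0,
    ("C", "C", 1.5): 518.0,
    ("C", "N", 1): 305.0,
    ("C", "N", 2): 615.0,
    ("C", "N", 1.5): 460.0,
    ("C", "O", 1): 358.0,
    ("C", "O", 2): 745.0,
    ("C", "O", 1.5): 552.0,
    ("C", "S", 1): 272.0,
    ("C", "H", 1): 411.0,
    ("H", "N", 1): 386.0,
    ("H", "O", 1): 459.0,
    ("H", "S", 1): 363.0,
    ("S", "S", 1): 226.0,
    ("N", "N", 1): 167.0,
    ("N", "O", 1): 201.0,
    ("O", "O", 1): 142.0,
    ("O", "P", 1): 335.0,
    ("O", "P", 2): 544.0,
    ("C", "P", 1): 264.0,
    ("H", "P", 1): 322.0,
    ("C", "F", 1): 485.0,
    ("C", "CL", 1): 327.0,
    ("C", "BR", 1): 285.0,
    ("C", "I", 1): 213.0,
}

#: Single-bond covalent radii (Å) for distance-based detection.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "FE": 1.32, "ZN": 1.22, "MG": 1.41, "MN": 1.39, "CA": 1.76,
    "NA": 1.66, "K": 2.03, "CU": 1.32, "NI": 1.24, "CO": 1.26,
}

#: Formal fractional charges for salt-bridge detection, keyed (res, atom).
DEFAULT_CHARGES: dict[tuple[str, str], float] = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
}


@dataclass(frozen=True)
class Bond:
    """A typed, energy-weighted undirected edge between two atoms."""

    i: int
    j: int
    weight: float
    kind: str
    midpoint: tuple[float, float, float]
    edge_id: int = -1

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")
        if not self.weight > 0:
            raise ValueError(f"bond weight must be positive, got {self.weight}")


@dataclass
class EnergyParameters:
    """All energy tables and geometric detection criteria, overridable
    from a YAML mapping via :meth:`from_dict` / :meth:`from_yaml`."""

    covalent_energies: dict[tuple[str, str, float], float] = field(
        default_factory=lambda: dict(STANDARD_BOND_ENERGIES)
    )
    covalent_default: float = 300.0
    covalent_radius_tolerance: float = 0.45
    peptide_bond_max: float = 1.8
    disulfide_max: float = 2.5
    max_h_attach: float = 1.6
    # Hydrogen bond: 12-10 potential with cos^4 angular modulation,
    # evaluated at the donor-acceptor distance R and the D-H...A angle.
    hbond_well_depth: float = 33.5       # kJ/mol
    hbond_r0: float = 2.8                # Å, equilibrium donor-acceptor
    hbond_da_max: float = 3.5            # Å, detection
    hbond_angle_min: float = 100.0       # degrees, D-H...A detection
    # Hydrophobic contacts: Lennard-Jones-type well between apolar C/S.
    hydrophobic_epsilon: float = 2.0     # kJ/mol well depth
    hydrophobic_rmin: float = 4.0        # Å, well position
    hydrophobic_cutoff: float = 5.0      # Å, detection
    # Electrostatics: Coulomb with distance-dependent screening eps(r)=k*r.
    coulomb_constant: float = 1389.35    # kJ Å / (mol e^2)
    dielectric_slope: float = 4.0
    electrostatic_cutoff: float = 5.0    # Å, detection
    charges: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CHARGES)
    )
    # Pi-stacking: constant well inside a ring-centroid window.
    pi_pi_energy: float = 8.0            # kJ/mol
    pi_pi_centroid_max: float = 5.5      # Å, detection

    def covalent_energy(self, el_a: str, el_b: str, order: float = 1) -> float:
        key = (*sorted((el_a.upper(), el_b.upper())), float(order))
        return self.covalent_energies.get(key, self.covalent_default)

    def covalent_radius(self, element: str) -> float:
        return COVALENT_RADII.get(element.upper(), 1.2)

    @classmethod
    def from_dict(cls, overrides: dict) -> "EnergyParameters":
        params = cls()
        for key, value in overrides.items():
            if not hasattr(params, key):
                raise KeyError(f"unknown energy parameter {key!r}")
            current = getattr(params, key)
            if isinstance(current, dict) and isinstance(value, dict):
                merged = dict(current)
                merged.update(value)
                value = merged
            setattr(params, key, value)
        return params

    @classmethod
    def from_yaml(cls, text: str) -> "EnergyParameters":
        data = yaml.safe_load(text) or {}
        # allow "C,C,1: 346"-style keys for the covalent table
        if "covalent_energies" in data:
            table = {}
            for key, val in data["covalent_energies"].items():
                if isinstance(key, str):
                    el_a, el_b, order = key.split(",")
                    key = (*sorted((el_a.strip(), el_b.strip())), float(order))
                table[key] = float(val)
            data["covalent_energies"] = table
        if "charges" in data:
            charges = {}
            for key, val in data["charges"].items():
                if isinstance(key, str):
                    res, atom = key.split(",")
                    key = (res.strip(), atom.strip())
                charges[key] = float(val)
            data["charges"] = charges
        return cls.from_dict(data)


@dataclass
class AtomisticGraph:
    """Atoms as nodes plus typed weighted bonds, with coordinates.

    ``residue_of[i]`` indexes into ``residue_keys``; synthetic graphs
    (see :mod:`bondprop.fixtures`) populate the same fields without a
    backing :class:`~bondprop.structure_io.StructureModel`.
    """

    coords: np.ndarray                      # (n, 3)
    bonds: list[Bond]
    residue_of: np.ndarray                  # (n,) int, residue index per node
    residue_keys: list[tuple]               # residue index -> key
    categories: list[str]                   # per node
    atom_names: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_of = np.asarray(self.residue_of, dtype=int)
        if not self.atom_names:
            self.atom_names = [f"X{i}" for i in range(self.n)]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        return len(self.bonds)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    def edge_array(self) -> np.ndarray:
        return np.array([(b.i, b.j) for b in self.bonds], dtype=int).reshape(-1, 2)

    def weight_array(self) -> np.ndarray:
        return np.array([b.weight for b in self.bonds], dtype=float)

    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self.bonds], dtype=float).reshape(-1, 3)

    def adjacency(self) -> csc_matrix:
        edges = self.edge_array()
        w = self.weight_array()
        rows = np.concatenate([edges[:, 0], edges[:, 1]])
        cols = np.concatenate([edges[:, 1], edges[:, 0]])
        data = np.concatenate([w, w])
        return csc_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def atoms_of_residue(self) -> dict[int, np.ndarray]:
        order = np.argsort(self.residue_of, kind="stable")
        split = np.searchsorted(
            self.residue_of[order], np.arange(self.n_residues + 1)
        )
        return {
            r: order[split[r]: split[r + 1]] for r in range(self.n_residues)
        }

    def bonds_of_residue(self, exclusive: bool = False) -> dict[int, list[int]]:
        """Residue index -> edge ids with >=1 endpoint in the residue.

        ``exclusive=True`` assigns each bond to the residue of its first
        endpoint only, making membership a partition.
        """
        out: dict[int, list[int]] = {r: [] for r in range(self.n_residues)}
        for bond in self.bonds:
            ri = int(self.residue_of[bond.i])
            rj = int(self.residue_of[bond.j])
            out[ri].append(bond.edge_id)
            if not exclusive and rj != ri:
                out[rj].append(bond.edge_id)
        return out

    def residue_category(self, residue_index: int) -> str:
        members = np.nonzero(self.residue_of == residue_index)[0]
        return self.categories[members[0]] if members.size else "other"

    def edge_table(self) -> str:
        """Tab-separated edge list for debugging."""
        lines = ["atom_i\tatom_j\tkind\tweight\tdistance"]
        for b in self.bonds:
            d = float(np.linalg.norm(self.coords[b.i] - self.coords[b.j]))
            lines.append(
                f"{self.atom_names[b.i]}\t{self.atom_names[b.j]}\t{b.kind}"
                f"\t{b.weight:.4f}\t{d:.3f}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# covalent detection
# ---------------------------------------------------------------------------

def _midpoint(coords: np.ndarray, i: int, j: int) -> tuple[float, float, float]:
    mid = 0.5 * (coords[i] + coords[j])
    return (float(mid[0]), float(mid[1]), float(mid[2]))


def detect_covalent(
    model: StructureModel, params: EnergyParameters | None = None
) -> list[Bond]:
    """Covalent bonds: residue templates for the 20 standard amino
    acids, nearest-heavy attachment for hydrogens, peptide links,
    disulfides, and distance-criterion bonds for hetero groups."""
    params = params or EnergyParameters()
    coords = model.coords()
    bonds: list[Bond] = []
    seen: set[frozenset[int]] = set()

    def add(i: int, j: int, order: float = 1) -> None:
        key = frozenset((i, j))
        if key in seen:
            return
        seen.add(key)
        energy = params.covalent_energy(
            model.atoms[i].element, model.atoms[j].element, order
        )
        bonds.append(Bond(i, j, energy, "covalent", _midpoint(coords, i, j)))

    residues = model.residues
    res_items = list(residues.items())

    for (chain, res_name, res_seq, icode), idxs in res_items:
        atom_by_name = {model.atoms[i].name: i for i in idxs}
        heavy = [i for i in idxs if not model.atoms[i].is_hydrogen]
        hydrogens = [i for i in idxs if model.atoms[i].is_hydrogen]
        template = template_bonds(res_name)
        if template is not None and model.atoms[idxs[0]].category == "protein":
            for name_a, name_b, order in template:
                ia, ib = atom_by_name.get(name_a), atom_by_name.get(name_b)
                if ia is not None and ib is not None:
                    add(ia, ib, order)
            # C-terminal carboxylate oxygen
            if "OXT" in atom_by_name and "C" in atom_by_name:
                add(atom_by_name["C"], atom_by_name["OXT"], 1)
            # hydrogens: nearest heavy atom in the same residue
            for ih in hydrogens:
                if not heavy:
                    continue
                dists = np.linalg.norm(coords[heavy] - coords[ih], axis=1)
                nearest = heavy[int(np.argmin(dists))]
                if dists.min() > params.max_h_attach:
                    model.log.append(
                        f"warning: H {model.atoms[ih].name} of "
                        f"{chain}/{res_name}{res_seq} attaches at "
                        f"{dists.min():.2f} Å"
                    )
                add(ih, nearest, 1)
        else:
            # non-template group: pure distance criterion via covalent radii
            n_found = _distance_bonds(model, coords, idxs, params, add)
            if len(idxs) > 1 and n_found == 0:
                model.log.append(
                    f"warning: no distance-resolvable bonds in non-template "
                    f"group {chain}/{res_name}{res_seq}; skipped"
                )

    # peptide bonds between consecutive residues of the same chain
    # (sorted by author numbering so atom input order does not matter)
    protein_items = sorted(
        (item for item in res_items if model.atoms[item[1][0]].category == "protein"),
        key=lambda item: (item[0][0], item[0][2], item[0][3]),
    )
    for (key_a, idxs_a), (key_b, idxs_b) in zip(protein_items, protein_items[1:]):
        if key_a[0] != key_b[0]:
            continue
        name_a = {model.atoms[i].name: i for i in idxs_a}
        name_b = {model.atoms[i].name: i for i in idxs_b}
        ic, in_ = name_a.get("C"), name_b.get("N")
        if ic is None or in_ is None:
            continue
        if np.linalg.norm(coords[ic] - coords[in_]) <= params.peptide_bond_max:
            add(ic, in_, 1)

    # disulfides
    sg = [
        i
        for i, a in enumerate(model.atoms)
        if a.res_name == "CYS" and a.name == "SG"
    ]
    for a_pos, ia in enumerate(sg):
        for ib in sg[a_pos + 1:]:
            if np.linalg.norm(coords[ia] - coords[ib]) <= params.disulfide_max:
                add(ia, ib, 1)

    # covalent links between hetero groups and anything else (distance
    # criterion between heavy atoms, e.g. glycosylation, metal bonds)
    hetero_heavy = [
        i
        for i, a in enumerate(model.atoms)
        if a.category in ("ligand", "other-hetero") and not a.is_hydrogen
    ]
    other_heavy = [
        i for i, a in enumerate(model.atoms) if not a.is_hydrogen
    ]
    if hetero_heavy and len(other_heavy) > len(hetero_heavy):
        tree = cKDTree(coords[other_heavy])
        for ih in hetero_heavy:
            r_h = params.covalent_radius(model.atoms[ih].element)
            max_r = r_h + 2.03 + params.covalent_radius_tolerance
            for pos in tree.query_ball_point(coords[ih], max_r):
                io = other_heavy[pos]
                if io == ih:
                    continue
                if model.atoms[io].residue_key == model.atoms[ih].residue_key:
                    continue
                limit = (
                    r_h
                    + params.covalent_radius(model.atoms[io].element)
                    + params.covalent_radius_tolerance
                )
                if np.linalg.norm(coords[ih] - coords[io]) <= limit:
                    add(ih, io, 1)

    return bonds


def _distance_bonds(model, coords, idxs, params, add) -> int:
    """Covalent bonds within one atom group by the covalent-radius
    criterion; returns the number of bonds added."""
    found = 0
    for pos, ia in enumerate(idxs):
        for ib in idxs[pos + 1:]:
            at_a, at_b = model.atoms[ia], model.atoms[ib]
            limit = (
                params.covalent_radius(at_a.element)
                + params.covalent_radius(at_b.element)
                + params.covalent_radius_tolerance
            )
            if at_a.is_hydrogen and at_b.is_hydrogen:
                continue
            if np.linalg.norm(coords[ia] - coords[ib]) <= limit:
                add(ia, ib, 1)
                found += 1
    return found


# ---------------------------------------------------------------------------
# non-covalent detection
# ---------------------------------------------------------------------------

def _neighbour_map(n_atoms: int, covalent: Iterable[Bond]) -> list[set[int]]:
    nbrs: list[set[int]] = [set() for _ in range(n_atoms)]
    for b in covalent:
        nbrs[b.i].add(b.j)
        nbrs[b.j].add(b.i)
    return nbrs


def _excluded(i: int, j: int, nbrs: list[set[int]]) -> bool:
    """True for covalently bonded (1-2) or angle (1-3) pairs."""
    return j in nbrs[i] or bool(nbrs[i] & nbrs[j])


def mayo_hbond_energy(
    r_da: float, angle_dha_deg: float, params: EnergyParameters
) -> float:
    """12-10 donor-acceptor potential with cos^4 angular modulation
    (attractive well returned as a magnitude)."""
    ratio = params.hbond_r0 / r_da
    radial = params.hbond_well_depth * (5.0 * ratio**12 - 6.0 * ratio**10)
    angular = math.cos(math.radians(angle_dha_deg)) ** 4
    return abs(radial * angular)


def lj_hydrophobic_energy(r: float, params: EnergyParameters) -> float:
    ratio = params.hydrophobic_rmin / r
    return abs(params.hydrophobic_epsilon * (ratio**12 - 2.0 * ratio**6))


def screened_coulomb_energy(
    q_a: float, q_b: float, r: float, params: EnergyParameters
) -> float:
    """Coulomb energy magnitude with distance-dependent dielectric
    eps(r) = slope * r."""
    return abs(params.coulomb_constant * q_a * q_b / (params.dielectric_slope * r * r))


def detect_noncovalent(
    model: StructureModel,
    params: EnergyParameters | None = None,
    covalent: Sequence[Bond] | None = None,
) -> list[Bond]:
    """Hydrogen bonds, hydrophobic contacts, salt bridges and
    pi-stacking edges passing each type's geometric criteria.

    ``covalent`` (from :func:`detect_covalent`) is used to exclude
    bonded and 1-3 pairs; it is recomputed when omitted.
    """
    params = params or EnergyParameters()
    if covalent is None:
        covalent = detect_covalent(model, params)
    coords = model.coords()
    nbrs = _neighbour_map(len(model.atoms), covalent)
    bonds: list[Bond] = []
    bonds += _detect_hbonds(model, coords, nbrs, params)
    bonds += _detect_hydrophobic(model, coords, nbrs, params)
    bonds += _detect_electrostatic(model, coords, nbrs, params)
    bonds += _detect_pi_pi(model, coords, params)
    return bonds


def _is_donor_heavy(model, i, nbrs) -> bool:
    atom = model.atoms[i]
    if atom.element not in ("N", "O", "S"):
        return False
    return any(model.atoms[j].is_hydrogen for j in nbrs[i])


def _is_acceptor(model, i, nbrs) -> bool:
    atom = model.atoms[i]
    if atom.element == "O":
        return True
    if atom.element == "N":
        has_h = any(model.atoms[j].is_hydrogen for j in nbrs[i])
        return not has_h and len(nbrs[i]) < 3
    return False


def _detect_hbonds(model, coords, nbrs, params) -> list[Bond]:
    donors = []  # (heavy, hydrogen)
    for i in range(len(model.atoms)):
        if _is_donor_heavy(model, i, nbrs):
            for j in nbrs[i]:
                if model.atoms[j].is_hydrogen:
                    donors.append((i, j))
    acceptors = [
        i for i in range(len(model.atoms)) if _is_acceptor(model, i, nbrs)
    ]
    out: list[Bond] = []
    if not donors or not acceptors:
        return out
    acc_tree = cKDTree(coords[acceptors])
    for heavy, hyd in donors:
        for pos in acc_tree.query_ball_point(coords[heavy], params.hbond_da_max):
            acc = acceptors[pos]
            if acc in (heavy, hyd):
                continue
            if model.atoms[acc].residue_key == model.atoms[heavy].residue_key:
                continue
            if _excluded(hyd, acc, nbrs) or _excluded(heavy, acc, nbrs):
                continue
            r_da = float(np.linalg.norm(coords[heavy] - coords[acc]))
            v1 = coords[heavy] - coords[hyd]
            v2 = coords[acc] - coords[hyd]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cosang = float(np.clip(v1 @ v2 / denom, -1.0, 1.0))
            angle = math.degrees(math.acos(cosang))
            if angle < params.hbond_angle_min:
                continue
            energy = mayo_hbond_energy(r_da, angle, params)
            if energy <= 0:
                continue
            out.append(
                Bond(hyd, acc, energy, "hydrogen_bond", _midpoint(coords, hyd, acc))
            )
    return out


def _is_hydrophobic(model, i, nbrs) -> bool:
    atom = model.atoms[i]
    if atom.element not in ("C", "S"):
        return False
    return not any(model.atoms[j].element in ("N", "O") for j in nbrs[i])


def _detect_hydrophobic(model, coords, nbrs, params) -> list[Bond]:
    apolar = [i for i in range(len(model.atoms)) if _is_hydrophobic(model, i, nbrs)]
    out: list[Bond] = []
    if len(apolar) < 2:
        return out
    tree = cKDTree(coords[apolar])
    for pos_a, pos_b in tree.query_pairs(params.hydrophobic_cutoff):
        ia, ib = apolar[pos_a], apolar[pos_b]
        if model.atoms[ia].residue_key == model.atoms[ib].residue_key:
            continue
        if _excluded(ia, ib, nbrs):
            continue
        r = float(np.linalg.norm(coords[ia] - coords[ib]))
        energy = lj_hydrophobic_energy(r, params)
        if energy <= 0:
            continue
        out.append(Bond(ia, ib, energy, "hydrophobic", _midpoint(coords, ia, ib)))
    return out


def _detect_electrostatic(model, coords, nbrs, params) -> list[Bond]:
    charged = [
        (i, params.charges[(a.res_name, a.name)])
        for i, a in enumerate(model.atoms)
        if (a.res_name, a.name) in params.charges
    ]
    out: list[Bond] = []
    for pos_a, (ia, qa) in enumerate(charged):
        for ib, qb in charged[pos_a + 1:]:
            if qa * qb >= 0:
                continue
            if model.atoms[ia].residue_key == model.atoms[ib].residue_key:
                continue
            if _excluded(ia, ib, nbrs):
                continue
            r = float(np.linalg.norm(coords[ia] - coords[ib]))
            if r > params.electrostatic_cutoff or r == 0:
                continue
            energy = screened_coulomb_energy(qa, qb, r, params)
            out.append(
                Bond(ia, ib, energy, "electrostatic", _midpoint(coords, ia, ib))
            )
    return out


def _detect_pi_pi(model, coords, params) -> list[Bond]:
    rings: list[tuple[list[int], np.ndarray]] = []
    for key, idxs in model.residues.items():
        ring_names = AROMATIC_RINGS.get(key[1])
        if not ring_names:
            continue
        by_name = {model.atoms[i].name: i for i in idxs}
        for names in ring_names:
            members = [by_name[n] for n in names if n in by_name]
            if len(members) == len(names):
                rings.append((members, coords[members].mean(axis=0)))
    out: list[Bond] = []
    for pos_a, (ring_a, cen_a) in enumerate(rings):
        for ring_b, cen_b in rings[pos_a + 1:]:
            if set(ring_a) & set(ring_b):
                continue  # fused rings of the same TRP
            if (
                model.atoms[ring_a[0]].residue_key
                == model.atoms[ring_b[0]].residue_key
            ):
                continue
            if np.linalg.norm(cen_a - cen_b) > params.pi_pi_centroid_max:
                continue
            # connect the closest atom pair between the rings
            sub = coords[ring_a][:, None, :] - coords[ring_b][None, :, :]
            dist = np.linalg.norm(sub, axis=2)
            a_pos, b_pos = np.unravel_index(np.argmin(dist), dist.shape)
            ia, ib = ring_a[int(a_pos)], ring_b[int(b_pos)]
            out.append(
                Bond(ia, ib, params.pi_pi_energy, "pi_pi", _midpoint(coords, ia, ib))
            )
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_graph(
    model: StructureModel, params: EnergyParameters | None = None
) -> AtomisticGraph:
    """Merge covalent and non-covalent edges into an
    :class:`AtomisticGraph`; duplicate atom pairs keep the strongest
    edge; degree-0 atoms are dropped with a log entry."""
    params = params or EnergyParameters()
    covalent = detect_covalent(model, params)
    noncovalent = detect_noncovalent(model, params, covalent=covalent)

    best: dict[frozenset[int], Bond] = {}
    for bond in covalent + noncovalent:
        key = frozenset((bond.i, bond.j))
        if key not in best or bond.weight > best[key].weight:
            best[key] = bond
    merged = list(best.values())
    if not merged:
        raise ValueError(f"graph construction produced no edges for {model.source}")

    connected = sorted({i for b in merged for i in (b.i, b.j)})
    remap = {old: new for new, old in enumerate(connected)}
    dropped = len(model.atoms) - len(connected)
    log = list(model.log)
    if dropped:
        log.append(f"dropped {dropped} degree-0 atoms")

    residue_keys: list[tuple] = []
    res_index: dict[tuple, int] = {}
    residue_of = np.empty(len(connected), dtype=int)
    categories: list[str] = []
    atom_names: list[str] = []
    coords = model.coords()[connected]
    for new, old in enumerate(connected):
        atom = model.atoms[old]
        key = atom.residue_key
        if key not in res_index:
            res_index[key] = len(residue_keys)
            residue_keys.append(key)
        residue_of[new] = res_index[key]
        categories.append(atom.category)
        atom_names.append(f"{atom.chain}/{atom.res_name}{atom.res_seq}/{atom.name}")

    bonds = [
        replace(b, i=remap[b.i], j=remap[b.j], edge_id=eid)
        for eid, b in enumerate(
            sorted(merged, key=lambda b: (min(b.i, b.j), max(b.i, b.j)))
        )
    ]
    counts: dict[str, int] = {}
    for b in bonds:
        counts[b.kind] = counts.get(b.kind, 0) + 1
    log.append(
        f"graph: n={len(connected)} m={len(bonds)} "
        + " ".join(f"{k}={v}" for k, v in sorted(counts.items()))
    )
    return AtomisticGraph(
        coords=coords,
        bonds=bonds,
        residue_of=residue_of,
        residue_keys=residue_keys,
        categories=categories,
        atom_names=atom_names,
        log=log,
    )


def incidence_and_weights(graph: AtomisticGraph) -> tuple[csc_matrix, csc_matrix]:
    """Signed incidence matrix B (n x m, one +1 and one -1 per column,
    orientation i->j) and diagonal weight matrix W (m x m)."""
    if graph.m == 0:
        raise ValueError("graph has no edges")
    edges = graph.edge_array()
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([np.arange(graph.m), np.arange(graph.m)])
    data = np.concatenate([np.ones(graph.m), -np.ones(graph.m)])
    B = csc_matrix((data, (rows, cols)), shape=(graph.n, graph.m))
    W = diags(graph.weight_array(), format="csc")
    return B, W
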