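"""Synthetic, download-free inputs for tests and calibration.

Three generators, each fully determined by its spec (seed mandatory,
planted truth emitted alongside the data):

* :func:`make_mini_pdb` — a geometrically idealised ALA/GLY peptide
  (optionally with a pseudo-ligand planted to form a hydrogen bond)
  written as PDB text plus a truth table of intended contacts;
* :func:`make_random_graph` — a connected, weighted geometric graph
  with coordinates and block residue grouping, compatible with
  :class:`~bondprop.graph_construction.AtomisticGraph`;
* :func:`make_planted_decay` — (propensity, distance) samples with a
  known log-linear decay for quantile-scoring tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from bondprop.graph_construction import (
    AtomisticGraph,
    Bond,
    EnergyParameters,
    mayo_hbond_energy,
)
from bondprop.residue_templates import template_hydrogen_count

__all__ = [
    "MiniPdbSpec",
    "RandomGraphSpec",
    "PlantedDecaySpec",
    "make_mini_pdb",
    "make_random_graph",
    "make_planted_decay",
]


# ---------------------------------------------------------------------------
# mini PDB generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiniPdbSpec:
    sequence: str = "AAAA"          # A (ALA) and G (GLY) only
    seed: int = 0
    conformation: str = "extended"  # extended | helix
    with_ligand: bool = False
    ligand_donor_residue: int | None = None  # residue index whose N-H is the donor
    chain: str = "A"


_BACKBONE = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "ang_n_ca_c": 111.0,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8,
}
_TORSIONS = {"extended": (-140.0, 135.0), "helix": (-57.0, -47.0)}


def _place(a, b, c, r, theta_deg, phi_deg):
    """Position a fourth atom from three reference atoms by internal
    coordinates (bond length r, angle theta at c, torsion phi)."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(phi),
            r * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _unit(v):
    return v / np.linalg.norm(v)


def _tetra_pair(center, u1, u2, length):
    """Two positions completing a tetrahedron around ``center`` whose
    two existing substituents point along u1, u2 (unit vectors)."""
    bisector = -_unit(u1 + u2)
    normal = _unit(np.cross(u1, u2))
    alpha = math.radians(54.75)
    return (
        center + length * (bisector * math.cos(alpha) + normal * math.sin(alpha)),
        center + length * (bisector * math.cos(alpha) - normal * math.sin(alpha)),
    )


def _methyl_hydrogens(c_pos, axis_from, length=1.09):
    """Three staggered hydrogens around a methyl carbon."""
    axis = _unit(c_pos - axis_from)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp1 = _unit(np.cross(axis, ref))
    perp2 = np.cross(axis, perp1)
    out = []
    for k in range(3):
        ang = math.radians(120.0 * k + 60.0)
        direction = _unit(
            axis * math.cos(math.radians(70.5))
            + (perp1 * math.cos(ang) + perp2 * math.sin(ang))
            * math.sin(math.radians(70.5))
        )
        out.append(c_pos + length * direction)
    return out


def make_mini_pdb(spec: MiniPdbSpec) -> tuple[str, dict]:
    """Build an idealised peptide as PDB text plus a truth table.

    The truth table records declared atom/residue counts, the expected
    covalent bond count of the assembled graph, and (when a ligand is
    planted) the intended hydrogen bond with its geometry and the energy
    of the default 12-10 potential at that geometry.
    """
    seq = spec.sequence.upper()
    if len(seq) < 2:
        raise ValueError("need at least 2 residues")
    if set(seq) - {"A", "G"}:
        raise ValueError("sequence may contain only A and G")
    phi, psi = _TORSIONS[spec.conformation]

    residues: list[dict] = []  # name -> coord per residue
    prev = None
    for i, code in enumerate(seq):
        atoms: dict[str, np.ndarray] = {}
        if i == 0:
            atoms["N"] = np.zeros(3)
            atoms["CA"] = np.array([_BACKBONE["n_ca"], 0.0, 0.0])
            atoms["C"] = _place(
                np.array([0.0, 1.0, 0.0]),
                atoms["N"],
                atoms["CA"],
                _BACKBONE["ca_c"],
                _BACKBONE["ang_n_ca_c"],
                0.0,
            )
        else:
            atoms["N"] = _place(
                prev["N"], prev["CA"], prev["C"],
                _BACKBONE["c_n"], _BACKBONE["ang_ca_c_n"], psi,
            )
            atoms["CA"] = _place(
                prev["CA"], prev["C"], atoms["N"],
                _BACKBONE["n_ca"], _BACKBONE["ang_c_n_ca"], 180.0,
            )
            atoms["C"] = _place(
                prev["C"], atoms["N"], atoms["CA"],
                _BACKBONE["ca_c"], _BACKBONE["ang_n_ca_c"], phi,
            )
        # carbonyl O anti to the following N (torsion N-CA-C-O = psi+180)
        atoms["O"] = _place(
            atoms["N"], atoms["CA"], atoms["C"],
            _BACKBONE["c_o"], _BACKBONE["ang_ca_c_o"], psi + 180.0,
        )
        residues.append({"code": code, "xyz": atoms})
        prev = atoms

    # C-terminal OXT at the position the next N would occupy
    last = residues[-1]["xyz"]
    last["OXT"] = _place(
        last["N"], last["CA"], last["C"],
        _BACKBONE["c_o"], _BACKBONE["ang_ca_c_o"], psi,
    )

    # hydrogens and CB
    for i, res in enumerate(residues):
        xyz = res["xyz"]
        n, ca, c = xyz["N"], xyz["CA"], xyz["C"]
        if i == 0:
            h_dir = _unit(_unit(n - ca) + np.array([0.0, 0.0, 1.0]))
        else:
            cp = residues[i - 1]["xyz"]["C"]
            h_dir = -_unit(_unit(ca - n) + _unit(cp - n))
        xyz["H"] = n + 1.01 * h_dir
        u1, u2 = _unit(n - ca), _unit(c - ca)
        pos_up, pos_down = _tetra_pair(ca, u1, u2, 1.53)
        if res["code"] == "A":
            xyz["CB"] = pos_up
            xyz["HA"] = ca + (1.09 / 1.53) * (pos_down - ca)
            for k, hpos in enumerate(_methyl_hydrogens(xyz["CB"], ca), start=1):
                xyz[f"HB{k}"] = hpos
        else:  # GLY
            xyz["HA2"] = ca + (1.09 / 1.53) * (pos_up - ca)
            xyz["HA3"] = ca + (1.09 / 1.53) * (pos_down - ca)

    truth: dict = {"sequence": seq, "seed": spec.seed}
    ligand_atoms: dict[str, np.ndarray] = {}
    if spec.with_ligand:
        donor_idx = (
            spec.ligand_donor_residue
            if spec.ligand_donor_residue is not None
            else len(seq) // 2
        )
        dxyz = residues[donor_idx]["xyz"]
        direction = _unit(dxyz["H"] - dxyz["N"])
        o1 = dxyz["H"] + 1.9 * direction
        c2 = o1 + 1.23 * direction
        side = _unit(np.cross(direction, np.array([0.0, 0.0, 1.0])))
        if not np.all(np.isfinite(side)):
            side = np.array([0.0, 1.0, 0.0])
        c3 = c2 + 1.5 * _unit(direction * 0.3 + side)
        ligand_atoms = {"O1": o1, "C2": c2, "C3": c3}
        r_da = float(np.linalg.norm(o1 - dxyz["N"]))
        truth["planted_hbond"] = {
            "donor_residue": donor_idx,
            "donor_atom": "N",
            "hydrogen": "H",
            "acceptor_atom": "O1",
            "r_donor_acceptor": r_da,
            "angle_dha": 180.0,
            "energy": mayo_hbond_energy(r_da, 180.0, EnergyParameters()),
        }

    # serialise
    lines = []
    serial = 0
    order = ["N", "CA", "C", "O", "CB", "OXT", "H", "HA", "HA2", "HA3",
             "HB1", "HB2", "HB3"]
    n_atoms = 0
    expected_covalent = 0
    for i, res in enumerate(residues):
        res_name = "ALA" if res["code"] == "A" else "GLY"
        n_heavy = 4 if res["code"] == "G" else 5  # backbone (+CB for ALA)
        # heavy template bonds form a tree (n_heavy - 1) plus one bond per H
        expected_covalent += (n_heavy - 1) + template_hydrogen_count(res_name)
        for name in order:
            if name not in res["xyz"]:
                continue
            serial += 1
            n_atoms += 1
            x, y, z = res["xyz"][name]
            element = name[0] if name[0] != "H" else "H"
            pad_name = f" {name:<3}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:>5} {pad_name:<4} {res_name:>3} "
                f"{spec.chain:1}{i + 1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2}"
            )
    expected_covalent += len(seq) - 1  # peptide C-N links
    expected_covalent += 1             # C-OXT

    for name, xyz in ligand_atoms.items():
        serial += 1
        n_atoms += 1
        x, y, z = xyz
        element = name[0]
        lines.append(
            f"HETATM{serial:>5}  {name:<3} LIG {spec.chain:1} 900    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2}"
        )
    if ligand_atoms:
        expected_covalent += 2  # O1-C2, C2-C3 by distance criterion

    lines.append("END")
    truth.update(
        {
            "atom_count": n_atoms,
            "residue_count": len(seq) + (1 if ligand_atoms else 0),
            "protein_residue_count": len(seq),
            "expected_covalent_bonds": expected_covalent,
            "has_ligand": bool(ligand_atoms),
        }
    )
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# random weighted graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomGraphSpec:
    n_nodes: int = 30
    seed: int = 0
    k_neighbours: int = 3
    block_size: int = 4       # atoms per pseudo-residue
    box_side: float | None = None
    weight_sigma: float = 0.5


def make_random_graph(spec: RandomGraphSpec) -> AtomisticGraph:
    """Connected weighted geometric graph with coordinates and block
    residue grouping (identical output for identical specs)."""
    if spec.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    rng = np.random.default_rng(spec.seed)
    side = spec.box_side or max(10.0, 2.5 * spec.n_nodes ** (1 / 3) * 2)
    coords = rng.uniform(0, side, size=(spec.n_nodes, 3))

    edges: set[tuple[int, int]] = set()
    # spanning path over a random permutation guarantees connectivity
    perm = rng.permutation(spec.n_nodes)
    for a, b in zip(perm, perm[1:]):
        edges.add((min(a, b), max(a, b)))
    # k nearest neighbours make the graph geometric (local edges)
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    _, nbrs = tree.query(coords, k=spec.k_neighbours + 1)
    for i in range(spec.n_nodes):
        for j in nbrs[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))

    weights = rng.lognormal(mean=0.0, sigma=spec.weight_sigma, size=len(edges))
    bonds = []
    for eid, ((i, j), w) in enumerate(zip(sorted(edges), weights)):
        mid = 0.5 * (coords[i] + coords[j])
        bonds.append(
            Bond(
                i=i,
                j=j,
                weight=float(w),
                kind="covalent",
                midpoint=(float(mid[0]), float(mid[1]), float(mid[2])),
                edge_id=eid,
            )
        )
    residue_of = np.arange(spec.n_nodes) // spec.block_size
    n_res = int(residue_of.max()) + 1
    return AtomisticGraph(
        coords=coords,
        bonds=bonds,
        residue_of=residue_of,
        residue_keys=[("A", "RES", r + 1, "") for r in range(n_res)],
        categories=["protein"] * spec.n_nodes,
        atom_names=[f"A/RES{r + 1}/X{i}" for i, r in enumerate(residue_of)],
    )


# ---------------------------------------------------------------------------
# planted decay samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedDecaySpec:
    n_points: int = 1000
    seed: int = 0
    intercept: float = -3.0
    slope: float = -0.3
    noise_sigma: float = 1.0
    d_max: float = 30.0


def make_planted_decay(spec: PlantedDecaySpec) -> tuple[np.ndarray, np.ndarray]:
    """(propensity, distance) samples with log(pi) = a + b*d + noise."""
    if spec.n_points < 100:
        raise ValueError("need at least 100 points")
    rng = np.random.default_rng(spec.seed)
    d = rng.uniform(0.0, spec.d_max, size=spec.n_points)
    log_pi = (
        spec.intercept
        + spec.slope * d
        + spec.noise_sigma * rng.standard_normal(spec.n_points)
    )
    return np.exp(log_pi), d
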