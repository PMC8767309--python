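"""Edge-to-edge coupling propensities on the energy-weighted graph.

The transfer matrix M = (1/2) W B^T L+ B couples every edge to every
other edge through the pseudoinverse of the weighted Laplacian.  Raw
propensities sum |M_{b,b'}| over a set of source edges b'.  Rather than
forming L+ (dense, O(n^3)), one sparse Laplacian solve is performed per
source edge: columns of B sum to zero, so any solution of L x = B[:, b']
on the source's connected component yields the same B^T x as the
pseudoinverse solution, and cost scales near-linearly with edge count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu
from scipy.spatial.distance import cdist

from bondprop.graph_construction import AtomisticGraph, incidence_and_weights

__all__ = [
    "PerturbationSource",
    "PropensityField",
    "weighted_laplacian",
    "raw_propensities",
    "normalize",
    "residue_propensities",
    "distances",
    "compute_field",
    "source_from_residues",
    "source_from_ligand",
]


@dataclass(frozen=True)
class PerturbationSource:
    """A set of graph edges acting as the perturbation origin."""

    source_edges: frozenset[int]
    description: str = "perturbation source"

    def __post_init__(self) -> None:
        if not self.source_edges:
            raise ValueError("perturbation source has no edges")

    def validate(self, graph: AtomisticGraph) -> None:
        bad = [e for e in self.source_edges if not 0 <= e < graph.m]
        if bad:
            raise ValueError(f"source edges not in graph: {sorted(bad)[:5]}")
        adj = graph.adjacency()
        _, labels = connected_components(adj, directed=False)
        comps = {
            labels[graph.bonds[e].i] for e in self.source_edges
        }
        if len(comps) > 1:
            raise ValueError(
                "source edges span multiple connected components"
            )


def source_from_residues(
    graph: AtomisticGraph, residue_indices: set[int], description: str = ""
) -> PerturbationSource:
    """All edges with at least one endpoint in the listed residues."""
    wanted = set(residue_indices)
    edges = frozenset(
        b.edge_id
        for b in graph.bonds
        if int(graph.residue_of[b.i]) in wanted or int(graph.residue_of[b.j]) in wanted
    )
    return PerturbationSource(
        edges, description or f"residues {sorted(wanted)}"
    )


def source_from_ligand(
    graph: AtomisticGraph, ligand_residues: set[int], description: str = ""
) -> PerturbationSource:
    """Non-covalent ligand-protein contact edges of the given ligand
    residues (ligand-internal covalent bonds excluded)."""
    wanted = set(ligand_residues)
    edges = set()
    for b in graph.bonds:
        ri, rj = int(graph.residue_of[b.i]), int(graph.residue_of[b.j])
        in_i, in_j = ri in wanted, rj in wanted
        if in_i == in_j:  # both inside or both outside
            continue
        if b.kind == "covalent":
            continue
        edges.add(b.edge_id)
    return PerturbationSource(
        frozenset(edges), description or f"ligand contacts {sorted(wanted)}"
    )


@dataclass
class PropensityField:
    """Raw/normalized bond propensities, residue propensities, and
    distances from the perturbation source."""

    raw: dict[int, float]
    normalized: dict[int, float]
    residue: dict[int, float]
    bond_distance: dict[int, float]
    residue_distance: dict[int, float]
    source: PerturbationSource
    log: list[str] = field(default_factory=list)


def weighted_laplacian(graph: AtomisticGraph) -> csc_matrix:
    """L = B W B^T: off-diagonals -w_ij, diagonal = weighted degree."""
    adj = graph.adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = -adj.tolil()
    lap.setdiag(deg)
    return lap.tocsc()


def raw_propensities(
    graph: AtomisticGraph, source: PerturbationSource
) -> dict[int, float]:
    """Pi_b^raw = sum over source edges b' of |M_{b,b'}|, via one
    Laplacian solve per source edge on the source's component."""
    source.validate(graph)
    adj = graph.adjacency()
    _, labels = connected_components(adj, directed=False)
    some_edge = next(iter(source.source_edges))
    comp = labels[graph.bonds[some_edge].i]

    nodes = np.nonzero(labels == comp)[0]
    local = -np.ones(graph.n, dtype=int)
    local[nodes] = np.arange(nodes.size)

    edges = graph.edge_array()
    weights = graph.weight_array()
    in_comp = labels[edges[:, 0]] == comp
    if not np.all(in_comp):
        n_out = int(np.sum(~in_comp))
        graph.log.append(
            f"{n_out} edges outside the source component contribute 0 propensity"
        )

    lap = weighted_laplacian(graph)
    sub = lap[np.ix_(nodes, nodes)].tocsc()
    # ground the first node of the component: the grounded solve differs
    # from the pseudoinverse solution only by a constant vector, which
    # B^T annihilates
    grounded = sub[1:, 1:].tocsc()
    solver = splu(grounded)

    li = local[edges[:, 0]]
    lj = local[edges[:, 1]]
    raw = np.zeros(graph.m, dtype=float)
    for b_src in sorted(source.source_edges):
        bond = graph.bonds[b_src]
        rhs = np.zeros(nodes.size)
        rhs[local[bond.i]] += 1.0
        rhs[local[bond.j]] -= 1.0
        x = np.zeros(nodes.size)
        x[1:] = solver.solve(rhs[1:])
        # M_{b, b'} = 0.5 * w_b * (x_i - x_j) for b = (i, j)
        col = np.zeros(graph.m)
        col[in_comp] = 0.5 * weights[in_comp] * (
            x[li[in_comp]] - x[lj[in_comp]]
        )
        raw += np.abs(col)
    return {int(e): float(v) for e, v in enumerate(raw)}


def normalize(raw: dict[int, float]) -> dict[int, float]:
    """Pi_b = Pi_b^raw / sum_b Pi_b^raw over the provided entries."""
    total = float(sum(raw.values()))
    if not total > 0:
        raise ValueError("degenerate source: all raw propensities are zero")
    return {e: v / total for e, v in raw.items()}


def residue_propensities(
    graph: AtomisticGraph,
    normalized: dict[int, float],
    exclusive: bool = False,
) -> dict[int, float]:
    """Pi_R = sum of normalized bond propensities of the bonds of R
    (an endpoint in R; ``exclusive=True`` partitions bonds by their
    first endpoint so the residue values sum to 1)."""
    membership = graph.bonds_of_residue(exclusive=exclusive)
    return {
        r: float(sum(normalized.get(e, 0.0) for e in edge_ids))
        for r, edge_ids in membership.items()
    }


def distances(
    graph: AtomisticGraph, source: PerturbationSource
) -> tuple[dict[int, float], dict[int, float]]:
    """Bond distances d_b (min midpoint-midpoint distance to a source
    bond) and residue distances d_R (min atom-atom distance between the
    residue's atoms and the atoms of the source edges)."""
    mids = graph.midpoints()
    src_ids = sorted(source.source_edges)
    src_mids = mids[src_ids]
    d_bond = cdist(mids, src_mids).min(axis=1)

    src_atoms = sorted(
        {i for e in src_ids for i in (graph.bonds[e].i, graph.bonds[e].j)}
    )
    src_coords = graph.coords[src_atoms]
    atom_d = cdist(graph.coords, src_coords).min(axis=1)
    d_res = {
        r: float(atom_d[members].min())
        for r, members in graph.atoms_of_residue().items()
        if members.size
    }
    return (
        {int(e): float(v) for e, v in enumerate(d_bond)},
        d_res,
    )


def compute_field(
    graph: AtomisticGraph,
    source: PerturbationSource,
    include_source_bonds: bool = False,
    exclusive_residue_membership: bool = False,
) -> PropensityField:
    """Full propensity field for one graph and source.

    Source bonds are by default excluded from the normalized field (they
    are the perturbation, not the response) and hence from residue
    propensities; ``include_source_bonds=True`` switches them back in.
    """
    raw = raw_propensities(graph, source)
    if include_source_bonds:
        kept = dict(raw)
    else:
        kept = {e: v for e, v in raw.items() if e not in source.source_edges}
    norm = normalize(kept)
    residue = residue_propensities(
        graph, norm, exclusive=exclusive_residue_membership
    )
    d_bond, d_res = distances(graph, source)
    return PropensityField(
        raw=raw,
        normalized=norm,
        residue=residue,
        bond_distance=d_bond,
        residue_distance=d_res,
        source=source,
        log=[
            f"source: {source.description} ({len(source.source_edges)} edges)",
            f"normalized over {len(norm)} bonds "
            f"(source bonds {'included' if include_source_bonds else 'excluded'})",
        ],
    )
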