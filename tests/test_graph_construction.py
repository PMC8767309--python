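import math

import numpy as np
import pytest

from bondprop.fixtures import MiniPdbSpec, make_mini_pdb
from bondprop.graph_construction import (
    EnergyParameters,
    assemble_graph,
    detect_covalent,
    detect_noncovalent,
    incidence_and_weights,
    mayo_hbond_energy,
    screened_coulomb_energy,
)
from bondprop.residue_templates import template_bonds, template_hydrogen_count
from bondprop.structure_io import parse_pdb
from tests.conftest import TOY_ALA


def pdb_line(serial, name, res_name, chain, res_seq, xyz, element, het=False):
    record = "HETATM" if het else "ATOM  "
    pad = f" {name:<3}" if len(name) < 4 else name
    x, y, z = xyz
    return (
        f"{record}{serial:>5} {pad:<4} {res_name:>3} {chain}{res_seq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
    )


def build_pdb(atoms):
    lines = [
        pdb_line(i + 1, *spec) for i, spec in enumerate(atoms)
    ]
    return "\n".join(lines) + "\nEND\n"


class TestDetectCovalent:
    def test_free_alanine_matches_template(self, dipeptide):
        text, _ = dipeptide
        model = parse_pdb(text)
        first = [a for a in model.atoms if a.res_seq == 1]
        sub = parse_pdb(
            build_pdb(
                [
                    (a.name, a.res_name, a.chain, a.res_seq, a.coords, a.element)
                    for a in first
                ]
            )
        )
        bonds = detect_covalent(sub)
        heavy_template = len(template_bonds("ALA"))
        expected = heavy_template + template_hydrogen_count("ALA")
        assert len(bonds) == expected

    def test_dipeptide_single_peptide_link(self, dipeptide):
        text, _ = dipeptide
        model = parse_pdb(text)
        bonds = detect_covalent(model)
        inter = [
            b
            for b in bonds
            if model.atoms[b.i].res_seq != model.atoms[b.j].res_seq
        ]
        assert len(inter) == 1
        names = {model.atoms[inter[0].i].name, model.atoms[inter[0].j].name}
        assert names == {"C", "N"}

    def test_disulfide_detected_at_2_05(self):
        # two stripped CYS side chains, SG-SG at 2.05 Å
        text = build_pdb(
            [
                ("CA", "CYS", "A", 1, (0.0, 0.0, 0.0), "C"),
                ("CB", "CYS", "A", 1, (1.53, 0.0, 0.0), "C"),
                ("SG", "CYS", "A", 1, (2.30, 1.55, 0.0), "S"),
                ("CA", "CYS", "A", 2, (7.20, 2.95, 0.0), "C"),
                ("CB", "CYS", "A", 2, (5.85, 2.25, 0.0), "C"),
                ("SG", "CYS", "A", 2, (4.35, 1.55, 0.0), "S"),
            ]
        )
        model = parse_pdb(text)
        d = np.linalg.norm(model.atoms[2].xyz - model.atoms[5].xyz)
        assert d == pytest.approx(2.05, abs=0.02)
        bonds = detect_covalent(model)
        ss = [
            b
            for b in bonds
            if {model.atoms[b.i].name, model.atoms[b.j].name} == {"SG"}
            and model.atoms[b.i].res_seq != model.atoms[b.j].res_seq
        ]
        assert len(ss) == 1
        params = EnergyParameters()
        assert ss[0].weight == params.covalent_energy("S", "S", 1)

    def test_covalent_weights_from_energy_table(self, dipeptide):
        text, _ = dipeptide
        model = parse_pdb(text)
        params = EnergyParameters()
        for b in detect_covalent(model, params):
            a1, a2 = model.atoms[b.i], model.atoms[b.j]
            assert b.weight > 0
            if {a1.name, a2.name} == {"C", "O"}:
                assert b.weight == params.covalent_energy("C", "O", 2)


class TestDetectNoncovalent:
    def test_planted_hbond_energy_matches_formula(self, pentapeptide_with_ligand):
        text, truth = pentapeptide_with_ligand
        model = parse_pdb(text)
        bonds = detect_noncovalent(model)
        hb = [b for b in bonds if b.kind == "hydrogen_bond"]
        assert len(hb) == 1
        planted = truth["planted_hbond"]
        params = EnergyParameters()
        # hand-evaluate the configured 12-10/cos^4 potential at the
        # observed geometry (PDB text rounds coords to 3 decimals)
        hyd, acc = hb[0].i, hb[0].j
        donor = next(
            i
            for i, a in enumerate(model.atoms)
            if a.res_seq == planted["donor_residue"] + 1 and a.name == "N"
        )
        r_da = float(np.linalg.norm(model.atoms[donor].xyz - model.atoms[acc].xyz))
        v1 = model.atoms[donor].xyz - model.atoms[hyd].xyz
        v2 = model.atoms[acc].xyz - model.atoms[hyd].xyz
        angle = math.degrees(
            math.acos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
        expected = params.hbond_well_depth * (
            5 * (params.hbond_r0 / r_da) ** 12 - 6 * (params.hbond_r0 / r_da) ** 10
        ) * math.cos(math.radians(angle)) ** 4
        assert hb[0].weight == pytest.approx(abs(expected), rel=1e-9)
        # and it agrees with the generator's declared truth up to rounding
        assert hb[0].weight == pytest.approx(planted["energy"], rel=0.02)

    def test_distant_donor_acceptor_no_edge(self):
        text = build_pdb(
            [
                ("N", "ALA", "A", 1, (0.0, 0.0, 0.0), "N"),
                ("H", "ALA", "A", 1, (1.01, 0.0, 0.0), "H"),
                ("O", "ALA", "A", 2, (16.0, 0.0, 0.0), "O"),
                ("C", "ALA", "A", 2, (17.2, 0.0, 0.0), "C"),
            ]
        )
        bonds = detect_noncovalent(parse_pdb(text))
        assert [b for b in bonds if b.kind == "hydrogen_bond"] == []

    def test_salt_bridge_energy(self):
        # LYS NZ+ and GLU OE- at 3.5 Å
        text = build_pdb(
            [
                ("CE", "LYS", "A", 1, (-1.5, 0.0, 0.0), "C"),
                ("NZ", "LYS", "A", 1, (0.0, 0.0, 0.0), "N"),
                ("CD", "GLU", "A", 2, (4.75, 0.0, 0.0), "C"),
                ("OE1", "GLU", "A", 2, (3.5, 0.0, 0.0), "O"),
            ]
        )
        model = parse_pdb(text)
        bonds = detect_noncovalent(model)
        es = [b for b in bonds if b.kind == "electrostatic"]
        assert len(es) == 1
        params = EnergyParameters()
        expected = screened_coulomb_energy(1.0, -0.5, 3.5, params)
        assert expected == pytest.approx(
            params.coulomb_constant * 0.5 / (4.0 * 3.5**2)
        )
        assert es[0].weight == pytest.approx(expected, rel=1e-6)

    def test_pi_stack_between_phe_rings(self):
        ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        atoms = []
        for res_seq, z in ((1, 0.0), (2, 3.8)):
            for k, name in enumerate(ring_names):
                ang = math.radians(60 * k)
                atoms.append(
                    (
                        name,
                        "PHE",
                        "A",
                        res_seq,
                        (1.39 * math.cos(ang), 1.39 * math.sin(ang), z),
                        "C",
                    )
                )
        model = parse_pdb(build_pdb(atoms))
        bonds = detect_noncovalent(model)
        assert any(b.kind == "pi_pi" for b in bonds)

    def test_hydrophobic_pair(self):
        text = build_pdb(
            [
                ("CB", "ALA", "A", 1, (0.0, 0.0, 0.0), "C"),
                ("CB", "ALA", "A", 5, (4.0, 0.0, 0.0), "C"),
            ]
        )
        bonds = detect_noncovalent(parse_pdb(text))
        hp = [b for b in bonds if b.kind == "hydrophobic"]
        assert len(hp) == 1
        params = EnergyParameters()
        assert hp[0].weight == pytest.approx(params.hydrophobic_epsilon, rel=1e-9)


class TestAssembleGraph:
    def test_toy_counts(self):
        graph = assemble_graph(parse_pdb(TOY_ALA))
        assert graph.n == 3
        assert graph.m == 2

    def test_dedup_keeps_max_weight(self):
        # stacked PHE rings: closest ring-atom pair is hit by both the
        # hydrophobic and the pi-stacking rules; one edge must survive
        ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        atoms = []
        for res_seq, z in ((1, 0.0), (2, 3.8)):
            for k, name in enumerate(ring_names):
                ang = math.radians(60 * k)
                atoms.append(
                    (
                        name,
                        "PHE",
                        "A",
                        res_seq,
                        (1.39 * math.cos(ang), 1.39 * math.sin(ang), z),
                        "C",
                    )
                )
        model = parse_pdb(build_pdb(atoms))
        raw = detect_noncovalent(model)
        pairs = {}
        for b in raw:
            pairs.setdefault(frozenset((b.i, b.j)), []).append(b)
        doubled = {k: v for k, v in pairs.items() if len(v) > 1}
        assert doubled, "expected at least one pair hit by two rules"
        graph = assemble_graph(model)
        by_pair = {}
        for b in graph.bonds:
            by_pair[frozenset((b.i, b.j))] = b
        for key, hits in doubled.items():
            # node ids are remapped in assemble_graph but the graph keeps
            # every atom here (all have degree >= 1), and the max weight wins
            best = max(h.weight for h in hits)
            survived = [
                b for b in graph.bonds if b.weight == pytest.approx(best)
            ]
            assert survived

    def test_midpoint_invariant(self, helix_graph):
        for b in helix_graph.bonds[::7]:
            np.testing.assert_allclose(
                b.midpoint,
                0.5 * (helix_graph.coords[b.i] + helix_graph.coords[b.j]),
                atol=1e-12,
            )

    def test_fixture_truth_edge_counts(self, pentapeptide_with_ligand):
        text, truth = pentapeptide_with_ligand
        graph = assemble_graph(parse_pdb(text))
        n_cov = sum(b.kind == "covalent" for b in graph.bonds)
        assert n_cov == truth["expected_covalent_bonds"]
        assert sum(b.kind == "hydrogen_bond" for b in graph.bonds) == 1

    def test_reproducible(self, pentapeptide_with_ligand):
        text, _ = pentapeptide_with_ligand
        g1 = assemble_graph(parse_pdb(text))
        g2 = assemble_graph(parse_pdb(text))
        assert [(b.i, b.j, b.weight, b.kind) for b in g1.bonds] == [
            (b.i, b.j, b.weight, b.kind) for b in g2.bonds
        ]

    def test_atom_order_invariance(self, pentapeptide_with_ligand):
        text, _ = pentapeptide_with_ligand
        lines = [l for l in text.splitlines() if l.startswith(("ATOM", "HETATM"))]
        reordered = "\n".join(list(reversed(lines))) + "\nEND\n"
        g1 = assemble_graph(parse_pdb(text))
        g2 = assemble_graph(parse_pdb(reordered))

        def edge_set(g):
            return {
                (frozenset((g.atom_names[b.i], g.atom_names[b.j])), b.kind,
                 round(b.weight, 9))
                for b in g.bonds
            }

        assert edge_set(g1) == edge_set(g2)

    def test_positive_weights_and_symmetry(self, helix_graph):
        assert (helix_graph.weight_array() > 0).all()
        adj = helix_graph.adjacency()
        assert abs(adj - adj.T).max() < 1e-12


class TestIncidence:
    def test_single_edge(self):
        graph = assemble_graph(parse_pdb(TOY_ALA))
        B, W = incidence_and_weights(graph)
        col = B.toarray()[:, 0]
        assert sorted(col.tolist()) == [-1.0, 0.0, 1.0]

    def test_columns_sum_zero_and_2m_nonzeros(self, helix_graph):
        B, W = incidence_and_weights(helix_graph)
        assert np.abs(np.asarray(B.sum(axis=0))).max() == 0
        assert B.nnz == 2 * helix_graph.m
        np.testing.assert_allclose(W.diagonal(), helix_graph.weight_array())


class TestEnergyParameters:
    def test_yaml_overrides(self):
        params = EnergyParameters.from_yaml(
            "hbond_r0: 3.0\ncovalent_energies:\n  'C,C,1': 350\n"
            "charges:\n  'HIS,NE2': 0.5\n"
        )
        assert params.hbond_r0 == 3.0
        assert params.covalent_energy("C", "C", 1) == 350
        assert params.charges[("HIS", "NE2")] == 0.5
        # untouched defaults retained
        assert params.covalent_energy("C", "O", 2) == 745.0

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            EnergyParameters.from_dict({"nope": 1})
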