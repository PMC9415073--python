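"""Breakable-bond detection, PNP-graph construction, edge-cut enumeration."""

import itertools
import random

import pytest

from pnpmatch.chem import monoisotopic_mass, parse_smiles
from pnpmatch.fragmentation import (
    build_pnp_graph,
    enumerate_fragments,
    find_breakable_bonds,
    fragment_masses,
)
from pnpmatch.synthetic import make_peptide

from conftest import brute_force_fragments, cycle_graph, make_graph, path_graph

TRIGLYCINE = "NCC(=O)NCC(=O)NCC(=O)O"
TRIGLYCINE_MASS = 189.074956  # C6H11N3O4 = 3 Gly − 2 H2O


class TestBreakableBonds:
    def test_triglycine_two_amides(self):
        bonds = find_breakable_bonds(parse_smiles(TRIGLYCINE))
        assert len(bonds) == 2
        assert all(b.kind == "amide" for b in bonds)

    def test_carboxylic_acid_not_an_ester(self):
        # acetic acid: C-OH is an acid terminus, not a linkage
        assert find_breakable_bonds(parse_smiles("CC(=O)O")) == []

    def test_methyl_acetate_one_ester(self):
        bonds = find_breakable_bonds(parse_smiles("CC(=O)OC"))
        assert [b.kind for b in bonds] == ["ester"]

    def test_cyclo_hexaglycine_six_amides(self):
        m = parse_smiles(make_peptide("GGGGGG", "cyclic"))
        bonds = find_breakable_bonds(m)
        assert len(bonds) == 6
        assert all(b.kind == "amide" for b in bonds)

    def test_ethanol_has_none(self):
        assert find_breakable_bonds(parse_smiles("CCO")) == []

    def test_small_lactam_ring_not_breakable(self):
        # 5-membered lactam: amide sits in a small ring, not a macrocycle
        assert find_breakable_bonds(parse_smiles("C1CNC(=O)C1")) == []

    def test_thiazole_linkages_detected(self):
        # exocyclic C-C bonds at thiazole positions 2 and 4
        bonds = find_breakable_bonds(parse_smiles("CCc1scc(CC)n1"))
        kinds = sorted(b.kind for b in bonds)
        assert kinds == ["azole_linkage", "azole_linkage"]

    def test_amide_takes_precedence_over_azole(self):
        # amide C-N adjacent to a thiazole: classified once, as amide
        bonds = find_breakable_bonds(parse_smiles("CC(=O)NCc1sccn1"))
        assert sum(b.kind == "amide" for b in bonds) == 1

    def test_adding_classes_never_decreases_bonds(self):
        depsi = parse_smiles("CC(=O)OC(C)C(=O)NCC(=O)O")
        for classes in itertools.permutations(("amide", "ester", "azole_linkage")):
            for k in range(1, 4):
                sub = classes[:k]
                assert len(find_breakable_bonds(depsi, sub)) <= len(
                    find_breakable_bonds(depsi)
                )


class TestBuildGraph:
    def test_triglycine_path(self):
        m = parse_smiles(TRIGLYCINE)
        g = build_pnp_graph(m, find_breakable_bonds(m))
        assert g.num_vertices == 3
        assert len(g.edges) == 2
        assert g.total_mass() == pytest.approx(TRIGLYCINE_MASS, abs=1e-4)
        assert g.total_mass() == pytest.approx(monoisotopic_mass(m), abs=1e-9)

    def test_cyclo_hexaglycine_cycle(self):
        m = parse_smiles(make_peptide("GGGGGG", "cyclic"))
        g = build_pnp_graph(m, find_breakable_bonds(m))
        assert g.num_vertices == 6
        assert len(g.edges) == 6
        assert all(v.mass == pytest.approx(57.02146, abs=1e-4) for v in g.vertices)

    def test_single_residue_degenerate(self):
        m = parse_smiles("NCC(=O)O")
        g = build_pnp_graph(m, find_breakable_bonds(m))
        assert g.num_vertices == 1
        assert g.edges == []

    def test_vertex_atom_sets_partition_molecule(self):
        m = parse_smiles(make_peptide("GALVF", "branched", branch_index=2))
        g = build_pnp_graph(m, find_breakable_bonds(m))
        union = frozenset().union(*(v.atom_indices for v in g.vertices))
        assert union == frozenset(range(m.num_atoms))
        assert sum(len(v.atom_indices) for v in g.vertices) == m.num_atoms


class TestEnumerateFragments:
    def test_three_vertex_path_by_hand(self):
        frags = enumerate_fragments(path_graph(3))
        vertex_sets = {f.vertex_set for f in frags}
        assert vertex_sets == {
            frozenset(s) for s in [{0}, {1}, {2}, {0, 1}, {1, 2}]
        }

    @pytest.mark.parametrize("n", range(2, 9))
    def test_path_count_closed_form(self, n):
        assert len(enumerate_fragments(path_graph(n))) == n * (n + 1) // 2 - 1

    @pytest.mark.parametrize("n", range(3, 9))
    def test_cycle_count_closed_form(self, n):
        assert len(enumerate_fragments(cycle_graph(n))) == n * (n - 1)

    def test_single_vertex_no_fragments(self):
        assert enumerate_fragments(make_graph(1, [])) == []

    def test_parallel_edges_two_residue_macrocycle(self):
        g = make_graph(2, [(0, 1), (0, 1)])
        frags = enumerate_fragments(g)
        assert {f.vertex_set for f in frags} == {frozenset([0]), frozenset([1])}
        # only the pair cut splits a digon
        assert all(f.generating_cuts == (frozenset([0, 1]),) for f in frags)

    def test_oracle_equivalence_on_random_graphs(self):
        rng = random.Random(20260928)
        for _ in range(60):
            n = rng.randint(2, 8)
            tree = [(rng.randrange(i), i) for i in range(1, n)]
            extra = rng.randint(0, min(4, 12 - len(tree)))
            edges = tree + [
                tuple(sorted(rng.sample(range(n), 2))) for _ in range(extra)
            ]
            g = make_graph(n, edges)
            got = {
                f.vertex_set: set(f.generating_cuts)
                for f in enumerate_fragments(g)
            }
            assert got == brute_force_fragments(g)

    def test_deduplicated_with_all_cuts_recorded(self):
        frags = enumerate_fragments(cycle_graph(4))
        assert len({f.vertex_set for f in frags}) == len(frags)
        # an arc of a cycle is generated by exactly one pair cut
        arc = next(f for f in frags if f.vertex_set == frozenset([1, 2]))
        assert arc.generating_cuts == (frozenset([0, 2]),)


class TestFragmentMasses:
    def test_triglycine_terminal_fragment(self):
        m = parse_smiles(TRIGLYCINE)
        g = build_pnp_graph(m, find_breakable_bonds(m))
        frags = enumerate_fragments(g)
        masses = sorted(f.neutral_mass for f in frags if len(f.vertex_set) == 1)
        # N-terminal glycyl unit NH2-CH2-C(=O) = C2H4NO
        assert masses[1] == pytest.approx(58.029289, abs=1e-4)

    def test_complementary_fragments_sum_to_molecule(self):
        for seq in ("GG", "GAG", "GALV"):
            m = parse_smiles(make_peptide(seq, "linear"))
            g = build_pnp_graph(m, find_breakable_bonds(m))
            frags = enumerate_fragments(g)
            total = monoisotopic_mass(m)
            by_set = {f.vertex_set: f.neutral_mass for f in frags}
            full = frozenset(v.index for v in g.vertices)
            for vs, mass in by_set.items():
                comp = full - vs
                if comp in by_set:
                    assert mass + by_set[comp] == pytest.approx(total, abs=1e-6)

    def test_cyclo_hexaglycine_arc_mass(self):
        m = parse_smiles(make_peptide("GGGGGG", "cyclic"))
        g = build_pnp_graph(m, find_breakable_bonds(m))
        arcs = [f for f in enumerate_fragments(g) if len(f.vertex_set) == 3]
        for f in arcs:
            assert f.neutral_mass == pytest.approx(3 * 57.02146, abs=1e-3)

    def test_fragment_masses_mapping_matches_attribute(self):
        g = cycle_graph(5)
        frags = enumerate_fragments(g)
        mapping = fragment_masses(frags, g)
        for f in frags:
            assert mapping[f] == pytest.approx(f.neutral_mass, abs=1e-9)
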