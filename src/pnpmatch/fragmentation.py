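"""Breakable bonds, the PNP graph, and 1-/2-edge-cut fragment enumeration.

The fragmentation model treats a peptidic natural product as a quotient
graph: bonds that plausibly cleave in a collision cell — amide and ester
linkages and the exocyclic bonds flanking thiazole/oxazole rings — become
edges, and the residue-sized atom groups between them become vertices
carrying their neutral monoisotopic masses. Tentative MS/MS fragments are
the connected components obtained by deleting every single edge and every
unordered pair of edges. Pair cuts matter for non-linear compounds: a
macrocycle only falls apart when two backbone bonds are removed.

Hydrogen bookkeeping is purely graph-theoretic here: every atom keeps the
implicit hydrogens it carries in the intact molecule. The b/y-type
hydrogen asymmetry of amide cleavage is handled downstream, at the
ion-hypothesis level, through a configurable hydrogen-adjustment set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import networkx as nx
from rdkit import Chem

from .chem import Molecule, monoisotopic_mass
from .errors import PnpError

BOND_CLASSES = ("amide", "ester", "azole_linkage")

#: Minimum ring size in which a backbone amide/ester is still considered
#: breakable. Macrocyclic backbones must open; small lactam/lactone rings
#: and aromatic rings do not cleave under this model.
MACROCYCLE_MIN_SIZE = 8

_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])-[#7X3]")
_ESTER = Chem.MolFromSmarts("[CX3](=[OX1])-[OX2H0]")


@dataclass(frozen=True)
class BreakableBond:
    bond_index: int  # index into Molecule.bonds (== RDKit bond index)
    atom_a: int
    atom_b: int
    kind: str  # amide | ester | azole_linkage


@dataclass(frozen=True)
class PNPVertex:
    index: int
    atom_indices: frozenset[int]
    mass: float
    label: str


@dataclass(frozen=True)
class PNPEdge:
    index: int
    bond: Optional[BreakableBond]
    vertex_a: int
    vertex_b: int


@dataclass
class PNPGraph:
    """Quotient graph of a compound over its breakable bonds.

    Vertex atom sets partition the molecule's atoms, so vertex masses sum
    exactly to the molecule's monoisotopic mass. Parallel edges (two
    breakable bonds joining the same vertex pair, as in a two-residue
    macrocycle) are kept distinct.
    """

    vertices: list[PNPVertex]
    edges: list[PNPEdge]
    molecule: Optional[Molecule] = field(default=None, repr=False, compare=False)

    @property
    def num_vertices(self) -> int:
        return len(self.vertices)

    def total_mass(self) -> float:
        return sum(v.mass for v in self.vertices)

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(v.index for v in self.vertices)
        for e in self.edges:
            g.add_edge(e.vertex_a, e.vertex_b, key=e.index)
        return g


@dataclass(frozen=True)
class Fragment:
    """Connected proper sub-structure produced by a 1- or 2-edge cut."""

    index: int
    vertex_set: frozenset[int]
    atom_set: frozenset[int]
    neutral_mass: float
    generating_cuts: tuple[frozenset[int], ...]  # edge-index sets, size 1 or 2

    def shifted(self, delta: float) -> "Fragment":
        return Fragment(
            self.index, self.vertex_set, self.atom_set,
            self.neutral_mass + delta, self.generating_cuts,
        )


def _min_ring_size(mol: Chem.Mol, bond_idx: int) -> Optional[int]:
    """Smallest SSSR ring containing the bond, or None if acyclic."""
    sizes = [len(r) for r in mol.GetRingInfo().BondRings() if bond_idx in r]
    return min(sizes) if sizes else None


def _ring_breakable(mol: Chem.Mol, bond_idx: int) -> bool:
    bond = mol.GetBondWithIdx(bond_idx)
    if bond.GetIsAromatic():
        return False
    size = _min_ring_size(mol, bond_idx)
    return size is None or size >= MACROCYCLE_MIN_SIZE


def _azole_bonds(mol: Chem.Mol) -> list[int]:
    """Exocyclic single bonds at the 2- and 4-position carbons of
    thiazole/oxazole rings (5-membered aromatic, one N, one S or O)."""
    found = []
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) != 5:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetIsAromatic() for a in atoms):
            continue
        symbols = [a.GetSymbol() for a in atoms]
        if symbols.count("N") != 1 or (symbols.count("S") + symbols.count("O")) != 1:
            continue
        n_idx = ring[symbols.index("N")]
        x_idx = ring[symbols.index("S") if "S" in symbols else symbols.index("O")]
        ring_set = set(ring)
        for a in atoms:
            if a.GetSymbol() != "C":
                continue
            nbrs_in_ring = {n.GetIdx() for n in a.GetNeighbors()} & ring_set
            is_c2 = nbrs_in_ring == {n_idx, x_idx}
            is_c4 = n_idx in nbrs_in_ring and x_idx not in nbrs_in_ring
            if not (is_c2 or is_c4):
                continue
            for nbr in a.GetNeighbors():
                if nbr.GetIdx() in ring_set or nbr.GetSymbol() != "C":
                    continue
                bond = mol.GetBondBetweenAtoms(a.GetIdx(), nbr.GetIdx())
                if bond.GetBondType() == Chem.BondType.SINGLE:
                    found.append(bond.GetIdx())
    return found


def find_breakable_bonds(
    m: Molecule, classes: Sequence[str] = BOND_CLASSES
) -> list[BreakableBond]:
    """Locate amide, ester and azole-linkage bonds in *m*.

    Amide: the single C–N bond of a carboxamide. Ester: the single
    C(=O)–O bond where the sp3 oxygen carries a non-hydrogen substituent
    (carboxylic-acid termini are not linkages and are excluded). Azole
    linkage: exocyclic C–C single bonds at the 2- and 4-positions of a
    thiazole or oxazole ring. A bond matching several classes is reported
    once, with amide taking precedence over ester over azole.

    Bonds inside aromatic rings never break; bonds inside non-aromatic
    rings break only when the smallest ring containing them has at least
    :data:`MACROCYCLE_MIN_SIZE` members (macrocyclic backbones).
    """
    for c in classes:
        if c not in BOND_CLASSES:
            raise PnpError(f"unknown breakable-bond class {c!r}; valid: {BOND_CLASSES}")
    if m.rdmol is None:
        raise PnpError("Molecule lacks its RDKit structure; re-parse the input")
    mol = m.rdmol

    by_bond: dict[int, str] = {}

    def consider(bond_idx: int, kind: str) -> None:
        if bond_idx not in by_bond and _ring_breakable(mol, bond_idx):
            by_bond[bond_idx] = kind

    # Precedence amide > ester > azole_linkage regardless of `classes` order.
    if "amide" in classes:
        for match in mol.GetSubstructMatches(_AMIDE):
            c_idx, _o, n_idx = match
            bond = mol.GetBondBetweenAtoms(c_idx, n_idx)
            if bond.GetBondType() == Chem.BondType.SINGLE:
                consider(bond.GetIdx(), "amide")
    if "ester" in classes:
        for match in mol.GetSubstructMatches(_ESTER):
            c_idx, _o, o_idx = match
            bond = mol.GetBondBetweenAtoms(c_idx, o_idx)
            if bond.GetBondType() == Chem.BondType.SINGLE:
                consider(bond.GetIdx(), "ester")
    if "azole_linkage" in classes:
        for bond_idx in _azole_bonds(mol):
            consider(bond_idx, "azole_linkage")

    out = []
    for bond_idx in sorted(by_bond):
        b = m.bonds[bond_idx]
        out.append(BreakableBond(bond_idx, b.atom_a, b.atom_b, by_bond[bond_idx]))
    return out


def build_pnp_graph(m: Molecule, bonds: Iterable[BreakableBond]) -> PNPGraph:
    """Quotient the atom graph of *m* by deleting its breakable *bonds*.

    Vertices are the resulting connected atom components (with masses over
    intact-molecule atoms, implicit hydrogens included); each breakable
    bond whose endpoints land in different components becomes one edge.
    """
    bonds = list(bonds)
    cut = {b.bond_index for b in bonds}
    atom_graph = nx.Graph()
    atom_graph.add_nodes_from(range(m.num_atoms))
    atom_graph.add_edges_from(
        (b.atom_a, b.atom_b) for b in m.bonds if b.index not in cut
    )
    components = sorted(nx.connected_components(atom_graph), key=min)
    vertex_of_atom: dict[int, int] = {}
    vertices = []
    for vi, comp in enumerate(components):
        comp = frozenset(comp)
        for a in comp:
            vertex_of_atom[a] = vi
        vertices.append(
            PNPVertex(
                index=vi,
                atom_indices=comp,
                mass=monoisotopic_mass(m, comp),
                label=m.formula(comp),
            )
        )
    edges = []
    for b in bonds:
        va, vb = vertex_of_atom[b.atom_a], vertex_of_atom[b.atom_b]
        if va == vb:
            # A non-bridge breakable bond (alternate non-breakable path
            # exists): cutting it alone cannot split the compound, so it
            # contributes no quotient edge.
            continue
        edges.append(PNPEdge(index=len(edges), bond=b, vertex_a=va, vertex_b=vb))
    return PNPGraph(vertices=vertices, edges=edges, molecule=m)


def enumerate_fragments(g: PNPGraph) -> list[Fragment]:
    """All tentative fragments of *g* from single- and double-edge cuts.

    Every connected component of the graph minus a cut that is a proper,
    nonempty vertex subset is a fragment; fragments are deduplicated by
    vertex set with all generating cuts recorded. Returned sorted by
    (vertex-set size, vertex indices) with contiguous ``index`` fields.
    """
    full = frozenset(v.index for v in g.vertices)
    base = g.to_networkx()
    if not nx.is_connected(base) and g.num_vertices > 1:
        raise PnpError("PNP graph is disconnected")
    edge_by_index = {e.index: e for e in g.edges}
    cuts = [frozenset([i]) for i in edge_by_index]
    cuts += [frozenset(pair) for pair in combinations(sorted(edge_by_index), 2)]

    found: dict[frozenset[int], list[frozenset[int]]] = {}
    for cut in cuts:
        h = base.copy()
        for ei in cut:
            e = edge_by_index[ei]
            h.remove_edge(e.vertex_a, e.vertex_b, key=ei)
        for comp in nx.connected_components(h):
            vs = frozenset(comp)
            if vs and vs != full:
                found.setdefault(vs, []).append(cut)

    mass_of = {v.index: v.mass for v in g.vertices}
    atoms_of = {v.index: v.atom_indices for v in g.vertices}
    fragments = []
    ordered = sorted(found, key=lambda vs: (len(vs), sorted(vs)))
    for idx, vs in enumerate(ordered):
        atom_set = frozenset().union(*(atoms_of[v] for v in vs))
        fragments.append(
            Fragment(
                index=idx,
                vertex_set=vs,
                atom_set=atom_set,
                neutral_mass=sum(mass_of[v] for v in vs),
                generating_cuts=tuple(sorted(found[vs], key=sorted)),
            )
        )
    return fragments


def fragment_masses(frags: Iterable[Fragment], g: PNPGraph) -> dict[Fragment, float]:
    """Neutral mass of each fragment as the sum of its member vertex masses."""
    mass_of = {v.index: v.mass for v in g.vertices}
    out = {}
    for f in frags:
        unknown = f.vertex_set - set(mass_of)
        if unknown:
            raise PnpError(f"fragment references unknown vertices {sorted(unknown)}")
        out[f] = sum(mass_of[v] for v in f.vertex_set)
    return out
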