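"""Compound structures: parsing and monoisotopic masses.

Structures arrive as MDL MOL V3000 files or SMILES strings and are held as a
plain atom/bond graph (:class:`Molecule`). Parsing is delegated to RDKit;
the resulting object keeps a reference to the RDKit mol so that downstream
substructure matching (breakable-bond detection) can reuse it.

Masses are neutral monoisotopic masses of the molecule *as drawn*: every
atom contributes its monoisotopic mass plus its implicit hydrogens. The
package rejects disconnected input (salts, mixtures) because the
fragmentation model assumes a single covalent scaffold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem
from rdkit import RDLogger

from .errors import StructureParseError, PnpError
from .masses import H_MASS, element_mass

RDLogger.DisableLog("rdApp.*")

BOND_ORDER_NAME = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    formal_charge: int
    implicit_hydrogens: int


@dataclass(frozen=True)
class Bond:
    index: int
    atom_a: int
    atom_b: int
    order: str  # single / double / triple / aromatic


@dataclass
class Molecule:
    """Connected atom/bond graph of one compound.

    ``atoms[i].index == i`` and ``bonds[j].index == j``; bond endpoints are
    valid atom indices. ``rdmol`` is the RDKit molecule the graph was built
    from (heavy atoms only, hydrogens implicit).
    """

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""
    rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    def formula(self, atom_indices: Optional[Iterable[int]] = None) -> str:
        """Hill-order molecular formula of the given atom subset (implicit H included)."""
        if atom_indices is None:
            atom_indices = range(self.num_atoms)
        counts: dict[str, int] = {}
        for i in atom_indices:
            a = self.atoms[i]
            counts[a.element] = counts.get(a.element, 0) + 1
            if a.implicit_hydrogens:
                counts["H"] = counts.get("H", 0) + a.implicit_hydrogens
        parts = []
        for el in ("C", "H"):
            if counts.get(el):
                n = counts.pop(el)
                parts.append(el if n == 1 else f"{el}{n}")
        for el in sorted(counts):
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)


def _check_connected(atoms: list[Atom], bonds: list[Bond], what: str) -> None:
    if not atoms:
        raise StructureParseError(f"{what}: structure has no atoms")
    parent = list(range(len(atoms)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in bonds:
        ra, rb = find(b.atom_a), find(b.atom_b)
        if ra != rb:
            parent[ra] = rb
    roots = {find(i) for i in range(len(atoms))}
    if len(roots) > 1:
        raise StructureParseError(
            f"{what}: structure has {len(roots)} disconnected components; "
            "provide a single covalent compound (strip salts/counter-ions first)"
        )


def _from_rdkit(mol: Chem.Mol, name: str, what: str) -> Molecule:
    isotopes = [a.GetIdx() for a in mol.GetAtoms() if a.GetIsotope()]
    if isotopes:
        warnings.warn(
            f"{what}: isotope labels on atoms {isotopes} are ignored; "
            "monoisotopic masses assume unlabeled atoms",
            stacklevel=3,
        )
    atoms = [
        Atom(
            index=a.GetIdx(),
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            implicit_hydrogens=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        Bond(
            index=b.GetIdx(),
            atom_a=b.GetBeginAtomIdx(),
            atom_b=b.GetEndAtomIdx(),
            order=BOND_ORDER_NAME.get(b.GetBondType(), "single"),
        )
        for b in mol.GetBonds()
    ]
    _check_connected(atoms, bonds, what)
    return Molecule(atoms=atoms, bonds=bonds, name=name, rdmol=mol)


def _prevalidate_v3000(text: str) -> None:
    """Line-level sanity checks that give more useful messages than RDKit's."""
    lines = text.splitlines()
    natoms = None
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if s.startswith("M  V30 COUNTS"):
            try:
                natoms = int(s.split()[3])
            except (IndexError, ValueError):
                raise StructureParseError(
                    f"malformed V3000 COUNTS line {lineno}: {line!r}"
                ) from None
    if natoms is None:
        return
    in_bonds = False
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if s == "M  V30 BEGIN BOND":
            in_bonds = True
        elif s == "M  V30 END BOND":
            in_bonds = False
        elif in_bonds and s.startswith("M  V30"):
            fields = s.split()
            if len(fields) < 6:
                raise StructureParseError(f"malformed V3000 bond line {lineno}: {line!r}")
            try:
                a, b = int(fields[4]), int(fields[5])
            except ValueError:
                raise StructureParseError(
                    f"malformed V3000 bond line {lineno}: {line!r}"
                ) from None
            for ref in (a, b):
                if not 1 <= ref <= natoms:
                    raise StructureParseError(
                        f"V3000 bond line {lineno} references atom {ref}, "
                        f"but the COUNTS block declares only {natoms} atoms"
                    )


def parse_mol_v3000(text: str, name: str = "") -> Molecule:
    """Parse an MDL MOL V3000 block into a :class:`Molecule`.

    V2000 input is rejected with a message suggesting conversion: only the
    V3000 dialect is supported.
    """
    if "V2000" in text and "V3000" not in text:
        raise StructureParseError(
            "MOL file is in the V2000 format; convert it to V3000 "
            "(e.g. with RDKit or Open Babel) and retry"
        )
    if "V3000" not in text:
        raise StructureParseError("input does not contain a V3000 CTAB block")
    _prevalidate_v3000(text)
    mol = Chem.MolFromMolBlock(text, sanitize=True)
    if mol is None:
        raise StructureParseError("RDKit could not parse the V3000 MOL block")
    header_name = text.splitlines()[0].strip() if text.splitlines() else ""
    return _from_rdkit(mol, name or header_name, "MOL V3000")


def parse_smiles(text: str, name: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` (aromaticity preserved)."""
    mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        raise StructureParseError(f"invalid SMILES: {text!r}")
    return _from_rdkit(mol, name, f"SMILES {text!r}")


def monoisotopic_mass(
    m: Molecule,
    atom_indices: Optional[Iterable[int]] = None,
    include_implicit_h: bool = True,
) -> float:
    """Neutral monoisotopic mass (Da) of an atom subset of *m*.

    Defaults to the whole molecule. Each atom contributes its elemental
    monoisotopic mass plus, when ``include_implicit_h``, its implicit
    hydrogens as drawn in the intact molecule.
    """
    if atom_indices is None:
        atom_indices = range(m.num_atoms)
    indices = list(atom_indices)
    if not indices:
        raise PnpError("monoisotopic_mass: empty atom set")
    total = 0.0
    for i in indices:
        a = m.atoms[i]
        total += element_mass(a.element)
        if include_implicit_h:
            total += a.implicit_hydrogens * H_MASS
    return total
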