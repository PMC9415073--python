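"""Toy peptide structures and simulated spectra with known ground truth.

The generator builds small linear, head-to-tail cyclic, or branched
(cyclic backbone with an amide-linked glycine arm) peptides over a
five-residue alphabet, then synthesizes a spectrum from the package's own
fragmentation/ion model: a seeded fraction of the theoretical ions becomes
peaks, m/z values get Gaussian noise truncated at ±4σ, and uniform decoy
peaks over [50, precursor m/z] stand in for chemical noise. Because the
simulated peaks come with their generating fragments, the generator
doubles as a closed-loop oracle for annotation and modification
localization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotation import DEFAULT_DELTA_SET, build_ion_hypotheses
from .chem import Molecule, monoisotopic_mass, parse_smiles
from .errors import ParameterError
from .fragmentation import PNPGraph, build_pnp_graph, enumerate_fragments, find_breakable_bonds
from .masses import cation_mass
from .spectra import Spectrum

#: Side chains attached at the alpha carbon, as SMILES branch strings.
RESIDUE_SIDE_CHAIN: dict[str, str] = {
    "G": "",
    "A": "C",
    "L": "CC(C)C",
    "V": "C(C)C",
    "F": "Cc1ccccc1",
}

#: Glycine arm used as the side chain of the branch residue: CH2–CO–NH–CH2–COOH.
_BRANCH_ARM = "CC(=O)NCC(=O)O"


def _unit(side_chain: str) -> str:
    return f"C({side_chain})" if side_chain else "C"


def make_peptide(
    sequence: str,
    topology: str = "linear",
    branch_index: Optional[int] = None,
    side_chains: Optional[dict[str, str]] = None,
) -> str:
    """SMILES of a toy peptide over the one-letter alphabet G/A/L/V/F.

    ``linear``: H2N-...-COOH chain. ``cyclic``: head-to-tail macrolactam
    (length >= 2). ``branched``: cyclic backbone whose residue at
    *branch_index* carries a glycine arm attached through an amide bond.
    Extra residues can be supplied via *side_chains* (symbol → side-chain
    SMILES branch).
    """
    table = dict(RESIDUE_SIDE_CHAIN)
    if side_chains:
        table.update(side_chains)
    chains = []
    for symbol in sequence:
        if symbol not in table:
            raise ParameterError(
                f"unknown residue symbol {symbol!r}; known: {sorted(table)}"
            )
        chains.append(table[symbol])
    n = len(chains)
    if n < 1:
        raise ParameterError("sequence must have at least one residue")

    if topology == "linear":
        body = "".join(f"N{_unit(sc)}C(=O)" for sc in chains)
        return body + "O"
    if topology in ("cyclic", "branched"):
        if n < 3:
            # a 1- or 2-residue head-to-tail closure gives a small ring
            # (e.g. a diketopiperazine), not a breakable macrocycle
            raise ParameterError(
                f"cannot macrocyclize a {n}-residue sequence (need >= 3)"
            )
        if topology == "branched":
            if branch_index is None or not 0 <= branch_index < n:
                raise ParameterError(
                    f"branched topology needs a branch_index in [0, {n})"
                )
            chains = list(chains)
            chains[branch_index] = _BRANCH_ARM
        # %99 ring-closure avoids collisions with digits in side-chain rings
        parts = [f"N%99{_unit(chains[0])}C(=O)"]
        parts += [f"N{_unit(sc)}C(=O)" for sc in chains[1:-1]]
        parts.append(f"N{_unit(chains[-1])}C%99=O")
        return "".join(parts)
    raise ParameterError(f"unknown topology {topology!r}")


@dataclass
class SimulationSpec:
    """Ground-truth recipe for one simulated spectrum."""

    sequence: str
    topology: str = "linear"
    branch_index: Optional[int] = None
    observed_fraction: float = 1.0  # fraction p of theoretical ions observed
    mz_sigma: float = 0.0  # Gaussian m/z noise (Da), truncated at ±4σ
    decoy_fraction: float = 0.0  # fraction of final peaks that are decoys
    modification: Optional[tuple[float, int]] = None  # (Δ Da, vertex index)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.observed_fraction <= 1:
            raise ParameterError("observed_fraction must be in (0, 1]")
        if self.mz_sigma < 0:
            raise ParameterError("mz_sigma must be >= 0")
        if not 0 <= self.decoy_fraction < 1:
            raise ParameterError("decoy_fraction must be in [0, 1)")


@dataclass
class GroundTruthPeak:
    peak_index: int  # index into the sorted Spectrum.peaks
    mz: float
    fragment_index: Optional[int]  # None for decoys
    hydrogen_adjustment: Optional[int]
    charge: Optional[int]

    @property
    def is_decoy(self) -> bool:
        return self.fragment_index is None


def build_graph(m: Molecule) -> PNPGraph:
    """Convenience: breakable bonds (all classes) → PNP graph."""
    return build_pnp_graph(m, find_breakable_bonds(m))


def simulate_spectrum(
    m: Molecule,
    spec: SimulationSpec,
    charge: int = 1,
    adduct: str = "H",
    delta_set: Sequence[int] = DEFAULT_DELTA_SET,
) -> tuple[Spectrum, list[GroundTruthPeak]]:
    """Simulated MS/MS spectrum of *m* under *spec*, plus ground truth.

    Theoretical ions come from the package's own fragmentation and ion
    model; a planted modification shifts every fragment containing its
    vertex (and the precursor) by Δ. All randomness flows from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    g = build_graph(m)
    fragments = enumerate_fragments(g)
    delta_mass = 0.0
    if spec.modification is not None:
        delta_mass, mod_vertex = spec.modification
        if not 0 <= mod_vertex < g.num_vertices:
            raise ParameterError(
                f"modification vertex {mod_vertex} out of range "
                f"[0, {g.num_vertices})"
            )
        fragments = [
            f.shifted(delta_mass) if mod_vertex in f.vertex_set else f
            for f in fragments
        ]
    ions = build_ion_hypotheses(fragments, charge=charge, adduct=adduct,
                                delta_set=delta_set)
    if spec.observed_fraction < 1 and ions:
        keep = max(1, int(round(spec.observed_fraction * len(ions))))
        idx = sorted(rng.choice(len(ions), size=keep, replace=False))
        ions = [ions[i] for i in idx]

    precursor_mz = (monoisotopic_mass(m) + delta_mass
                    + charge * cation_mass(adduct)) / charge

    records = []  # (mz, intensity, fragment_index, delta_h, z)
    for ion in ions:
        noise = 0.0
        if spec.mz_sigma > 0:
            noise = float(np.clip(rng.normal(0.0, spec.mz_sigma),
                                  -4 * spec.mz_sigma, 4 * spec.mz_sigma))
        records.append(
            (ion.theoretical_mz + noise, float(rng.uniform(20.0, 100.0)),
             ion.fragment.index, ion.hydrogen_adjustment, ion.charge)
        )
    if spec.decoy_fraction > 0 and records:
        n_true = len(records)
        n_decoy = int(round(spec.decoy_fraction * n_true
                            / (1 - spec.decoy_fraction)))
        for _ in range(n_decoy):
            records.append(
                (float(rng.uniform(50.0, precursor_mz)),
                 float(rng.uniform(1.0, 30.0)), None, None, None)
            )

    records.sort(key=lambda r: r[0])
    peaks = [(mz, inten) for mz, inten, *_ in records]
    spectrum = Spectrum(
        peaks=peaks,
        precursor_mz=precursor_mz,
        charge=charge,
        scan_id=f"sim:{spec.sequence}:{spec.topology}:{spec.seed}",
        source_file="simulated",
    )
    truth = [
        GroundTruthPeak(i, mz, frag_idx, dh, z)
        for i, (mz, _inten, frag_idx, dh, z) in enumerate(records)
    ]
    spectrum.ground_truth = truth
    return spectrum, truth


def write_mgf(s: Spectrum) -> str:
    """Render *s* as one standards-conformant MGF block (charge as '2+')."""
    lines = ["BEGIN IONS"]
    if s.scan_id:
        lines.append(f"TITLE={s.scan_id}")
    lines.append(f"PEPMASS={s.precursor_mz:.5f}")
    lines.append(f"CHARGE={s.charge}+")
    for mz, inten in s.peaks:
        lines.append(f"{mz:.5f} {inten:.4f}")
    lines.append("END IONS")
    return "\n".join(lines) + "\n"
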