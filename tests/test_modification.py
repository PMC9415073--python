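"""Modification mass Δ and its localization on the PNP graph."""

import numpy as np
import pytest

from pnpmatch.chem import monoisotopic_mass, parse_smiles
from pnpmatch.masses import PROTON_MASS
from pnpmatch.modification import localize_modification, modification_mass, suggest_residue
from pnpmatch.spectra import Spectrum
from pnpmatch.synthetic import SimulationSpec, build_graph, make_peptide, simulate_spectrum

from conftest import make_graph

LEU_RESIDUE = 113.08406
GLY_RESIDUE = 57.02146


def spectrum_with_neutral_mass(neutral, charge=1):
    return Spectrum(
        peaks=[(100.0, 1.0)],
        precursor_mz=(neutral + charge * PROTON_MASS) / charge,
        charge=charge,
    )


class TestModificationMass:
    def test_leucine_insertion_magnitude(self):
        m = parse_smiles(make_peptide("GGG", "linear"))
        base = monoisotopic_mass(m)
        s = spectrum_with_neutral_mass(base + 113.085)
        assert modification_mass(s, m) == pytest.approx(113.085, abs=1e-4)

    def test_exact_precursor_gives_zero(self):
        m = parse_smiles("NCC(=O)O")
        s = spectrum_with_neutral_mass(monoisotopic_mass(m))
        assert modification_mass(s, m) == pytest.approx(0.0, abs=1e-9)

    def test_loss_gives_negative_delta(self):
        m = parse_smiles(make_peptide("GGG", "linear"))
        s = spectrum_with_neutral_mass(monoisotopic_mass(m) - 18.010565)
        assert modification_mass(s, m) == pytest.approx(-18.010565, abs=1e-5)


class TestLocalizeModification:
    def _planted(self, seq, topo, delta, vertex, seed, sigma=0.0, decoys=0.0,
                 branch_index=None):
        m = parse_smiles(make_peptide(seq, topo, branch_index=branch_index))
        sim = SimulationSpec(
            seq, topo, branch_index=branch_index, mz_sigma=sigma,
            decoy_fraction=decoys, modification=(delta, vertex), seed=seed,
        )
        s, _ = simulate_spectrum(m, sim)
        return build_graph(m), s, modification_mass(s, m)

    def test_noiseless_planted_vertex_recovered(self):
        g, s, delta = self._planted("GALVFG", "cyclic", LEU_RESIDUE, 3, seed=2)
        placement = localize_modification(g, s, delta)
        assert placement.vertex_index == 3
        assert delta == pytest.approx(LEU_RESIDUE, abs=1e-4)
        # every simulated peak is explained by the true placement
        assert placement.score == len(s.peaks)

    def test_true_placement_is_argmax_by_brute_force(self):
        g, s, delta = self._planted("GAVLF", "branched", GLY_RESIDUE, 2,
                                    seed=9, branch_index=1)
        placement = localize_modification(g, s, delta)
        scores = placement.per_vertex_scores
        assert all(
            scores[placement.vertex_index] >= sc for sc in scores.values()
        )
        assert placement.vertex_index == 2

    def test_single_vertex_graph_trivial(self):
        g = make_graph(1, [])
        s = spectrum_with_neutral_mass(300.0)
        placement = localize_modification(g, s, 42.0)
        assert placement.vertex_index == 0

    def test_symmetric_compound_ties_to_vertex_zero(self):
        # unshifted cyclo-Gly6 spectrum scored with a Δ that explains no
        # peaks: all placements equal, tie broken to the lowest index
        m = parse_smiles(make_peptide("GGGGGG", "cyclic"))
        s, _ = simulate_spectrum(m, SimulationSpec("GGGGGG", "cyclic", seed=4))
        g = build_graph(m)
        placement = localize_modification(g, s, 500.0)
        scores = set(placement.per_vertex_scores.values())
        assert len(scores) == 1
        assert placement.tie_broken
        assert placement.vertex_index == 0

    def test_zero_delta_scores_all_vertices_equally(self):
        m = parse_smiles(make_peptide("GALV", "cyclic"))
        s, _ = simulate_spectrum(m, SimulationSpec("GALV", "cyclic", seed=6))
        g = build_graph(m)
        placement = localize_modification(g, s, 0.0)
        assert placement.unmodified
        assert len(set(placement.per_vertex_scores.values())) == 1

    def test_vertex_with_nonpositive_shifted_mass_skipped(self):
        g = make_graph(3, [(0, 1), (1, 2)], masses=[50.0, 300.0, 300.0])
        s = spectrum_with_neutral_mass(600.0)
        with pytest.warns(UserWarning, match="skipped"):
            placement = localize_modification(g, s, -60.0)
        assert 0 not in placement.per_vertex_scores

    def test_recovery_under_noise_and_decoys(self):
        # scaled-down replica of the full recovery study in the acceptance
        # suite: a handful of seeded noisy simulations must all localize
        rng = np.random.default_rng(123)
        hits = 0
        trials = 10
        for k in range(trials):
            seq = "".join(rng.choice(list("GALVF"), size=rng.integers(5, 9)))
            vertex = int(rng.integers(0, len(seq)))
            g, s, delta = self._planted(
                seq, "cyclic", LEU_RESIDUE, vertex, seed=1000 + k,
                sigma=0.005, decoys=0.3,
            )
            # only count cases the noiseless spectrum can identify at all
            g0, s0, d0 = self._planted(seq, "cyclic", LEU_RESIDUE, vertex,
                                       seed=1000 + k)
            p0 = localize_modification(g0, s0, d0)
            best = max(p0.per_vertex_scores.values())
            if sum(v == best for v in p0.per_vertex_scores.values()) > 1:
                hits += 1  # degenerate by symmetry, excluded
                continue
            if localize_modification(g, s, delta).vertex_index == vertex:
                hits += 1
        assert hits >= trials - 1


class TestSuggestResidue:
    def test_leucine_isoleucine_pair(self):
        hits = suggest_residue(113.085, 0.01)
        assert {name for name, _ in hits} == {"Leu", "Ile"}
        assert all(mass == pytest.approx(113.08406) for _, mass in hits)

    def test_glycine_shift(self):
        assert [name for name, _ in suggest_residue(57.021, 0.01)] == ["Gly"]

    def test_no_residue_near(self):
        assert suggest_residue(200.0, 0.01) == []

    def test_negative_delta_matches_by_magnitude(self):
        assert [name for name, _ in suggest_residue(-57.021, 0.01)] == ["Gly"]
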