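# Methods

## Fragmentation model

A peptidic natural product is modeled as a quotient graph over its
*breakable bonds*. Three bond classes are recognized:

- **amide** — the single C–N bond of a carboxamide (`[CX3](=O)-[NX3]`);
- **ester** — the single C(=O)–O bond whose sp³ oxygen carries a
  non-hydrogen substituent. Requiring a substituent excludes carboxylic
  acid termini: an acid O–H is a chain end, not a linkage. This covers the
  lactone bridge of depsipeptides;
- **azole linkage** — the exocyclic C–C single bonds at the 2- and
  4-position carbons of a five-membered aromatic ring with exactly one N
  and one S or O (thiazole/oxazole). These rings arise from backbone
  Cys/Ser cyclodehydration, so the bonds flanking them are the remnants of
  backbone linkages. The rule is a deliberate heuristic; finer patterns
  (oxazoline, methyloxazole substitution) are not distinguished.

A bond matching several classes is reported once, with precedence
amide > ester > azole.

**Ring handling.** Bonds in aromatic rings never break. For non-aromatic
rings the smallest ring containing the bond must have ≥ 8 members
(`MACROCYCLE_MIN_SIZE`): macrocyclic backbones must open, whereas
β-lactams, γ/δ-lactams, diketopiperazines and lactones in 5–7-membered
rings are treated as stable ring systems rather than linkages. The ≥ 8
threshold is the smallest ring a two-residue-plus bridge backbone can
form; it is exposed as a module constant.

**PNP graph.** Deleting the breakable bonds partitions the atom graph into
connected components; each becomes a vertex with (a) the atom set, (b) the
neutral monoisotopic mass of those atoms *as drawn in the intact molecule*
(implicit hydrogens included), and (c) a molecular-formula label. Each
breakable bond whose endpoints fall in different components becomes one
edge; parallel edges are kept (a two-vertex macrocycle is a digon, and
only the pair cut splits it). A breakable bond whose endpoints land in the
same component (a non-bridge bond with an unbreakable back path) yields no
edge: no 1- or 2-edge cut through it alone can separate the compound, and
dropping it keeps the quotient graph loop-free.

**Hydrogen bookkeeping.** No hydrogens move at cut time, so vertex masses
sum exactly to the molecular mass and complementary fragments of any
single cut conserve mass to machine precision. The chemistry of cleavage —
which side keeps the amide proton, proton transfer in y-type ions — is
deferred to the ion level, where each fragment is tried with hydrogen
adjustments δ ∈ {0, +1, +2} by default. This factorization keeps the
enumeration purely graph-theoretic and makes the ion chemistry a
configurable run parameter rather than a structural assumption.

**Enumeration.** Fragments are the connected proper vertex subsets
produced by removing any one edge or any unordered pair of edges.
Duplicated vertex sets are merged, and every generating cut is recorded
for reporting. Complexity is O(E²·(V+E)) — trivial at PNP scale (a
compound rarely has more than ~20 breakable bonds). Three-edge cuts,
side-chain cleavages and internal rearrangements are out of scope, as are
neutral-loss ions.

## Ion model and annotation

An ion hypothesis is (fragment, δ, adduct, z) with
m/z = (M + δ·m_H + z·m_cation)/z, using the hydrogen *atom* mass for δ and
cation masses (proton 1.007276 Da; Na⁺, K⁺ as atom minus electron) for
charge bookkeeping. Hypotheses are generated for all charges 1..z of the
precursor, one adduct per run.

Matching uses an absolute Da tolerance (default 0.03 Da; 0.01–0.05 Da
suits high-resolution instruments, 0.5–2 Da low-resolution ones) with an
inclusive window. A ppm tolerance was rejected because the same window
then shrinks exactly where fragment density is highest (low m/z); ppm
errors are still reported per annotation. Each peak receives at most one
annotation — the hypothesis with the smallest |error|, ties broken toward
smaller δ, then smaller fragment, then lower fragment index, then lower
charge — with the number of alternative hypotheses preserved. Intensity is
ignored for matching and passed through to reports. The intact molecule is
not a fragment; a precursor peak is annotated only if it coincides with a
fragment ion.

## Modification localization

Δ = z·(precursor m/z) − z·m_cation − M(compound), signed; negative Δ
(losses) are placed identically. The shift is applied to one vertex at a
time: every fragment containing that vertex moves by Δ, ions are rebuilt,
the spectrum re-annotated, and the placement scored by **annotated-peak
count** (shared-peak count). This score is the simplest one consistent
with ranking modified variants against a spectrum; the scoring function is
an injectable callable so a calibrated probabilistic score can replace it
without touching the search. Only single-site modifications are
considered. Ties (symmetric compounds, or Δ values explaining nothing)
break toward the smaller summed |error| and then the lowest vertex index,
with a `tie_broken` flag set; Δ = 0 short-circuits to an "unmodified"
result in which all scores are equal by construction. Vertices whose mass
would become non-positive under Δ are skipped with a warning. For
interpretation, the 20 proteinogenic residue masses within a tolerance of
|Δ| are suggested, nearest first.

## Synthetic data: what it emulates and what it does not

The generator assembles toy peptides over Gly/Ala/Leu/Val/Phe (user
residues can be added as side-chain SMILES) in three topologies: linear,
head-to-tail cyclic (≥ 3 residues — a smaller "cycle" is a
diketopiperazine whose amides sit in a 6-ring and are rightly
unbreakable), and branched (cyclic backbone with a glycine arm
amide-linked at a chosen residue, the cycle-with-tail architecture common
among PNPs). Spectra are simulated from the package's *own* ion model: a
fraction *p* (default 1.0) of the theoretical ions is sampled, m/z values
get Gaussian noise (default σ = 0 Da; studies use 0.005 Da,
high-resolution scale) truncated at ±4σ so planted peaks stay near their
ions, and decoy peaks (default fraction 0; studies use 0.3) are drawn
uniformly on [50, precursor m/z] — decoys may land inside a tolerance
window, which is a realistic confounder. Intensities are uniform draws
with decoys weaker than true peaks. All randomness flows from one seed;
equal specs give byte-identical spectra.

Because the simulator reuses the annotation-side ion model, closed-loop
tests (noiseless spectra annotate at rate 1.0; planted shifts localize
exactly) validate internal consistency, determinism and the combinatorics
— they cannot validate the chemistry. Real spectra contain neutral losses,
isotope envelopes, multiply-sourced peaks and intensity structure that the
generator does not emulate, so a high annotation rate on simulated data
does not predict annotation rates on instrument data.

## Validation studies and problem sizes

- **Fragment-count laws.** Paths of n = 2..8 vertices give n(n+1)/2 − 1
  fragments; cycles give n(n−1) (30 for a cyclic hexapeptide).
- **Subset oracle.** On 200 random connected multigraphs (≤ 8 vertices,
  ≤ 12 edges; random spanning tree plus extra edges) the edge-cut
  enumeration is compared with an independent all-subsets oracle: a proper
  nonempty subset is a fragment iff it is induced-connected and at most
  two edges cross its boundary. The test suite additionally compares the
  generating cuts themselves.
- **Recovery study.** 100 trials: random 5–8-residue cyclic or branched
  peptides, a planted shift from {+14.016, +57.021, +113.084} Da on a
  uniformly random vertex, σ = 0.005 Da, 30% decoys. A trial is
  *symmetry-identifiable* when the noiseless spectrum yields a unique
  score argmax (repeated residues can make arcs mass-equivalent, in which
  case no scorer could distinguish the sites). Localization is required to
  recover every identifiable noiseless case and ≥ 95% of the identifiable
  noisy cases. These sizes keep the whole suite and the acceptance script
  in the seconds-to-minutes range on one CPU.

## Numerical choices and edge cases

- Atomic masses: NIST monoisotopic values to ≥ 6 decimals, hard-coded;
  masses are deterministic sums, reproducible to 1e-6 Da.
- Structures must be single covalent components; salts/mixtures are
  rejected rather than silently stripped. MOL V2000 is rejected with a
  conversion hint (only V3000 is parsed). Isotope labels are ignored with
  a warning.
- Spectra: peaks are sorted on load; zero-intensity peaks and duplicate
  m/z values are retained; NaN or negative values are errors; negative-
  mode spectra are rejected (the adduct model is cationic). A missing MGF
  CHARGE defaults to 1 with a warning, PEPMASS is always read as m/z.
- Reports: JSON floats are rounded on construction (masses 6 decimals,
  ppm 1), making serialization lossless and repeated runs byte-identical.
  The HTML report is static XHTML with inline SVG; compound 2D depiction
  and interactive panels are out of scope, with the fragment table (keyed
  by vertex formula labels) standing in for a structure drawing.

## Known limitations

The breakable-bond patterns are heuristics — unusual linkages (thioesters,
ureas, N-methylated imides) are not cleaved. The shared-peak score ignores
intensity and peak ambiguity, so placements on small symmetric compounds
can tie. Only one modification site is ever considered. mzML, profile-mode
data, neutral losses and isotope envelopes are unsupported.
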