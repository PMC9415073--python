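"""Unknown-modification mass and its localization on the PNP graph.

When a spectrum belongs to a modified or mutated variant of the provided
compound, the modification mass Δ is the difference between the neutral
precursor mass and the compound's monoisotopic mass. Localization applies
Δ to each graph vertex in turn — shifting the mass of every fragment that
contains that vertex — rescoring the spectrum each time; the vertex whose
shifted fragment ladder explains the most peaks wins.

The score is the annotated-peak count (shared-peak count). It is
injectable, so a probabilistic score can be swapped in without touching
the search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .annotation import (
    DEFAULT_DELTA_SET,
    DEFAULT_TOLERANCE,
    Annotation,
    annotate_peaks,
    build_ion_hypotheses,
)
from .chem import Molecule, monoisotopic_mass
from .errors import ParameterError
from .fragmentation import PNPGraph, enumerate_fragments
from .masses import RESIDUE_MASS
from .spectra import Spectrum, neutral_precursor_mass

ScoreFunction = Callable[[Sequence[Annotation], Spectrum], float]


def shared_peak_count(annotations: Sequence[Annotation], s: Spectrum) -> float:
    """Default placement score: number of annotated peaks."""
    return float(len(annotations))


@dataclass
class ModificationPlacement:
    delta_mass: float  # signed Δ, Da
    vertex_index: int
    score: float
    per_vertex_scores: dict[int, float]
    tie_broken: bool
    unmodified: bool = False  # Δ == 0 short-circuit
    annotations: list[Annotation] = field(default_factory=list, repr=False)
    per_vertex_total_abs_error: dict[int, float] = field(default_factory=dict, repr=False)


def modification_mass(s: Spectrum, m: Molecule, adduct: str = "H") -> float:
    """Signed modification mass Δ = neutral precursor mass − compound mass."""
    return neutral_precursor_mass(s, adduct) - monoisotopic_mass(m)


def localize_modification(
    g: PNPGraph,
    s: Spectrum,
    delta: float,
    tolerance: float = DEFAULT_TOLERANCE,
    charge: int = 1,
    adduct: str = "H",
    delta_set: Sequence[int] = DEFAULT_DELTA_SET,
    score_fn: Optional[ScoreFunction] = None,
) -> ModificationPlacement:
    """Place the mass shift *delta* on the vertex that best explains *s*.

    For each candidate vertex the neutral mass of every fragment containing
    it is shifted by Δ, ion hypotheses are rebuilt and the spectrum is
    re-annotated. The highest-scoring vertex is returned; ties break toward
    the smaller summed |mass error| over annotations, then the lower vertex
    index, with ``tie_broken`` set. Δ = 0 yields identical scores for every
    vertex and is flagged ``unmodified``. Vertices whose mass would become
    non-positive under Δ are skipped with a warning.
    """
    if g.num_vertices < 1:
        raise ParameterError("PNP graph has no vertices")
    score_fn = score_fn or shared_peak_count
    fragments = enumerate_fragments(g)

    scores: dict[int, float] = {}
    total_err: dict[int, float] = {}
    anns: dict[int, list[Annotation]] = {}
    for v in g.vertices:
        if v.mass + delta <= 0:
            warnings.warn(
                f"vertex {v.index} ({v.label}) skipped: mass {v.mass:.4f} + "
                f"Δ {delta:+.4f} would be non-positive",
                stacklevel=2,
            )
            continue
        shifted = [
            f.shifted(delta) if v.index in f.vertex_set else f for f in fragments
        ]
        ions = build_ion_hypotheses(shifted, charge=charge, adduct=adduct,
                                    delta_set=delta_set)
        ann = annotate_peaks(s, ions, tolerance) if ions else []
        scores[v.index] = score_fn(ann, s)
        total_err[v.index] = sum(abs(a.error_da) for a in ann)
        anns[v.index] = ann
    if not scores:
        raise ParameterError("no vertex admits the modification mass")

    best_score = max(scores.values())
    top = [v for v, sc in scores.items() if sc == best_score]
    if len(top) > 1:
        best_err = min(total_err[v] for v in top)
        top = [v for v in top if total_err[v] == best_err]
    winner = min(top)
    return ModificationPlacement(
        delta_mass=delta,
        vertex_index=winner,
        score=best_score,
        per_vertex_scores=scores,
        tie_broken=len(top) > 1,
        unmodified=(delta == 0),
        annotations=anns[winner],
        per_vertex_total_abs_error=total_err,
    )


def suggest_residue(delta: float, tolerance: float = 0.01) -> list[tuple[str, float]]:
    """Proteinogenic residues whose monoisotopic mass is within *tolerance*
    of |Δ|, sorted by closeness (then name). Empty when nothing is near."""
    hits = [
        (name, mass)
        for name, mass in RESIDUE_MASS.items()
        if abs(abs(delta) - mass) <= tolerance
    ]
    return sorted(hits, key=lambda nm: (abs(abs(delta) - nm[1]), nm[0]))
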