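"""Matching experimental peaks to theoretical fragment ions.

Each fragment spawns a small family of ion hypotheses: a hydrogen
adjustment δ (default {0, +1, +2}, covering b-like ions, y-like ions after
hydrogen transfer, and doubly hydrogen-compensated ring-opening ions of
cyclic compounds), one adduct per run, and charges 1..z. A peak is
annotated when some hypothesis lies within an absolute m/z tolerance
(default 0.03 Da; the window is inclusive at both ends). Intensity plays
no role in matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .fragmentation import Fragment
from .masses import H_MASS, cation_mass
from .spectra import Spectrum

DEFAULT_TOLERANCE = 0.03
DEFAULT_DELTA_SET = (0, 1, 2)


@dataclass(frozen=True)
class IonHypothesis:
    fragment: Fragment
    hydrogen_adjustment: int  # δ, number of H atoms gained (+) or lost (−)
    adduct: str
    charge: int
    theoretical_mz: float


@dataclass(frozen=True)
class Annotation:
    peak_index: int
    peak_mz: float
    peak_intensity: float
    ion: IonHypothesis
    error_da: float  # observed − theoretical
    error_ppm: float
    alternative_count: int  # other hypotheses also inside the window


def build_ion_hypotheses(
    frags: Iterable[Fragment],
    charge: int = 1,
    adduct: str = "H",
    delta_set: Sequence[int] = DEFAULT_DELTA_SET,
) -> list[IonHypothesis]:
    """Cartesian product of fragments × δ values × charges 1..*charge*.

    Ordering is deterministic: fragment index, then δ, then charge.
    """
    if charge < 1:
        raise ParameterError(f"charge must be >= 1, got {charge}")
    if not delta_set:
        raise ParameterError("hydrogen-adjustment set must be nonempty")
    cat = cation_mass(adduct)
    ions = []
    for frag in sorted(frags, key=lambda f: f.index):
        for delta in sorted(delta_set):
            for z in range(1, charge + 1):
                mz = (frag.neutral_mass + delta * H_MASS + z * cat) / z
                if mz <= 0:
                    continue
                ions.append(IonHypothesis(frag, delta, adduct, z, mz))
    return ions


def annotate_peaks(
    s: Spectrum, ions: Sequence[IonHypothesis], tolerance: float = DEFAULT_TOLERANCE
) -> list[Annotation]:
    """Best-match annotation of every peak within the absolute tolerance.

    A peak matched by several hypotheses takes the one with the smallest
    |error|; ties break toward smaller δ, then smaller fragment vertex-set
    size, then lower fragment index, then lower charge. Exactly one
    annotation per matched peak, ordered by peak m/z; unmatched peaks are
    simply absent from the result.
    """
    if tolerance <= 0:
        raise ParameterError(f"tolerance must be > 0 Da, got {tolerance}")
    if not ions:
        raise ParameterError("no ion hypotheses supplied")

    theo = np.array([ion.theoretical_mz for ion in ions])
    order = np.argsort(theo, kind="stable")
    theo_sorted = theo[order]

    annotations = []
    for peak_index, (mz, inten) in enumerate(s.peaks):
        lo = np.searchsorted(theo_sorted, mz - tolerance, side="left")
        hi = np.searchsorted(theo_sorted, mz + tolerance, side="right")
        if lo == hi:
            continue
        candidates = [ions[order[k]] for k in range(lo, hi)]
        # inclusive window; searchsorted bounds are already inclusive for
        # exact endpoint values since side='left'/'right' bracket equals
        best = min(
            candidates,
            key=lambda ion: (
                abs(mz - ion.theoretical_mz),
                ion.hydrogen_adjustment,
                len(ion.fragment.vertex_set),
                ion.fragment.index,
                ion.charge,
            ),
        )
        err = mz - best.theoretical_mz
        annotations.append(
            Annotation(
                peak_index=peak_index,
                peak_mz=mz,
                peak_intensity=inten,
                ion=best,
                error_da=err,
                error_ppm=err / best.theoretical_mz * 1e6,
                alternative_count=len(candidates) - 1,
            )
        )
    return annotations


def annotation_rate(annotations: Sequence[Annotation], s: Spectrum) -> float:
    """Fraction of the spectrum's peaks that received an annotation."""
    if not s.peaks:
        raise ParameterError("annotation rate is undefined for an empty spectrum")
    return len(annotations) / len(s.peaks)
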