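"""Monoisotopic mass constants.

All masses are in daltons (Da). Atomic masses are the NIST monoisotopic
(most abundant isotope) values; cation masses account for the missing
electron, so ``m/z = (M_neutral + z * CATION_MASS[adduct]) / z`` for an
[M + z·adduct]^z+ ion.
"""

from __future__ import annotations

from .errors import PnpError

#: Monoisotopic atomic masses (Da), NIST.
ELEMENT_MASS: dict[str, float] = {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "S": 31.972070690,
    "P": 30.973761510,
    "F": 18.998403163,
    "Cl": 34.968852682,
    "Br": 78.918337600,
    "I": 126.904473000,
    "Se": 79.916521800,
    "B": 11.009305400,
    "Si": 27.976926535,
    "Na": 22.989769282,
    "K": 38.963706487,
}

H_MASS = ELEMENT_MASS["H"]
WATER_MASS = 2 * H_MASS + ELEMENT_MASS["O"]

#: Mass of a bare proton (H minus one electron), used for charge bookkeeping.
PROTON_MASS = 1.007276

ELECTRON_MASS = 0.000548580

#: Cationizing adduct masses (Da): atom mass minus one electron.
CATION_MASS: dict[str, float] = {
    "H": PROTON_MASS,
    "Na": ELEMENT_MASS["Na"] - ELECTRON_MASS,
    "K": ELEMENT_MASS["K"] - ELECTRON_MASS,
}

ADDUCTS = tuple(CATION_MASS)

#: Monoisotopic residue masses (Da) of the 20 proteinogenic amino acids
#: (residue = amino acid minus water, i.e. the chain-internal unit).
RESIDUE_MASS: dict[str, float] = {
    "Gly": 57.02146,
    "Ala": 71.03711,
    "Ser": 87.03203,
    "Pro": 97.05276,
    "Val": 99.06841,
    "Thr": 101.04768,
    "Cys": 103.00919,
    "Leu": 113.08406,
    "Ile": 113.08406,
    "Asn": 114.04293,
    "Asp": 115.02694,
    "Gln": 128.05858,
    "Lys": 128.09496,
    "Glu": 129.04259,
    "Met": 131.04049,
    "His": 137.05891,
    "Phe": 147.06841,
    "Arg": 156.10111,
    "Tyr": 163.06333,
    "Trp": 186.07931,
}


def element_mass(symbol: str) -> float:
    """Monoisotopic mass of one atom of *symbol*; raises if unknown."""
    try:
        return ELEMENT_MASS[symbol]
    except KeyError:
        raise PnpError(f"no monoisotopic mass known for element {symbol!r}") from None


def cation_mass(adduct: str) -> float:
    """Mass of the cationizing adduct ('H', 'Na' or 'K')."""
    try:
        return CATION_MASS[adduct]
    except KeyError:
        raise PnpError(
            f"unknown adduct {adduct!r}; supported: {', '.join(ADDUCTS)}"
        ) from None
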