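"""Monoisotopic mass arithmetic for negative-mode LC-MS/MS annotation.

This module is the numeric substrate of the package: elemental-formula
parsing, monoisotopic (most-abundant-isotope) masses, deprotonated-ion and
formate-adduct m/z, signed ppm mass error, and neutral-loss arithmetic.

Conventions
-----------
* Monoisotopic element masses are IUPAC values hard-coded to >= 6 decimals.
* The deprotonated ion [M-H]- is computed by subtracting the mass of a
  hydrogen *atom* and adding back the electron mass, i.e. a net loss of one
  proton (1.007276 Da).  This convention reproduces reference calculated m/z
  values such as 679.3699 for C36H56O12.
* ppm error is signed: (observed - calculated) / calculated * 1e6.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "FormulaError",
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "Adduct",
    "ADDUCTS",
    "get_adduct",
    "adduct_mz",
    "MassMeasurement",
    "ppm_error",
    "neutral_losses",
]

#: Most-abundant-isotope masses (Da), IUPAC.  The supported element table is
#: deliberately small: CHNOPS covers saponins, oligosaccharide esters and
#: xanthone glycosides.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

ELECTRON_MASS: float = 0.00054857990946
#: Mass of a proton = H atom minus its electron; the net mass removed on
#: deprotonation.
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS


class FormulaError(ValueError):
    """Raised for malformed formula strings or unsupported elements."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map; the unit of all mass arithmetic.

    Counts are non-negative integers over the supported element table.
    Instances round-trip through their canonical Hill-order string form
    (carbon first, then hydrogen, then remaining elements alphabetically).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element symbol: {element!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {element}: {n}")
            if n:
                clean[element] = n
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"cannot remove {other} from {self}: element {el} underflows"
                )
        return MolecularFormula(merged)

    def contains(self, other: "MolecularFormula") -> bool:
        """Element-wise containment (every count of *other* <= ours)."""
        return all(self.counts.get(el, 0) >= n for el, n in other.counts.items())

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        parts = []
        for el in ("C", "H"):
            n = self.counts.get(el, 0)
            if n:
                parts.append(el if n == 1 else f"{el}{n}")
        for el in sorted(self.counts):
            if el in ("C", "H"):
                continue
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __bool__(self) -> bool:
        return bool(self.counts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse an elemental formula string such as ``"C36H56O12"``.

    Underscore-decorated dialects (``"C_36_H_56_O_12_"``) and embedded
    whitespace are accepted.  Raises :class:`FormulaError` naming the
    offending token for unknown symbols or malformed input.
    """
    stripped = re.sub(r"[\s_]+", "", text or "")
    if not stripped:
        raise FormulaError(f"empty formula string: {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(stripped):
        match = _TOKEN.match(stripped, pos)
        if match is None or match.start() != pos or not match.group(0):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {stripped[pos:]!r}"
            )
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Sum of count x most-abundant-isotope mass over all elements (Da)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if not formula:
        raise FormulaError("cannot compute the mass of an empty formula")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items())


@dataclass(frozen=True)
class Adduct:
    """A quasi-molecular ion species: name, signed mass delta (Da), charge."""

    name: str
    mass_delta: float
    charge: int = -1


_FORMIC_ACID = MolecularFormula({"C": 1, "H": 2, "O": 2})

#: Supported negative-mode quasi-molecular ions.
ADDUCTS: dict[str, Adduct] = {
    "[M-H]-": Adduct("[M-H]-", -PROTON_MASS, -1),
    "[M+HCOOH-H]-": Adduct(
        "[M+HCOOH-H]-", monoisotopic_mass(_FORMIC_ACID) - PROTON_MASS, -1
    ),
}


def get_adduct(name: str | Adduct) -> Adduct:
    """Resolve an adduct by name; unicode minus signs are normalized."""
    if isinstance(name, Adduct):
        return name
    key = name.replace("−", "-").replace("⁻", "-").replace(" ", "")
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(
            f"unsupported adduct {name!r}; supported: {sorted(ADDUCTS)}"
        ) from None


def adduct_mz(formula: MolecularFormula | str, adduct: str | Adduct = "[M-H]-") -> float:
    """Theoretical m/z of *formula* under the given singly-charged adduct."""
    return monoisotopic_mass(formula) + get_adduct(adduct).mass_delta


@dataclass(frozen=True)
class MassMeasurement:
    """A (calculated, observed) m/z pair with its signed ppm error."""

    calc_mz: float
    obs_mz: float

    @property
    def ppm(self) -> float:
        return ppm_error(self.calc_mz, self.obs_mz)


def ppm_error(calc: float, obs: float) -> float:
    """Signed mass error (obs - calc) / calc * 1e6; requires calc > 0."""
    if not calc > 0:
        raise ValueError(f"calculated m/z must be positive, got {calc}")
    return (obs - calc) / calc * 1e6


def neutral_losses(
    precursor_mz: float,
    fragments: Iterable[float],
    tol: float = 0.02,
    pairwise: bool = False,
) -> list[tuple[float, float]]:
    """Neutral-loss ladder: (fragment, precursor - fragment) for each fragment.

    Fragments lying above the precursor by more than *tol* are flagged with a
    warning and skipped rather than raising.  With ``pairwise=True`` the
    consecutive-ladder differences (lower fragment, upper - lower) are
    appended, which is how sequential glycosyl losses between product ions
    are read off a spectrum.
    """
    frags = sorted(float(f) for f in fragments)
    losses: list[tuple[float, float]] = []
    for f in frags:
        if f > precursor_mz + tol:
            warnings.warn(
                f"fragment m/z {f} exceeds precursor {precursor_mz} by more "
                f"than {tol} Da; skipped",
                stacklevel=2,
            )
            continue
        losses.append((f, precursor_mz - f))
    if pairwise:
        kept = [f for f, _ in losses]
        for lo, hi in zip(kept, kept[1:]):
            losses.append((lo, hi - lo))
    return losses
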