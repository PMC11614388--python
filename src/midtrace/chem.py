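"""Elemental formulas, TBDMS fragment arithmetic, and natural isotope patterns.

GC-MS isotopologue data report intensities at nominal mass shifts m+0..m+K
above the monoisotopic fragment mass.  The theoretical pattern of an
unlabeled fragment is the convolution, over every atom, of that atom's
single-atom mass-shift distribution.  For TBDMS-derivatized metabolites the
characteristic M-57 fragment (loss of a tert-butyl radical from the
derivative) carries silicon, whose heavy isotopes (29Si, 30Si) contribute
substantially at m+1/m+2 and must be included in the correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "FormulaError",
    "ElementalFormula",
    "IsotopeTable",
    "DEFAULT_ISOTOPES",
    "parse_formula",
    "tbdms_m57_fragment",
    "natural_pattern",
    "convolve",
]


class FormulaError(ValueError):
    """Malformed formula string or infeasible formula arithmetic."""


# IUPAC-style terrestrial isotopic abundances, indexed by integer mass shift
# above the lightest isotope.  Gaps (e.g. 35S does not exist) are zeros.
_RAW_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "Si": (0.92223, 0.04685, 0.03092),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "P": (1.0,),
}


class IsotopeTable:
    """Per-element single-atom mass-shift distributions.

    Each element maps to a dense abundance vector indexed by mass shift
    (index 0 = lightest isotope).  Abundances must sum to 1 within 1e-12.
    """

    def __init__(self, abundances: Mapping[str, tuple[float, ...]] | None = None):
        raw = dict(_RAW_ABUNDANCES)
        if abundances:
            raw.update({k: tuple(v) for k, v in abundances.items()})
        self._patterns: dict[str, np.ndarray] = {}
        for element, values in raw.items():
            vec = np.asarray(values, dtype=float)
            if vec.ndim != 1 or vec.size == 0:
                raise ValueError(f"{element}: abundance vector must be 1-D and non-empty")
            if np.any(vec < 0) or np.any(vec > 1):
                raise ValueError(f"{element}: abundances must lie in [0, 1]")
            if abs(vec.sum() - 1.0) > 1e-12:
                raise ValueError(f"{element}: abundances sum to {vec.sum()!r}, not 1")
            self._patterns[element] = vec

    def __contains__(self, element: str) -> bool:
        return element in self._patterns

    def elements(self) -> Iterator[str]:
        return iter(self._patterns)

    def pattern(self, element: str) -> np.ndarray:
        """Single-atom mass-shift distribution of *element* (copy)."""
        try:
            return self._patterns[element].copy()
        except KeyError:
            raise KeyError(f"no isotope data for element {element!r}") from None


DEFAULT_ISOTOPES = IsotopeTable()

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Integer atom counts of a (possibly derivatized) fragment.

    Immutable; arithmetic returns new formulas and refuses to go negative.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        if any(n < 0 for n in clean.values()):
            raise FormulaError(f"negative atom count in {clean}")
        # the empty formula is allowed: it is the identity of formula
        # addition and its isotope pattern is a delta at m+0
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            new = merged.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"cannot remove {n} {el} from {self}: only {merged.get(el, 0)} present"
                )
            merged[el] = new
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 1:
            raise FormulaError(f"formula multiplier must be a positive integer, got {k!r}")
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        ordered = sorted(
            self.counts, key=lambda el: (el != "C", el != "H", el)
        )
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in ordered
        )

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())


def parse_formula(text: str, isotopes: IsotopeTable = DEFAULT_ISOTOPES) -> ElementalFormula:
    """Parse a molecular formula string such as ``"C11H25O3Si2"``.

    A count of 1 may be implicit.  Element symbols absent from the isotope
    table are rejected so typos never propagate into correction matrices.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"empty formula string: {text!r}")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at {text[pos:]!r}")
        element, digits = m.group(1), m.group(2)
        if element not in isotopes:
            raise FormulaError(f"unknown element {element!r} in formula {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


# One TBDMS group replaces an active hydrogen with Si(CH3)2C(CH3)3 = C6H15Si;
# the M-57 ion then loses one tert-butyl radical, C4H9.
_TBDMS_GROUP = ElementalFormula({"C": 6, "H": 15, "Si": 1})
_TERT_BUTYL = ElementalFormula({"C": 4, "H": 9})
_H = ElementalFormula({"H": 1})


def tbdms_m57_fragment(parent: ElementalFormula, n_sites: int) -> ElementalFormula:
    """Elemental composition of the M-57 fragment of a TBDMS derivative.

    Each of the *n_sites* active hydrogens (carboxyl, hydroxyl, amine) is
    replaced by a TBDMS group; the monitored M-57 ion has lost a single
    tert-butyl group regardless of the number of sites.
    """
    if n_sites < 1:
        raise FormulaError(f"n_sites must be >= 1, got {n_sites}")
    if parent["H"] < n_sites:
        raise FormulaError(
            f"{parent} has {parent['H']} H but {n_sites} derivatization sites"
        )
    return parent - n_sites * _H + n_sites * _TBDMS_GROUP - _TERT_BUTYL


def convolve(a: np.ndarray, b: np.ndarray, K: int | None = None) -> np.ndarray:
    """Discrete convolution of two mass-shift patterns, truncated at m+K.

    Truncation only drops tail mass; a delta at m+0 is the identity.
    """
    out = np.convolve(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    if K is not None:
        out = out[: K + 1]
        if out.size < K + 1:
            out = np.pad(out, (0, K + 1 - out.size))
    return out


def _pattern_power(single: np.ndarray, n: int, K: int | None) -> np.ndarray:
    """single-atom pattern convolved with itself n times (binary exponentiation)."""
    result = np.array([1.0])
    base = single
    while n:
        if n & 1:
            result = convolve(result, base, K)
        n >>= 1
        if n:
            base = convolve(base, base, K)
    return result


def natural_pattern(
    formula: ElementalFormula | None,
    isotopes: IsotopeTable = DEFAULT_ISOTOPES,
    K: int | None = None,
) -> np.ndarray:
    """Theoretical natural-abundance isotope pattern of *formula* up to m+K.

    The m+0 entry equals the product over elements of (lightest-isotope
    abundance)**count.  ``formula=None`` denotes the empty formula and yields
    the identity pattern (delta at m+0).
    """
    result = np.array([1.0])
    if formula is None:
        atoms: Mapping[str, int] = {}
    else:
        atoms = formula.counts
    for element, count in atoms.items():
        single = isotopes.pattern(element)
        result = convolve(result, _pattern_power(single, count, K), K)
    if K is not None and result.size < K + 1:
        result = np.pad(result, (0, K + 1 - result.size))
    return result
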