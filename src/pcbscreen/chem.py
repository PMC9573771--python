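"""Elemental-formula algebra and accurate-mass arithmetic for negative-mode
suspect screening.

The element set is restricted to C, H, N, O, S, Cl — the composition space of
(chloro)biphenyl metabolites and their phase-II conjugates. All masses are
monoisotopic, in Da. Deprotonated-ion m/z values are computed *without* an
electron-mass correction: the convention reproduces the accurate masses
conventionally printed for [M-H]- screening work, and including the ~0.55 mDa
electron term would shift every value by about half a millidalton.
"""

from __future__ import annotations

import math
import re
from collections.abc import Mapping
from dataclasses import dataclass, field

__all__ = [
    "ElementalFormula",
    "FormulaError",
    "InfeasibleTransformation",
    "IonSpecies",
    "IsotopePattern",
    "IsotopePeak",
    "MONOISOTOPIC_MASS",
    "chlorine_isotope_pattern",
    "combine",
    "formula_mass",
    "monoisotopic_mz",
    "parse_formula",
    "ppm_difference",
]

#: IUPAC monoisotopic atomic masses (Da) of the supported elements.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "Cl": 34.96885268,
}

#: Natural isotopic abundances of chlorine (35Cl / 37Cl).
CL35_ABUNDANCE = 0.7576
CL37_ABUNDANCE = 0.2424
#: Mass gap between 37Cl and 35Cl (Da); the "M+2" spacing of Cl patterns.
CL_MASS_DELTA = 36.96590260 - 34.96885268

#: Hill-order listing: C first, H second, then alphabetical.
_HILL_ORDER = ("C", "H", "Cl", "N", "O", "S")

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE_TRAIL_RE = re.compile(r"(\^\d*[+\-−–]+|[+\-−–]+)$")


class FormulaError(ValueError):
    """Malformed or unsupported formula text or composition."""


class InfeasibleTransformation(ValueError):
    """A formula delta would drive some element count negative."""


@dataclass(frozen=True)
class ElementalFormula(Mapping):
    """Immutable element->count map over {C, H, N, O, S, Cl}.

    Behaves as a mapping; absent elements read as count 0. Equality is
    count-wise, so ``parse_formula("C12H9Cl") == parse_formula("H9C12Cl")``.
    """

    _counts: tuple[tuple[str, int], ...] = field(default=())

    @staticmethod
    def from_counts(counts: Mapping[str, int]) -> "ElementalFormula":
        clean = {}
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element {el!r}")
            if n < 0:
                raise InfeasibleTransformation(
                    f"negative count for {el}: {n}"
                )
            if n:
                clean[el] = int(n)
        ordered = tuple((el, clean[el]) for el in _HILL_ORDER if el in clean)
        return ElementalFormula(ordered)

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return dict(self._counts).get(el, 0)

    def __iter__(self):
        return iter(el for el, _ in self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el) -> bool:  # Mapping default uses __getitem__
        return any(e == el for e, _ in self._counts)

    # -- algebra -----------------------------------------------------------
    def __add__(self, delta: Mapping[str, int]) -> "ElementalFormula":
        return combine(self, delta)

    @property
    def mass(self) -> float:
        """Monoisotopic mass of the neutral composition (Da)."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self._counts)

    def hill(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        for el, n in self._counts:
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-order formula string such as ``"C12H8ClO"``.

    A trailing charge marker (``-``, ``^-``, unicode minus/en-dash) is
    ignored, so anion strings transcribed from screening tables parse
    directly. Underscores used as subscript markers are stripped.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"not a formula string: {text!r}")
    body = text.strip().replace("_", "")
    body = _CHARGE_TRAIL_RE.sub("", body)
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN_RE.finditer(body):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormulaError(f"cannot parse {text!r} at {body[pos:]!r}")
        pos = m.end()
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {el!r} in {text!r}")
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n == 0:
                raise FormulaError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(body) or not counts:
        raise FormulaError(f"cannot parse {text!r}")
    return ElementalFormula.from_counts(counts)


def combine(base: ElementalFormula, delta: Mapping[str, int]) -> ElementalFormula:
    """Count-wise sum of a formula and a signed delta.

    Raises :class:`InfeasibleTransformation` if any resulting count would be
    negative (e.g. removing two Cl from a monochlorinated skeleton).
    """
    counts = {el: base[el] for el in base}
    for el, n in delta.items():
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {el!r} in delta")
        new = counts.get(el, 0) + n
        if new < 0:
            raise InfeasibleTransformation(
                f"{base.hill()} {'+' if n >= 0 else ''}{n}{el} "
                f"would give count {new}"
            )
        counts[el] = new
    return ElementalFormula.from_counts(counts)


def delta_mass(delta: Mapping[str, int]) -> float:
    """Monoisotopic mass of a signed formula delta (Da)."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in delta.items())


def formula_mass(f: ElementalFormula | Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a neutral composition."""
    if isinstance(f, ElementalFormula):
        return f.mass
    return delta_mass(f)


@dataclass(frozen=True)
class IonSpecies:
    """A charged species observed in negative-mode electrospray.

    Only the deprotonated molecular anion [M-H]- is supported, the ion type
    under which conjugated biphenyl metabolites are detected.
    """

    neutral: ElementalFormula
    adduct: str = "[M-H]-"
    charge: int = -1

    def __post_init__(self):
        if self.adduct != "[M-H]-" or self.charge != -1:
            raise FormulaError(f"unsupported adduct {self.adduct!r}")

    @property
    def formula(self) -> ElementalFormula:
        """Composition of the anion (neutral minus one H)."""
        return combine(self.neutral, {"H": -1})


def monoisotopic_mz(ion: IonSpecies) -> float:
    """m/z of a deprotonated ion: monoisotopic mass of (neutral - H).

    No electron-mass term is added (see module docstring).
    """
    if ion.neutral["H"] < 1:
        raise FormulaError(
            f"{ion.neutral.hill()} has no H to remove for [M-H]-"
        )
    return ion.neutral.mass - MONOISOTOPIC_MASS["H"]


def anion_mz(neutral: ElementalFormula) -> float:
    """Convenience wrapper: [M-H]- m/z of a neutral formula."""
    return monoisotopic_mz(IonSpecies(neutral))


def ppm_difference(measured: float, calculated: float) -> float:
    """Absolute mass error in parts per million.

    |measured - calculated| / calculated * 1e6, always non-negative.
    """
    if calculated <= 0:
        raise ValueError(f"calculated m/z must be positive, got {calculated}")
    return abs(measured - calculated) / calculated * 1e6


@dataclass(frozen=True)
class IsotopePeak:
    offset: float      # Da above the monoisotopic peak
    abundance: float   # probability of this isotopologue
    fraction: float    # abundance relative to the base (most abundant) peak


@dataclass(frozen=True)
class IsotopePattern:
    """Chlorine isotopologue ladder (M, M+2, M+4, ...) of a composition."""

    peaks: tuple[IsotopePeak, ...]

    @property
    def m2_over_m(self) -> float:
        """(M+2)/(M) abundance ratio; 0.0 for chlorine-free compositions."""
        if len(self.peaks) < 2:
            return 0.0
        return self.peaks[1].abundance / self.peaks[0].abundance


def chlorine_isotope_pattern(f: ElementalFormula) -> IsotopePattern:
    """Binomial 35Cl/37Cl pattern of a formula with n chlorine atoms.

    Peak k sits k*1.99705 Da above the monoisotopic peak with probability
    C(n,k) * 0.7576^(n-k) * 0.2424^k. 13C and other minor isotopes are
    ignored: the chlorine M+2 ladder alone carries the halogenation
    signature used to verify candidate hits.
    """
    n = f["Cl"]
    abunds = [
        math.comb(n, k) * CL35_ABUNDANCE ** (n - k) * CL37_ABUNDANCE ** k
        for k in range(n + 1)
    ]
    base = max(abunds)
    peaks = tuple(
        IsotopePeak(offset=k * CL_MASS_DELTA, abundance=a, fraction=a / base)
        for k, a in enumerate(abunds)
    )
    return IsotopePattern(peaks)
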