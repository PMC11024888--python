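"""Elemental-composition arithmetic and mass bookkeeping.

All masses in the package flow through this module: monoisotopic and
nominal mass of an elemental composition, m/z of adducted species, and
ppm-tolerance comparison. Monoisotopic atomic masses are used throughout
because every printed fragment and precursor value in the source data is
monoisotopic; charged-species m/z uses the electron-corrected proton mass
(1.00727646 Da) so that ppm-level matching is exact, not just correct to
one decimal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

__all__ = [
    "ATOMIC_MASS",
    "NOMINAL_MASS",
    "PROTON_MASS",
    "ElementalComposition",
    "Adduct",
    "ADDUCTS",
    "WATER",
    "monoisotopic_mass",
    "nominal_mass",
    "adduct_mz",
    "within_ppm",
    "ppm_error",
    "round_half_up",
]

#: Monoisotopic atomic masses (Da) of the supported elements.
ATOMIC_MASS: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Integer mass numbers used for nominal (unit-resolution) masses.
NOMINAL_MASS: Dict[str, int] = {"H": 1, "C": 12, "N": 14, "O": 16, "P": 31, "S": 32}

#: Mass of a proton (electron-corrected), Da per charge.
PROTON_MASS = 1.00727646

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """An immutable element -> count map over {C, H, N, O, P, S}.

    Counts are non-negative integers; addition and subtraction are
    element-wise and subtraction raises rather than produce a negative
    count (a composition is a molecule fragment, not a delta).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for elem, n in self.counts.items():
            if elem not in ATOMIC_MASS:
                raise ValueError(f"unsupported element: {elem!r}")
            if not isinstance(n, int):
                raise TypeError(f"count for {elem} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for {elem}: {n}")
            if n > 0:
                clean[elem] = n
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    @classmethod
    def parse(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-like formula string such as ``"C42H81NO8"``."""
        if not formula:
            return cls({})
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
            pos = m.end()
            elem = m.group(1)
            if elem not in ATOMIC_MASS:
                raise ValueError(f"unsupported element: {elem!r} in {formula!r}")
            counts[elem] = counts.get(elem, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        return cls(counts)

    def formula(self) -> str:
        """Hill-notation formula string (C, H first, then alphabetical)."""
        order = [e for e in ("C", "H") if e in self.counts]
        order += sorted(e for e in self.counts if e not in ("C", "H"))
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] != 1 else e for e in order
        )

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for elem, n in other.counts.items():
            merged[elem] = merged.get(elem, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for elem, n in other.counts.items():
            left = merged.get(elem, 0) - n
            if left < 0:
                raise ValueError(
                    f"subtraction yields negative {elem} count "
                    f"({self.formula()} - {other.formula()})"
                )
            merged[elem] = left
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("multiplier must be a non-negative integer")
        return ElementalComposition({e: n * k for e, n in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, elem: str) -> int:
        return self.counts.get(elem, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(ATOMIC_MASS[e] * n for e, n in self.counts.items())

    @property
    def nominal_mass(self) -> int:
        return sum(NOMINAL_MASS[e] * n for e, n in self.counts.items())


WATER = ElementalComposition({"H": 2, "O": 1})


def monoisotopic_mass(composition: ElementalComposition | str) -> float:
    """Monoisotopic mass (Da) of a composition or formula string."""
    if isinstance(composition, str):
        composition = ElementalComposition.parse(composition)
    return composition.monoisotopic_mass


def nominal_mass(composition: ElementalComposition | str) -> int:
    """Nominal (integer, unit-resolution) mass of a composition."""
    if isinstance(composition, str):
        composition = ElementalComposition.parse(composition)
    return composition.nominal_mass


@dataclass(frozen=True)
class Adduct:
    """A positive-mode adduct: name, charge, and the neutral atoms added.

    The added composition excludes the charging protons: ``[M+NH4]+`` adds
    NH3 and one proton, ``[M+2H]2+`` adds nothing but two protons.
    """

    name: str
    charge: int
    added_composition: ElementalComposition

    def __post_init__(self) -> None:
        if self.charge not in (1, 2):
            raise ValueError(f"adduct charge must be 1 or 2, got {self.charge}")

    def mz(self, neutral_mass: float) -> float:
        return adduct_mz(neutral_mass, self)


_NH3 = ElementalComposition({"N": 1, "H": 3})

#: The five positive-mode adducts observed for sphingolipids.
ADDUCTS: Dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", 1, ElementalComposition({})),
    "[M+NH4]+": Adduct("[M+NH4]+", 1, _NH3),
    "[M+2H]2+": Adduct("[M+2H]2+", 2, ElementalComposition({})),
    "[M+H+NH4]2+": Adduct("[M+H+NH4]2+", 2, _NH3),
    "[M+2NH4]2+": Adduct("[M+2NH4]2+", 2, _NH3 * 2),
}


def adduct_mz(neutral_mass: float, adduct: Adduct) -> float:
    """m/z of an adducted species.

    m/z = (M + mass(added atoms) + z * m_proton) / z.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (
        neutral_mass
        + adduct.added_composition.monoisotopic_mass
        + adduct.charge * PROTON_MASS
    ) / adduct.charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error of *observed* relative to *theoretical*, in ppm."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return (observed - theoretical) / theoretical * 1e6


def within_ppm(observed: float, theoretical: float, tol: float) -> bool:
    """True when |observed - theoretical| / theoretical <= tol ppm."""
    return abs(ppm_error(observed, theoretical)) <= tol


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed m/z tables do."""
    factor = 10.0**ndigits
    import math

    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
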