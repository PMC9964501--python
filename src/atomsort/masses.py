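"""Molecular-formula parsing, monoisotopic/average masses, and adduct m/z.

Masses are computed from tables pinned in this module so reported values do
not drift with an external dependency:

* monoisotopic masses: most-abundant-isotope masses, CODATA/AME2020 values
  (≥ 6 decimals);
* average masses: IUPAC 2021 standard atomic weights (conventional values
  for the interval elements H, C, N, O, S, Cl).

Adduct m/z values carry the electron-mass correction
(m/z = (mass − z·mₑ)/|z| with mₑ = 0.000549 Da), which is what
high-resolution MS "calcd." values print.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "Formula",
    "AdductSpec",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "average_mass",
    "adduct_mz",
    "ELECTRON_MASS",
    "PROTON_MASS",
]

# most-abundant-isotope masses, Da
MONOISOTOPIC: Mapping[str, float] = {
    "H": 1.0078250319,
    "D": 2.0141017781,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
}

# standard atomic weights (conventional values), g/mol
AVERAGE: Mapping[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.973762,
    "Na": 22.98976928,
    "K": 39.0983,
    "Cl": 35.45,
}

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS  # 1.007276...


@dataclass(frozen=True)
class Formula:
    """Element → count mapping over the supported element set."""

    element_counts: tuple[tuple[str, int], ...]

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.element_counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def is_empty(self) -> bool:
        return all(n == 0 for _, n in self.element_counts)

    def add(self, other: "Formula") -> "Formula":
        merged = self.counts
        for el, n in other.element_counts:
            merged[el] = merged.get(el, 0) + n
        return _from_counts(merged)

    def subtract(self, other: "Formula") -> "Formula":
        merged = self.counts
        for el, n in other.element_counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(f"negative count for {el} after subtraction")
        return _from_counts(merged)


@dataclass(frozen=True)
class AdductSpec:
    """Ion species: 'M+H', 'M+Na', 'M-H', or 'as-given' (formula is already
    the ion).  Only |charge| = 1 is supported."""

    kind: str
    charge: int

    def __post_init__(self) -> None:
        if self.kind not in ("M+H", "M+Na", "M-H", "as-given"):
            raise ValueError(f"unsupported adduct kind {self.kind!r}")
        if abs(self.charge) != 1:
            raise ValueError("only singly charged species are supported")


def _hill_order(counts: dict[str, int]) -> list[str]:
    els = [e for e, n in counts.items() if n > 0]
    if "C" in els:
        rest = sorted(e for e in els if e not in ("C", "H"))
        return ["C"] + (["H"] if "H" in els else []) + rest
    return sorted(els)


def _from_counts(counts: dict[str, int]) -> Formula:
    return Formula(tuple((e, counts[e]) for e in _hill_order(counts)))


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a molecular formula string such as ``C14H17N2O3``.

    Counts default to 1; parenthesised groups with multipliers are allowed
    (``(CH2)6``).  Unknown element symbols raise a :class:`ValueError`
    naming the symbol.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    stack: list[dict[str, int]] = [{}]
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos:
            raise ValueError(f"cannot parse formula at {text[pos:]!r}")
        if m.group(3):  # '('
            stack.append({})
        elif m.group(4):  # ')'
            if len(stack) == 1:
                raise ValueError("unbalanced ')' in formula")
            group = stack.pop()
            mult = int(m.group(5)) if m.group(5) else 1
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + n * mult
        else:
            el = m.group(1)
            if el not in MONOISOTOPIC:
                raise ValueError(f"unknown element symbol {el!r}")
            n = int(m.group(2)) if m.group(2) else 1
            stack[-1][el] = stack[-1].get(el, 0) + n
        pos = m.end()
    if len(stack) != 1:
        raise ValueError("unbalanced '(' in formula")
    if all(n == 0 for n in stack[0].values()) or not stack[0]:
        raise ValueError("formula has no atoms")
    return _from_counts(stack[0])


def format_formula(formula: Formula) -> str:
    """Canonical (Hill order) formula string; count 1 is implicit."""
    parts = []
    for el, n in formula.element_counts:
        if n > 0:
            parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of most-abundant-isotope masses, Da."""
    if formula.is_empty():
        raise ValueError("empty formula")
    return sum(MONOISOTOPIC[el] * n for el, n in formula.element_counts)


def average_mass(formula: Formula) -> float:
    """Sum of standard atomic weights, g/mol."""
    if formula.is_empty():
        raise ValueError("empty formula")
    return sum(AVERAGE[el] * n for el, n in formula.element_counts)


_H = Formula((("H", 1),))
_NA = Formula((("Na", 1),))


def adduct_mz(formula: Formula, adduct: AdductSpec) -> float:
    """Electron-corrected monoisotopic m/z of an adduct ion.

    For kinds ``M+H``/``M+Na``/``M-H`` the formula is the NEUTRAL molecule;
    for ``as-given`` it is already the ion composition.  m/z =
    (monoisotopic(ion) − charge·mₑ)/|charge|.
    """
    if adduct.kind == "M+H":
        ion = formula.add(_H)
        expected_charge = 1
    elif adduct.kind == "M+Na":
        ion = formula.add(_NA)
        expected_charge = 1
    elif adduct.kind == "M-H":
        ion = formula.subtract(_H)
        expected_charge = -1
    else:
        ion = formula
        expected_charge = adduct.charge
    if adduct.charge != expected_charge:
        raise ValueError(
            f"adduct kind {adduct.kind} implies charge {expected_charge:+d}"
        )
    mass = monoisotopic_mass(ion)
    return (mass - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)
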