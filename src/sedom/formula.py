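"""Neutral molecular formulas and exact-mass arithmetic.

A dissolved organic matter (DOM) molecule measured by negative-ion FT-ICR MS
is represented here by its neutral elemental composition over C, H, N, O, S
and P. Ions are singly charged deprotonated molecules [M-H]-, so the measured
m/z is the neutral monoisotopic mass minus one proton (both electrons are
retained by the anion).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "FormulaComposition",
    "neutral_mass",
    "ion_mz",
    "parse_formula",
]

# IUPAC/CODATA monoisotopic atomic masses (Da), most abundant isotope.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of the proton (Da). Deprotonation of M to [M-H]- removes one proton
#: but no electrons, so ion m/z = neutral mass - PROTON_MASS.
PROTON_MASS = 1.00727646

_HILL_ORDER = ("C", "H", "N", "O", "P", "S")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True, order=True)
class FormulaComposition:
    """Element counts of one neutral molecular formula.

    Counts are non-negative integers; at least one carbon and one hydrogen
    are required (CH-free species are outside the assignment domain).
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"element count {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"element count {name} must be >= 0, got {v}")
        if self.c < 1:
            raise ValueError("composition must contain at least one carbon")
        if self.h < 1:
            raise ValueError("composition must contain at least one hydrogen")

    @property
    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s, "P": self.p}

    @property
    def family(self) -> str:
        """Heteroatom family: CHO, CHON, CHOS or CHONS (P appended if present)."""
        fam = "CHO" + ("N" if self.n else "") + ("S" if self.s else "")
        return fam + ("P" if self.p else "")

    def hill(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        for el in _HILL_ORDER:
            cnt = self.counts[el]
            if cnt == 0:
                continue
            parts.append(el if cnt == 1 else f"{el}{cnt}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def neutral_mass(f: FormulaComposition) -> float:
    """Monoisotopic mass (Da) of the neutral molecule."""
    return sum(MONOISOTOPIC_MASS[el] * cnt for el, cnt in f.counts.items())


def ion_mz(f: FormulaComposition) -> float:
    """m/z of the singly charged deprotonated anion [M-H]-.

    Requires at least one hydrogen to remove (guaranteed by the type).
    """
    if f.h < 1:  # defensive; the dataclass already enforces h >= 1
        raise ValueError("cannot deprotonate a composition without hydrogen")
    return neutral_mass(f) - PROTON_MASS


def parse_formula(text: str) -> FormulaComposition:
    """Parse a Hill-order formula string such as ``C15H20O6``.

    Round-trips with :meth:`FormulaComposition.hill`. Unknown elements or
    repeated element symbols are rejected.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty formula string")
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos or not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {el!r} in formula {text!r}")
        if el in counts:
            raise ValueError(f"element {el} repeated in formula {text!r}")
        counts[el] = int(num) if num else 1
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"could not parse formula {text!r}")
    return FormulaComposition(
        c=counts.get("C", 0),
        h=counts.get("H", 0),
        n=counts.get("N", 0),
        o=counts.get("O", 0),
        s=counts.get("S", 0),
        p=counts.get("P", 0),
    )
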