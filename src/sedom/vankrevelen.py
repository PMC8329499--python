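"""Van Krevelen compound-class windows over (O/C, H/C) space.

Each formula is binned into one of seven biochemical compound categories by
its O/C and H/C ratios. Window endpoints carry explicit open/closed flags
(interval notation like ``(0,0.3]``); adjacent windows share boundary lines,
so windows are evaluated in a fixed priority order and the first match wins.
Formulas matching no window are "unassigned".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "Interval",
    "ClassWindow",
    "DEFAULT_SCHEME",
    "UNASSIGNED",
    "classify",
    "classify_formulas",
    "class_summary",
    "load_scheme",
    "dump_scheme",
]

UNASSIGNED = "unassigned"

_INTERVAL_RE = re.compile(r"^\s*([\[\(])\s*([^,\s]+)\s*,\s*([^,\s\]\)]+)\s*([\]\)])\s*$")


@dataclass(frozen=True)
class Interval:
    """A 1-D interval with open/closed endpoint flags."""

    lo: float
    hi: float
    lo_closed: bool
    hi_closed: bool

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"interval low {self.lo} > high {self.hi}")

    def contains(self, x: float) -> bool:
        lo_ok = x >= self.lo if self.lo_closed else x > self.lo
        hi_ok = x <= self.hi if self.hi_closed else x < self.hi
        return lo_ok and hi_ok

    @classmethod
    def parse(cls, text: str) -> "Interval":
        m = _INTERVAL_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse interval {text!r}")
        return cls(
            lo=float(m.group(2)),
            hi=float(m.group(3)),
            lo_closed=m.group(1) == "[",
            hi_closed=m.group(4) == "]",
        )

    def notation(self) -> str:
        return f"{'[' if self.lo_closed else '('}{self.lo:g},{self.hi:g}{']' if self.hi_closed else ')'}"


@dataclass(frozen=True)
class ClassWindow:
    name: str
    oc: Interval
    hc: Interval
    priority: int

    def contains(self, oc: float, hc: float) -> bool:
        return self.oc.contains(oc) and self.hc.contains(hc)


def _w(priority: int, name: str, oc: str, hc: str) -> ClassWindow:
    return ClassWindow(name=name, oc=Interval.parse(oc), hc=Interval.parse(hc), priority=priority)


#: The seven compound-class windows in evaluation (priority) order. The
#: unsaturated-hydrocarbons window (O/C 0.7-1.5 with H/C below 0.1) is kept
#: exactly as published although it is a suspected transposition of the usual
#: convention; override via a custom scheme if needed.
DEFAULT_SCHEME: tuple[ClassWindow, ...] = (
    _w(1, "lipids", "(0,0.3]", "[1.5,2.0]"),
    _w(2, "aliphatic/proteins", "[0.3,0.67)", "[1.5,2.2]"),
    _w(3, "lignins/CRAM-like", "[0.1,0.67]", "[0.7,1.5]"),
    _w(4, "carbohydrates", "(0.67,1.2]", "[1.5,2.4]"),
    _w(5, "unsaturated hydrocarbons", "[0.7,1.5]", "(0,0.1]"),
    _w(6, "aromatic", "(0,0.67]", "[0.2,0.7)"),
    _w(7, "tannins", "(0.67,1.0]", "[0.6,1.5]"),
)

CLASS_NAMES = tuple(w.name for w in DEFAULT_SCHEME)


def classify(oc: float, hc: float, scheme=DEFAULT_SCHEME) -> str:
    """Category of a formula with the given O/C and H/C ratios."""
    if oc < 0:
        raise ValueError("O/C must be >= 0")
    if hc <= 0:
        raise ValueError("H/C must be > 0")
    for window in sorted(scheme, key=lambda w: w.priority):
        if window.contains(oc, hc):
            return window.name
    return UNASSIGNED


def classify_formulas(indices: pd.DataFrame, scheme=DEFAULT_SCHEME) -> pd.Series:
    """Per-formula category for an index table with ``oc``/``hc`` columns."""
    cats = [classify(row.oc, row.hc, scheme) for row in indices.itertuples(index=False)]
    return pd.Series(cats, index=indices.index, name="category")


def class_summary(
    matrix: pd.DataFrame,
    categories: pd.Series,
    scheme=DEFAULT_SCHEME,
    include_unassigned: bool = False,
) -> pd.DataFrame:
    """Category x sample relative-abundance table.

    ``matrix`` holds per-sample molecule fractions (columns are samples);
    category abundance is the sum of member-molecule fractions, so each
    sample's categories sum to one minus its unassigned fraction.
    """
    missing = matrix.index.difference(categories.index)
    if len(missing):
        raise KeyError(f"molecules without a class assignment: {list(missing)[:5]}")
    names = [w.name for w in sorted(scheme, key=lambda w: w.priority)]
    if include_unassigned:
        names = names + [UNASSIGNED]
    cats = categories.loc[matrix.index]
    out = matrix.groupby(cats, observed=False).sum().reindex(names).fillna(0.0)
    out.index.name = "category"
    return out


def load_scheme(path) -> tuple[ClassWindow, ...]:
    """Read a scheme from YAML: a list of {name, oc, hc} with interval strings."""
    raw = yaml.safe_load(Path(path).read_text())
    windows = []
    for i, entry in enumerate(raw, start=1):
        windows.append(
            ClassWindow(
                name=entry["name"],
                oc=Interval.parse(entry["oc"]),
                hc=Interval.parse(entry["hc"]),
                priority=int(entry.get("priority", i)),
            )
        )
    names = [w.name for w in windows]
    if len(set(names)) != len(names):
        raise ValueError("window names must be unique")
    return tuple(windows)


def dump_scheme(scheme, path) -> None:
    data = [
        {"name": w.name, "oc": w.oc.notation(), "hc": w.hc.notation(), "priority": w.priority}
        for w in sorted(scheme, key=lambda w: w.priority)
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
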