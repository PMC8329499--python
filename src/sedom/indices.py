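"""Per-formula molecular indices and per-sample magnitude-weighted bulk parameters.

Indices
-------
DBE
    double bond equivalents, ``1 + (2C - H + N + P)/2`` — rings plus double
    bonds of the neutral molecule.
AI-mod
    modified aromaticity index, ``(1 + C - O/2 - S - H/2) / (C - O/2 - S - N - P)``,
    a conservative estimate of aromatic character; clamped to [0, 1] (a
    non-positive denominator or a negative raw value maps to 0, values above
    1 to 1).
NOSC
    nominal oxidation state of carbon, ``4 - (4C + H - 3N - 2O - 2S)/C``.
I_DEG
    degradation index: the summed intensity of a fixed list of formulas whose
    relative intensity rises as DOM ages ("positive" list), divided by the
    summed intensity of the positive and negative lists together. The default
    ten-formula set ships as editable package data.

Bulk parameters are magnitude-weighted averages: each per-formula index is
averaged with the formula's within-sample relative intensity as weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .formula import FormulaComposition, neutral_mass, parse_formula

__all__ = [
    "dbe",
    "ai_mod",
    "nosc",
    "index_table",
    "relative_abundance",
    "BulkParameters",
    "bulk_weighted",
    "bulk_table",
    "IdegSet",
    "load_default_ideg_set",
    "degradation_index",
]

BULK_INDEX_COLUMNS = ("mw", "c", "oc", "hc", "nosc", "dbe", "ai_mod")


def dbe(f: FormulaComposition) -> float:
    """Double bond equivalents of the neutral formula."""
    return 1.0 + (2 * f.c - f.h + f.n + f.p) / 2.0


def ai_mod(f: FormulaComposition) -> float:
    """Modified aromaticity index, clamped to [0, 1]."""
    denom = f.c - 0.5 * f.o - f.s - f.n - f.p
    if denom <= 0:
        return 0.0
    raw = (1.0 + f.c - 0.5 * f.o - f.s - 0.5 * f.h) / denom
    return float(min(max(raw, 0.0), 1.0))


def nosc(f: FormulaComposition) -> float:
    """Nominal oxidation state of carbon."""
    return 4.0 - (4 * f.c + f.h - 3 * f.n - 2 * f.o - 2 * f.s) / f.c


def index_table(formulas) -> pd.DataFrame:
    """Tabulate indices for an iterable of formulas (or Hill strings).

    Returns a DataFrame indexed by Hill formula string with columns
    mw, c, h, n, o, s, p, oc, hc, nosc, dbe, ai_mod and family.
    """
    rows = {}
    for f in formulas:
        comp = parse_formula(f) if isinstance(f, str) else f
        key = comp.hill()
        if key in rows:
            continue
        rows[key] = {
            "mw": neutral_mass(comp),
            "c": comp.c,
            "h": comp.h,
            "n": comp.n,
            "o": comp.o,
            "s": comp.s,
            "p": comp.p,
            "oc": comp.o / comp.c,
            "hc": comp.h / comp.c,
            "nosc": nosc(comp),
            "dbe": dbe(comp),
            "ai_mod": ai_mod(comp),
            "family": comp.family,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "formula"
    return out


def relative_abundance(intensities) -> np.ndarray:
    """Normalize one sample's peak magnitudes to fractions of their sum."""
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D intensity vector")
    if (x < 0).any():
        raise ValueError("intensities must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero sample")
    return x / total


@dataclass(frozen=True)
class BulkParameters:
    """Per-sample magnitude-weighted bulk molecular parameters."""

    mw_wa: float
    c_wa: float
    oc_wa: float
    hc_wa: float
    nosc_wa: float
    dbe_wa: float
    aimod_wa: float
    i_deg: float | None
    n_formulas: int

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "mw_wa": self.mw_wa,
            "c_wa": self.c_wa,
            "oc_wa": self.oc_wa,
            "hc_wa": self.hc_wa,
            "nosc_wa": self.nosc_wa,
            "dbe_wa": self.dbe_wa,
            "aimod_wa": self.aimod_wa,
            "i_deg": self.i_deg,
            "n_formulas": self.n_formulas,
        }


def bulk_weighted(
    fractions: pd.Series,
    indices: pd.DataFrame,
    ideg_set: "IdegSet | None" = None,
) -> BulkParameters:
    """Magnitude-weighted bulk parameters for one sample.

    Parameters
    ----------
    fractions
        Relative intensities indexed by Hill formula string. Zero entries are
        treated as undetected. Need not be pre-normalized; weights are taken
        proportional to the values.
    indices
        Output of :func:`index_table` covering every detected formula.
    ideg_set
        Degradation-index formula lists; defaults to the packaged set.
    """
    fractions = fractions[fractions > 0]
    if fractions.empty:
        raise ValueError("sample has no detected formulas")
    missing = fractions.index.difference(indices.index)
    if len(missing):
        raise KeyError(f"formulas missing from the index table: {list(missing)[:5]}")
    w = fractions / fractions.sum()
    sub = indices.loc[w.index]
    means = {col: float((w * sub[col]).sum()) for col in BULK_INDEX_COLUMNS}
    if ideg_set is None:
        ideg_set = load_default_ideg_set()
    return BulkParameters(
        mw_wa=means["mw"],
        c_wa=means["c"],
        oc_wa=means["oc"],
        hc_wa=means["hc"],
        nosc_wa=means["nosc"],
        dbe_wa=means["dbe"],
        aimod_wa=means["ai_mod"],
        i_deg=degradation_index(fractions, ideg_set),
        n_formulas=int(len(w)),
    )


def bulk_table(matrix: pd.DataFrame, indices: pd.DataFrame, ideg_set: "IdegSet | None" = None) -> pd.DataFrame:
    """Bulk parameters for every sample (column) of a molecule x sample matrix."""
    if ideg_set is None:
        ideg_set = load_default_ideg_set()
    rows = {
        sample: bulk_weighted(matrix[sample], indices, ideg_set).as_dict()
        for sample in matrix.columns
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


@dataclass(frozen=True)
class IdegSet:
    """The degradation-index formula lists.

    ``positive`` formulas gain relative intensity as DOM degrades, ``negative``
    ones lose it; I_DEG = sum(positive) / sum(positive + negative).
    """

    positive: tuple[str, ...]
    negative: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"I_DEG lists overlap: {sorted(overlap)}")


_DEFAULT_IDEG: list[IdegSet] = []


def load_default_ideg_set() -> IdegSet:
    """Load the packaged ten-formula degradation-index set.

    The set is a transcription from the literature (the source study does not
    print the formulas); it is deliberately shipped as editable YAML so users
    can substitute a verified or alternative set.
    """
    if not _DEFAULT_IDEG:
        text = resources.files("sedom.data").joinpath("ideg_flerus2012.yaml").read_text()
        raw = yaml.safe_load(text)
        _DEFAULT_IDEG.append(
            IdegSet(positive=tuple(raw["positive"]), negative=tuple(raw["negative"]))
        )
    return _DEFAULT_IDEG[0]


def degradation_index(fractions: pd.Series, ideg_set: IdegSet | None = None) -> float | None:
    """I_DEG for one sample; ``None`` when no listed formula was detected."""
    if ideg_set is None:
        ideg_set = load_default_ideg_set()
    pos = float(fractions.reindex(list(ideg_set.positive)).fillna(0.0).clip(lower=0).sum())
    neg = float(fractions.reindex(list(ideg_set.negative)).fillna(0.0).clip(lower=0).sum())
    total = pos + neg
    if total <= 0:
        return None
    return pos / total
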