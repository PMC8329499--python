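"""Molecular formula assignment for negative-ion FT-ICR MS peak lists.

Peaks are singly charged [M-H]- ions. A peak is retained when its
signal-to-noise ratio exceeds ``sn_min`` (strict) and its m/z falls inside
``mass_range`` (inclusive); each retained peak receives the candidate neutral
formula whose deprotonated m/z is nearest in relative error, provided the
error is within ``tolerance_ppm``. The mass-accuracy criterion is applied to
the ion m/z (not the neutral mass).

Candidate formulas come from an exhaustive element grid filtered by
conventional DOM plausibility rules: H/C and O/C windows and a non-negative
integer DBE for the neutral molecule. The grid is precomputed, mass-sorted
and cached per configuration so assignment of a full peak list is a windowed
binary search per peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .formula import MONOISOTOPIC_MASS, PROTON_MASS, FormulaComposition, ion_mz, neutral_mass

__all__ = [
    "Peak",
    "AssignmentConfig",
    "enumerate_candidates",
    "assign_peaklist",
    "read_peaklist",
    "canonicalize_peaklist",
    "write_assignments",
]

_ELEMENTS = ("C", "H", "N", "O", "S", "P")

# Rejection reason codes used in the log.
REASON_SN = "s/n"
REASON_MASS_RANGE = "mass range"
REASON_UNASSIGNED = "unassigned"
REASON_COLLISION = "collision"


class Peak(NamedTuple):
    """One measured mass with magnitude and signal-to-noise ratio."""

    mz: float
    intensity: float
    sn: float


@dataclass(frozen=True)
class AssignmentConfig:
    """Quality criteria and search space for formula assignment."""

    tolerance_ppm: float = 1.0
    sn_min: float = 4.0
    #: candidates whose |error| is within this window of the best candidate's
    #: are treated as tied and ranked by heteroatom parsimony (fewest N+S+P);
    #: an exact tie has measure zero with continuous mass errors, so the
    #: parsimony rule needs an error-equivalence band to act at all
    tie_window_ppm: float = 0.5
    mass_range: tuple[float, float] = (200.0, 800.0)
    element_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "C": (4, 60),
            "H": (4, 120),
            "N": (0, 4),
            "O": (0, 30),
            "S": (0, 2),
            "P": (0, 0),
        }
    )
    hc_range: tuple[float, float] = (0.3, 2.5)
    oc_range: tuple[float, float] = (0.0, 1.2)
    require_integer_dbe_nonneg: bool = True
    #: the DBE - O plausibility window; rejects exotic compositions (e.g.
    #: near-carbon-cluster formulas) that are exact-mass twins of common DOM
    #: molecules. None disables the rule.
    dbe_o_range: tuple[float, float] | None = (-10.0, 10.0)

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be > 0")
        lo, hi = self.mass_range
        if not lo < hi:
            raise ValueError("mass_range low must be < high")
        for el in _ELEMENTS:
            if el not in self.element_ranges:
                raise ValueError(f"element_ranges missing {el}")
            emin, emax = self.element_ranges[el]
            if emin < 0 or emax < emin:
                raise ValueError(f"bad range for {el}: ({emin}, {emax})")

    def _grid_key(self) -> tuple:
        return (
            tuple(sorted((el, tuple(rng)) for el, rng in self.element_ranges.items())),
            tuple(self.hc_range),
            tuple(self.oc_range),
            self.require_integer_dbe_nonneg,
            None if self.dbe_o_range is None else tuple(self.dbe_o_range),
            tuple(self.mass_range),
        )

    @classmethod
    def from_yaml(cls, path) -> "AssignmentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "element_ranges" in raw:
            raw["element_ranges"] = {
                el: tuple(v) for el, v in raw["element_ranges"].items()
            }
        for key in ("mass_range", "hc_range", "oc_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class _CandidateLibrary:
    """Mass-sorted table of every composition allowed by a config's grid."""

    def __init__(self, cfg: AssignmentConfig):
        counts, masses = _build_grid(cfg)
        order = np.argsort(masses, kind="stable")
        self.counts = counts[order]  # (N, 6) int32, columns C H N O S P
        self.masses = masses[order]  # neutral monoisotopic masses, ascending

    def window(self, lo: float, hi: float) -> slice:
        i = int(np.searchsorted(self.masses, lo, side="left"))
        j = int(np.searchsorted(self.masses, hi, side="right"))
        return slice(i, j)


def _build_grid(cfg: AssignmentConfig) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate the allowed composition grid (vectorized over C, H, O)."""
    er = cfg.element_ranges
    c = np.arange(er["C"][0], er["C"][1] + 1, dtype=np.int32)
    h = np.arange(er["H"][0], er["H"][1] + 1, dtype=np.int32)
    o = np.arange(er["O"][0], er["O"][1] + 1, dtype=np.int32)
    mC, mH, mN, mO, mS, mP = (MONOISOTOPIC_MASS[el] for el in _ELEMENTS)
    lo, hi = cfg.mass_range
    # small margin so in-tolerance candidates at the window edge survive
    margin = hi * 1e-5
    cc = c[:, None, None]
    hh = h[None, :, None]
    oo = o[None, None, :]
    base_mask = (
        (hh >= cfg.hc_range[0] * cc)
        & (hh <= cfg.hc_range[1] * cc)
        & (oo >= cfg.oc_range[0] * cc)
        & (oo <= cfg.oc_range[1] * cc)
    )
    chunks_counts = []
    chunks_mass = []
    for n in range(er["N"][0], er["N"][1] + 1):
        for s in range(er["S"][0], er["S"][1] + 1):
            for p in range(er["P"][0], er["P"][1] + 1):
                mask = base_mask
                if cfg.require_integer_dbe_nonneg:
                    # DBE = 1 + (2C - H + N + P)/2 integer  <=>  H = N + P (mod 2)
                    mask = mask & ((hh % 2) == ((n + p) % 2))
                    # DBE >= 0  <=>  H <= 2C + N + P + 2
                    mask = mask & (hh <= 2 * cc + n + p + 2)
                if cfg.dbe_o_range is not None:
                    dbe_minus_o = 1.0 + (2 * cc - hh + n + p) / 2.0 - oo
                    mask = mask & (dbe_minus_o >= cfg.dbe_o_range[0])
                    mask = mask & (dbe_minus_o <= cfg.dbe_o_range[1])
                mass = mC * cc + mH * hh + mO * oo + (mN * n + mS * s + mP * p)
                mask = mask & (mass >= lo - margin) & (mass <= hi + margin)
                idx = np.nonzero(mask)
                if idx[0].size == 0:
                    continue
                k = idx[0].size
                cnt = np.empty((k, 6), dtype=np.int32)
                cnt[:, 0] = c[idx[0]]
                cnt[:, 1] = h[idx[1]]
                cnt[:, 2] = n
                cnt[:, 3] = o[idx[2]]
                cnt[:, 4] = s
                cnt[:, 5] = p
                chunks_counts.append(cnt)
                chunks_mass.append(mass[mask].astype(np.float64))
    if not chunks_counts:
        return np.empty((0, 6), dtype=np.int32), np.empty(0, dtype=np.float64)
    return np.concatenate(chunks_counts), np.concatenate(chunks_mass)


_LIBRARY_CACHE: dict[tuple, _CandidateLibrary] = {}


def _library(cfg: AssignmentConfig) -> _CandidateLibrary:
    key = cfg._grid_key()
    lib = _LIBRARY_CACHE.get(key)
    if lib is None:
        lib = _CandidateLibrary(cfg)
        _LIBRARY_CACHE[key] = lib
    return lib


def _composition_from_row(row: np.ndarray) -> FormulaComposition:
    return FormulaComposition(
        c=int(row[0]), h=int(row[1]), n=int(row[2]), o=int(row[3]), s=int(row[4]), p=int(row[5])
    )


def _rank_key(comp: FormulaComposition, err: float) -> tuple:
    # |error| ascending, then fewer heteroatoms (N+S+P), then Hill order
    return (abs(err), comp.n + comp.s + comp.p, comp.hill())


def enumerate_candidates(
    target_mass: float, cfg: AssignmentConfig | None = None
) -> list[FormulaComposition]:
    """All grid compositions whose neutral mass matches ``target_mass``.

    Candidates are within ``cfg.tolerance_ppm`` relative error of the given
    neutral mass and pass the configured H/C, O/C and DBE rules. Sorted by
    |error| ascending, ties broken by fewer heteroatoms then Hill order.
    """
    if cfg is None:
        cfg = AssignmentConfig()
    if target_mass <= 0:
        raise ValueError("target mass must be positive")
    lib = _library(cfg)
    tol = cfg.tolerance_ppm * 1e-6 * target_mass
    sl = lib.window(target_mass - tol, target_mass + tol)
    out = []
    for row, mass in zip(lib.counts[sl], lib.masses[sl]):
        err_ppm = (mass - target_mass) / target_mass * 1e6
        if abs(err_ppm) <= cfg.tolerance_ppm:
            out.append((_composition_from_row(row), err_ppm))
    out.sort(key=lambda t: _rank_key(t[0], t[1]))
    return [comp for comp, _ in out]


def canonicalize_peaklist(peaks) -> list[Peak]:
    """Sort by m/z and merge exact duplicates (summing intensity, max s/n)."""
    cleaned: dict[float, Peak] = {}
    for pk in peaks:
        pk = Peak(float(pk[0]), float(pk[1]), float(pk[2]))
        if pk.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {pk.mz}")
        if pk.intensity < 0 or pk.sn < 0:
            raise ValueError("peak intensity and s/n must be non-negative")
        prev = cleaned.get(pk.mz)
        if prev is not None:
            pk = Peak(pk.mz, prev.intensity + pk.intensity, max(prev.sn, pk.sn))
        cleaned[pk.mz] = pk
    return sorted(cleaned.values(), key=lambda q: q.mz)


def read_peaklist(path) -> list[Peak]:
    """Read a 3-column delimited peak list (mz, intensity, sn; header required)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ValueError(f"could not parse peak list {path}: {exc}") from exc
    required = {"mz", "intensity", "sn"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: peak list must have columns {sorted(required)}")
    peaks = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            peaks.append(Peak(float(row.mz), float(row.intensity), float(row.sn)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed peak row at line {i}: {exc}") from exc
    return canonicalize_peaklist(peaks)


def assign_peaklist(
    peaks, cfg: AssignmentConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign formulas to a canonical peak list.

    Returns ``(assignments, rejections)``. Assignments has one row per
    retained peak: formula (Hill string), mz, error_ppm (relative to the ion
    m/z), intensity, sn, candidates_considered. Rejections has mz, intensity,
    sn and a single reason code per dropped peak: ``s/n``, ``mass range``,
    ``unassigned`` or ``collision`` (duplicate formula; lower-|error| peak
    kept). Output is deterministic for identical input and config.
    """
    if cfg is None:
        cfg = AssignmentConfig()
    peaks = canonicalize_peaklist(peaks)
    lib = _library(cfg)
    assigned: dict[str, dict] = {}
    rejections: list[dict] = []

    def reject(pk: Peak, reason: str) -> None:
        rejections.append(
            {"mz": pk.mz, "intensity": pk.intensity, "sn": pk.sn, "reason": reason}
        )

    for pk in peaks:
        if not pk.sn > cfg.sn_min:
            reject(pk, REASON_SN)
            continue
        if not (cfg.mass_range[0] <= pk.mz <= cfg.mass_range[1]):
            reject(pk, REASON_MASS_RANGE)
            continue
        target = pk.mz + PROTON_MASS  # neutral mass of the candidate molecule
        tol = cfg.tolerance_ppm * 1e-6 * pk.mz
        sl = lib.window(target - tol * 1.001, target + tol * 1.001)
        in_tol = []
        for row, mass in zip(lib.counts[sl], lib.masses[sl]):
            err_ppm = ((mass - PROTON_MASS) - pk.mz) / pk.mz * 1e6
            if abs(err_ppm) <= cfg.tolerance_ppm:
                in_tol.append((abs(err_ppm), row, err_ppm))
        if not in_tol:
            reject(pk, REASON_UNASSIGNED)
            continue
        considered = len(in_tol)
        # candidates within tie_window_ppm of the best error are equivalent in
        # accuracy; prefer heteroatom parsimony among them
        best_err = min(e for e, _, _ in in_tol)
        shortlist = [
            (_composition_from_row(row), err)
            for e, row, err in in_tol
            if e <= best_err + cfg.tie_window_ppm
        ]
        comp, err_ppm = min(
            shortlist, key=lambda t: (t[0].n + t[0].s + t[0].p, abs(t[1]), t[0].hill())
        )
        record = {
            "formula": comp.hill(),
            "mz": pk.mz,
            "error_ppm": err_ppm,
            "intensity": pk.intensity,
            "sn": pk.sn,
            "candidates_considered": considered,
        }
        prev = assigned.get(record["formula"])
        if prev is not None:
            # duplicate formula within one sample: keep the lower |error|
            keep, drop = (record, prev) if abs(err_ppm) < abs(prev["error_ppm"]) else (prev, record)
            assigned[record["formula"]] = keep
            reject(Peak(drop["mz"], drop["intensity"], drop["sn"]), REASON_COLLISION)
        else:
            assigned[record["formula"]] = record

    a = pd.DataFrame(
        sorted(assigned.values(), key=lambda r: r["mz"]),
        columns=["formula", "mz", "error_ppm", "intensity", "sn", "candidates_considered"],
    )
    r = pd.DataFrame(rejections, columns=["mz", "intensity", "sn", "reason"])
    return a, r


def write_assignments(assignments: pd.DataFrame, path, sample: str | None = None) -> None:
    out = assignments.copy()
    if sample is not None:
        out.insert(0, "sample", sample)
    out.to_csv(path, sep="\t", index=False)
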