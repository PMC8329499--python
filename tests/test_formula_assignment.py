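"""Formula arithmetic and peak assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sedom.assignment import (
    AssignmentConfig,
    Peak,
    assign_peaklist,
    canonicalize_peaklist,
    enumerate_candidates,
    read_peaklist,
)
from sedom.formula import (
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    FormulaComposition,
    ion_mz,
    neutral_mass,
    parse_formula,
)

# -- masses -----------------------------------------------------------------


@pytest.mark.parametrize(
    "formula, expected",
    [
        ("CH4", 16.031300),
        ("C15H20O6", 296.125988),  # 15*12 + 20*1.00782503 + 6*15.99491462
        ("C6H12O6", 180.063388),
    ],
)
def test_neutral_mass_hand_sums(formula, expected):
    assert neutral_mass(parse_formula(formula)) == pytest.approx(expected, abs=1e-5)


@pytest.mark.parametrize(
    "formula, expected",
    [("C15H20O6", 295.118712), ("C6H12O6", 179.056112)],
)
def test_ion_mz_is_deprotonated_neutral(formula, expected):
    f = parse_formula(formula)
    assert ion_mz(f) == pytest.approx(expected, abs=1e-5)
    assert ion_mz(f) < neutral_mass(f)


def test_empty_or_ch_free_composition_rejected():
    with pytest.raises(ValueError):
        FormulaComposition(c=0, h=4)
    with pytest.raises(ValueError):
        FormulaComposition(c=5, h=0)
    with pytest.raises(ValueError):
        FormulaComposition(c=5, h=4, o=-1)


comp_strategy = st.builds(
    FormulaComposition,
    c=st.integers(1, 60),
    h=st.integers(1, 120),
    n=st.integers(0, 4),
    o=st.integers(0, 30),
    s=st.integers(0, 2),
    p=st.integers(0, 1),
)


@given(comp_strategy)
def test_hill_string_round_trips(f):
    assert parse_formula(f.hill()) == f


@given(comp_strategy)
def test_family_classification(f):
    fam = f.family
    assert fam.startswith("CHO")
    assert ("N" in fam) == (f.n > 0)
    assert ("S" in fam) == (f.s > 0)


# -- candidate enumeration ---------------------------------------------------

SMALL_CFG = AssignmentConfig(
    tolerance_ppm=5.0,
    mass_range=(150.0, 500.0),
    element_ranges={"C": (4, 20), "H": (4, 40), "N": (0, 2), "O": (0, 10), "S": (0, 1), "P": (0, 0)},
)


def brute_force_candidates(target_mass, cfg):
    """Independent six-nested-loop oracle over the element grid."""
    out = []
    er = cfg.element_ranges
    for c in range(er["C"][0], er["C"][1] + 1):
        for h in range(er["H"][0], er["H"][1] + 1):
            for n in range(er["N"][0], er["N"][1] + 1):
                for o in range(er["O"][0], er["O"][1] + 1):
                    for s in range(er["S"][0], er["S"][1] + 1):
                        for p in range(er["P"][0], er["P"][1] + 1):
                            if not (cfg.hc_range[0] * c <= h <= cfg.hc_range[1] * c):
                                continue
                            if not (cfg.oc_range[0] * c <= o <= cfg.oc_range[1] * c):
                                continue
                            dbe = 1 + (2 * c - h + n + p) / 2
                            if cfg.require_integer_dbe_nonneg:
                                if dbe != int(dbe) or dbe < 0:
                                    continue
                            if cfg.dbe_o_range is not None:
                                if not (cfg.dbe_o_range[0] <= dbe - o <= cfg.dbe_o_range[1]):
                                    continue
                            mass = (
                                12.0 * c
                                + MONOISOTOPIC_MASS["H"] * h
                                + MONOISOTOPIC_MASS["N"] * n
                                + MONOISOTOPIC_MASS["O"] * o
                                + MONOISOTOPIC_MASS["S"] * s
                                + MONOISOTOPIC_MASS["P"] * p
                            )
                            err = (mass - target_mass) / target_mass * 1e6
                            if abs(err) <= cfg.tolerance_ppm:
                                out.append((FormulaComposition(c, h, n, o, s, p), err))
    out.sort(key=lambda t: (abs(t[1]), t[0].n + t[0].s + t[0].p, t[0].hill()))
    return [f for f, _ in out]


def test_enumerate_contains_exact_match_with_near_zero_error():
    target = neutral_mass(parse_formula("C15H20O6"))
    cands = enumerate_candidates(target, AssignmentConfig())
    assert parse_formula("C15H20O6") in cands
    assert cands[0] == parse_formula("C15H20O6")


def test_enumerate_excludes_out_of_tolerance():
    target = neutral_mass(parse_formula("C15H20O6")) * (1 + 3e-6)  # +3 ppm
    cands = enumerate_candidates(target, AssignmentConfig(tolerance_ppm=1.0))
    assert parse_formula("C15H20O6") not in cands


def test_wider_tolerance_gives_superset():
    target = neutral_mass(parse_formula("C15H20O6"))
    narrow = set(enumerate_candidates(target, AssignmentConfig(tolerance_ppm=1.0)))
    wide = set(enumerate_candidates(target, AssignmentConfig(tolerance_ppm=50.0)))
    assert narrow <= wide


def test_enumerate_agrees_with_nested_loop_oracle(rng):
    masses = rng.uniform(180.0, 450.0, size=12)
    for m in masses:
        assert enumerate_candidates(float(m), SMALL_CFG) == brute_force_candidates(m, SMALL_CFG)


def test_roundtrip_through_enumeration():
    # ion_mz -> neutral -> top candidate recovers the formula at zero error
    for hill in ("C11H16O4", "C20H30O8", "C12H17NO6", "C15H22O7S"):
        f = parse_formula(hill)
        cands = enumerate_candidates(neutral_mass(f), AssignmentConfig())
        assert cands[0] == f


# -- peak list assignment ----------------------------------------------------


def test_sn_and_mass_range_rejections():
    peaks = [
        Peak(295.2, 100.0, 3.0),  # s/n too low (<= 4)
        Peak(150.0, 100.0, 50.0),  # below mass range
        Peak(295.118712, 100.0, 50.0),  # good
    ]
    a, r = assign_peaklist(peaks, AssignmentConfig())
    reasons = dict(zip(r.mz, r.reason))
    assert reasons[295.2] == "s/n"
    assert reasons[150.0] == "mass range"
    assert len(a) == 1
    # exact boundary: s/n == 4 is rejected (strict inequality)
    a2, r2 = assign_peaklist([Peak(295.118712, 1.0, 4.0)], AssignmentConfig())
    assert len(a2) == 0 and list(r2.reason) == ["s/n"]
    a3, r3 = assign_peaklist([Peak(150.0, 1.0, 50.0)], AssignmentConfig())
    assert list(r3.reason) == ["mass range"]


def test_assignment_unique_formula_per_sample_and_collision_logged():
    mz = ion_mz(parse_formula("C15H20O6"))
    peaks = [Peak(mz * (1 - 2e-7), 5.0, 10.0), Peak(mz * (1 + 1e-7), 7.0, 10.0)]
    a, r = assign_peaklist(peaks, AssignmentConfig())
    assert list(a.formula) == ["C15H20O6"]
    assert a.error_ppm.abs().iloc[0] == pytest.approx(0.1, abs=0.02)
    assert "collision" in set(r.reason)


def test_assignment_deterministic():
    rng = np.random.default_rng(3)
    peaks = [
        Peak(float(m), float(i), 20.0)
        for m, i in zip(rng.uniform(200, 780, 50), rng.uniform(1, 100, 50))
    ]
    a1, r1 = assign_peaklist(peaks, AssignmentConfig())
    a2, r2 = assign_peaklist(peaks, AssignmentConfig())
    assert a1.equals(a2) and r1.equals(r2)


def test_output_counts_and_single_reason():
    rng = np.random.default_rng(4)
    peaks = [Peak(float(m), 1.0, float(s)) for m, s in zip(rng.uniform(100, 900, 80), rng.uniform(0, 50, 80))]
    a, r = assign_peaklist(peaks, AssignmentConfig())
    assert len(a) + len(r) >= len(set(p.mz for p in peaks))  # collisions add log rows
    assert len(a) <= len(peaks)
    assert r.reason.isin(["s/n", "mass range", "unassigned", "collision"]).all()


def test_canonicalization_sorts_and_merges():
    peaks = [Peak(300.0, 1.0, 5.0), Peak(250.0, 2.0, 6.0), Peak(300.0, 3.0, 9.0)]
    canon = canonicalize_peaklist(peaks)
    assert [p.mz for p in canon] == [250.0, 300.0]
    assert canon[1].intensity == 4.0 and canon[1].sn == 9.0


def test_read_peaklist_errors_on_malformed(tmp_path):
    path = tmp_path / "peaks.tsv"
    path.write_text("mz\tintensity\tsn\n300.1\t5\t10\nnot_a_number\t1\t2\n")
    with pytest.raises(ValueError, match="line 3"):
        read_peaklist(path)
    path2 = tmp_path / "bad_header.tsv"
    path2.write_text("a\tb\tc\n1\t2\t3\n")
    with pytest.raises(ValueError, match="columns"):
        read_peaklist(path2)
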