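"""Interface detection, translational metrics, contacts and composition."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from cotasm.interfaces import (
    AFFINITY_COEFFICIENT_KEYS,
    ContactSet,
    build_profiles,
    charged_fractions,
    first_last_interfaces,
    interface_midpoint,
    interpolate_pi,
    mean_fragment_pi,
    nis_parameters,
    NestedInterfacesError,
    pairwise_interfaces,
    predict_affinity,
    relative_interface_location,
    relative_size_difference,
    relative_translational_distance,
    residue_contacts,
)
from cotasm.sasa import chain_sasa, complex_sasa
from cotasm.structio import Atom, Chain, ComplexStructure, Residue
from cotasm.synth import ComplexSpec, InterfacePlan, generate_complex


def _abstract_interface(per_res, aa=None, pair=("A", "B"), homomeric=False):
    from cotasm.interfaces import Interface

    aa = aa or {p: "L" for p in per_res}
    return Interface(
        complex_id="t", chain_pair=pair,
        per_residue_bsa={pair[0]: dict(per_res), pair[1]: dict(per_res)},
        aa_by_pos={pair[0]: dict(aa), pair[1]: dict(aa)},
        homomeric=homomeric,
    )


# ---------------------------------------------------------------- pairwise BSA

def test_distant_chains_have_no_interface():
    spec = ComplexSpec("far", {"A": 20, "B": 20}, plan=[])
    cx = generate_complex(spec)
    assert pairwise_interfaces(cx, min_area=None) == []


def test_homodimer_sides_symmetric(homodimer):
    """Symmetric homodimer sides agree up to lattice discretisation error."""
    ifaces = pairwise_interfaces(homodimer, min_area=None, n_points=3840)
    assert len(ifaces) == 1
    iface = ifaces[0]
    assert iface.homomeric
    assert iface.bsa_side("A") == pytest.approx(iface.bsa_side("B"), rel=2e-2)


def test_bsa_matches_brute_force_oracle(bead_trimer):
    """Pairwise BSA equals independent per-residue ASA-difference sums."""
    ifaces = pairwise_interfaces(bead_trimer, min_area=None)
    by_pair = {i.chain_pair: i for i in ifaces}
    chains = {c.chain_id: c for c in bead_trimer.chains}
    for (a, b), iface in by_pair.items():
        for target, cid in ((chains[a], a), (chains[b], b)):
            iso = chain_sasa(target).residue_asa
            partner = chains[b if cid == a else a]
            ctx = chain_sasa(target, [partner]).residue_asa
            oracle = sum(max(0.0, iso[p] - ctx[p]) for p in iso)
            assert iface.bsa_side(cid) == pytest.approx(oracle, rel=1e-9)


def test_side_total_is_sum_of_residue_bsa(bead_trimer):
    ifaces = pairwise_interfaces(bead_trimer, min_area=None)
    for iface in ifaces:
        for cid in iface.chain_pair:
            assert iface.bsa_side(cid) == pytest.approx(
                sum(iface.side(cid).values()), rel=1e-9)


def test_min_area_filter_drops_small_interfaces(bead_trimer):
    sizes = [i.bsa_total for i in pairwise_interfaces(bead_trimer, min_area=None)]
    big = pairwise_interfaces(bead_trimer, min_area=max(sizes) - 1.0)
    assert len(big) == 1


def test_separated_chains_zero_bsa_and_contacts():
    """Chains farther apart than the occlusion reach share nothing."""
    spec = ComplexSpec("far2", {"A": 10, "B": 10}, plan=[])
    cx = generate_complex(spec)
    assert pairwise_interfaces(cx, min_area=None) == []
    contacts = residue_contacts(cx, ("A", "B"), cutoff=5.5)
    assert contacts.n_contacts == 0


# ----------------------------------------------------------------- apolar area

@pytest.mark.parametrize(
    "aa_map, expected_fraction",
    [
        ({1: "L", 2: "L"}, 1.0),     # all apolar: apolar == total
        ({1: "D", 2: "K"}, 0.0),     # all charged: apolar == 0
    ],
)
def test_apolar_area_subsets(aa_map, expected_fraction):
    iface = _abstract_interface({p: 100.0 for p in aa_map}, aa=aa_map)
    assert iface.apolar_side("A") == pytest.approx(
        expected_fraction * iface.bsa_side("A"))


def test_apolar_area_mixed():
    iface = _abstract_interface({1: 100.0, 2: 50.0}, aa={1: "L", 2: "D"})
    assert iface.apolar_side("A") == pytest.approx(100.0)


# ------------------------------------------------------------------- midpoint

@pytest.mark.parametrize(
    "per_res, expected",
    [
        ({42: 7.5}, 42),                          # single residue
        ({5: 10, 6: 10, 7: 10, 8: 10}, 6),        # cumulative 20 >= 20
        ({1: 30, 9: 10}, 1),                      # first residue passes half
    ],
)
def test_interface_midpoint(per_res, expected):
    assert interface_midpoint(per_res) == expected


@given(hst.floats(min_value=0.01, max_value=1e4))
def test_midpoint_invariant_to_uniform_scaling(scale):
    per_res = {3: 12.0, 7: 5.0, 11: 20.0, 20: 8.0}
    scaled = {p: v * scale for p, v in per_res.items()}
    assert interface_midpoint(per_res) == interface_midpoint(scaled)


# ------------------------------------------------------- relative location etc.

@pytest.mark.parametrize("i, L, expected", [
    (1, 100, 0.0), (100, 100, 1.0), (51, 101, 0.5),
])
def test_relative_interface_location(i, L, expected):
    assert relative_interface_location(i, L) == pytest.approx(expected)


def test_relative_location_requires_two_residues():
    with pytest.raises(ValueError):
        relative_interface_location(1, 1)


@pytest.mark.parametrize("f_first, f_last, L, expected", [
    (10, 110, 200, 0.5), (37, 37, 99, 0.0), (1, 400, 400, 0.9975),
])
def test_relative_translational_distance(f_first, f_last, L, expected):
    assert relative_translational_distance(f_first, f_last, L) == pytest.approx(
        expected)


def test_translational_distance_ordering_enforced():
    with pytest.raises(ValueError):
        relative_translational_distance(50, 10, 100)


@pytest.mark.parametrize("first, last, expected", [
    (4226.0, 484.0, 0.79448),  # published Fas2 first/last areas
    (1000.0, 1000.0, 0.0),
    (0.0, 250.0, -1.0),
])
def test_relative_size_difference(first, last, expected):
    assert relative_size_difference(first, last) == pytest.approx(
        expected, abs=5e-5)


@given(
    hst.floats(min_value=1.0, max_value=1e5),
    hst.floats(min_value=1.0, max_value=1e5),
)
def test_relative_size_difference_antisymmetric(x, y):
    assert relative_size_difference(x, y) == pytest.approx(
        -relative_size_difference(y, x))


def test_relative_size_difference_undefined_for_zero():
    with pytest.raises(ValueError):
        relative_size_difference(0.0, 0.0)


# ---------------------------------------------------------- first / last iface

def _profile_with(windows_and_areas, L=400):
    """Subunit profile with abstract interfaces over given windows."""
    from cotasm.interfaces import SubunitProfile

    profile = SubunitProfile(protein_id="P", chain_id="A", complex_id="t", L=L)
    for k, ((lo, hi), area) in enumerate(windows_and_areas):
        n = hi - lo + 1
        per_res = {p: area / n for p in range(lo, hi + 1)}
        profile.interfaces.append(
            _abstract_interface(per_res, pair=("A", f"B{k}")))
    return profile


def test_first_last_by_terminal_residues():
    profile = _profile_with([((10, 200), 2000.0), ((150, 300), 1500.0)])
    first, last = first_last_interfaces(profile)
    assert first.chain_pair[1] == "B0"
    assert last.chain_pair[1] == "B1"


def test_fully_nested_interfaces_excluded():
    profile = _profile_with([((10, 300), 2000.0), ((150, 200), 1500.0)])
    with pytest.raises(NestedInterfacesError):
        first_last_interfaces(profile)


def test_first_res_tie_goes_to_larger_interface():
    profile = _profile_with(
        [((10, 100), 900.0), ((10, 300), 2500.0), ((250, 390), 1200.0)])
    first, last = first_last_interfaces(profile)
    assert first.chain_pair[1] == "B1"       # larger area wins the tie at 10
    assert last.chain_pair[1] == "B2"


def test_single_interface_subunit_rejected():
    profile = _profile_with([((10, 100), 900.0)])
    with pytest.raises(ValueError):
        first_last_interfaces(profile)


# ------------------------------------------------------------------- contacts

def _two_bead_complex(distance):
    a = Chain("A", "PA", [Residue(1, "K", [Atom("C", 0, 0, 0, 1.7)])])
    b = Chain("B", "PB", [Residue(1, "D", [Atom("C", distance, 0, 0, 1.7)])])
    return ComplexStructure("pairtest", [a, b])


@pytest.mark.parametrize("distance, expected", [(5.4, 1), (5.6, 0)])
def test_contact_cutoff_edge(distance, expected):
    contacts = residue_contacts(_two_bead_complex(distance), ("A", "B"))
    assert contacts.n_contacts == expected
    if expected:
        assert contacts.class_counts["charged-charged"] == 1


def test_contacts_match_brute_force(bead_dimer):
    """KD-tree contact listing equals all-pairs enumeration."""
    contacts = residue_contacts(bead_dimer, ("A", "B"), cutoff=5.5)
    a, b = bead_dimer.chains
    expected = {}
    for ra in a.residues:
        for rb in b.residues:
            dmin = min(
                math.dist(at1.coords(), at2.coords())
                for at1 in ra.atoms for at2 in rb.atoms
            )
            if dmin <= 5.5:
                expected[(ra.seq_pos, rb.seq_pos)] = dmin
    assert {(ra, rb): pytest.approx(d) for ra, rb, d in contacts.pairs} == expected
    assert sum(contacts.class_counts.values()) == contacts.n_contacts


# ------------------------------------------------- surface composition and pI

def test_nis_parameters_arithmetic(bead_trimer):
    """NIS percentages are over surface residues only."""
    chain = bead_trimer.chains[0]
    in_cx = complex_sasa(bead_trimer)[chain.chain_id]
    nis_a, nis_c = nis_parameters(chain, in_cx)
    from cotasm.chemdata import APOLAR_AA, CHARGED_AA
    from cotasm.sasa import chain_relative_asa

    surface = [e for e in chain_relative_asa(chain, in_cx) if e.surface]
    assert nis_a == pytest.approx(
        100 * sum(e.aa in APOLAR_AA for e in surface) / len(surface))
    assert nis_c == pytest.approx(
        100 * sum(e.aa in CHARGED_AA for e in surface) / len(surface))
    assert 0 <= nis_a + nis_c <= 100


@pytest.mark.parametrize("seq, expected", [
    ("DEKR", (0.5, 0.5)),
    ("AAAA", (0.0, 0.0)),
    ("DDKA", (0.25, 0.5)),
])
def test_charged_fractions(seq, expected):
    assert charged_fractions(seq) == pytest.approx(expected)


@pytest.mark.parametrize("curve, expected", [
    ([(6.0, 2.0), (8.0, -2.0)], 7.0),
    ([(7.0, 0.5), (8.0, -0.75)], 7.4),
])
def test_interpolate_pi(curve, expected):
    assert interpolate_pi(curve) == pytest.approx(expected)


def test_interpolate_pi_reports_sign_without_crossing():
    with pytest.raises(ValueError, match="positive"):
        interpolate_pi([(2.0, 5.0), (12.0, 1.0)])


def test_mean_fragment_pi():
    assert mean_fragment_pi([6.0, 8.0]) == pytest.approx(7.0)


# ------------------------------------------------------------------- affinity

def test_affinity_linear_model():
    contacts = ContactSet(("A", "B"), 5.5, [(1, 1, 4.0)] * 3,
                          {"charged-charged": 3})
    zero = {k: 0.0 for k in AFFINITY_COEFFICIENT_KEYS}
    assert predict_affinity(contacts, (0.0, 0.0), zero) == 0.0
    intercept_only = dict(zero, intercept=-5.2)
    assert predict_affinity(contacts, (30.0, 20.0), intercept_only) == -5.2
    unit = {k: 1.0 for k in AFFINITY_COEFFICIENT_KEYS}
    unit["intercept"] = 2.0
    assert predict_affinity(contacts, (0.0, 0.0), unit) == pytest.approx(5.0)


def test_affinity_missing_coefficient_raises():
    contacts = ContactSet(("A", "B"), 5.5, [], {})
    with pytest.raises(KeyError):
        predict_affinity(contacts, (0.0, 0.0), {"intercept": 0.0})


# ------------------------------------------------------------------- profiles

def test_build_profiles_assigns_interfaces(bead_trimer):
    ifaces = pairwise_interfaces(bead_trimer, min_area=None)
    profiles = build_profiles(bead_trimer, ifaces)
    assert len(profiles["B"].interfaces) == 2   # B touches both A and C
    assert len(profiles["A"].interfaces) == 1
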