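"""Oscillation classification: preconditions, families, planar cases,
regime analyses, and the general trimolecular decision."""

import numpy as np
import pytest

from crnosc.classify import (
    CASE_TEMPLATES,
    classify_no_form9,
    classify_trimolecular_general,
    family12,
    family12_regime,
    generalized_lotka,
    generalized_lva,
    generalized_lva_check,
    has_autocatalytic_form9,
    hopf_verdict_planar,
    identify_family,
    lifted_lva,
    lifted_lva_regime,
    oscillation_preconditions,
    source_case_planar,
    tetramolecular_hopf_network,
)
from crnosc.dynamics import MassActionSystem, detect_periodicity
from crnosc.network import parse_network


class TestPreconditions:
    def test_lotka_passes(self, lotka):
        assert oscillation_preconditions(lotka)["passed"]

    def test_two_reactions_fail(self):
        net = parse_network("X -> 2X\n2X -> X")
        rep = oscillation_preconditions(net)
        assert not rep["passed"]
        assert rep["first_failure"] == "at_least_three_reactions"

    def test_collinear_nontrivial_fails_on_collinearity(self):
        # dynamically nontrivial, rank two, but sources 2X, X+Y, 2Y on a line
        net = parse_network("2X -> X + Y\nX + Y -> 2X + Y\n2Y -> Y")
        rep = oscillation_preconditions(net)
        assert rep["first_failure"] == "sources_not_collinear"


class TestForm9:
    def test_examples(self, lva, lotka):
        assert has_autocatalytic_form9(lva) == (True, 0)
        assert not has_autocatalytic_form9(lotka)[0]
        assert has_autocatalytic_form9(parse_network("2X -> 3X + Y\nY -> X"))[0]
        # 2X -> X + Y loses X: not of the autocatalytic form
        assert not has_autocatalytic_form9(parse_network("2X -> X + Y\nY -> X"))[0]


class TestNoForm9Classification:
    def test_ivanova_center(self, ivanova):
        v = classify_no_form9(ivanova)
        assert v.outcome == "center_for_all_k" and v.family == "ivanova"

    def test_generalized_lotka_members(self):
        for c, d in [(1, 1), (2, 1), (1, 2), (3, 4)]:
            v = classify_no_form9(generalized_lotka(c, d))
            assert v.outcome == "center_for_all_k"
            assert v.params == (c, d)

    def test_family12_member(self, fam12):
        v = classify_no_form9(fam12)
        assert v.outcome == "center_on_condition" and v.family == "family_12"

    def test_inflow_network_gets_dulac_verdict(self):
        net = parse_network("0 -> X\nX + Y -> 2Y\nY -> X")
        v = classify_no_form9(net)
        assert v.outcome == "no_periodic_orbit"
        assert v.fired_rule == "dulac_negative_divergence"


class TestRegimes:
    @pytest.mark.parametrize(
        "kappa,D,expected",
        [
            ((3.0, 1.0, 1.0), -1.0, "center"),
            ((3.0, 1.0, 1.0), 1.0, "no_equilibrium"),
            ((2.0, 1.0, 1.0), 0.0, "invariant_rays"),
            ((2.0, 1.0, 1.0), 1.0, "no_equilibrium"),
            ((1.0, 1.0, 1.0), 1.0, "saddle"),
            ((1.0, 1.0, 1.0), -1.0, "no_equilibrium"),
        ],
    )
    def test_family12_regimes(self, kappa, D, expected):
        assert family12_regime(1, 1, kappa, D) == expected

    @pytest.mark.parametrize(
        "kappa,C,expected",
        [
            ((1.0, 2.0, 2.0), 1.0, "center"),
            ((1.0, 2.0, 3.0), 1.0, "globally_stable"),
            ((1.0, 3.0, 2.0), 1.0, "repellor"),
            ((4.0, 1.0, 2.0), 1.0, "no_equilibrium"),  # d k2^2 < k1 k3, C > 0
            ((4.0, 1.0, 2.0), -1.0, "saddle"),
            ((2.0, 2.0, 2.0), 0.0, "line_of_equilibria"),
        ],
    )
    def test_lifted_lva_regimes(self, kappa, C, expected):
        assert lifted_lva_regime(1, kappa, C) == expected


class TestSourceCases:
    @pytest.mark.parametrize(
        "text,case_id",
        [
            ("X -> 2X\nX + Y -> 2Y\nY -> 0", 7),
            ("2X -> 3X\nX + Y -> 0\nX -> X + Y", 8),
            ("2X -> 3X\nX + Y -> 2Y\nY -> 0", 9),
            ("2X -> 3X\nX + Y -> 0\n0 -> X", 10),
        ],
    )
    def test_theorem_cases(self, text, case_id):
        assert source_case_planar(parse_network(text)).case_id == case_id

    def test_case8_after_swap(self):
        # sources X+Y, 2Y, Y (X listed first): matches the case-8 template
        # only after exchanging the species
        net = parse_network("X + Y -> X\n2Y -> 3Y\nY -> X + 2Y")
        sc = source_case_planar(net)
        assert sc.case_id == 8 and sc.species_swap_applied

    def test_every_noncollinear_triple_is_matched(self):
        import itertools

        from crnosc.census import enumerate_complexes, _affinely_independent

        complexes = enumerate_complexes(2, 2)
        for triple in itertools.combinations(complexes, 3):
            if not _affinely_independent(*triple):
                continue
            # build any network over those sources (species order fixed)
            from crnosc.network import network_from_arrays

            tgts = [(s[0] + 1, s[1]) for s in triple]
            net = network_from_arrays(triple, tgts, species=("X", "Y"))
            sc = source_case_planar(net)
            assert 1 <= sc.case_id <= 10
            # normalised order reproduces the template
            pts = [triple[i] for i in sc.reaction_order]
            if sc.species_swap_applied:
                pts = [(b, a) for a, b in pts]
            assert tuple(pts) == CASE_TEMPLATES[sc.case_id]


class TestPlanarHopfVerdicts:
    def test_network4(self, net4):
        v = hopf_verdict_planar(net4)
        assert v.outcome == "supercritical_hopf"
        assert v.certificate["case"] == 9

    def test_lotka_center(self, lotka):
        assert hopf_verdict_planar(lotka).outcome == "center_for_all_k"

    def test_lva_no_periodic_orbit(self, lva):
        v = hopf_verdict_planar(lva)
        assert v.outcome == "no_periodic_orbit"
        assert v.family == "generalized_LVA"

    def test_case_1_to_6_network(self):
        # sources 0, X, Y (case 1), dynamically nontrivial
        net = parse_network("0 -> X + Y\nX -> 0\nY -> 0")
        v = hopf_verdict_planar(net)
        assert v.outcome == "no_periodic_orbit"

    def test_case8_vertical(self):
        net = parse_network("2X -> 3X + 2Y\nX + Y -> 0\nX -> 2X")
        assert hopf_verdict_planar(net).outcome == "vertical_hopf"

    def test_tetramolecular_family(self):
        for d in range(4):
            v = hopf_verdict_planar(tetramolecular_hopf_network(d))
            assert v.outcome == "supercritical_hopf" and v.certificate["case"] == 9

    def test_generalized_lva_check(self, lva, net4):
        assert generalized_lva_check(lva) == (True, 1)
        assert generalized_lva_check(generalized_lva(3)) == (True, 3)
        assert generalized_lva_check(net4) == (False, None)


class TestGeneralTrimolecular:
    def test_families(self, lotka, ivanova, lifted, net27, lva):
        assert classify_trimolecular_general(lotka).outcome == "center_for_all_k"
        assert classify_trimolecular_general(ivanova).outcome == "center_for_all_k"
        assert classify_trimolecular_general(lifted).outcome == "vertical_hopf"
        assert classify_trimolecular_general(net27).outcome == "saddle_always"
        assert classify_trimolecular_general(lva).outcome == "no_periodic_orbit"

    def test_trivial_species_stripped_and_reported(self):
        aug = parse_network("X + Z -> 2X + Z\nX + Y -> 2Y\nY -> 0")
        v = classify_trimolecular_general(aug)
        assert v.outcome == "center_for_all_k"
        assert v.removed_trivial_species == ("Z",)

    def test_five_species_dynamically_trivial(self):
        # rank two, quadratic, trimolecular, no trivial species, contains
        # 2X -> 3X: with five species this is necessarily dynamically trivial
        net = parse_network("2X -> 3X\nX + Y -> Z + W + V\nX -> 2X")
        from crnosc.network import network_rank, trivial_species

        assert network_rank(net) == 2 and not trivial_species(net)
        v = classify_trimolecular_general(net)
        assert v.outcome == "dynamically_trivial"

    def test_identify_family(self, lotka, ivanova, lifted, fam12, lva):
        assert identify_family(lotka).name == "generalized_lotka"
        assert identify_family(ivanova).name == "ivanova"
        assert identify_family(lifted).name == "lifted_LVA"
        assert identify_family(fam12).name == "family_12"
        assert identify_family(lva).name == "generalized_LVA"

    def test_center_verdicts_corroborated_by_simulation(self, ivanova):
        v = classify_trimolecular_general(ivanova)
        assert v.oscillatory
        res = detect_periodicity(
            MassActionSystem(ivanova, (1.0, 1.0, 1.0)), (1.0, 2.0, 3.0), t_max=60.0
        )
        assert res["periodic"] is True
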