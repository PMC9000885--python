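"""Skeleton registry, RDA cleavage arithmetic, loss series, theoretical
spectra and the conservation invariants behind them."""

import math

import pytest

from flavotier.flavochem import (
    CompoundTemplate,
    FragmentIon,
    complementary_pair_check,
    compound_formula,
    conservation_check,
    expected_ions,
    loss_series,
    rda_fragment_ions,
    registry,
    theoretical_spectrum,
)
from flavotier.formulae import F, IonSpec, ion_mz, subformula
from flavotier.spectra import Peak

DAIDZEIN = CompoundTemplate("daidzein", "isoflavone",
                            {"hydroxyl": 1}, {"hydroxyl": 1})
APIGENIN = CompoundTemplate("apigenin", "flavone",
                            {"hydroxyl": 2}, {"hydroxyl": 1})
PINOCEMBRIN = CompoundTemplate("pinocembrin", "flavanone", {"hydroxyl": 2}, {})


class TestRegistry:
    def test_twelve_skeletons(self):
        assert len(registry()) == 12

    def test_cleavage_parts_sum_to_scaffold(self):
        for skel in registry().values():
            for c in skel.cleavages.values():
                assert c.part_a + c.part_b == skel.scaffold, (
                    skel.subclass, c.label
                )

    def test_rules_cite_registered_ions(self):
        for skel in registry().values():
            labels = {i.label for i in skel.ions}
            for lbl in skel.rule.mandatory + skel.rule.supporting:
                assert lbl in labels


class TestCompoundFormula:
    @pytest.mark.parametrize(
        "template,expected",
        [
            (DAIDZEIN, "C15H10O4"),
            (APIGENIN, "C15H10O5"),
            (CompoundTemplate("bare", "flavone"), "C15H10O2"),
        ],
    )
    def test_examples(self, template, expected):
        assert str(compound_formula(template)) == expected

    def test_unknown_skeleton_is_error(self):
        with pytest.raises(KeyError):
            compound_formula(CompoundTemplate("x", "flavanonol"))


class TestRdaFragments:
    def test_daidzein_13_pair(self):
        ions = {i.label: i for i in rda_fragment_ions(DAIDZEIN, "1,3")}
        a, b = ions["[1,3A+H]+"], ions["[1,3B+H]+"]
        assert (str(a.formula), round(a.mz, 4)) == ("C7H5O3", 137.0233)
        assert (str(b.formula), round(b.mz, 4)) == ("C8H7O", 119.0491)
        # two-decimal rendering matches the conventional notation
        assert f"{a.mz:.2f}" == "137.02" and f"{b.mz:.2f}" == "119.05"

    def test_dihydroxyflavanone_13(self):
        ions = {i.label: i for i in rda_fragment_ions(PINOCEMBRIN, "1,3")}
        assert round(ions["[1,3A+H]+"].mz, 4) == 153.0182
        # complementary neutral B part of the scaffold cleavage
        skel = registry()["flavanone"]
        assert skel.cleavages["1,3"].part_b == F("C8H8")

    def test_unknown_label_lists_valid_ones(self):
        with pytest.raises(KeyError, match="1,3"):
            rda_fragment_ions(DAIDZEIN, "9,9")

    def test_part_sum_equals_compound_formula(self, fixture_library):
        for _, t in fixture_library:
            skel = registry()[t.skeleton]
            for c in skel.cleavages.values():
                total = c.part_a + t.delta("a") + c.part_b + t.delta("b")
                assert total == compound_formula(t)

    def test_hydroxyl_move_shifts_parts_by_one_oxygen(self):
        o_mass = 15.9949
        before = {i.label: i for i in rda_fragment_ions(DAIDZEIN, "1,3")}
        moved = CompoundTemplate("iso", "isoflavone", {}, {"hydroxyl": 2})
        after = {i.label: i for i in rda_fragment_ions(moved, "1,3")}
        assert math.isclose(
            after["[1,3A+H]+"].mz - before["[1,3A+H]+"].mz, -o_mass,
            abs_tol=1e-4,
        )
        assert math.isclose(
            after["[1,3B+H]+"].mz - before["[1,3B+H]+"].mz, +o_mass,
            abs_tol=1e-4,
        )


class TestLossSeries:
    def test_co_cascade_prints_anchor_values(self):
        start = FragmentIon("[M+H]+", F("C15H9O5"),
                            ion_mz(IonSpec(F("C15H9O5"), "cation")), "even")
        series = loss_series(start, [F("CO")], depth=2)
        mzs = sorted(round(i.mz, 4) for i in series)
        assert mzs == [213.0546, 241.0495, 269.0444]

    def test_depth_zero_is_start_only(self):
        start = FragmentIon("[M+H]+", F("C10H10O2"), 163.0754, "even")
        assert loss_series(start, [F("CO"), F("H2O")], 0) == [start]

    def test_infeasible_losses_pruned(self):
        start = FragmentIon("[M+H]+", F("C7H5O"),
                            ion_mz(IonSpec(F("C7H5O"), "cation")), "even")
        series = loss_series(start, [F("H2O")], depth=3)
        # only one dehydration possible before oxygen runs out
        assert [str(i.formula) for i in series] == ["C7H5O", "C7H3"]


class TestTheoreticalSpectrum:
    def test_flavanone_base_peak_share(self):
        sp = theoretical_spectrum(PINOCEMBRIN)
        frag = [p for p in sp.peaks if p.mz < sp.precursor_mz - 0.5]
        top = max(frag, key=lambda p: p.intensity)
        assert round(top.mz, 4) == 153.0182
        assert top.intensity / sum(p.intensity for p in frag) >= 0.40

    def test_flavonol_base_and_dehydration(self):
        t = CompoundTemplate("galangin", "flavonol", {"hydroxyl": 2}, {})
        sp = theoretical_spectrum(t)
        base = sp.base_peak
        ions = {lbl: ion for lbl, (ion, _) in expected_ions(t).items()}
        assert math.isclose(base.mz, ions["[1,3A+H]+"].mz, abs_tol=1e-3)
        assert round(ions["[1,3A+H]+"].mz, 4) == 153.0182
        assert any(
            abs(p.mz - ions["[M-H2O+H]+"].mz) < 1e-3 for p in sp.peaks
        )

    def test_aurone_base_is_radical_b_fragment(self):
        t = CompoundTemplate("sulfuretin", "aurone",
                            {"hydroxyl": 1}, {"hydroxyl": 2})
        ions = {lbl: ion for lbl, (ion, _) in expected_ions(t).items()}
        b = ions["[1,3B]+."]
        assert b.parity == "radical"
        assert round(b.mz, 4) == 134.0362
        assert round(ions["[1,3A+H]+"].mz, 4) == 137.0233
        sp = theoretical_spectrum(t)
        assert math.isclose(sp.base_peak.mz, b.mz, abs_tol=1e-3)

    def test_methyl_radical_loss_requires_methoxyl(self):
        plain = CompoundTemplate("genistein", "isoflavone",
                                 {"hydroxyl": 2}, {"hydroxyl": 1})
        methylated = CompoundTemplate("biochanin A", "isoflavone",
                                      {"hydroxyl": 2}, {"methoxyl": 1})
        assert "[M-CH3+H]+." not in expected_ions(plain)
        assert "[M-CH3+H]+." in expected_ions(methylated)

    def test_every_ion_is_subformula_of_protonated_molecule(
            self, fixture_library):
        for _, t in fixture_library:
            conservation_check(t)
            cation = compound_formula(t) + F("H")
            for lbl, (ion, _) in expected_ions(t).items():
                if "H2O+H" in lbl:  # water-transfer ion may exceed by H2O
                    continue
                assert subformula(ion.formula, cation), (t.name, lbl)


class TestComplementaryPair:
    def test_apigenin_h_transfer_pair(self):
        assert complementary_pair_check(
            Peak(153.0182, 1), Peak(119.0491, 1), 271.0601
        )

    def test_nonsense_pair_rejected(self):
        assert not complementary_pair_check(Peak(100, 1), Peak(100, 1), 300.0)

    def test_same_peak_twice_h_transfer_branch(self):
        p = Peak(120.0, 1.0)
        assert complementary_pair_check(p, p, 2 * 120.0 - 1.0078)

    def test_radical_split_branch(self):
        # aurone-style pair: [A+H]+ + [B]+. sums to precursor minus an electron
        assert complementary_pair_check(
            Peak(137.0233, 1), Peak(134.0362, 1), 271.0601
        )
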