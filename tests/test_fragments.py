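"""CID fragment prediction rules against the published diagnostic ions."""

import pytest

from gslprof.chem import ADDUCTS, adduct_mz, round_half_up
from gslprof.fragments import (
    PE_NEUTRAL_LOSS_MASS,
    PHOSPHOCHOLINE_FRAGMENT_MZ,
    ceramide_ions,
    flag_contaminant_spectrum,
    glycan_b_ion,
    glycan_b_water_loss,
    lcb_ions,
    pe_pc_discriminators,
    predict_fragments,
)
from gslprof.structures import LongChainBase


class TestGlycanBIons:
    @pytest.mark.parametrize(
        "composition, modification, expected",
        [
            ({"HexNAc": 1}, None, 204.1),
            ({"Neu5Ac": 1}, None, 292.1),
            ({"Hex": 1, "HexNAc": 1}, None, 366.1),
            ({"Hex": 1, "Neu5Ac": 1}, None, 454.2),
            ({"Hex": 1, "HexNAc": 1, "Fuc": 1}, None, 512.2),
            ({"Hex": 1, "HexNAc": 1, "Neu5Ac": 1}, None, 657.2),
            ({"Hex": 2, "HexNAc": 1, "Neu5Ac": 1}, None, 819.3),
            ({"Hex": 1, "HexNAc": 1, "Neu5Ac": 2}, None, 948.3),
            ({"Neu5Ac": 1}, "O-acetyl", 334.1),
        ],
    )
    def test_oxocarbenium_table(self, composition, modification, expected):
        assert round_half_up(glycan_b_ion(composition, modification)) == expected

    @pytest.mark.parametrize(
        "composition, modification, expected",
        [
            ({"Neu5Ac": 1}, None, 274.1),
            ({"Hex": 1, "HexNAc": 1, "Neu5Ac": 2}, None, 930.3),
            ({"Neu5Ac": 1}, "O-acetyl", 316.1),
        ],
    )
    def test_water_loss_companions(self, composition, modification, expected):
        assert round_half_up(glycan_b_water_loss(composition, modification)) == expected

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            glycan_b_ion({})

    def test_o_methyl_not_supported(self):
        # the +OMe table entry is internally inconsistent and not reproduced
        with pytest.raises(ValueError):
            glycan_b_ion({"Neu5Ac": 1}, "O-methyl")


class TestLipidIons:
    @pytest.mark.parametrize(
        "lcb, expected",
        [
            ("d18:1", (282.3, 264.3)),
            ("d18:2", (280.3, 262.3)),
            ("t18:0", (300.3, 282.3)),
            ("t18:1", (298.3, 280.3)),
            ("d18:0", (302.3, 284.3)),  # saturated base keeps [M+H]+
        ],
    )
    def test_lcb_pairs(self, lcb, expected):
        got = tuple(round_half_up(i.mz) for i in lcb_ions(LongChainBase.parse(lcb)))
        assert got == expected

    def test_ceramide_triplet(self, make_structure):
        ions = ceramide_ions(make_structure("Hex", "d18:1", "C18"))
        assert [round_half_up(i.mz) for i in ions] == [566.6, 548.5, 530.5]

    def test_ceramide_ions_headgroup_independent(self, make_structure):
        hex_ions = ceramide_ions(make_structure("Hex", "d18:1", "C18"))
        sm_ions = ceramide_ions(make_structure("SM", "d18:1", "C18"))
        assert [i.mz for i in hex_ions] == [i.mz for i in sm_ions]

    def test_long_unsaturated_ceramide_from_composition(self, make_structure):
        # oracle: [Cer+H]+ = mass(C42H81NO3) + proton
        from gslprof.chem import ElementalComposition, PROTON_MASS

        s = make_structure("Hex", "d18:1", "C24:1")
        expected = ElementalComposition.parse("C42H81NO3").monoisotopic_mass + PROTON_MASS
        assert ceramide_ions(s)[0].mz == pytest.approx(expected, abs=1e-6)


class TestPredictFragments:
    def test_cerebroside_contains_published_ions(self, make_structure):
        pred = predict_fragments(make_structure("Hex", "d18:1", "C18"))
        got = {round_half_up(i.mz) for i in pred.ions}
        assert {710.6, 566.6, 548.5, 530.5, 282.3, 264.3} <= got

    def test_sphingomyelin_has_phosphocholine_ion(self, make_structure):
        pred = predict_fragments(make_structure("SM", "d18:1", "C24:1"))
        assert any(round_half_up(i.mz) == 184.1 for i in pred.ions)

    def test_sulfatide_h2o_so3_loss(self, make_structure):
        s = make_structure("SHex", "d18:1", "C24:1")
        pred = predict_fragments(s)
        precursor = adduct_mz(s.neutral_mass, ADDUCTS["[M+H]+"])
        expected = precursor - 18.0106 - 79.9568
        assert any(i.mz == pytest.approx(expected, abs=1e-3) for i in pred.ions)

    def test_all_ions_below_protonated_precursor(self, make_structure):
        for head in ("Hex", "SM", "GM1", "GD1", "GQ1", "Fuc-GD1", "SHex"):
            s = make_structure(head, "d18:1", "C18")
            precursor = adduct_mz(s.neutral_mass, ADDUCTS["[M+H]+"])
            assert all(i.mz < precursor for i in predict_fragments(s).ions)

    def test_y_series_telescopes_by_single_residues(self, make_structure):
        from gslprof.structures import GLYCAN_RESIDUES

        residue_masses = {
            round(c.monoisotopic_mass, 4) for c in GLYCAN_RESIDUES.values()
        }
        pred = predict_fragments(make_structure("GT1", "d18:1", "C18"))
        y_mzs = [i.mz for i in pred.ions if i.ion_class == "glycan_Y"]
        precursor = adduct_mz(
            make_structure("GT1", "d18:1", "C18").neutral_mass, ADDUCTS["[M+H]+"]
        )
        previous = precursor
        for mz in y_mzs:
            assert round(previous - mz, 4) in residue_masses
            previous = mz

    def test_b_ions_capped_at_four_residues(self, make_structure):
        pred = predict_fragments(make_structure("GQ1", "d18:1", "C18"))
        for ion in pred.ions:
            if ion.ion_class == "glycan_B":
                label = ion.label.removeprefix("B ").split(" ")[0]
                n = sum(int(part[0]) for part in label.split("+"))
                assert n <= 4

    def test_fucose_b_ions_downweighted(self, make_structure):
        pred = predict_fragments(make_structure("Fuc-GD1", "d18:1", "C18"))
        fuc_b = [
            i for i in pred.ions if i.ion_class == "glycan_B" and "Fuc" in i.label
        ]
        plain_b = [
            i for i in pred.ions if i.ion_class == "glycan_B" and "Fuc" not in i.label
            and "-H2O" not in i.label
        ]
        assert fuc_b and plain_b
        assert max(i.diagnostic_weight for i in fuc_b) < min(
            i.diagnostic_weight for i in plain_b
        )

    def test_no_duplicate_labels(self, make_structure, default_db):
        for s in default_db[::97]:
            pred = predict_fragments(s)  # constructor enforces uniqueness
            assert pred.ions


class TestContaminantDiscriminators:
    def test_rule_masses(self):
        rules = pe_pc_discriminators()
        assert round_half_up(rules["pc_fragment_mz"]) == 184.1
        assert round(rules["pe_neutral_loss"]) == 141

    def test_pe_neutral_loss_flags(self):
        precursor = 718.539
        peaks = [(precursor - PE_NEUTRAL_LOSS_MASS, 5000.0), (500.0, 800.0)]
        assert flag_contaminant_spectrum(peaks, precursor) == {"pe_contaminant"}

    def test_pc_even_precursor_flags(self):
        peaks = [(PHOSPHOCHOLINE_FRAGMENT_MZ, 9000.0)]
        assert "pc_contaminant" in flag_contaminant_spectrum(peaks, 760.585)

    def test_odd_precursor_with_184_is_sm_consistent(self):
        # odd protonated nominal mass: no PC veto
        peaks = [(PHOSPHOCHOLINE_FRAGMENT_MZ, 9000.0)]
        assert flag_contaminant_spectrum(peaks, 731.606) == set()

    def test_empty_spectrum_no_flags(self):
        assert flag_contaminant_spectrum([], 731.606) == set()
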