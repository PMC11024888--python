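"""Precursor matching, composite scoring, and disambiguation rules."""

import numpy as np
import pytest

from gslprof.annotate import (
    AnnotatedFeature,
    AnnotationConfig,
    AnnotationScore,
    extrapolate_ids,
    match_precursors,
    resolve_isobars,
    score_annotation,
)
from gslprof.chem import ADDUCTS, adduct_mz
from gslprof.features import CompoundFeatureGroup, Feature, Spectrum
from gslprof.fragments import predict_fragments

CONFIG = AnnotationConfig()


class TestMatchPrecursors:
    def test_protonated_cerebroside_matched(self, default_db, make_structure):
        target = make_structure("Hex", "d18:1", "C18")
        mz = adduct_mz(target.neutral_mass, ADDUCTS["[M+H]+"])
        hits = match_precursors(mz, default_db)
        assert any(s.name == target.name for s, _ in hits)

    def test_far_off_mass_matches_nothing(self, default_db):
        assert match_precursors(123.456, default_db) == []

    def test_charge_two_preferred(self, default_db, make_structure):
        gm1 = make_structure("GM1", "d18:1", "C18")
        mz = adduct_mz(gm1.neutral_mass, ADDUCTS["[M+2H]2+"])
        hits = match_precursors(mz, default_db)
        assert hits and hits[0][1].charge == 2

    def test_sulfatide_in_source_mass_is_ambiguous(self, default_db, make_structure):
        # SHex minus SO3 lands exactly on a HexCer mass; both interpretations
        # must be offered and left to downstream RT logic
        shex = make_structure("SHex", "d18:1", "C18")
        hexcer_mass = shex.neutral_mass - 79.95682
        mz = adduct_mz(hexcer_mass, ADDUCTS["[M+H]+"])
        names = {s.name for s, _ in match_precursors(mz, default_db)}
        assert "Hex-d18:1/C18" in names


def _spectrum_from(ions, scan_id="m1", precursor=None):
    mzs = np.array([i.mz for i in ions])
    ints = np.full(mzs.size, 1000.0)
    return Spectrum(scan_id, 2, 30.0, mzs, ints, precursor_mz=precursor)


class TestScoreAnnotation:
    def test_perfect_evidence_scores_twenty(self, make_structure):
        s = make_structure("GM1", "d18:1", "C18")
        pred = predict_fragments(s)
        score = score_annotation(pred, [_spectrum_from(pred.ions)], 0.0, 0.839, 0.839)
        assert score.total == pytest.approx(20.0)

    def test_no_ms2_no_rt_caps_at_five(self, make_structure):
        pred = predict_fragments(make_structure("GM1", "d18:1", "C18"))
        score = score_annotation(pred, [], 0.0, None, None)
        assert score.total == pytest.approx(5.0)
        assert score.total < CONFIG.score_threshold

    def test_true_structure_outscores_lipid_decoy(self, make_structure):
        """Spectrum holds the true ceramide/LCB ions but a decoy's glycan
        ions; the structure whose lipid ions match must win."""
        true = make_structure("GM1", "d18:1", "C18")
        decoy = make_structure("GM1", "t18:0", "C18:1")  # same headgroup, wrong lipid
        true_pred = predict_fragments(true)
        decoy_pred = predict_fragments(decoy)
        spectrum = _spectrum_from(
            [i for i in true_pred.ions if i.ion_class in ("ceramide", "lcb")]
            + [i for i in decoy_pred.ions if i.ion_class == "glycan_B"]
        )
        s_true = score_annotation(true_pred, [spectrum], 0.0, 0.839, 0.839)
        s_decoy = score_annotation(decoy_pred, [spectrum], 0.0, 0.839, 0.839)
        assert s_true.total > s_decoy.total

    def test_monotone_in_matched_ions(self, make_structure):
        pred = predict_fragments(make_structure("GM1", "d18:1", "C18"))
        totals = []
        for k in (3, 6, len(pred.ions)):
            spec = _spectrum_from(pred.ions[:k])
            totals.append(score_annotation(pred, [spec], 0.0, 0.839, 0.839).total)
        assert totals == sorted(totals)

    def test_monotone_in_ppm_error(self, make_structure):
        pred = predict_fragments(make_structure("GM1", "d18:1", "C18"))
        spec = _spectrum_from(pred.ions)
        totals = [
            score_annotation(pred, [spec], ppm, 0.839, 0.839).total
            for ppm in (0.0, 5.0, 15.0, 25.0, 40.0)
        ]
        assert totals == sorted(totals, reverse=True)

    def test_component_ranges_validated(self):
        with pytest.raises(ValueError):
            AnnotationScore(11.0, 0.0, 0.0)


def _annotation(structure, rt, area, observed_rrt, expected_rrt, score):
    feature = Feature(
        mz=adduct_mz(structure.neutral_mass, ADDUCTS["[M+H]+"]),
        rt=rt, area=area, height=area, rt_start=rt - 0.3, rt_end=rt + 0.3,
        adduct=ADDUCTS["[M+H]+"],
    )
    return AnnotatedFeature(
        structure=structure,
        group=CompoundFeatureGroup([feature]),
        score=score,
        observed_rrt=observed_rrt,
        expected_rrt=expected_rrt,
        ppm=0.0,
        adducts=("[M+H]+",),
    )


class TestResolveIsobars:
    def test_in_source_hex_removed_at_parent_rt(self, make_structure):
        """A HexCer candidate sitting at the sulfatide's RT at 0.5% of its
        area is explained as in-source sulfate loss and removed."""
        shex = make_structure("SHex", "d18:1", "C18")
        hexcer = make_structure("Hex", "d18:1", "C18")
        parent = _annotation(shex, 39.06, 1e6, 0.868, 0.868, AnnotationScore(10, 5, 5))
        artifact = _annotation(hexcer, 39.06, 5e3, 0.868, 0.987, AnnotationScore(9, 5, 0))
        kept = resolve_isobars([parent, artifact], CONFIG)
        assert parent in kept and artifact not in kept
        assert "in_source_suspect" in artifact.flags

    def test_hex_at_own_rrt_retained(self, make_structure):
        shex = make_structure("SHex", "d18:1", "C18")
        hexcer = make_structure("Hex", "d18:1", "C18")
        parent = _annotation(shex, 39.06, 1e6, 0.868, 0.868, AnnotationScore(10, 5, 5))
        genuine = _annotation(hexcer, 44.4, 5e3, 0.987, 0.987, AnnotationScore(10, 5, 5))
        kept = resolve_isobars([parent, genuine], CONFIG)
        assert genuine in kept

    def test_gm3_coeluting_with_gd3_removed(self, make_structure):
        gd3 = make_structure("GD3", "d18:1", "C18")
        gm3 = make_structure("GM3", "d18:1", "C18")
        parent = _annotation(gd3, 34.7, 2e6, 0.771, 0.771, AnnotationScore(10, 5, 5))
        artifact = _annotation(gm3, 34.72, 1e4, 0.771, 0.861, AnnotationScore(8, 5, 0))
        kept = resolve_isobars([parent, artifact], CONFIG)
        assert artifact not in kept and "in_source_suspect" in artifact.flags

    def test_large_companion_not_removed(self, make_structure):
        # area above the artifact ceiling: a genuine co-eluting compound
        shex = make_structure("SHex", "d18:1", "C18")
        hexcer = make_structure("Hex", "d18:1", "C18")
        parent = _annotation(shex, 39.06, 1e6, 0.868, 0.868, AnnotationScore(10, 5, 5))
        big = _annotation(hexcer, 39.06, 5e5, 0.868, 0.987, AnnotationScore(9, 5, 0))
        assert big in resolve_isobars([parent, big], CONFIG)


class TestExtrapolateIds:
    def _confident(self, make_structure, acyl, rt):
        s = make_structure("GD1", "d18:1", acyl)
        return _annotation(s, rt, 1e6, 0.755, 0.755, AnnotationScore(10, 5, 5))

    def test_homolog_at_predicted_rt_rescued(self, make_structure):
        accepted = [
            self._confident(make_structure, "C16", 33.0),
            self._confident(make_structure, "C18", 33.5),
            self._confident(make_structure, "C20", 34.0),
        ]
        candidate = _annotation(
            make_structure("GD1", "d18:1", "C22"), 34.5, 2e4, 0.76, 0.755,
            AnnotationScore(0, 5, 4),
        )
        rescued, fits = extrapolate_ids(accepted, [candidate], CONFIG)
        assert candidate in rescued
        assert "rt_extrapolated" in candidate.flags
        assert fits["GD1|d18:1"].slope == pytest.approx(0.25)

    def test_wrong_rt_not_rescued(self, make_structure):
        accepted = [
            self._confident(make_structure, "C16", 33.0),
            self._confident(make_structure, "C18", 33.5),
            self._confident(make_structure, "C20", 34.0),
        ]
        candidate = _annotation(
            make_structure("GD1", "d18:1", "C22"), 36.5, 2e4, 0.81, 0.755,
            AnnotationScore(0, 5, 0),
        )
        rescued, _ = extrapolate_ids(accepted, [candidate], CONFIG)
        assert candidate not in rescued

    def test_two_members_insufficient(self, make_structure):
        accepted = [
            self._confident(make_structure, "C16", 33.0),
            self._confident(make_structure, "C18", 33.5),
        ]
        candidate = _annotation(
            make_structure("GD1", "d18:1", "C22"), 34.5, 2e4, 0.76, 0.755,
            AnnotationScore(0, 5, 4),
        )
        rescued, fits = extrapolate_ids(accepted, [candidate], CONFIG)
        assert rescued == [] and fits == {}
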