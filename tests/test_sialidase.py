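"""Neuraminidase digest rule and a/b/c series assignment by differencing."""

import pytest

from gslprof.sialidase import (
    assign_series,
    digest_product,
    full_series_name,
    series_letter,
)
from gslprof.structures import GLYCAN_RESIDUES, Headgroup, assemble_structure
from gslprof.structures import AcylChain, LongChainBase

NEU5AC = GLYCAN_RESIDUES["Neu5Ac"].monoisotopic_mass


class TestDigestProduct:
    @pytest.mark.parametrize(
        "head, product_series_name",
        [
            ("GD1", "GM1a-d18:1/C18"),  # GD1a: terminal sialic cleaved
            ("GT1", "GD1b-d18:1/C18"),  # GT1b: protected disialyl core kept
            ("GM1", "GM1a-d18:1/C18"),  # core-linked sialic survives
            ("GA1", "GA1-d18:1/C18"),   # no substrate
        ],
    )
    def test_published_mappings(self, make_structure, head, product_series_name):
        product = digest_product(make_structure(head, "d18:1", "C18"))
        assert full_series_name(product) == product_series_name

    def test_idempotent(self, make_structure, catalog):
        for head in catalog:
            s = make_structure(head, "d18:1", "C18")
            once = digest_product(s)
            assert digest_product(once).composition == once.composition

    def test_mass_drops_by_cleaved_sialic_acids(self, make_structure):
        for head, cleaved in (("GD1", 1), ("GT1", 1), ("GQ1", 2), ("GM1", 0)):
            s = make_structure(head, "d18:1", "C18")
            product = digest_product(s)
            assert s.neutral_mass - product.neutral_mass == pytest.approx(
                cleaved * NEU5AC, abs=1e-6
            )

    def test_neu5ac_count_never_increases(self, make_structure, catalog):
        for head in catalog:
            s = make_structure(head, "d18:1", "C18")
            product = digest_product(s)
            assert (
                product.headgroup.glycan.get("Neu5Ac", 0)
                <= s.headgroup.glycan.get("Neu5Ac", 0)
            )

    def test_positions_required_for_gangliosides(self):
        headless = Headgroup("GM-x", {"Hex": 2, "Neu5Ac": 1})
        s = assemble_structure(
            headless, LongChainBase.parse("d18:1"), AcylChain.parse("C18")
        )
        with pytest.raises(ValueError, match="sialic_positions"):
            digest_product(s)

    def test_series_letters(self, catalog):
        assert series_letter(catalog["GD1"]) == "a"
        assert series_letter(catalog["GT1"]) == "b"
        assert series_letter(catalog["GA1"]) == ""


class TestAssignSeries:
    @pytest.fixture()
    def db(self, default_db):
        return {s.name: s for s in default_db}

    def test_gd1_drop_with_gm1_rise_is_a_series(self, db):
        untreated = {"GD1-d18:1/C18": 100.0, "GM1-d18:1/C18": 50.0}
        treated = {"GM1-d18:1/C18": 150.0}
        result = {a.structure_name: a.series for a in assign_series(untreated, treated, db)}
        assert result["GD1-d18:1/C18"] == "a"

    def test_unchanged_gd1_is_b_series(self, db):
        # the other ceramide's digest proves the enzyme acted; the
        # untouched GD1 pool then means both sialic acids sit on the core
        untreated = {"GD1-d18:1/C18": 100.0, "GD1-d18:1/C20": 100.0}
        treated = {"GD1-d18:1/C18": 100.0, "GM1-d18:1/C20": 100.0}
        result = {a.structure_name: a.series for a in assign_series(untreated, treated, db)}
        assert result["GD1-d18:1/C18"] == "b"
        assert result["GD1-d18:1/C20"] == "a"

    def test_inactive_enzyme_gives_no_assignments(self, db):
        # a lone unchanged GD1 could also mean a failed digest: undetermined
        untreated = {"GD1-d18:1/C18": 100.0}
        treated = {"GD1-d18:1/C18": 100.0}
        result = {a.structure_name: a.series for a in assign_series(untreated, treated, db)}
        assert result["GD1-d18:1/C18"] == "undetermined"

    def test_no_change_anywhere_undetermined(self, db):
        # multi-configuration gangliosides with no observable shift
        untreated = {"GT1-d18:1/C18": 100.0, "GD1-d18:1/C18": 80.0}
        treated = dict(untreated)
        for a in assign_series(untreated, treated, db):
            assert a.series == "undetermined"

    def test_shared_ceramide_cascade_resolved_jointly(self, db):
        """GT1b and GD1a share a ceramide: GT1 feeds the GD1 pool while
        GD1 drains into GM1; the joint fit untangles both."""
        untreated = {
            "GT1-d18:1/C18": 100.0,
            "GD1-d18:1/C18": 200.0,
            "GM1-d18:1/C18": 50.0,
        }
        treated = {
            "GD1-d18:1/C18": 100.0,  # +100 from GT1b, -200 own digest
            "GM1-d18:1/C18": 250.0,  # +200 from GD1a
        }
        result = {a.structure_name: a.series for a in assign_series(untreated, treated, db)}
        assert result["GT1-d18:1/C18"] == "b"
        assert result["GD1-d18:1/C18"] == "a"
        assert result["GM1-d18:1/C18"] == "a"

    def test_missing_treated_profile_rejected(self, db):
        with pytest.raises(ValueError):
            assign_series({"GD1-d18:1/C18": 1.0}, None, db)

    def test_full_benchmark_profile_recovered(self, db):
        """On the simulated treated/untreated pair, every ganglioside's
        catalog series is recovered."""
        from gslprof.synth import default_benchmark_profile, treated_profile

        profile = default_benchmark_profile(include_artifacts=False)
        treated = treated_profile(profile)
        untreated_tbl = {e.structure.name: e.abundance for e in profile.entries}
        treated_tbl = {e.structure.name: e.abundance for e in treated.entries}
        truth = {
            e.structure.name: series_letter(e.structure.headgroup)
            for e in profile.entries
            if e.structure.headgroup.is_ganglioside
        }
        result = {
            a.structure_name: a.series
            for a in assign_series(untreated_tbl, treated_tbl, db)
        }
        assert result == truth
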