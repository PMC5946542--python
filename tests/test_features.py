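"""Feature detectors and hotspot locus assignment."""

import pytest

from mitorder import (
    GenerationParams,
    count_control_regions,
    detect_extra_copies,
    detect_nc_insertions,
    detect_ol,
    detect_pseudogenes,
    detect_translocations,
    feature_report,
    generate_record,
    hotspot_assignment,
)
from mitorder.classify import THE_ELEVEN
from mitorder.features import (
    HOTSPOT_CR_FLANK,
    HOTSPOT_OTHER,
    HOTSPOT_WANCY,
    FeatureReport,
    cr_flank_type_count,
)
from mitorder.model import GeneOrder


class TestDetectOl:
    def test_absent_in_blind_snake_orders(self, registry):
        for label in ("I", "II"):
            present, ctx = detect_ol(registry.get(label).reference_order)
            assert not present and ctx is None

    def test_present_with_wancy_neighbors_in_iii(self, registry):
        present, ctx = detect_ol(registry.get("III").reference_order)
        assert present and ctx == ("N", "C")

    def test_present_in_canonical_baseline(self, canonical):
        assert detect_ol(canonical)[0]

    def test_two_ol_tokens_is_integrity_error(self, registry):
        order = registry.get("III").reference_order
        i = order.indices_of("OL")[0]
        doubled = GeneOrder(order.tokens[:i] + (order.tokens[i],)
                            + order.tokens[i:])
        with pytest.raises(ValueError, match="OL"):
            detect_ol(doubled)


class TestControlRegions:
    def test_published_iii_e_lengths_are_asymmetric(self, registry):
        rec = generate_record(GenerationParams("III-E", seed=0),
                              registry=registry)
        count, lengths, asym = count_control_regions(rec)
        assert count == 2
        assert sorted(lengths) == [2878, 4110]
        assert asym
        assert max(lengths) / min(lengths) == pytest.approx(1.428, abs=1e-3)

    def test_equal_lengths_are_symmetric(self, registry):
        rec = generate_record(GenerationParams(
            "III", seed=0, length_overrides={"CR1": 1100, "CR2": 1100}))
        count, lengths, asym = count_control_regions(rec)
        assert count == 2 and not asym

    def test_single_cr_has_no_asymmetry(self, registry):
        rec = generate_record(GenerationParams("I", seed=0))
        count, _, asym = count_control_regions(rec)
        assert count == 1 and not asym


class TestTranslocations:
    def test_q_moved_into_wancy_in_type_i(self, registry, canonical):
        calls = detect_translocations(
            registry.get("I").reference_order, canonical)
        assert ("Q", ("I", "M"), ("W", "A")) in calls

    def test_k_moved_before_atp6_in_iii_a(self, registry):
        calls = detect_translocations(
            registry.get("III-A").reference_order,
            registry.get("III").reference_order)
        assert calls == [("K", ("COX2", "ATP8"), ("ATP8", "ATP6"))]

    def test_order_vs_itself_is_empty(self, registry):
        for atype in registry:
            assert detect_translocations(
                atype.reference_order, atype.reference_order) == []

    def test_pro_moved_between_the_two_crs_in_iii_b(self, registry):
        calls = detect_translocations(
            registry.get("III-B").reference_order,
            registry.get("III").reference_order)
        assert calls == [("P", ("T", "CR"), ("I", "CR"))]


class TestPseudogenesAndCopies:
    def test_iii_c_pseudo_pro_flanks(self, registry):
        assert detect_pseudogenes(registry.get("III-C").reference_order) \
            == [("P*", ("I", "CR"))]

    def test_iii_d_extra_ile_adjacent_to_cr(self, registry):
        order = registry.get("III-D").reference_order
        assert detect_extra_copies(order) == ["I"]
        i_last = order.indices_of("I")[-1]
        left, right = order.neighbors(i_last)
        assert "CR" in (left.name, right.name)

    def test_plain_iii_is_clean(self, registry):
        order = registry.get("III").reference_order
        assert detect_pseudogenes(order) == []
        assert detect_extra_copies(order) == []


class TestNcInsertions:
    def test_iii_g_insertion_between_cys_and_tyr(self, registry):
        rec = generate_record(GenerationParams("III-G", seed=0))
        assert detect_nc_insertions(rec.order) == [(5702, ("C", "Y"))]

    def test_iii_f_insertion_between_nd5_and_nd6(self, registry):
        rec = generate_record(GenerationParams("III-F", seed=0))
        assert detect_nc_insertions(rec.order) == [(342, ("ND5", "ND6"))]

    def test_type_ii_has_none(self, registry):
        assert detect_nc_insertions(
            registry.get("II").reference_order) == []


GOLDEN_LOCI = {
    "I": {HOTSPOT_WANCY},
    "II": {HOTSPOT_WANCY},
    "III": {HOTSPOT_CR_FLANK},
    "III-A": {HOTSPOT_OTHER},
    "III-B": {HOTSPOT_CR_FLANK},
    "III-B1": {HOTSPOT_CR_FLANK},
    "III-C": {HOTSPOT_CR_FLANK},
    "III-D": {HOTSPOT_CR_FLANK},
    "III-E": {HOTSPOT_CR_FLANK},
    "III-F": {HOTSPOT_CR_FLANK, HOTSPOT_OTHER},
    "III-G": {HOTSPOT_WANCY},
}


class TestHotspots:
    @pytest.mark.parametrize("label", THE_ELEVEN)
    def test_locus_assignment_per_type(self, registry, label):
        assert hotspot_assignment(registry.get(label)) == \
            GOLDEN_LOCI[label]

    def test_seven_types_rearranged_at_cr_flanks(self, registry):
        assert cr_flank_type_count(registry) == 7

    def test_three_types_carry_wancy_events(self, registry):
        wancy = {t.label for t in registry
                 if HOTSPOT_WANCY in hotspot_assignment(t)}
        assert wancy == {"I", "II", "III-G"}

    def test_empty_event_list_is_error(self, registry):
        bare = type(registry.get("III"))(
            label="X", reference_order=registry.get("III").reference_order)
        with pytest.raises(ValueError, match="diagnostic"):
            hotspot_assignment(bare)


class TestFeatureReport:
    def test_per_type_feature_table(self, registry, canonical):
        """Each arrangement type shows exactly its named diagnostic
        features relative to the canonical squamate baseline."""
        reports = {}
        for atype in registry:
            rec = generate_record(GenerationParams(atype.label, seed=0),
                                  registry=registry)
            reports[atype.label] = feature_report(rec, canonical)
        assert not reports["I"].ol_present
        assert not reports["II"].ol_present
        for lab in THE_ELEVEN[2:]:
            assert reports[lab].ol_present
        assert reports["I"].cr_count == 1
        assert all(reports[lab].cr_count == 2 for lab in THE_ELEVEN[2:])
        assert [p[0] for p in reports["III-C"].pseudogenes] == ["P*"]
        assert [p[0] for p in reports["III-B1"].pseudogenes] == ["P*"]
        assert reports["III-D"].extra_copies == ["I"]
        assert reports["III-E"].cr_asymmetric
        assert reports["III-F"].cr_asymmetric
        assert not reports["III"].cr_asymmetric
        assert [n[0] for n in reports["III-F"].nc_insertions] == [342]
        assert [n[0] for n in reports["III-G"].nc_insertions] == [5702]
        trans = {g for g, _, _ in reports["III-A"].translocations}
        assert "K" in trans

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            FeatureReport("t", True, 1, [100, 200], False, [], [], [])
        with pytest.raises(ValueError):
            FeatureReport("t", True, 1, [100], True, [], [], [])
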