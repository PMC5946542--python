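"""The arrangement-identity rule and type assignment."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitorder import (
    GenerationParams,
    MitogenomeRecord,
    canonical_key,
    classify_record,
    generate_record,
    novel_types,
    same_arrangement,
    type_census,
)
from mitorder.classify import THE_ELEVEN, TypeRegistry, is_cr_asymmetric


def _record(order, tid="t1"):
    return MitogenomeRecord(taxon_id=tid, species="s", family="f",
                            order=order, source="generated")


class TestCanonicalKey:
    def test_rotation_invariance(self, registry):
        rng = random.Random(11)
        for atype in registry:
            key = canonical_key(atype.reference_order)
            for _ in range(5):
                k = rng.randrange(len(atype.reference_order))
                assert canonical_key(atype.reference_order.rotate(k)) == key

    def test_the_eleven_keys_distinct_up_to_asymmetry(self, registry):
        # III and III-E share a token-level key by design; all other
        # pairs are distinct
        keys = {t.label: t.key() for t in registry}
        for a in THE_ELEVEN:
            for b in THE_ELEVEN:
                if a >= b:
                    continue
                if {a, b} == {"III", "III-E"}:
                    assert keys[a] == keys[b]
                else:
                    assert keys[a] != keys[b], (a, b)

    def test_pseudo_copy_changes_the_key(self, registry):
        assert registry.get("III").key() != registry.get("III-C").key()

    def test_q_position_distinguishes_blind_snake_orders(self, registry):
        assert registry.get("I").key() != registry.get("II").key()

    def test_lengths_excluded_unless_requested(self, registry):
        e = registry.get("III-E").reference_order
        iii = registry.get("III").reference_order
        assert canonical_key(e) == canonical_key(iii)
        assert canonical_key(e, compare_lengths=True) != \
            canonical_key(iii, compare_lengths=True)


class TestSameArrangement:
    def test_rotated_copy_is_identical(self, registry):
        order = registry.get("III").reference_order
        assert same_arrangement(order, order.rotate(13))

    def test_cr_length_differences_are_abstracted(self, registry):
        a = generate_record(GenerationParams(
            "III-C", seed=0, length_overrides={"CR1": 1100}))
        b = generate_record(GenerationParams(
            "III-C", seed=1, length_overrides={"CR1": 1400}))
        assert same_arrangement(a.order, b.order)

    def test_extra_pseudo_breaks_identity(self, registry):
        assert not same_arrangement(
            registry.get("III-B").reference_order,
            registry.get("III-B1").reference_order,
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.sampled_from(THE_ELEVEN),
        b=st.sampled_from(THE_ELEVEN),
        ka=st.integers(0, 50),
        kb=st.integers(0, 50),
    )
    def test_equivalence_relation(self, registry, a, b, ka, kb):
        oa = registry.get(a).reference_order.rotate(ka)
        ob = registry.get(b).reference_order.rotate(kb)
        assert same_arrangement(oa, oa)  # reflexive
        assert same_arrangement(oa, ob) == same_arrangement(ob, oa)
        if same_arrangement(oa, ob):  # agrees with key equality
            assert canonical_key(oa) == canonical_key(ob)


class TestClassify:
    @pytest.mark.parametrize("label", THE_ELEVEN)
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_generate_classify_round_trip(self, registry, label, seed):
        rec = generate_record(GenerationParams(label, seed=seed),
                              registry=registry)
        assert classify_record(rec, registry) == label

    def test_canonical_baseline_is_novel(self, registry, canonical):
        assert classify_record(_record(canonical), registry) == "NEW-1"

    def test_new_labels_are_input_order_deterministic(self, registry,
                                                      canonical):
        from mitorder.classify import builtin_registry
        reg = builtin_registry()
        rotated = canonical.rotate(5)
        other = registry.get("I").reference_order
        # drop Q entirely: a second unseen arrangement
        from mitorder.model import GeneOrder
        other = GeneOrder(tuple(t for t in other if t.name != "Q"))
        assert classify_record(_record(rotated), reg) == "NEW-1"
        assert classify_record(_record(other), reg) == "NEW-2"
        # same key re-presented reuses its label
        assert classify_record(_record(canonical), reg) == "NEW-1"

    def test_asymmetry_promotes_iii_to_iii_e(self, registry):
        symmetric = generate_record(GenerationParams(
            "III", seed=0, length_overrides={"CR1": 1100, "CR2": 1100}))
        asym = generate_record(GenerationParams(
            "III", seed=0, length_overrides={"CR1": 1100, "CR2": 2000}))
        assert classify_record(symmetric, registry) == "III"
        assert classify_record(asym, registry) == "III-E"
        assert is_cr_asymmetric(asym.order)

    def test_viperid_panel_labels(self, panel):
        vipers = [r for r in panel.records if r.family == "Viperidae"]
        labels = {r.taxon_id: classify_record(r, panel.registry)
                  for r in vipers}
        assert set(labels.values()) == {"III-B", "III-B1"}
        b1 = [t for t, lab in labels.items() if lab == "III-B1"]
        assert b1 == ["Ovophis_okinavensis"]

    def test_registry_with_clashing_types_rejected(self, registry):
        t = registry.get("III")
        clone = type(t)(label="III-X", reference_order=t.reference_order)
        with pytest.raises(ValueError, match="integrity"):
            TypeRegistry([t, clone])


class TestCensus:
    def test_full_panel_counts(self, panel):
        census, distinct = type_census(panel.records, panel.registry)
        assert distinct == 11
        assert int(census.sum()) == 65

    def test_single_record(self, registry):
        rec = generate_record(GenerationParams("III", seed=0))
        census, distinct = type_census([rec], registry)
        assert distinct == 1 and census["III"] == 1

    def test_scolecophidian_families_carry_only_i_and_ii(self, panel):
        blind = [r for r in panel.records
                 if r.family in ("Leptotyphlopidae", "Typhlopidae")]
        census, _ = type_census(blind, panel.registry)
        assert set(census.index) == {"I", "II"}

    def test_empty_input_rejected(self, registry):
        with pytest.raises(ValueError):
            type_census([], registry)


class TestNovelTypes:
    def test_five_types_new_relative_to_prior_six(self, registry, prior):
        assert novel_types(registry, prior) == \
            ["III-A", "III-D", "III-E", "III-F", "III-G"]

    def test_registry_vs_itself_is_empty(self, registry):
        assert novel_types(registry, registry) == []

    def test_empty_prior_makes_all_eleven_novel(self, registry):
        empty = TypeRegistry([])
        assert novel_types(registry, empty) == sorted(THE_ELEVEN)
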