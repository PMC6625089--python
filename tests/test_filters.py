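"""Operator derivation, predicate semantics, LIFO stack laws, serialization."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from vcfstack import (
    FieldDef,
    FilterStack,
    make_filter,
    operators_for,
    parse_filter_string,
    pop_filter,
    push_filter,
    record_passes,
    render_filter,
    survivors,
    value_domain,
)
from vcfstack.errors import (
    FilterConstructionError,
    StackEmptyError,
    WrongTypeError,
)


class TestOperatorsFor:
    def test_numeric_fields_get_relational_operators(self):
        ops = operators_for(FieldDef("AF", "INFO", "A", "Float"))
        assert {">", "<", ">=", "<=", "==", "!="} <= ops
        assert {"is_missing", "not_missing"} <= ops

    def test_flag_fields_get_presence_operators(self):
        assert operators_for(FieldDef("DB", "INFO", 0, "Flag")) == {
            "present", "absent"}

    def test_string_fields_get_equality_and_set_membership(self):
        ops = operators_for(FieldDef("CLASS", "INFO", 1, "String"))
        assert ops == {"==", "!=", "in_set", "is_missing", "not_missing"}

    def test_gt_gets_genotype_class_operators(self):
        ops = operators_for(FieldDef("GT", "FORMAT", 1, "String"))
        assert ops == {"is_hom_ref", "is_het", "is_hom_alt", "is_hemi",
                       "is_missing", "has_alt"}


class TestMakeFilter:
    def test_basic_category_excludes_ref_alt(self, tiny_store):
        with pytest.raises(FilterConstructionError, match="REF/ALT"):
            make_filter(tiny_store.header, "basic", "REF", "==", "A")

    def test_operand_type_checked_at_make_time(self, tiny_store):
        with pytest.raises(FilterConstructionError):
            make_filter(tiny_store.header, "info", "AF", "<", "low")
        with pytest.raises(FilterConstructionError):
            make_filter(tiny_store.header, "info", "CLASS", "==", 3)

    def test_inapplicable_operator_rejected(self, tiny_store):
        with pytest.raises(FilterConstructionError, match="applicable"):
            make_filter(tiny_store.header, "info", "DB", "<", 1)

    def test_scope_must_be_known_samples(self, tiny_store):
        with pytest.raises(FilterConstructionError, match="GHOST"):
            make_filter(tiny_store.header, "format", "GT", "is_het",
                        sample_scope=("GHOST",))


class TestRecordPasses:
    def test_any_semantics_for_multivalued_info(self, tiny_store):
        # AF=[0.1, 0.005]: one element below the cutoff is enough
        filt = make_filter(tiny_store.header, "info", "AF", "<", 0.01)
        assert record_passes(tiny_store.records[2], filt, tiny_store.header)

    def test_all_modifier_requires_every_element(self, tiny_store):
        filt = make_filter(tiny_store.header, "info", "AF", "<", 0.01,
                           elementwise="all")
        assert not record_passes(tiny_store.records[2], filt, tiny_store.header)

    def test_missing_fails_everything_except_is_missing(self, tiny_store):
        rec = tiny_store.records[1]  # QUAL is "."
        header = tiny_store.header
        assert not record_passes(
            rec, make_filter(header, "basic", "QUAL", ">", 30), header)
        assert not record_passes(
            rec, make_filter(header, "basic", "QUAL", "<", 30), header)
        assert record_passes(
            rec, make_filter(header, "basic", "QUAL", "is_missing"), header)

    def test_trio_parents_het_via_sample_scope(self, tiny_store):
        header = tiny_store.header
        filt = make_filter(header, "format", "GT", "is_het",
                           sample_scope=("FATHER", "MOTHER"))
        assert record_passes(tiny_store.records[0], filt, header)  # 0/1, 0|1
        assert not record_passes(tiny_store.records[1], filt, header)  # 0/0 dad

    def test_flag_presence(self, tiny_store):
        header = tiny_store.header
        present = make_filter(header, "info", "DB", "present")
        absent = make_filter(header, "info", "DB", "absent")
        assert record_passes(tiny_store.records[0], present, header)
        assert not record_passes(tiny_store.records[1], present, header)
        assert record_passes(tiny_store.records[1], absent, header)

    def test_filter_column_matches_per_member(self, tiny_store):
        header = tiny_store.header
        q10 = make_filter(header, "basic", "FILTER", "==", "q10")
        assert record_passes(tiny_store.records[1], q10, header)  # q10;s50
        pass_only = make_filter(header, "basic", "FILTER", "==", "PASS")
        assert not record_passes(tiny_store.records[1], pass_only, header)

    def test_chrom_comparison_is_normalized(self, tiny_store):
        header = tiny_store.header
        filt = make_filter(header, "basic", "CHROM", "==", "chr1")
        assert record_passes(tiny_store.records[0], filt, header)  # "1"
        assert record_passes(tiny_store.records[2], filt, header)  # "chr1"

    def test_format_field_absent_from_record_fails(self, tiny_store):
        header = tiny_store.header
        filt = make_filter(header, "format", "DP", ">", 0,
                           sample_scope=("FATHER",))
        assert not record_passes(tiny_store.records[4], filt, header)


class TestValueDomain:
    def test_filter_members_split_on_semicolons(self, tiny_store):
        assert value_domain(tiny_store, "FILTER") == [
            "PASS", "lowDP", "q10", "s50"]

    def test_chrom_domain_normalized(self, tiny_store):
        assert value_domain(tiny_store, "CHROM") == ["1", "2", "X"]

    def test_numeric_field_rejected(self, tiny_store):
        with pytest.raises(WrongTypeError):
            value_domain(tiny_store, "AF")

    def test_empty_store_has_empty_domain(self, tiny_store):
        from vcfstack import VariantStore
        empty = VariantStore.load(tiny_store.header, [])
        assert value_domain(empty, "FILTER") == []


class TestStack:
    def test_pass_filter_survivor_count_on_planted_fixture(self, small_store):
        # generator plants exactly 700/1000 FILTER=PASS records
        filt = make_filter(small_store.header, "basic", "FILTER", "==", "PASS")
        _, count = push_filter(FilterStack(small_store), filt)
        assert count == 700

    def test_tautology_keeps_count(self, small_store):
        stack = FilterStack(small_store)
        stack = stack.push(make_filter(
            small_store.header, "info", "DP", ">=", 0))
        assert len(stack.survivor_ids) == len(small_store)

    def test_push_onto_empty_stays_empty(self, tiny_store):
        header = tiny_store.header
        stack = FilterStack(tiny_store)
        stack = stack.push(make_filter(header, "basic", "POS", ">", 10**9))
        assert stack.survivor_ids == frozenset()
        stack = stack.push(make_filter(header, "basic", "QUAL", ">=", 0))
        assert stack.survivor_ids == frozenset()

    def test_counts_non_increasing(self, small_store):
        header = small_store.header
        stack = FilterStack(small_store)
        for filt in [make_filter(header, "basic", "FILTER", "==", "PASS"),
                     make_filter(header, "info", "AF_1KG", "<", 0.2),
                     make_filter(header, "info", "FUNC", "in_set",
                                 {"missense", "nonsense"})]:
            stack = stack.push(filt)
        assert stack.counts == sorted(stack.counts, reverse=True)

    def test_pop_restores_previous_top(self, tiny_store):
        header = tiny_store.header
        a = make_filter(header, "basic", "FILTER", "==", "PASS")
        b = make_filter(header, "info", "AF", "<", 0.05)
        s0 = FilterStack(tiny_store)
        s1 = s0.push(a)
        s2 = s1.push(b)
        assert pop_filter(s2).survivor_ids == s1.survivor_ids
        assert pop_filter(s1).survivor_ids == s0.base_ids

    def test_pop_on_empty_raises(self, tiny_store):
        with pytest.raises(StackEmptyError):
            pop_filter(FilterStack(tiny_store))

    def test_survivors_in_genomic_order(self, tiny_store):
        recs = survivors(FilterStack(tiny_store))
        keys = [r.sort_key() for r in recs]
        assert keys == sorted(keys)
        assert len(recs) == len(tiny_store)

    def test_conjunction_equals_bruteforce_and_order_invariant(self, small_store):
        header = small_store.header
        filters = [
            make_filter(header, "basic", "FILTER", "==", "PASS"),
            make_filter(header, "info", "AF_EXAC", "<", 0.25),
            make_filter(header, "format", "GT", "has_alt",
                        sample_scope=("CHILD",)),
        ]
        brute = {i for i, rec in enumerate(small_store.records)
                 if all(record_passes(rec, f, header) for f in filters)}
        stack = FilterStack(small_store)
        for f in filters:
            stack = stack.push(f)
        assert stack.survivor_ids == brute
        rng = random.Random(5)
        for _ in range(4):
            order = filters[:]
            rng.shuffle(order)
            permuted = FilterStack(small_store)
            for f in order:
                permuted = permuted.push(f)
            assert permuted.survivor_ids == brute

    def test_format_scope_and_law(self, small_store):
        # one filter scoped {FATHER, MOTHER} == two filters scoped singly
        header = small_store.header
        joint = FilterStack(small_store).push(make_filter(
            header, "format", "GT", "is_het",
            sample_scope=("FATHER", "MOTHER")))
        split = FilterStack(small_store)
        for s in ("FATHER", "MOTHER"):
            split = split.push(make_filter(header, "format", "GT", "is_het",
                                           sample_scope=(s,)))
        assert joint.survivor_ids == split.survivor_ids

    def test_empty_scope_means_all_samples(self, small_store):
        header = small_store.header
        implicit = FilterStack(small_store).push(
            make_filter(header, "format", "DP", ">", 15))
        explicit = FilterStack(small_store).push(
            make_filter(header, "format", "DP", ">", 15,
                        sample_scope=tuple(header.sample_names)))
        assert implicit.survivor_ids == explicit.survivor_ids


class TestSerialization:
    @pytest.mark.parametrize("text", [
        "info:AF < 0.01",
        "basic:FILTER == PASS",
        "info:DB present",
        "format:GT is_het @FATHER,MOTHER",
        "info:CLASS in_set {missense,nonsense}",
        "info:AF all_< 0.5",
        "basic:QUAL is_missing",
    ])
    def test_parse_render_inverse_on_canonical_strings(self, text, tiny_store):
        filt = parse_filter_string(text, tiny_store.header)
        assert render_filter(filt) == text
        assert parse_filter_string(render_filter(filt),
                                   tiny_store.header) == filt

    def test_unparsable_string_quotes_grammar(self, tiny_store):
        with pytest.raises(FilterConstructionError, match="category:field"):
            parse_filter_string("AF lower than 1%", tiny_store.header)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_render_parse_round_trip_property(self, data):
        import vcfstack
        header = vcfstack.parse_header(
            [ln for ln in __import__("conftest").TINY_VCF.splitlines()
             if ln.startswith("#")])
        kind = data.draw(st.sampled_from(
            ["num", "str", "set", "flag", "gt", "missing"]))
        if kind == "num":
            field, cat = data.draw(st.sampled_from(
                [("AF", "info"), ("DP", "info"), ("QUAL", "basic"),
                 ("POS", "basic")]))
            op = data.draw(st.sampled_from([">", "<", ">=", "<=", "==", "!="]))
            operand = data.draw(st.one_of(
                st.integers(-1000, 1000),
                st.floats(allow_nan=False, allow_infinity=False,
                          min_value=-100, max_value=100)))
            elementwise = data.draw(st.sampled_from(["any", "all"]))
            filt = vcfstack.make_filter(header, cat, field, op, operand,
                                        elementwise=elementwise)
        elif kind == "str":
            op = data.draw(st.sampled_from(["==", "!="]))
            operand = data.draw(st.text(
                alphabet=st.characters(blacklist_categories=("Cs", "Cc")),
                min_size=1, max_size=12))
            filt = vcfstack.make_filter(header, "info", "CLASS", op, operand)
        elif kind == "set":
            members = data.draw(st.sets(st.text(
                alphabet="abcXYZ_,\"\\ {}", min_size=1, max_size=6),
                min_size=1, max_size=4))
            filt = vcfstack.make_filter(header, "info", "CLASS", "in_set",
                                        members)
        elif kind == "flag":
            op = data.draw(st.sampled_from(["present", "absent"]))
            filt = vcfstack.make_filter(header, "info", "DB", op)
        elif kind == "gt":
            op = data.draw(st.sampled_from(sorted(
                vcfstack.operators_for(header.format_defs["GT"]))))
            scope = data.draw(st.sampled_from(
                [(), ("FATHER",), ("FATHER", "CHILD")]))
            filt = vcfstack.make_filter(header, "format", "GT", op,
                                        sample_scope=scope)
        else:
            filt = vcfstack.make_filter(header, "info", "AF", "is_missing")
        text = render_filter(filt)
        assert parse_filter_string(text, header) == filt
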