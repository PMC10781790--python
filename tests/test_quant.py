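"""Unit tests for trimming, collapsing, annotation, and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evsmall.quant import (
    AnnotationRecord,
    CollapsedRead,
    build_count_matrix,
    classify_read,
    collapse_reads,
    compute_size_factors,
    count_mirna_match,
    filter_expressed,
    match_read,
    normalize_counts,
    trim_and_filter,
)
from evsmall.reference import ReferenceBundle, SncRnaReference

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestTrimAndFilter:
    def test_full_adapter_clipped(self):
        insert = "ACGTACGTACGTACGTACGT"  # 20 nt
        kept, log = trim_and_filter([insert + ADAPTER], ADAPTER)
        assert kept == [insert]
        assert log.kept == 1

    def test_short_insert_discarded(self):
        insert = "ACGTACGTACGTACGT"  # 16 nt, below the 17-nt floor
        kept, log = trim_and_filter([insert + ADAPTER], ADAPTER)
        assert kept == []
        # trimming would yield a 16-nt read only if the adapter could be
        # located at a position >= 17; with no match there, the read is
        # discarded (adapter-required mode)
        assert log.no_adapter + log.too_short == 1

    def test_no_adapter_discarded_with_reason(self):
        kept, log = trim_and_filter(["A" * 30], ADAPTER)
        assert kept == []
        assert log.no_adapter == 1

    def test_adapter_optional_mode_keeps_untrimmed(self):
        read = "ACGT" * 8
        kept, _ = trim_and_filter([read], ADAPTER, require_adapter=False)
        assert kept == [read]

    def test_partial_adapter_at_read_end(self):
        insert = "ACGTACGTACGTACGTAC"  # 18 nt
        read = insert + ADAPTER[:8]  # adapter truncated by the read end
        kept, _ = trim_and_filter([read], ADAPTER)
        assert kept == [insert]

    def test_no_trimming_when_adapter_none(self):
        kept, _ = trim_and_filter(["ACGT" * 5], None)
        assert kept == ["ACGT" * 5]

    def test_empty_input(self):
        kept, log = trim_and_filter([], ADAPTER)
        assert kept == [] and log.total == 0

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_and_filter(["ACGT" * 6], "")


class TestCollapseReads:
    @pytest.mark.parametrize(
        "reads,expected",
        [
            (["S1", "S1", "S2"], {"S1": 2, "S2": 1}),
            (["A", "B", "C"], {"A": 1, "B": 1, "C": 1}),
            ([], {}),
        ],
    )
    def test_definition(self, reads, expected):
        collapsed = {c.sequence: c.multiplicity for c in collapse_reads(reads)}
        assert collapsed == expected

    @given(st.lists(st.sampled_from(["AAAA", "CCCC", "GGGG", "TTTT"]), max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_multiplicity_conservation(self, reads):
        collapsed = collapse_reads(reads)
        assert sum(c.multiplicity for c in collapsed) == len(reads)
        assert len({c.sequence for c in collapsed}) == len(collapsed)


class TestCountMirnaMatch:
    """Boundary behavior of the 5'-anchored, templated-3' isomiR rule."""

    def test_exact_mature(self, mirna_ref):
        assert count_mirna_match(mirna_ref.sequence, mirna_ref)

    @pytest.mark.parametrize("trim,expected", [(1, True), (3, True), (4, False)])
    def test_3prime_deletions(self, mirna_ref, trim, expected):
        read = mirna_ref.sequence[:-trim]
        assert count_mirna_match(read, mirna_ref) is expected

    @pytest.mark.parametrize("ext,expected", [(1, True), (3, True), (4, False)])
    def test_templated_extensions(self, mirna_ref, ext, expected):
        pre = mirna_ref.precursor_sequence
        read = pre[mirna_ref.mature_start : mirna_ref.mature_end + ext]
        assert count_mirna_match(read, mirna_ref) is expected

    def test_non_templated_tail_rejected(self, mirna_ref):
        downstream = mirna_ref.precursor_sequence[
            mirna_ref.mature_end : mirna_ref.mature_end + 3
        ]
        tail = "".join("A" if c != "A" else "C" for c in downstream)
        assert not count_mirna_match(mirna_ref.sequence + tail, mirna_ref)

    @pytest.mark.parametrize("shift", [-1, 1])
    def test_5prime_shift_rejected(self, mirna_ref, shift):
        pre = mirna_ref.precursor_sequence
        start = mirna_ref.mature_start + shift
        read = pre[start : start + len(mirna_ref.sequence)]
        assert not count_mirna_match(read, mirna_ref)

    def test_internal_mismatch_rejected(self, mirna_ref):
        seq = list(mirna_ref.sequence)
        seq[10] = "A" if seq[10] != "A" else "C"
        assert not count_mirna_match("".join(seq), mirna_ref)

    def test_non_mirna_reference_rejected(self):
        ref = SncRnaReference("y", "ysRNA", "ACGT" * 8)
        with pytest.raises(ValueError):
            count_mirna_match("ACGT" * 5, ref)

    def test_mirna_requires_precursor_anchoring(self):
        with pytest.raises(ValueError, match="precursor"):
            SncRnaReference("m", "miRNA", "ACGTACGTACGTACGTAC")


class TestMatchAndClassify:
    def test_identity_substring_match(self, small_bundle):
        read = small_bundle["tsRNA-a"].sequence[:20]
        candidates = match_read(read, small_bundle)
        assert candidates == {"tsRNA": ["tsRNA-a"]}

    def test_no_match_empty(self, small_bundle):
        assert match_read("ACGT" * 5 + "AT", small_bundle) == {}

    def test_multi_reference_match_reports_both(self, small_bundle):
        read = "AAAATTTTGGGGCCCCAAAA"
        candidates = match_read(read, small_bundle)
        assert sorted(candidates["ysRNA"]) == ["ysRNA-a", "ysRNA-b"]
        # brute-force substring scan agrees
        brute = [
            r.feature_id
            for r in small_bundle.references.values()
            if r.rna_class == "ysRNA" and read in r.sequence
        ]
        assert sorted(brute) == sorted(candidates["ysRNA"])

    def test_priority_mirna_over_ysrna(self):
        read = CollapsedRead("ACGT" * 5, 1)
        rec = classify_read(read, {"miRNA": ["m1"], "ysRNA": ["y1"]})
        assert rec.assigned_class == "miRNA"
        assert rec.weights == {"m1": 1.0}

    def test_equal_split_within_class(self):
        read = CollapsedRead("ACGT" * 5, 1)
        rec = classify_read(read, {"ysRNA": ["y1", "y2"]})
        assert rec.assigned_class == "ysRNA"
        assert rec.weights == {"y1": 0.5, "y2": 0.5}

    def test_unmatched_is_others(self):
        rec = classify_read(CollapsedRead("ACGT" * 5, 3), {})
        assert rec.assigned_class == "others" and rec.weights == {}

    def test_priority_is_the_eight_class_order(self):
        from evsmall.reference import RNA_CLASSES

        assert RNA_CLASSES == (
            "miRNA", "ysRNA", "tsRNA", "rsRNA", "snRNA", "snoRNA", "lncRNA", "mRNA",
        )
        read = CollapsedRead("ACGT" * 5, 1)
        for hi_idx, hi in enumerate(RNA_CLASSES[:-1]):
            lo = RNA_CLASSES[hi_idx + 1]
            rec = classify_read(read, {lo: ["b"], hi: ["a"]})
            assert rec.assigned_class == hi


class TestBuildCountMatrix:
    def test_single_read_full_weight(self, small_bundle):
        rec = AnnotationRecord("X", 5, "miRNA", {"miR-toy": 1.0})
        cm = build_count_matrix({"s1": [rec]}, small_bundle)
        assert cm.raw.loc["miR-toy", "s1"] == 5

    def test_split_weights(self, small_bundle):
        rec = AnnotationRecord("X", 4, "ysRNA", {"ysRNA-a": 0.5, "ysRNA-b": 0.5})
        cm = build_count_matrix({"s1": [rec]}, small_bundle)
        assert cm.raw.loc["ysRNA-a", "s1"] == 2
        assert cm.raw.loc["ysRNA-b", "s1"] == 2

    def test_read_conservation(self, small_bundle):
        records = [
            AnnotationRecord("A", 5, "miRNA", {"miR-toy": 1.0}),
            AnnotationRecord("B", 4, "ysRNA", {"ysRNA-a": 0.5, "ysRNA-b": 0.5}),
            AnnotationRecord("C", 7, "others", {}),
        ]
        cm = build_count_matrix({"s1": records}, small_bundle)
        total = cm.raw["s1"].sum() + cm.others["s1"]
        assert total == pytest.approx(16)
        assert cm.class_composition["s1"].sum() == pytest.approx(1.0)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        raw = pd.DataFrame({"a": [2.0, 6.0], "b": [2.0, 6.0]}, index=["f1", "f2"])
        sf = compute_size_factors(raw)
        assert np.allclose(sf, 1.0)

    def test_hand_computed_two_by_two(self):
        raw = pd.DataFrame({"c1": [2.0, 6.0], "c2": [4.0, 12.0]}, index=["f1", "f2"])
        sf = compute_size_factors(raw)
        assert sf["c1"] == pytest.approx(0.7071, abs=1e-4)
        assert sf["c2"] == pytest.approx(1.4142, abs=1e-4)

    def test_scale_equivariance(self, rng):
        # size factors are defined up to a common constant, so the exact
        # equivariance statement is on factor ratios: scaling sample b by c
        # scales s_b/s_k by c and leaves s_k/s_l (k,l != b) unchanged
        raw = pd.DataFrame(
            rng.poisson(50, size=(30, 4)) + 1.0, columns=list("abcd")
        )
        sf = compute_size_factors(raw)
        scaled = raw.copy()
        scaled["b"] = scaled["b"] * 3.0
        sf2 = compute_size_factors(scaled)
        for col in "acd":
            assert sf2["b"] / sf2[col] == pytest.approx(3.0 * sf["b"] / sf[col])
        assert sf2["a"] / sf2["c"] == pytest.approx(sf["a"] / sf["c"])
        assert sf2["a"] / sf2["d"] == pytest.approx(sf["a"] / sf["d"])

    def test_feature_order_invariance(self, rng):
        raw = pd.DataFrame(rng.poisson(20, size=(25, 3)) + 1.0, columns=list("xyz"))
        shuffled = raw.sample(frac=1.0, random_state=3)
        assert np.allclose(compute_size_factors(raw), compute_size_factors(shuffled))

    def test_undefined_without_everywhere_positive_feature(self):
        raw = pd.DataFrame({"a": [0.0, 5.0], "b": [3.0, 0.0]})
        with pytest.raises(ValueError, match="size factors undefined"):
            compute_size_factors(raw)


class TestNormalize:
    def test_unit_factors_identity(self):
        raw = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        sf = pd.Series({"a": 1.0, "b": 1.0})
        assert normalize_counts(raw, sf).equals(raw)

    def test_division(self):
        raw = pd.DataFrame({"a": [10.0]}, index=["f"])
        assert normalize_counts(raw, pd.Series({"a": 2.0})).loc["f", "a"] == 5.0

    def test_renormalization_fixed_point(self, rng):
        raw = pd.DataFrame(rng.poisson(40, size=(40, 5)) + 1.0)
        normalized = normalize_counts(raw, compute_size_factors(raw))
        assert np.allclose(compute_size_factors(normalized), 1.0, atol=1e-9)

    def test_nonpositive_factor_rejected(self):
        raw = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            normalize_counts(raw, pd.Series({"a": 0.0}))


class TestFilterExpressed:
    def test_boundary_frequency_dropped(self):
        # nonzero in exactly 25% of samples -> dropped (strict >)
        norm = pd.DataFrame([[40.0, 0.0, 0.0, 0.0]], index=["f"])
        assert filter_expressed(norm).empty

    def test_low_mean_dropped(self):
        norm = pd.DataFrame([[0.9, 0.9, 0.9, 0.9]], index=["f"])
        assert filter_expressed(norm).empty

    def test_all_zero_matrix(self):
        norm = pd.DataFrame(np.zeros((3, 4)))
        assert filter_expressed(norm).empty

    def test_expressed_feature_kept(self):
        norm = pd.DataFrame([[5.0, 3.0, 0.0, 2.0]], index=["f"])
        assert list(filter_expressed(norm).index) == ["f"]
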