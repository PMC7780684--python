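"""Reference matching, junction validation/snapping, merging and filters."""

from __future__ import annotations

from itertools import combinations

import pytest

from isocatalog.detection import (
    CatalogFilterParams,
    apply_catalog_filters,
    match_reference,
    merge_and_count,
    quantify_tpm,
    tpm_per_mrna_copy,
    validate_junctions,
)
from isocatalog.models import (
    AlignedLongRead,
    IsoformCandidate,
    Junction,
    JunctionSupportTable,
    ReadClass,
    TranscriptModel,
)

EXONS = [(100, 200), (400, 500), (700, 800), (1000, 1100), (1300, 1400)]


@pytest.fixture()
def transcript():
    return TranscriptModel("G", "G.t1", "chr1", "+", EXONS)


def chain(intron_pairs, strand="+"):
    return [Junction("chr1", strand, s, e) for s, e in intron_pairs]


class TestMatchReference:
    def test_exact_match_is_type_a(self, transcript):
        flags, cls = match_reference(chain(transcript.introns), [transcript])
        assert cls is ReadClass.TYPE_A and all(flags)

    def test_prefix_with_end_inside_exon_is_type_b(self, transcript):
        sub = chain(transcript.introns[:3])
        _, cls = match_reference(sub, [transcript], read_span=(150, 1050))
        assert cls is ReadClass.TYPE_B

    def test_infix_truncation_is_type_b(self, transcript):
        sub = chain(transcript.introns[1:3])
        _, cls = match_reference(sub, [transcript], read_span=(450, 1050))
        assert cls is ReadClass.TYPE_B

    def test_truncated_end_outside_exon_is_candidate(self, transcript):
        sub = chain(transcript.introns[:3])
        # right end in the downstream intron, 30 bp past the exon
        _, cls = match_reference(sub, [transcript], read_span=(150, 1130))
        assert cls is ReadClass.ISOFORM_CANDIDATE

    @pytest.mark.parametrize("offset,matched", [(20, True), (21, False)])
    def test_margin_boundary_per_junction(self, transcript, offset, matched):
        introns = [(s + offset, e) for s, e in transcript.introns]
        flags, cls = match_reference(chain(introns), [transcript], read_span=(100, 1400))
        assert all(flags) == matched
        assert (cls is ReadClass.TYPE_A) == matched

    def test_mono_exonic_excluded_as_type_b(self, transcript):
        _, cls = match_reference([], [transcript], read_span=(120, 180))
        assert cls is ReadClass.TYPE_B

    def test_agrees_with_brute_force_on_all_junction_subsets(self, transcript):
        """Oracle: enumerate every subset of a 5-exon gene's junctions and
        classify by first principles."""
        introns = transcript.introns
        full = set(range(len(introns)))
        for r in range(len(introns) + 1):
            for subset in combinations(range(len(introns)), r):
                sub = [introns[i] for i in subset]
                read_chain = chain(sub)
                # read ends inside the exons flanking the subset's outermost
                # junctions (a spliced read cannot extend past the introns
                # it does not splice)
                lo = transcript.exons[min(subset, default=0)]
                hi = transcript.exons[max(subset, default=-2) + 1]
                span = (lo[0] + 5, hi[1] - 5)
                _, got = match_reference(read_chain, [transcript], read_span=span)
                if not subset:
                    expected = ReadClass.TYPE_B
                elif set(subset) == full:
                    expected = ReadClass.TYPE_A
                elif subset == tuple(range(subset[0], subset[0] + len(subset))):
                    expected = ReadClass.TYPE_B  # contiguous run, ends exonic
                else:
                    expected = ReadClass.ISOFORM_CANDIDATE
                assert got is expected, (subset, got, expected)


class TestValidateJunctions:
    def _support(self, pairs_counts):
        t = JunctionSupportTable()
        for (s, e), c in pairs_counts.items():
            t.add(Junction("chr1", ".", s, e), c)
        return t

    def test_novel_junction_support_5_kept_4_dropped(self, transcript):
        novel = (200, 1000)  # skips exons 2-3
        for count, ok in [(5, True), (4, False)]:
            support = self._support({novel: count})
            out = validate_junctions(chain([novel]), [transcript], support)
            assert (out is not None) is ok

    def test_annotated_junction_needs_no_support(self, transcript):
        out = validate_junctions(chain(transcript.introns), [transcript], self._support({}))
        assert out is not None

    def test_within_margin_snaps_to_short_read_coordinates(self, transcript):
        support = self._support({(200, 1000): 9})
        out = validate_junctions(chain([(203, 997)]), [transcript], support)
        assert [(j.start, j.end) for j in out] == [(200, 1000)]

    def test_off_annotated_junction_snaps_to_annotation(self, transcript):
        out = validate_junctions(
            chain([(transcript.introns[0][0] + 3, transcript.introns[0][1] - 2)]),
            [transcript],
            self._support({}),
        )
        assert [(j.start, j.end) for j in out] == [transcript.introns[0]]

    def test_snapping_idempotent(self, transcript):
        support = self._support({(200, 1000): 9})
        once = validate_junctions(chain([(203, 997)]), [transcript], support)
        twice = validate_junctions(list(once), [transcript], support)
        assert twice == once


class TestMergeAndCount:
    def _read(self, rid, blocks):
        return AlignedLongRead(rid, "chr1", "+", blocks,
                               n_match=sum(e - s for s, e in blocks),
                               junction_insertions=[0] * (len(blocks) - 1))

    def test_identical_chains_merge_with_count(self):
        j = (Junction("chr1", "+", 200, 400),)
        reads = [(self._read(f"r{i}", [(100, 200), (400, 500)]), j) for i in range(3)]
        (cand,) = merge_and_count("G", reads)
        assert cand.minion_read_count == 3
        assert cand.exons == [(100, 200), (400, 500)]

    def test_distinct_chains_stay_separate_and_counts_sum(self):
        j1 = (Junction("chr1", "+", 200, 400),)
        j2 = (Junction("chr1", "+", 200, 420),)
        reads = [
            (self._read("a", [(100, 200), (400, 500)]), j1),
            (self._read("b", [(100, 200), (420, 500)]), j2),
            (self._read("c", [(100, 200), (400, 500)]), j1),
        ]
        cands = merge_and_count("G", reads)
        assert len(cands) == 2
        assert sum(c.minion_read_count for c in cands) == 3

    def test_empty_input(self):
        assert merge_and_count("G", []) == []

    def test_terminal_ends_are_modal(self):
        j = (Junction("chr1", "+", 200, 400),)
        reads = [
            (self._read("a", [(100, 200), (400, 500)]), j),
            (self._read("b", [(100, 200), (400, 500)]), j),
            (self._read("c", [(130, 200), (400, 480)]), j),
        ]
        (cand,) = merge_and_count("G", reads)
        assert cand.exons == [(100, 200), (400, 500)]


class TestCatalogFilters:
    def _cand(self, count, tpm):
        return IsoformCandidate(
            "i", "G", "chr1", "+", (), [(0, 100)],
            supporting_read_ids=[f"r{k}" for k in range(count)], tpm=tpm,
        )

    def test_coverage_rule_total_over_100k(self):
        # total 1,000,000 -> threshold 10 reads
        dropped = apply_catalog_filters([self._cand(9, 50)], 1_000_000, {"G": 1000})
        kept = apply_catalog_filters([self._cand(10, 50)], 1_000_000, {"G": 90})
        assert dropped == [] and len(kept) == 1

    def test_gene_fraction_strictly_greater_than_10_percent(self):
        ten = apply_catalog_filters([self._cand(10, 50)], 100, {"G": 100})
        eleven = apply_catalog_filters([self._cand(11, 50)], 100, {"G": 100})
        assert ten == [] and len(eleven) == 1

    def test_tpm_threshold_at_least_10(self):
        low = apply_catalog_filters([self._cand(50, 9.99)], 100, {"G": 100})
        edge = apply_catalog_filters([self._cand(50, 10.0)], 100, {"G": 100})
        assert low == [] and len(edge) == 1

    def test_monotone_in_min_tpm(self):
        cands = [self._cand(50, t) for t in (5.0, 15.0, 30.0)]
        loose = apply_catalog_filters(cands, 100, {"G": 100}, CatalogFilterParams(min_tpm=10))
        tight = apply_catalog_filters(cands, 100, {"G": 100}, CatalogFilterParams(min_tpm=20))
        assert {c.tpm for c in tight} <= {c.tpm for c in loose}


class TestQuantifyTpm:
    def test_symmetric_unique_counts(self):
        tpm = quantify_tpm(
            [(frozenset({"a"}), 100), (frozenset({"b"}), 100)],
            {"a": 1000.0, "b": 1000.0},
        )
        assert tpm["a"] == pytest.approx(500_000) and tpm["b"] == pytest.approx(500_000)

    def test_single_transcript_gets_all(self):
        tpm = quantify_tpm([(frozenset({"a"}), 7)], {"a": 500.0})
        assert tpm["a"] == pytest.approx(1e6)

    def test_shared_class_resolved_by_unique_evidence(self):
        # 90 unique to a, 10 unique to b, 100 shared: EM should assign the
        # shared mass ~9:1, matching the closed-form 900k/100k split
        tpm = quantify_tpm(
            [
                (frozenset({"a"}), 90),
                (frozenset({"b"}), 10),
                (frozenset({"a", "b"}), 100),
            ],
            {"a": 1000.0, "b": 1000.0},
        )
        assert tpm["a"] == pytest.approx(900_000, rel=1e-3)

    def test_sums_to_one_million(self):
        tpm = quantify_tpm(
            [(frozenset({"a"}), 3), (frozenset({"b", "c"}), 11)],
            {"a": 900.0, "b": 400.0, "c": 1600.0},
        )
        assert sum(tpm.values()) == pytest.approx(1e6, rel=1e-6)

    def test_all_zero_counts_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            tpm = quantify_tpm([(frozenset({"a"}), 0)], {"a": 100.0})
        assert tpm == {"a": 0.0}


def test_one_mrna_copy_is_three_tpm_at_integer_precision():
    value = tpm_per_mrna_copy(360_000)
    assert value == pytest.approx(2.7778, abs=1e-3)
    assert round(value) == 3
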