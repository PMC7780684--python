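"""Isoform-specific counting, panels, tumor-specific selection, statistics."""

from __future__ import annotations

from itertools import combinations
from math import comb

import pytest

from isocatalog.models import GenomeRef, IsoformCandidate, Junction, TranscriptModel
from isocatalog.requant import (
    build_normal_junction_set,
    build_panel_of_normals,
    count_isoforms_in_sample,
    extract_specific_features,
    extract_windows,
    junction_feature,
    nmd_mutation_association,
    rpm,
    scan_motifs,
    select_tumor_specific,
    subsample_detection,
)


def _gene():
    return TranscriptModel("G", "G.t1", "chr1", "+",
                           [(100, 200), (400, 500), (700, 800), (1000, 1100)])


def _iso(iso_id, exons, gene_id="G"):
    juncs = tuple(Junction("chr1", "+", a[1], b[0]) for a, b in zip(exons, exons[1:]))
    return IsoformCandidate(iso_id, gene_id, "chr1", "+", juncs, list(exons), ["r"])


class TestSpecificFeatures:
    def test_single_novel_junction_is_the_feature(self):
        g = _gene()
        iso = _iso("i1", [(100, 200), (700, 800), (1000, 1100)])  # skips exon 2
        feats = extract_specific_features([iso], [g])
        assert feats["i1"] == {junction_feature(Junction("chr1", "+", 200, 700))}

    def test_sibling_shared_feature_excluded(self):
        g = _gene()
        skip = [(100, 200), (700, 800), (1000, 1100)]
        iso1 = _iso("i1", skip)
        iso2 = _iso("i2", [(120, 200), (700, 800), (1000, 1100)])  # same junctions
        feats = extract_specific_features([iso1, iso2], [g])
        assert feats["i1"] == set() and feats["i2"] == set()

    def test_retained_intron_exon_is_a_feature(self):
        g = _gene()
        iso = _iso("i1", [(100, 200), (400, 800), (1000, 1100)])  # retains intron 2
        feats = extract_specific_features([iso], [g])
        assert any(f.endswith(":E") for f in feats["i1"])


class TestCounting:
    @pytest.mark.parametrize("reads,detected", [(20, True), (19, False)])
    def test_min_reads_boundary(self, reads, detected):
        feats = {"i1": {"f1"}}
        out = count_isoforms_in_sample({"f1": reads}, feats)
        assert ("i1" in out) is detected

    def test_count_is_max_over_features(self):
        feats = {"i1": {"f1", "f2"}}
        out = count_isoforms_in_sample({"f1": 25, "f2": 70}, feats)
        assert out["i1"] == 70

    def test_empty_counts_empty_result(self):
        assert count_isoforms_in_sample({}, {"i1": {"f1"}}) == {}

    def test_rpm_definition_and_total(self):
        table = rpm({"a": 250_000, "b": 750_000}, 1_000_000)
        assert table == {"a": 250_000.0, "b": 750_000.0}
        assert sum(table.values()) == pytest.approx(1e6)


class TestPanelOfNormals:
    def test_max_rpm(self):
        panel = build_panel_of_normals([{"i": float(v)} for v in (1, 2, 3, 4, 5)])
        assert panel["i"] == 5.0

    def test_fewer_than_five_normals_refused(self):
        with pytest.raises(ValueError, match="at least 5"):
            build_panel_of_normals([{}] * 4)

    def test_absent_isoform_defaults_to_zero(self):
        panel = build_panel_of_normals([{}] * 5)
        assert panel.get("unseen", 0.0) == 0.0


class TestNormalJunctionSet:
    def _j(self):
        return Junction("chr1", "+", 200, 400)

    @pytest.mark.parametrize("n_expressing,is_normal", [(6, True), (5, False)])
    def test_strictly_more_than_half(self, n_expressing, is_normal):
        j = self._j()
        samples = [{j: 25} if i < n_expressing else {} for i in range(10)]
        assert (j in build_normal_junction_set(samples)) is is_normal

    def test_twenty_read_floor_per_sample(self):
        j = self._j()
        samples = [{j: 19} for _ in range(10)]
        assert build_normal_junction_set(samples) == set()
        samples = [{j: 20} for _ in range(10)]
        assert build_normal_junction_set(samples) == {j}

    def test_empty_cohort(self):
        assert build_normal_junction_set([]) == set()


class TestTumorSpecific:
    @pytest.mark.parametrize("tumor,kept", [(10.0, True), (9.9, False)])
    def test_twofold_boundary_against_panel(self, tumor, kept):
        sel = select_tumor_specific(
            {"i": tumor}, {"i": {"fX"}}, mode="tcga", panel={"i": 5.0},
            normal_junctions=set(),
        )
        assert (sel == ["i"]) is kept

    def test_panel_zero_any_positive_passes(self):
        sel = select_tumor_specific(
            {"i": 0.5}, {"i": {"fX"}}, mode="tcga", panel={}, normal_junctions=set()
        )
        assert sel == ["i"]

    def test_normal_junction_excludes(self):
        j = Junction("chr1", "+", 200, 700)
        sel = select_tumor_specific(
            {"i": 100.0}, {"i": {junction_feature(j)}}, mode="tcga",
            panel={}, normal_junctions={j},
        )
        assert sel == []

    @pytest.mark.parametrize(
        "tumor,normal,kept",
        [(10.0, 0.0, True), (9.9, 0.0, False), (20.0, 10.0, True), (19.9, 10.0, False)],
    )
    def test_clinical_mode_tpm_and_fold(self, tumor, normal, kept):
        sel = select_tumor_specific(
            {"i": tumor}, {"i": set()}, mode="clinical", normal_values={"i": normal}
        )
        assert (sel == ["i"]) is kept

    def test_monotone_raising_panel_never_adds(self):
        tumor = {"a": 30.0, "b": 8.0, "c": 50.0}
        feats = {k: {f"f{k}"} for k in tumor}
        low = select_tumor_specific(tumor, feats, panel={"a": 10.0, "b": 5.0}, normal_junctions=set())
        high = select_tumor_specific(tumor, feats, panel={"a": 20.0, "b": 5.0}, normal_junctions=set())
        assert set(high) <= set(low)


def rank_sum_oracle(a, b):
    """Exact one-tailed permutation p-value for group ``a`` being higher."""
    pooled = sorted(a + b)
    ranks = {}
    for v in set(pooled):
        idxs = [i + 1 for i, x in enumerate(pooled) if x == v]
        ranks[v] = sum(idxs) / len(idxs)
    obs = sum(ranks[v] for v in a)
    n = len(a)
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n):
        s = sum(ranks[pooled[i]] for i in combo)
        if s >= obs - 1e-9:
            count += 1
        total += 1
    assert total == comb(len(pooled), n)
    return count / total


class TestRankSum:
    def test_separated_groups_exact_value(self):
        # mutated {10,11,12} vs wild {1,2,3}: 1 of C(6,3)=20 assignments
        assert nmd_mutation_association([10, 11, 12], [1, 2, 3]) == pytest.approx(1 / 20)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([10, 11, 12], [1, 2, 3]),
            ([5, 9, 2, 7], [1, 3, 4]),
            ([2, 4, 6, 8, 10], [1, 3, 5, 7]),
        ],
    )
    def test_matches_permutation_oracle_small_n(self, a, b):
        assert nmd_mutation_association(a, b) == pytest.approx(rank_sum_oracle(a, b), rel=1e-9)

    def test_identical_groups_not_significant(self):
        assert nmd_mutation_association([5, 6, 7], [5, 6, 7]) >= 0.5

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            nmd_mutation_association([], [1, 2])


class TestMotifs:
    def test_dna_sequence_matches_rna_motif(self):
        hits, n = scan_motifs(["AAACCTGGGGAAA"])
        assert n == 1 and hits == [(0, "CCUGGGG", 3)]

    def test_no_hits(self):
        assert scan_motifs(["AAAA"]) == ([], 0)

    def test_motifs_at_both_ends_counted_twice(self):
        hits, n = scan_motifs(["CCTGGGG" + "TTT" + "CCTGAGA"])
        assert n == 1 and len(hits) == 2

    def test_overlapping_occurrences_reported(self):
        hits, _ = scan_motifs(["CCTGGGGGG"])  # CCUGGGG at 0 only once, shifted Gs
        assert (0, "CCUGGGG", 0) in hits


class TestWindows:
    def test_plus_strand_arithmetic(self):
        genome = GenomeRef({"c": "A" * 300})
        (seq, clipped), = extract_windows(genome, [("c", 100, "+")], half_width=10)
        assert len(seq) == 21 and not clipped

    def test_clipping_flagged(self):
        genome = GenomeRef({"c": "A" * 300})
        (seq, clipped), = extract_windows(genome, [("c", 5, "+")], half_width=50)
        assert clipped and len(seq) == 56

    def test_minus_strand_reverse_complement(self):
        genome = GenomeRef({"c": "ACGTACGTACGT"})
        (plus, _), = extract_windows(genome, [("c", 5, "+")], half_width=2)
        (minus, _), = extract_windows(genome, [("c", 5, "-")], half_width=2)
        import re

        comp = str.maketrans("ACGT", "TGCA")
        assert minus == plus.translate(comp)[::-1]


@pytest.fixture(scope="module")
def small_run(dataset):
    """A few genes only, to keep replicate re-detection cheap."""
    from isocatalog.filtering import FilterParams, filter_and_assign
    from isocatalog.models import group_by_gene

    by_gene, _ = filter_and_assign(
        dataset.reads,
        dataset.reference.models,
        FilterParams(pseudogene_intervals=dataset.reference.pseudogene_intervals),
    )
    genes = sorted(by_gene)[:4]
    sub = {g: by_gene[g] for g in genes}
    return sub, group_by_gene(dataset.reference.models), dataset


class TestSubsampling:
    def test_full_fraction_probability_one(self, small_run):
        sub, ann, ds = small_run
        res = subsample_detection(sub, ann, ds.sj_table, ds.tpm,
                                  fractions=(1.0,), n_reps=3, seed=5)
        assert res.probabilities, "baseline catalog must be non-empty"
        assert all(p[1.0] == 1.0 for p in res.probabilities.values())

    def test_probability_decreases_with_fraction(self, small_run):
        sub, ann, ds = small_run
        res = subsample_detection(sub, ann, ds.sj_table, ds.tpm,
                                  fractions=(0.5, 0.05), n_reps=10, seed=5)
        for p in res.probabilities.values():
            assert p[0.05] <= p[0.5]

    def test_same_seed_identical(self, small_run):
        sub, ann, ds = small_run
        kw = dict(fractions=(0.2,), n_reps=8)
        r1 = subsample_detection(sub, ann, ds.sj_table, ds.tpm, seed=9, **kw)
        r2 = subsample_detection(sub, ann, ds.sj_table, ds.tpm, seed=9, **kw)
        assert r1.probabilities == r2.probabilities
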