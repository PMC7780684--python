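"""Somatic filtering, variant application and 9-mer enumeration."""

from __future__ import annotations

import pytest

from isocatalog.models import VariantRecord
from isocatalog.neoantigen import (
    CLASS_FRAMESHIFT,
    CLASS_IN_FRAME,
    CLASS_MISSENSE,
    CLASS_NONSENSE,
    MockBindingScorer,
    apply_variant,
    build_reference_peptidome,
    enumerate_novel_peptides,
    filter_somatic_variants,
    isoform_novel_peptides,
    score_and_call,
    tabulate_by_source,
)
from isocatalog.orf import _translate_from


def var(depth=10, dbsnp=False, cosmic=0):
    return VariantRecord("chr1", 100, "A", "T", allele_depth=depth,
                         in_dbsnp=dbsnp, cosmic_sample_count=cosmic)


class TestSomaticFilter:
    @pytest.mark.parametrize("depth,kept", [(4, False), (5, True)])
    def test_allele_depth_boundary(self, depth, kept):
        assert bool(filter_somatic_variants([var(depth=depth)])) is kept

    @pytest.mark.parametrize("cosmic,kept", [(4, False), (5, True)])
    def test_dbsnp_needs_cosmic_recurrence(self, cosmic, kept):
        assert bool(filter_somatic_variants([var(dbsnp=True, cosmic=cosmic)])) is kept

    def test_non_dbsnp_kept(self):
        assert len(filter_somatic_variants([var()])) == 1

    def test_unknown_depth_dropped(self):
        assert filter_somatic_variants([var(depth=None)]) == []


def make_mrna(codons, utr3="GGGCCCGGGCCC"):
    """mRNA with CDS 'ATG' + codons + 'TAA' and a short 3' UTR."""
    return "ATG" + "".join(codons) + "TAA" + utr3


class TestApplyVariant:
    def test_substitution_to_stop_is_nonsense(self):
        mrna = make_mrna(["AAA", "TCA", "GGA"])  # M K S G
        # TCA -> TGA at position 3+3+1
        mut = apply_variant(mrna, 0, 7, "C", "G")
        assert mut.variant_class == CLASS_NONSENSE
        assert mut.protein == "MK"

    def test_missense_single_residue_span(self):
        mrna = make_mrna(["AAA", "TCA", "GGA"])
        mut = apply_variant(mrna, 0, 3, "A", "C")  # AAA (K) -> CAA (Q)
        assert mut.variant_class == CLASS_MISSENSE
        assert mut.altered_span == (1, 2)

    def test_silent_substitution_is_noop(self):
        mrna = make_mrna(["AAA", "TCA"])
        assert apply_variant(mrna, 0, 5, "A", "G") is None  # AAA -> AAG, both K

    def test_in_frame_insertion(self):
        mrna = make_mrna(["AAA", "TCA", "GGA"])
        mut = apply_variant(mrna, 0, 5, "A", "AGCT")  # +GCT after codon 1
        assert mut.variant_class == CLASS_IN_FRAME
        assert len(mut.protein) == len("MKSG") + 1

    def test_frameshift_matches_brute_force_retranslation(self):
        mrna = make_mrna(["AAA", "TCA", "GGA", "CCA"], utr3="GGGTTTAAACCCTAAGG")
        mut = apply_variant(mrna, 0, 5, "AT", "A")  # delete one base
        assert mut.variant_class == CLASS_FRAMESHIFT
        mutated = mrna[:6] + mrna[7:]
        expected, _ = _translate_from(mutated, 0)
        assert mut.protein == expected
        # novel tail: everything from the first changed residue onward
        lo, hi = mut.altered_span
        assert hi == len(mut.protein)

    def test_variant_outside_cds_is_noop(self):
        mrna = "GGGG" + make_mrna(["AAA"])
        assert apply_variant(mrna, 4, 0, "G", "C") is None

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_variant(make_mrna(["AAA"]), 0, 3, "C", "T")


class TestPeptidome:
    def test_protein_length_9_yields_one(self):
        assert len(build_reference_peptidome({"p": "ACDEFGHIK"})) == 1

    def test_protein_length_8_yields_none(self):
        assert build_reference_peptidome({"p": "ACDEFGHI"}) == set()

    def test_shared_9mer_counted_once(self):
        pep = build_reference_peptidome({"a": "ACDEFGHIK", "b": "ACDEFGHIK"})
        assert pep == {"ACDEFGHIK"}

    def test_count_identity_l_minus_8(self):
        prot = "ACDEFGHIKLMNPQRSTVWY"  # 20 distinct residues
        assert len(build_reference_peptidome({"p": prot})) == len(prot) - 8


class TestEnumerate:
    def test_missense_window_count_at_most_nine(self):
        prot = "A" * 8 + "W" + "C" * 8  # single changed residue at index 8
        peps = enumerate_novel_peptides(prot, (8, 9), set(), "s", CLASS_MISSENSE)
        assert len(peps) == 9
        assert all(p.peptide.count("W") >= 1 for p in peps)

    def test_frameshift_tail_matches_window_oracle(self):
        head = "ACDEFGHIKL"
        tail = "MNPQRSTVWYACDEFGHIKW"  # 20-residue novel tail
        prot = head + tail
        span = (len(head), len(prot))
        peps = enumerate_novel_peptides(prot, span, set(), "s", CLASS_FRAMESHIFT)
        oracle = {
            prot[i : i + 9]
            for i in range(len(prot) - 8)
            if i + 9 > span[0]  # overlaps the altered span
        }
        assert {p.peptide for p in peps} == oracle
        assert len(oracle) == (len(tail) + 8) - 8

    def test_reference_9mers_excluded(self):
        prot = "A" * 8 + "W" + "C" * 8
        ref = {prot[0:9]}
        peps = enumerate_novel_peptides(prot, (8, 9), ref, "s", CLASS_MISSENSE)
        assert prot[0:9] not in {p.peptide for p in peps}
        assert len(peps) == 8

    def test_unmutated_reference_protein_yields_nothing(self):
        prot = "ACDEFGHIKLMNPQRSTVWY"
        assert isoform_novel_peptides(prot, prot, set(), "s") == []

    def test_every_emitted_peptide_is_novel_9mer(self, dataset, pipeline_result):
        from isocatalog.models import group_by_gene
        from isocatalog.neoantigen import call_isoform_peptides

        peptidome = build_reference_peptidome(dataset.reference.proteome)
        peps = call_isoform_peptides(
            pipeline_result.catalog,
            group_by_gene(dataset.reference.models),
            dataset.reference.genome,
            peptidome,
        )
        assert peps, "planted isoforms must produce novel peptides"
        assert all(len(p.peptide) == 9 for p in peps)
        assert all(p.peptide not in peptidome for p in peps)

    def test_frameshift_outproduces_missense_with_long_tail(self):
        """One frameshift with a >9-residue novel tail yields more novel
        peptides than one missense in the same protein."""
        mrna = make_mrna(
            ["GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAG", "CTG"],
            utr3="ATGAATCCTCAAAGATCAACTGTTTGGTATTAA",
        )
        fs = apply_variant(mrna, 0, 10, "AT", "A")
        ms = apply_variant(mrna, 0, 10, "A", "C")
        n_fs = len(enumerate_novel_peptides(fs.protein, fs.altered_span, set(), "s", fs.variant_class))
        n_ms = len(enumerate_novel_peptides(ms.protein, ms.altered_span, set(), "s", ms.variant_class))
        assert fs.variant_class == CLASS_FRAMESHIFT and ms.variant_class == CLASS_MISSENSE
        assert n_fs >= n_ms


class TestScoring:
    def test_strong_binder_boundary(self):
        class Fixed:
            def __init__(self, r):
                self.r = r

            def score(self, p, a):
                return self.r

        from isocatalog.models import PeptideCandidate

        pep = [PeptideCandidate("ACDEFGHIK", "s", "isoform")]
        strong = score_and_call(pep, ["A*01:01"], Fixed(0.49))[0]
        weak = score_and_call(pep, ["A*01:01"], Fixed(0.50))[0]
        assert strong.strong_binder is True and weak.strong_binder is False

    def test_mock_scorer_deterministic(self):
        s = MockBindingScorer()
        assert s.score("ACDEFGHIK", "HLA-A24:02") == s.score("ACDEFGHIK", "HLA-A24:02")
        assert 0.0 <= s.score("ACDEFGHIK", "HLA-A24:02") < 2.0

    def test_scorer_failure_keeps_candidate(self):
        class Broken:
            def score(self, p, a):
                raise RuntimeError("predictor offline")

        from isocatalog.models import PeptideCandidate

        out = score_and_call(
            [PeptideCandidate("ACDEFGHIK", "s", "isoform")], ["X"], Broken()
        )
        assert len(out) == 1 and out[0].percent_rank is None

    def test_tabulate_counts_and_best_rank(self):
        from isocatalog.models import PeptideCandidate

        cands = [
            PeptideCandidate("ACDEFGHIK", "s1", "isoform", "A", 0.4),
            PeptideCandidate("CCDEFGHIK", "s1", "isoform", "A", 0.1),
            PeptideCandidate("DCDEFGHIK", "s2", "frameshift", "A", 1.5),
        ]
        tab = tabulate_by_source(cands)
        assert tab["counts_by_class"] == {"isoform": 2, "frameshift": 1}
        assert tab["best_rank_by_source"] == {"s1": 0.1, "s2": 1.5}

    def test_empty_input_empty_tables(self):
        tab = tabulate_by_source([])
        assert tab == {"counts_by_class": {}, "best_rank_by_source": {}}
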