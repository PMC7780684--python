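"""Candidate neoantigen enumeration.

Somatic variants are applied onto transcript CDSs, every 9-mer peptide
overlapping an altered protein region is enumerated, 9-mers present in the
reference proteome are subtracted, and the survivors are scored against
HLA class I alleles through a pluggable binding predictor (%rank < 0.5 =
strong binder). Aberrant isoforms contribute peptides through the same
path: their proteins are diffed against the gene's reference protein and
windows overlapping the divergent region are enumerated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Optional, Protocol, Sequence

from Bio import SeqIO

from .models import PeptideCandidate, VariantRecord
from .orf import _translate_from

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

CLASS_MISSENSE = "missense"
CLASS_NONSENSE = "nonsense"
CLASS_IN_FRAME = "in_frame"
CLASS_FRAMESHIFT = "frameshift"
CLASS_ISOFORM = "isoform"


# ---------------------------------------------------------------------------
# Somatic variant filter
# ---------------------------------------------------------------------------

def filter_somatic_variants(
    variants: Sequence[VariantRecord],
    min_allele_depth: int = 5,
    dbsnp_cosmic_rule: bool = True,
    min_cosmic_samples: int = 5,
) -> list[VariantRecord]:
    """Drop low-depth and germline-looking variants.

    Variants with allele depth < 5 (or unknown depth) are removed; dbSNP
    records are removed unless seen in ≥5 COSMIC samples.
    """
    out = []
    for v in variants:
        if v.allele_depth is None or v.allele_depth < min_allele_depth:
            continue
        if dbsnp_cosmic_rule and v.in_dbsnp and v.cosmic_sample_count < min_cosmic_samples:
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# Variant application
# ---------------------------------------------------------------------------

@dataclass
class MutatedCds:
    """A CDS after variant application.

    ``altered_span`` is in protein coordinates of the mutated protein:
    first changed residue to the end of the novel sequence. For a pure
    truncation (nonsense) the span marks the truncation point just past
    the protein end, so no peptide window can overlap it — a truncation
    exposes no novel residues.
    """

    protein: str
    variant_class: str
    altered_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.altered_span[1] <= self.altered_span[0]:
            raise ValueError("altered span must be non-empty")


def _diff_span(ref_prot: str, alt_prot: str) -> Optional[tuple[int, int]]:
    """Altered region of ``alt_prot`` relative to ``ref_prot``.

    Longest common prefix/suffix bracketing; silent (identical) → None.
    """
    if ref_prot == alt_prot:
        return None
    p = 0
    while p < min(len(ref_prot), len(alt_prot)) and ref_prot[p] == alt_prot[p]:
        p += 1
    s = 0
    while (
        s < min(len(ref_prot), len(alt_prot)) - p
        and ref_prot[len(ref_prot) - 1 - s] == alt_prot[len(alt_prot) - 1 - s]
    ):
        s += 1
    lo, hi = p, len(alt_prot) - s
    if hi <= lo:
        # pure deletion/truncation: mark the boundary position
        return (lo, lo + 1)
    return (lo, hi)


def apply_variant(
    mrna: str,
    cds_start: int,
    pos: int,
    ref: str,
    alt: str,
) -> Optional[MutatedCds]:
    """Apply one variant (transcript coordinates) and classify its effect.

    ``pos`` is the variant's position on the mRNA. Substitutions become
    missense or nonsense by their codon effect; indels are in-frame when
    the length change is divisible by 3, else frameshift with translation
    continuing in the new frame (through the 3' UTR if needed) to the
    first stop. Variants upstream of the CDS, silent substitutions and
    variants landing at/after the stop are no-ops returning None.
    """
    if pos < cds_start or pos + len(ref) > len(mrna):
        return None
    if mrna[pos : pos + len(ref)] != ref:
        raise ValueError(f"reference allele mismatch at transcript position {pos}")
    ref_prot, _ = _translate_from(mrna, cds_start)
    if pos >= cds_start + 3 * (len(ref_prot) + 1):
        return None  # downstream of the stop codon
    mutated = mrna[:pos] + alt + mrna[pos + len(ref) :]
    alt_prot, _ = _translate_from(mutated, cds_start)

    shift = len(alt) - len(ref)
    if shift == 0 and len(ref) == 1:
        if alt_prot == ref_prot:
            return None  # silent
        cls = CLASS_NONSENSE if len(alt_prot) < len(ref_prot) else CLASS_MISSENSE
    elif shift % 3 == 0:
        cls = CLASS_IN_FRAME
    else:
        cls = CLASS_FRAMESHIFT
    span = _diff_span(ref_prot, alt_prot)
    if span is None:
        return None
    return MutatedCds(protein=alt_prot, variant_class=cls, altered_span=span)


# ---------------------------------------------------------------------------
# Peptide enumeration
# ---------------------------------------------------------------------------

def build_reference_peptidome(proteome, k: int = 9) -> set[str]:
    """All length-``k`` substrings over the reference proteins.

    ``proteome`` is a FASTA path or a mapping name → protein string.
    """
    if isinstance(proteome, (str, bytes)) or hasattr(proteome, "__fspath__"):
        proteins: Iterable[str] = (str(rec.seq) for rec in SeqIO.parse(str(proteome), "fasta"))
    else:
        proteins = proteome.values()
    out: set[str] = set()
    for prot in proteins:
        prot = prot.rstrip("*")
        for i in range(len(prot) - k + 1):
            out.add(prot[i : i + k])
    return out


def enumerate_novel_peptides(
    protein: str,
    altered_span: tuple[int, int],
    reference_peptidome: set[str],
    source: str,
    source_class: str,
    k: int = 9,
) -> list[PeptideCandidate]:
    """All ``k``-mers overlapping the altered span, minus reference hits.

    Windows containing stop/ambiguous residues are discarded; duplicates
    are removed per source.
    """
    lo, hi = altered_span
    seen: set[str] = set()
    out = []
    for i in range(max(0, lo - k + 1), min(len(protein) - k, hi - 1) + 1):
        pep = protein[i : i + k]
        if set(pep) - AA20:
            continue
        if pep in reference_peptidome or pep in seen:
            continue
        seen.add(pep)
        out.append(PeptideCandidate(peptide=pep, source=source, source_class=source_class))
    return out


def isoform_novel_peptides(
    isoform_protein: str,
    reference_protein: str,
    reference_peptidome: set[str],
    source: str,
    k: int = 9,
) -> list[PeptideCandidate]:
    """Novel peptides from an aberrant isoform's divergent protein region."""
    span = _diff_span(reference_protein, isoform_protein)
    if span is None:
        return []
    return enumerate_novel_peptides(
        isoform_protein, span, reference_peptidome, source, CLASS_ISOFORM, k
    )


def call_variant_peptides(
    variants: Sequence[VariantRecord],
    transcripts,
    genome,
    reference_peptidome: set[str],
    k: int = 9,
) -> list[PeptideCandidate]:
    """Apply each variant to every coding transcript it lands in and
    enumerate the novel peptides (no phasing assumed)."""
    from .orf import build_transcript_sequence, genomic_to_transcript

    out = []
    for v in variants:
        for t in transcripts:
            if t.cds_start is None or t.chrom != v.chrom:
                continue
            tpos = genomic_to_transcript(t.exons, t.strand, v.pos)
            if tpos is None:
                continue
            mrna = build_transcript_sequence(t.exons, genome, t.chrom, t.strand)
            cds_tpos = genomic_to_transcript(t.exons, t.strand, t.cds_start)
            if cds_tpos is None:
                continue
            ref, alt = v.ref, v.alt
            if t.strand == "-":
                comp = str.maketrans("ACGTN", "TGCAN")
                ref, alt = ref.translate(comp)[::-1], alt.translate(comp)[::-1]
                tpos = tpos - len(ref) + 1
            mut = apply_variant(mrna, cds_tpos, tpos, ref, alt)
            if mut is None:
                continue
            src = f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}|{t.transcript_id}"
            out.extend(
                enumerate_novel_peptides(
                    mut.protein, mut.altered_span, reference_peptidome, src,
                    mut.variant_class, k,
                )
            )
    return out


def call_isoform_peptides(
    catalog,
    annotation_by_gene,
    genome,
    reference_peptidome: set[str],
    k: int = 9,
) -> list[PeptideCandidate]:
    """Novel peptides from every catalog isoform's divergent protein region."""
    from .orf import analyze_isoform, build_transcript_sequence, genomic_to_transcript
    from .orf import _translate_from as _tf

    out = []
    for iso in catalog:
        transcripts = annotation_by_gene[iso.gene_id]
        orf = analyze_isoform(iso, genome, transcripts)
        if orf is None or not orf.protein:
            continue
        ref_prot = ""
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            if t.cds_start is None:
                continue
            mrna = build_transcript_sequence(t.exons, genome, t.chrom, t.strand)
            cds_tpos = genomic_to_transcript(t.exons, t.strand, t.cds_start)
            if cds_tpos is not None:
                ref_prot, _ = _tf(mrna, cds_tpos)
                break
        out.extend(
            isoform_novel_peptides(orf.protein, ref_prot, reference_peptidome, iso.isoform_id, k)
        )
    return out


# ---------------------------------------------------------------------------
# HLA binding
# ---------------------------------------------------------------------------

class BindingScorer(Protocol):
    def score(self, peptide: str, allele: str) -> float:  # %rank
        ...


class MockBindingScorer:
    """Deterministic stand-in predictor for tests and examples.

    The %rank is a stable hash of (peptide, allele) mapped onto [0, 2) —
    reproducible across runs and platforms, with no biological meaning.
    """

    def score(self, peptide: str, allele: str) -> float:
        digest = hashlib.md5(f"{peptide}|{allele}".encode()).hexdigest()
        return (int(digest[:8], 16) % 20000) / 10000.0


def score_and_call(
    peptides: Sequence[PeptideCandidate],
    hla_alleles: Sequence[str],
    scorer: BindingScorer,
    strong_rank: float = 0.5,
) -> list[PeptideCandidate]:
    """Attach %rank per (peptide, allele); strong binder = rank < 0.5.

    A scorer failure leaves the candidate with rank unavailable rather
    than dropping it.
    """
    out = []
    for cand in peptides:
        for allele in hla_alleles:
            try:
                rank = float(scorer.score(cand.peptide, allele))
            except Exception:
                rank = None
            out.append(
                PeptideCandidate(
                    peptide=cand.peptide,
                    source=cand.source,
                    source_class=cand.source_class,
                    hla_allele=allele,
                    percent_rank=rank,
                )
            )
    return out


def tabulate_by_source(candidates: Sequence[PeptideCandidate]) -> dict:
    """Counts per source class and best (minimum) %rank per source."""
    counts: dict[str, int] = {}
    best_rank: dict[str, float] = {}
    for c in candidates:
        counts[c.source_class] = counts.get(c.source_class, 0) + 1
        if c.percent_rank is not None:
            prev = best_rank.get(c.source)
            if prev is None or c.percent_rank < prev:
                best_rank[c.source] = c.percent_rank
    return {"counts_by_class": counts, "best_rank_by_source": best_rank}
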