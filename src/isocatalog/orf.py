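"""ORF reconstruction and premature-termination-codon (NMD target) flagging.

An isoform's mRNA is rebuilt from its exon chain, its ORF is inferred
(annotated start codon when it survives in the isoform, else the longest
ATG-initiated ORF), and the stop codon's position is compared with the
last exon–exon junction: a stop at least 50 nt upstream of the final
junction (the canonical NMD rule, configurable) marks the isoform as a
PTC-containing, NMD-targetable transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq
from scipy import stats

from .models import GenomeRef, Interval, IsoformCandidate, TranscriptModel


@dataclass
class NmdRuleParams:
    """``min_distance_nt``: stop ≥ this many nt upstream of the last
    exon–exon junction ⇒ PTC."""

    min_distance_nt: int = 50


@dataclass
class OrfResult:
    """Inferred ORF of one isoform, all coordinates transcript-relative.

    ``stop_pos`` is the first base of the stop codon (None for open-ended
    ORFs). ``distance_to_last_junction`` = last-junction position − end of
    the stop codon, in nt; negative when the stop is downstream of the
    junction; None for mono-exonic isoforms or open-ended ORFs.
    """

    cds_start: Optional[int]
    protein: str
    stop_pos: Optional[int]
    distance_to_last_junction: Optional[int]
    ptc_flag: bool


def build_transcript_sequence(
    exons: Sequence[Interval], genome: GenomeRef, chrom: str, strand: str
) -> str:
    """Concatenate exon sequences 5'→3' (reverse-complemented on minus)."""
    if not exons:
        raise ValueError("empty exon list")
    seq = "".join(genome.fetch(chrom, s, e) for s, e in sorted(exons))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def transcript_junction_positions(exons: Sequence[Interval], strand: str) -> list[int]:
    """Exon–exon junction positions in transcript coordinates.

    Each position is the transcript offset of the first base of the exon
    downstream of the junction.
    """
    lengths = [e - s for s, e in sorted(exons)]
    if strand == "-":
        lengths = lengths[::-1]
    out, acc = [], 0
    for ln in lengths[:-1]:
        acc += ln
        out.append(acc)
    return out


def genomic_to_transcript(
    exons: Sequence[Interval], strand: str, gpos: int
) -> Optional[int]:
    """Map a genomic coordinate to a transcript coordinate (None if intronic)."""
    exs = sorted(exons)
    if strand == "-":
        acc = 0
        for s, e in reversed(exs):
            if s <= gpos < e:
                return acc + (e - 1 - gpos)
            acc += e - s
        return None
    acc = 0
    for s, e in exs:
        if s <= gpos < e:
            return acc + (gpos - s)
        acc += e - s
    return None


def _translate_from(mrna: str, start: int) -> tuple[str, Optional[int]]:
    """Translate from ``start`` to the first stop codon or transcript end.

    Returns (protein, stop codon start position or None if open-ended).
    """
    prot = []
    i = start
    while i + 3 <= len(mrna):
        codon = mrna[i : i + 3]
        aa = str(Seq(codon).translate())
        if aa == "*":
            return "".join(prot), i
        prot.append(aa)
        i += 3
    return "".join(prot), None


def infer_orf(
    mrna: str,
    annotated_start: Optional[int] = None,
    junction_positions: Optional[Sequence[int]] = None,
    params: Optional[NmdRuleParams] = None,
) -> Optional[OrfResult]:
    """Infer the ORF of an mRNA and flag a PTC.

    If ``annotated_start`` (a transcript coordinate) still reads ATG in the
    isoform, translation starts there; otherwise the longest ATG-initiated
    ORF is chosen (ties break to the 5'-most start). Translation stops at
    the first in-frame stop or runs open-ended to the transcript end
    (open-ended ⇒ no PTC). Returns None when the mRNA contains no ATG.
    """
    params = params or NmdRuleParams()
    if len(mrna) < 3:
        raise ValueError("mRNA shorter than one codon")
    start: Optional[int] = None
    if annotated_start is not None and mrna[annotated_start : annotated_start + 3] == "ATG":
        start = annotated_start
    else:
        best_len = -1
        i = mrna.find("ATG")
        while i != -1:
            prot, stop = _translate_from(mrna, i)
            if len(prot) > best_len:
                best_len, start = len(prot), i
            i = mrna.find("ATG", i + 1)
        if start is None:
            return None
    protein, stop_pos = _translate_from(mrna, start)
    distance = None
    ptc = False
    if stop_pos is not None and junction_positions:
        distance = max(junction_positions) - (stop_pos + 3)
        ptc = flag_ptc_distance(distance, params)
    return OrfResult(
        cds_start=start,
        protein=protein,
        stop_pos=stop_pos,
        distance_to_last_junction=distance,
        ptc_flag=ptc,
    )


def flag_ptc_distance(distance_nt: int, params: Optional[NmdRuleParams] = None) -> bool:
    params = params or NmdRuleParams()
    return distance_nt >= params.min_distance_nt


def flag_ptc(
    orf: OrfResult,
    junction_positions: Sequence[int],
    params: Optional[NmdRuleParams] = None,
) -> bool:
    """True iff the stop codon lies ≥ ``min_distance_nt`` upstream of the
    last exon–exon junction. Open-ended ORFs and mono-exonic transcripts
    are never PTC."""
    if orf.stop_pos is None or not junction_positions:
        return False
    distance = max(junction_positions) - (orf.stop_pos + 3)
    return flag_ptc_distance(distance, params)


def analyze_isoform(
    isoform: IsoformCandidate,
    genome: GenomeRef,
    transcripts: Sequence[TranscriptModel],
    params: Optional[NmdRuleParams] = None,
) -> Optional[OrfResult]:
    """ORF + PTC analysis of one isoform against its gene's annotation.

    The annotated start codon of the gene (any transcript, deterministic
    order) is used when its genomic position is exonic in the isoform and
    still reads ATG.
    """
    mrna = build_transcript_sequence(isoform.exons, genome, isoform.chrom, isoform.strand)
    annotated_start = None
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        if t.cds_start is None:
            continue
        tpos = genomic_to_transcript(isoform.exons, isoform.strand, t.cds_start)
        if tpos is not None and mrna[tpos : tpos + 3] == "ATG":
            annotated_start = tpos
            break
    jpos = transcript_junction_positions(isoform.exons, isoform.strand)
    return infer_orf(mrna, annotated_start, jpos, params)


def annotate_catalog_ptc(
    catalog: Sequence[IsoformCandidate],
    genome: GenomeRef,
    annotation_by_gene: dict[str, list[TranscriptModel]],
    params: Optional[NmdRuleParams] = None,
) -> None:
    """Fill ``ptc_flag`` in place for every catalog isoform."""
    for iso in catalog:
        orf = analyze_isoform(iso, genome, annotation_by_gene[iso.gene_id], params)
        iso.ptc_flag = bool(orf and orf.ptc_flag)


def compare_ptc_proportions(
    n_ptc_a: int, n_total_a: int, n_ptc_b: int, n_total_b: int
) -> float:
    """Two-sided Fisher's exact p-value comparing PTC proportions."""
    if not (0 <= n_ptc_a <= n_total_a and 0 <= n_ptc_b <= n_total_b):
        raise ValueError("counts exceed totals")
    table = [[n_ptc_a, n_total_a - n_ptc_a], [n_ptc_b, n_total_b - n_ptc_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
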