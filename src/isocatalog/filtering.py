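"""Long-read quality filtering, short-intron correction and gene assignment.

Five rejection rules are applied to every spliced alignment:

1. secondary or supplementary flag set;
2. mapping identity — matched bases over matched + substituted + inserted
   + deleted bases — below 0.8;
3. more than 10 read bases inserted immediately adjacent to a splice
   junction;
4. any exonic block shorter than 25 bp;
5. overlap with a pseudogene interval.

Surviving reads have introns shorter than 50 bp absorbed into their
flanking blocks and are then assigned to the single gene sharing the most
exonic overlap on the same strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import AlignedLongRead, Interval, TranscriptModel, group_by_gene

REASON_SECONDARY = "secondary_supplementary"
REASON_IDENTITY = "low_identity"
REASON_JUNCTION_INS = "junction_insertion"
REASON_SHORT_EXON = "short_exon"
REASON_PSEUDOGENE = "pseudogene"
REASON_UNASSIGNED = "unassigned_gene"


@dataclass
class FilterParams:
    min_identity: float = 0.8
    max_junction_insertion: int = 10
    min_exon_len: int = 25
    min_intron_len: int = 50
    pseudogene_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    pseudogene_min_overlap: int = 1


@dataclass
class RejectionLog:
    """Per-read rejection reason codes; kept reads have empty lists."""

    reasons: dict[str, list[str]] = field(default_factory=dict)

    def add(self, read_id: str, reason: str) -> None:
        self.reasons.setdefault(read_id, []).append(reason)

    def __getitem__(self, read_id: str) -> list[str]:
        return self.reasons.get(read_id, [])


def mapping_identity(read: AlignedLongRead) -> Optional[float]:
    """Matched bases / (matched + substituted + inserted + deleted).

    Returns ``None`` when the denominator is zero (identity unevaluable,
    e.g. no =/X operations and no NM tag in the source alignment).
    """
    denom = read.n_match + read.n_sub + read.n_ins + read.n_del
    if denom == 0:
        return None
    return read.n_match / denom


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def filter_reads(
    reads: Sequence[AlignedLongRead],
    params: Optional[FilterParams] = None,
) -> tuple[list[AlignedLongRead], RejectionLog]:
    """Apply the five rejection rules; a read may collect several reasons."""
    params = params or FilterParams()
    kept = []
    log = RejectionLog()
    pseudo = params.pseudogene_intervals
    for read in reads:
        reasons = []
        if read.is_secondary or read.is_supplementary:
            reasons.append(REASON_SECONDARY)
        ident = mapping_identity(read)
        if ident is None or ident < params.min_identity:
            reasons.append(REASON_IDENTITY)
        if any(ins > params.max_junction_insertion for ins in read.junction_insertions):
            reasons.append(REASON_JUNCTION_INS)
        if any(e - s < params.min_exon_len for s, e in read.blocks):
            reasons.append(REASON_SHORT_EXON)
        if pseudo:
            for chrom, ps, pe in pseudo:
                if chrom != read.chrom:
                    continue
                if any(_overlap(b, (ps, pe)) >= params.pseudogene_min_overlap for b in read.blocks):
                    reasons.append(REASON_PSEUDOGENE)
                    break
        if reasons:
            for r in reasons:
                log.add(read.read_id, r)
        else:
            log.reasons.setdefault(read.read_id, [])
            kept.append(read)
    return kept, log


def correct_short_introns(read: AlignedLongRead, min_intron_len: int = 50) -> AlignedLongRead:
    """Absorb introns shorter than ``min_intron_len`` into exonic blocks.

    Merging is applied iteratively until no short gap remains; total exonic
    span never decreases and blocks never overlap.
    """
    blocks = list(read.blocks)
    ji = list(read.junction_insertions)
    changed = True
    while changed:
        changed = False
        for i in range(len(blocks) - 1):
            gap = blocks[i + 1][0] - blocks[i][1]
            if gap < min_intron_len:
                blocks[i : i + 2] = [(blocks[i][0], blocks[i + 1][1])]
                del ji[i]
                changed = True
                break
    return AlignedLongRead(
        read_id=read.read_id,
        chrom=read.chrom,
        strand=read.strand,
        blocks=blocks,
        n_match=read.n_match,
        n_sub=read.n_sub,
        n_ins=read.n_ins,
        n_del=read.n_del,
        is_secondary=read.is_secondary,
        is_supplementary=read.is_supplementary,
        junction_insertions=ji,
    )


def assign_gene(
    read: AlignedLongRead,
    annotation: Sequence[TranscriptModel],
) -> Optional[str]:
    """Assign a read to the gene with the largest same-strand exonic overlap.

    Exact ties break to the lexicographically smaller gene_id. Antisense
    reads (no same-strand overlap) are unassigned.
    """
    best_gene: Optional[str] = None
    best_overlap = 0
    for gene_id, transcripts in sorted(group_by_gene(annotation).items()):
        total = 0
        for t in transcripts:
            if t.chrom != read.chrom or t.strand != read.strand:
                continue
            # overlap against the union of this transcript's exons would
            # double-count shared exons across transcripts; take the max
            # per-transcript overlap as the gene's score
            o = sum(_overlap(b, ex) for b in read.blocks for ex in t.exons)
            total = max(total, o)
        if total > best_overlap:
            best_overlap, best_gene = total, gene_id
    return best_gene


def filter_and_assign(
    reads: Sequence[AlignedLongRead],
    annotation: Sequence[TranscriptModel],
    params: Optional[FilterParams] = None,
) -> tuple[dict[str, list[AlignedLongRead]], RejectionLog]:
    """Full pre-processing: filter, correct short introns, assign genes.

    Returns reads grouped per gene_id plus the rejection log (unassigned
    reads are logged with reason ``unassigned_gene``).
    """
    params = params or FilterParams()
    kept, log = filter_reads(reads, params)
    by_gene: dict[str, list[AlignedLongRead]] = {}
    for read in kept:
        corrected = correct_short_introns(read, params.min_intron_len)
        gene = assign_gene(corrected, annotation)
        if gene is None:
            log.add(read.read_id, REASON_UNASSIGNED)
            continue
        by_gene.setdefault(gene, []).append(corrected)
    return by_gene, log
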