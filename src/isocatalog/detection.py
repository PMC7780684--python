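"""Isoform detection from filtered long reads.

The detection logic compares each read's junction chain to the reference
transcripts of its assigned gene (± a 20 bp matching margin per boundary),
removes reads identical to (Type A) or truncations of (Type B) a reference
transcript, requires every novel junction to be confirmed by short-read
junctions seen in at least five unique reads, snaps junction coordinates to
the best evidence (annotation first, then short reads), merges reads with
identical snapped chains into isoform candidates, and applies the coverage
/ TPM / gene-fraction expression filters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .models import (
    AlignedLongRead,
    Interval,
    IsoformCandidate,
    Junction,
    JunctionSupportTable,
    ReadClass,
    TranscriptModel,
)


@dataclass
class CatalogFilterParams:
    """Expression filters applied to merged candidates.

    ``coverage_divisor``: minimum read support is total long reads divided
    by this (default 100,000). ``min_tpm`` and ``min_gene_fraction`` are
    the short-read expression filters (TPM ≥ 10, isoform reads / gene
    reads > 10%). ``margin`` is the junction matching margin in bp and
    ``min_sj_support`` the short-read junction confirmation threshold.
    """

    coverage_divisor: float = 100_000.0
    min_tpm: float = 10.0
    min_gene_fraction: float = 0.10
    margin: int = 20
    min_sj_support: int = 5
    snap_to_evidence: bool = True


def _within_margin(a: Interval, b: Interval, margin: int) -> bool:
    return abs(a[0] - b[0]) <= margin and abs(a[1] - b[1]) <= margin


def match_reference(
    chain: Sequence[Junction],
    transcripts: Sequence[TranscriptModel],
    margin: int = 20,
    read_span: Optional[Interval] = None,
) -> tuple[list[bool], ReadClass]:
    """Compare a junction chain against a gene's reference transcripts.

    Returns per-junction "annotated" flags (within ±margin of any annotated
    junction of the gene) and the read class:

    * ``TYPE_A`` — same number of junctions as some transcript and a
      one-to-one in-order match with that transcript's junctions (terminal
      end differences ignored);
    * ``TYPE_B`` — the chain matches a contiguous run of some transcript's
      junctions and each truncated read end (``read_span``) lies within the
      flanking exon of that transcript; mono-exonic chains are Type B-like
      and excluded from candidacy;
    * ``ISOFORM_CANDIDATE`` — anything else.
    """
    introns = [(j.start, j.end) for j in chain]
    annotated_set: list[Interval] = []
    for t in transcripts:
        annotated_set.extend(t.introns)
    flags = [any(_within_margin(iv, a, margin) for a in annotated_set) for iv in introns]

    if not introns:
        return flags, ReadClass.TYPE_B

    for t in transcripts:
        t_introns = t.introns
        n, m = len(introns), len(t_introns)
        if n == m and all(_within_margin(a, b, margin) for a, b in zip(introns, t_introns)):
            return flags, ReadClass.TYPE_A
        if n < m:
            for k in range(m - n + 1):
                if all(
                    _within_margin(a, b, margin)
                    for a, b in zip(introns, t_introns[k : k + n])
                ):
                    # truncated ends must fall within the flanking exons
                    left_exon = t.exons[k]
                    right_exon = t.exons[k + n]
                    if read_span is None:
                        return flags, ReadClass.TYPE_B
                    rs, re = read_span
                    if (
                        left_exon[0] - margin <= rs < left_exon[1] + margin
                        and right_exon[0] - margin < re <= right_exon[1] + margin
                    ):
                        return flags, ReadClass.TYPE_B
    return flags, ReadClass.ISOFORM_CANDIDATE


def _nearest(target: Interval, options: Iterable[Interval], margin: int) -> Optional[Interval]:
    best, best_d = None, None
    for opt in options:
        if not _within_margin(target, opt, margin):
            continue
        d = abs(target[0] - opt[0]) + abs(target[1] - opt[1])
        if best_d is None or d < best_d or (d == best_d and opt < best):
            best, best_d = opt, d
    return best


def validate_junctions(
    chain: Sequence[Junction],
    transcripts: Sequence[TranscriptModel],
    support: JunctionSupportTable,
    min_reads: int = 5,
    margin: int = 20,
    snap: bool = True,
) -> Optional[tuple[Junction, ...]]:
    """Confirm and snap a candidate read's junction chain.

    Junctions within the margin of an annotated junction snap to the
    annotated coordinates. Novel junctions must lie within the margin of a
    short-read junction supported by ≥ ``min_reads`` unique reads and snap
    to the short-read coordinates (exact matches preferred). Returns the
    snapped chain, or ``None`` if any novel junction lacks support
    (the read is UNCONFIRMED).
    """
    annotated: set[Interval] = set()
    for t in transcripts:
        annotated.update(t.introns)

    snapped: list[Junction] = []
    for j in chain:
        iv = (j.start, j.end)
        hit = _nearest(iv, annotated, margin)
        if hit is not None:
            snapped.append(Junction(j.chrom, j.strand, *(hit if snap else iv)))
            continue
        near = support.junctions_near(j.chrom, j.start, j.end, margin)
        near = [(sj, n) for sj, n in near if n >= min_reads and sj.strand in (j.strand, ".")]
        if not near:
            return None
        best = _nearest(iv, [(sj.start, sj.end) for sj, _ in near], margin)
        snapped.append(Junction(j.chrom, j.strand, *(best if snap else iv)))

    coords = [(j.start, j.end) for j in snapped]
    for (a, b) in zip(coords, coords[1:]):
        if b[0] <= a[1]:
            return None  # snapping produced an inconsistent chain
    return tuple(snapped)


def merge_and_count(
    gene_id: str,
    validated: Sequence[tuple[AlignedLongRead, tuple[Junction, ...]]],
    id_prefix: str = "ISO",
) -> list[IsoformCandidate]:
    """Merge validated reads with identical snapped chains into candidates.

    The representative exon chain spans from the modal read start to the
    modal read end (ties break to the smaller coordinate), with internal
    boundaries given by the snapped junctions.
    """
    groups: dict[tuple, list[tuple[AlignedLongRead, tuple[Junction, ...]]]] = {}
    for read, chain in validated:
        key = tuple((j.chrom, j.strand, j.start, j.end) for j in chain)
        groups.setdefault(key, []).append((read, chain))

    out = []
    for idx, key in enumerate(sorted(groups), start=1):
        members = groups[key]
        chain = members[0][1]
        starts = Counter(r.blocks[0][0] for r, _ in members)
        ends = Counter(r.blocks[-1][1] for r, _ in members)
        start = min(s for s, c in starts.items() if c == max(starts.values()))
        end = min(e for e, c in ends.items() if c == max(ends.values()))
        bounds = [start] + [x for j in chain for x in (j.start, j.end)] + [end]
        exons = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]
        read0 = members[0][0]
        out.append(
            IsoformCandidate(
                isoform_id=f"{id_prefix}_{gene_id}_{idx:03d}",
                gene_id=gene_id,
                chrom=read0.chrom,
                strand=read0.strand,
                junctions=chain,
                exons=exons,
                supporting_read_ids=sorted(r.read_id for r, _ in members),
            )
        )
    return out


def apply_catalog_filters(
    candidates: Sequence[IsoformCandidate],
    total_minion_reads: int,
    gene_read_totals: dict[str, int],
    params: Optional[CatalogFilterParams] = None,
) -> list[IsoformCandidate]:
    """Keep candidates passing coverage, TPM and gene-fraction filters.

    A candidate passes iff read count ≥ total/coverage_divisor AND
    TPM ≥ min_tpm AND count / gene total > min_gene_fraction (strict).
    Candidates must carry a TPM (set ``tpm`` from the external table or the
    EM quantifier before calling).
    """
    params = params or CatalogFilterParams()
    min_cov = total_minion_reads / params.coverage_divisor
    kept = []
    for c in candidates:
        gene_total = gene_read_totals[c.gene_id]
        assert gene_total > 0, "gene with a candidate must have assigned reads"
        if c.minion_read_count < min_cov:
            continue
        if c.tpm is None or c.tpm < params.min_tpm:
            continue
        if c.minion_read_count / gene_total <= params.min_gene_fraction:
            continue
        kept.append(c)
    return kept


def classify_and_collect(
    reads_by_gene: dict[str, list[AlignedLongRead]],
    annotation_by_gene: dict[str, list[TranscriptModel]],
    support: JunctionSupportTable,
    params: Optional[CatalogFilterParams] = None,
) -> tuple[dict[str, list], dict[str, ReadClass]]:
    """Classify every kept read and collect validated candidate reads per gene.

    Returns ``(validated_by_gene, read_classes)`` where ``validated_by_gene``
    maps gene_id to (read, snapped chain) pairs, and ``read_classes`` records
    the final class of every read (TYPE_A / TYPE_B / ISOFORM_CANDIDATE /
    UNCONFIRMED) — the four classes partition the kept reads.
    """
    params = params or CatalogFilterParams()
    validated_by_gene: dict[str, list] = {}
    read_classes: dict[str, ReadClass] = {}
    for gene_id, reads in reads_by_gene.items():
        transcripts = annotation_by_gene.get(gene_id, [])
        for read in reads:
            chain = read.junctions()
            span = (read.blocks[0][0], read.blocks[-1][1])
            _, cls = match_reference(chain, transcripts, params.margin, read_span=span)
            if cls is ReadClass.ISOFORM_CANDIDATE:
                snapped = validate_junctions(
                    chain,
                    transcripts,
                    support,
                    min_reads=params.min_sj_support,
                    margin=params.margin,
                    snap=params.snap_to_evidence,
                )
                if snapped is None:
                    cls = ReadClass.UNCONFIRMED
                else:
                    validated_by_gene.setdefault(gene_id, []).append((read, snapped))
            read_classes[read.read_id] = cls
    return validated_by_gene, read_classes


def detect_isoforms(
    reads_by_gene: dict[str, list[AlignedLongRead]],
    annotation_by_gene: dict[str, list[TranscriptModel]],
    support: JunctionSupportTable,
    tpm: dict[tuple, float] | None = None,
    total_minion_reads: Optional[int] = None,
    params: Optional[CatalogFilterParams] = None,
) -> tuple[list[IsoformCandidate], dict[str, ReadClass]]:
    """Full detection: classify, validate, merge, filter.

    ``tpm`` maps candidate chain keys (:meth:`IsoformCandidate.chain_key`)
    to short-read TPM values; candidates missing from the map get TPM 0 and
    fail the TPM filter.
    """
    params = params or CatalogFilterParams()
    if total_minion_reads is None:
        total_minion_reads = sum(len(v) for v in reads_by_gene.values())
    gene_totals = {g: len(v) for g, v in reads_by_gene.items()}

    validated_by_gene, read_classes = classify_and_collect(
        reads_by_gene, annotation_by_gene, support, params
    )
    candidates: list[IsoformCandidate] = []
    for gene_id in sorted(validated_by_gene):
        candidates.extend(merge_and_count(gene_id, validated_by_gene[gene_id]))
    for c in candidates:
        c.tpm = (tpm or {}).get(c.chain_key(), 0.0)
    catalog = apply_catalog_filters(candidates, total_minion_reads, gene_totals, params)
    return catalog, read_classes


# ---------------------------------------------------------------------------
# TPM quantification (internal EM fallback)
# ---------------------------------------------------------------------------

def quantify_tpm(
    eq_classes: Sequence[tuple[frozenset, int]],
    effective_lengths: dict[str, float],
    max_iters: int = 100,
    tol: float = 1e-8,
) -> dict[str, float]:
    """Expectation-maximization transcript quantifier.

    ``eq_classes`` are (set of compatible transcript ids, fragment count)
    pairs. Fractional assignments are re-estimated until the relative
    change in abundances falls below ``tol`` or ``max_iters`` is reached.
    Returned TPMs sum to 1e6 (all-zero counts return all-zero TPM with a
    warning).
    """
    import warnings

    tids = sorted(effective_lengths)
    total = sum(c for _, c in eq_classes)
    if total == 0:
        warnings.warn("all-zero fragment counts; TPM undefined, returning zeros")
        return {t: 0.0 for t in tids}

    alpha = {t: 1.0 / len(tids) for t in tids}
    for _ in range(max_iters):
        assigned = {t: 0.0 for t in tids}
        for members, count in eq_classes:
            weights = {t: alpha[t] / effective_lengths[t] for t in members}
            z = sum(weights.values())
            if z == 0:
                continue
            for t in members:
                assigned[t] += count * weights[t] / z
        new_alpha = {t: assigned[t] / total for t in tids}
        delta = max(abs(new_alpha[t] - alpha[t]) / max(alpha[t], 1e-12) for t in tids)
        alpha = new_alpha
        if delta < tol:
            break

    rates = {t: alpha[t] / effective_lengths[t] for t in tids}
    z = sum(rates.values())
    return {t: (rates[t] / z) * 1e6 if z else 0.0 for t in tids}


def tpm_per_mrna_copy(molecules_per_cell: int = 360_000) -> float:
    """TPM corresponding to one mRNA copy per cell.

    With ~360,000 mRNA molecules per cell, one copy is 1e6/360,000 ≈ 2.78
    TPM — about 3 TPM at integer precision.
    """
    return 1e6 / molecules_per_cell
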