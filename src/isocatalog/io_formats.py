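"""Readers and writers for every external format the pipeline touches.

All conversions to/from the internal 0-based half-open convention happen
here and only here:

* GTF exons: 1-based inclusive on disk.
* STAR ``SJ.out.tab``: 1-based inclusive intron coordinates, strand code
  0/1/2 (unknown/+/-).
* VCF: 1-based POS.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional, Sequence

import gffutils
import pysam
from pyfaidx import Fasta

from .models import (
    AlignedLongRead,
    GenomeRef,
    IsoformCandidate,
    Junction,
    JunctionSupportTable,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_SJ_STRAND = {0: ".", 1: "+", 2: "-"}
_SJ_STRAND_CODE = {".": 0, "+": 1, "-": 2}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(fasta_path: str) -> GenomeRef:
    """Load a genome FASTA into memory (uppercased)."""
    fa = Fasta(str(fasta_path), rebuild=True)
    return GenomeRef({name: str(fa[name][:]) for name in fa.keys()})


def write_fasta(sequences: dict[str, str], out_path: str, width: int = 70) -> None:
    with open(out_path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _prevalidate_gtf(gtf_path: str) -> None:
    """Cheap structural pass so parse errors can name the offending line."""
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}: line {lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(f"{gtf_path}: line {lineno}: non-integer coordinates") from None
            if end < start:
                raise ValueError(f"{gtf_path}: line {lineno}: end < start")


def read_annotation(gtf_path: str) -> list[TranscriptModel]:
    """Parse a GTF into :class:`TranscriptModel` objects.

    Exons are converted from 1-based inclusive to 0-based half-open and
    sorted. A ``start_codon`` feature, when present, supplies
    ``cds_start`` (first base of the codon on the transcript strand).
    Transcripts with zero exon lines are dropped with a warning.
    """
    _prevalidate_gtf(str(gtf_path))
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    exons: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    starts: dict[str, tuple[int, int]] = {}
    declared: set[str] = set()

    for feat in db.all_features():
        tids = feat.attributes.get("transcript_id")
        if not tids:
            continue
        tid = tids[0]
        if feat.featuretype == "transcript":
            declared.add(tid)
            meta.setdefault(tid, (feat.attributes["gene_id"][0], feat.seqid, feat.strand))
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start - 1, feat.end))
            meta.setdefault(tid, (feat.attributes["gene_id"][0], feat.seqid, feat.strand))
        elif feat.featuretype == "start_codon":
            starts[tid] = (feat.start - 1, feat.end)

    for tid in declared - set(exons):
        warnings.warn(f"transcript {tid} has zero exons; dropped")

    out = []
    for tid, ex in exons.items():
        gene_id, chrom, strand = meta[tid]
        cds_start = None
        if tid in starts:
            s, e = starts[tid]
            cds_start = s if strand == "+" else e - 1
        out.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=sorted(ex),
                cds_start=cds_start,
            )
        )
    return out


def _gtf_attr(pairs: Sequence[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_annotation(models: Iterable[TranscriptModel], out_path: str, source: str = "isocatalog") -> None:
    """Write transcript models as GTF (transcript/exon/start_codon lines)."""
    with open(out_path, "w") as fh:
        for m in models:
            attrs = [("gene_id", m.gene_id), ("transcript_id", m.transcript_id)]
            s, e = m.span
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{_gtf_attr(attrs)}\n"
            )
            for (xs, xe) in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t{_gtf_attr(attrs)}\n"
                )
            if m.cds_start is not None:
                if m.strand == "+":
                    cs, ce = m.cds_start, m.cds_start + 3
                else:
                    cs, ce = m.cds_start - 2, m.cds_start + 1
                fh.write(
                    f"{m.chrom}\t{source}\tstart_codon\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t{_gtf_attr(attrs)}\n"
                )


def write_isoform_gtf(
    catalog: Sequence[IsoformCandidate],
    reference_models: Sequence[TranscriptModel],
    out_path: str,
) -> None:
    """Emit the isoform catalog plus all reference transcripts as one GTF.

    Isoform transcript lines carry ``isoform_id``, the event label and the
    PTC flag as attributes; coordinates are back-converted to 1-based
    inclusive.
    """
    with open(out_path, "w") as fh:
        for iso in catalog:
            attrs = [
                ("gene_id", iso.gene_id),
                ("transcript_id", iso.isoform_id),
                ("isoform_id", iso.isoform_id),
            ]
            if iso.label is not None:
                attrs.append(("event_label", iso.label))
            if iso.event_labels:
                attrs.append(("events", ",".join(iso.event_labels)))
            if iso.ptc_flag is not None:
                attrs.append(("ptc", "yes" if iso.ptc_flag else "no"))
            s, e = iso.exons[0][0], iso.exons[-1][1]
            fh.write(
                f"{iso.chrom}\tisocatalog\ttranscript\t{s + 1}\t{e}\t.\t{iso.strand}\t.\t{_gtf_attr(attrs)}\n"
            )
            for (xs, xe) in iso.exons:
                fh.write(
                    f"{iso.chrom}\tisocatalog\texon\t{xs + 1}\t{xe}\t.\t{iso.strand}\t.\t{_gtf_attr(attrs)}\n"
                )
        for m in reference_models:
            attrs = [("gene_id", m.gene_id), ("transcript_id", m.transcript_id)]
            s, e = m.span
            fh.write(
                f"{m.chrom}\tisocatalog\ttranscript\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{_gtf_attr(attrs)}\n"
            )
            for (xs, xe) in m.exons:
                fh.write(
                    f"{m.chrom}\tisocatalog\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t{_gtf_attr(attrs)}\n"
                )


def read_isoform_gtf(gtf_path: str) -> list[IsoformCandidate]:
    """Read back a catalog GTF written by :func:`write_isoform_gtf`.

    Only transcripts carrying an ``isoform_id`` attribute are returned;
    plain reference transcripts in the same file are ignored.
    """
    _prevalidate_gtf(str(gtf_path))
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    by_iso: dict[str, dict] = {}
    for feat in db.all_features():
        if "isoform_id" not in feat.attributes:
            continue
        iid = feat.attributes["isoform_id"][0]
        rec = by_iso.setdefault(
            iid,
            {
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "label": None,
                "events": [],
                "ptc": None,
            },
        )
        if feat.featuretype == "exon":
            rec["exons"].append((feat.start - 1, feat.end))
        if "event_label" in feat.attributes:
            rec["label"] = feat.attributes["event_label"][0]
        if "events" in feat.attributes:
            rec["events"] = feat.attributes["events"][0].split(",")
        if "ptc" in feat.attributes:
            rec["ptc"] = feat.attributes["ptc"][0] == "yes"

    out = []
    for iid, rec in by_iso.items():
        exons = sorted(rec["exons"])
        juncs = tuple(
            Junction(rec["chrom"], rec["strand"], a[1], b[0])
            for a, b in zip(exons, exons[1:])
        )
        out.append(
            IsoformCandidate(
                isoform_id=iid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                junctions=juncs,
                exons=exons,
                event_labels=rec["events"],
                label=rec["label"],
                ptc_flag=rec["ptc"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------

_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_H = 0, 1, 2, 3, 4, 5
_CIG_EQ, _CIG_X = 7, 8


def _segment_to_read(seg: pysam.AlignedSegment) -> AlignedLongRead:
    blocks: list[tuple[int, int]] = []
    pos = seg.reference_start
    block_start = pos
    n_match = n_sub = n_ins = n_del = 0
    has_eq_x = False
    junction_insertions: list[int] = []
    pending_ins = 0  # insertion immediately before the next op
    cig = seg.cigartuples or []
    for idx, (op, length) in enumerate(cig):
        if op in (_CIG_M, _CIG_EQ, _CIG_X, _CIG_D):
            pos += length
            if op == _CIG_EQ:
                n_match += length
                has_eq_x = True
            elif op == _CIG_X:
                n_sub += length
                has_eq_x = True
            elif op == _CIG_D:
                n_del += length
            pending_ins = 0
        elif op == _CIG_I:
            n_ins += length
            # adjacent to an intron on either side?
            prev_n = idx > 0 and cig[idx - 1][0] == _CIG_N
            next_n = idx + 1 < len(cig) and cig[idx + 1][0] == _CIG_N
            if prev_n and junction_insertions:
                junction_insertions[-1] += length
            if next_n:
                pending_ins += length
        elif op == _CIG_N:
            blocks.append((block_start, pos))
            junction_insertions.append(pending_ins)
            pending_ins = 0
            pos += length
            block_start = pos
    blocks.append((block_start, pos))

    if not has_eq_x:
        m_total = sum(l for op, l in cig if op == _CIG_M)
        nm = seg.get_tag("NM") if seg.has_tag("NM") else None
        if nm is not None:
            n_sub = max(0, int(nm) - n_ins - n_del)
            n_match = max(0, m_total - n_sub)
        else:
            # neither =/X nor NM: mapping identity is unevaluable; leave all
            # tallies zero so the identity rule fails conservatively
            n_match = n_sub = 0

    return AlignedLongRead(
        read_id=seg.query_name,
        chrom=seg.reference_name,
        strand="-" if seg.is_reverse else "+",
        blocks=blocks,
        n_match=n_match,
        n_sub=n_sub,
        n_ins=n_ins,
        n_del=n_del,
        is_secondary=seg.is_secondary,
        is_supplementary=seg.is_supplementary,
        junction_insertions=junction_insertions,
    )


def read_alignments(sam_path: str) -> list[AlignedLongRead]:
    """Read spliced long-read alignments from SAM/BAM.

    Unmapped records and records without a CIGAR are skipped (counted in
    the log). N operations delimit introns; =/X give match/substitution
    tallies directly, with an NM-tag fallback for M-only CIGARs.
    """
    out = []
    n_skipped = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                n_skipped += 1
                continue
            out.append(_segment_to_read(seg))
    if n_skipped:
        logger.info("skipped %d unmapped/CIGAR-less records", n_skipped)
    return out


def sam_header(genome: GenomeRef) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.sequences.items()],
        }
    )


def write_sam(segments: Iterable[pysam.AlignedSegment], header: pysam.AlignmentHeader, out_path: str) -> None:
    with pysam.AlignmentFile(str(out_path), "w", header=header) as fh:
        for seg in segments:
            fh.write(seg)


# ---------------------------------------------------------------------------
# STAR SJ.out.tab
# ---------------------------------------------------------------------------

def read_star_junctions(sj_path: str) -> JunctionSupportTable:
    """Parse a STAR ``SJ.out.tab`` into a :class:`JunctionSupportTable`.

    Column 7 (unique-mapping reads) is the support count; intron
    coordinates are converted from 1-based inclusive to 0-based half-open.
    Strand code 0 is stored as the strand-unknown wildcard ``.``.
    """
    table = JunctionSupportTable()
    with open(sj_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{sj_path}: line {lineno}: expected ≥7 columns")
            try:
                chrom = fields[0]
                start1, end1 = int(fields[1]), int(fields[2])
                strand = _SJ_STRAND[int(fields[3])]
                unique = int(fields[6])
            except (ValueError, KeyError):
                raise ValueError(f"{sj_path}: line {lineno}: malformed record") from None
            table.add(Junction(chrom, strand, start1 - 1, end1), unique)
    return table


def write_star_junctions(entries: Iterable[tuple[Junction, int]], out_path: str) -> None:
    """Write junctions + unique-read counts in the SJ.out.tab dialect."""
    with open(out_path, "w") as fh:
        for j, count in entries:
            fh.write(
                f"{j.chrom}\t{j.start + 1}\t{j.end}\t{_SJ_STRAND_CODE[j.strand]}\t0\t0\t{count}\t0\t30\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(vcf_path: str, depth_key: str = "AD") -> list:
    """Read a VCF 4.x into :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alt. Allele depth is
    taken from FORMAT/AD of the first sample (per-alt entry) or INFO/AD;
    a missing depth field leaves the record with depth unknown (logged).
    dbSNP membership comes from an INFO ``DBSNP`` flag or an ``rs``-prefixed
    ID; COSMIC recurrence from INFO ``COSMIC_CNT``.
    """
    from .models import VariantRecord

    out = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            in_dbsnp = bool(rec.info.get("DBSNP", False)) or (
                rec.id is not None and rec.id.startswith("rs")
            )
            cosmic = int(rec.info.get("COSMIC_CNT", 0))
            for ai, alt in enumerate(alts):
                depth: Optional[int] = None
                if rec.samples and depth_key in rec.format:
                    ad = rec.samples[0].get(depth_key)
                    if ad is not None and len(ad) > ai + 1 and ad[ai + 1] is not None:
                        depth = int(ad[ai + 1])
                elif depth_key in rec.info:
                    v = rec.info[depth_key]
                    depth = int(v[ai + 1] if isinstance(v, tuple) else v)
                if depth is None:
                    logger.info("variant %s:%d lacks %s; depth unknown", rec.chrom, rec.pos, depth_key)
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alt=alt,
                        allele_depth=depth,
                        in_dbsnp=in_dbsnp,
                        cosmic_sample_count=cosmic,
                        variant_id=rec.id or ".",
                    )
                )
    return out


def write_variants(
    variants: Sequence,
    contig_lengths: dict[str, int],
    out_path: str,
    sample: str = "TUMOR",
) -> None:
    """Write variants as a minimal single-sample VCF 4.2 with AD genotypes."""
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##INFO=<ID=DBSNP,Number=0,Type=Flag,Description="Registered in dbSNP">\n')
        fh.write('##INFO=<ID=COSMIC_CNT,Number=1,Type=Integer,Description="COSMIC sample count">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in variants:
            info_parts = []
            if v.in_dbsnp:
                info_parts.append("DBSNP")
            if v.cosmic_sample_count:
                info_parts.append(f"COSMIC_CNT={v.cosmic_sample_count}")
            info = ";".join(info_parts) or "."
            ad_str = "." if v.allele_depth is None else f"20,{v.allele_depth}"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT:AD\t0/1:{ad_str}\n"
            )
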