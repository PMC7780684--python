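"""Synthetic dataset generator with planted ground truth.

Generates, from a single seed, a toy genome with multi-exon gene models
(canonical GT/AG introns, clean coding sequences), planted aberrant
isoforms realizing each splicing-event type, long-read alignments with
configurable error/jitter/truncation behaviour plus decoy reads violating
each read-rejection rule, short-read junction support, somatic variants of
every consequence class, and tumor/normal cohort count tables — each with
truth labels for the downstream stage that consumes it.

The generator's defaults define the package's reference study conditions
(depth 30 per transcript, three genes per event type, noise-free reads);
every test that claims exact recovery runs under these conditions.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import (
    AlignedLongRead,
    GenomeRef,
    Interval,
    Junction,
    JunctionSupportTable,
    TranscriptModel,
    VariantRecord,
)

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]

EVENT_PLAN = (
    "exon_skipping",
    "intron_retention",
    "alt_5ss",
    "alt_3ss",
    "alt_first_exon",
    "alt_last_exon",
    "unannotated_exon",
    "exon_shuffling",
    "combination",
)


@dataclass
class SimParams:
    seed: int = 0
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (5, 7)
    exon_len_range: tuple[int, int] = (100, 220)
    intron_len_range: tuple[int, int] = (220, 320)
    utr5_len: int = 30
    utr3_len: int = 40
    read_depth: int = 30
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    truncation_probability: float = 0.0
    junction_jitter: int = 0
    events_per_type: int = 3
    sj_support: int = 25
    isoform_tpm: float = 50.0
    n_tumor: int = 3
    n_normal: int = 6
    cohort_library_size: int = 1_000_000
    decoys_per_rule: int = 1

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate, self.truncation_probability):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")
        if self.junction_jitter < 0:
            raise ValueError("jitter bound must be ≥ 0")


@dataclass
class PlantedIsoform:
    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    event_types: list[str]
    label: str
    expected_ptc: bool
    tpm: float

    def junctions(self) -> list[Junction]:
        return [
            Junction(self.chrom, self.strand, a[1], b[0])
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def chain_key(self) -> tuple:
        return (self.gene_id,) + tuple(
            (self.chrom, self.strand, a[1], b[0])
            for a, b in zip(self.exons, self.exons[1:])
        )


@dataclass
class SyntheticReference:
    genome: GenomeRef
    models: list[TranscriptModel]
    proteome: dict[str, str]  # transcript_id -> protein
    pseudogene_intervals: list[tuple[str, int, int]]
    mrnas: dict[str, str] = field(default_factory=dict)


@dataclass
class TruthSet:
    planted_isoforms: list[PlantedIsoform]
    planted_variants: list[tuple[VariantRecord, str]] = field(default_factory=list)
    cohort_truth: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


_AA: dict[str, str] = {}


def _init_codon_table() -> None:
    from Bio.Seq import Seq

    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                codon = a + b + c
                _AA[codon] = str(Seq(codon).translate())


_init_codon_table()


def make_reference(params: SimParams) -> SyntheticReference:
    """Build the toy genome, gene models and reference proteome.

    Every gene has ≥4 exons, GT/AG dinucleotides at each intron on the
    gene strand, and a CDS (ATG at transcript position ``utr5_len``,
    stop codon inside the last exon) that translates without internal
    stops. Genes destined for exon-shuffling isoforms get a second,
    non-coding transcript whose middle exon is mutually exclusive with
    the primary transcript's.
    """
    rng = random.Random(params.seed)
    chrom = "chr1"
    pieces: list[str] = []
    cursor = 0
    models: list[TranscriptModel] = []
    proteome: dict[str, str] = {}
    mrnas: dict[str, str] = {}

    n_shuffle_genes = params.events_per_type if params.events_per_type else 0

    for g in range(params.n_genes):
        gene_id = f"G{g:03d}"
        strand = "+" if g % 2 == 0 else "-"
        n_exons = rng.randint(*params.exons_per_gene)
        exon_lens = [rng.randint(*params.exon_len_range) for _ in range(n_exons)]
        exon_lens[-1] = max(exon_lens[-1], params.utr3_len + 60)  # stop stays in last exon
        intron_lens = [rng.randint(*params.intron_len_range) for _ in range(n_exons - 1)]
        L = sum(exon_lens)

        cds_len = ((L - params.utr5_len - params.utr3_len) // 3) * 3
        n_codons = cds_len // 3 - 2  # minus start and stop
        utr5 = _random_seq(rng, params.utr5_len)
        body = "".join(rng.choice(_CODONS) for _ in range(n_codons))
        cds = "ATG" + body + rng.choice(sorted(_STOPS))
        utr3 = _random_seq(rng, L - params.utr5_len - cds_len)
        mrna = utr5 + cds + utr3
        assert len(mrna) == L

        # split the mRNA across exons; introns are GT...AG on the gene strand
        exon_seqs = []
        off = 0
        for ln in exon_lens:
            exon_seqs.append(mrna[off : off + ln])
            off += ln
        intron_seqs = ["GT" + _random_seq(rng, ln - 4) + "AG" for ln in intron_lens]

        gene_strand_seq = exon_seqs[0]
        for iseq, eseq in zip(intron_seqs, exon_seqs[1:]):
            gene_strand_seq += iseq + eseq

        gene_start = cursor + 500  # spacer
        genomic_seq = gene_strand_seq if strand == "+" else _revcomp(gene_strand_seq)

        # exon coordinates in gene-strand order, then map to genome
        exons_gs: list[Interval] = []
        off = 0
        for ln, iln in zip(exon_lens, intron_lens + [0]):
            exons_gs.append((off, off + ln))
            off += ln + iln
        glen = len(gene_strand_seq)
        if strand == "+":
            exons = [(gene_start + s, gene_start + e) for s, e in exons_gs]
        else:
            exons = sorted((gene_start + glen - e, gene_start + glen - s) for s, e in exons_gs)

        # genomic coordinate of the start codon's first base (transcript sense)
        t_start = params.utr5_len
        if strand == "+":
            cds_start = gene_start + exons_gs[0][0] + t_start  # within exon 1
        else:
            cds_start = gene_start + glen - 1 - t_start

        tid = f"{gene_id}.t1"
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
            )
        )
        proteome[tid] = "M" + "".join(_AA[body[i : i + 3]] for i in range(0, len(body), 3))
        mrnas[tid] = mrna

        pieces.append(_random_seq(rng, 500) + genomic_seq)
        cursor = gene_start + len(genomic_seq)

    # pseudogene region in a dedicated spacer at the end
    pseudo_start = cursor + 200
    pieces.append(_random_seq(rng, 200) + _random_seq(rng, 300) + _random_seq(rng, 200))
    pseudogene = [(chrom, pseudo_start, pseudo_start + 300)]
    genome = GenomeRef({chrom: "".join(pieces)})

    ref = SyntheticReference(
        genome=genome,
        models=models,
        proteome=proteome,
        pseudogene_intervals=pseudogene,
        mrnas=mrnas,
    )

    # second transcripts with mutually exclusive middle exons for the genes
    # that will host exon-shuffling isoforms (chosen deterministically later)
    _add_shuffle_transcripts(ref, params, n_shuffle_genes)
    return ref


def _shuffle_gene_ids(params: SimParams) -> list[str]:
    """Genes reserved for exon shuffling: the last events_per_type genes."""
    start = params.n_genes - params.events_per_type
    return [f"G{g:03d}" for g in range(start, params.n_genes)]


def _add_shuffle_transcripts(ref: SyntheticReference, params: SimParams, n: int) -> None:
    for gene_id in _shuffle_gene_ids(params)[:n]:
        t1 = next(m for m in ref.models if m.gene_id == gene_id)
        exons = list(t1.exons)
        k = len(exons) // 2  # replace this internal exon
        intron = (exons[k][1], exons[k + 1][0])
        alt_exon = (intron[0] + 70, intron[0] + 130)
        # write GT/AG (gene strand) at the two new sub-intron boundaries
        chrom_seq = ref.genome.sequences[t1.chrom]
        if t1.strand == "+":
            edits = {alt_exon[0] - 2: "AG", alt_exon[1]: "GT"}
        else:
            # minus strand: the gene-strand GT of the upstream sub-intron sits
            # at the exon's genomic start (revcomp), the AG at its genomic end
            edits = {alt_exon[0] - 2: "AC", alt_exon[1]: "CT"}
        for pos, dinuc in edits.items():
            chrom_seq = chrom_seq[:pos] + dinuc + chrom_seq[pos + 2 :]
        ref.genome.sequences[t1.chrom] = chrom_seq
        alt_exons = exons[:k] + [alt_exon] + exons[k + 1 :]
        ref.models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t2",
                chrom=t1.chrom,
                strand=t1.strand,
                exons=alt_exons,
                cds_start=None,
            )
        )


# ---------------------------------------------------------------------------
# PTC truth oracle (generator-internal)
# ---------------------------------------------------------------------------

def _expected_ptc(
    exons: Sequence[Interval],
    strand: str,
    genome: GenomeRef,
    chrom: str,
    cds_start_genomic: Optional[int],
    min_distance: int = 50,
) -> bool:
    """Straight-line translation scan implementing the documented ORF/PTC
    policy, used to label planted isoforms with their expected flag."""
    exs = sorted(exons)
    seq = "".join(genome.fetch(chrom, s, e) for s, e in exs)
    if strand == "-":
        seq = _revcomp(seq)
    # transcript coordinate of the annotated start, if exonic
    tpos = None
    if cds_start_genomic is not None:
        acc = 0
        ordered = exs if strand == "+" else list(reversed(exs))
        for s, e in ordered:
            if s <= cds_start_genomic < e:
                tpos = acc + (
                    cds_start_genomic - s if strand == "+" else e - 1 - cds_start_genomic
                )
                break
            acc += e - s
    start = tpos if tpos is not None and seq[tpos : tpos + 3] == "ATG" else None
    if start is None:
        best = (-1, None)
        i = seq.find("ATG")
        while i != -1:
            n = 0
            j = i
            while j + 3 <= len(seq) and seq[j : j + 3] not in _STOPS:
                n += 1
                j += 3
            if n > best[0]:
                best = (n, i)
            i = seq.find("ATG", i + 1)
        start = best[1]
    if start is None:
        return False
    stop = None
    j = start
    while j + 3 <= len(seq):
        if seq[j : j + 3] in _STOPS:
            stop = j
            break
        j += 3
    if stop is None or len(exs) < 2:
        return False
    lens = [e - s for s, e in exs]
    if strand == "-":
        lens = lens[::-1]
    last_junction = sum(lens[:-1])
    return last_junction - (stop + 3) >= min_distance


# ---------------------------------------------------------------------------
# Isoform planting
# ---------------------------------------------------------------------------

def _plant_event(
    event: str,
    t1: TranscriptModel,
    rng: random.Random,
) -> Optional[list[Interval]]:
    """Realize one event on a gene's primary transcript; returns the
    isoform's exon chain or None when the gene cannot host the event."""
    exons = list(t1.exons)
    n = len(exons)
    if n < 4:
        return None
    strand = t1.strand

    if event == "exon_skipping":
        k = rng.randint(1, n - 2)
        return exons[:k] + exons[k + 1 :]

    if event == "intron_retention":
        k = rng.randint(0, max(0, n - 3))  # avoid the last intron: keep a junction downstream
        merged = (exons[k][0], exons[k + 1][1])
        return exons[:k] + [merged] + exons[k + 2 :]

    if event in ("alt_5ss", "alt_3ss"):
        j = rng.randint(1, n - 3)  # internal junction, away from terminal exons
        delta = 30
        donor_on_left = strand == "+"
        move_left = (event == "alt_5ss") == donor_on_left
        new = list(exons)
        if move_left:
            s, e = new[j]
            new[j] = (s, e - delta)  # truncate the left exon's end
        else:
            s, e = new[j + 1]
            new[j + 1] = (s + delta, e)  # truncate the right exon's start
        return new

    if event in ("alt_first_exon", "alt_last_exon"):
        # a novel terminal exon placed inside the flanking intron
        first_is_left = strand == "+"
        replace_left = (event == "alt_first_exon") == first_is_left
        if replace_left:
            intron = (exons[0][1], exons[1][0])
            if intron[1] - intron[0] < 200:
                return None
            novel = (intron[0] + 80, intron[0] + 140)
            return [novel] + exons[1:]
        intron = (exons[-2][1], exons[-1][0])
        if intron[1] - intron[0] < 200:
            return None
        novel = (intron[1] - 140, intron[1] - 80)
        return exons[:-1] + [novel]

    if event == "unannotated_exon":
        k = rng.randint(1, n - 3)
        intron = (exons[k][1], exons[k + 1][0])
        if intron[1] - intron[0] < 200:
            return None
        novel = (intron[0] + 70, intron[0] + 130)
        return exons[: k + 1] + [novel] + exons[k + 1 :]

    if event == "combination":
        # exon skipping early + intron retention later, distinct loci
        if n < 5:
            return None
        skipped = exons[:1] + exons[2:]  # skip exon 2 (index 1)
        m = len(skipped)
        merged = (skipped[m - 3][0], skipped[m - 2][1])  # retain a late intron
        return skipped[: m - 3] + [merged] + skipped[m - 1 :]

    raise ValueError(f"unknown event {event}")


def _plant_shuffling(t1: TranscriptModel, t2: TranscriptModel) -> list[Interval]:
    """Isoform containing both mutually exclusive exons of the gene."""
    exons = list(t1.exons)
    alt_exon = next(e for e in t2.exons if e not in exons)
    out = sorted(exons + [alt_exon])
    return out


def plant_isoforms(ref: SyntheticReference, params: SimParams) -> TruthSet:
    """Plant ``events_per_type`` isoforms of each event type.

    Each isoform lives on its own gene so labels never interact. Expected
    PTC flags come from the generator's internal translation scan.
    """
    rng = random.Random(params.seed + 1)
    by_gene = {}
    for m in ref.models:
        by_gene.setdefault(m.gene_id, []).append(m)
    shuffle_ids = _shuffle_gene_ids(params)
    plain_genes = [g for g in sorted(by_gene) if g not in shuffle_ids]

    needed = params.events_per_type * (len(EVENT_PLAN) - 1)
    if len(plain_genes) < needed:
        raise ValueError(
            f"need ≥{needed} non-shuffling genes for {params.events_per_type} "
            f"isoforms of each type; have {len(plain_genes)}"
        )

    planted: list[PlantedIsoform] = []
    gi = 0
    for event in EVENT_PLAN:
        for rep in range(params.events_per_type):
            if event == "exon_shuffling":
                gene_id = shuffle_ids[rep]
                t1 = next(m for m in by_gene[gene_id] if m.transcript_id.endswith(".t1"))
                t2 = next(m for m in by_gene[gene_id] if m.transcript_id.endswith(".t2"))
                exons = _plant_shuffling(t1, t2)
            else:
                exons = None
                while exons is None:
                    if gi >= len(plain_genes):
                        raise ValueError(f"no gene can host event {event}")
                    gene_id = plain_genes[gi]
                    gi += 1
                    t1 = by_gene[gene_id][0]
                    exons = _plant_event(event, t1, rng)
            label = "combination" if event == "combination" else event
            events = (
                ["exon_skipping", "intron_retention"] if event == "combination" else [event]
            )
            ptc = _expected_ptc(
                exons, t1.strand, ref.genome, t1.chrom, t1.cds_start
            )
            planted.append(
                PlantedIsoform(
                    isoform_id=f"PLANT_{event}_{rep}",
                    gene_id=gene_id,
                    chrom=t1.chrom,
                    strand=t1.strand,
                    exons=exons,
                    event_types=events,
                    label=label,
                    expected_ptc=ptc,
                    tpm=params.isoform_tpm,
                )
            )
    return TruthSet(planted_isoforms=planted)


# ---------------------------------------------------------------------------
# Long-read simulation
# ---------------------------------------------------------------------------

def _jitter_blocks(blocks: list[Interval], rng: random.Random, bound: int) -> list[Interval]:
    if bound == 0:
        return blocks
    out = [list(b) for b in blocks]
    for i in range(len(out) - 1):
        out[i][1] += rng.randint(-bound, bound)   # donor-side boundary
        out[i + 1][0] += rng.randint(-bound, bound)
    return [(b[0], b[1]) for b in out]


def _make_read(
    read_id: str,
    chrom: str,
    strand: str,
    blocks: list[Interval],
    rng: random.Random,
    params: SimParams,
) -> AlignedLongRead:
    aligned = sum(e - s for s, e in blocks)
    n_sub = int(aligned * params.substitution_rate)
    n_ins = int(aligned * params.indel_rate / 2)
    n_del = int(aligned * params.indel_rate / 2)
    return AlignedLongRead(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        blocks=blocks,
        n_match=aligned - n_sub - n_del,
        n_sub=n_sub,
        n_ins=n_ins,
        n_del=n_del,
        junction_insertions=[0] * (len(blocks) - 1),
    )


def simulate_long_reads(
    truth: TruthSet,
    ref: SyntheticReference,
    params: SimParams,
) -> tuple[list[AlignedLongRead], dict[str, str]]:
    """Simulate long-read alignments with per-read truth labels.

    Per gene: ``read_depth`` reads of the primary reference transcript
    (Type A material, truncated with ``truncation_probability`` into
    Type B mimics) and ``read_depth`` reads per planted isoform. Decoy
    reads violating each of the five rejection rules are appended with
    ``reject:<reason>`` labels.
    """
    rng = random.Random(params.seed + 2)
    reads: list[AlignedLongRead] = []
    labels: dict[str, str] = {}
    n = 0

    def emit(blocks, chrom, strand, label, **kw):
        nonlocal n
        rid = f"R{n:06d}"
        n += 1
        blocks = _jitter_blocks([tuple(b) for b in blocks], rng, params.junction_jitter)
        read = _make_read(rid, chrom, strand, blocks, rng, params)
        for k, v in kw.items():
            setattr(read, k, v)
        reads.append(read)
        labels[rid] = label
        return read

    primaries = [m for m in ref.models if m.transcript_id.endswith(".t1")]
    for t in primaries:
        for _ in range(params.read_depth):
            if params.truncation_probability and rng.random() < params.truncation_probability:
                # Type B mimic: contiguous exon run with ends inside exons
                n_ex = len(t.exons)
                i = rng.randint(0, n_ex - 2)
                j = rng.randint(i + 1, n_ex - 1)
                if i == 0 and j == n_ex - 1:
                    j -= 1  # a truncation must drop at least one junction
                blocks = list(t.exons[i : j + 1])
                s, e = blocks[0]
                blocks[0] = (min(s + rng.randint(5, 20), e - 30), e)
                s, e = blocks[-1]
                blocks[-1] = (s, max(e - rng.randint(5, 20), s + 30))
                emit(blocks, t.chrom, t.strand, f"truncation:{t.transcript_id}")
            else:
                emit(list(t.exons), t.chrom, t.strand, f"ref:{t.transcript_id}")

    for iso in truth.planted_isoforms:
        for _ in range(params.read_depth):
            emit(list(iso.exons), iso.chrom, iso.strand, f"iso:{iso.isoform_id}")

    # decoys, one batch per rejection rule
    t0 = primaries[0]
    for _ in range(params.decoys_per_rule):
        emit(list(t0.exons), t0.chrom, t0.strand, "reject:secondary_supplementary", is_secondary=True)

        bad = emit(list(t0.exons), t0.chrom, t0.strand, "reject:low_identity")
        total = bad.n_match + bad.n_sub + bad.n_ins + bad.n_del
        bad.n_sub = int(total * 0.21) + 1
        bad.n_match = total - bad.n_sub - bad.n_ins - bad.n_del

        bad = emit(list(t0.exons), t0.chrom, t0.strand, "reject:junction_insertion")
        bad.junction_insertions[0] = 11
        bad.n_ins += 11

        s, e = t0.exons[0]
        blocks = [(e - 24, e)] + list(t0.exons[1:])
        emit(blocks, t0.chrom, t0.strand, "reject:short_exon")

        pchrom, ps, pe = ref.pseudogene_intervals[0]
        emit([(ps + 10, ps + 210)], pchrom, "+", "reject:pseudogene")

    return reads, labels


# ---------------------------------------------------------------------------
# Short-read junction support and TPM
# ---------------------------------------------------------------------------

def simulate_short_read_junctions(
    truth: TruthSet,
    ref: SyntheticReference,
    params: SimParams,
    unsupported_isoforms: Sequence[str] = (),
) -> JunctionSupportTable:
    """Support every true junction at ``sj_support`` unique reads.

    Novel junctions of isoforms named in ``unsupported_isoforms`` get
    support 4 instead (one below the validation threshold) so the
    confirmation rule can be exercised.
    """
    ref_junctions = set()
    table = JunctionSupportTable()
    for m in ref.models:
        for j in m.junctions():
            ref_junctions.add((j.chrom, j.start, j.end))
            table.add(Junction(j.chrom, ".", j.start, j.end), params.sj_support)
    for iso in truth.planted_isoforms:
        low = iso.isoform_id in unsupported_isoforms
        for j in iso.junctions():
            if (j.chrom, j.start, j.end) in ref_junctions:
                continue
            table.add(Junction(j.chrom, ".", j.start, j.end), 4 if low else params.sj_support)
    return table


def truth_tpm_table(truth: TruthSet, ref: SyntheticReference, params: SimParams) -> dict[tuple, float]:
    """Chain-key → TPM map mirroring an external short-read quantifier."""
    return {iso.chain_key(): iso.tpm for iso in truth.planted_isoforms}


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _transcript_to_genomic(t: TranscriptModel, tpos: int) -> int:
    exs = sorted(t.exons)
    ordered = exs if t.strand == "+" else list(reversed(exs))
    acc = 0
    for s, e in ordered:
        if tpos < acc + (e - s):
            return s + (tpos - acc) if t.strand == "+" else e - 1 - (tpos - acc)
        acc += e - s
    raise ValueError("transcript position outside transcript")


def plant_variants(ref: SyntheticReference, params: SimParams) -> list[tuple[VariantRecord, str]]:
    """Plant one somatic variant per consequence class on plus-strand genes.

    Classes: missense, nonsense, in_frame (3-nt insertion), frameshift
    (1-nt deletion). Three filter decoys are appended: depth 4, dbSNP
    without COSMIC recurrence, and dbSNP with COSMIC count 5 (kept).
    """
    rng = random.Random(params.seed + 3)
    plus_coding = [m for m in ref.models if m.strand == "+" and m.cds_start is not None]
    out: list[tuple[VariantRecord, str]] = []
    genes = iter(plus_coding)

    def mrna_of(t):
        return ref.mrnas[t.transcript_id]

    def find_substitution(t, want_stop: bool):
        """First internal-codon substitution creating (or avoiding) a stop."""
        mrna = mrna_of(t)
        for codon_i in range(10, 60):
            tp = params.utr5_len + codon_i * 3
            codon = mrna[tp : tp + 3]
            for off in range(3):
                for alt_base in "ACGT":
                    cand = codon[:off] + alt_base + codon[off + 1 :]
                    if cand == codon:
                        continue
                    if want_stop and cand in _STOPS:
                        return tp + off, alt_base
                    if not want_stop and cand not in _STOPS and _AA[cand] != _AA[codon]:
                        return tp + off, alt_base
        return None

    t = next(genes)
    tp, alt = find_substitution(t, want_stop=False)
    g = _transcript_to_genomic(t, tp)
    out.append((VariantRecord(t.chrom, g, mrna_of(t)[tp], alt, allele_depth=20), "missense"))

    t = next(genes)
    tp, alt = find_substitution(t, want_stop=True)
    g = _transcript_to_genomic(t, tp)
    out.append((VariantRecord(t.chrom, g, mrna_of(t)[tp], alt, allele_depth=18), "nonsense"))

    # in-frame: 3-nt insertion after an anchor base early in the CDS (the
    # anchor and the next base must sit in the same exon so the VCF REF
    # string is genomically contiguous; the first exon is ≥100 bp)
    t = next(genes)
    mrna = mrna_of(t)
    tp = params.utr5_len + 15 * 3 - 1
    g = _transcript_to_genomic(t, tp)
    out.append(
        (VariantRecord(t.chrom, g, mrna[tp], mrna[tp] + "GCT", allele_depth=25), "in_frame")
    )

    # frameshift: 1-nt deletion early in the CDS (same contiguity concern)
    t = next(genes)
    mrna = mrna_of(t)
    tp = params.utr5_len + 12 * 3 - 1
    g = _transcript_to_genomic(t, tp)
    out.append(
        (
            VariantRecord(t.chrom, g, mrna[tp : tp + 2], mrna[tp], allele_depth=30),
            "frameshift",
        )
    )

    # filter decoys
    t = next(genes)
    mrna = mrna_of(t)
    tp = params.utr5_len + 12 * 3 + 1
    g = _transcript_to_genomic(t, tp)
    base = mrna[tp]
    alt = "A" if base != "A" else "G"
    out.append((VariantRecord(t.chrom, g, base, alt, allele_depth=4), "decoy_low_depth"))
    out.append(
        (
            VariantRecord(t.chrom, g + 3, mrna[tp + 3], "C" if mrna[tp + 3] != "C" else "T",
                          allele_depth=30, in_dbsnp=True),
            "decoy_dbsnp",
        )
    )
    out.append(
        (
            VariantRecord(t.chrom, g + 6, mrna[tp + 6], "C" if mrna[tp + 6] != "C" else "T",
                          allele_depth=30, in_dbsnp=True, cosmic_sample_count=5),
            "kept_dbsnp_cosmic",
        )
    )
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    tumor_counts: dict[str, dict[str, int]]  # sample -> feature key -> reads
    normal_counts: dict[str, dict[str, int]]
    library_size: int
    gtex_junction_counts: list[dict[Junction, int]]
    normal_expressed_isoform: Optional[str]  # planted in normals, fails the panel
    gtex_junction_isoform: Optional[str]  # carries a "normal" junction


def simulate_cohort(
    truth: TruthSet,
    ref: SyntheticReference,
    params: SimParams,
) -> CohortData:
    """Tumor/normal cohort feature counts with planted tumor specificity.

    Every planted isoform's specific features get 40 reads in each tumor
    sample and 0 in normals — except one isoform expressed across the
    normals (to exercise the panel-of-normals fold rule) and one whose
    novel junction is seen at ≥20 reads in >50% of the GTEx-style normal
    samples (to exercise the normal-junction filter). ``cohort_truth``
    lists the isoforms that remain genuinely tumor-specific.
    """
    from .requant import junction_feature

    rng = random.Random(params.seed + 4)
    isoforms = truth.planted_isoforms
    ref_junctions = {(j.chrom, j.start, j.end) for m in ref.models for j in m.junctions()}

    def novel_junction_features(iso: PlantedIsoform) -> list[str]:
        return [
            junction_feature(Junction(j.chrom, j.strand, j.start, j.end))
            for j in iso.junctions()
            if (j.chrom, j.start, j.end) not in ref_junctions
        ]

    with_novel = [iso for iso in isoforms if novel_junction_features(iso)]
    normal_expressed = with_novel[0].isoform_id if len(with_novel) > 2 else None
    gtex_iso = with_novel[1].isoform_id if len(with_novel) > 2 else None

    tumor_counts: dict[str, dict[str, int]] = {}
    normal_counts: dict[str, dict[str, int]] = {}
    for s in range(params.n_tumor):
        counts: dict[str, int] = {}
        for iso in isoforms:
            for f in novel_junction_features(iso):
                counts[f] = 40
        tumor_counts[f"tumor{s}"] = counts
    for s in range(params.n_normal):
        counts = {}
        if normal_expressed is not None:
            iso = next(i for i in isoforms if i.isoform_id == normal_expressed)
            for f in novel_junction_features(iso):
                counts[f] = 30  # tumor 40 < 2×30: fails the fold rule
        normal_counts[f"normal{s}"] = counts

    gtex: list[dict[Junction, int]] = []
    gtex_junctions = []
    if gtex_iso is not None:
        iso = next(i for i in isoforms if i.isoform_id == gtex_iso)
        gtex_junctions = [
            j for j in iso.junctions() if (j.chrom, j.start, j.end) not in ref_junctions
        ]
    n_expressing = int(params.n_normal * 0.6 + 1)  # strictly more than half
    for s in range(params.n_normal):
        sample: dict[Junction, int] = {}
        if s < n_expressing:
            for j in gtex_junctions:
                sample[j] = 25
        gtex.append(sample)

    excluded = {normal_expressed, gtex_iso}
    truth.cohort_truth = {
        f"tumor{s}": sorted(
            iso.isoform_id
            for iso in isoforms
            if novel_junction_features(iso) and iso.isoform_id not in excluded
        )
        for s in range(params.n_tumor)
    }
    return CohortData(
        tumor_counts=tumor_counts,
        normal_counts=normal_counts,
        library_size=params.cohort_library_size,
        gtex_junction_counts=gtex,
        normal_expressed_isoform=normal_expressed,
        gtex_junction_isoform=gtex_iso,
    )


# ---------------------------------------------------------------------------
# Whole-dataset convenience + disk emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    params: SimParams
    reference: SyntheticReference
    truth: TruthSet
    reads: list[AlignedLongRead]
    read_labels: dict[str, str]
    sj_table: JunctionSupportTable
    tpm: dict[tuple, float]
    cohort: CohortData


def simulate_dataset(params: Optional[SimParams] = None, **overrides) -> SyntheticDataset:
    """One-call generation of the full synthetic study."""
    if params is None:
        params = SimParams(**overrides)
    ref = make_reference(params)
    truth = plant_isoforms(ref, params)
    truth.planted_variants = plant_variants(ref, params)
    reads, labels = simulate_long_reads(truth, ref, params)
    sj = simulate_short_read_junctions(truth, ref, params)
    tpm = truth_tpm_table(truth, ref, params)
    cohort = simulate_cohort(truth, ref, params)
    return SyntheticDataset(params, ref, truth, reads, labels, sj, tpm, cohort)


def _read_to_segment(read: AlignedLongRead, header) -> "pysam.AlignedSegment":
    import pysam

    seg = pysam.AlignedSegment(header)
    seg.query_name = read.read_id
    seg.reference_id = list(header.references).index(read.chrom)
    seg.reference_start = read.blocks[0][0]
    seg.mapping_quality = 60
    flag = 0
    if read.strand == "-":
        flag |= 0x10
    if read.is_secondary:
        flag |= 0x100
    if read.is_supplementary:
        flag |= 0x800
    seg.flag = flag

    # spread the substitution/deletion tallies across blocks as X/D runs so
    # the identity fraction survives a SAM round trip exactly
    cig: list[tuple[int, int]] = []
    n_sub_left = read.n_sub
    n_ins_left = read.n_ins - sum(read.junction_insertions)
    n_del_left = read.n_del
    for i, (s, e) in enumerate(read.blocks):
        ln = e - s
        x = min(n_sub_left, max(0, ln - 2))
        d = min(n_del_left, max(0, ln - 2 - x))
        n_sub_left -= x
        n_del_left -= d
        cig.append((7, 1))
        if x:
            cig.append((8, x))
        if d:
            cig.append((2, d))
        if n_ins_left > 0:
            cig.append((1, n_ins_left))
            n_ins_left = 0
        cig.append((7, ln - 1 - x - d))
        if i < len(read.blocks) - 1:
            ji = read.junction_insertions[i]
            if ji:
                cig.append((1, ji))
            cig.append((3, read.blocks[i + 1][0] - e))
    seg.cigartuples = cig
    return seg


def write_dataset(ds: SyntheticDataset, outdir: str) -> dict[str, str]:
    """Emit the dataset to disk (FASTA/GTF/SAM/SJ/VCF/JSON) and return paths."""
    import os

    from . import io_formats

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.gtf"),
        "reads": os.path.join(outdir, "long_reads.sam"),
        "sj": os.path.join(outdir, "SJ.out.tab"),
        "vcf": os.path.join(outdir, "somatic.vcf"),
        "proteome": os.path.join(outdir, "proteome.fa"),
        "tpm": os.path.join(outdir, "tpm.tsv"),
        "pseudogenes": os.path.join(outdir, "pseudogenes.bed"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    with open(paths["pseudogenes"], "w") as fh:
        for chrom, s, e in ds.reference.pseudogene_intervals:
            fh.write(f"{chrom}\t{s}\t{e}\tpseudogene\n")
    with open(paths["tpm"], "w") as fh:
        for key, value in sorted(ds.tpm.items()):
            gene_id, juncs = key[0], key[1:]
            chain = ",".join(f"{c}:{s}:{a}:{b}" for c, s, a, b in juncs)
            fh.write(f"{gene_id}\t{chain}\t{value}\n")
    io_formats.write_fasta(ds.reference.genome.sequences, paths["genome"])
    io_formats.write_annotation(ds.reference.models, paths["annotation"])
    header = io_formats.sam_header(ds.reference.genome)
    io_formats.write_sam(
        (_read_to_segment(r, header) for r in ds.reads), header, paths["reads"]
    )
    io_formats.write_star_junctions(ds.sj_table.items(), paths["sj"])
    io_formats.write_variants(
        [v for v, _ in ds.truth.planted_variants],
        {c: len(s) for c, s in ds.reference.genome.sequences.items()},
        paths["vcf"],
    )
    io_formats.write_fasta(ds.reference.proteome, paths["proteome"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "planted_isoforms": [
                    {
                        "isoform_id": p.isoform_id,
                        "gene_id": p.gene_id,
                        "exons": p.exons,
                        "events": p.event_types,
                        "label": p.label,
                        "expected_ptc": p.expected_ptc,
                        "tpm": p.tpm,
                    }
                    for p in ds.truth.planted_isoforms
                ],
                "read_labels": ds.read_labels,
                "variants": [
                    {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "class": c}
                    for v, c in ds.truth.planted_variants
                ],
                "cohort_truth": ds.truth.cohort_truth,
            },
            fh,
            indent=1,
        )
    return paths
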