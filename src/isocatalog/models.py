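"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open throughout the package.
External formats (GTF, VCF, STAR SJ.out.tab) are converted at the I/O
boundary and back-converted on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

Interval = tuple[int, int]


@dataclass
class GenomeRef:
    """A reference genome held in memory as uppercase DNA strings."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            up = seq.upper()
            if set(up) - set("ACGTN"):
                raise ValueError(f"non-ACGTN characters in {name}")
            self.sequences[name] = up

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class TranscriptModel:
    """An annotated transcript: strand and ordered exon intervals.

    ``cds_start`` is the genomic coordinate of the first base of the
    annotated start codon (leftmost base for ``+``, rightmost for ``-``),
    or ``None`` for non-coding models.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_start: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon ({s},{e}) in {self.transcript_id}")
        for (a, b) in zip(self.exons, self.exons[1:]):
            if b[0] < a[1]:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, 0-based half-open."""
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]

    def junctions(self) -> list["Junction"]:
        return [Junction(self.chrom, self.strand, s, e) for s, e in self.introns]


@dataclass(frozen=True, order=True)
class Junction:
    """One intron: (chrom, strand, intron_start, intron_end), half-open.

    Strand ``.`` is the strand-unknown wildcard used by unstranded
    short-read junction tables; it matches either strand on coordinates
    (see :func:`junctions_compatible`).
    """

    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty intron ({self.start},{self.end})")


def junctions_compatible(a: Junction, b: Junction) -> bool:
    """Coordinate equality with the strand-unknown wildcard rule."""
    return (
        a.chrom == b.chrom
        and a.start == b.start
        and a.end == b.end
        and (a.strand == b.strand or "." in (a.strand, b.strand))
    )


@dataclass
class AlignedLongRead:
    """One spliced long-read alignment.

    ``blocks`` are the exonic segments (M/=/X/D runs split at N).
    ``junction_insertions[i]`` counts read bases inserted immediately
    adjacent to intron ``i`` — the "unmapped length within splice
    junctions" used by the read filter.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: list[Interval]
    n_match: int = 0
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    is_secondary: bool = False
    is_supplementary: bool = False
    junction_insertions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks = [tuple(b) for b in self.blocks]
        if any(e <= s for s, e in self.blocks):
            raise ValueError("empty block")
        if self.blocks != sorted(self.blocks):
            raise ValueError("blocks out of order")
        if len(self.junction_insertions) != max(0, len(self.blocks) - 1):
            raise ValueError("junction_insertions length must be n_blocks - 1")
        for v in (self.n_match, self.n_sub, self.n_ins, self.n_del):
            if v < 0:
                raise ValueError("negative base tally")

    @property
    def introns(self) -> list[Interval]:
        return [(a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])]

    def junctions(self) -> list[Junction]:
        return [Junction(self.chrom, self.strand, s, e) for s, e in self.introns]


class JunctionSupportTable:
    """Unique-read support per junction from short-read alignment.

    Lookup honours the strand-unknown wildcard: a table entry recorded
    with strand ``.`` answers queries on either strand.
    """

    def __init__(self, counts: Optional[dict[Junction, int]] = None):
        self._by_coord: dict[tuple[str, int, int], dict[str, int]] = {}
        for j, c in (counts or {}).items():
            self.add(j, c)

    def add(self, junction: Junction, count: int) -> None:
        if count < 0:
            raise ValueError("negative support")
        d = self._by_coord.setdefault((junction.chrom, junction.start, junction.end), {})
        d[junction.strand] = d.get(junction.strand, 0) + count

    def support(self, junction: Junction) -> int:
        d = self._by_coord.get((junction.chrom, junction.start, junction.end))
        if not d:
            return 0
        if junction.strand == ".":
            return max(d.values())
        return max(d.get(junction.strand, 0), d.get(".", 0))

    def junctions_near(self, chrom: str, start: int, end: int, margin: int):
        """All table junctions whose both boundaries are within ±margin."""
        out = []
        for (c, s, e), d in self._by_coord.items():
            if c == chrom and abs(s - start) <= margin and abs(e - end) <= margin:
                for strand, n in d.items():
                    out.append((Junction(c, strand, s, e), n))
        return out

    def __len__(self) -> int:
        return sum(len(d) for d in self._by_coord.values())

    def items(self):
        for (c, s, e), d in self._by_coord.items():
            for strand, n in d.items():
                yield Junction(c, strand, s, e), n


@dataclass
class VariantRecord:
    """A single-alt variant with the annotation flags the somatic filter needs."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    allele_depth: Optional[int] = None  # None = unknown (depth field absent)
    in_dbsnp: bool = False
    cosmic_sample_count: int = 0
    variant_id: str = "."

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.allele_depth is not None and self.allele_depth < 0:
            raise ValueError("negative allele depth")


class ReadClass(Enum):
    """Outcome of comparing a read's junction chain to the reference model."""

    TYPE_A = "type_a"  # identical to a reference transcript (ends ignored)
    TYPE_B = "type_b"  # truncation of a reference transcript
    ISOFORM_CANDIDATE = "isoform_candidate"
    UNCONFIRMED = "unconfirmed"  # novel junction lacking short-read support


@dataclass
class IsoformCandidate:
    """A merged junction-chain pattern with its supporting evidence."""

    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    junctions: tuple[Junction, ...]
    exons: list[Interval]
    supporting_read_ids: list[str] = field(default_factory=list)
    tpm: Optional[float] = None
    event_labels: list[str] = field(default_factory=list)
    label: Optional[str] = None
    ptc_flag: Optional[bool] = None

    @property
    def minion_read_count(self) -> int:
        return len(self.supporting_read_ids)

    def chain_key(self) -> tuple:
        return (self.gene_id,) + tuple(
            (j.chrom, j.strand, j.start, j.end) for j in self.junctions
        )


@dataclass
class PeptideCandidate:
    """A novel 9-mer with its source and (optional) HLA binding rank."""

    peptide: str
    source: str
    source_class: str  # isoform | frameshift | missense | in_frame
    hla_allele: Optional[str] = None
    percent_rank: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.peptide) != 9:
            raise ValueError("peptides are 9-mers")
        if set(self.peptide) - set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(f"non-standard residue in {self.peptide}")

    @property
    def strong_binder(self) -> Optional[bool]:
        if self.percent_rank is None:
            return None
        return self.percent_rank < 0.5


def group_by_gene(models: Sequence[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    out: dict[str, list[TranscriptModel]] = {}
    for m in models:
        out.setdefault(m.gene_id, []).append(m)
    return out
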