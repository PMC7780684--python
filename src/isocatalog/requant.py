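"""Cohort re-quantification, panel-of-normals filtering and catalog statistics.

A catalog isoform is re-quantified in short-read samples through its
*specific features*: junctions and exonic intervals present in that isoform
but in no reference transcript and no sibling isoform of the gene. An
isoform counts as detected in a sample when any specific feature carries at
least 20 reads. Tumor-specific selection supports two modes: a TCGA-style
panel of normals (max RPM over ≥5 normals, two-fold enrichment, GTEx-style
normal-junction exclusion) and a clinical tumor/normal pair rule (TPM ≥ 10,
fold change ≥ 2).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .models import (
    AlignedLongRead,
    GenomeRef,
    Interval,
    IsoformCandidate,
    Junction,
    JunctionSupportTable,
    TranscriptModel,
)

UPF1_MOTIFS = ("CCUGGGG", "CCUGGGA", "CCUGGAA", "CCUGAGA")


def junction_feature(j: Junction) -> str:
    return f"{j.chrom}:{j.start}-{j.end}:{j.strand}:J"


def exon_feature(chrom: str, iv: Interval, strand: str) -> str:
    return f"{chrom}:{iv[0]}-{iv[1]}:{strand}:E"


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def extract_specific_features(
    catalog: Sequence[IsoformCandidate],
    reference_models: Sequence[TranscriptModel],
) -> dict[str, set[str]]:
    """Per-isoform feature sets usable for isoform-specific counting.

    Features are (a) junctions absent from every reference transcript and
    (b) exonic intervals that either fully span a reference intron
    (retention) or overlap no reference exon (novel exons) — minus any
    feature shared with another catalog isoform of the same gene. Isoforms
    left with no feature map to an empty set (unquantifiable).
    """
    ref_junctions: set[tuple] = set()
    ref_exons: list[tuple[str, Interval]] = []
    ref_introns: list[tuple[str, Interval]] = []
    for t in reference_models:
        for iv in t.introns:
            ref_junctions.add((t.chrom, iv[0], iv[1]))
        ref_exons.extend((t.chrom, e) for e in t.exons)
        ref_introns.extend((t.chrom, iv) for iv in t.introns)

    raw: dict[str, set[str]] = {}
    for iso in catalog:
        feats: set[str] = set()
        for j in iso.junctions:
            if (j.chrom, j.start, j.end) not in ref_junctions:
                feats.add(junction_feature(j))
        for exon in iso.exons:
            spans_intron = any(
                c == iso.chrom and exon[0] < iv[0] and exon[1] > iv[1]
                for c, iv in ref_introns
            )
            no_exon_overlap = all(
                not (c == iso.chrom and _overlap(exon, e) > 0) for c, e in ref_exons
            )
            if spans_intron or no_exon_overlap:
                feats.add(exon_feature(iso.chrom, exon, iso.strand))
        raw[iso.isoform_id] = feats

    # remove features shared between sibling isoforms of the same gene
    by_gene: dict[str, list[IsoformCandidate]] = {}
    for iso in catalog:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    out: dict[str, set[str]] = {}
    for gene, isos in by_gene.items():
        for iso in isos:
            shared = set()
            for other in isos:
                if other.isoform_id != iso.isoform_id:
                    shared |= raw[other.isoform_id]
            out[iso.isoform_id] = raw[iso.isoform_id] - shared
    return out


def count_isoforms_in_sample(
    sample_feature_counts: dict[str, int],
    features: dict[str, set[str]],
    min_reads: int = 20,
) -> dict[str, int]:
    """Detected isoforms (any specific feature ≥ ``min_reads``) with the
    max read count over their features."""
    out = {}
    for iso_id, feats in features.items():
        if not feats:
            continue
        best = max((sample_feature_counts.get(f, 0) for f in feats), default=0)
        if best >= min_reads:
            out[iso_id] = best
    return out


def rpm(counts: dict[str, int], library_size: int) -> dict[str, float]:
    """Reads per million: count × 1e6 / library size."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return {k: v * 1e6 / library_size for k, v in counts.items()}


def build_panel_of_normals(
    normal_rpm_tables: Sequence[dict[str, float]],
    min_normals: int = 5,
) -> dict[str, float]:
    """Per-isoform max RPM across ≥5 normal samples.

    Isoforms absent from every normal get panel value 0 implicitly
    (lookups default to 0).
    """
    if len(normal_rpm_tables) < min_normals:
        raise ValueError(
            f"panel of normals requires at least {min_normals} normal samples, "
            f"got {len(normal_rpm_tables)}"
        )
    panel: dict[str, float] = {}
    for table in normal_rpm_tables:
        for iso, v in table.items():
            panel[iso] = max(panel.get(iso, 0.0), v)
    return panel


def build_normal_junction_set(
    per_sample_junction_counts: Sequence[dict[Junction, int]],
    min_reads: int = 20,
    min_fraction: float = 0.5,
) -> set[Junction]:
    """Junctions seen at ≥ ``min_reads`` in strictly more than
    ``min_fraction`` of the samples."""
    n = len(per_sample_junction_counts)
    if n == 0:
        return set()
    tally: dict[Junction, int] = {}
    for sample in per_sample_junction_counts:
        for j, c in sample.items():
            if c >= min_reads:
                tally[j] = tally.get(j, 0) + 1
    return {j for j, k in tally.items() if k / n > min_fraction}


def select_tumor_specific(
    tumor_values: dict[str, float],
    features: dict[str, set[str]],
    mode: str = "tcga",
    panel: Optional[dict[str, float]] = None,
    normal_junctions: Optional[set[Junction]] = None,
    normal_values: Optional[dict[str, float]] = None,
    fold: float = 2.0,
    min_clinical_tpm: float = 10.0,
) -> list[str]:
    """Tumor-specific isoform selection.

    TCGA mode: tumor RPM ≥ fold × panel value (panel 0 ⇒ any positive
    expression passes) and no isoform-specific junction in the normal
    junction set. Clinical mode: tumor TPM ≥ 10 and tumor/normal fold
    change ≥ 2 (normal 0 ⇒ passes).
    """
    normal_junction_keys = {junction_feature(j) for j in (normal_junctions or set())}
    out = []
    for iso_id, value in sorted(tumor_values.items()):
        if mode == "tcga":
            pv = (panel or {}).get(iso_id, 0.0)
            if pv == 0.0:
                if value <= 0:
                    continue
            elif value < fold * pv:
                continue
            specific_junctions = {
                f for f in features.get(iso_id, set()) if f.endswith(":J")
            }
            if specific_junctions & normal_junction_keys:
                continue
        elif mode == "clinical":
            if value < min_clinical_tpm:
                continue
            nv = (normal_values or {}).get(iso_id, 0.0)
            if nv > 0 and value / nv < fold:
                continue
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append(iso_id)
    return out


def nmd_mutation_association(
    counts_mutated: Sequence[float],
    counts_wildtype: Sequence[float],
) -> float:
    """One-tailed Mann–Whitney U p-value for NMD-factor-mutated samples
    carrying MORE isoforms than wild-type samples (exact for small n)."""
    if not counts_mutated or not counts_wildtype:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (len(counts_mutated) <= 8 and len(counts_wildtype) <= 8) else "auto"
    res = stats.mannwhitneyu(
        counts_mutated, counts_wildtype, alternative="greater", method=method
    )
    return float(res.pvalue)


def scan_motifs(
    sequences: Sequence[str],
    motifs: Sequence[str] = UPF1_MOTIFS,
) -> tuple[list[tuple[int, str, int]], int]:
    """Scan RNA-sense sequences for the p-UPF1 binding motifs (U ≡ T).

    Returns (hits, n_sequences_with_hit) where each hit is
    (sequence index, motif, position); overlapping occurrences are all
    reported.
    """
    dna_motifs = [m.replace("U", "T").upper() for m in motifs]
    hits = []
    n_with = 0
    for idx, seq in enumerate(sequences):
        s = seq.upper().replace("U", "T")
        found = False
        for motif, dna in zip(motifs, dna_motifs):
            start = s.find(dna)
            while start != -1:
                hits.append((idx, motif, start))
                found = True
                start = s.find(dna, start + 1)
        if found:
            n_with += 1
    return hits, n_with


def extract_windows(
    genome: GenomeRef,
    sites: Sequence[tuple[str, int, str]],
    half_width: int = 50,
) -> list[tuple[str, bool]]:
    """±half_width windows around splice-site positions, strand-oriented.

    A site (chrom, pos, strand) yields the interval
    (pos − half_width, pos + half_width + 1), clipped at the chromosome
    bounds (clipping flagged); minus-strand windows are
    reverse-complemented.
    """
    from Bio.Seq import Seq

    out = []
    for chrom, pos, strand in sites:
        chrom_len = len(genome.sequences[chrom])
        lo, hi = pos - half_width, pos + half_width + 1
        clipped = lo < 0 or hi > chrom_len
        seq = genome.fetch(chrom, max(0, lo), min(chrom_len, hi))
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out.append((seq, clipped))
    return out


@dataclass
class SubsampleResult:
    fractions: list[float]
    # isoform chain key -> {fraction: detection probability}
    probabilities: dict[tuple, dict[float, float]]


def subsample_detection(
    reads_by_gene: dict[str, list[AlignedLongRead]],
    annotation_by_gene: dict[str, list[TranscriptModel]],
    support: JunctionSupportTable,
    tpm: dict[tuple, float],
    fractions: Sequence[float] = (0.5, 0.2, 0.1, 0.02, 0.01),
    n_reps: int = 100,
    seed: int = 0,
    params=None,
) -> SubsampleResult:
    """Detection probability per catalog isoform under read subsampling.

    For each fraction and replicate, reads are drawn without replacement,
    detection is re-run with the coverage filter rescaled to the
    subsampled total, and the probability is the share of replicates in
    which the isoform's chain reappears in the catalog.
    """
    from .detection import detect_isoforms

    baseline, _ = detect_isoforms(reads_by_gene, annotation_by_gene, support, tpm, params=params)
    targets = {iso.chain_key() for iso in baseline}
    all_reads = [
        (gene, read) for gene, reads in reads_by_gene.items() for read in reads
    ]
    rng = random.Random(seed)
    probs: dict[tuple, dict[float, float]] = {t: {} for t in targets}
    for frac in fractions:
        n_draw = max(1, round(frac * len(all_reads)))
        detected_counts = {t: 0 for t in targets}
        for _ in range(n_reps):
            sample = rng.sample(all_reads, n_draw) if frac < 1.0 else all_reads
            by_gene: dict[str, list[AlignedLongRead]] = {}
            for gene, read in sample:
                by_gene.setdefault(gene, []).append(read)
            catalog, _ = detect_isoforms(by_gene, annotation_by_gene, support, tpm, params=params)
            got = {iso.chain_key() for iso in catalog}
            for t in targets & got:
                detected_counts[t] += 1
        for t in targets:
            probs[t][frac] = detected_counts[t] / n_reps
    return SubsampleResult(fractions=list(fractions), probabilities=probs)
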