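"""Classification of novel splicing features into event types.

Each catalog isoform is compared against the union of its gene's annotated
transcripts and every novel feature is assigned one of eight event types —
alternative 5'/3' splice site, alternative first/last exon, intron
retention, exon skipping, exon shuffling, unannotated exon — with isoforms
carrying two or more event instances labelled "combination".

Rules are evaluated in a documented precedence order (terminal-exon events
first, then intron retention, exon skipping, unannotated exon, alternative
splice sites, and exon shuffling last); junctions explained by an earlier
event are not re-counted by a later rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import Interval, IsoformCandidate, TranscriptModel

ALT_5SS = "alt_5ss"
ALT_3SS = "alt_3ss"
ALT_FIRST_EXON = "alt_first_exon"
ALT_LAST_EXON = "alt_last_exon"
INTRON_RETENTION = "intron_retention"
EXON_SKIPPING = "exon_skipping"
EXON_SHUFFLING = "exon_shuffling"
UNANNOTATED_EXON = "unannotated_exon"
COMBINATION = "combination"

EVENT_TYPES = (
    ALT_5SS,
    ALT_3SS,
    ALT_FIRST_EXON,
    ALT_LAST_EXON,
    INTRON_RETENTION,
    EXON_SKIPPING,
    EXON_SHUFFLING,
    UNANNOTATED_EXON,
)


@dataclass
class EventCall:
    event_type: str
    intervals: list[Interval] = field(default_factory=list)
    junctions: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type}")


@dataclass
class _GeneAnnotation:
    """Pre-computed boundary/exon sets for one gene."""

    exons: list[Interval]
    first_exons: list[Interval]  # 5'-most exon of each transcript
    last_exons: list[Interval]
    intron_lefts: set[int]
    intron_rights: set[int]
    junction_pairs: set[Interval]
    introns_by_transcript: list[list[Interval]]
    exons_by_transcript: list[list[Interval]]
    strand: str


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _gene_annotation(transcripts: Sequence[TranscriptModel]) -> _GeneAnnotation:
    exons: list[Interval] = []
    first, last = [], []
    lefts: set[int] = set()
    rights: set[int] = set()
    pairs: set[Interval] = set()
    for t in transcripts:
        exons.extend(t.exons)
        if t.strand == "+":
            first.append(t.exons[0])
            last.append(t.exons[-1])
        else:
            first.append(t.exons[-1])
            last.append(t.exons[0])
        for (s, e) in t.introns:
            lefts.add(s)
            rights.add(e)
            pairs.add((s, e))
    return _GeneAnnotation(
        exons=exons,
        first_exons=first,
        last_exons=last,
        intron_lefts=lefts,
        intron_rights=rights,
        junction_pairs=pairs,
        introns_by_transcript=[t.introns for t in transcripts],
        exons_by_transcript=[list(t.exons) for t in transcripts],
        strand=transcripts[0].strand,
    )


def annotate_sites(
    junction: Interval,
    transcripts: Sequence[TranscriptModel],
) -> tuple[bool, bool, Optional[tuple[Optional[Interval], Optional[Interval]]]]:
    """Donor/acceptor annotation flags for one junction, strand-aware.

    Returns (donor_annotated, acceptor_annotated, (donor_exon, acceptor_exon))
    where the exons are the annotated exons owning each annotated boundary
    (None for a novel boundary).
    """
    ann = _gene_annotation(transcripts)
    s, e = junction
    left_ann = s in ann.intron_lefts
    right_ann = e in ann.intron_rights
    left_exon = next((x for x in ann.exons if x[1] == s), None)
    right_exon = next((x for x in ann.exons if x[0] == e), None)
    if ann.strand == "+":
        donor_ann, acceptor_ann = left_ann, right_ann
        adjacency = (left_exon, right_exon)
    else:
        donor_ann, acceptor_ann = right_ann, left_ann
        adjacency = (right_exon, left_exon)
    if not (left_exon or right_exon):
        return donor_ann, acceptor_ann, None
    return donor_ann, acceptor_ann, adjacency


def _is_skipping(junction: Interval, ann: _GeneAnnotation) -> Optional[list[Interval]]:
    """Skipped annotated exons if the junction joins non-adjacent exons of
    some single transcript; None otherwise."""
    s, e = junction
    for exons in ann.exons_by_transcript:
        i = next((k for k, x in enumerate(exons) if x[1] == s), None)
        j = next((k for k, x in enumerate(exons) if x[0] == e), None)
        if i is not None and j is not None and j >= i + 2:
            return exons[i + 1 : j]
    return None


def classify_events(
    isoform: IsoformCandidate,
    transcripts: Sequence[TranscriptModel],
) -> list[EventCall]:
    """Emit one :class:`EventCall` per novel feature of the isoform."""
    ann = _gene_annotation(transcripts)
    strand = isoform.strand
    exons = list(isoform.exons)
    junctions = [(j.start, j.end) for j in isoform.junctions]
    novel = [j for j in junctions if j not in ann.junction_pairs]
    consumed: set[Interval] = set()
    calls: list[EventCall] = []

    # --- terminal exons (alternative first / last) ---------------------
    if junctions:
        for side in ("left", "right"):
            if side == "left":
                term_exon, term_junction = exons[0], junctions[0]
            else:
                term_exon, term_junction = exons[-1], junctions[-1]
            if term_junction in ann.junction_pairs:
                continue  # joined into the body by an annotated junction
            is_first = (side == "left") == (strand == "+")
            ref_terms = ann.first_exons if is_first else ann.last_exons
            if all(_overlap(term_exon, x) == 0 for x in ref_terms):
                # must join into the annotated body: the body-side boundary
                # of its junction is an annotated boundary
                body_ok = (
                    term_junction[1] in ann.intron_rights
                    if side == "left"
                    else term_junction[0] in ann.intron_lefts
                )
                if body_ok:
                    calls.append(
                        EventCall(
                            ALT_FIRST_EXON if is_first else ALT_LAST_EXON,
                            intervals=[term_exon],
                            junctions=[term_junction],
                        )
                    )
                    consumed.add(term_junction)

    # --- intron retention ----------------------------------------------
    retained: set[Interval] = set()
    for exon in exons:
        for intron in {iv for introns in ann.introns_by_transcript for iv in introns}:
            if exon[0] < intron[0] and exon[1] > intron[1] and intron not in retained:
                # novel only if no annotated exon already spans this intron
                if any(x[0] < intron[0] and x[1] > intron[1] for x in ann.exons):
                    continue
                retained.add(intron)
                calls.append(EventCall(INTRON_RETENTION, intervals=[exon], junctions=[intron]))

    # --- exon skipping ---------------------------------------------------
    for j in novel:
        if j in consumed:
            continue
        if j[0] in ann.intron_lefts and j[1] in ann.intron_rights:
            skipped = _is_skipping(j, ann)
            if skipped is not None:
                calls.append(EventCall(EXON_SKIPPING, intervals=skipped, junctions=[j]))
                consumed.add(j)

    # --- unannotated internal exon --------------------------------------
    for exon in exons[1:-1]:
        if all(_overlap(exon, x) == 0 for x in ann.exons):
            flanks = [j for j in junctions if j[1] == exon[0] or j[0] == exon[1]]
            calls.append(EventCall(UNANNOTATED_EXON, intervals=[exon], junctions=flanks))
            consumed.update(flanks)

    # --- alternative 5'/3' splice sites ----------------------------------
    for j in novel:
        if j in consumed:
            continue
        left_ann = j[0] in ann.intron_lefts
        right_ann = j[1] in ann.intron_rights
        if left_ann == right_ann:
            continue  # both novel or both annotated: not an alt-ss call
        novel_is_left = not left_ann
        donor_novel = novel_is_left == (strand == "+")
        calls.append(EventCall(ALT_5SS if donor_novel else ALT_3SS, junctions=[j]))
        consumed.add(j)

    # --- exon shuffling (annotated boundaries, unexplained pairing) ------
    for j in novel:
        if j in consumed:
            continue
        if j[0] in ann.intron_lefts and j[1] in ann.intron_rights:
            calls.append(EventCall(EXON_SHUFFLING, junctions=[j]))
            consumed.add(j)

    return calls


def label_isoform(calls: Sequence[EventCall]) -> str:
    """Single event type, or "combination" for ≥2 calls of any types."""
    if not calls:
        raise ValueError("annotated: isoform has no novel feature")
    if len(calls) == 1:
        return calls[0].event_type
    return COMBINATION


def classify_catalog(
    catalog: Sequence[IsoformCandidate],
    annotation_by_gene: dict[str, list[TranscriptModel]],
) -> None:
    """Fill ``event_labels`` and ``label`` in place for every catalog isoform."""
    for iso in catalog:
        calls = classify_events(iso, annotation_by_gene[iso.gene_id])
        iso.event_labels = [c.event_type for c in calls]
        iso.label = label_isoform(calls) if calls else None


def summarize_events(
    catalogs_by_sample: dict[str, Sequence[IsoformCandidate]],
) -> dict:
    """Per-type counts per sample, multi-isoform genes, cross-sample sharing.

    Sharing is exact junction-chain identity across samples.
    """
    per_sample_counts: dict[str, dict[str, int]] = {}
    gene_isoforms: dict[str, set[str]] = {}
    chain_samples: dict[tuple, set[str]] = {}
    for sample, catalog in catalogs_by_sample.items():
        counts: dict[str, int] = {}
        for iso in catalog:
            if iso.label is not None:
                counts[iso.label] = counts.get(iso.label, 0) + 1
            gene_isoforms.setdefault(iso.gene_id, set()).add(iso.isoform_id)
            chain_samples.setdefault(iso.chain_key(), set()).add(sample)
        per_sample_counts[sample] = counts
    return {
        "per_sample_counts": per_sample_counts,
        "genes_with_multiple_isoforms": sorted(
            g for g, ids in gene_isoforms.items() if len(ids) >= 2
        ),
        "shared_chains": {k: sorted(v) for k, v in chain_samples.items() if len(v) >= 2},
    }
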