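"""End-to-end orchestration: filter → detect → classify → PTC-flag."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .detection import CatalogFilterParams, detect_isoforms
from .events import classify_catalog
from .filtering import FilterParams, RejectionLog, filter_and_assign
from .models import (
    AlignedLongRead,
    GenomeRef,
    IsoformCandidate,
    JunctionSupportTable,
    ReadClass,
    TranscriptModel,
    group_by_gene,
)
from .orf import NmdRuleParams, annotate_catalog_ptc


@dataclass
class PipelineResult:
    catalog: list[IsoformCandidate]
    rejection_log: RejectionLog
    read_classes: dict[str, ReadClass]
    reads_by_gene: dict[str, list[AlignedLongRead]]


def run_catalog_pipeline(
    reads: Sequence[AlignedLongRead],
    annotation: Sequence[TranscriptModel],
    support: JunctionSupportTable,
    tpm: dict[tuple, float],
    genome: Optional[GenomeRef] = None,
    filter_params: Optional[FilterParams] = None,
    catalog_params: Optional[CatalogFilterParams] = None,
    nmd_params: Optional[NmdRuleParams] = None,
) -> PipelineResult:
    """Run the full catalog pipeline on in-memory inputs.

    Reads are filtered by the five rejection rules, short introns are
    corrected, reads are assigned to genes, isoforms are detected against
    the annotation with short-read junction confirmation, events are
    classified, and (when a genome is supplied) PTC flags are computed.
    """
    annotation_by_gene = group_by_gene(annotation)
    reads_by_gene, log = filter_and_assign(reads, annotation, filter_params)
    catalog, read_classes = detect_isoforms(
        reads_by_gene, annotation_by_gene, support, tpm, params=catalog_params
    )
    classify_catalog(catalog, annotation_by_gene)
    if genome is not None:
        annotate_catalog_ptc(catalog, genome, annotation_by_gene, nmd_params)
    return PipelineResult(
        catalog=catalog,
        rejection_log=log,
        read_classes=read_classes,
        reads_by_gene=reads_by_gene,
    )
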