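"""Shared fixtures: one noise-free synthetic study reused across the suite."""

from __future__ import annotations

import pytest

from isocatalog import SimParams, run_catalog_pipeline, simulate_dataset
from isocatalog.filtering import FilterParams

SEED = 11


@pytest.fixture(scope="session")
def dataset():
    """Noise-free study: 30 genes, 3 isoforms per event type, depth 30."""
    return simulate_dataset(SimParams(seed=SEED))


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    fp = FilterParams(pseudogene_intervals=dataset.reference.pseudogene_intervals)
    return run_catalog_pipeline(
        dataset.reads,
        dataset.reference.models,
        dataset.sj_table,
        dataset.tpm,
        genome=dataset.reference.genome,
        filter_params=fp,
    )


@pytest.fixture(scope="session")
def toy_gene():
    """A hand-built 5-exon plus-strand gene on a tiny genome."""
    from isocatalog.models import GenomeRef, TranscriptModel

    import random

    rng = random.Random(5)
    seq = "".join(rng.choice("ACGT") for _ in range(3000))
    exons = [(100, 200), (400, 500), (700, 800), (1000, 1100), (1300, 1400)]
    model = TranscriptModel("GX", "GX.t1", "chrT", "+", exons, cds_start=130)
    return GenomeRef({"chrT": seq}), model
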