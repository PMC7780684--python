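"""Enumerate candidate neoantigen 9-mers from isoforms and somatic variants.

Somatic variants pass an allele-depth ≥ 5 filter (dbSNP entries need ≥ 5
COSMIC samples), are applied onto transcript CDSs, and every 9-mer
overlapping an altered protein region is checked against the reference
peptidome. Survivors are scored per HLA allele; %rank < 0.5 = strong
binder. The scorer here is the deterministic mock (no external predictor).
"""

from isocatalog import (
    MockBindingScorer,
    SimParams,
    build_reference_peptidome,
    run_catalog_pipeline,
    simulate_dataset,
)
from isocatalog.filtering import FilterParams
from isocatalog.models import group_by_gene
from isocatalog.neoantigen import (
    call_isoform_peptides,
    call_variant_peptides,
    filter_somatic_variants,
    score_and_call,
    tabulate_by_source,
)

ds = simulate_dataset(SimParams(seed=7))
result = run_catalog_pipeline(
    ds.reads, ds.reference.models, ds.sj_table, ds.tpm,
    genome=ds.reference.genome,
    filter_params=FilterParams(pseudogene_intervals=ds.reference.pseudogene_intervals),
)

peptidome = build_reference_peptidome(ds.reference.proteome)
variants = filter_somatic_variants([v for v, _ in ds.truth.planted_variants])
print(f"somatic variants kept: {len(variants)} of {len(ds.truth.planted_variants)}")

peptides = call_variant_peptides(
    variants, ds.reference.models, ds.reference.genome, peptidome
) + call_isoform_peptides(
    result.catalog, group_by_gene(ds.reference.models), ds.reference.genome, peptidome
)
scored = score_and_call(peptides, ["HLA-A24:02", "HLA-A02:01"], MockBindingScorer())
tab = tabulate_by_source(scored)

print(f"novel 9-mers:          {len(peptides)}")
print(f"candidates by class:   {tab['counts_by_class']}")
print(f"strong binders:        {sum(1 for c in scored if c.strong_binder)}")
# Frameshifts and aberrant isoforms contribute long novel tails, hence many
# more candidate peptides than single-residue missense changes.
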