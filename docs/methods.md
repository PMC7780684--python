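# Methods

This note records the models, rules and numerical choices behind
`isocatalog`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open; GTF (1-based inclusive),
STAR `SJ.out.tab` (1-based inclusive intron coordinates, strand code
0/1/2) and VCF (1-based POS) are converted at the I/O boundary and
back-converted on write, so every reader/writer pair is a bijection on
its dialect. Junction identity is (chrom, strand, intron start, intron
end), with strand-unknown short-read junctions (`.`) matching either
strand on coordinates alone. GTF parsing goes through gffutils (in-memory
database, inference disabled), alignments through pysam, VCF through
pysam's VariantFile, FASTA through pyfaidx/Biopython; the GTF/SJ/VCF
writers are small text emitters for the exact dialects the readers
accept.

## Read filtering

Mapping identity is matched bases over matched + substituted + inserted
+ deleted bases, taken from =/X CIGAR operations when present, else from
the NM tag (substitutions = NM − insertions − deletions); with neither,
the identity is unevaluable and the read fails the rule conservatively.
"Unmapped length within splice junctions" is operationalized as read
bases in insertion operations immediately adjacent (distance 0,
configurable) to an intron operation. The exon-length rule applies to
all blocks, terminal included. Pseudogene overlap of ≥ 1 bp rejects
(threshold configurable). Short-intron correction merges blocks
separated by < 50 bp iteratively; it never reduces the exonic span and
never produces overlapping blocks. Gene assignment takes the gene with
the largest same-strand exonic overlap (per-transcript maximum, so
shared exons are not double-counted); exact ties break to the
lexicographically smaller gene id, and antisense reads stay unassigned
rather than being force-assigned.

## Detection

The matching margin (default 20 bp) applies per intron boundary — both
the donor and the acceptor offset must be within the margin. Type A
requires the same junction count as some transcript and an in-order
one-to-one match; Type B requires the chain to match a contiguous run of
one transcript's junctions with each truncated read end inside the
flanking exon of that transcript (exon interval expanded by the margin).
Mono-exonic reads cannot define a junction chain and are excluded from
candidacy (treated as Type B-like). Candidate junctions within the
margin of an annotated junction snap to the annotation; novel junctions
must be within the margin of a short-read junction with ≥ 5 unique reads
and snap to the short-read coordinates (exact matches preferred, then
smallest total offset). Snapping makes merged chains well-defined and is
idempotent; it can be disabled for exact-only confirmation. Merged
candidates take their internal structure from the snapped junctions and
their terminal ends from the modal read start/end (ties to the smaller
coordinate).

The expression filters follow the stated thresholds exactly: read count
at least total long reads / 100,000; TPM ≥ 10; isoform reads strictly
greater than 10% of the gene's kept, assigned reads (gene totals taken
over all kept reads of the gene, before Type A/B removal — configurable).
TPM is pluggable: either an external per-isoform table (the normal
workflow, mirroring a short-read quantifier) or the internal
expectation-maximization quantifier over fragment equivalence classes
with effective-length normalization (100 iterations or relative change
< 1e-8; TPM sums to 1e6). One mRNA copy per cell corresponds to
1e6 / 360,000 ≈ 2.78 ≈ 3 TPM under the 360,000-molecules-per-cell
estimate used for interpretation of low-abundance detection.

## Event classification

Events are computed against the union of all the gene's annotated
transcripts. Rules are evaluated in a fixed precedence —
alternative first/last exon, then intron retention, exon skipping,
unannotated exon, alternative 5′/3′ splice site, exon shuffling — and a
junction explained by an earlier call is not re-counted by a later rule
(e.g. the two novel junctions flanking a cassette exon belong to that
single unannotated-exon call). A terminal-exon call additionally
requires the exon's junction into the gene body to be novel, so an
isoform that merely starts at an internal annotated exon is not called an
alternative first exon. Exon shuffling is operationalized as: both
boundaries annotated, the junction pair unannotated, and the pairing not
explainable as skipping within any single transcript — the natural
reading for strictly increasing junction chains, realizable e.g. when a
chain joins two mutually exclusive annotated exons. Repeated instances
of the same event type, like any two calls, label the isoform
"combination".

## ORF inference and PTC flagging

The isoform mRNA is the 5′→3′ concatenation of exon sequences
(reverse-complemented on minus-strand genes). If the gene's annotated
start codon is exonic in the isoform and still reads ATG, translation
starts there; otherwise the longest ATG-initiated ORF is used (ties to
the 5′-most start). Translation uses the standard code and stops at the
first stop codon, or runs open-ended to the transcript end (open-ended
⇒ never a PTC). The NMD criterion is the canonical junction rule: a stop
codon ending ≥ 50 nt upstream of the last exon–exon junction flags the
isoform (distance configurable; 55 nt is a common alternative and
changes none of the synthetic truth labels at default parameters, since
planted stops land far from the boundary in either direction except by
construction in the boundary tests). Retained introns are part of the
mRNA, so retention reduces the junction count and moves the "last
junction" accordingly. Proportions of PTC isoforms between two
conditions are compared with a two-sided Fisher exact test.

## Neoantigen enumeration

Variants are applied per transcript wherever their genomic position is
exonic; no phasing is assumed. Substitutions classify as missense or
nonsense by codon effect (silent changes are no-ops); indels are
in-frame when the length change is divisible by 3, else frameshift, with
translation continuing in the new frame through the 3′ UTR to the first
stop. The altered protein span is the longest-common-prefix/suffix
bracket of the mutated versus reference protein; a pure truncation
(nonsense) marks only the truncation point, so it contributes no novel
9-mers — consistent with peptide source classes being isoform /
frameshift / missense / in-frame. Novelty is defined against the 9-mer
set of the supplied reference proteome only; windows containing
stop/ambiguous residues are discarded. HLA typing is an input. The
binding predictor is pluggable; the packaged `MockBindingScorer` is a
deterministic hash of (peptide, allele) onto [0, 2), existing so tests
and examples never require an external neural predictor, and carries no
biological meaning.

## Cohort re-quantification

Isoform-specific features are junctions absent from every reference
transcript plus exonic intervals that span a reference intron
(retention) or overlap no reference exon, minus anything shared with a
sibling isoform of the same gene; isoforms left with no feature are
unquantifiable. Detection needs ≥ 20 reads on some specific feature;
the isoform count is the maximum over its features. RPM is count × 1e6 /
library size. The panel of normals stores the per-isoform max RPM and
refuses to build from fewer than 5 normal samples. Tumor-specific calls
require tumor RPM ≥ 2 × panel (non-strict fold, configurable; a panel
value of 0 passes any positive expression) and no specific junction in
the normal-junction set (≥ 20 reads in strictly more than 50% of normal
specimens; the filter looks only at isoform-specific junctions, so an
isoform is not penalized for its annotated junctions). Clinical mode
uses tumor TPM ≥ 10 and fold ≥ 2 against the matched normal, with
normal 0 passing. The NMD-factor association is a one-tailed
Mann–Whitney U (mutated group higher), exact for small groups.
Subsampling draws reads without replacement and re-runs detection with
the coverage filter rescaled to the subsampled total.

## Synthetic data

The generator emulates the full study from a single seed: a toy
single-chromosome genome of multi-exon genes (5–7 exons of 100–220 bp,
introns of 220–320 bp, GT/AG on the gene strand at every annotated
intron, both strands represented), clean CDSs (ATG after a 30 nt 5′ UTR,
stop inside the last exon, no internal stops) whose translations form
the reference proteome; planted isoforms realizing each event type on
its own gene (3 per type by default, including combinations and
shuffling genes that carry a second transcript with a mutually exclusive
exon); long reads at depth 30 per transcript and per isoform, with
optional substitution/indel tallies, uniform junction jitter, Type B
truncations, and one decoy per rejection rule with its reason recorded;
short-read junction support at 25 reads per true junction (selected
isoforms can be demoted to 4 to exercise the confirmation rule); an
external-style TPM table at 50 TPM per planted isoform; one somatic
variant per consequence class plus filter decoys, on plus-strand genes;
and a tumor/normal cohort where tumors carry 40 reads on each isoform's
specific features, one isoform is expressed across normals (to fail the
fold rule) and one carries a junction seen in > 50% of normals (to be
excluded by the normal-junction set). Expected PTC flags come from the
generator's own straight-line translation scan implementing the
documented ORF policy.

What passing these tests shows: the decision rules, thresholds,
coordinate handling and bookkeeping are implemented exactly as
specified, and the pipeline is deterministic under a seed. What it does
not show: performance on real nanopore data — the generator does not
model base-level error processes, alignment artifacts, expression
dispersion, incomplete annotation or repeat-mediated mis-splicing, so
real-data precision/recall will be lower and threshold-sensitive.

## Problem sizes and determinism

The default study (30 genes, 27 planted isoforms, ~1,700 reads) runs the
full pipeline in about a second; acceptance analyses use the same scale,
with subsampling restricted to a handful of genes and 20–25 replicates
per fraction, which is enough to see the depth dependence while staying
cheap. All randomness flows from explicit seeds through dedicated
`random.Random` instances per stage; reruns are byte-identical, and the
mock binding ranks are stable hashes.
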