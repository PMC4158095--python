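# Methods

## The measurement model

DGE-tag (SAGE-style) sequencing reduces each transcript molecule to one
short tag: NlaIII cuts at its palindromic CATG site, adaptor ligation to
the bead-bound 3' fragment places an MmeI recognition junction at the
CATG, and MmeI releases the 17 bases downstream. Every informative tag
is therefore a 21-mer of the form `CATG + 17 nt`, and gene expression is
inferred from tag copy numbers, not read coverage. The pipeline models
exactly this: reference interpretation pre-enumerates *all* possible
CATG-anchored 21-mers of the reference (`tag_reference`), sequencing
output is reduced to a clean-tag multiset (`tag_qc`), and quantification
assigns unambiguous tag mass to genes (`tag_mapping`).

Strandedness: transcript databases use the sense strand only (tags
derive from mRNA); genome databases enumerate both strands, since an
unannotated transcription unit may lie on either. One-mismatch lookup
tolerates the mismatch only in the 17 nt suffix by default
(`anchor_strict=True`): the anchor is enzymatically defined, so an
anchor mismatch implies a different digestion product rather than a
sequencing error. The alternative is exposed as a flag. Exact hits
always take priority and are never mixed with one-mismatch hits.

## Cleaning rules

Raw 49 bp reads are filtered in a fixed order: empty records;
adaptor-only records (empty-insert ligations, recognized by an adaptor
prefix); records not starting with CATG (`anchor_missing`); tags
containing N; tags with any base below the Phred quality floor
(default 10 — "low quality" has no standard definition in tag
protocols, so the rule is configurable); tags whose length is not 21
after trimming (pre-counted TSV input can carry those); and finally
tags seen only once in the library. The singleton filter is applied per
library, not pooled across replicates, matching per-library accounting.
Every removal is booked under its reason, so
`raw = clean + Σ removed` holds exactly and is asserted by
`TagLibrary.validate`.

## Quantification

A tag whose exact (or, failing that, one-mismatch) matches all fall in
one gene contributes its full copy number to that gene; multi-gene tags
count toward "all mapped" mass only — no fractional allocation, since
only unambiguous tags are interpretable at tag resolution. Tags missing
the transcript database fall through to the genome database
(unannotated transcription); the remainder is "unknown". TPM is
`count / clean_tags × 10⁶` with the library's **clean-tag total** as
denominator — the protocol's "per million clean tags" — so TPM columns
do not generally sum to 10⁶ (the unambiguous mass is the numerator
universe). Gene-universe percentages for "genes detected" are left to
the caller: the natural denominator (annotated genes, expressed genes,
tag-bearing genes) is context-dependent, so summaries report raw gene
counts.

## Differential expression

For a contrast with conditions 1 and 2 (replicates j = 1..r), per gene:

    M = log2( x̄₁ / x̄₂ ),   D = | x̄₁ − x̄₂ |

on replicate-mean TPM. The null is empirical: for every gene and every
unordered within-condition replicate pair, the same (|M*|, |D*|) pair is
computed and pooled across both conditions and all genes (with r = 2
per condition: two noise pairs per gene). The probability of
differential expression is the strict joint exceedance

    P1(g) = #{ (|M*|,|D*|) : |M*| < |M_g| and |D*| < |D_g| } / #noise,

P0 = 1 − P1. A gene is called significant when P1 ≥ 0.8 — equivalent to
odds P1/P0 of 4:1 — **and** |M| ≥ 1 (two-fold). Strict inequalities are
used throughout, so ties never count as exceedance and an all-zero gene
has P1 = 0 exactly.

Numerical choices: zero values entering a log ratio (condition means in
the signal, replicate values in noise pairs) are replaced by a
pseudo-expression of 0.5 TPM; D is always computed on the raw,
unsmoothed values. The pseudo keeps M finite without touching non-zero
genes; it is configurable. The exceedance count is evaluated in
vectorized chunks and agrees with a double-loop count to machine
precision (it counts the same integers).

Known behaviour worth stating: because the noise pool is shared across
genes, a low-abundance gene competes against the absolute differences
D* of high-abundance genes, so weak or shallow genes saturate at
moderate P1 even under a true fold change — low-expression DE is
intrinsically hard for this statistic. Study-level DEG totals are
therefore unions over pairwise contrasts ("differs in at least one
comparison"), which is also how the package measures planted-effect
recovery.

## Enrichment

Upper-tail hypergeometric per term: with N annotated genes, n DEGs
inside that universe, M genes carrying the term and m DEGs among them,

    P = 1 − Σ_{i=0}^{m−1} C(M,i) C(N−M,n−i) / C(N,n),

computed via `scipy.stats.hypergeom.sf` (log-space stable). Genes with
no annotation are excluded from both N and n. Benjamini–Hochberg
adjustment across tested terms yields Q; both P < 0.05 and Q < 0.05
flags are reported and configurable. No ontology-graph propagation is
performed — terms are used exactly as annotated, and pathway enrichment
reuses the identical machinery with a pathway table.

## Ratio clustering

For each gene and stage, the ratio of the two species' replicate-mean
TPM is taken, a zero mean on either side is replaced by 0.01 (the
denominator rule is stated by the protocol; the numerator substitution
is applied symmetrically so ratios stay finite in both directions, and
every substitution is recorded per cell), and the log2-transformed
matrix is clustered with average linkage on Euclidean distances (the
Cluster 3.0 conventions; both configurable) via
`scipy.cluster.hierarchy`, which breaks ties deterministically by
cluster index. Outputs are the linkage tree (also as Newick), the leaf
order, and the leaf-ordered matrix for external heatmap tools.

## The synthetic experiment

The generator reproduces the statistical structure the analysis
assumes, with full bookkeeping of every emitted read. Defaults define
the reference study conditions:

| parameter | default | why |
|---|---|---|
| genes | 2,000 | desk-scale stand-in for a ~10⁴-gene transcriptome |
| transcript length | uniform 400–1500 bp | a few CATG sites per transcript at random-sequence density (~1/256 bp) |
| design | 2 species × 3 stages × 2 replicates | the reference layout; 60 pooled workers per library (720 total) |
| library depth | 100,000 tags | scaled from the real ~6M so the full run takes seconds |
| baseline abundance | log-normal(μ=1, σ=1.5) | reproduces the skew where high-copy tags dominate mass while most distinct tags sit at 2–5 copies |
| species effect | 10% of genes, &#124;log2FC&#124; = 3, half up per species | the planted signal for recovery measurement |
| stage effect | 10% of genes, ×2^1.5 per stage step, declining from newly-emerged | the qualitative stage profile: highest at emergence, lowest in foragers |
| replicate dispersion | σ = 0.2 (natural log) | closed form R = (e^{σ_A²}−1)/(e^{σ_A²}e^{σ²}−1) puts linear-TPM replicate correlation ≈ 0.95, mid-band of the reported 0.88–0.99 reproducibility |
| tag-site usage | geometric, factor 0.7 per site upstream of the 3'-most | partial-digest model of 3'-fragment capture |
| divergence | 1% per base | cross-species mapping against the species-1 reference |
| error rate | 10⁻³ per base | Illumina-scale; mostly produces singletons that the copy-number filter removes |
| contaminants | 3% genomic-background + 5% unknown tags | exercise the genome-fallback and unknown paths; unknown tags are built ≥2 mismatches from every reference tag |

Planted effects are drawn from genes at or above the median baseline
abundance: at 10⁵ tags/library a below-median gene carries ~10 tags
spread over several sites, below the level at which any fold change is
measurable after the singleton filter — and empirical DEG sets are, by
construction, detected genes. Replicate reproducibility is quantified
as Pearson r on linear TPM (the scale on which replicate scatter plots
are drawn).

What the generator does **not** emulate: real sequence composition and
GC structure, real error profiles (errors are uniform substitutions),
positional quality decay, PCR duplication, and isoform structure
(one transcript per gene). Passing recovery tests therefore demonstrate
the statistical machinery under the assumed model, not performance on
real libraries with composition biases.

Determinism: all randomness flows from `numpy` `SeedSequence` children
of the single mandatory seed; the same seed yields byte-identical
FASTA/FASTQ/TSV output trees.

## Problem sizes in the test suite

Unit and property tests run on 40–200-gene instances (seconds). The
end-to-end recovery checks use the default conditions above — 2,000
genes, 12 × 10⁵ tags — which complete in well under a minute; the same
configuration backs `scripts/acceptance.py`. Oracles are independent
implementations: an all-positions scan for tag extraction, a full
Hamming scan for lookup, double-loop exceedance counts for P1,
exhaustive C(N,n) enumeration (N ≤ 12) for the hypergeometric tail, and
an O(n³) UPGMA for linkage heights.

## Known limitations

- In-memory hash-map databases: fine for desk-scale references, not for
  mammalian-genome-scale both-strand enumeration.
- The DE statistic has no replicate-free fallback; r ≥ 2 per condition
  is required (the error names the offending condition).
- No positional weighting of tags at mapping time (all reference sites
  are equivalent); the generator's 3'-bias is a property of the data,
  not of the mapper.
- Enrichment treats terms independently; correlated terms inflate the
  number of nominally significant items, as for any per-term
  hypergeometric screen.
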