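# Methods

This note documents the model, the numerical and design choices, what the
synthetic data does and does not emulate, and the known limitations.

## Data model and coordinates

The unit of analysis is a biallelic SNV with (i) diploid genotype calls for
a configurable roster of archaic individuals (default Denisovan, Altai
Neanderthal, Vindija Neanderthal), (ii) human variation as
reference/alternative **allele counts** over a cohort of chromosomes, and
(iii) an ancestral state from a multiple-genome alignment with the macaque
reference base recorded separately as fallback. Counts rather than
frequencies make "the ancestral allele is absent from all sampled humans"
an exact, cohort-size-robust predicate (ancestral count = 0) and let the
">99.999% ancestral" condition be evaluated without rounding.

Internal coordinates are 1-based inclusive (the VCF/GFF3 convention); BED
input is converted on read and back on write. Only the 22 autosomes and X
are processed (the archaic individuals are female); other sequences are
dropped with a logged count. X genotypes are treated as diploid. Indels and
non-biallelic human rows are excluded — the catalog is restricted to
biallelic SNVs.

## Filters and admission

Per-genotype filters: depth < 5; depth > 105 (Altai Neanderthal) or > 75
(other individuals, both configurable per individual); genotype quality
< 20; heterozygous calls with minor-read fraction `min(AD)/sum(AD)` < 0.2.
All four comparisons are strict, so DP = 5, DP = 105/75, GQ = 20 and minor
fraction = 0.2 pass; each boundary is pinned by a unit test. Heterozygotes
without AD cannot be imbalance-tested and pass on DP/GQ alone (discarding
them would silently shrink the catalog). A failed genotype is downstream
*missing*, never an error.

Admission: the human reference allele is observed by definition (it is the
reference sequence), so a site is admitted iff at least one archaic
genotype passes filtering **and** the alternative allele is observed either
in the human counts or in a passing archaic genotype. This admits sites
whose alternative allele occurs only in archaics — required for the
archaic-fixed category, where the derived allele may be absent from the
human cohort entirely.

## Classification

Polarization: if the alignment-derived ancestral allele equals ref or alt,
the derived allele is the other one and f = derived count / total. If the
ancestral state is unknown, f is undefined and only the macaque-based
extended pathways can classify the site; an alignment allele matching
neither ref nor alt is tallied and treated as unknown. (An option exists to
promote the macaque base to the ancestral state globally, but the default
keeps macaque evidence confined to the extended categories, which carry the
lower-confidence label.)

Category predicates are evaluated first-match in the order fixed → HF →
extended(a) → (b) → (c) → (d) for the human lineage, then fixed → HF →
extended for the archaic lineage; the two lineages' frequency conditions
(f > 0.9 vs f < 0.01) are disjoint, so no site can receive two labels.
Interpretation choices where the definitions are ambiguous:

* "Carries the ancestral allele" = homozygous-ancestral (strict mode,
  default); a heterozygote counts as carrying the derived allele. Lenient
  mode (heterozygote counts as ancestral) is a flag; on synthetic bundles
  toggling it changes labels only at sites planted with heterozygous
  archaic calls.
* Extended (c) accepts *at least one* derived Neanderthal (an
  `extended_c_exactly_one` switch restricts to exactly one). Because (c) is
  evaluated only after HF fails, (c) and HF never overlap.
* Extended (b) requires at least one passing archaic homozygous for a third
  allele and no passing archaic carrying the derived allele.
* Extended (d) requires all three archaics present and homozygous for the
  macaque base.
* Archaic-extended requires the macaque base to equal the major human
  allele (minor frequency below the 1% HF ceiling) with ≥ 2 archaics
  carrying the minor allele.

Reported tallies use union semantics for fixed ⊆ HF: the HF column of every
summary includes fixed-labelled sites, while the per-site label keeps the
most specific category. The extended column is a separate tally (extended
sites fail the stricter predicates by construction). The
extended-minus-HF remainder is exactly the lower-confidence portion of the
catalog.

## Consequence annotation

A deliberately minimal, transparent annotator stands in for a full
VEP run (a precomputed VEP-style TSV can be supplied instead; the two paths
are never mixed in a run). Coding consequences are computed by strand-aware
codon substitution under the standard genetic code, with mid-codon
exon junctions handled through an explicit CDS coordinate map; splice sites
are the first/last 2 intronic bases; UTRs are exonic positions outside the
CDS; upstream/downstream extend 5,000 bp from the transcript span (the
conventional default of annotation tools; configurable); TFBS, miRNA and
regulatory-element classes come from user-supplied BED tracks. Classes are
not mutually exclusive across transcripts; per-site summaries count each
class once per site. A transcript failing translation sanity checks
(CDS length not a multiple of 3, internal stop codons) falls back to an
intronic-level call with a warning.

"Start/stop" in the summary table is the union of start-lost, stop-gained
and stop-lost. Per-chromosome missense/synonymous ratios are computed over
HF (incl. fixed) changes per lineage; a zero-synonymous denominator yields
a missing value, not infinity.

### Grantham scores

Missense changes are scored with the published Grantham matrix, bundled as
`data/grantham_published.tsv` (symmetric, zero diagonal, mean distance over
the 190 unordered pairs ≈ 100). The analytic formula

    D(i,j) = rho * sqrt(alpha*Δc² + beta*Δp² + gamma*Δv²),
    alpha = 1.833, beta = 0.1018, gamma = 0.000399, rho = 50.723

with the published composition/polarity/volume values is implemented in
`GranthamParams`. A fresh evaluation of this formula does **not** reproduce
the published table exactly: about three quarters of the pairs match, the
rest differ by one unit under any choice of scale, and the D–W entry is 181
in the published table versus ≈ 190.7 from the formula — the historical
table was evidently produced with coarser intermediate arithmetic. Because
the published integers are what the field's tools and thresholds are
calibrated against, the package scores substitutions from the bundled
table; the formula remains available for parameter studies, and the
agreement profile is asserted in the test suite. The deleteriousness flag
is strict: score > 180 (181 flags, 180 does not). SIFT/PolyPhen/CADD/GWAVA
are consumed as optional annotation columns only (defaults: SIFT < 0.05,
PolyPhen > 0.908, CADD/GWAVA by top-rank count); the package never computes
them.

## Gene ranking

Gene length is the genomic span (end − start + 1), not summed exon length —
the rankings divide by genomic length and the long-gene caveats concern
spans. Sites contribute to a gene when they fall in its span or when a
consequence record names the gene (e.g. upstream/downstream), de-duplicated
per gene. The segregating-site eligibility count includes every admitted
site at any frequency, not only classified ones.

Density ranking: genes with span ≥ 5,000 bp and ≥ 25 segregating sites are
eligible; the top 5% by lineage-specific HF changes per bp are flagged, with
ties at the threshold density all included (set size is between
⌈0.05·n⌉ and that plus the ties). Ratio ranking: genes with ≥ 20 combined
HF changes are eligible; the top 10% by hf_human/hf_archaic are flagged,
with zero-denominator genes ranked above every finite ratio and ordered
among themselves by their HF count (genes with no archaic HF changes at all
belong at the top, not excluded). Both rankings refuse to run with fewer
than 20 eligible genes. Length correlations are plain Pearson
product-moment on untransformed counts; fewer than 3 genes or a
zero-variance vector is an error/missing value.

## Enrichment statistics

* **G-test**: G = 2·Σ O·ln(O/E) over cells with O > 0 on a 2×2 table,
  expected counts from independence, chi-square p with 1 df, no continuity
  correction (Williams correction behind a flag). Cross-checked in tests
  against direct formula evaluation and scipy's log-likelihood-ratio mode.
* **Length-matched empirical test**: the gene universe is cut into 20
  log-spaced length bins (configurable, recorded in the output; bins are
  halved automatically if a target bin exceeds the universe bin). Each of B
  = 1,000 random sets reproduces the target's per-bin composition, sampled
  without replacement within bins (nothing is excluded from sampling). The
  statistic is the hit-gene overlap, or a weighted sum when per-gene change
  counts are supplied. "Fewer" is read strictly — ties do not count toward
  the criterion — which is the conservative reading; as a consequence the
  ≥90%-of-sets criterion is slightly conservative for small, heavily tied
  target sets (its null pass rate approaches the nominal 10% as target sets
  grow; the calibration check uses 50-gene sets).
* **GWAS-trait screen**: a trait (≥ 10 associated genes in the universe) is
  enriched for a lineage iff (i) a genome-wide G-test of that lineage's HF
  missense changes in trait genes vs trait gene count against genome totals
  has p < 0.1 with the trait over-represented, (ii) a between-lineage
  G-test on trait-associated changes has p < 0.1 with the focal lineage
  over-represented, and (iii) the empirical criterion holds. Stages are
  logged individually.
* **Category tests**: hypergeometric mode tests a foreground gene set
  against a foreground∪background universe (the intended background for
  missense foregrounds is genes with synonymous changes on the same
  lineage); Wilcoxon mode rank-sum-tests per-gene scores in- vs
  out-of-category (one-sided). Raw p-values are Holm-adjusted, and a
  permutation max-statistic FWER (resampled foregrounds / permuted scores,
  B permutations) is estimated alongside; a category is reported iff
  adjusted p < 0.05 and permutation FWER < 0.05.
* **Sweep overlap**: a site qualifies iff its distance to any sweep region
  is ≤ 50,000 bp (0 inside), implemented with padded interval trees.

All resampling flows from one explicit seed; per-test substreams are
derived deterministically from (seed, test name), so runs are reproducible
and independent tests do not share streams.

## Synthetic data

The generator targets *predicate coverage*, not population-genetic realism:
no coalescent, recombination, demography or linkage. Each planted site is
built from a category template that satisfies exactly its category's
predicate and no stronger one (e.g. an HF-human site keeps ancestral count
≥ 1 so it cannot be fixed; an extended-(a) site hides the Denisovan so the
HF predicate cannot fire). Distractor sites violate exactly one filter in
every genotype. Default study conditions: a 5,008-chromosome human cohort
(the scale at which near-fixation is distinguishable from fixation), three
archaic individuals with negative-binomial depths (mean ≈ 40) truncated to
the planted filter fate, ≥ 35 sites per extended condition and ≥ 50 per
fixed category, ~120 genes (log-normal spans, median ≈ 11 kb) each carrying
Poisson-distributed HF changes at 0.9 changes/kb/lineage, five genes with a
10× human HF density, six genes per lineage with one-sided HF counts
(27 vs 0), three eligibility-boundary genes (4,999 bp span; exactly 24
segregating sites; 19 combined HF changes), 25 GWAS-style traits of 12
genes including one trait whose genes carry a 5× missense excess and one
undersized 9-gene trait, and sweep regions covering the density-enriched
genes. Coding sites are placed by codon arithmetic written independently of
the annotation module, so consequence recovery is a genuine two-path check.
Planted-enrichment genes are drawn with spans ≥ 6,000 bp so they clear the
eligibility floor by construction.

Passing tests on these bundles demonstrate that the *logic* of every stage
is correct under its defining conditions; they do not demonstrate
robustness to mapping artifacts, genotype error correlated with depth,
segmental duplication, or ancestral-state misassignment in real data.

## Numerical choices

Quantile/top-fraction rules use the empirical distribution with boundary
ties included. Ratio sorting uses (ratio, count) key tuples with +inf for
zero denominators. Random sampling without replacement inside the empirical
test draws B sets simultaneously by ranking uniform keys per row
(argpartition), which is unbiased and keeps B = 1,000 cheap. Grantham
formula values are rounded half-up. Hypergeometric p-values are upper-tail
`sf(k−1)`. Undefined ratios and correlations are missing values, never
infinities. The problem sizes used by the test suite and the acceptance
script (5,000-gene calibration universe, 500 null sets at B = 200,
~5,000-site bundles) were chosen so the full analysis re-runs comfortably
on a laptop-class single core.

## Limitations

The annotator is minimal by design (no canonical-transcript logic, no
indels, no regulatory build — regulatory classes come from user BEDs).
STRING interaction enrichment and atlas-bound brain-expression statistics
are out of scope; externally computed gene sets can be fed to the generic
length-matched test instead. The original genome-wide counts require the
full archaic VCFs, dbSNP allele counts and an Ensembl annotation release,
and are not reproducible at desk scale; the package's validation is
therefore property-based on planted truth.
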