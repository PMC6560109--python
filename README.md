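# sncatalog

A catalog-building pipeline for **lineage-specific single nucleotide changes
(SNCs)** separating present-day humans from archaic hominins (Neanderthals
and Denisovans).

Given diploid genotypes for a small roster of high-coverage archaic genomes
(default: one Denisovan, the Altai Neanderthal and the Vindija Neanderthal),
present-day human variation summarized as per-site allele counts over
thousands of chromosomes, and ancestral alleles inferred from a
multiple-genome alignment (with the macaque reference base as fallback), the
pipeline answers: *which single-base changes became (nearly) fixed on the
modern-human lineage since its split from archaics, which became fixed on
the archaic lineage, and what do they do?*

It is written for population geneticists and evolutionary biologists who
want a tested, reusable, scriptable version of this catalog analysis —
including a seeded synthetic-data generator with planted ground truth so
every stage can be validated without multi-gigabyte downloads.

## The classification model

For each biallelic site, let *f* be the derived-allele frequency in the
human cohort (from allele counts, after polarizing ref/alt against the
ancestral state). Archaic genotype calls are first filtered: depth < 5,
depth > 105 (Altai) or > 75 (others), genotype quality < 20, or heterozygous
calls with minor-read fraction < 0.2 are treated as missing. A site enters
the catalog when both alleles were observed among the human reference and at
least one covered archaic chromosome. Admitted sites are classified:

**Human lineage**

* *Fixed* — the ancestral allele is absent from the human cohort
  (ancestral count = 0) and ≥ 2 of 3 archaics carry the ancestral allele
  (allowing for human→Neanderthal gene flow).
* *High-frequency (HF)* — f > 0.90 and the Denisovan plus ≥ 1 Neanderthal
  carry the ancestral allele.
* *Extended* — f > 0.90 under relaxed evidence: (a) some archaic genotypes
  unreliable, the reliable ones ancestral; (b) an archaic carries a third
  allele; (c) Denisovan ancestral while a Neanderthal is derived; (d) the
  ancestral allele is unknown but the macaque base matches all three
  archaics.

**Archaic lineage** (mirrored) — *fixed*: all three archaics derived while
humans are ancestral at > 99.999%; *HF*: f < 0.01 with ≥ 2 archaics derived;
*extended*: ancestral unknown but the macaque base equals the major human
allele while ≥ 2 archaics carry the minor allele.

Fixed changes are a subset of HF changes in all reported tallies. "Carries
the ancestral allele" means homozygous-ancestral by default (a heterozygote
counts as carrying the derived allele); a lenient mode is available.

Downstream, sites are annotated VEP-style (missense/synonymous/start-stop/
splice/UTR/up-downstream/regulatory, with Grantham scores — > 180 flagged as
radical — for missense changes), genes are ranked by HF-change density
(top 5% of genes spanning ≥ 5,000 bp with ≥ 25 segregating sites) and by the
human/archaic HF-change ratio (top 10% of genes with ≥ 20 combined HF
changes), and enrichment is tested with G-tests, hypergeometric and
Wilcoxon rank-sum category tests (Holm + permutation FWER), a
1,000-random-set length-matched empirical test, and a 50-kb selective-sweep
overlap.

## Worked example

Generate a synthetic bundle (three archaic individuals, a 5,008-chromosome
human cohort, planted site categories, planted gene-level and trait-level
enrichments) and run the full pipeline:

```python
from pathlib import Path
from sncatalog import (SimulationConfig, simulate_bundle, PipelineConfig,
                       run_pipeline, EnrichmentConfig)

bundle = simulate_bundle(SimulationConfig(rng_seed=7), "demo_bundle")
cfg = PipelineConfig(
    vcf=bundle.vcf, frequency_table=bundle.frequency_table,
    ancestral_track=bundle.ancestral_track, genome_fasta=bundle.genome_fasta,
    gene_models=bundle.gene_models, tfbs_bed=bundle.tfbs_bed,
    mirna_bed=bundle.mirna_bed, regulatory_bed=bundle.regulatory_bed,
    sweeps_bed=bundle.sweeps_bed, trait_table=bundle.trait_table,
    out_dir=Path("demo_run"),
    enrichment=EnrichmentConfig(n_random_sets=1000, rng_seed=7))
results = run_pipeline(cfg)

print(results["summary_table"].loc[["All", "Non-synonymous", "Synonymous"]])
print("Pearson R, segregating sites vs gene length:",
      round(results["correlations"]["segregating_sites"], 2))
print("enriched traits:",
      [r.target for r in results["trait_enrichment"] if r.decision])
print("HHMC sites within 50 kb of a sweep region:",
      len(results["sweep_hits"]))
```

which prints:

```
                fixed_human  hf_human  extended_human  fixed_archaic  hf_archaic  extended_archaic
All                      60      2053             140             50        1391                35
Non-synonymous            5       812              17             13         467                 4
Synonymous                9       396              26              3         259                 5
Pearson R, segregating sites vs gene length: 0.37
enriched traits: ['planted_trait [human]']
HHMC sites within 50 kb of a sweep region: 146
```

The count table has the catalog's headline shape: columns are
fixed/HF/extended per lineage (HF includes fixed), rows are consequence
classes, and each cell counts sites once. Here the 60 planted fixed-human
sites, the planted trait with a 5× excess of human missense changes, and the
planted sweep-adjacent genes are all recovered exactly; classification
labels agree with the generator's truth table at 100%.

The same stages are available from the shell:

```bash
sncatalog simulate --seed 7 --out demo_bundle
sncatalog run --config pipeline.yaml     # filter → classify → annotate → rank → enrich → summarize
sncatalog verify --bundle demo_bundle    # diff recovered labels against planted truth
```

## Layout

* `src/sncatalog/model.py` — typed data model (sites, genotypes, genes,
  features, traits)
* `src/sncatalog/io.py` — VCF (pysam), TSV, FASTA, GFF3 (gffutils), BED
  readers/writers; 1-based internal coordinates
* `src/sncatalog/filtering.py` — genotype quality filters + admission rule
* `src/sncatalog/classification.py` — polarization and category assignment
* `src/sncatalog/annotation.py` — consequence annotation and catalog summary
* `src/sncatalog/grantham.py` — Grantham distances (published matrix +
  analytic formula)
* `src/sncatalog/ranking.py` — per-gene statistics, density/ratio rankings,
  length correlations
* `src/sncatalog/enrichment.py` — G-test, empirical length-matched test,
  GWAS-trait screen, category tests with FWER, sweep overlap
* `src/sncatalog/simulate.py` — synthetic-data generator with planted truth
* `src/sncatalog/pipeline.py`, `src/sncatalog/cli.py` — orchestration + CLI
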