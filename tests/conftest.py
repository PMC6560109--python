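import numpy as np
import pytest

from sncatalog.filtering import FilterThresholds, filter_site
from sncatalog.model import ArchaicGenotype, SiteObservation, DEFAULT_ROSTER
from sncatalog.pipeline import PipelineConfig, run_pipeline
from sncatalog.enrichment import EnrichmentConfig
from sncatalog.simulate import SimulationConfig, simulate_bundle

COHORT = 5008


def make_genotype(ind="Denisovan", a1="A", a2="A", dp=40, gq=60, ad=None):
    return ArchaicGenotype(individual_id=ind, allele1=a1, allele2=a2,
                           depth=dp, genotype_quality=gq, allelic_depths=ad)


def make_site(derived_count, *, ref="A", alt="G", ancestral="ref",
              macaque=None, genotypes=None, total=COHORT, chrom="1", pos=100):
    """Site with the given derived-allele count, ancestral defaulting to ref
    (so derived = alt and alt_count = derived_count)."""
    if ancestral == "ref":
        ref_count, alt_count = total - derived_count, derived_count
        source = "alignment"
    elif ancestral == "alt":
        ref_count, alt_count = derived_count, total - derived_count
        source = "alignment"
    else:
        ref_count, alt_count = total - derived_count, derived_count
        source = "none"
    return SiteObservation(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        ref_count=ref_count, alt_count=alt_count, ancestral=ancestral,
        ancestral_source=source, macaque_allele=macaque,
        archaic_genotypes=genotypes or {})


def states_to_genotypes(states, anc="A", der="G", third="T"):
    """Genotype dict realizing per-individual carrier states (all passing)."""
    out = {}
    for ind, st in states.items():
        if st == "missing":
            out[ind] = make_genotype(ind, None, None)
        elif st == "ancestral_hom":
            out[ind] = make_genotype(ind, anc, anc)
        elif st == "derived_hom":
            out[ind] = make_genotype(ind, der, der)
        elif st == "heterozygous":
            out[ind] = make_genotype(ind, anc, der, ad=(20, 20))
        elif st == "other_allele":
            out[ind] = make_genotype(ind, third, third)
        else:
            raise ValueError(st)
    return out


def verdicts_for(site, thresholds=FilterThresholds()):
    return filter_site(site, thresholds)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle shared by the heavier tests."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(SimulationConfig(rng_seed=2024), out)


@pytest.fixture(scope="session")
def pipeline_results(default_bundle, tmp_path_factory):
    b = default_bundle
    cfg = PipelineConfig(
        vcf=b.vcf, frequency_table=b.frequency_table,
        ancestral_track=b.ancestral_track, genome_fasta=b.genome_fasta,
        gene_models=b.gene_models, tfbs_bed=b.tfbs_bed, mirna_bed=b.mirna_bed,
        regulatory_bed=b.regulatory_bed, sweeps_bed=b.sweeps_bed,
        trait_table=b.trait_table,
        out_dir=tmp_path_factory.mktemp("run"),
        enrichment=EnrichmentConfig(n_random_sets=200, rng_seed=2024))
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
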