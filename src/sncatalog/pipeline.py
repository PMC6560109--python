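"""End-to-end orchestration: filter -> classify -> annotate -> rank ->
enrich -> summarize, with per-stage TSV outputs and JSON sidecars.

A run is fully reproducible from (inputs, config, seed); the manifest
records the seed and a hash over the semantic configuration fields (paths
excluded), so the hash changes iff a threshold or seed changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as sio
from .annotation import (Annotator, GenomeSequence, annotate_sites,
                         flag_deleterious, read_precomputed_annotation,
                         summarize_catalog, DeleteriousnessRules)
from .classification import (ClassificationThresholds, ClassifiedSite,
                             classify_site)
from .enrichment import (EnrichmentConfig, gwas_trait_enrichment,
                         sweep_overlap)
from .filtering import FilterThresholds, admit_site, filter_site
from .model import DEFAULT_ROSTER
from .ranking import (RankingConfig, aggregate_gene_stats,
                      length_correlations, rank_by_density, rank_by_ratio)

logger = logging.getLogger("sncatalog")


@dataclass
class PipelineConfig:
    """Paths plus the per-stage threshold blocks."""

    vcf: Path
    frequency_table: Path
    ancestral_track: Path
    genome_fasta: Optional[Path] = None
    gene_models: Optional[Path] = None
    tfbs_bed: Optional[Path] = None
    mirna_bed: Optional[Path] = None
    regulatory_bed: Optional[Path] = None
    sweeps_bed: Optional[Path] = None
    trait_table: Optional[Path] = None
    precomputed_annotation: Optional[Path] = None
    out_dir: Path = Path("sncatalog_run")
    roster: tuple[str, ...] = DEFAULT_ROSTER
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    classification: ClassificationThresholds = field(
        default_factory=ClassificationThresholds)
    ranking: RankingConfig = field(default_factory=RankingConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    annotation_window: int = 5000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("vcf", "frequency_table", "ancestral_track",
                    "genome_fasta", "gene_models", "tfbs_bed", "mirna_bed",
                    "regulatory_bed", "sweeps_bed", "trait_table",
                    "precomputed_annotation", "out_dir"):
            if key in raw:
                kwargs[key] = Path(raw[key])
        for key, ctor in (("filters", FilterThresholds),
                          ("classification", ClassificationThresholds),
                          ("ranking", RankingConfig),
                          ("enrichment", EnrichmentConfig)):
            if key in raw:
                kwargs[key] = ctor(**raw[key])
        if "roster" in raw:
            kwargs["roster"] = tuple(raw["roster"])
        if "annotation_window" in raw:
            kwargs["annotation_window"] = int(raw["annotation_window"])
        missing = [k for k in ("vcf", "frequency_table", "ancestral_track")
                   if k not in kwargs]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        return cls(**kwargs)

    def validate_paths(self) -> None:
        for name in ("vcf", "frequency_table", "ancestral_track",
                     "genome_fasta", "gene_models", "tfbs_bed", "mirna_bed",
                     "regulatory_bed", "sweeps_bed", "trait_table",
                     "precomputed_annotation"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config key {name!r}: {p} does not exist")

    def semantic_hash(self) -> str:
        """Hash over the semantic fields (thresholds, roster, seed) only."""
        payload = json.dumps({
            "roster": list(self.roster),
            "filters": dataclasses.asdict(self.filters),
            "classification": dataclasses.asdict(self.classification),
            "ranking": dataclasses.asdict(self.ranking),
            "enrichment": dataclasses.asdict(self.enrichment),
            "annotation_window": self.annotation_window,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def load_sites(cfg: PipelineConfig):
    counts = sio.read_frequency_table(cfg.frequency_table)
    vcf_records = sio.read_archaic_vcf(cfg.vcf, cfg.roster)
    ancestral = sio.read_ancestral_track(cfg.ancestral_track)
    return sio.build_site_observations(counts, vcf_records, ancestral)


def filter_and_classify(sites, cfg: PipelineConfig):
    """Verdicts, admission and classification for every site.

    Returns (classified admitted sites, per-site verdict dict, per-site
    inadmissibility reason for sites that were rejected).
    """
    classified: list[ClassifiedSite] = []
    all_verdicts = {}
    rejected: dict[tuple[str, int], str] = {}
    for s in sites:
        verdicts = filter_site(s, cfg.filters)
        all_verdicts[(s.chrom, s.pos)] = verdicts
        if not admit_site(s, verdicts):
            reasons = {v.reason for v in verdicts.values() if not v.passed}
            if any(v.passed for v in verdicts.values()):
                rejected[(s.chrom, s.pos)] = "not_segregating"
            else:
                rejected[(s.chrom, s.pos)] = (reasons.pop()
                                              if len(reasons) == 1 else "mixed")
            continue
        classified.append(classify_site(s, verdicts, cfg.classification,
                                        roster=cfg.roster))
    return classified, all_verdicts, rejected


def classify_bundle(bundle, **overrides):
    """Convenience entry point used by bundle verification: classify all
    sites of a simulated bundle with default (or overridden) thresholds."""
    cfg = PipelineConfig(
        vcf=bundle.vcf, frequency_table=bundle.frequency_table,
        ancestral_track=bundle.ancestral_track, **overrides)
    sites = load_sites(cfg)
    classified, _, rejected = filter_and_classify(sites, cfg)
    return classified, rejected


# ---------------------------------------------------------------------------
# the omnibus run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report directory.

    Any stage error aborts with the stage name; outputs written so far are
    retained.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load"
    try:
        sites = load_sites(cfg)
        results["n_sites"] = len(sites)

        stage = "filter/classify"
        classified, verdicts, rejected = filter_and_classify(sites, cfg)
        results["classified"] = classified
        _write_verdicts(verdicts, rejected, out / "01_filter_verdicts.tsv")
        _write_classified(classified, out / "02_classified.tsv")
        summary_counts = _category_counts(classified)
        (out / "02_summary.json").write_text(
            json.dumps(summary_counts, indent=2, sort_keys=True) + "\n")

        stage = "annotate"
        records = []
        genes = []
        if cfg.precomputed_annotation is not None:
            records = read_precomputed_annotation(cfg.precomputed_annotation)
            if cfg.gene_models is not None:
                genes = sio.read_gene_models(cfg.gene_models)
        elif cfg.gene_models is not None and cfg.genome_fasta is not None:
            genes = sio.read_gene_models(cfg.gene_models)
            features = []
            for attr, fclass in (("tfbs_bed", "tfbs"), ("mirna_bed", "mirna"),
                                 ("regulatory_bed", "regulatory_element")):
                p = getattr(cfg, attr)
                if p is not None:
                    features.extend(sio.read_bed_features(p, fclass))
            annotator = Annotator(genes, GenomeSequence.from_fasta(cfg.genome_fasta),
                                  features, window=cfg.annotation_window)
            records = annotate_sites([c.site for c in classified], annotator)
        results["records"] = records
        results["genes"] = genes
        _write_records(records, out / "03_consequences.tsv")
        results["deleterious"] = flag_deleterious(records, DeleteriousnessRules())

        stage = "rank"
        if genes:
            stats = aggregate_gene_stats(classified, genes, records)
            results["gene_stats"] = stats
            corr = length_correlations(stats)
            rankings = {}
            try:
                rankings["density_human"] = sorted(
                    rank_by_density(stats, cfg.ranking, "human"))
                rankings["density_archaic"] = sorted(
                    rank_by_density(stats, cfg.ranking, "archaic"))
                hum, arc = rank_by_ratio(stats, cfg.ranking)
                rankings["ratio_human"] = sorted(hum)
                rankings["ratio_archaic"] = sorted(arc)
            except ValueError as exc:
                logger.warning("ranking skipped: %s", exc)
            results["rankings"] = rankings
            stats_out = stats.copy()
            for name in ("density_human", "density_archaic",
                         "ratio_human", "ratio_archaic"):
                flagged = set(rankings.get(name, ()))
                stats_out[f"enriched_{name}"] = stats_out.gene_id.isin(flagged)
            stats_out.to_csv(out / "04_gene_stats.tsv", sep="\t", index=False)
            (out / "04_correlations.json").write_text(json.dumps(
                {k: (None if v is None else round(v, 6))
                 for k, v in corr.items()}, indent=2, sort_keys=True) + "\n")
            results["correlations"] = corr

        stage = "enrich"
        enrichment_results = []
        if cfg.trait_table is not None and genes:
            traits = sio.read_trait_table(cfg.trait_table)
            lengths = {g.gene_id: g.length_bp for g in genes}
            changes = {
                "human": dict(zip(stats.gene_id, stats.hhmc_count)),
                "archaic": dict(zip(stats.gene_id, stats.ahmc_count)),
            }
            enrichment_results = gwas_trait_enrichment(
                traits, changes, lengths, cfg.enrichment)
            results["trait_enrichment"] = enrichment_results
        if cfg.sweeps_bed is not None:
            sweeps = sio.read_bed_features(cfg.sweeps_bed, "sweep_region")
            hhmc_positions = sorted({
                (r.chrom, r.pos) for r in records
                if r.consequence_class == "missense"}
                & {(c.site.chrom, c.site.pos) for c in classified
                   if c.lineage == "human"
                   and c.category in ("fixed", "high_frequency")})
            results["sweep_hits"] = sweep_overlap(
                hhmc_positions, sweeps, cfg.enrichment.sweep_window_bp)
        _write_enrichment(enrichment_results, out / "05_enrichment.tsv")

        stage = "summarize"
        table, ratios = summarize_catalog(classified, records)
        table.to_csv(out / "06_report.tsv", sep="\t")
        ratios.to_csv(out / "06_chromosome_ratios.tsv", sep="\t")
        results["summary_table"] = table
        results["chromosome_ratios"] = ratios

        (out / "manifest.json").write_text(json.dumps({
            "config_hash": cfg.semantic_hash(),
            "seed": cfg.enrichment.rng_seed,
            "n_sites": len(sites),
            "n_admitted": len(classified),
        }, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_verdicts(verdicts, rejected, path: Path) -> None:
    rows = []
    for (chrom, pos), vd in sorted(verdicts.items()):
        row = {"chrom": chrom, "pos": pos,
               "admitted": (chrom, pos) not in rejected,
               "rejection_reason": rejected.get((chrom, pos), "")}
        for ind, v in vd.items():
            row[f"{ind}_pass"] = v.passed
            row[f"{ind}_reason"] = v.reason
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_classified(classified, path: Path) -> None:
    rows = []
    for c in sorted(classified, key=lambda c: (c.site.chrom, c.site.pos)):
        s = c.site
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref_allele,
               "alt": s.alt_allele, "ancestral": s.ancestral_allele or ".",
               "derived": c.derived_allele or ".",
               "human_derived_freq": ("" if c.human_derived_freq is None
                                      else f"{c.human_derived_freq:.6f}"),
               "lineage": c.lineage, "category": c.category,
               "extended_condition": c.extended_condition or ""}
        for ind, st in c.states.items():
            row[f"{ind}_state"] = st
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _category_counts(classified) -> dict:
    counts: dict[str, int] = {}
    for c in classified:
        if c.lineage == "none":
            key = "unclassified"
        else:
            key = f"{c.lineage}_{c.category}"
            if c.extended_condition:
                key += f"_{c.extended_condition}"
        counts[key] = counts.get(key, 0) + 1
    counts["total_admitted"] = len(classified)
    return counts


def _write_records(records, path: Path) -> None:
    rows = [{
        "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
        "gene_id": r.gene_id or "", "transcript_id": r.transcript_id or "",
        "consequence_class": r.consequence_class,
        "ref_aa": r.ref_aa or "", "alt_aa": r.alt_aa or "",
        "grantham": "" if r.grantham is None else r.grantham,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_enrichment(results, path: Path) -> None:
    rows = [{
        "test_name": r.test_name, "target": r.target,
        "statistic": r.statistic,
        "p_value": "" if r.p_value is None else r.p_value,
        "empirical_fraction": ("" if r.empirical_fraction is None
                               else r.empirical_fraction),
        "n_random_sets": r.n_random_sets or "",
        "decision": r.decision,
        "null": r.null_description,
    } for r in results]
    pd.DataFrame(rows, columns=["test_name", "target", "statistic", "p_value",
                                "empirical_fraction", "n_random_sets",
                                "decision", "null"]
                 ).to_csv(path, sep="\t", index=False)
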