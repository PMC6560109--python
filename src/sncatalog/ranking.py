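"""Per-gene aggregation, density and lineage-ratio rankings, correlations.

A gene's mutation density is its number of lineage-specific HF changes
(fixed changes included, as a subset of HF) divided by its genomic span
length.  Genes spanning at least 5,000 bp and carrying at least 25
segregating sites (at any frequency) are eligible; the top 5% of the
empirical density distribution is flagged as putatively enriched.  The
lineage ratio hf_human / hf_archaic is ranked for genes with at least 20
combined lineage-specific HF changes; the top 10% is flagged, with
zero-denominator genes (no archaic HF changes at all) ranked above every
finite ratio and ordered among themselves by their human HF count.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import ConsequenceRecord
from .classification import ClassifiedSite
from .model import GeneRecord

logger = logging.getLogger("sncatalog")

MIN_ELIGIBLE_GENES = 20


@dataclass(frozen=True)
class RankingConfig:
    min_length_bp: int = 5000
    min_segregating: int = 25
    density_top_fraction: float = 0.05
    ratio_min_total: int = 20
    ratio_top_fraction: float = 0.10

    def __post_init__(self) -> None:
        for f in (self.density_top_fraction, self.ratio_top_fraction):
            if not 0 < f < 1:
                raise ValueError("top fractions must lie in (0, 1)")


GENE_STATS_COLUMNS = [
    "gene_id", "chrom", "length_bp", "segregating_sites",
    "fixed_human", "hf_human", "fixed_archaic", "hf_archaic",
    "hhmc_count", "ahmc_count", "density_human", "density_archaic", "ratio",
]


def aggregate_gene_stats(classified: Sequence[ClassifiedSite],
                         genes: Sequence[GeneRecord],
                         records: Sequence[ConsequenceRecord] = (),
                         ) -> pd.DataFrame:
    """Per-gene site counts; one row per gene with a genomic span.

    A site contributes to a gene when its position lies in the gene span or
    when one of its consequence records names the gene; per-gene site sets
    are de-duplicated.  HF counts include fixed changes.  The segregating
    count includes every admitted site regardless of classification.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    by_id: dict[str, GeneRecord] = {}
    for g in genes:
        trees[g.chrom].addi(g.start, g.end + 1, g.gene_id)
        by_id[g.gene_id] = g

    rec_genes: dict[tuple, set[str]] = defaultdict(set)
    missense_sites: dict[tuple, bool] = {}
    for r in records:
        if r.gene_id is not None:
            rec_genes[r.site_key].add(r.gene_id)
        if r.consequence_class == "missense":
            missense_sites[r.site_key] = True

    seg: dict[str, set] = defaultdict(set)
    counts: dict[str, dict[str, set]] = defaultdict(lambda: defaultdict(set))
    for c in classified:
        key = c.site.key
        gene_ids = {iv.data for iv in trees[c.site.chrom][c.site.pos]}
        gene_ids |= {g for g in rec_genes.get(key, ()) if g in by_id}
        for gid in gene_ids:
            seg[gid].add(key)
            if c.lineage in ("human", "archaic") and c.category in ("fixed", "high_frequency"):
                counts[gid][f"hf_{c.lineage}"].add(key)
                if c.category == "fixed":
                    counts[gid][f"fixed_{c.lineage}"].add(key)
                if missense_sites.get(key):
                    counts[gid][("hhmc" if c.lineage == "human" else "ahmc")].add(key)

    rows = []
    for gid, g in by_id.items():
        n = counts[gid]
        hf_h, hf_a = len(n["hf_human"]), len(n["hf_archaic"])
        rows.append({
            "gene_id": gid, "chrom": g.chrom, "length_bp": g.length_bp,
            "segregating_sites": len(seg[gid]),
            "fixed_human": len(n["fixed_human"]), "hf_human": hf_h,
            "fixed_archaic": len(n["fixed_archaic"]), "hf_archaic": hf_a,
            "hhmc_count": len(n["hhmc"]), "ahmc_count": len(n["ahmc"]),
            "density_human": hf_h / g.length_bp,
            "density_archaic": hf_a / g.length_bp,
            "ratio": hf_h / hf_a if hf_a > 0 else
            (math.inf if hf_h > 0 else float("nan")),
        })
    return pd.DataFrame(rows, columns=GENE_STATS_COLUMNS)


def _eligible_for_density(stats_df: pd.DataFrame, cfg: RankingConfig) -> pd.DataFrame:
    return stats_df[(stats_df.length_bp >= cfg.min_length_bp)
                    & (stats_df.segregating_sites >= cfg.min_segregating)]


def rank_by_density(stats_df: pd.DataFrame, cfg: RankingConfig,
                    lineage: str) -> set[str]:
    """Gene ids in the top `density_top_fraction` of HF-change density.

    Ties at the threshold density are all included.
    """
    if lineage not in ("human", "archaic"):
        raise ValueError("lineage must be 'human' or 'archaic'")
    eligible = _eligible_for_density(stats_df, cfg)
    n = len(eligible)
    if n < MIN_ELIGIBLE_GENES:
        raise ValueError(f"only {n} eligible genes; need >= {MIN_ELIGIBLE_GENES} "
                         "— provide a larger input")
    dens = eligible[f"density_{lineage}"].to_numpy()
    k = math.ceil(cfg.density_top_fraction * n)
    threshold = np.sort(dens)[::-1][k - 1]
    return set(eligible.gene_id[dens >= threshold])


def rank_by_ratio(stats_df: pd.DataFrame, cfg: RankingConfig
                  ) -> tuple[set[str], set[str]]:
    """(human-enriched, archaic-enriched) gene sets by HF-change ratio."""
    eligible = stats_df[(stats_df.hf_human + stats_df.hf_archaic)
                        >= cfg.ratio_min_total]
    n = len(eligible)
    if n < MIN_ELIGIBLE_GENES:
        raise ValueError(f"only {n} eligible genes; need >= {MIN_ELIGIBLE_GENES} "
                         "— provide a larger input")

    def top(keys: list[tuple]) -> set[str]:
        order = sorted(range(n), key=lambda i: keys[i], reverse=True)
        k = math.ceil(cfg.ratio_top_fraction * n)
        threshold = keys[order[k - 1]]
        return {eligible.gene_id.iloc[i] for i in order if keys[i] >= threshold}

    hum_keys = []
    arc_keys = []
    for row in eligible.itertuples(index=False):
        if row.hf_archaic == 0:
            hum_keys.append((math.inf, row.hf_human))
        else:
            hum_keys.append((row.hf_human / row.hf_archaic, row.hf_human))
        if row.hf_human == 0:
            arc_keys.append((math.inf, row.hf_archaic))
        else:
            arc_keys.append((row.hf_archaic / row.hf_human, row.hf_archaic))
    return top(hum_keys), top(arc_keys)


def length_correlations(stats_df: pd.DataFrame) -> dict[str, Optional[float]]:
    """Pearson correlations of per-gene counts with genomic span length."""
    if len(stats_df) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    out: dict[str, Optional[float]] = {}
    length = stats_df.length_bp.to_numpy(dtype=float)
    for col in ("segregating_sites", "hf_human", "fixed_human",
                "hf_archaic", "fixed_archaic"):
        y = stats_df[col].to_numpy(dtype=float)
        if np.ptp(length) == 0 or np.ptp(y) == 0:
            out[col] = None
            continue
        out[col] = float(stats.pearsonr(length, y).statistic)
    return out
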