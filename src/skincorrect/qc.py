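"""Feature- and sample-level quality control for ASV tables.

The fixed pipeline is: drop eukaryote/organelle lineages, keep ASVs seen at
>= ``min_feature_count`` copies in >= ``min_feature_samples`` samples, then
drop samples shallower than ``min_sample_depth`` reads.  A Shannon
rarefaction curve supports choosing the depth threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FeatureTable, TaxonomyTable, ValidationError


@dataclass
class QCConfig:
    min_feature_count: int = 100
    min_feature_samples: int = 2
    min_sample_depth: int = 1000
    organelle_keywords: tuple = ("Chloroplast", "Mitochondria", "Eukaryota")

    def __post_init__(self) -> None:
        if min(self.min_feature_count, self.min_feature_samples,
               self.min_sample_depth) < 0:
            raise ValueError("QC thresholds must be non-negative")


def exclude_organelles(table: FeatureTable, taxonomy: TaxonomyTable,
                       cfg: QCConfig = QCConfig()) -> tuple[FeatureTable, list]:
    """Remove features whose lineage contains an organelle/eukaryote keyword
    (case-insensitive substring at any rank).

    Features missing from the taxonomy are retained and returned in the
    uncovered report.
    """
    keywords = [k.lower() for k in cfg.organelle_keywords]
    lineages = taxonomy.lineages
    uncovered, keep = [], []
    for fid in table.feature_ids:
        if fid not in lineages.index:
            uncovered.append(fid)
            keep.append(fid)
            continue
        tokens = [t.strip().lower() for t in str(lineages[fid]).split(";")]
        if any(kw in tok for tok in tokens for kw in keywords):
            continue
        keep.append(fid)
    return table.select_features(keep), uncovered


def filter_features(table: FeatureTable,
                    cfg: QCConfig = QCConfig()) -> FeatureTable:
    """Keep features with count >= min_feature_count in >= min_feature_samples
    samples (thresholds inclusive)."""
    qualifying = (table.counts >= cfg.min_feature_count).sum(axis=0)
    keep = qualifying.index[qualifying >= cfg.min_feature_samples]
    return table.select_features(list(keep))


def filter_samples(table: FeatureTable,
                   cfg: QCConfig = QCConfig()) -> FeatureTable:
    """Keep samples with total reads >= min_sample_depth."""
    totals = table.sample_totals()
    keep = totals.index[totals >= cfg.min_sample_depth]
    if len(keep) == 0:
        raise ValidationError(
            f"all samples fall below the depth threshold {cfg.min_sample_depth}"
        )
    return table.select_samples(list(keep))


def apply_qc(table: FeatureTable, taxonomy: TaxonomyTable | None,
             cfg: QCConfig = QCConfig()) -> tuple[FeatureTable, dict]:
    """Fixed-order QC pipeline: organelles -> features -> samples."""
    report: dict = {}
    if taxonomy is not None:
        n0 = len(table.feature_ids)
        table, uncovered = exclude_organelles(table, taxonomy, cfg)
        report["organelle_features_removed"] = n0 - len(table.feature_ids)
        report["features_without_taxonomy"] = uncovered
    n0 = len(table.feature_ids)
    table = filter_features(table, cfg)
    report["low_abundance_features_removed"] = n0 - len(table.feature_ids)
    n0 = len(table.sample_ids)
    table = filter_samples(table, cfg)
    report["shallow_samples_removed"] = n0 - len(table.sample_ids)
    return table, report


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (natural log) of a count vector."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        return 0.0
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def rarefaction_curve(table: FeatureTable, depths, replicates: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Mean Shannon diversity of without-replacement subsamples.

    Returns a samples x depths frame; entries are NaN where the requested
    depth exceeds the sample's total read count.
    """
    depths = list(depths)
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depth grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    out = np.full((len(table.sample_ids), len(depths)), np.nan)
    counts = table.counts.to_numpy()
    for i, total in enumerate(counts.sum(axis=1)):
        row = counts[i]
        for j, depth in enumerate(depths):
            if depth > total:
                continue
            values = []
            for _ in range(replicates):
                sub = rng.multivariate_hypergeometric(row, depth)
                values.append(shannon(sub))
            out[i, j] = float(np.mean(values))
    return pd.DataFrame(out, index=table.sample_ids, columns=depths)
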