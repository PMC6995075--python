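"""Taxonomic collapsing, the Proteobacteria:Bacteroidetes ratio, and ANCOM.

The Proteobacteria-to-Bacteroidetes relationship is a fish-health indicator:
compromised fish show elevated Bacteroidetes relative abundance, and in this
workflow the ratio is compared across sampling sites to flag eutrophication-
driven dysbiosis.  ANCOM is the compositional differential-abundance test:
for each ASV it counts how many of its pairwise log-ratios against the other
ASVs differ significantly between groups (the W statistic), so its output is
invariant to per-sample scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correction import bh_adjust
from .data_model import FeatureTable, TaxonomyTable

UNASSIGNED = "Unassigned"


@dataclass
class CollapsedTable:
    """Per-sample taxon counts and relative abundances at one rank."""

    rank: str
    counts: pd.DataFrame       # samples x taxa (summed feature counts)
    proportions: pd.DataFrame  # rows sum to 1


def collapse(table: FeatureTable, taxonomy: TaxonomyTable,
             rank: str = "phylum") -> CollapsedTable:
    """Sum counts over features sharing a rank label, then normalise.

    Features with an unassigned rank (or missing from the taxonomy) pool
    into ``Unassigned``.
    """
    labels = taxonomy.rank_label(rank)
    mapping = {}
    for fid in table.feature_ids:
        lab = labels.get(fid, "")
        mapping[fid] = lab if isinstance(lab, str) and lab.strip() else UNASSIGNED
    grouped = table.counts.T.groupby(pd.Series(mapping)).sum().T
    totals = grouped.sum(axis=1)
    proportions = grouped.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return CollapsedTable(rank=rank, counts=grouped, proportions=proportions)


def dysbiosis_ratio(collapsed: CollapsedTable, meta: pd.DataFrame,
                    numerator: str = "Proteobacteria",
                    denominator: str = "Bacteroidetes") -> pd.DataFrame:
    """Per-site mean relative abundance of the two phyla and their ratio.

    The ratio is Proteobacteria mean over Bacteroidetes mean; when the
    denominator phylum is absent at a site the ratio is reported as
    infinite, explicitly.  Phylum labels match case-insensitively.
    """
    if collapsed.rank != "phylum":
        raise ValueError("dysbiosis ratio requires a phylum-level table")
    lower = {c.lower(): c for c in collapsed.proportions.columns}
    num_col = lower.get(numerator.lower())
    den_col = lower.get(denominator.lower())
    props = collapsed.proportions
    sites = meta.loc[props.index, "site"]
    rows = []
    for site, ids in props.groupby(sites).groups.items():
        sub = props.loc[ids]
        num = float(sub[num_col].mean()) if num_col else 0.0
        den = float(sub[den_col].mean()) if den_col else 0.0
        ratio = num / den if den > 0 else float("inf")
        rows.append({"site": site, "n_samples": len(ids),
                     f"{numerator.lower()}_mean": num,
                     f"{denominator.lower()}_mean": den,
                     "ratio": ratio,
                     "ratio_infinite": den == 0})
    return pd.DataFrame(rows).set_index("site")


def ancom(table: FeatureTable, groups, tau: float = 0.05,
          theta: float = 0.7) -> pd.DataFrame:
    """ANCOM W statistics and detection calls for a two-group comparison.

    With pseudocount 1 added throughout, every feature pair (i, j) is tested
    with a two-sided Mann-Whitney U on log(count_i / count_j) across the two
    groups; p-values are BH-adjusted within each feature's row of m - 1
    ratios, W_i counts the rejections at level ``tau``, and feature i is
    detected when W_i >= theta * (m - 1).
    """
    m = len(table.feature_ids)
    if m < 2:
        raise ValueError("ANCOM needs at least two features (log-ratios)")
    labels = pd.Series(list(groups), index=table.sample_ids)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError("ANCOM here compares exactly two groups")
    g1 = labels.index[labels == uniq[0]]
    g2 = labels.index[labels == uniq[1]]
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("each group needs at least three samples")
    logc = np.log(table.counts.to_numpy(dtype=float) + 1.0)
    a = logc[[table.sample_ids.index(s) for s in g1]]
    b = logc[[table.sample_ids.index(s) for s in g2]]
    pvals = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            res = stats.mannwhitneyu(a[:, i] - a[:, j], b[:, i] - b[:, j],
                                     alternative="two-sided",
                                     method="asymptotic")
            pvals[i, j] = pvals[j, i] = res.pvalue
    w = np.zeros(m, dtype=int)
    for i in range(m):
        row = np.delete(pvals[i], i)
        q = bh_adjust(row)
        w[i] = int((q < tau).sum())
    detected = w >= theta * (m - 1)
    return pd.DataFrame({"W": w, "detected": detected},
                        index=table.feature_ids)
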