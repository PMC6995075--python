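"""Functional-profile shift between raw and corrected communities.

Pathway abundances are predicted as the matrix product of ASV counts with a
genome-content table (copies of each pathway per ASV genome), normalised to
per-sample relative abundances.  The raw-vs-corrected comparison is a paired
Wilcoxon signed-rank test per pathway term (the same swab sample appears in
both datasets), BH-corrected across terms, followed by a per-category tally
of significant terms split by direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correction import bh_adjust
from .data_model import FeatureTable, ValidationError

UNCATEGORIZED = "Uncategorized"


def predict_pathways(table: FeatureTable,
                     genome: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Samples x pathway relative abundance matrix.

    ``genome`` is features x pathway terms with non-negative contribution
    weights.  Table features absent from the genome table contribute a zero
    row and are returned in the report list.
    """
    if (np.asarray(genome, dtype=float) < 0).any():
        raise ValidationError("genome-content weights must be non-negative")
    missing = [f for f in table.feature_ids if f not in genome.index]
    aligned = genome.reindex(table.feature_ids).fillna(0.0)
    raw = table.counts.to_numpy(dtype=float) @ aligned.to_numpy(dtype=float)
    totals = raw.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"sample(s) with all-zero pathway abundance: "
            f"{[table.sample_ids[i] for i in zero]}"
        )
    rel = raw / totals[:, None]
    return pd.DataFrame(rel, index=table.sample_ids,
                        columns=list(genome.columns)), missing


@dataclass
class FunctionalShift:
    per_term: pd.DataFrame        # term, p, q, direction
    category_counts: pd.DataFrame  # category x direction counts
    skipped_terms: list


def compare_raw_corrected(raw_pathways: pd.DataFrame,
                          corrected_pathways: pd.DataFrame,
                          category_map: pd.Series | dict | None = None,
                          alpha: float = 0.05,
                          paired: bool = True) -> FunctionalShift:
    """Per-term Wilcoxon comparison of raw vs corrected pathway profiles.

    The exact signed-rank distribution is used for n <= 25 pairs without
    ties or zero differences; direction is the sign of the mean difference
    (``raw>corrected`` or ``corrected>raw``).  Terms that are constant zero
    in both datasets are skipped and reported.
    """
    samples = list(raw_pathways.index)
    if set(samples) != set(corrected_pathways.index):
        raise ValidationError("raw and corrected matrices must share samples")
    corrected_pathways = corrected_pathways.loc[samples]
    terms = [t for t in raw_pathways.columns if t in corrected_pathways.columns]
    rows, skipped = [], []
    for term in terms:
        x = raw_pathways[term].to_numpy(dtype=float)
        y = corrected_pathways[term].to_numpy(dtype=float)
        if not (x.any() or y.any()):
            skipped.append(term)
            continue
        diff = x - y
        if paired:
            if np.all(diff == 0):
                p = 1.0
            else:
                method = "exact" if diff.size <= 25 else "approx"
                res = stats.wilcoxon(x, y, alternative="two-sided",
                                     method=method)
                p = float(res.pvalue)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
            p = float(res.pvalue)
        direction = "raw>corrected" if diff.mean() > 0 else "corrected>raw"
        rows.append({"term": term, "p_value": p, "direction": direction})
    per_term = pd.DataFrame(rows).set_index("term") if rows else \
        pd.DataFrame(columns=["p_value", "direction"])
    if len(per_term):
        per_term["q_value"] = bh_adjust(per_term["p_value"].to_numpy())
        per_term["significant"] = per_term["q_value"] < alpha
    else:
        per_term["q_value"] = []
        per_term["significant"] = []

    if category_map is None:
        category_map = {}
    cat = pd.Series({t: category_map.get(t, UNCATEGORIZED)
                     for t in per_term.index}) if len(per_term) else pd.Series(dtype=object)
    sig = per_term[per_term.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    counts = (
        sig.assign(category=cat.loc[sig.index])
        .groupby(["category", "direction"]).size().unstack(fill_value=0)
        if len(sig) else pd.DataFrame()
    )
    return FunctionalShift(per_term=per_term, category_counts=counts,
                           skipped_terms=skipped)
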