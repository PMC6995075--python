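"""Water-background correction of swab communities.

Skin swabs taken in situ carry reads from the ambient water as well as from
the fish's indigenous skin community.  The correction implemented here keeps
an ASV in the "corrected skin community" only if it is either unique to the
swab samples (zero reads in every water sample) or significantly *more*
abundant, in relative terms, in swabs than in water — a one-sided
Mann-Whitney U test per ASV, Benjamini-Hochberg corrected across all tested
ASVs.

:class:`BackgroundCorrector` exposes the procedure as a scikit-learn style
feature-selection transformer: ``fit`` on a counts frame plus swab/water
labels learns the retained ASV set, ``transform`` restricts swab samples to
it.  :func:`correct` is the one-call functional form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_model import FeatureTable, ValidationError

STATUS_UNIQUE = "unique_to_swab"
STATUS_TESTED = "tested"


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample proportions; every row sums to one.

    Raises on a zero-total sample — those should have been removed by depth
    filtering before any compositional step.
    """
    totals = table.counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {list(zero)}")
    return table.counts.div(totals, axis=0)


def mann_whitney_greater(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Mann-Whitney U of ``x`` vs ``y``.

    U counts pairs with x_i > y_j plus half the ties.  The exact null
    distribution is enumerated when both groups together hold at most 12
    observations and there are no ties; otherwise the normal approximation
    with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CorrectionResult:
    """Per-feature correction outcome plus the retained set."""

    per_feature: pd.DataFrame  # index: feature id
    retained_features: list
    alpha: float

    @property
    def removed_features(self) -> list:
        return [f for f in self.per_feature.index
                if f not in set(self.retained_features)]


class BackgroundCorrector(BaseEstimator):
    """Select ASVs over-represented in swabs relative to ambient water.

    Parameters
    ----------
    alpha : float
        FDR threshold on BH-adjusted one-sided p-values (default 0.05).
    alternative : {"greater", "two-sided"}
        Direction of the per-ASV rank test; the default tests whether swab
        relative abundances are stochastically greater than water ones.

    Attributes
    ----------
    result_ : CorrectionResult
        Per-feature statistics, q-values and retention decisions.
    retained_features_ : list of feature ids kept in the corrected community.
    """

    def __init__(self, alpha: float = 0.05, alternative: str = "greater"):
        self.alpha = alpha
        self.alternative = alternative

    def fit(self, X: pd.DataFrame, y) -> "BackgroundCorrector":
        """Learn the retained feature set.

        X is a samples x features count frame; y gives each sample's type
        ("swab" or "water").
        """
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        swabs = X.index[y == "swab"]
        waters = X.index[y == "water"]
        if len(waters) == 0:
            raise ValidationError(
                "no water samples: skip background correction explicitly "
                "rather than running it without a comparison group"
            )
        if len(swabs) == 0:
            raise ValidationError("no swab samples to correct")
        rel = relative_abundance(FeatureTable(X))
        rel_s, rel_w = rel.loc[swabs], rel.loc[waters]
        water_totals = X.loc[waters].sum(axis=0)

        records: dict[str, dict] = {}
        tested_ids, tested_p = [], []
        for fid in X.columns:
            xs = rel_s[fid].to_numpy()
            xw = rel_w[fid].to_numpy()
            rec = {
                "swab_median_relabund": float(np.median(xs)),
                "water_median_relabund": float(np.median(xw)),
            }
            if water_totals[fid] == 0:
                rec.update(status=STATUS_UNIQUE, U=np.nan, p_value=np.nan,
                           q_value=np.nan, retained=True)
            else:
                U, p = mann_whitney_greater(xs, xw, self.alternative)
                rec.update(status=STATUS_TESTED, U=U, p_value=p,
                           q_value=np.nan, retained=False)
                tested_ids.append(fid)
                tested_p.append(p)
            records[fid] = rec

        per_feature = pd.DataFrame.from_dict(records, orient="index")
        per_feature = per_feature[
            ["status", "U", "p_value", "q_value",
             "swab_median_relabund", "water_median_relabund", "retained"]
        ]
        if tested_ids:
            q = bh_adjust(tested_p)
            per_feature.loc[tested_ids, "q_value"] = q
            keep = per_feature.loc[tested_ids, "q_value"] < self.alpha
            per_feature.loc[tested_ids, "retained"] = keep
        retained = [f for f in X.columns if per_feature.loc[f, "retained"]]
        self.result_ = CorrectionResult(per_feature, retained, self.alpha)
        self.retained_features_ = retained
        self._swab_samples = list(swabs)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict to the retained features (all rows of X are kept; pass
        the swab subset to obtain the corrected skin community)."""
        if not hasattr(self, "result_"):
            raise RuntimeError("BackgroundCorrector is not fitted")
        return X[self.retained_features_].copy()

    def fit_transform(self, X: pd.DataFrame, y) -> pd.DataFrame:
        self.fit(X, y)
        return self.transform(X.loc[self._swab_samples])


def correct(table: FeatureTable, meta: pd.DataFrame, alpha: float = 0.05,
            alternative: str = "greater") -> tuple[CorrectionResult, FeatureTable]:
    """Run the background correction; return the per-feature result and the
    corrected table (swab samples only, retained features only)."""
    y = meta.loc[table.sample_ids, "sample_type"]
    corrector = BackgroundCorrector(alpha=alpha, alternative=alternative)
    corrected = corrector.fit_transform(table.counts, y)
    return corrector.result_, FeatureTable(corrected)
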