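"""Ordination (PCoA with biplots) and the rank/permutation tests around it.

PCoA is classical metric scaling: double-centre -D^2/2, eigendecompose, keep
positive eigenvalues.  Explained-variance fractions use the positive
eigenvalues only (no Cailliez/Lingoes correction by default).  PERMANOVA
follows the within/between sum-of-squared-distances pseudo-F with a
label-permutation null and the +1-corrected p-value, so p can never be
exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .correction import bh_adjust


@dataclass
class OrdinationResult:
    sample_ids: list
    coordinates: pd.DataFrame        # samples x axes
    eigenvalues: np.ndarray          # descending, positive axes first
    explained_fraction: np.ndarray   # per retained axis, in [0, 1]
    biplot_features: pd.DataFrame | None = None


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each axis's largest-magnitude loading positive (deterministic
    orientation)."""
    vectors = vectors.copy()
    for k in range(vectors.shape[1]):
        col = vectors[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            vectors[:, k] = -col
    return vectors


class PCoA(BaseEstimator):
    """Principal coordinates analysis of a distance matrix.

    Parameters
    ----------
    n_axes : int
        Number of axes to retain; truncated (with a warning) if the positive
        spectrum has lower rank.
    """

    def __init__(self, n_axes: int = 2):
        self.n_axes = n_axes

    def fit(self, d: pd.DataFrame) -> "PCoA":
        self.fit_transform(d)
        return self

    def fit_transform(self, d: pd.DataFrame) -> pd.DataFrame:
        dm = np.asarray(d, dtype=float)
        ids = list(d.index) if isinstance(d, pd.DataFrame) else list(range(len(dm)))
        n = dm.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dm ** 2) @ j
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        tol = max(np.abs(eigval).max(), 1.0) * 1e-10
        positive = eigval > tol
        n_pos = int(positive.sum())
        k = min(self.n_axes, n_pos)
        if k < self.n_axes:
            import warnings

            warnings.warn(
                f"requested {self.n_axes} axes but the positive spectrum has "
                f"rank {n_pos}; returning {k}", stacklevel=2)
        coords = _fix_signs(eigvec[:, :k]) * np.sqrt(eigval[:k]) if k else \
            np.zeros((n, 0))
        denom = eigval[positive].sum()
        frac = (eigval[:k] / denom) if denom > 0 else np.zeros(k)
        self.eigenvalues_ = eigval[:k]
        self.explained_fraction_ = frac
        self.all_eigenvalues_ = eigval
        coords_df = pd.DataFrame(
            coords, index=ids, columns=[f"PC{i+1}" for i in range(k)])
        self.coordinates_ = coords_df
        self.result_ = OrdinationResult(ids, coords_df, self.eigenvalues_, frac)
        return coords_df


def pcoa(d: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    model = PCoA(n_axes=n_axes)
    model.fit(d)
    return model.result_


def biplot(ordination: OrdinationResult, table_counts: pd.DataFrame,
           k: int = 4) -> pd.DataFrame:
    """Feature arrows for a PCoA plot.

    Each feature's arrow is the mean of sample coordinates weighted by the
    feature's per-sample proportions (normalised over samples); its effect
    size is the arrow's Euclidean length.  Returns the top-k features by
    effect size, ties broken lexicographically by feature id.
    """
    coords = ordination.coordinates.loc[list(table_counts.index)]
    rel = table_counts.div(table_counts.sum(axis=1), axis=0)
    weights = rel / rel.sum(axis=0)  # normalise each feature over samples
    arrows = weights.T @ coords      # features x axes
    effect = np.sqrt((arrows ** 2).sum(axis=1))
    out = arrows.copy()
    out["effect_size"] = effect
    # effect size descending, ties broken by feature id ascending
    out = out.iloc[np.lexsort((out.index.to_numpy(), -out["effect_size"].to_numpy()))]
    return out.head(min(k, len(out)))


def _permanova_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    a = groups.size
    ss_among = ss_total - ss_within
    # zero within-group scatter gives an infinite pseudo-F, deliberately
    with np.errstate(divide="ignore"):
        return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(d: pd.DataFrame, groups, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns the pseudo-F and the +1-corrected permutation p-value
    ``(1 + #(F_perm >= F_obs)) / (1 + n_perm)``.
    """
    labels = np.asarray(pd.Series(groups), dtype=object)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = np.asarray(d, dtype=float) ** 2
    f_obs = _permanova_f(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_f(d2, perm, uniq) >= f_obs:
            hits += 1
    return float(f_obs), (1 + hits) / (1 + n_perm)


def pairwise_permanova(d: pd.DataFrame, groups, n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """PERMANOVA on every group pair, BH-corrected across pairs."""
    labels = pd.Series(groups, index=d.index)
    uniq = sorted(labels.unique())
    rows = []
    for i, (g1, g2) in enumerate(itertools.combinations(uniq, 2)):
        ids = labels.index[labels.isin([g1, g2])]
        sub = d.loc[ids, ids]
        f, p = permanova(sub, labels.loc[ids], n_perm=n_perm, seed=seed + i)
        rows.append({"group_1": g1, "group_2": g2, "pseudo_F": f, "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test (tie-corrected H, chi-squared p on g-1 df)."""
    frame = pd.DataFrame({"v": np.asarray(values, float), "g": list(groups)})
    samples = [sub["v"].to_numpy() for _, sub in frame.groupby("g")]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(frame["v"].to_numpy()) == 0:  # all values identical
        return 0.0, 1.0
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def pairwise_kruskal_wallis(values, groups) -> pd.DataFrame:
    """Kruskal-Wallis on every group pair, BH-corrected across pairs."""
    frame = pd.DataFrame({"v": np.asarray(values, float), "g": list(groups)})
    uniq = sorted(frame["g"].unique())
    rows = []
    for g1, g2 in itertools.combinations(uniq, 2):
        sub = frame[frame["g"].isin([g1, g2])]
        h, p = kruskal_wallis(sub["v"], sub["g"])
        rows.append({"group_1": g1, "group_2": g2, "H": h, "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def pearson_r2(x, y) -> tuple[float, float]:
    """Pearson r and r^2 over complete pairs; missing values drop the pair.

    Returns (nan, nan) when either side has zero variance over the complete
    pairs (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        raise ValueError("need at least three complete pairs")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), float("nan")
    r = float(stats.pearsonr(xs, ys).statistic)
    return r, r * r
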