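"""Linearity audit: kernel PCA (linear vs RBF) followed by epsilon-SVR.

PCoA and Pearson correlation both assume linear structure.  To gauge how
much that assumption shapes the conclusions, the same ordination-then-
regression analysis is repeated with a kernel PCA on relative abundances —
once with a linear kernel (equivalent to classical PCA) and once with an
RBF kernel — and each principal component is regressed on each water
measurement by support vector regression with the matching kernel.  The
output is a grid of in-sample R^2 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.svm import SVR

from .ordination import OrdinationResult, _fix_signs


@dataclass
class KernelConfig:
    kernel: str = "rbf"
    gamma: float | None = None      # None -> median heuristic
    svr_epsilon: float = 0.1
    svr_C: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.svr_C <= 0 or self.svr_epsilon < 0:
            raise ValueError("require C > 0 and epsilon >= 0")


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width 1 / median(nonzero pairwise squared Euclidean distances)."""
    from scipy.spatial.distance import pdist

    d2 = pdist(X, "sqeuclidean")
    d2 = d2[d2 > 0]
    if d2.size == 0:
        return 1.0
    return float(1.0 / np.median(d2))


class KernelPCoA(BaseEstimator):
    """Kernel principal component analysis of a samples x features matrix.

    The kernel matrix is double-centred and eigendecomposed; scores are
    eigenvectors scaled by the square root of their eigenvalues, with the
    same deterministic sign convention as PCoA.  Negative eigenvalues of the
    centred kernel (numerically possible) are dropped with a warning.
    """

    def __init__(self, kernel: str = "linear", gamma: float | None = None,
                 n_axes: int = 2):
        self.kernel = kernel
        self.gamma = gamma
        self.n_axes = n_axes

    def _kernel_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return X @ X.T
        if self.kernel == "rbf":
            gamma = self.gamma if self.gamma is not None else \
                median_heuristic_gamma(X)
            self.gamma_ = gamma
            sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
            return np.exp(-gamma * sq)
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def fit_transform(self, X) -> pd.DataFrame:
        ids = list(X.index) if isinstance(X, pd.DataFrame) else \
            list(range(len(X)))
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least two samples")
        K = self._kernel_matrix(X)
        n = K.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        Kc = j @ K @ j
        eigval, eigvec = np.linalg.eigh((Kc + Kc.T) / 2)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        tol = max(abs(eigval).max(), 1.0) * 1e-10
        if eigval.min() < -tol:
            warnings.warn("centred kernel is not PSD beyond tolerance; "
                          "negative eigenvalues dropped", stacklevel=2)
        positive = eigval > tol
        k = min(self.n_axes, int(positive.sum()))
        scores = _fix_signs(eigvec[:, :k]) * np.sqrt(np.maximum(eigval[:k], 0))
        denom = eigval[positive].sum()
        self.eigenvalues_ = eigval[:k]
        self.explained_fraction_ = (eigval[:k] / denom) if denom > 0 else \
            np.zeros(k)
        coords = pd.DataFrame(scores, index=ids,
                              columns=[f"PC{i+1}" for i in range(k)])
        self.coordinates_ = coords
        self.result_ = OrdinationResult(ids, coords, self.eigenvalues_,
                                        self.explained_fraction_)
        return coords

    def fit(self, X) -> "KernelPCoA":
        self.fit_transform(X)
        return self


def kernel_pca(features: pd.DataFrame, cfg: KernelConfig = KernelConfig(),
               n_axes: int = 2) -> OrdinationResult:
    model = KernelPCoA(kernel=cfg.kernel, gamma=cfg.gamma, n_axes=n_axes)
    model.fit(features)
    return model.result_


def svr_r2(x, y, cfg: KernelConfig = KernelConfig()) -> float:
    """In-sample R^2 of an epsilon-SVR of y on x (pairs with missing y drop).

    Returns NaN when y has zero variance over the complete pairs.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(x[:, 0])
    if mask.sum() < 5:
        raise ValueError("need at least five complete pairs")
    xs, ys = x[mask], y[mask]
    if np.ptp(ys) == 0:
        return float("nan")
    gamma = cfg.gamma if cfg.gamma is not None else \
        median_heuristic_gamma(xs)
    model = SVR(kernel=cfg.kernel, C=cfg.svr_C, epsilon=cfg.svr_epsilon,
                gamma=gamma if cfg.kernel == "rbf" else "scale")
    model.fit(xs, ys)
    pred = model.predict(xs)
    sse = float(((ys - pred) ** 2).sum())
    sst = float(((ys - ys.mean()) ** 2).sum())
    return 1.0 - sse / sst


def linearity_report(raw_rel: pd.DataFrame, corrected_rel: pd.DataFrame,
                     measurements: pd.DataFrame,
                     svr_epsilon: float = 0.1, svr_C: float = 1.0) -> pd.DataFrame:
    """Full R^2 grid: dataset x PC{1,2} x measurement x kernel.

    ``raw_rel`` and ``corrected_rel`` are samples x features relative
    abundance matrices; ``measurements`` holds one column per water
    measurement (missing allowed), indexed by sample.
    """
    rows = []
    for ds_name, rel in (("raw", raw_rel), ("corrected", corrected_rel)):
        meas = measurements.loc[rel.index]
        for kernel in ("linear", "rbf"):
            cfg = KernelConfig(kernel=kernel, svr_epsilon=svr_epsilon,
                               svr_C=svr_C)
            scores = kernel_pca(rel, cfg, n_axes=2).coordinates
            for pc in scores.columns:
                for col in meas.columns:
                    r2 = svr_r2(scores[pc], meas[col], cfg)
                    rows.append({"dataset": ds_name, "component": pc,
                                 "measurement": col, "kernel": kernel,
                                 "r2": r2,
                                 "svr_epsilon": svr_epsilon, "svr_C": svr_C})
    return pd.DataFrame(rows)
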