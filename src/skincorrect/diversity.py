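"""Faith phylogenetic diversity and unweighted UniFrac on a rooted tree.

Both metrics are computed from a branch/leaf incidence structure built once
per tree: for every branch, the set of feature leaves it subtends.  Faith PD
of a sample is the total length of branches on the minimal subtree that
connects the sample's observed leaves to the root (the rooted, QIIME-style
convention).  Unweighted UniFrac between two samples is the fraction of
observed branch length subtended exclusively by one of the two presence
sets; it is a proper metric, so the resulting distance matrices satisfy the
triangle inequality exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_model import FeatureTable, ValidationError


def _branch_incidence(tree: TreeNode, feature_ids) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and the branch x feature incidence matrix.

    A branch's incidence row marks the features among ``feature_ids`` found
    at or below it; the root's own branch subtends every feature, matching
    the rooted convention of the QIIME toolchain for both Faith PD and
    UniFrac.  Features must all be leaves of the tree.
    """
    index = {f: i for i, f in enumerate(feature_ids)}
    tips = {t.name for t in tree.tips()}
    missing = [f for f in feature_ids if f not in tips]
    if missing:
        raise ValidationError(f"feature(s) not in tree: {missing}")
    n = len(feature_ids)
    lengths, rows = [], []
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        mask = np.zeros(n, dtype=bool)
        if node.is_tip():
            if node.name in index:
                mask[index[node.name]] = True
        else:
            for child in node.children:
                mask |= masks.pop(id(child))
        masks[id(node)] = mask
        lengths.append(node.length or 0.0)
        rows.append(mask)
    return np.asarray(lengths), np.asarray(rows)


def faith_pd(sample_features, tree: TreeNode) -> float:
    """Total branch length connecting the observed leaves to the root.

    The empty set has PD zero.
    """
    present = set(sample_features)
    if not present:
        return 0.0
    feature_ids = sorted(present)
    lengths, incidence = _branch_incidence(tree, feature_ids)
    observed = incidence.any(axis=1)
    return float(lengths[observed].sum())


def unweighted_unifrac(sample_a, sample_b, tree: TreeNode) -> float:
    """Presence/absence UniFrac: unique observed branch length over total
    observed branch length."""
    a, b = set(sample_a), set(sample_b)
    if not a and not b:
        raise ValidationError("both samples are empty")
    feature_ids = sorted(a | b)
    lengths, incidence = _branch_incidence(tree, feature_ids)
    in_a = np.array([f in a for f in feature_ids])
    in_b = np.array([f in b for f in feature_ids])
    obs_a = incidence[:, in_a].any(axis=1) if in_a.any() else np.zeros(len(lengths), bool)
    obs_b = incidence[:, in_b].any(axis=1) if in_b.any() else np.zeros(len(lengths), bool)
    union = obs_a | obs_b
    shared = obs_a & obs_b
    total = lengths[union].sum()
    if total == 0:
        return 0.0
    return float(lengths[union & ~shared].sum() / total)


def faith_pd_table(table: FeatureTable, tree: TreeNode) -> pd.Series:
    """Faith PD for every sample of a feature table (presence = count >= 1)."""
    lengths, incidence = _branch_incidence(tree, table.feature_ids)
    presence = table.counts.to_numpy() > 0
    # branch observed in sample s iff any subtended feature present
    observed = presence @ incidence.T.astype(np.int64) > 0
    pd_values = observed @ lengths
    return pd.Series(pd_values, index=table.sample_ids, name="faith_pd")


def pairwise_unifrac(table: FeatureTable, tree: TreeNode) -> pd.DataFrame:
    """Unweighted UniFrac distance matrix over all sample pairs.

    Computed in one pass from the branch incidence structure: with
    L_i the observed branch length of sample i and S_ij the length shared by
    samples i and j, d(i, j) = 1 - S_ij / (L_i + L_j - S_ij).
    """
    presence = table.counts.to_numpy() > 0
    empty = np.flatnonzero(~presence.any(axis=1))
    if empty.size:
        raise ValidationError(
            f"sample(s) with no observed features: "
            f"{[table.sample_ids[i] for i in empty]}"
        )
    lengths, incidence = _branch_incidence(tree, table.feature_ids)
    observed = (presence @ incidence.T.astype(np.int64) > 0).astype(float)
    weighted = observed * lengths  # n_samples x n_branches
    shared = weighted @ observed.T  # S_ij
    own = weighted.sum(axis=1)
    union = own[:, None] + own[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - shared / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # symmetrise away float noise
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def write_distance_matrix(dm: pd.DataFrame, path, provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            for line in provenance.splitlines():
                fh.write(f"## {line}\n")
        dm.to_csv(fh, sep="\t")


def read_distance_matrix(path) -> pd.DataFrame:
    from io import StringIO

    from .data_model import _open_skipping_provenance

    lines = _open_skipping_provenance(path)
    df = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return df
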