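"""Variable clustering: |Kendall tau-b| similarity + Ward agglomeration.

Variables (not patients) are clustered.  The similarity between two
variables is the absolute value of their tie-corrected Kendall rank
correlation; the dendrogram is built by Ward linkage on the dissimilarity
d = 1 - |tau| (the square-root variant sqrt(1 - |tau|) is available), and
can be cut at any number of clusters k.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._kendall import pairwise_abs_tau


def kendall_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise |tau-b| similarity matrix over feature columns.

    Constant columns cannot be ranked against anything: they get similarity
    0 to every other column (diagonal stays 1), are reported in the second
    return value, and should be excluded from clustering.
    """
    if len(features) < 3:
        raise ValueError("kendall_matrix: need at least 3 patients")
    cols = list(features.columns)
    X = features.to_numpy(dtype=float)
    constant = [c for j, c in enumerate(cols) if np.nanstd(X[:, j]) == 0.0]
    if constant:
        warnings.warn(f"{len(constant)} constant feature(s) excluded from clustering: "
                      f"{constant[:5]}{'...' if len(constant) > 5 else ''}")
    S = pairwise_abs_tau(X)
    S[~np.isfinite(S)] = 0.0
    np.fill_diagonal(S, 1.0)
    for c in constant:
        j = cols.index(c)
        S[j, :] = S[:, j] = 0.0
        S[j, j] = 1.0
    return pd.DataFrame(S, index=cols, columns=cols), constant


def ward_tree(similarity: pd.DataFrame, dissimilarity: str = "one-minus-abs-tau") -> np.ndarray:
    """Ward linkage matrix from a similarity matrix.

    The similarity is converted to a dissimilarity (1 - S by default,
    sqrt(1 - S) optionally) and agglomerated with the Lance–Williams Ward
    update on the precomputed distances.  Returns a scipy-format linkage
    matrix (left, right, height, count) with n-1 rows.
    """
    S = similarity.to_numpy(dtype=float)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("ward_tree: similarity matrix must be square and symmetric")
    if S.shape[0] < 2:
        raise ValueError("ward_tree: need at least 2 features")
    D = 1.0 - S
    if dissimilarity == "sqrt":
        D = np.sqrt(np.maximum(D, 0.0))
    elif dissimilarity != "one-minus-abs-tau":
        raise ValueError(f"unknown dissimilarity: {dissimilarity!r}")
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="ward")


def cut_k(tree: np.ndarray, k: int, labels: list[str] | None = None) -> pd.Series:
    """Cut the dendrogram into exactly k clusters.

    Cluster ids are renumbered 1..k in order of each cluster's smallest
    member index, so the assignment is stable across runs and feature
    permutations (up to the permutation itself).
    """
    n = tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"cut_k: k must be in [1, {n}], got {k}")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # stable relabelling by first occurrence
    order = {}
    for cid in raw:
        if cid not in order:
            order[cid] = len(order) + 1
    stable = np.array([order[c] for c in raw])
    idx = labels if labels is not None else list(range(n))
    return pd.Series(stable, index=idx, name="cluster")


def merge_sets(tree: np.ndarray) -> list[frozenset[int]]:
    """Leaf-index sets created at each merge, in merge order (for oracles)."""
    n = tree.shape[0] + 1
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(tree):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out
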