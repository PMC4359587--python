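"""Correlation-network grouping of MS features into feature-sets.

LC-MS feature tables routinely contain many near-duplicate features (H/Na
adducts, isotopes, in-source fragments of one metabolite) whose pairwise
correlations approach 1.  Testing them separately multiplies hypotheses
without adding information.  Features are therefore grouped: each feature
is a node, an edge joins two nodes whose absolute correlation exceeds a
threshold, and the connected components of this graph become the
feature-sets.  Connectivity — not pairwise correlation within the whole
set — is deliberate: requiring every pair in a set to correlate is too
stringent and fragments pathways into tiny sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import spearmanr

__all__ = [
    "FeatureSetPartition",
    "pairwise_correlation",
    "threshold_graph",
    "connected_components",
    "group_features",
]

METHODS = ("pearson", "spearman")


@dataclass
class FeatureSetPartition:
    """Disjoint, exhaustive assignment of feature indices to sets.

    ``sets`` is ordered by smallest member index, members sorted; every
    feature appears in exactly one set.
    """

    sets: list[list[int]]
    threshold: float
    method: str

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def labels(self, n_features: int | None = None) -> np.ndarray:
        """Per-feature set index, aligned with the input feature order."""
        if n_features is None:
            n_features = sum(len(s) for s in self.sets)
        out = np.full(n_features, -1, dtype=int)
        for set_id, members in enumerate(self.sets):
            out[members] = set_id
        return out


def _corr_matrix(values: np.ndarray, method: str) -> np.ndarray:
    n_feat = values.shape[0]
    if n_feat == 1:
        return np.ones((1, 1))
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values)
    else:
        corr, _ = spearmanr(values.T)
        if n_feat == 2:  # spearmanr collapses the 2-variable case to a scalar
            corr = np.array([[1.0, corr], [corr, 1.0]])
    return np.asarray(corr, dtype=float)


def pairwise_correlation(
    values: np.ndarray,
    method: str = "pearson",
    jointly_present: bool = False,
) -> np.ndarray:
    """Feature-by-feature correlation matrix of an abundance table.

    ``values`` is features-by-samples.  Zeros (absences) enter the
    correlation as ordinary values unless ``jointly_present=True``, in
    which case each pair is correlated over the samples where both
    features are nonzero (pairs with fewer than 3 such samples get 0).
    Constant (zero-variance) features are assigned correlation 0 with
    every other feature so they can never be grouped.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a features x samples matrix")
    n_feat, n_samp = values.shape
    if n_samp < 3:
        raise ValueError("need at least 3 samples to correlate features")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")

    if jointly_present:
        corr = np.zeros((n_feat, n_feat))
        present = values != 0
        for i in range(n_feat):
            for j in range(i + 1, n_feat):
                both = present[i] & present[j]
                if np.count_nonzero(both) < 3:
                    continue
                sub = _corr_matrix(values[[i, j]][:, both], method)
                corr[i, j] = corr[j, i] = sub[0, 1]
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        return np.clip(corr, -1.0, 1.0)

    corr = _corr_matrix(values, method)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance features
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def threshold_graph(corr: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean adjacency: edge (i, j) iff ``|corr_ij| > threshold`` (strict)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    corr = np.asarray(corr, dtype=float)
    adj = np.abs(corr) > threshold
    np.fill_diagonal(adj, False)
    return adj


def connected_components(
    adjacency: np.ndarray,
    threshold: float = float("nan"),
    method: str = "pearson",
) -> FeatureSetPartition:
    """Connected components of the thresholded correlation graph.

    Isolated features become singleton sets.  Sets are reported in order
    of their smallest member index, with members sorted.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    graph = nx.from_numpy_array(adjacency)
    sets = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda s: s[0])
    return FeatureSetPartition(sets=[list(map(int, s)) for s in sets],
                               threshold=threshold, method=method)


def group_features(
    values: np.ndarray,
    threshold: float = 0.95,
    method: str = "pearson",
    jointly_present: bool = False,
) -> FeatureSetPartition:
    """Correlate, threshold, and extract feature-sets in one call."""
    corr = pairwise_correlation(values, method=method, jointly_present=jointly_present)
    adj = threshold_graph(corr, threshold)
    return connected_components(adj, threshold=threshold, method=method)
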