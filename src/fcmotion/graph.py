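"""Node-strength summaries of consensus edge sets and within/between
network tabulations.

Node strength is the sum over a region's incident connections-of-interest
of the absolute edge weight (a z-score: for diagnosis contrasts the
two-sample t statistic converted to a normal z, for age contrasts the
Fisher z of the age correlation).  Regions with no connection of interest
have strength 0.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

from .connectivity import edge_index
from .io import RoiSet

__all__ = [
    "consensus_features",
    "node_strength",
    "within_between_tabulation",
    "t_to_z",
]


def consensus_features(fold_feature_sets: list[np.ndarray]) -> np.ndarray:
    """Edge indices present in every fold's selection."""
    if not fold_feature_sets:
        raise ValueError("need at least one fold")
    consensus = np.asarray(fold_feature_sets[0])
    for idx in fold_feature_sets[1:]:
        consensus = np.intersect1d(consensus, idx)
    return consensus


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Convert t statistics to standard-normal z scores (sign preserved)."""
    t = np.asarray(t, dtype=float)
    p_one = _stats.t.sf(np.abs(t), df)
    p_one = np.clip(p_one, 1e-300, 1.0)
    return np.sign(t) * _stats.norm.isf(p_one)


def node_strength(edges: np.ndarray, weights: np.ndarray, rois: RoiSet) -> np.ndarray:
    """Per-ROI strength: sum of |weight| over incident edges of the set.

    ``edges`` are canonical edge indices into the upper triangle;
    ``weights`` is the full per-edge weight vector (indexed by the same
    canonical order) or a vector aligned with ``edges``.  ROIs without an
    incident edge get strength 0.
    """
    edges = np.asarray(edges, dtype=int)
    weights = np.asarray(weights, dtype=float)
    n = rois.n_rois
    n_edges = n * (n - 1) // 2
    if edges.size and (edges.min() < 0 or edges.max() >= n_edges):
        raise ValueError(
            f"edge index out of range for a {n}-ROI set ({n_edges} edges)"
        )
    if weights.size == n_edges:
        w = weights[edges]
    elif weights.size == edges.size:
        w = weights
    else:
        raise ValueError("weights must align with the edge set or the full edge list")
    if edges.size and not np.all(np.isfinite(w)):
        raise ValueError("edge weights must be finite on the edge set")
    iu, ju = edge_index(n)
    strength = np.zeros(n)
    np.add.at(strength, iu[edges], np.abs(w))
    np.add.at(strength, ju[edges], np.abs(w))
    return strength


def within_between_tabulation(edges: np.ndarray, signs: np.ndarray,
                              rois: RoiSet) -> dict[str, dict[str, int]]:
    """2x2 counts of significant edges: age-effect sign (stronger/weaker)
    by network relation (within = both endpoints share a network label)."""
    edges = np.asarray(edges, dtype=int)
    signs = np.asarray(signs)
    if edges.size != signs.size:
        raise ValueError("edge set and signs must align")
    nets = rois.networks
    if (np.asarray([len(x) for x in nets]) == 0).any():
        raise ValueError("missing network label")
    iu, ju = edge_index(rois.n_rois)
    counts = {"stronger": {"within": 0, "between": 0},
              "weaker": {"within": 0, "between": 0}}
    for e, s in zip(edges, signs):
        relation = "within" if nets[iu[e]] == nets[ju[e]] else "between"
        key = "stronger" if float(s) > 0 else "weaker"
        counts[key][relation] += 1
    return counts
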