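"""Topological filtering with orthogonal MSTs and Laplacian spectra.

Each connectivity snapshot is sparsified with the Orthogonal Minimal
Spanning Trees (OMST) scheme: successive edge-disjoint minimum spanning
trees are extracted on the distance transform d = 1/w and unioned round by
round, and the round count that maximizes the global cost efficiency

    GCE(m) = GE(m) - Cost(m)

is kept, where GE is the mean inverse shortest-path distance over ordered
node pairs of the selected weighted graph and Cost the fraction of total
edge weight it consumes.  Weights are normalized to unit maximum before the
distance transform so the selection is invariant to a global rescaling of
the weights.  The filtered graph is then summarized by the ascending
eigenvalues of its symmetric normalized Laplacian L_sym = D^{-1/2} (D - A)
D^{-1/2}, whose spectrum lies in [0, 2]; stacking the spectra of successive
windows yields the eigenvalue network-metric time series fed to the
microstate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import (connected_components, minimum_spanning_tree,
                                  shortest_path)

__all__ = [
    "DisconnectedGraphWarning",
    "FilteredGraph",
    "EigenTimeSeries",
    "omst_filter",
    "global_cost_efficiency",
    "normalized_laplacian_eigenvalues",
    "build_nmts",
]


class DisconnectedGraphWarning(UserWarning):
    """The input graph is disconnected; OMST runs per component."""


@dataclass
class FilteredGraph:
    """OMST-filtered adjacency with bookkeeping of the selection."""

    adjacency: np.ndarray
    edges: list[tuple[int, int]]
    rounds_used: int
    gce_by_round: np.ndarray = field(default_factory=lambda: np.empty(0))
    cost_by_round: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class EigenTimeSeries:
    """Ascending L_sym eigenvalues per window: matrix of shape (N, W)."""

    values: np.ndarray
    subject_id: str | None = None

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def _validate_adjacency(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.any(np.diag(w) != 0):
        raise ValueError("diagonal must be zero")
    return w


def global_cost_efficiency(selected: np.ndarray, reference: np.ndarray
                           ) -> float:
    """GCE of a selected subgraph relative to the full reference graph.

    Both arguments are weighted adjacencies; weights are normalized by the
    reference maximum, distances are the reciprocal normalized weights, GE
    averages 1/shortest-path over ordered node pairs (unreachable pairs
    contribute 0) and Cost is the selected fraction of total weight.
    """
    wmax = reference.max()
    if wmax == 0:
        raise ValueError("reference graph has no edges")
    sel = selected / wmax
    ref = reference / wmax
    n = sel.shape[0]
    with np.errstate(divide="ignore"):
        dist = np.where(sel > 0, 1.0 / sel, 0.0)
    sp = shortest_path(csr_matrix(dist), directed=False)
    inv = np.zeros_like(sp)
    finite = np.isfinite(sp) & (sp > 0)
    inv[finite] = 1.0 / sp[finite]
    ge = inv.sum() / (n * (n - 1))
    cost = np.triu(sel).sum() / np.triu(ref).sum()
    return float(ge - cost)


def omst_filter(weighted_adjacency: np.ndarray,
                patience: int | None = None) -> FilteredGraph:
    """Filter a weighted graph by unioning successive orthogonal MSTs.

    Rounds m = 1, 2, ... extract edge-disjoint minimum spanning
    trees/forests on the distance transform d = 1/w of the not-yet-selected
    edges; the returned graph is the union of the first m* trees, with m*
    the argmax of GCE over rounds (first maximum on ties).  Rounds run until
    min(N-1, edge exhaustion); `patience` optionally stops early after that
    many consecutive GCE decreases.

    Edge weights in the output are unchanged from the input.  A disconnected
    input is filtered per connected component (spanning forests) with a
    warning; graphs with fewer than 2 nodes are rejected.
    """
    w = _validate_adjacency(weighted_adjacency)
    n = w.shape[0]
    if n < 2:
        raise ValueError("graph must have at least 2 nodes")
    if w.max() == 0:
        return FilteredGraph(adjacency=np.zeros_like(w), edges=[],
                             rounds_used=0)
    n_comp, _ = connected_components(csr_matrix(w), directed=False)
    if n_comp > 1:
        warnings.warn("input graph is disconnected; filtering per component",
                      DisconnectedGraphWarning, stacklevel=2)
    wn = w / w.max()
    with np.errstate(divide="ignore"):
        dist = np.where(wn > 0, 1.0 / wn, 0.0)
    remaining = dist.copy()
    selected = np.zeros_like(w, dtype=bool)
    total_weight = np.triu(wn).sum()
    masks: list[np.ndarray] = []
    gce: list[float] = []
    cost: list[float] = []
    decreases = 0
    m_max = n - 1
    for _ in range(m_max):
        tree = minimum_spanning_tree(csr_matrix(remaining)).toarray()
        ti, tj = np.nonzero(tree)
        if ti.size == 0:
            break
        selected[ti, tj] = selected[tj, ti] = True
        remaining[ti, tj] = remaining[tj, ti] = 0.0
        masks.append(selected.copy())
        gce.append(global_cost_efficiency(np.where(selected, w, 0.0), w))
        cost.append(float(np.triu(np.where(selected, wn, 0.0)).sum()
                          / total_weight))
        if len(gce) > 1 and gce[-1] < gce[-2]:
            decreases += 1
            if patience is not None and decreases >= patience:
                break
        else:
            decreases = 0
    m_star = int(np.argmax(gce)) + 1
    adj = np.where(masks[m_star - 1], w, 0.0)
    ei, ej = np.nonzero(np.triu(masks[m_star - 1]))
    return FilteredGraph(adjacency=adj,
                         edges=list(zip(ei.tolist(), ej.tolist())),
                         rounds_used=m_star,
                         gce_by_round=np.asarray(gce),
                         cost_by_round=np.asarray(cost))


def normalized_laplacian_eigenvalues(adjacency: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of L_sym = D^{-1/2} (D - A) D^{-1/2}.

    Isolated (degree-0) nodes have their L_sym row/column set to zero and
    contribute an eigenvalue of 0 apiece, so the number of zero eigenvalues
    equals the number of connected components, isolates included.
    """
    a = _validate_adjacency(adjacency)
    deg = a.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    pos = deg > 0
    inv_sqrt[pos] = deg[pos] ** -0.5
    lsym = np.diag(pos.astype(float)) - inv_sqrt[:, None] * a * inv_sqrt[None, :]
    vals = np.linalg.eigvalsh(lsym)
    if vals.min() < -1e-9 or vals.max() > 2 + 1e-9:
        raise FloatingPointError("eigenvalues escaped the [0, 2] bound")
    return np.clip(np.sort(vals), 0.0, 2.0)


def build_nmts(snapshots, subject_id: str | None = None) -> EigenTimeSeries:
    """OMST-filter every snapshot and stack its L_sym spectrum column-wise.

    Empty snapshots (no significant couplings anywhere) contribute an
    all-zero column; disconnected-graph warnings from per-window filtering
    are suppressed here since sparse snapshots routinely leave isolates.
    """
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("need at least one snapshot")
    n = snapshots[0].strength.shape[0]
    out = np.zeros((n, len(snapshots)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedGraphWarning)
        for w, snap in enumerate(snapshots):
            filtered = omst_filter(snap.strength)
            out[:, w] = normalized_laplacian_eigenvalues(filtered.adjacency)
    return EigenTimeSeries(values=out, subject_id=subject_id)
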