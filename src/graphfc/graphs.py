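"""Group-consensus connectome, filter-graph variants, nulls, search information.

The consensus builder retains, separately for intra- and interhemispheric
edges and within equal-count Euclidean-distance bins, the most consistently
present edges until the class's mean single-subject density is matched —
so that interhemispheric edges, which are sparser and less reliably tracked,
are not wiped out by a single global threshold.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .datatypes import (
    FilterGraph,
    Parcellation,
    SearchInformationMatrix,
    StructuralConnectome,
)

__all__ = [
    "consensus_sc",
    "rewire_degree_preserving",
    "build_filter_graph",
    "search_information",
]

logger = logging.getLogger(__name__)


def _stack_scs(subject_scs) -> np.ndarray:
    mats = []
    for sc in subject_scs:
        w = sc.weights if isinstance(sc, StructuralConnectome) else np.asarray(sc, float)
        mats.append(w)
    stack = np.stack(mats)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("subject SCs must share one square shape")
    return stack


def _quotas(total: int, sizes: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of `total` across bins of given sizes."""
    if sizes.sum() == 0:
        return np.zeros_like(sizes)
    exact = total * sizes / sizes.sum()
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:rem]] += 1
    return np.minimum(base, sizes)


def consensus_sc(
    subject_scs,
    parcellation: Parcellation,
    recurrence_min: float = 0.3,
    target_intra_density: float | None = None,
    n_bins: int | None = None,
) -> StructuralConnectome:
    """Distance-dependent group-consensus structural connectome.

    Edges are split into intra-/interhemispheric classes; within each class
    the ED range is cut into equal-count bins (default ceil(sqrt(#candidate
    edges))) and the most recurrent edges per bin are kept until the class's
    mean single-subject edge count is reached (or ``target_intra_density``
    for the intrahemispheric class when given). An edge must additionally
    recur in at least ``recurrence_min`` of subjects. Retained weights are
    the mean fiber count over the subjects that have the edge.
    """
    stack = _stack_scs(subject_scs)
    n_subj, n = stack.shape[0], stack.shape[1]
    if n_subj < 2:
        raise ValueError("consensus needs at least 2 subjects")
    if not (0 < recurrence_min <= 1):
        raise ValueError("recurrence_min must lie in (0, 1]")
    if n != parcellation.n_rois:
        raise ValueError("SC dimension does not match parcellation")

    ed = parcellation.distances()
    intra = parcellation.intra_mask()
    iu = np.triu_indices(n, k=1)
    present = stack[:, iu[0], iu[1]] > 0  # (S, M)
    recurrence = present.mean(axis=0)
    sums = stack[:, iu[0], iu[1]].sum(axis=0)
    counts = present.sum(axis=0)
    mean_weight = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    ed_vec = ed[iu]
    intra_vec = intra[iu]

    keep = np.zeros(ed_vec.size, dtype=bool)
    for cls_mask, cls_name in ((intra_vec, "intra"), (~intra_vec, "inter")):
        cls_idx = np.flatnonzero(cls_mask)
        if cls_idx.size == 0:
            continue
        mean_count = present[:, cls_idx].sum(axis=1).mean()
        if cls_name == "intra" and target_intra_density is not None:
            target = int(round(target_intra_density * cls_idx.size))
        else:
            target = int(round(mean_count))
        cand = cls_idx[recurrence[cls_idx] >= recurrence_min]
        if cand.size == 0:
            logger.warning("no %shemispheric edge satisfies recurrence", cls_name)
            continue
        bins = n_bins or max(1, math.ceil(math.sqrt(cand.size)))
        order = cand[np.argsort(ed_vec[cand], kind="stable")]
        groups = np.array_split(order, bins)
        sizes = np.array([len(g) for g in groups])
        quotas = _quotas(target, sizes)
        for grp, q in zip(groups, quotas):
            if len(grp) == 0:
                continue
            # most recurrent first; ties by mean weight, then pair order
            rank = np.lexsort((grp, -mean_weight[grp], -recurrence[grp]))
            keep[grp[rank[:q]]] = True
        if quotas.sum() < target:
            logger.warning(
                "%shemispheric class short of target: %d/%d edges retained",
                cls_name,
                int(quotas.sum()),
                target,
            )
    if not keep.any():
        raise ValueError("consensus is empty: no edge satisfies the retention rules")

    weights = np.zeros((n, n))
    weights[iu[0][keep], iu[1][keep]] = mean_weight[keep]
    weights = weights + weights.T
    return StructuralConnectome(weights=weights, hemisphere=parcellation.hemisphere)


def _is_connected(adj: np.ndarray) -> bool:
    ncomp, _ = connected_components(csr_matrix(adj), directed=False)
    return ncomp == 1


def rewire_degree_preserving(
    sc: StructuralConnectome, n_iter_per_edge: int = 100, seed: int = 0
) -> StructuralConnectome:
    """Maslov-Sneppen rewiring preserving degree sequence and connectedness.

    Each accepted swap replaces edges (a,b),(c,d) by (a,d),(c,b), carrying
    the edge weights along; swaps that would disconnect the graph are
    reverted. Targets ``n_iter_per_edge`` accepted swaps per edge with a
    bounded number of attempts.
    """
    w = sc.weights.copy()
    if not _is_connected(w > 0):
        raise ValueError("rewiring requires a connected graph")
    rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in zip(*np.triu_indices_from(w, k=1)) if w[e] > 0]
    n_edges = len(edges)
    target_swaps = n_iter_per_edge * n_edges
    attempts_left = max(10 * target_swaps, 100)
    accepted = 0
    while accepted < target_swaps and attempts_left > 0:
        attempts_left -= 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4 or w[a, d] > 0 or w[c, b] > 0:
            continue
        wab, wcd = w[a, b], w[c, d]
        w[a, b] = w[b, a] = 0.0
        w[c, d] = w[d, c] = 0.0
        w[a, d] = w[d, a] = wab
        w[c, b] = w[b, c] = wcd
        if _is_connected(w > 0):
            edges[i] = (min(a, d), max(a, d))
            edges[j] = (min(c, b), max(c, b))
            accepted += 1
        else:  # revert
            w[a, d] = w[d, a] = 0.0
            w[c, b] = w[b, c] = 0.0
            w[a, b] = w[b, a] = wab
            w[c, d] = w[d, c] = wcd
    if accepted < target_swaps:
        logger.warning("rewiring stopped at %d/%d swaps", accepted, target_swaps)
    return StructuralConnectome(weights=w, hemisphere=sc.hemisphere)


def _auto_k(sc: StructuralConnectome, ed: np.ndarray) -> float:
    """Scale k of exp(-k*ED) so the median dense weight matches the median
    nonzero max-normalized consensus weight."""
    w = sc.weights
    nz = w[w > 0]
    if nz.size == 0:
        raise ValueError("cannot set k automatically from an empty SC")
    med_w = float(np.median(nz / nz.max()))
    iu = np.triu_indices_from(ed, k=1)
    med_ed = float(np.median(ed[iu]))
    med_w = min(max(med_w, 1e-12), 1.0)
    return -math.log(med_w) / med_ed if med_w < 1.0 else 0.0


def build_filter_graph(
    variant: str,
    sc: StructuralConnectome | None = None,
    parcellation: Parcellation | None = None,
    k="auto",
    normalization: str = "max1",
    seed: int = 0,
    n_iter_per_edge: int = 100,
) -> FilterGraph:
    """Build one of the filter-graph variants.

    - ``sc``: consensus fiber counts;
    - ``ed_full``: exp(-k*ED) on every off-diagonal pair (dense);
    - ``ed_match``: exp(-k*ED) restricted to the SC support;
    - ``ed_dens``: exp(-k*ED) on the shortest-ED pairs, matching the SC's
      edge count (cutoff ties broken by lexicographic pair order);
    - ``randomized``: degree-preserving rewiring of the SC.
    """
    if variant in ("sc", "ed_match", "ed_dens", "randomized") and sc is None:
        raise ValueError(f"variant {variant!r} requires a consensus SC")
    if variant in ("ed_full", "ed_match", "ed_dens") and parcellation is None:
        raise ValueError(f"variant {variant!r} requires a parcellation")

    if variant == "sc":
        weights = sc.weights.copy()
    elif variant == "randomized":
        weights = rewire_degree_preserving(sc, n_iter_per_edge, seed).weights
    else:
        ed = parcellation.distances()
        kk = _auto_k(sc, ed) if k == "auto" else float(k)
        dense = np.exp(-kk * ed)
        np.fill_diagonal(dense, 0.0)
        if variant == "ed_full":
            weights = dense
        elif variant == "ed_match":
            weights = dense * (sc.weights > 0)
        elif variant == "ed_dens":
            m = int(np.count_nonzero(sc.weights[np.triu_indices_from(sc.weights, k=1)]))
            iu = np.triu_indices_from(ed, k=1)
            order = np.lexsort((iu[1], iu[0], ed[iu]))  # ED, then pair order
            weights = np.zeros_like(ed)
            sel = order[:m]
            weights[iu[0][sel], iu[1][sel]] = dense[iu[0][sel], iu[1][sel]]
            weights = weights + weights.T
        else:
            raise ValueError(f"unknown variant {variant!r}")

    if normalization == "max1":
        mx = weights.max()
        if mx > 0:
            weights = weights / mx
    elif normalization != "none":
        raise ValueError("normalization must be 'max1' or 'none'")
    return FilterGraph(variant=variant, weights=weights, normalization=normalization)


def search_information(
    sc: StructuralConnectome, symmetrize: bool = True, edge_length: str = "inverse"
) -> SearchInformationMatrix:
    """Search information S(s->t) = -log2 P(shortest path followed).

    Shortest paths are computed on edge lengths 1/weight (or -log of the
    max-normalized weight with ``edge_length='neglog'``). P multiplies, over
    the nodes of the path excluding the target, the probability that a
    random walker leaving node i takes the path's outgoing edge:
    weight(i, next) / strength(i). Disconnected pairs are infinite.
    """
    w = sc.weights
    n = w.shape[0]
    if edge_length == "inverse":
        lengths = np.divide(1.0, w, out=np.zeros_like(w), where=w > 0)
    elif edge_length == "neglog":
        wn = w / w.max()
        lengths = np.where(w > 0, -np.log(np.minimum(wn, 1.0)) + 1e-12, 0.0)
    else:
        raise ValueError("edge_length must be 'inverse' or 'neglog'")
    graph = csr_matrix(lengths)
    dist, pred = dijkstra(graph, directed=False, return_predecessors=True)
    strength = w.sum(axis=1)
    if np.any(~np.isfinite(dist[~np.eye(n, dtype=bool)])):
        logger.warning("graph is disconnected: unreachable pairs set to inf")

    si = np.zeros((n, n))
    log2w = np.zeros_like(w)
    np.log2(w, out=log2w, where=w > 0)
    log2s = np.zeros_like(strength)
    np.log2(strength, out=log2s, where=strength > 0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            if not np.isfinite(dist[s, t]):
                si[s, t] = np.inf
                continue
            # walk back from t to s along predecessors, accumulating
            # log2(w(u,v)) - log2(strength(u)) for each step u->v
            total = 0.0
            v = t
            while v != s:
                u = pred[s, v]
                total += log2w[u, v] - log2s[u]
                v = u
            si[s, t] = -total
    si[si < 0] = 0.0  # guard tiny negative rounding
    if symmetrize:
        si = 0.5 * (si + si.T)
    return SearchInformationMatrix(si=si, symmetrized=symmetrize)
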