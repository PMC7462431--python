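"""Repeated-Louvain co-assignment matrices and cross-FC community agreement.

Louvain is run on the signed modularity objective with resolution parameter
gamma: positive and negative weights contribute asymmetrically (the standard
signed-modularity choice), or negatives can be zeroed. Repeating the
stochastic optimisation yields a co-assignment ("community") matrix whose
entry (i, j) is the fraction of runs assigning i and j to the same
community; community structures of two FCs are compared by the per-ROI
Spearman correlation of their co-assignment profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CommunityMatrix, CommunitySettings, FCMatrix

__all__ = [
    "louvain_partition",
    "louvain_coassignment",
    "community_agreement",
    "reference_communities",
    "sweep",
    "sweep_seed",
    "CommunityAgreement",
    "SweepResult",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _modularity_matrix(w: np.ndarray, gamma: float, mode: str) -> np.ndarray:
    """Signed modularity matrix B; maximizing sum of B[i,j] over
    within-community pairs is the (asymmetric) signed-modularity objective."""
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    wp = np.clip(w, 0.0, None)
    wn = np.clip(-w, 0.0, None)
    sp = wp.sum(axis=1)
    vp = sp.sum()
    if vp <= 0:
        raise ValueError("no positive weights: modularity undefined")
    b = (wp - gamma * np.outer(sp, sp) / vp) / vp
    if mode == "asym":
        sn = wn.sum(axis=1)
        vn = sn.sum()
        if vn > 0:
            b = b - (wn - gamma * np.outer(sn, sn) / vn) / (vp + vn)
    elif mode != "zero":
        raise ValueError("negative_weight_mode must be 'asym' or 'zero'")
    np.fill_diagonal(b, 0.0)
    return 0.5 * (b + b.T)


def _local_move(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = b.shape[0]
    labels = np.arange(n)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            row = b[i].copy()
            row[i] = 0.0
            gains = np.bincount(labels, weights=row, minlength=n)
            best = int(np.argmax(gains))
            if gains[best] > gains[labels[i]] + _EPS and best != labels[i]:
                labels[i] = best
                improved = True
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def louvain_partition(w: np.ndarray, gamma: float, rng, mode: str = "asym") -> np.ndarray:
    """One Louvain run: greedy local moves plus community aggregation.

    Returns integer community labels for every node. Stochastic through the
    node visiting order drawn from ``rng``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    b = _modularity_matrix(w, gamma, mode)
    n = b.shape[0]
    node_labels = np.arange(n)
    while True:
        part = _local_move(b, rng)
        k = part.max() + 1
        if k == b.shape[0]:  # no merge happened
            break
        node_labels = part[node_labels]
        onehot = np.eye(k)[part]
        b = onehot.T @ b @ onehot
    _, node_labels = np.unique(node_labels, return_inverse=True)
    return node_labels


def louvain_coassignment(fc, settings: CommunitySettings) -> CommunityMatrix:
    """Co-assignment probabilities over ``settings.n_reps`` Louvain runs.

    Each repetition draws its node order from an independent substream of
    the run seed, so single partitions are reproducible by repetition index.
    """
    w = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n = w.shape[0]
    if n < 3:
        raise ValueError("need at least 3 ROIs for community detection")
    off = w[~np.eye(n, dtype=bool)]
    if np.all(off == 0):
        raise ValueError("all-zero FC matrix: no community structure")
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_reps)
    coassign = np.zeros((n, n))
    n_comms = []
    for ss in seeds:
        labels = louvain_partition(
            w, settings.gamma, np.random.default_rng(ss), settings.negative_weight_mode
        )
        coassign += labels[:, None] == labels[None, :]
        n_comms.append(labels.max() + 1)
    coassign /= settings.n_reps
    np.fill_diagonal(coassign, 1.0)
    return CommunityMatrix(
        coassign=coassign, n_communities_mean=float(np.mean(n_comms)), settings=settings
    )


@dataclass
class CommunityAgreement:
    """Per-ROI Spearman correlations of co-assignment profiles."""

    per_roi: np.ndarray  # nan where a profile was constant
    mean: float

    @property
    def n_defined(self) -> int:
        return int(np.sum(np.isfinite(self.per_roi)))


def community_agreement(cm_a, cm_b) -> CommunityAgreement:
    """Spearman correlation of each ROI's co-assignment profile in A vs B.

    The diagonal entry is excluded from each profile; ROIs with a constant
    profile in either matrix are excluded from the mean.
    """
    a = cm_a.coassign if isinstance(cm_a, CommunityMatrix) else np.asarray(cm_a, float)
    b = cm_b.coassign if isinstance(cm_b, CommunityMatrix) else np.asarray(cm_b, float)
    if a.shape != b.shape:
        raise ValueError("community matrices differ in dimension")
    n = a.shape[0]
    per_roi = np.full(n, np.nan)
    for i in range(n):
        mask = np.arange(n) != i
        pa, pb = a[i, mask], b[i, mask]
        if np.all(pa == pa[0]) or np.all(pb == pb[0]):
            logger.info("ROI %d has a constant co-assignment profile: excluded", i)
            continue
        per_roi[i] = stats.spearmanr(pa, pb).statistic
    if not np.any(np.isfinite(per_roi)):
        raise ValueError("no ROI with a non-constant profile in both matrices")
    return CommunityAgreement(per_roi=per_roi, mean=float(np.nanmean(per_roi)))


def sweep_seed(base_seed: int, gamma: float, g: float) -> int:
    """Deterministic per-(gamma, G) seed used by :func:`sweep`."""
    g_code = 0 if g < 0 else int(round(g * 1000)) + 1  # g < 0: reference stream
    ss = np.random.SeedSequence(entropy=(abs(int(base_seed)), int(round(gamma * 1000)), g_code))
    return int(ss.generate_state(1)[0] % (2**31))


def reference_communities(reference_fc, gamma_grid, settings: CommunitySettings) -> dict:
    """Co-assignment matrix of a reference FC at every gamma.

    Seeds follow the same (gamma, G=0 reference stream) derivation as the
    sweep so results are reproducible.
    """
    out = {}
    for gamma in gamma_grid:
        s = replace(settings, gamma=float(gamma), seed=sweep_seed(settings.seed, gamma, -1.0))
        out[float(gamma)] = louvain_coassignment(reference_fc, s)
    return out


@dataclass
class SweepResult:
    """Agreement and community-count surfaces over (gamma, G)."""

    table: pd.DataFrame  # gamma, G, agreement, n_communities, pareto
    community_matrices: dict  # (gamma, G) -> CommunityMatrix
    per_roi_agreement: dict  # (gamma, G) -> np.ndarray
    best_G_per_gamma: pd.DataFrame  # gamma, best_G, agreement


def sweep(
    fc_by_G: dict,
    reference_cm_by_gamma: dict,
    gamma_grid,
    settings: CommunitySettings,
) -> SweepResult:
    """(gamma, G) sweep of community agreement against a reference.

    For each grid point the (filtered) FC's co-assignment matrix is compared
    to the reference community matrix at the same gamma; the mean community
    count and the G maximizing agreement per gamma are also reported. The
    'pareto' flag marks grid points not dominated in (higher agreement,
    fewer communities).
    """
    rows = []
    cms: dict = {}
    per_roi: dict = {}
    for gamma in [float(g) for g in gamma_grid]:
        if gamma not in reference_cm_by_gamma:
            raise KeyError(f"no reference community matrix for gamma={gamma}")
        ref_cm = reference_cm_by_gamma[gamma]
        for g, fc in sorted(fc_by_G.items()):
            g = float(g)
            s = replace(settings, gamma=gamma, seed=sweep_seed(settings.seed, gamma, g))
            cm = louvain_coassignment(fc, s)
            agg = community_agreement(cm, ref_cm)
            cms[(gamma, g)] = cm
            per_roi[(gamma, g)] = agg.per_roi
            rows.append(
                {
                    "gamma": gamma,
                    "G": g,
                    "agreement": agg.mean,
                    "n_communities": cm.n_communities_mean,
                }
            )
    table = pd.DataFrame(rows)
    agreement = table["agreement"].to_numpy()
    n_comm = table["n_communities"].to_numpy()
    pareto = np.ones(len(table), dtype=bool)
    for k in range(len(table)):
        dominated = (
            (agreement >= agreement[k])
            & (n_comm <= n_comm[k])
            & ((agreement > agreement[k]) | (n_comm < n_comm[k]))
        )
        pareto[k] = not dominated.any()
    table["pareto"] = pareto
    best_idx = table.groupby("gamma")["agreement"].idxmax()
    best = table.loc[best_idx, ["gamma", "G", "agreement"]].rename(columns={"G": "best_G"})
    return SweepResult(
        table=table,
        community_matrices=cms,
        per_roi_agreement=per_roi,
        best_G_per_gamma=best.reset_index(drop=True),
    )
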