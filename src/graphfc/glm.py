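"""Structure-function statistics on ROI pairs.

Each unordered ROI pair is one sample (M = (N^2 - N)/2). FC is regressed on
Euclidean distance, search information, relative regional variance and ROI
size with a forward-backward stepwise Gaussian GLM (deviance chi-square
entry/removal tests, interactions only after both mains), and SC-connected
vs unconnected pairs are compared under Euclidean-distance matching with a
Wilcoxon signed-rank test across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    FCMatrix,
    Parcellation,
    SearchInformationMatrix,
    StructuralConnectome,
)

__all__ = [
    "rrv",
    "build_pair_table",
    "stepwise_glm",
    "matched_sc_comparison",
    "GLMResult",
    "MatchedComparison",
    "MAIN_EFFECTS",
]

logger = logging.getLogger(__name__)

MAIN_EFFECTS = ("ed", "sc_si", "rrv_pair", "roi_size_pair")


def rrv(epochs_by_subject: dict) -> np.ndarray:
    """Relative regional variance, a per-ROI proxy for signal-to-noise.

    Per subject: mean over intervals of each ROI's variance, scaled so the
    maximum over ROIs is 1; then averaged over subjects.
    """
    if not epochs_by_subject:
        raise ValueError("no subjects given")
    per_subject = []
    for subject, epochs in epochs_by_subject.items():
        v = np.mean([ep.data.var(axis=1) for ep in epochs], axis=0)
        vmax = v.max()
        if vmax == 0:
            raise ValueError(f"{subject}: all-zero signals, RRV undefined")
        per_subject.append(v / vmax)
    return np.mean(per_subject, axis=0)


def _values(obj, attr):
    if isinstance(obj, (FCMatrix,)):
        return obj.values
    if isinstance(obj, SearchInformationMatrix):
        return obj.si
    if isinstance(obj, StructuralConnectome):
        return obj.weights
    return np.asarray(obj, dtype=float)


def build_pair_table(
    fc,
    si,
    parcellation: Parcellation,
    rrv_vector: np.ndarray,
    sc,
    pair_reduce: str = "mean",
) -> pd.DataFrame:
    """One row per unordered ROI pair, in lexicographic (i < j) order.

    Nodal RRV and ROI size are reduced to pair level by the symmetric
    ``pair_reduce`` ('mean' or 'min'); ``sc_connected`` flags a positive
    consensus weight.
    """
    fcv = _values(fc, "values")
    siv = _values(si, "si")
    scv = _values(sc, "weights")
    n = parcellation.n_rois
    for name, m in (("fc", fcv), ("si", siv), ("sc", scv)):
        if m.shape != (n, n):
            raise ValueError(f"{name} matrix does not match parcellation dimension")
    rrv_vector = np.asarray(rrv_vector, dtype=float)
    if rrv_vector.shape != (n,):
        raise ValueError("rrv vector does not match parcellation dimension")
    if pair_reduce == "mean":
        reduce = lambda a, i, j: 0.5 * (a[i] + a[j])  # noqa: E731
    elif pair_reduce == "min":
        reduce = lambda a, i, j: np.minimum(a[i], a[j])  # noqa: E731
    else:
        raise ValueError("pair_reduce must be 'mean' or 'min'")
    ed = parcellation.distances()
    i, j = np.triu_indices(n, k=1)
    size = parcellation.roi_size.astype(float)
    table = pd.DataFrame(
        {
            "roi_a": np.asarray(parcellation.roi_names)[i],
            "roi_b": np.asarray(parcellation.roi_names)[j],
            "fc": fcv[i, j],
            "ed": ed[i, j],
            "sc_si": siv[i, j],
            "rrv_pair": reduce(rrv_vector, i, j),
            "roi_size_pair": reduce(size, i, j),
            "sc_connected": scv[i, j] > 0,
        }
    )
    if not np.all(np.isfinite(table[list(MAIN_EFFECTS)].to_numpy())):
        raise ValueError("non-finite predictor values in pair table")
    return table


@dataclass
class GLMResult:
    """Outcome of the stepwise fit."""

    entered: list  # final terms in order of first entry
    steps: list  # dicts: term, action, deviance_change, p_value
    r2_single: dict  # per main effect, single-predictor r^2
    r2_cumulative: list  # r^2 of nested models over `entered`
    r2_final: float = 0.0
    coefficients: dict = field(default_factory=dict)


def _candidate_terms():
    mains = list(MAIN_EFFECTS)
    inters = [
        (mains[a], mains[b]) for a in range(len(mains)) for b in range(a + 1, len(mains))
    ]
    return mains, inters


def _design_columns(table: pd.DataFrame):
    cols = {}
    for m in MAIN_EFFECTS:
        x = table[m].to_numpy(dtype=float)
        sd = x.std()
        cols[m] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    mains, inters = _candidate_terms()
    for a, b in inters:
        x = cols[a] * cols[b]
        sd = x.std()
        cols[(a, b)] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    return cols


def _rss(y: np.ndarray, xcols: list) -> float:
    x = np.column_stack([np.ones_like(y)] + xcols)
    _, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        return float("nan")  # rank-deficient design
    if res.size:
        return float(res[0])
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    return float(np.sum((y - x @ beta) ** 2))


def _dev_p(d0: float, d1: float, n: int, p1: int, df: int = 1) -> float:
    """Chi-square p-value for a deviance drop d0 - d1 (Gaussian, estimated
    dispersion phi = d1 / (n - p1))."""
    phi = d1 / max(n - p1, 1)
    if phi <= 0:
        return 0.0
    return float(stats.chi2.sf(max(d0 - d1, 0.0) / phi, df))


def stepwise_glm(
    table: pd.DataFrame, alpha_add: float = 0.05, alpha_remove: float = 0.10
) -> GLMResult:
    """Forward-backward stepwise Gaussian GLM over 4 mains + 6 interactions.

    At each step the candidate with the smallest deviance-test p-value below
    ``alpha_add`` enters (interactions only once both mains are in); entered
    terms whose removal p-value exceeds ``alpha_remove`` leave (mains are
    protected while their interaction is in). Also fits the four
    single-predictor models for ``r2_single``.
    """
    y = table["fc"].to_numpy(dtype=float)
    n = y.size
    cols = _design_columns(table)
    mains, inters = _candidate_terms()
    d_null = _rss(y, [])

    r2_single = {
        m: (1.0 - _rss(y, [cols[m]]) / d_null) if d_null > 0 else 0.0 for m in mains
    }

    entered: list = []
    entry_order: list = []
    steps: list = []
    d_current = d_null
    while True:
        changed = False
        # forward step
        eligible = [m for m in mains if m not in entered]
        eligible += [
            t for t in inters if t not in entered and t[0] in entered and t[1] in entered
        ]
        best = None
        for term in eligible:
            d1 = _rss(y, [cols[t] for t in entered] + [cols[term]])
            if np.isnan(d1):
                logger.info("skipping rank-deficient candidate %s", term)
                continue
            p = _dev_p(d_current, d1, n, len(entered) + 2)
            if p < alpha_add and (best is None or p < best[1]):
                best = (term, p, d1)
        if best is not None:
            term, p, d1 = best
            steps.append(
                {"term": term, "action": "add", "deviance_change": d_current - d1, "p_value": p}
            )
            entered.append(term)
            if term not in entry_order:
                entry_order.append(term)
            d_current = d1
            changed = True
        # backward step
        removable = [
            t
            for t in entered
            if not (t in mains and any(isinstance(u, tuple) and t in u for u in entered))
        ]
        worst = None
        for term in removable:
            rest = [t for t in entered if t != term]
            d0 = _rss(y, [cols[t] for t in rest])
            if np.isnan(d0):
                continue
            p = _dev_p(d0, d_current, n, len(entered) + 1)
            if p > alpha_remove and (worst is None or p > worst[1]):
                worst = (term, p, d0)
        if worst is not None:
            term, p, d0 = worst
            steps.append(
                {
                    "term": term,
                    "action": "remove",
                    "deviance_change": d0 - d_current,
                    "p_value": p,
                }
            )
            entered.remove(term)
            d_current = d0
            changed = True
        if not changed:
            break

    final_order = [t for t in entry_order if t in entered]
    r2_cum = []
    for k in range(1, len(final_order) + 1):
        d_k = _rss(y, [cols[t] for t in final_order[:k]])
        r2_cum.append(1.0 - d_k / d_null if d_null > 0 else 0.0)
    r2_final = r2_cum[-1] if r2_cum else 0.0

    x = np.column_stack([np.ones_like(y)] + [cols[t] for t in final_order])
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    coefs = {"intercept": float(beta[0])}
    for t, b in zip(final_order, beta[1:]):
        coefs[t] = float(b)

    return GLMResult(
        entered=final_order,
        steps=steps,
        r2_single=r2_single,
        r2_cumulative=r2_cum,
        r2_final=r2_final,
        coefficients=coefs,
    )


@dataclass
class MatchedComparison:
    """SC+ vs SC- FC comparison on distance-matched subsamples."""

    mean_sc_plus: np.ndarray  # per subject
    mean_sc_minus: np.ndarray
    statistic: float
    p_value: float
    p_bonferroni: float
    significant: bool
    bin_edges: np.ndarray
    n_matched_per_bin: np.ndarray
    degenerate: bool = False

    @property
    def differences(self) -> np.ndarray:
        return self.mean_sc_plus - self.mean_sc_minus


def matched_sc_comparison(
    tables_by_subject,
    n_bins: int = 10,
    n_resamples: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> MatchedComparison:
    """Compare mean FC of SC-connected vs unconnected pairs, ED-matched.

    The pooled ED range is restricted to the overlap of the two classes'
    supports and split into ``n_bins`` equal-count bins; per bin the larger
    class is subsampled without replacement to the smaller one's count. Per
    subject, mean FC per class is averaged over ``n_resamples`` subsample
    draws; across subjects a Wilcoxon signed-rank test is applied to the
    per-subject differences, Bonferroni-corrected over ``n_comparisons``.
    """
    tables = list(tables_by_subject.values()) if isinstance(tables_by_subject, dict) else list(
        tables_by_subject
    )
    if not tables:
        raise ValueError("no subjects given")
    ed = tables[0]["ed"].to_numpy(dtype=float)
    conn = tables[0]["sc_connected"].to_numpy(dtype=bool)
    for t in tables[1:]:
        if not np.allclose(t["ed"].to_numpy(dtype=float), ed):
            raise ValueError("pair tables disagree on ED: ROI order mismatch?")
    fc_all = np.stack([t["fc"].to_numpy(dtype=float) for t in tables])  # (S, M)

    if conn.sum() == 0 or (~conn).sum() == 0:
        raise ValueError("need both SC-connected and unconnected pairs")
    lo = max(ed[conn].min(), ed[~conn].min())
    hi = min(ed[conn].max(), ed[~conn].max())
    in_overlap = (ed >= lo) & (ed <= hi)
    if not np.any(in_overlap & conn) or not np.any(in_overlap & ~conn):
        raise ValueError("ED supports of SC+ and SC- do not overlap")

    edges = np.quantile(ed[in_overlap], np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    which = np.digitize(ed, edges) - 1  # bins 0..n_bins-1 inside overlap

    rng = np.random.default_rng(seed)
    sel_plus, sel_minus, n_per_bin = [], [], []
    for b in range(n_bins):
        in_bin = in_overlap & (which == b)
        plus = np.flatnonzero(in_bin & conn)
        minus = np.flatnonzero(in_bin & ~conn)
        m = min(plus.size, minus.size)
        if m == 0:
            logger.info("ED bin %d has no pairs of one class: dropped", b)
            n_per_bin.append(0)
            continue
        n_per_bin.append(m)
        sel_plus.append((plus, m))
        sel_minus.append((minus, m))
    if not sel_plus:
        raise ValueError("no ED bin retained both classes")

    sums_plus = np.zeros(fc_all.shape[0])
    sums_minus = np.zeros(fc_all.shape[0])
    for _ in range(n_resamples):
        idx_p = np.concatenate(
            [p if p.size == m else rng.choice(p, m, replace=False) for p, m in sel_plus]
        )
        idx_m = np.concatenate(
            [q if q.size == m else rng.choice(q, m, replace=False) for q, m in sel_minus]
        )
        sums_plus += fc_all[:, idx_p].mean(axis=1)
        sums_minus += fc_all[:, idx_m].mean(axis=1)
    mean_plus = sums_plus / n_resamples
    mean_minus = sums_minus / n_resamples

    diffs = mean_plus - mean_minus
    degenerate = bool(np.allclose(diffs, 0))
    if degenerate:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(diffs)
    p_bonf = min(1.0, p * n_comparisons)
    return MatchedComparison(
        mean_sc_plus=mean_plus,
        mean_sc_minus=mean_minus,
        statistic=float(stat),
        p_value=float(p),
        p_bonferroni=float(p_bonf),
        significant=bool(p_bonf < alpha),
        bin_edges=edges,
        n_matched_per_bin=np.asarray(n_per_bin),
        degenerate=degenerate,
    )
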