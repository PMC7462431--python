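"""Fit-vs-G curves against a reference FC, variant comparisons, WGN controls.

The fit of a subject's (filtered) EEG-FC to a reference FC is the Pearson
correlation over the strict upper triangles, stored as Fisher z. Variants
are compared within subject on their maximum fit over the G grid with
Wilcoxon signed-rank tests, Bonferroni-corrected over all comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FCMatrix, FilterGraph
from .fc import envelope_fc
from .smoothing import smooth_study
from .synthetic import make_wgn_like

__all__ = [
    "filtered_fc_study",
    "fit_curve",
    "compare_variants",
    "wgn_control",
    "FitCurve",
    "PairedComparisonResult",
    "WGNControl",
]

logger = logging.getLogger(__name__)

_Z_CAP = 18.0  # atanh(1 - 1e-15) ~ 17.8; r = +/-1 clips here


def filtered_fc_study(
    epochs_by_subject: dict,
    graph: FilterGraph,
    G_grid,
    band: tuple,
    envelope_cutoff: float = 0.5,
    min_duration_s: float = 19.0,
    fast: bool = True,
) -> dict:
    """Envelope FC per subject and filter weight: {subject: {G: FCMatrix}}.

    With ``fast=True`` the band-pass and Hilbert transform — both linear and
    therefore commuting with the time-pointwise mixing (I + G*C) — are
    computed once per interval and the mixing is applied to the complex
    analytic signal per G; the result equals the literal
    smooth-then-:func:`~graphfc.fc.envelope_fc` route (``fast=False``) to
    numerical precision.
    """
    if not fast:
        filtered = smooth_study(epochs_by_subject, graph, G_grid)
        return {
            subject: {
                g: envelope_fc(eps, band, envelope_cutoff, min_duration_s=min_duration_s)
                for g, eps in by_g.items()
            }
            for subject, by_g in filtered.items()
        }

    from scipy.signal import hilbert

    from ._filters import fir_bandpass, fir_lowpass, zero_phase
    from .fc import _CLIP, EDGE_TRIM_S, _safe_corrcoef

    c = graph.weights
    low, high = band
    label = f"{low:g}-{high:g}Hz"
    taps_cache: dict = {}
    out: dict = {}
    for subject, epochs in epochs_by_subject.items():
        analytic = []
        for ep in epochs:
            if ep.duration < min_duration_s:
                raise ValueError(
                    f"interval of {ep.duration:.1f}s is shorter than the "
                    f"{min_duration_s:.0f}s minimum for envelope estimation"
                )
            if ep.rate < 2 * high:
                raise ValueError(f"rate {ep.rate} Hz too low for band ({low}, {high}) Hz")
            if ep.rate not in taps_cache:
                taps_cache[ep.rate] = (
                    fir_bandpass(ep.rate, low, high),
                    fir_lowpass(ep.rate, envelope_cutoff),
                )
            bp_taps, _ = taps_cache[ep.rate]
            analytic.append(hilbert(zero_phase(ep.data, bp_taps), axis=-1))
        durations = np.asarray([ep.duration for ep in epochs])
        w = durations / durations.sum()
        out[subject] = {}
        for g in G_grid:
            g = float(g)
            zs = []
            for ep, an in zip(epochs, analytic):
                mixed = an if g == 0 else an + g * (c @ an)
                env = zero_phase(np.abs(mixed), taps_cache[ep.rate][1])
                trim = int(EDGE_TRIM_S * ep.rate)
                if env.shape[1] > 4 * trim:
                    env = env[:, trim:-trim]
                r = _safe_corrcoef(env)
                zs.append(np.arctanh(np.clip(r, -_CLIP, _CLIP)))
            z = np.tensordot(w, np.asarray(zs), axes=1)
            values = np.tanh(z)
            np.fill_diagonal(values, 1.0)
            values = 0.5 * (values + values.T)
            out[subject][g] = FCMatrix(values=values, measure="envelope_corr", band=label)
    return out


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _fit_z(fc_values: np.ndarray, ref_vec: np.ndarray):
    v = _upper(fc_values)
    if v.std() == 0 or ref_vec.std() == 0:
        raise ValueError("constant FC matrix: fit undefined")
    r = float(np.corrcoef(v, ref_vec)[0, 1])
    clipped = abs(r) >= 1.0
    z = float(np.clip(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)), -_Z_CAP, _Z_CAP))
    return r, z, clipped


@dataclass
class FitCurve:
    """Per-(subject, G) fit to the reference, as Fisher z."""

    table: pd.DataFrame  # columns: subject, G, r, z, clipped
    variant: str = ""

    def best_per_subject(self) -> pd.DataFrame:
        """Per subject: argmax-G and maximum fit (on z)."""
        idx = self.table.groupby("subject")["z"].idxmax()
        best = self.table.loc[idx, ["subject", "G", "r", "z"]].reset_index(drop=True)
        return best.rename(columns={"G": "best_G", "r": "max_r", "z": "max_z"})

    def baseline_per_subject(self) -> pd.DataFrame:
        base = self.table[self.table["G"] == 0.0]
        if base.empty:
            raise ValueError("G grid must include 0 for the baseline")
        return base[["subject", "r", "z"]].reset_index(drop=True)

    def mean_z_by_G(self) -> pd.Series:
        return self.table.groupby("G")["z"].mean()


def fit_curve(fcs_by_subject_G: dict, reference_fc, variant: str = "") -> FitCurve:
    """Correlate each subject's FC at each G with the reference FC.

    Correlations use the strict upper triangle only and are Fisher
    z-transformed; r = +/-1 (e.g. self-comparison) is clipped and flagged.
    """
    ref = reference_fc.values if isinstance(reference_fc, FCMatrix) else np.asarray(
        reference_fc, dtype=float
    )
    ref_vec = _upper(ref)
    rows = []
    for subject, by_g in fcs_by_subject_G.items():
        for g, fc in sorted(by_g.items()):
            vals = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
            if vals.shape != ref.shape:
                raise ValueError("FC and reference dimensions differ")
            r, z, clipped = _fit_z(vals, ref_vec)
            if clipped:
                logger.warning("|r| = 1 for %s at G=%g: z clipped to %g", subject, g, _Z_CAP)
            rows.append(
                {"subject": subject, "G": float(g), "r": r, "z": z, "clipped": clipped}
            )
    return FitCurve(table=pd.DataFrame(rows), variant=variant)


@dataclass
class PairedComparisonResult:
    """Within-subject signed-rank comparison of maximum fits."""

    label: str
    differences: np.ndarray
    statistic: float
    p_value: float
    p_bonferroni: float
    significant: bool
    degenerate: bool = False


def _signed_rank(diffs: np.ndarray, label: str, bonferroni: int, alpha: float):
    degenerate = bool(np.allclose(diffs, 0))
    if degenerate:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(diffs)
    p_bonf = min(1.0, p * bonferroni)
    return PairedComparisonResult(
        label=label,
        differences=np.asarray(diffs, dtype=float),
        statistic=float(stat),
        p_value=float(p),
        p_bonferroni=float(p_bonf),
        significant=bool(p_bonf < alpha),
        degenerate=degenerate,
    )


def compare_variants(
    curves_by_variant: dict, alpha: float = 0.05, bonferroni: int | None = None
) -> list:
    """All variant-vs-baseline and pairwise signed-rank comparisons.

    Maximum fits (over G, per subject) of every variant are compared to the
    unfiltered G=0 baseline and to each other; with four variants this gives
    the canonical 10 comparisons and Bonferroni factor 10.
    """
    variants = list(curves_by_variant)
    n_v = len(variants)
    n_comp = n_v + n_v * (n_v - 1) // 2
    factor = bonferroni if bonferroni is not None else n_comp
    best = {}
    baseline = None
    for v in variants:
        curve = curves_by_variant[v]
        b = curve.best_per_subject().set_index("subject")["max_z"]
        best[v] = b
        base = curve.baseline_per_subject().set_index("subject")["z"]
        if baseline is None:
            baseline = base
        elif not np.allclose(baseline.reindex(base.index), base):
            raise ValueError("G=0 baselines differ across variants: inconsistent inputs")
    results = []
    for v in variants:
        common = best[v].index.intersection(baseline.index)
        if len(common) < len(best[v]):
            logger.warning("%s: %d subjects missing from baseline", v, len(best[v]) - len(common))
        diffs = (best[v].loc[common] - baseline.loc[common]).to_numpy()
        results.append(_signed_rank(diffs, f"{v} vs baseline", factor, alpha))
    for a in range(n_v):
        for b in range(a + 1, n_v):
            va, vb = variants[a], variants[b]
            common = best[va].index.intersection(best[vb].index)
            diffs = (best[va].loc[common] - best[vb].loc[common]).to_numpy()
            results.append(_signed_rank(diffs, f"{va} vs {vb}", factor, alpha))
    return results


@dataclass
class WGNControl:
    """White-noise control analyses for one graph."""

    wgn_fit: FitCurve  # fit of WGN-FCs to the reference per G
    similarity: pd.DataFrame  # per (subject, G): max r of empirical FC to any WGN-FC
    graph_imprint: pd.Series  # per G: mean corr of WGN-FC with the graph weights


def wgn_control(
    epochs_by_subject: dict,
    graph: FilterGraph,
    G_grid,
    reference_fc,
    band: tuple,
    seed: int = 0,
    envelope_cutoff: float = 0.5,
    min_duration_s: float = 19.0,
    empirical_fcs: dict | None = None,
) -> WGNControl:
    """Repeat the fit analysis on variance-matched white Gaussian noise.

    WGN epochs are generated per subject/interval with :func:`make_wgn_like`,
    filtered and FC'd identically to the empirical data. Reports (a) the fit
    of WGN-FCs to the reference per G, (b) the per-G maximum correlation
    between each subject's empirical FC and any (same-G) WGN-FC, and (c) the
    mean correlation between WGN-FCs and the filter graph's weights.
    """
    rng = np.random.default_rng(seed)
    wgn_epochs = {
        s: make_wgn_like(eps, seed=int(rng.integers(2**31)))
        for s, eps in epochs_by_subject.items()
    }
    wgn_fcs = filtered_fc_study(
        wgn_epochs, graph, G_grid, band, envelope_cutoff, min_duration_s
    )
    if empirical_fcs is None:
        empirical_fcs = filtered_fc_study(
            epochs_by_subject, graph, G_grid, band, envelope_cutoff, min_duration_s
        )
    curve = fit_curve(wgn_fcs, reference_fc, variant=f"wgn-{graph.variant}")

    graph_vec = _upper(graph.weights)
    rows = []
    imprint: dict = {}
    for g in [float(x) for x in G_grid]:
        wgn_vecs = {s: _upper(wgn_fcs[s][g].values) for s in wgn_fcs}
        imprint[g] = float(
            np.mean([np.corrcoef(v, graph_vec)[0, 1] for v in wgn_vecs.values()])
        )
        for subject, by_g in empirical_fcs.items():
            emp = _upper(by_g[g].values)
            best = max(np.corrcoef(emp, v)[0, 1] for v in wgn_vecs.values())
            rows.append({"subject": subject, "G": g, "max_r_wgn": float(best)})
    return WGNControl(
        wgn_fit=curve,
        similarity=pd.DataFrame(rows),
        graph_imprint=pd.Series(imprint).sort_index(),
    )
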