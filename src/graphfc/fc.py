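"""Functional-connectivity estimation.

The primary measure is the power-envelope correlation: zero-phase band-pass,
Hilbert envelope, 0.5 Hz low-pass, Pearson correlation over time, with
per-interval matrices combined by duration-weighted Fisher-z averaging.
Coherence and imaginary coherence (Welch cross-spectra, five 50 %-overlapping
Hann segments per ~3 s window) are provided for comparison.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from ._filters import band_envelope
from .datatypes import FCMatrix, SourceEpoch

__all__ = [
    "resample_epochs",
    "segment_and_reject",
    "envelope_fc",
    "spectral_fc",
    "fisher_z",
    "inverse_fisher_z",
    "rank_normal",
]

logger = logging.getLogger(__name__)

MIN_INTERVAL_S = 19.0  # minimum interval length for reliable slow envelopes
_CLIP = 1.0 - 1e-15
# seconds discarded at each end of the low-passed envelope before correlating:
# Hilbert + low-pass edge transients are common across channels and would
# otherwise bias all pairwise correlations upward
EDGE_TRIM_S = 2.0


def resample_epochs(epochs: list, rate: float) -> list:
    """Polyphase resampling (with anti-alias filtering) to a target rate.

    Applied before band-pass filtering so that narrow low-frequency bands
    are not processed at an excessive sampling rate.
    """
    from fractions import Fraction

    from scipy.signal import resample_poly

    out = []
    for ep in epochs:
        if ep.rate == rate:
            out.append(ep)
            continue
        frac = Fraction(rate / ep.rate).limit_denominator(1000)
        data = resample_poly(ep.data, frac.numerator, frac.denominator, axis=-1)
        out.append(
            SourceEpoch(
                data=data, rate=rate, subject=ep.subject, interval=ep.interval, band=ep.band
            )
        )
    return out


def segment_and_reject(
    epochs: list,
    min_duration_s: float = MIN_INTERVAL_S,
    window_s: float | None = None,
    reject_sd: float = 6.0,
) -> list:
    """Drop short intervals, optionally window, and reject artifact windows.

    Intervals shorter than ``min_duration_s`` are dropped. If ``window_s``
    is given, surviving intervals are cut into non-overlapping windows of
    that length; a window containing any sample deviating from its
    per-channel mean by more than ``reject_sd`` standard deviations is
    rejected.
    """
    if not epochs:
        raise ValueError("no epochs given")
    kept: list = []
    n_short = n_rejected = 0
    for ep in epochs:
        if ep.duration < min_duration_s:
            n_short += 1
            continue
        if window_s is None:
            kept.append(ep)
            continue
        w = int(round(window_s * ep.rate))
        n_win = ep.n_samples // w
        for k in range(n_win):
            seg = ep.data[:, k * w : (k + 1) * w]
            mu = seg.mean(axis=1, keepdims=True)
            sd = seg.std(axis=1, keepdims=True)
            sd[sd == 0] = np.inf  # constant channel never triggers rejection
            if np.any(np.abs(seg - mu) > reject_sd * sd):
                n_rejected += 1
                continue
            kept.append(
                SourceEpoch(
                    data=seg.copy(),
                    rate=ep.rate,
                    subject=ep.subject,
                    interval=ep.interval * 10_000 + k,
                    band=ep.band,
                )
            )
    if not kept:
        raise ValueError(
            f"all data rejected ({n_short} short intervals, {n_rejected} artifact windows)"
        )
    if n_short or n_rejected:
        logger.info("dropped %d short intervals, %d artifact windows", n_short, n_rejected)
    return kept


def _safe_corrcoef(x: np.ndarray) -> np.ndarray:
    """Pearson correlation over rows; constant rows give 0 with a warning."""
    sd = x.std(axis=1)
    bad = sd == 0
    if np.any(bad):
        logger.warning("%d constant channel(s): correlation entries set to 0", bad.sum())
        x = x.copy()
        x[bad] = np.random.default_rng(0).standard_normal(x.shape[1])  # placeholder rows
    r = np.corrcoef(x)
    if np.any(bad):
        r[bad, :] = 0.0
        r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def envelope_fc(
    epochs: list,
    band: tuple,
    envelope_cutoff: float = 0.5,
    band_label: str | None = None,
    min_duration_s: float = MIN_INTERVAL_S,
) -> FCMatrix:
    """Power-envelope correlation FC for one subject.

    Per interval: band-pass -> Hilbert magnitude -> low-pass at
    ``envelope_cutoff`` -> Pearson correlation. Per-interval matrices are
    combined as the inverse Fisher transform of the duration-weighted mean
    of Fisher-z matrices.
    """
    if not epochs:
        raise ValueError("no epochs given")
    low, high = band
    zs, weights = [], []
    for ep in epochs:
        if ep.duration < min_duration_s:
            raise ValueError(
                f"interval of {ep.duration:.1f}s is shorter than the "
                f"{min_duration_s:.0f}s minimum for envelope estimation"
            )
        if ep.rate < 2 * high:
            raise ValueError(f"rate {ep.rate} Hz too low for band ({low}, {high}) Hz")
        env = band_envelope(ep.data, ep.rate, band, envelope_cutoff)
        trim = int(EDGE_TRIM_S * ep.rate)
        if env.shape[1] > 4 * trim:
            env = env[:, trim:-trim]
        r = _safe_corrcoef(env)
        zs.append(np.arctanh(np.clip(r, -_CLIP, _CLIP)))
        weights.append(ep.duration)
    w = np.asarray(weights) / np.sum(weights)
    z = np.tensordot(w, np.asarray(zs), axes=1)
    values = np.tanh(z)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)
    label = band_label or f"{low:g}-{high:g}Hz"
    return FCMatrix(values=values, measure="envelope_corr", band=label)


def _welch_cross(data: np.ndarray, rate: float, n_windows: int, overlap: float):
    """Cross-spectral matrix per frequency from Hann-tapered segments."""
    n, t = data.shape
    step_frac = 1 + (n_windows - 1) * (1 - overlap)
    nperseg = int(t // step_frac)
    if nperseg < 8:
        raise ValueError(
            f"window of {t} samples too short: need >= {int(8 * step_frac)} samples "
            f"for {n_windows} segments with {overlap:.0%} overlap"
        )
    step = max(int(nperseg * (1 - overlap)), 1)
    starts = range(0, t - nperseg + 1, step)
    taper = np.hanning(nperseg)
    segs = np.stack([data[:, s : s + nperseg] * taper for s in starts])  # (S, N, F_t)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(segs, axis=-1)  # (S, N, F)
    s_xy = np.einsum("sif,sjf->ijf", spec, np.conj(spec)) / len(segs)
    freqs = np.fft.rfftfreq(nperseg, d=1 / rate)
    return s_xy, freqs


def spectral_fc(
    epochs: list,
    band: tuple,
    measure: str = "coherence",
    n_windows: int = 5,
    overlap: float = 0.5,
    band_label: str | None = None,
) -> FCMatrix:
    """(Imaginary) coherence FC for one subject.

    Each input epoch is treated as one (~3 s) window; within it, Welch
    cross-spectra are estimated from ``n_windows`` Hann segments with
    ``overlap`` fractional overlap, coherency is averaged over the band's
    frequency bins, and window-level matrices are averaged.
    """
    if measure not in ("coherence", "icoherence"):
        raise ValueError("measure must be 'coherence' or 'icoherence'")
    if not epochs:
        raise ValueError("no epochs given")
    low, high = band
    mats = []
    for ep in epochs:
        s_xy, freqs = _welch_cross(ep.data, ep.rate, n_windows, overlap)
        in_band = (freqs >= low) & (freqs <= high)
        if not np.any(in_band):
            raise ValueError(f"no frequency bins inside band ({low}, {high}) Hz")
        auto = np.real(np.einsum("iif->if", s_xy))
        denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
        denom[denom == 0] = np.inf
        coherency = s_xy / denom
        if measure == "coherence":
            mats.append(np.abs(coherency[:, :, in_band]).mean(axis=-1))
        else:
            mats.append(np.imag(coherency[:, :, in_band]).mean(axis=-1))
    values = np.mean(mats, axis=0)
    # coherency is Hermitian: Im part is antisymmetric, so mirror the upper
    # triangle rather than averaging (which would cancel icoherence)
    values = np.triu(values, k=1)
    values = values + values.T
    np.fill_diagonal(values, 1.0 if measure == "coherence" else 0.0)
    label = band_label or f"{low:g}-{high:g}Hz"
    return FCMatrix(
        values=values,
        measure=measure,
        band=label,
        diagonal="one" if measure == "coherence" else "zero",
    )


def fisher_z(fc: FCMatrix) -> FCMatrix:
    """Elementwise atanh; values at +/-1 are clipped just inside (-1, 1)."""
    v = fc.values
    clipped = np.abs(v) >= 1.0
    if np.any(clipped & ~np.eye(fc.n_rois, dtype=bool)):
        logger.info("clipping %d off-diagonal |r|>=1 before atanh", int(clipped.sum()))
    z = np.arctanh(np.clip(v, -_CLIP, _CLIP))
    return FCMatrix(
        values=z, measure=fc.measure, band=fc.band, transform="fisher_z", diagonal=fc.diagonal
    )


def inverse_fisher_z(fc: FCMatrix) -> FCMatrix:
    return FCMatrix(
        values=np.tanh(fc.values),
        measure=fc.measure,
        band=fc.band,
        transform="raw",
        diagonal=fc.diagonal,
    )


def rank_normal(fc: FCMatrix) -> FCMatrix:
    """Map off-diagonal values to standard-normal quantiles of their ranks.

    Ranks use average tie handling; the quantile for rank k of M values is
    ndtri((k - 0.5) / M). The diagonal is untouched and rank order is
    preserved exactly.
    """
    n = fc.n_rois
    iu = np.triu_indices(n, k=1)
    off = fc.values[iu]
    ranks = rankdata(off, method="average")
    q = ndtri((ranks - 0.5) / off.size)
    out = fc.values.copy()
    out[iu] = q
    out.T[iu] = q
    return FCMatrix(
        values=out, measure=fc.measure, band=fc.band, transform="rank_normal", diagonal=fc.diagonal
    )
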