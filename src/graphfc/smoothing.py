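"""One-hop low-pass filtering of ROI signals on a connectome graph.

The operator is x_hat_i(t) = x_i(t) + G * sum_j c_ij x_j(t), i.e. the
time-pointwise linear map (I + G*C) applied to the ROI dimension. G tunes
the impact of a node's structurally connected neighbors; G = 0 is the
identity.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FilterGraph, FilterSettings, SourceEpoch

__all__ = ["smooth", "smooth_study"]


def smooth(epoch: SourceEpoch, settings: FilterSettings) -> SourceEpoch:
    """Apply x_hat = (I + G*C) x columnwise over time.

    Linear, time-pointwise (no temporal mixing); G = 0 returns the input
    data bitwise unchanged.
    """
    c = settings.graph.weights
    if c.shape[0] != epoch.n_rois:
        raise ValueError(
            f"graph has {c.shape[0]} nodes but epoch has {epoch.n_rois} ROIs"
        )
    if settings.G == 0:
        return epoch.copy_with(epoch.data.copy())
    out = epoch.data + settings.G * (c @ epoch.data)
    return epoch.copy_with(out)


def smooth_study(epochs_by_subject: dict, graph: FilterGraph, G_grid) -> dict:
    """Filter every interval of every subject at every G.

    Returns ``{subject: {G: [SourceEpoch, ...]}}``; each entry equals a
    direct per-call :func:`smooth`.
    """
    out: dict = {}
    for subject, epochs in epochs_by_subject.items():
        out[subject] = {}
        for g in G_grid:
            settings = FilterSettings(G=float(g), graph=graph)
            out[subject][float(g)] = [smooth(ep, settings) for ep in epochs]
    return out
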