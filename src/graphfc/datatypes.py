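"""Core containers shared across the pipeline.

Every matrix-valued object is indexed in the ROI order defined by the
:class:`Parcellation` it was built from; mixing objects with different ROI
orders raises before any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Parcellation",
    "SourceEpoch",
    "StructuralConnectome",
    "FilterGraph",
    "FilterSettings",
    "SearchInformationMatrix",
    "FCMatrix",
    "CommunitySettings",
    "CommunityMatrix",
    "SyntheticTruth",
]


def _as_2d(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {a.shape}")
    return a


def check_square_symmetric(a, name: str = "matrix", *, rtol: float = 1e-9) -> np.ndarray:
    """Validate a square symmetric matrix; returns the float array."""
    a = _as_2d(a, name)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    scale = np.max(np.abs(a)) if a.size else 0.0
    if scale > 0 and np.max(np.abs(a - a.T)) > rtol * scale:
        raise ValueError(f"{name} is not symmetric within tolerance")
    return a


@dataclass(frozen=True)
class Parcellation:
    """ROI geometry and metadata of a cortical parcellation.

    Attributes
    ----------
    roi_names : unique text labels, one per ROI.
    hemisphere : per-ROI hemisphere label, 'L' or 'R'.
    centroids : (N, 3) ROI centroid coordinates in mm.
    roi_size : per-ROI size in voxels (>= 1).
    """

    roi_names: tuple
    hemisphere: np.ndarray
    centroids: np.ndarray
    roi_size: np.ndarray

    def __post_init__(self):
        names = tuple(str(n) for n in self.roi_names)
        object.__setattr__(self, "roi_names", names)
        hemi = np.asarray(self.hemisphere, dtype="U1")
        cent = np.asarray(self.centroids, dtype=float)
        size = np.asarray(self.roi_size, dtype=int)
        n = len(names)
        if n < 2:
            raise ValueError("parcellation needs at least 2 ROIs")
        if len(set(names)) != n:
            raise ValueError("ROI names must be unique")
        if hemi.shape != (n,) or not np.all(np.isin(hemi, ["L", "R"])):
            raise ValueError("hemisphere must be length-N with values in {L, R}")
        if cent.shape != (n, 3) or not np.all(np.isfinite(cent)):
            raise ValueError("centroids must be finite with shape (N, 3)")
        if size.shape != (n,) or np.any(size < 1):
            raise ValueError("roi_size must be length-N positive integers")
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "centroids", cent)
        object.__setattr__(self, "roi_size", size)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between centroids, mm (N x N)."""
        return squareform(pdist(self.centroids))

    def intra_mask(self) -> np.ndarray:
        """Boolean (N, N): True for intrahemispheric off-diagonal pairs."""
        same = self.hemisphere[:, None] == self.hemisphere[None, :]
        np.fill_diagonal(same, False)
        return same


@dataclass
class SourceEpoch:
    """One artifact-free interval of source-space ROI time courses.

    ``data`` is (N, T): rows are ROIs, columns time samples at ``rate`` Hz.
    """

    data: np.ndarray
    rate: float
    subject: str = "sub-00"
    interval: int = 0
    band: str = "broadband"

    def __post_init__(self):
        self.data = _as_2d(self.data, "epoch data")
        if self.data.shape[1] < 2:
            raise ValueError("epoch needs at least 2 time samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Interval duration in seconds."""
        return self.data.shape[1] / self.rate

    def copy_with(self, data: np.ndarray, band: str | None = None) -> "SourceEpoch":
        return SourceEpoch(
            data=data,
            rate=self.rate,
            subject=self.subject,
            interval=self.interval,
            band=self.band if band is None else band,
        )


def _densities(weights: np.ndarray, hemisphere: np.ndarray):
    n = weights.shape[0]
    same = hemisphere[:, None] == hemisphere[None, :]
    iu = np.triu_indices(n, k=1)
    present = weights[iu] > 0
    intra = same[iu]
    d_intra = present[intra].mean() if intra.any() else 0.0
    d_inter = present[~intra].mean() if (~intra).any() else 0.0
    return float(present.mean()), float(d_intra), float(d_inter)


@dataclass
class StructuralConnectome:
    """Group or subject structural connectome (average fiber counts).

    Densities are fractions of possible off-diagonal pairs carrying an edge,
    overall and split by hemisphere class.
    """

    weights: np.ndarray
    hemisphere: np.ndarray
    density_overall: float = field(init=False)
    density_intra: float = field(init=False)
    density_inter: float = field(init=False)

    def __post_init__(self):
        w = check_square_symmetric(self.weights, "SC weights")
        if np.any(w < 0):
            raise ValueError("SC weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("SC diagonal must be zero")
        self.weights = 0.5 * (w + w.T)  # enforce exact symmetry
        self.hemisphere = np.asarray(self.hemisphere, dtype="U1")
        if self.hemisphere.shape != (w.shape[0],):
            raise ValueError("hemisphere labels must match SC dimension")
        d, di, dx = _densities(self.weights, self.hemisphere)
        self.density_overall, self.density_intra, self.density_inter = d, di, dx

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


VARIANTS = ("sc", "ed_full", "ed_match", "ed_dens", "randomized")


@dataclass
class FilterGraph:
    """Weight matrix c_ij used by the graph-smoothing operator."""

    variant: str
    weights: np.ndarray
    normalization: str = "max1"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.normalization not in ("max1", "none"):
            raise ValueError("normalization must be 'max1' or 'none'")
        w = check_square_symmetric(self.weights, "filter-graph weights")
        if np.any(w < 0):
            raise ValueError("filter-graph weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("filter-graph diagonal must be zero")
        self.weights = 0.5 * (w + w.T)

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class FilterSettings:
    """Scalar filter weight G plus the graph it applies to."""

    G: float
    graph: FilterGraph

    def __post_init__(self):
        if self.G < 0:
            raise ValueError("filter weight G must be nonnegative")


@dataclass
class SearchInformationMatrix:
    """Search information S(s->t) = -log2 of the probability that a naive
    random walker follows the shortest path from s to t."""

    si: np.ndarray
    symmetrized: bool

    def __post_init__(self):
        self.si = _as_2d(self.si, "search information")
        if np.any(np.diag(self.si) != 0):
            raise ValueError("search-information diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(self.si[np.isfinite(self.si)] < -1e-12):
                raise ValueError("search information must be nonnegative")

    @property
    def n_rois(self) -> int:
        return self.si.shape[0]


MEASURES = ("envelope_corr", "coherence", "icoherence")
TRANSFORMS = ("raw", "fisher_z", "rank_normal")


@dataclass
class FCMatrix:
    """Symmetric functional-connectivity matrix for one measure/band."""

    values: np.ndarray
    measure: str
    band: str = "broadband"
    transform: str = "raw"
    diagonal: str = "one"

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        v = check_square_symmetric(self.values, "FC values")
        self.values = 0.5 * (v + v.T)
        if self.transform == "raw":
            off = self.values[~np.eye(v.shape[0], dtype=bool)]
            if self.measure in ("envelope_corr", "icoherence") and np.any(np.abs(off) > 1 + 1e-9):
                raise ValueError(f"{self.measure} values must lie in [-1, 1]")
            if self.measure == "coherence" and (np.any(off < -1e-9) or np.any(off > 1 + 1e-9)):
                raise ValueError("coherence values must lie in [0, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Strict upper-triangle vector in lexicographic pair order."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class CommunitySettings:
    """Settings for repeated Louvain community detection."""

    gamma: float = 1.1
    n_reps: int = 200
    negative_weight_mode: str = "asym"
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("resolution parameter gamma must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.negative_weight_mode not in ("asym", "zero"):
            raise ValueError("negative_weight_mode must be 'asym' or 'zero'")


@dataclass
class CommunityMatrix:
    """Pairwise co-assignment probabilities over repeated Louvain runs."""

    coassign: np.ndarray
    n_communities_mean: float
    settings: CommunitySettings

    def __post_init__(self):
        c = check_square_symmetric(self.coassign, "co-assignment matrix")
        if np.any(c < -1e-12) or np.any(c > 1 + 1e-12):
            raise ValueError("co-assignment probabilities must lie in [0, 1]")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("co-assignment diagonal must be 1")
        self.coassign = c

    @property
    def n_rois(self) -> int:
        return self.coassign.shape[0]


@dataclass
class SyntheticTruth:
    """Ground truth attached to a synthetic cohort.

    genuine_fc is the leakage-free envelope FC; leakage_kernel the
    row-normalized instantaneous mixing matrix; subject_scs the per-subject
    structural connectomes the sources were coupled through.
    """

    genuine_fc: np.ndarray
    leakage_kernel: np.ndarray
    subject_scs: list
    seed: int

    def __post_init__(self):
        g = check_square_symmetric(self.genuine_fc, "genuine FC")
        if not np.allclose(np.diag(g), 1.0):
            raise ValueError("genuine FC must have unit diagonal")
        self.genuine_fc = g
        k = _as_2d(self.leakage_kernel, "leakage kernel")
        if np.any(k < 0):
            raise ValueError("leakage kernel must be nonnegative")
        if not np.allclose(k.sum(axis=1), 1.0):
            raise ValueError("leakage kernel rows must sum to 1")
        self.leakage_kernel = k
        for s in self.subject_scs:
            if np.any(np.diag(np.asarray(s)) != 0):
                raise ValueError("subject SCs must have zero diagonal")
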