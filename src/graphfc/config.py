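"""Run configuration: defaults, validation, JSON round trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "DEFAULT_BANDS", "load_config", "save_config"]

# canonical EEG bands used throughout: label, low (Hz), high (Hz)
DEFAULT_BANDS = (("alpha", 8.0, 13.0), ("beta", 13.0, 30.0), ("gamma", 30.0, 40.0))

DEFAULT_G_GRID = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 800.0, 1000.0)
DEFAULT_GAMMA_GRID = tuple(round(0.9 + 0.025 * i, 3) for i in range(17))  # 0.9 .. 1.3

G_MAX = 1000.0


@dataclass
class RunConfig:
    """All pipeline knobs in one place.

    G values are filter weights applied to a max-normalized graph; gamma is
    the Louvain resolution parameter.
    """

    bands: tuple = DEFAULT_BANDS
    envelope_cutoff: float = 0.5
    resample_rate: float = 250.0
    G_grid: tuple = DEFAULT_G_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    n_louvain_reps: int = 200
    seed: int = 0
    graph_normalization: str = "max1"
    negative_weight_mode: str = "asym"

    def __post_init__(self):
        self.bands = tuple((str(l), float(lo), float(hi)) for l, lo, hi in self.bands)
        self.G_grid = tuple(float(g) for g in self.G_grid)
        self.gamma_grid = tuple(float(g) for g in self.gamma_grid)
        for label, lo, hi in self.bands:
            if not (0 < lo < hi < self.resample_rate / 2):
                raise ValueError(
                    f"band {label!r}: need 0 < low < high < rate/2, got "
                    f"({lo}, {hi}) at rate {self.resample_rate}"
                )
        if any(g < 0 or g > G_MAX for g in self.G_grid):
            raise ValueError(f"G values must lie in [0, {G_MAX}]")
        if any(g <= 0 or g > 5 for g in self.gamma_grid):
            raise ValueError("gamma values must lie in (0, 5]")
        if self.n_louvain_reps < 1:
            raise ValueError("n_louvain_reps must be >= 1")
        if self.graph_normalization not in ("max1", "none"):
            raise ValueError("graph_normalization must be 'max1' or 'none'")
        if self.negative_weight_mode not in ("asym", "zero"):
            raise ValueError("negative_weight_mode must be 'asym' or 'zero'")
        if self.envelope_cutoff <= 0:
            raise ValueError("envelope_cutoff must be positive")

    def band(self, label: str):
        for lab, lo, hi in self.bands:
            if lab == label:
                return (lo, hi)
        raise KeyError(f"no band labelled {label!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        d["G_grid"] = list(self.G_grid)
        d["gamma_grid"] = list(self.gamma_grid)
        return d

    def hash(self) -> str:
        """Stable hash of the effective configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = json.load(fh)
    raw["bands"] = [tuple(b) for b in raw.get("bands", DEFAULT_BANDS)]
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
        fh.write("\n")
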