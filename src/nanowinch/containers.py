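"""Shared data containers used across the mechanics and readout modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DistanceSample:
    """A set of backstop–cylinder (or piston-tip) distances in nm.

    ``source`` records provenance: ``"measured"`` for experimental tables,
    ``"synthetic"`` for generator output, ``"mc"`` for Metropolis draws.
    """

    values: np.ndarray
    label: str = ""
    source: str = "measured"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("a distance sample needs at least one value")
        # physical distances are non-negative; "mc" draws of an abstract test
        # coordinate (e.g. the harmonic hook) are exempt
        if self.source != "mc" and np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if self.source not in ("measured", "synthetic", "mc"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class EnsembleSummary:
    """Summary statistics of a 1-D distance/position distribution.

    ``quantiles`` maps percent levels (5, 50, 95) to nm values.  The histogram
    (``bin_edges`` of length m+1, ``densities`` of length m) integrates to 1.
    ``sd`` is None when undefined (single observation).
    """

    mean: float
    sd: float | None
    quantiles: dict[int, float]
    bin_edges: np.ndarray
    densities: np.ndarray
    n: int | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.bin_edges.size != self.densities.size + 1:
            raise ValueError("need len(bin_edges) == len(densities) + 1")
        mass = float(np.sum(self.densities * np.diff(self.bin_edges)))
        if abs(mass - 1.0) > 1e-6:
            raise ValueError(f"histogram densities integrate to {mass}, not 1")
        if not (self.quantiles[5] <= self.quantiles[50] <= self.quantiles[95]):
            raise ValueError("quantiles must be ordered 5% <= 50% <= 95%")

    def cdf(self, x) -> np.ndarray:
        """Piecewise-linear CDF implied by the histogram, evaluated at x (nm)."""
        edges = self.bin_edges
        cum = np.concatenate([[0.0], np.cumsum(self.densities * np.diff(edges))])
        cum = cum / cum[-1]
        return np.interp(np.asarray(x, dtype=float), edges, cum, left=0.0, right=1.0)


@dataclass(frozen=True)
class ComparisonReport:
    """Descriptive comparison of a distance sample against a model or second sample."""

    mean_difference_nm: float
    sd_ratio: float | None
    ks_statistic: float
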