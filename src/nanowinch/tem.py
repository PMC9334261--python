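"""TEM inter-domain distance tables: I/O, reduction, and model comparison.

Negative-stain TEM yields per-particle measurements of the backstop–cylinder
distance r, which correlates directly with the actuation distance d at the
piston tip (identity mapping by default; any geometric offset enters through
an explicit :class:`AffineMap`).  This module reads/writes the distance CSV
dialect (``distance_nm[,label]``), reduces samples to summary statistics,
and compares measured distributions against model ensembles descriptively
(mean difference, sd ratio, Kolmogorov–Smirnov statistic — no p-value
headline, since the ensemble is a model, not a fit).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .containers import ComparisonReport, DistanceSample, EnsembleSummary

__all__ = ["AffineMap", "read_distance_table", "write_distance_table",
           "r_to_d", "summarize", "compare_to_model"]


@dataclass(frozen=True)
class AffineMap:
    """Affine map from measured r to actuation distance d: d = slope·r + intercept."""

    slope: float = 1.0
    intercept: float = 0.0  # nm

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")

    def inverse(self) -> "AffineMap":
        return AffineMap(slope=1.0 / self.slope, intercept=-self.intercept / self.slope)


def read_distance_table(path) -> DistanceSample:
    """Read a distance CSV (header ``distance_nm[,label]``, '.' decimal, UTF-8)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValueError(f"distance table {path} is empty") from None
    if "distance_nm" not in df.columns:
        raise ValueError(f"distance table {path} is missing the 'distance_nm' column "
                         f"(found {list(df.columns)})")
    if df.empty:
        raise ValueError(f"distance table {path} has a header but no rows")
    values = pd.to_numeric(df["distance_nm"], errors="coerce")
    bad = values.index[values.isna()]
    if len(bad):
        raise ValueError(f"non-numeric distance in row(s) {list(bad)} of {path}")
    neg = values.index[values < 0]
    if len(neg):
        raise ValueError(f"negative distance in row(s) {list(neg)} of {path}")
    label = ""
    if "label" in df.columns and df["label"].nunique() == 1:
        label = str(df["label"].iloc[0])
    return DistanceSample(values=values.to_numpy(), label=label, source="measured")


def write_distance_table(sample: DistanceSample, path) -> None:
    """Write a sample in the same CSV dialect that :func:`read_distance_table` reads."""
    df = pd.DataFrame({"distance_nm": sample.values})
    if sample.label:
        df["label"] = sample.label
    df.to_csv(path, index=False, encoding="utf-8")


def r_to_d(sample: DistanceSample, mapping: AffineMap = AffineMap()) -> DistanceSample:
    """Convert measured r to actuation distance d elementwise, floored at 0 nm."""
    d = np.clip(mapping.slope * sample.values + mapping.intercept, 0.0, None)
    return DistanceSample(values=d, label=sample.label, source=sample.source,
                          metadata={**sample.metadata, "map": (mapping.slope, mapping.intercept)})


def summarize(sample: DistanceSample, bin_width: float = 2.0) -> EnsembleSummary:
    """Reduce a distance sample to mean, sd (n−1), quantiles and a density histogram.

    With a single observation the sd is reported as None.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = sample.values
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else None
    q = {p: float(np.quantile(v, p / 100)) for p in (5, 50, 95)}
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    dens, edges = np.histogram(v, bins=edges, density=True)
    return EnsembleSummary(mean=mean, sd=sd, quantiles=q,
                           bin_edges=edges, densities=dens, n=v.size)


def _ks_vs_summary(values: np.ndarray, summary: EnsembleSummary) -> float:
    """One-sample KS statistic of a sample against a histogram-implied CDF."""
    x = np.sort(values)
    n = x.size
    cdf = summary.cdf(x)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    return float(max(d_plus, d_minus))


def compare_to_model(sample: DistanceSample, model) -> ComparisonReport:
    """Descriptive comparison of a sample against a model ensemble or second sample.

    ``model`` may be an :class:`EnsembleSummary` (histogram-implied CDF;
    one-sample KS) or another :class:`DistanceSample` (two-sample KS).
    Reports mean difference (sample − model, nm), sd ratio (sample/model;
    None when undefined) and the KS statistic only.
    """
    if isinstance(model, DistanceSample):
        other_mean = float(np.mean(model.values))
        other_sd = float(np.std(model.values, ddof=1)) if model.n >= 2 else None
        ks = float(ks_2samp(sample.values, model.values).statistic)
    elif isinstance(model, EnsembleSummary):
        other_mean, other_sd = model.mean, model.sd
        ks = _ks_vs_summary(sample.values, model)
    else:
        raise TypeError(f"cannot compare against {type(model).__name__}")
    own_sd = float(np.std(sample.values, ddof=1)) if sample.n >= 2 else None
    ratio = own_sd / other_sd if own_sd is not None and other_sd else None
    return ComparisonReport(mean_difference_nm=float(np.mean(sample.values)) - other_mean,
                            sd_ratio=ratio, ks_statistic=ks)
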