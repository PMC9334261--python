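"""Quantitative readouts: bead calibration, LRET plate ratios, trace idealization.

Three independent assay reductions used to quantify the actuator's activity:

* QIFIKIT-style flow-cytometry calibration — ordinary least squares of
  log10(fluorophores/bead) on log10(MFI) over defined bead populations, then
  conversion of a background-subtracted cell MFI to molecules per cell.
* HTRF/LRET plate reduction — per-well scaled acceptor/donor ratio
  R = scale·I665/I620, condition mean minus the antibody-only background R0,
  with the SD over replicate wells.
* Two-state idealization of single-channel current traces — a 2-means level
  split, midpoint threshold with a hysteresis band of ±¼ of the level
  separation, and merging of dwells shorter than ``min_dwell`` samples.
  Deliberately not an HMM: the reported closed/open levels are far apart
  relative to the noise and a threshold idealizer is transparent and exact
  on clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = ["CalibrationLine", "CurrentTrace", "TraceSegmentation",
           "fit_bead_calibration", "count_from_mfi", "lret_ratio", "segment_trace"]


# ---------------------------------------------------------------------------
# bead calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationLine:
    """log-log calibration: log(molecules) = slope·log(MFI) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float = float("nan")
    log_base: float = 10.0


def fit_bead_calibration(beads: pd.DataFrame, log_base: float = 10.0) -> CalibrationLine:
    """OLS of log(molecules_per_bead) on log(mfi) over the bead populations.

    ``beads`` needs columns ``mfi`` and ``molecules_per_bead``, both positive,
    with at least two distinct MFI values.
    """
    for col in ("mfi", "molecules_per_bead"):
        if col not in beads.columns:
            raise ValueError(f"bead table is missing the '{col}' column")
    mfi = beads["mfi"].to_numpy(dtype=float)
    mol = beads["molecules_per_bead"].to_numpy(dtype=float)
    if np.any(mfi <= 0) or np.any(mol <= 0):
        raise ValueError("bead MFIs and molecule counts must be positive")
    if len(mfi) < 2 or np.unique(mfi).size < 2:
        raise ValueError("bead calibration needs at least two distinct MFI populations")
    lx = np.log(mfi) / np.log(log_base)
    ly = np.log(mol) / np.log(log_base)
    fit = linregress(lx, ly)
    return CalibrationLine(slope=float(fit.slope), intercept=float(fit.intercept),
                           r_squared=float(fit.rvalue**2),
                           slope_stderr=float(fit.stderr), log_base=log_base)


def count_from_mfi(line: CalibrationLine, sample_mfi: float,
                   background_mfi: float = 0.0) -> float:
    """Molecules per cell from a sample MFI via the calibration line.

    The autofluorescence background is subtracted on the linear MFI scale
    before entering log space.
    """
    if background_mfi < 0:
        raise ValueError("background MFI must be >= 0")
    net = sample_mfi - background_mfi
    if net <= 0:
        raise ValueError(f"sample MFI ({sample_mfi}) does not exceed background "
                         f"({background_mfi}); no signal to quantify")
    log_net = np.log(net) / np.log(line.log_base)
    return float(line.log_base ** (line.slope * log_net + line.intercept))


# ---------------------------------------------------------------------------
# LRET / HTRF plate reduction
# ---------------------------------------------------------------------------

def lret_ratio(plate: pd.DataFrame, scale: float = 1e4,
               background_condition: str = "background") -> pd.DataFrame:
    """Per-condition LRET response (R_AD − R0) with SD over replicate wells.

    ``plate`` needs columns ``condition``, ``donor_620`` and ``acceptor_665``
    (a ``well`` column is carried along if present).  Each well's ratio is
    R = scale × acceptor/donor; R0 is the mean ratio of the background
    (antibody-only) wells and is subtracted from every condition mean.

    Returns a DataFrame with columns ``condition``, ``response``, ``sd``,
    ``n_wells`` (background excluded).
    """
    for col in ("condition", "donor_620", "acceptor_665"):
        if col not in plate.columns:
            raise ValueError(f"plate table is missing the '{col}' column")
    donors = plate["donor_620"].to_numpy(dtype=float)
    if np.any(donors <= 0):
        bad = plate.index[plate["donor_620"] <= 0].tolist()
        raise ValueError(f"non-positive donor intensity in well row(s) {bad}")
    if np.any(plate["acceptor_665"].to_numpy(dtype=float) <= 0):
        raise ValueError("acceptor intensities must be positive")
    ratios = scale * plate["acceptor_665"] / plate["donor_620"]
    is_bg = plate["condition"] == background_condition
    if not is_bg.any():
        raise ValueError(f"no background wells (condition == {background_condition!r})")
    if is_bg.all():
        raise ValueError("plate contains only background wells")
    r0 = float(ratios[is_bg].mean())
    rows = []
    for cond, grp in ratios[~is_bg].groupby(plate.loc[~is_bg, "condition"]):
        sd = float(grp.std(ddof=1)) if len(grp) >= 2 else float("nan")
        rows.append((cond, float(grp.mean()) - r0, sd, len(grp)))
    return pd.DataFrame(rows, columns=["condition", "response", "sd", "n_wells"])


# ---------------------------------------------------------------------------
# two-state trace idealization
# ---------------------------------------------------------------------------

@dataclass
class CurrentTrace:
    """Uniformly sampled current recording: time in s, current in pA."""

    time: np.ndarray
    current: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape or self.time.ndim != 1:
            raise ValueError("time and current must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("current trace contains non-finite values")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("trace must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size >= 2 else float("nan")

    @classmethod
    def from_csv(cls, path) -> "CurrentTrace":
        df = pd.read_csv(path)
        for col in ("time_s", "current_pA"):
            if col not in df.columns:
                raise ValueError(f"trace table is missing the '{col}' column")
        return cls(df["time_s"].to_numpy(), df["current_pA"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "current_pA": self.current}).to_csv(path, index=False)


@dataclass
class TraceSegmentation:
    """Idealized two-state assignment: 0 = closed, 1 = open."""

    states: np.ndarray
    closed_mean: float
    closed_sd: float
    open_mean: float
    open_sd: float
    n_transitions: int
    dwell_lengths: list = field(default_factory=list)  # (state, n_samples) runs
    single_state: bool = False


def _two_means(values: np.ndarray, max_iter: int = 200) -> tuple[float, float]:
    """Deterministic 1-D 2-means split initialized at the 5th/95th percentiles."""
    lo, hi = np.percentile(values, [5, 95])
    if lo == hi:
        return float(lo), float(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        low_mask = values <= mid
        new_lo = float(values[low_mask].mean()) if low_mask.any() else lo
        new_hi = float(values[~low_mask].mean()) if (~low_mask).any() else hi
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return lo, hi


def _runs(states: np.ndarray) -> list[tuple[int, int]]:
    out = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append((int(states[start]), i - start))
            start = i
    return out


def segment_trace(trace: CurrentTrace, min_dwell: int = 5) -> TraceSegmentation:
    """Two-state idealization of a current trace.

    Levels come from a 2-means split of the current values; samples are then
    tracked through a midpoint threshold with a hysteresis band of ±¼ of the
    level separation (a state flips only when the current crosses out of the
    band on the far side).  Dwells shorter than ``min_dwell`` samples are
    merged into their neighbours, and the per-state statistics are recomputed
    from the final assignment.

    A trace whose level separation is below twice the pooled within-level sd
    is reported as single-state with zero transitions.
    """
    cur = trace.current
    if cur.size < 100:
        raise ValueError(f"trace too short to segment ({cur.size} samples; need >= 100)")
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")

    mu_c, mu_o = _two_means(cur)
    low_mask = cur <= 0.5 * (mu_c + mu_o)
    sds = []
    for mask in (low_mask, ~low_mask):
        if mask.sum() >= 2:
            sds.append(np.var(cur[mask], ddof=1))
    pooled_sd = float(np.sqrt(np.mean(sds))) if sds else 0.0
    sep = mu_o - mu_c

    if sep < 2.0 * pooled_sd or sep == 0.0:
        # unimodal: one conductance level only
        states = np.zeros(cur.size, dtype=int)
        mean = float(cur.mean())
        sd = float(cur.std(ddof=1)) if cur.size >= 2 else 0.0
        return TraceSegmentation(states=states, closed_mean=mean, closed_sd=sd,
                                 open_mean=mean, open_sd=sd, n_transitions=0,
                                 dwell_lengths=[(0, cur.size)], single_state=True)

    mid = 0.5 * (mu_c + mu_o)
    upper, lower = mid + sep / 4.0, mid - sep / 4.0
    states = np.empty(cur.size, dtype=int)
    state = int(abs(cur[0] - mu_o) < abs(cur[0] - mu_c))
    for i, c in enumerate(cur):
        if state == 0 and c > upper:
            state = 1
        elif state == 1 and c < lower:
            state = 0
        states[i] = state

    # merge dwells shorter than min_dwell into their neighbours, shortest first
    runs = _runs(states)
    while len(runs) > 1:
        lengths = [r[1] for r in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_dwell:
            break
        s, ln = runs[shortest]
        pos = sum(r[1] for r in runs[:shortest])
        states[pos:pos + ln] = 1 - s
        runs = _runs(states)

    closed = cur[states == 0]
    opened = cur[states == 1]
    if closed.size == 0 or opened.size == 0:
        mean = float(cur.mean())
        sd = float(cur.std(ddof=1))
        return TraceSegmentation(states=np.zeros_like(states), closed_mean=mean,
                                 closed_sd=sd, open_mean=mean, open_sd=sd,
                                 n_transitions=0, dwell_lengths=[(0, cur.size)],
                                 single_state=True)
    runs = _runs(states)
    return TraceSegmentation(
        states=states,
        closed_mean=float(closed.mean()),
        closed_sd=float(closed.std(ddof=1)) if closed.size >= 2 else 0.0,
        open_mean=float(opened.mean()),
        open_sd=float(opened.std(ddof=1)) if opened.size >= 2 else 0.0,
        n_transitions=len(runs) - 1,
        dwell_lengths=runs,
        single_state=False,
    )
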