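"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one experimental data stream at the study's reported
operating statistics, so the full pipeline is testable without any
experimental download:

* TEM distances — truncated normal on [0, ∞) at the reported per-variant
  means (the measured distributions are unimodal and bounded below).
* Bead calibration tables — defined molecules-per-bead populations with
  lognormal multiplicative MFI noise around an exact log-log line, plus
  replicate cell MFIs for a configured true molecules-per-cell count.
* LRET plates — donor intensities at a fixed scale, acceptor intensities set
  so the expected scaled ratio minus background equals a configured true
  response, multiplicative noise on both channels.
* Channel traces — a two-state continuous-time Markov chain sampled
  uniformly with additive Gaussian noise.

Every generator takes an explicit integer seed and is exactly reproducible.
File writers emit a JSON metadata sidecar (generator name, parameters, seed,
package version) from which :func:`regenerate` reproduces the CSV
byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .containers import DistanceSample
from .readouts import CurrentTrace
from .tem import write_distance_table

__all__ = ["TEM_DEFAULTS", "PER_CELL_COUNT_DEFAULT", "CHANNEL_DEFAULTS",
           "LRET_DEFAULTS", "gen_tem_distances", "gen_bead_table", "gen_plate",
           "gen_trace", "save_with_sidecar", "regenerate"]

#: Reported mean TEM actuation distance per device variant (nm) and the
#: fixture spread convention (sd 5 nm, matching the visual width of the
#: published distributions; the per-variant sds are not printed).
TEM_DEFAULTS: dict[str, dict[str, float]] = {
    "ss97": {"mean": 17.7, "sd": 5.0},
    "ss60": {"mean": 14.0, "sd": 5.0},
    "ss30": {"mean": 9.3, "sd": 5.0},
    "ds30": {"mean": 10.7, "sd": 5.0},
    "ds60": {"mean": 19.0, "sd": 5.0},
    "ds97": {"mean": 31.3, "sd": 5.0},
}

#: Reported mean number of devices bound per cell.
PER_CELL_COUNT_DEFAULT = 9200.0

#: Reported channel current levels (pA): closed 4 ± 4, open 16 ± 4.
CHANNEL_DEFAULTS = {"closed_pA": 4.0, "open_pA": 16.0, "noise_sd_pA": 4.0}

#: Reported LRET response of the active device and plate conventions.
LRET_DEFAULTS = {"true_response": 1.23e4, "r0": 1.0e4, "scale": 1e4,
                 "donor_level": 1e4}


def gen_tem_distances(mean: float, sd: float, n: int, seed: int,
                      label: str = "") -> DistanceSample:
    """Truncated-normal distance sample on [0, ∞) at the given mean/sd (nm)."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a = (0.0 - mean) / sd
    values = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    meta = {"generator": "gen_tem_distances", "seed": int(seed),
            "params": {"mean": mean, "sd": sd, "n": n, "label": label}}
    return DistanceSample(values=values, label=label, source="synthetic", metadata=meta)


def gen_tem_defaults(variant: str, n: int, seed: int) -> DistanceSample:
    """Distance sample for a named device variant at its documented defaults."""
    if variant not in TEM_DEFAULTS:
        raise ValueError(f"unknown variant {variant!r}; known: {sorted(TEM_DEFAULTS)}")
    p = TEM_DEFAULTS[variant]
    return gen_tem_distances(p["mean"], p["sd"], n, seed, label=variant)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def gen_bead_table(slope: float = 1.0, intercept: float = 0.0,
                   populations=(1e2, 1e3, 1e4, 1e5, 1e6),
                   cv: float = 0.05, seed: int = 0,
                   true_count: float | None = PER_CELL_COUNT_DEFAULT,
                   n_cell_replicates: int = 3):
    """Synthetic bead-calibration table and replicate cell MFIs.

    The beads sit on the exact line log10(molecules) = slope·log10(MFI) +
    intercept, with lognormal multiplicative MFI noise of coefficient of
    variation ``cv``.  When ``true_count`` is given, replicate cell MFIs are
    drawn around the MFI that the exact line maps to that molecules-per-cell
    count.

    Returns ``(beads, cell_mfi, metadata)``: a DataFrame with columns
    ``mfi``/``molecules_per_bead``, an array of cell MFIs (or None), and the
    sidecar metadata dict.
    """
    populations = tuple(float(p) for p in populations)
    if len(populations) < 2:
        raise ValueError("need at least two bead populations")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    mol = np.asarray(populations)
    mfi_true = 10.0 ** ((np.log10(mol) - intercept) / slope)
    mfi = mfi_true * _lognormal_factors(rng, cv, mol.size)
    beads = pd.DataFrame({"mfi": mfi, "molecules_per_bead": mol})
    cell_mfi = None
    if true_count is not None:
        base = 10.0 ** ((np.log10(true_count) - intercept) / slope)
        cell_mfi = base * _lognormal_factors(rng, cv, n_cell_replicates)
    meta = {"generator": "gen_bead_table", "seed": int(seed),
            "params": {"slope": slope, "intercept": intercept,
                       "populations": list(populations), "cv": cv,
                       "true_count": true_count,
                       "n_cell_replicates": n_cell_replicates}}
    return beads, cell_mfi, meta


def gen_plate(true_response: float = LRET_DEFAULTS["true_response"],
              r0: float = LRET_DEFAULTS["r0"],
              cv: float = 0.10, wells_per_condition: int = 3, seed: int = 0,
              condition: str = "treated", scale: float = LRET_DEFAULTS["scale"],
              donor_level: float = LRET_DEFAULTS["donor_level"]) -> pd.DataFrame:
    """Synthetic LRET plate with one condition plus antibody-only background wells.

    The acceptor intensities are set so the expected scaled ratio is
    ``r0 + true_response`` in the condition wells and ``r0`` in background
    wells; both channels carry independent multiplicative noise of
    coefficient of variation ``cv``.
    """
    if wells_per_condition < 1:
        raise ValueError("need at least one well per condition")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, ratio in ((condition, r0 + true_response), ("background", r0)):
        for w in range(wells_per_condition):
            donor = donor_level * _lognormal_factors(rng, cv, None)
            acceptor = donor_level * ratio / scale * _lognormal_factors(rng, cv, None)
            rows.append((f"{cond}_{w + 1}", cond, float(donor), float(acceptor)))
    plate = pd.DataFrame(rows, columns=["well", "condition", "donor_620", "acceptor_665"])
    plate.attrs["metadata"] = {
        "generator": "gen_plate", "seed": int(seed),
        "params": {"true_response": true_response, "r0": r0, "cv": cv,
                   "wells_per_condition": wells_per_condition,
                   "condition": condition, "scale": scale,
                   "donor_level": donor_level}}
    return plate


def gen_trace(closed_pA: float = CHANNEL_DEFAULTS["closed_pA"],
              open_pA: float = CHANNEL_DEFAULTS["open_pA"],
              noise_sd: float = CHANNEL_DEFAULTS["noise_sd_pA"],
              rate_Hz: float = 1000.0,
              dwell_means_s: tuple[float, float] = (1.0, 1.0),
              duration_s: float = 60.0, seed: int = 0):
    """Two-state Markov channel trace sampled at ``rate_Hz`` with Gaussian noise.

    ``dwell_means_s`` are the mean closed and open dwell times of the
    continuous-time chain.  Returns ``(trace, true_states, metadata)`` where
    ``true_states`` is the noiseless 0/1 state per sample (ground truth for
    segmentation benchmarks).
    """
    if min(dwell_means_s) <= 0 or rate_Hz <= 0 or duration_s <= 0:
        raise ValueError("dwell means, rate and duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_Hz))
    state = 0
    t = 0.0
    seq = []
    while t < duration_s:
        dwell = rng.exponential(dwell_means_s[state])
        seq.append((state, t, min(t + dwell, duration_s)))
        t += dwell
        state = 1 - state
    times = np.arange(n) / rate_Hz
    states = np.zeros(n, dtype=int)
    for s, t0, t1 in seq:
        states[(times >= t0) & (times < t1)] = s
    levels = np.where(states == 1, open_pA, closed_pA)
    current = levels + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    meta = {"generator": "gen_trace", "seed": int(seed),
            "params": {"closed_pA": closed_pA, "open_pA": open_pA,
                       "noise_sd": noise_sd, "rate_Hz": rate_Hz,
                       "dwell_means_s": list(dwell_means_s),
                       "duration_s": duration_s}}
    return CurrentTrace(time=times, current=current), states, meta


# ---------------------------------------------------------------------------
# sidecar I/O
# ---------------------------------------------------------------------------

_GENERATORS = {
    "gen_tem_distances": gen_tem_distances,
    "gen_bead_table": gen_bead_table,
    "gen_plate": gen_plate,
    "gen_trace": gen_trace,
}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_with_sidecar(obj, metadata: dict, path) -> Path:
    """Write a generated object as CSV plus a JSON metadata sidecar.

    Supports :class:`DistanceSample`, :class:`CurrentTrace` and DataFrames.
    Returns the sidecar path.
    """
    from . import __version__

    path = Path(path)
    if isinstance(obj, DistanceSample):
        write_distance_table(obj, path)
    elif isinstance(obj, CurrentTrace):
        obj.to_csv(path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({**metadata, "version": __version__}, indent=2))
    return sidecar


def regenerate(sidecar_path, out_path) -> None:
    """Re-run the generator named in a sidecar and write the CSV again.

    With the recorded seed and parameters the output is byte-identical to the
    original file.
    """
    meta = json.loads(Path(sidecar_path).read_text())
    name = meta["generator"]
    if name not in _GENERATORS:
        raise ValueError(f"unknown generator {name!r} in sidecar")
    params = dict(meta["params"])
    seed = meta["seed"]
    if name == "gen_tem_distances":
        obj = gen_tem_distances(seed=seed, **params)
    elif name == "gen_bead_table":
        beads, _, _ = gen_bead_table(seed=seed, **params)
        obj = beads
    elif name == "gen_plate":
        obj = gen_plate(seed=seed, **params)
    else:  # gen_trace
        params["dwell_means_s"] = tuple(params["dwell_means_s"])
        obj, _, _ = gen_trace(seed=seed, **params)
    save_with_sidecar(obj, {k: meta[k] for k in ("generator", "seed", "params")}, out_path)
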