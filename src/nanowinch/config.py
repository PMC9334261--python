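"""YAML/dict configuration of polymer and actuator parameters.

A config file has a ``polymer`` section (or ``top_polymer``/``bottom_polymer``
pair) and an ``actuator`` section, mapping directly onto the dataclasses in
:mod:`nanowinch.polymer` and :mod:`nanowinch.actuator`:

.. code-block:: yaml

    polymer:
      n_units: 97
      rise_per_unit_nm: 0.63
      persistence_length_nm: 1.0
      strandedness: single
      temperature_K: 296.15
    actuator:
      n_top: 6
      n_bottom: 6
      mode: autonomous_ss
      span_D_nm: 31.718850152
      top_offset_nm: -2.135573476
      bottom_offset_nm: 0.0
      k_protein_pN_per_nm: 0.1
      rest_position_nm: 0.0
      k_eff_ds_pN_per_nm: 8.0
      k_eff_ss_pN_per_nm: 3.0

Omitted actuator keys fall back to the calibrated package defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .actuator import (
    CALIBRATED_SPAN_D_NM,
    CALIBRATED_TOP_OFFSET_NM,
    ActuatorModel,
    EffectiveStiffness,
    GeometryMap,
    ProteinSpring,
)
from .constants import ThermalState
from .polymer import PolymerSpec

__all__ = ["load_config", "polymer_from_config", "actuator_from_config",
           "default_config"]


def load_config(path) -> dict:
    """Load a YAML config file into a plain dict."""
    with open(Path(path), "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def default_config() -> dict:
    """The shipped default configuration (calibrated autonomous 97-nt device)."""
    return {
        "polymer": {"n_units": 97, "rise_per_unit_nm": 0.63,
                    "persistence_length_nm": 1.0, "strandedness": "single",
                    "temperature_K": 296.15},
        "actuator": {"n_top": 6, "n_bottom": 6, "mode": "autonomous_ss",
                     "span_D_nm": CALIBRATED_SPAN_D_NM,
                     "top_offset_nm": CALIBRATED_TOP_OFFSET_NM,
                     "bottom_offset_nm": 0.0,
                     "k_protein_pN_per_nm": 0.0, "rest_position_nm": 0.0,
                     "k_eff_ds_pN_per_nm": 8.0, "k_eff_ss_pN_per_nm": 3.0},
    }


def polymer_from_config(section: dict) -> PolymerSpec:
    """Build a PolymerSpec from a ``polymer`` config section."""
    strand = section.get("strandedness", "single")
    defaults = {"single": (0.63, 1.0), "double": (0.34, 50.0)}
    if strand not in defaults:
        raise ValueError(f"unknown strandedness {strand!r}")
    rise_def, lp_def = defaults[strand]
    return PolymerSpec(
        n_units=int(section["n_units"]),
        rise_per_unit=float(section.get("rise_per_unit_nm", rise_def)),
        persistence_length=float(section.get("persistence_length_nm", lp_def)),
        strandedness=strand,
    )


def actuator_from_config(cfg: dict) -> ActuatorModel:
    """Build an ActuatorModel from a full config dict."""
    if "top_polymer" in cfg or "bottom_polymer" in cfg:
        top = polymer_from_config(cfg["top_polymer"])
        bottom = polymer_from_config(cfg["bottom_polymer"])
        temp = float(cfg["top_polymer"].get("temperature_K", 296.15))
    else:
        top = bottom = polymer_from_config(cfg["polymer"])
        temp = float(cfg["polymer"].get("temperature_K", 296.15))
    act = cfg.get("actuator", {})
    geometry = GeometryMap(
        span_D=float(act.get("span_D_nm", CALIBRATED_SPAN_D_NM)),
        top_offset=float(act.get("top_offset_nm", CALIBRATED_TOP_OFFSET_NM)),
        bottom_offset=float(act.get("bottom_offset_nm", 0.0)),
        x_min=act.get("x_min_nm"), x_max=act.get("x_max_nm"),
    )
    return ActuatorModel(
        top_spec=top, bottom_spec=bottom, geometry=geometry,
        protein=ProteinSpring(k=float(act.get("k_protein_pN_per_nm", 0.0)),
                              rest_position=float(act.get("rest_position_nm", 0.0))),
        n_top=int(act.get("n_top", 6)), n_bottom=int(act.get("n_bottom", 6)),
        thermal=ThermalState(temperature=temp),
        mode=act.get("mode", "autonomous_ss"),
        k_eff=EffectiveStiffness(k_eff_ds=float(act.get("k_eff_ds_pN_per_nm", 8.0)),
                                 k_eff_ss=float(act.get("k_eff_ss_pN_per_nm", 3.0))),
    )
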