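"""Boundary-condition and waveform config files (YAML or JSON).

Interface units are clinical — flow in cm^3/s, pressure in Pa — and are
converted to SI on load. Example::

    inlet_flow_cm3s: 5.0          # or a waveform block:
    # waveform:
    #   mean_flow_cm3s: 5.0
    #   period_s: 0.8
    #   pulsatility_index: 1.0
    target_total_pressure_Pa: 2000
    non_target_pressure_Pa: 300
    outlet_pressures_Pa:          # optional per-outlet overrides
      v012: 450
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .solver import BoundaryConditions, PulsatileWaveform

__all__ = ["load_boundary_conditions", "load_waveform"]

CM3S = 1e-6


def _load_doc(path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        doc = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
    except (json.JSONDecodeError, yaml.YAMLError) as e:
        raise ConfigurationError(f"unparseable config {path}: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return doc


def _waveform_from(doc: dict) -> PulsatileWaveform:
    known = {"mean_flow_cm3s", "period_s", "pulsatility_index",
             "harmonic_amplitudes", "harmonic_phases"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"unknown waveform keys: {sorted(unknown)}")
    mean = float(doc.get("mean_flow_cm3s", 5.0)) * CM3S
    period = float(doc.get("period_s", 0.8))
    if "harmonic_amplitudes" in doc:
        return PulsatileWaveform(
            mean_flow=mean,
            period=period,
            harmonic_amplitudes=tuple(float(a) for a in doc["harmonic_amplitudes"]),
            harmonic_phases=tuple(float(p) for p in doc.get("harmonic_phases", ())),
        )
    return PulsatileWaveform.default(
        mean_flow=mean,
        period=period,
        pulsatility_index=float(doc.get("pulsatility_index", 1.0)),
    )


def load_waveform(path) -> PulsatileWaveform:
    """Load a pulsatile waveform description from YAML/JSON."""
    return _waveform_from(_load_doc(path))


def load_boundary_conditions(path) -> BoundaryConditions:
    """Load boundary conditions from YAML/JSON (flows cm^3/s, pressures Pa)."""
    doc = _load_doc(path)
    known = {"inlet_flow_cm3s", "waveform", "target_total_pressure_Pa",
             "non_target_pressure_Pa", "outlet_pressures_Pa",
             "target_pressure_mode"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if ("waveform" in doc) == ("inlet_flow_cm3s" in doc):
        raise ConfigurationError(
            "config must give exactly one of inlet_flow_cm3s or waveform"
        )
    inlet = (
        _waveform_from(doc["waveform"])
        if "waveform" in doc
        else float(doc["inlet_flow_cm3s"]) * CM3S
    )
    outlet_p = doc.get("outlet_pressures_Pa")
    return BoundaryConditions(
        inlet_flow=inlet,
        outlet_pressures=None
        if outlet_p is None
        else {str(k): float(v) for k, v in outlet_p.items()},
        target_total_pressure=(
            None
            if doc.get("target_total_pressure_Pa") is None
            else float(doc["target_total_pressure_Pa"])
        ),
        non_target_pressure=float(doc.get("non_target_pressure_Pa", 300.0)),
        target_pressure_mode=doc.get("target_pressure_mode", "partition"),
    )
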