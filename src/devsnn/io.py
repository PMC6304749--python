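"""Flat-file serialization of parameter sets and network artifacts."""

from __future__ import annotations

from dataclasses import asdict, fields

import pandas as pd
import yaml

from .connectivity import DelayParams, LatticeGeometry, SynapseTable
from .model_core import MaturationState, NeuronParams, SynapseParams

__all__ = [
    "params_to_yaml",
    "params_from_yaml",
    "write_positions",
    "read_positions",
]

_PARAM_TYPES = {
    "neuron": NeuronParams,
    "synapse": SynapseParams,
    "delay": DelayParams,
}


def params_to_yaml(path, neuron=None, synapse=None, delay=None, maturation=None):
    """Serialize parameter blocks to one flat YAML file (keys match field
    names; units: ms, mV, nS, pF, m/s as documented on each type)."""
    doc = {}
    if neuron is not None:
        doc["neuron"] = asdict(neuron)
    if synapse is not None:
        doc["synapse"] = asdict(synapse)
    if delay is not None:
        doc["delay"] = asdict(delay)
    if maturation is not None:
        doc["maturation"] = {
            "label": maturation.label.value,
            "E_gaba": maturation.E_gaba,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def params_from_yaml(path) -> dict:
    """Load parameter blocks back; unknown keys in a block are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = {}
    for key, cls in _PARAM_TYPES.items():
        if key in doc:
            allowed = {f.name for f in fields(cls)}
            unknown = set(doc[key]) - allowed
            if unknown:
                raise ValueError(f"unknown {key} parameter keys: {sorted(unknown)}")
            out[key] = cls(**doc[key])
    if "maturation" in doc:
        out["maturation"] = MaturationState.from_label(doc["maturation"]["label"])
    return out


def write_positions(geom: LatticeGeometry, path) -> None:
    pd.DataFrame(
        {
            "id": range(geom.n),
            "x_mm": geom.positions[:, 0],
            "y_mm": geom.positions[:, 1],
        }
    ).to_csv(path, index=False)


def read_positions(path, L: float = 1.0) -> LatticeGeometry:
    df = pd.read_csv(path).sort_values("id")
    return LatticeGeometry(L=L, positions=df[["x_mm", "y_mm"]].to_numpy(float))
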