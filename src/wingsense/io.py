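"""HDF5 / JSON persistence for pipeline artifacts, with provenance."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .encoding import EncodingParams, SpikeData
from .placement import SensorSet, SSPOCParams
from .wing_model import StrainField

__all__ = ["save_strain", "load_strain", "save_spikes", "load_spikes",
           "save_sensors", "load_sensors"]


def _write_attrs(grp, mapping):
    for k, v in mapping.items():
        if isinstance(v, dict):
            sub = grp.create_group(k)
            _write_attrs(sub, v)
        elif v is None:
            grp.attrs[k] = "__none__"
        else:
            grp.attrs[k] = v


def _read_attrs(grp):
    out = {k: (None if isinstance(v, str) and v == "__none__" else v)
           for k, v in grp.attrs.items()}
    for k, v in grp.items():
        if isinstance(v, h5py.Group):
            out[k] = _read_attrs(v)
    return out


def save_strain(path, field: StrainField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epsilon_xx", data=field.epsilon_xx, compression="gzip")
        f.create_dataset("times", data=field.times)
        f.create_dataset("X", data=field.X)
        f.create_dataset("Y", data=field.Y)
        f.attrs["grid_shape"] = field.grid_shape
        f.attrs["condition"] = field.condition
        f.attrs["wingbeat_window"] = field.wingbeat_window
        f.attrs["dt"] = field.dt
        f.attrs["periodicity_error"] = field.periodicity_error
        f.attrs["warnings"] = json.dumps(field.warnings)
        _write_attrs(f.create_group("provenance"), field.provenance)


def load_strain(path) -> StrainField:
    with h5py.File(path, "r") as f:
        return StrainField(
            epsilon_xx=f["epsilon_xx"][...], times=f["times"][...],
            X=f["X"][...], Y=f["Y"][...],
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
            condition=str(f.attrs["condition"]),
            wingbeat_window=tuple(int(v) for v in f.attrs["wingbeat_window"]),
            dt=float(f.attrs["dt"]),
            periodicity_error=float(f.attrs["periodicity_error"]),
            provenance=_read_attrs(f["provenance"]),
            warnings=json.loads(f.attrs["warnings"]),
        )


def save_spikes(path, *spike_sets: SpikeData) -> None:
    with h5py.File(path, "w") as f:
        for sd in spike_sets:
            g = f.create_group(sd.class_label)
            g.create_dataset("first_spike", data=sd.first_spike, compression="gzip")
            g.attrs["wingbeat_period"] = sd.wingbeat_period
            if sd.params is not None:
                _write_attrs(g.create_group("params"), asdict(sd.params))


def load_spikes(path) -> dict[str, SpikeData]:
    out = {}
    with h5py.File(path, "r") as f:
        for label, g in f.items():
            params = None
            if "params" in g:
                params = EncodingParams(**_read_attrs(g["params"]))
            out[label] = SpikeData(
                first_spike=g["first_spike"][...],
                wingbeat_period=float(g.attrs["wingbeat_period"]),
                class_label=label, params=params)
    return out


def save_sensors(path, sensors: SensorSet) -> None:
    payload = {
        "selected": sensors.selected.tolist(),
        "weights": sensors.weights.tolist(),
        "locations": (sensors.locations.tolist()
                      if sensors.locations is not None else None),
        "params": asdict(sensors.params) if sensors.params else None,
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


def load_sensors(path) -> SensorSet:
    with open(path) as f:
        payload = json.load(f)
    params = SSPOCParams(**payload["params"]) if payload.get("params") else None
    loc = payload.get("locations")
    return SensorSet(
        weights=np.asarray(payload["weights"], dtype=float),
        selected=np.asarray(payload["selected"], dtype=int),
        locations=None if loc is None else np.asarray(loc, dtype=float),
        params=params)
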