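"""Spike records: the unit of exchange between simulation and analysis.

A record is a flat event list (time in seconds, neuron id) plus the neuron
count, the recorded duration and optional per-neuron class labels and
metadata.  Persisted as plain two-column text with ``# key=value`` header
lines so records survive in text-only archives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeRecord", "write_spike_record", "read_spike_record"]


@dataclass(frozen=True)
class SpikeRecord:
    """Ordered spike events for one run.

    ``times`` are in seconds, sorted (ties broken by id); ``ids`` are neuron
    indices in ``[0, n_neurons)``.  ``is_inhibitory`` labels neuron classes
    when known.  ``meta`` carries configuration provenance (seed, dt, ...).
    """

    times: np.ndarray
    ids: np.ndarray
    n_neurons: int
    duration: float  # s
    is_inhibitory: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.ids, dtype=np.int64)
        if t.shape != i.shape:
            raise ValueError("times and ids must have the same length")
        order = np.lexsort((i, t))
        object.__setattr__(self, "times", t[order])
        object.__setattr__(self, "ids", i[order])
        if t.size and (t.min() < 0 or t.max() > self.duration):
            raise ValueError("spike times must lie in [0, duration]")
        if i.size and (i.min() < 0 or i.max() >= self.n_neurons):
            raise ValueError("neuron ids out of range")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def train(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]

    def trains(self) -> list[np.ndarray]:
        out: list[list[float]] = [[] for _ in range(self.n_neurons)]
        for t, i in zip(self.times, self.ids):
            out[i].append(t)
        return [np.asarray(a) for a in out]

    def min_isi(self) -> float:
        """Smallest inter-spike interval over all neurons (s); inf if none."""
        best = np.inf
        order = np.lexsort((self.times, self.ids))
        ids = self.ids[order]
        times = self.times[order]
        same = ids[1:] == ids[:-1]
        if np.any(same):
            best = float(np.min(np.diff(times)[same]))
        return best


def write_spike_record(rec: SpikeRecord, path) -> None:
    header = {
        "n_neurons": rec.n_neurons,
        "duration_s": rec.duration,
        "meta": rec.meta,
    }
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={json.dumps(value)}\n")
        if rec.is_inhibitory is not None:
            flags = "".join("1" if x else "0" for x in rec.is_inhibitory)
            fh.write(f"# is_inhibitory={flags}\n")
        fh.write("# time_s\tneuron_id\n")
        for t, i in zip(rec.times, rec.ids):
            fh.write(f"{t:.6f}\t{i}\n")


def read_spike_record(path) -> SpikeRecord:
    header: dict[str, str] = {}
    times: list[float] = []
    ids: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value
                continue
            t_str, i_str = line.split()
            times.append(float(t_str))
            ids.append(int(i_str))
    inh = None
    if "is_inhibitory" in header:
        inh = np.array([c == "1" for c in header["is_inhibitory"]])
    return SpikeRecord(
        times=np.asarray(times),
        ids=np.asarray(ids, dtype=np.int64),
        n_neurons=int(json.loads(header["n_neurons"])),
        duration=float(json.loads(header["duration_s"])),
        is_inhibitory=inh,
        meta=json.loads(header.get("meta", "{}")),
    )
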