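"""Time-indexed simulation records with HDF5 / CSV serialisation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimulationRecord"]


@dataclass
class SimulationRecord:
    """Downsampled traces of a simulation plus reproducibility metadata.

    All traces share the ``t_ms`` axis (samples every ``record_every``
    integration steps).  ``weights`` holds named weight snapshots (e.g.
    'initial', 'final' or phase boundaries).  ``meta`` carries the seed,
    preset name and parameter values needed to re-run bit-identically.
    """

    t_ms: np.ndarray
    z: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    pos: np.ndarray | None = None
    arm: np.ndarray | None = None
    moving: np.ndarray | None = None
    running: np.ndarray | None = None
    inh_dnd: np.ndarray | None = None
    weights: dict = field(default_factory=dict)
    series: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    _ARRAYS = ("t_ms", "z", "x", "y", "pos", "arm", "moving", "running", "inh_dnd")

    @property
    def sample_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0]) if len(self.t_ms) > 1 else 1.0

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in self._ARRAYS:
                val = getattr(self, name)
                if val is not None:
                    f.create_dataset(name, data=np.asarray(val))
            wg = f.create_group("weights")
            for k, v in self.weights.items():
                wg.create_dataset(k, data=np.asarray(v))
            sg = f.create_group("series")
            for k, v in self.series.items():
                sg.create_dataset(k, data=np.asarray(v))
            f.attrs["meta"] = json.dumps(self.meta, default=float)

    @classmethod
    def from_hdf5(cls, path) -> "SimulationRecord":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {name: f[name][...] for name in cls._ARRAYS if name in f}
            weights = {k: f["weights"][k][...] for k in f["weights"]}
            series = {k: f["series"][k][...] for k in f.get("series", {})}
            meta = json.loads(f.attrs.get("meta", "{}"))
        return cls(weights=weights, series=series, meta=meta, **kw)

    def behavior_to_csv(self, path) -> None:
        """Two-column (plus covariates) time/position table."""
        import pandas as pd

        cols = {"t_ms": self.t_ms}
        for name in ("pos", "arm", "moving", "running"):
            val = getattr(self, name)
            if val is not None:
                cols[name] = val
        pd.DataFrame(cols).to_csv(path, index=False)

    def weights_to_csv(self, directory) -> list:
        """Write each stored weight snapshot as a plain CSV matrix."""
        import pathlib

        import pandas as pd

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, mat in self.weights.items():
            path = directory / f"{name}.csv"
            pd.DataFrame(np.asarray(mat)).to_csv(path, index=False, header=False)
            written.append(path)
        return written

    def equals(self, other: "SimulationRecord") -> bool:
        """Bit-identical comparison of all stored arrays."""
        for name in self._ARRAYS:
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        if set(self.weights) != set(other.weights):
            return False
        return all(np.array_equal(self.weights[k], other.weights[k])
                   for k in self.weights)
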