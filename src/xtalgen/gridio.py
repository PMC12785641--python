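"""HDF5 serialization of amplitude/phase grids for training pipelines."""
from __future__ import annotations

import h5py
import numpy as np

__all__ = ["save_grids", "load_grids"]


def save_grids(path, amplitude: np.ndarray, phase: np.ndarray, index_cap: int) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitude", data=amplitude)
        f.create_dataset("phase", data=phase)
        f.attrs["index_cap"] = index_cap
        f.attrs["layout"] = "grid[h, k+cap, l+cap]; Friedel hemisphere h>=0"


def load_grids(path) -> tuple[np.ndarray, np.ndarray, int]:
    with h5py.File(path, "r") as f:
        return f["amplitude"][...], f["phase"][...], int(f.attrs["index_cap"])
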