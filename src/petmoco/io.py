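"""NIfTI / CSV output helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import Phantom

__all__ = ["save_nifti", "load_nifti", "save_property_table"]


def save_nifti(path: str | Path, array: np.ndarray, pixel_size: float) -> Path:
    """Write a 2D map or a (frames, rows, cols) stack as NIfTI."""
    arr = np.asarray(array, dtype=np.float32)
    if arr.ndim == 3:  # frame axis last for viewers
        arr = np.moveaxis(arr, 0, -1)
    affine = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    path = Path(path)
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    return path


def load_nifti(path: str | Path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    return arr


def save_property_table(path: str | Path, phantom: Phantom) -> Path:
    rows = [
        {"label": p.tissue_label, "name": p.name, "K1": p.K1, "k2": p.k2,
         "mu": p.mu, "pd": p.pd, "t1": p.t1, "t2": p.t2}
        for p in sorted(phantom.properties.values(), key=lambda p: p.tissue_label)
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
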