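"""I/O helpers: CSV tables with JSON sidecar manifests, NIfTI volumes."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["write_table", "read_table", "save_nifti", "load_nifti", "write_json"]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def write_table(df: pd.DataFrame, path, manifest: dict | None = None) -> None:
    """Write a CSV; an optional JSON sidecar records provenance (profile,
    model parameters, seed) next to it as ``<name>.manifest.json``."""
    path = Path(path)
    df.to_csv(path, index=False)
    if manifest is not None:
        write_json(manifest, path.with_suffix(path.suffix + ".manifest.json"))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_nifti(volume: np.ndarray, spacing, path) -> None:
    """Save an (x, y, z)-indexed volume with the spacing carried in the affine."""
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(path))


def load_nifti(path):
    """Load a volume; returns (array indexed (x, y, z), spacing tuple)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing
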