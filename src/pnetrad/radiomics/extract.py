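"""High-level feature extraction for one or two ROIs of a volume."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ExtractionConfig, preprocess
from .firstorder import first_order
from .shape import shape_features
from .texture import texture_matrices, texture_features

__all__ = ["extract_features", "extract_pair"]


def extract_features(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    config: ExtractionConfig | None = None,
    roi_name: str = "ROI",
    include_shape: bool = True,
) -> dict[str, float]:
    """Run the full chain (preprocess -> first-order + shape + texture) on one ROI.

    Returns a flat ``{class_Name: value}`` map.  When the config carries a
    ``feature_inventory`` only those names are retained.
    """
    config = config or ExtractionConfig()
    sample = preprocess(volume, mask, config, spacing=spacing, roi_name=roi_name)
    feats: dict[str, float] = {}
    for k, v in first_order(sample).items():
        feats[f"firstorder_{k}"] = v
    if include_shape:
        for k, v in shape_features(sample.mask, sample.spacing, surface=config.surface_mode).items():
            feats[f"shape_{k}"] = v
    feats.update(texture_features(texture_matrices(sample)))
    if config.feature_inventory is not None:
        feats = {k: feats[k] for k in config.feature_inventory if k in feats}
    return feats


def extract_pair(
    volume: np.ndarray,
    lesion_mask: np.ndarray,
    pancreas_mask: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    config: ExtractionConfig | None = None,
    patient_id: str = "P001",
    center: str = "C1",
) -> pd.DataFrame:
    """Extract lesion and contralateral-pancreas features as a two-row table."""
    rows = []
    for roi, mask in (("lesion", lesion_mask), ("pancreas", pancreas_mask)):
        feats = extract_features(volume, mask, spacing, config, roi_name=roi)
        rows.append({"patient_id": patient_id, "roi": roi, "center": center, **feats})
    return pd.DataFrame(rows)
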