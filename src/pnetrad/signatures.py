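"""Spatial delta-features, shape PCA, and the hybrid clinico-radiomic panel.

Family A signatures multiply harmonized lesion radiomic primitives with
preoperative clinical multiplicands (Ki-67 fraction, biopsy grade 1/2/3,
functional status 0/1, metastatic-organ count).  Family B replaces the
lesion primitive with its delta counterpart: lesion minus contralateral
pancreas, both ComBat-harmonized, so per-patient common-mode nuisance
(body habitus, contrast timing, residual scanner bias) cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClinicalEncoding",
    "encode_clinical",
    "delta_features",
    "shape_pca",
    "load_panel",
    "compute_signatures",
    "SIGNATURES_WITH_GRADE",
]

#: signatures whose formula contains biopsy grade (excluded for grade prediction)
SIGNATURES_WITH_GRADE: tuple[str, ...] = ("A3", "A4", "A7", "B3")


@dataclass
class ClinicalEncoding:
    """Per-patient clinical multiplicands, aligned by patient_id index."""

    table: pd.DataFrame  # columns: ki67_fraction, grade, functional, n_met_organs

    def __post_init__(self) -> None:
        t = self.table
        kf = t["ki67_fraction"].dropna()
        if ((kf < 0) | (kf > 1)).any():
            raise ValueError("ki67_fraction outside [0, 1]")
        g = t["grade"].dropna()
        if (~g.isin([1, 2, 3])).any():
            raise ValueError("grade must be in {1, 2, 3}")


def encode_clinical(cohort: pd.DataFrame) -> ClinicalEncoding:
    """Encode the cohort table: Ki-67 % -> fraction, grade 1/2/3, functional 0/1."""
    ki67 = cohort["ki67"].astype(float)
    bad = ki67.dropna()
    if ((bad < 0) | (bad > 100)).any():
        raise ValueError("Ki-67 must be a percentage in [0, 100]")
    table = pd.DataFrame(
        {
            "ki67_fraction": (ki67 / 100.0).to_numpy(),
            "grade": cohort["grade"].to_numpy(float),
            "functional": cohort["functional"].to_numpy(float),
            "n_met_organs": cohort["n_met_organs"].to_numpy(float),
        },
        index=pd.Index(cohort["patient_id"].to_numpy(), name="patient_id"),
    )
    return ClinicalEncoding(table)


def _by_patient(features: pd.DataFrame) -> pd.DataFrame:
    if "patient_id" in features.columns:
        features = features.set_index("patient_id")
    return features.drop(columns=[c for c in ("roi", "center") if c in features.columns])


def delta_features(lesion: pd.DataFrame, pancreas: pd.DataFrame) -> pd.DataFrame:
    """Lesion minus matched-pancreas feature values, shape features excluded.

    Shape primitives are dominated by lesion-vs-pancreas volume differences
    rather than tissue signal, so they never enter the delta pool.
    """
    les, pan = _by_patient(lesion), _by_patient(pancreas)
    missing = set(les.index).symmetric_difference(pan.index)
    if missing:
        raise ValueError(f"unmatched patients in lesion/pancreas tables: {sorted(missing)}")
    cols = [c for c in les.columns if not c.startswith("shape_")]
    missing_cols = set(cols).symmetric_difference(
        c for c in pan.columns if not c.startswith("shape_")
    )
    if missing_cols:
        raise ValueError(f"feature sets differ between ROIs: {sorted(missing_cols)}")
    pan = pan.loc[les.index]
    return les[cols] - pan[cols]


def shape_pca(shape_feats: pd.DataFrame, n_components: int = 3):
    """PCA of z-scored shape descriptors (correlation-matrix eigendecomposition).

    Returns (scores, variance_fractions) where scores holds the first
    ``n_components`` component scores per patient and variance_fractions the
    per-component explained-variance fractions (all components sum to 1).
    Sign convention: each loading vector's largest-magnitude entry is positive.
    """
    X = _by_patient(shape_feats)
    complete = X.dropna()
    if len(complete) < 4:
        raise ValueError("shape PCA requires >= 4 complete rows")
    sds = complete.std(ddof=1)
    const = sds[sds == 0].index.tolist()
    if const:
        warnings.warn(f"shape PCA: dropping constant features {const}")
        complete = complete.drop(columns=const)
    Z = (complete - complete.mean()) / complete.std(ddof=1)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    k = min(n_components, eigvec.shape[1])
    scores = pd.DataFrame(
        Z.to_numpy() @ eigvec[:, :k],
        index=complete.index,
        columns=[f"shape_pc{i + 1}" for i in range(k)],
    ).reindex(X.index)
    frac = eigval / eigval.sum()
    return scores, frac


def load_panel() -> dict:
    """Load the declarative signature registry shipped with the package."""
    text = resources.files("pnetrad").joinpath("panel.yaml").read_text()
    return yaml.safe_load(text)["signatures"]


_TRANSFORMS = {
    None: lambda v: v,
    "one_minus": lambda v: 1.0 - v,
    "one_plus": lambda v: 1.0 + v,
    "log1p": lambda v: np.log1p(v),
}


def compute_signatures(
    lesion: pd.DataFrame,
    deltas: pd.DataFrame,
    clinical: ClinicalEncoding,
    panel: dict | None = None,
) -> pd.DataFrame:
    """Evaluate the signature panel per patient.

    A signature is missing (NaN) whenever any multiplicand is missing; in
    particular Family B values exist only where both ROIs' harmonized
    features exist.  Composites (A5 = A1 x A2) are evaluated after their
    parents.
    """
    panel = panel or load_panel()
    les = _by_patient(lesion)
    dlt = _by_patient(deltas) if deltas is not None else pd.DataFrame(index=les.index)
    clin = clinical.table
    patients = les.index
    sources = {"lesion": les, "delta": dlt.reindex(patients), "clinical": clin.reindex(patients)}

    out = pd.DataFrame(index=patients)
    composites = {}
    for sig_id, spec in panel.items():
        if "composite" in spec:
            composites[sig_id] = spec["composite"]
            continue
        val = pd.Series(1.0, index=patients)
        for factor in spec["factors"]:
            table = sources[factor["source"]]
            key = factor["key"]
            if key not in table.columns:
                raise KeyError(f"signature {sig_id}: unknown {factor['source']} column {key!r}")
            term = _TRANSFORMS[factor.get("transform")](table[key].astype(float))
            # NaN must win over a zero multiplicand (missing, not zero)
            val = val * term
            val[term.isna()] = np.nan
        out[sig_id] = val
    for sig_id, parents in composites.items():
        val = pd.Series(1.0, index=patients)
        for p in parents:
            val = val * out[p]
            val[out[p].isna()] = np.nan
        out[sig_id] = val
    return out[list(panel.keys())]
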