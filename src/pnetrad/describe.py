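"""Descriptive statistics: lesion-vs-pancreas volcano and clinical correlations."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "lesion_vs_pancreas",
    "radiomic_clinical_correlations",
    "group_comparisons",
]


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d of (mean(a) - mean(b)); denominator n1+n2-2."""
    n1, n2 = len(a), len(b)
    s2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(s2))


def lesion_vs_pancreas(
    lesion: pd.DataFrame, pancreas: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature lesion-vs-pancreas comparison (volcano-plot statistics).

    Two-sided unpaired Mann-Whitney U p per feature with BH-FDR q across all
    tested features, and Cohen's d signed as pancreas mean minus lesion mean
    over the pooled SD (so features elevated in lesions get negative d).
    Features present in only one table are skipped with a warning.
    """
    lcols = [c for c in lesion.columns if np.issubdtype(lesion[c].dtype, np.number)]
    pcols = [c for c in pancreas.columns if np.issubdtype(pancreas[c].dtype, np.number)]
    only = sorted(set(lcols).symmetric_difference(pcols))
    if only:
        warnings.warn(f"features present in a single table skipped: {only}")
    common = [c for c in lcols if c in set(pcols)]
    rows = []
    for feat in common:
        a = lesion[feat].dropna().to_numpy(float)
        b = pancreas[feat].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"feature": feat, "cohens_d": _cohens_d(b, a), "mwu_p": p})
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["mwu_p"].to_numpy(), method="fdr_bh")
        out["fdr_q"] = q
        out["significant"] = out["fdr_q"] < alpha
    return out


def radiomic_clinical_correlations(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman rho (average-rank ties) per feature x clinical-variable cell,
    with BH-FDR across the full grid.  Constant columns or cells with fewer
    than ``min_pairs`` complete pairs are flagged undefined, not errors."""
    rows = []
    for feat in features.columns:
        for var in clinical.columns:
            x = features[feat]
            yv = clinical[var]
            mask = x.notna() & yv.notna()
            if mask.sum() < min_pairs:
                rows.append({"feature": feat, "clinical": var, "rho": np.nan, "p": np.nan})
                continue
            a, b = x[mask].to_numpy(float), yv[mask].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rows.append({"feature": feat, "clinical": var, "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(a, b)
            rows.append({"feature": feat, "clinical": var, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr_q"] = np.nan
    defined = out["p"].notna()
    if defined.any():
        _, q, _, _ = multipletests(out.loc[defined, "p"].to_numpy(), method="fdr_bh")
        out.loc[defined, "fdr_q"] = q
    out["significant"] = out["fdr_q"] < alpha
    return out


def group_comparisons(values, groups) -> float:
    """Two groups -> Mann-Whitney U; three or more -> Kruskal-Wallis."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 nonempty groups")
    if np.ptp(values) == 0:
        return 1.0
    if len(samples) == 2:
        return float(stats.mannwhitneyu(*samples, alternative="two-sided").pvalue)
    return float(stats.kruskal(*samples).pvalue)
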