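"""Parametric ComBat batch correction across imaging centers.

Implements the classical empirical-Bayes location/scale model: features are
standardized by their grand mean and pooled variance, per-batch location
(gamma) and scale (delta^2) effects are estimated and shrunk toward
parametric priors (normal for gamma, inverse-gamma for delta^2) with
method-of-moments hyperparameters, and the shrunk estimates are removed.
No biological covariates enter the design; covariate balance across centers
is checked beforehand (``balance_check``), mirroring a design where the
batch variable is the center and biology is verified to be balanced rather
than modeled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CombatModel", "balance_check", "combat_fit", "combat_transform", "harmonize"]


@dataclass
class CombatModel:
    """Fitted ComBat parameters (one gamma*/delta2* pair per batch x feature)."""

    feature_names: list[str]
    batches: list[str]
    grand_mean: np.ndarray  # (F,)
    var_pooled: np.ndarray  # (F,)
    gamma_star: np.ndarray  # (B, F), on the standardized scale
    delta2_star: np.ndarray  # (B, F)
    dropped: list[str] = field(default_factory=list)  # zero-variance pass-through

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "batches": self.batches,
                "grand_mean": self.grand_mean.tolist(),
                "var_pooled": self.var_pooled.tolist(),
                "gamma_star": self.gamma_star.tolist(),
                "delta2_star": self.delta2_star.tolist(),
                "dropped": self.dropped,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CombatModel":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            batches=d["batches"],
            grand_mean=np.asarray(d["grand_mean"]),
            var_pooled=np.asarray(d["var_pooled"]),
            gamma_star=np.asarray(d["gamma_star"]),
            delta2_star=np.asarray(d["delta2_star"]),
            dropped=d["dropped"],
        )


def balance_check(cohort: pd.DataFrame, covariates: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """Per-covariate balance across the two centers.

    Continuous covariates use a two-sided Mann-Whitney U test; binary
    covariates (<= 2 distinct non-missing values) use Fisher's exact test.
    Returns a table with columns covariate, test, p, flagged (p < alpha).
    """
    centers = sorted(cohort["center"].dropna().unique())
    if len(centers) < 2:
        raise ValueError("balance check requires two centers")
    rows = []
    for cov in covariates:
        vals = cohort[[cov, "center"]].dropna()
        a = vals.loc[vals["center"] == centers[0], cov]
        b = vals.loc[vals["center"] == centers[1], cov]
        uniq = vals[cov].unique()
        if vals[cov].dtype == object or len(uniq) <= 2:
            cats = sorted(pd.unique(vals[cov]))
            if len(cats) == 1:
                p, test = 1.0, "fisher"
            else:
                table = [
                    [int((a == cats[0]).sum()), int((a == cats[1]).sum())],
                    [int((b == cats[0]).sum()), int((b == cats[1]).sum())],
                ]
                p = float(stats.fisher_exact(table)[1])
                test = "fisher"
        else:
            if a.nunique() <= 1 and b.nunique() <= 1 and a.iloc[0] == b.iloc[0]:
                p, test = 1.0, "mannwhitney"
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                test = "mannwhitney"
        rows.append({"covariate": cov, "test": test, "p": p, "flagged": p < alpha})
    return pd.DataFrame(rows)


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (2 * s2 + m**2) / s2 if s2 > 0 else 2.0


def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else m

def _postmean(ghat, gbar, n, dstar, tau2):
    return (tau2 * n * ghat + dstar * gbar) / (tau2 * n + dstar)


def _postvar(ssq, n, a, b):
    return (0.5 * ssq + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch, ghat, dhat, gbar, tau2, a, b, tol=1e-6, max_iter=100):
    """Iterative conditional estimation of (gamma*, delta2*) for one batch."""
    n = z_batch.shape[0]
    g_old, d_old = ghat.copy(), dhat.copy()
    for _ in range(max_iter):
        g_new = _postmean(ghat, gbar, n, d_old, tau2)
        ssq = ((z_batch - g_new) ** 2).sum(axis=0)
        d_new = _postvar(ssq, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat_fit(features: pd.DataFrame, batch: pd.Series, tol: float = 1e-6) -> CombatModel:
    """Fit parametric ComBat on a samples x features numeric frame.

    Lesion and pancreas rows of the same patient are expected to be pooled in
    a single matrix so both ROIs share their center's correction.  Features
    with zero pooled variance are excluded (warned) and passed through
    unadjusted by ``combat_transform``.  A single batch is allowed (with a
    warning); fit+transform is then the identity up to round-off.
    """
    X = features.to_numpy(float)
    batch = pd.Series(np.asarray(batch).astype(str), index=features.index)
    batches = sorted(batch.unique())
    if len(batches) < 2:
        warnings.warn("ComBat fitted on a single batch: transform is the identity")
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValueError("each batch needs >= 2 samples")

    var0 = X.var(axis=0)
    dropped = [f for f, v in zip(features.columns, var0) if v == 0 or not np.isfinite(v)]
    if dropped:
        warnings.warn(f"ComBat: excluding zero-variance features: {dropped}")
    keep = [f for f in features.columns if f not in dropped]
    X = features[keep].to_numpy(float)
    nb, nf = len(batches), len(keep)
    n = X.shape[0]

    masks = [batch.to_numpy() == b for b in batches]
    batch_means = np.vstack([X[m].mean(axis=0) for m in masks])  # (B, F)
    w = np.array([m.sum() / n for m in masks])
    grand_mean = w @ batch_means
    fitted = np.vstack([np.tile(batch_means[k], (masks[k].sum(), 1)) for k in range(nb)])
    X_sorted = np.vstack([X[m] for m in masks])
    var_pooled = ((X_sorted - fitted) ** 2).mean(axis=0)
    var_pooled = np.where(var_pooled > 0, var_pooled, 1e-12)

    sd = np.sqrt(var_pooled)
    Z = (X - grand_mean) / sd

    gamma_star = np.zeros((nb, nf))
    delta2_star = np.ones((nb, nf))
    for k, m in enumerate(masks):
        zb = Z[m]
        ghat = zb.mean(axis=0)
        dhat = zb.var(axis=0, ddof=1)
        if nb == 1:
            # degenerate single-batch fit: the standardization already centers
            # and unit-scales, so the adjustment must be the exact identity
            gamma_star[k] = ghat  # == 0
            delta2_star[k] = zb.var(axis=0, ddof=0)  # == 1
        elif nf > 1:
            gbar, tau2 = ghat.mean(), ghat.var(ddof=1)
            a, b = _aprior(dhat), _bprior(dhat)
            gamma_star[k], delta2_star[k] = _it_sol(zb, ghat, dhat, gbar, tau2, a, b, tol=tol)
        else:
            # no cross-feature information to form priors: use naive estimates
            gamma_star[k], delta2_star[k] = ghat, np.maximum(dhat, 1e-12)
    delta2_star = np.maximum(delta2_star, 1e-12)

    return CombatModel(
        feature_names=keep,
        batches=batches,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        dropped=dropped,
    )


def combat_transform(model: CombatModel, features: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Apply a fitted ComBat model; unseen batch labels raise ``ValueError``."""
    batch = pd.Series(np.asarray(batch).astype(str), index=features.index)
    unseen = set(batch.unique()) - set(model.batches)
    if unseen:
        raise ValueError(f"unseen batch labels: {sorted(unseen)}")
    out = features.copy()
    sd = np.sqrt(model.var_pooled)
    X = features[model.feature_names].to_numpy(float)
    Z = (X - model.grand_mean) / sd
    for k, b in enumerate(model.batches):
        m = (batch == b).to_numpy()
        if not m.any():
            continue
        Z[m] = (Z[m] - model.gamma_star[k]) / np.sqrt(model.delta2_star[k])
    out[model.feature_names] = Z * sd + model.grand_mean
    return out


def harmonize(features: pd.DataFrame, batch: pd.Series, tol: float = 1e-6):
    """Convenience fit+transform; returns (harmonized frame, model)."""
    model = combat_fit(features, batch, tol=tol)
    return combat_transform(model, features, batch), model
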