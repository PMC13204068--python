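"""Feature screening, predictor blocks, nested cross-validation, calibration, LOCO.

Three predictor blocks are compared per binary target (progression and
higher-grade disease): M0 (five preoperative clinical variables), MA
(M0 + Family A signatures), MB (M0 + Family B delta-signatures).  For the
higher-grade target biopsy grade leaves M0 and every signature whose
formula contains grade (A3, A4, A7, B3) is excluded to prevent label
leakage.  Out-of-fold probabilities come from outer 5-fold stratified CV
with inner 5-fold selection of the SelectKBest k in {2, 3, 5}; imputation,
scaling, and selection all live inside the CV pipeline so no test-fold
information leaks into preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import brier_score_loss, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BlockSpec",
    "PredictionResult",
    "correlation_cluster",
    "baseline_adjusted_lrt",
    "stability_selection",
    "assemble_blocks",
    "nested_cv",
    "calibration_metrics",
    "loco_cv",
    "bootstrap_auc_ci",
    "DEFAULT_CLASSIFIERS",
    "A_SIGNATURES",
    "B_SIGNATURES",
]

_EPS = 1e-6
A_SIGNATURES = ("A1", "A2", "A3", "A4", "A5", "A6", "A7")
B_SIGNATURES = ("B1", "B2", "B3")
_GRADE_SIGNATURES = ("A3", "A4", "A7", "B3")


@dataclass(frozen=True)
class BlockSpec:
    name: str  # M0 | MA | MB
    target: str  # progression | higher_grade
    variables: tuple[str, ...]
    exclusions: tuple[str, ...] = ()


@dataclass
class PredictionResult:
    block: str
    target: str
    classifier: str
    oof_probabilities: np.ndarray
    y: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    brier: float
    calib_intercept: float
    calib_slope: float
    calib_intercept_ci: tuple[float, float] = (np.nan, np.nan)
    calib_slope_ci: tuple[float, float] = (np.nan, np.nan)
    chosen_k: list[int] = field(default_factory=list)
    loco_auc: float = np.nan
    loco_auc_ci: tuple[float, float] = (np.nan, np.nan)


# ---------------------------------------------------------------------------
# screening cascade


def correlation_cluster(features: pd.DataFrame, threshold: float = 0.80):
    """Connected components of the |Spearman rho| >= threshold graph.

    Returns (clusters, representatives): each cluster's representative is its
    medoid (maximal mean |rho| to the other members), ties broken by name.
    All-missing features are dropped with a warning.
    """
    feats = features.copy()
    empty = [c for c in feats.columns if feats[c].notna().sum() == 0]
    if empty:
        warnings.warn(f"dropping all-missing features: {empty}")
        feats = feats.drop(columns=empty)
    names = list(feats.columns)
    if len(names) < 2:
        return [names], {names[0]: names} if names else {}
    rho = feats.corr(method="spearman").abs().to_numpy()
    np.fill_diagonal(rho, 1.0)
    adj = np.nan_to_num(rho) >= threshold

    # union-find over the adjacency graph
    parent = list(range(len(names)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if adj[i, j]:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(names)):
        groups.setdefault(find(i), []).append(i)

    clusters, representatives = [], {}
    for members in groups.values():
        cluster = sorted(names[i] for i in members)
        if len(members) == 1:
            rep = cluster[0]
        else:
            mean_rho = {
                names[i]: np.nanmean([rho[i, j] for j in members if j != i]) for i in members
            }
            rep = max(sorted(mean_rho), key=lambda f: mean_rho[f])
        clusters.append(cluster)
        representatives[rep] = cluster
    return clusters, representatives


def _ridge_logit_loglik(y, X, alpha=1e-3):
    """Ridge-penalized logistic fit (intercept unpenalized); returns the
    unpenalized log-likelihood at the penalized optimum."""
    from scipy.optimize import minimize

    def negll(beta):
        eta = np.clip(X @ beta, -500, 500)
        ll = np.sum(y * eta - np.log1p(np.exp(eta)))
        return -ll + 0.5 * alpha * np.sum(beta[1:] ** 2)

    res = minimize(negll, np.zeros(X.shape[1]), method="BFGS")
    eta = np.clip(X @ res.x, -500, 500)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def _logit_loglik(y, X):
    """MLE binary-outcome regression; falls back to a light ridge penalty on
    separation or collinearity so the LRT remains computable."""
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params) > 50):
                raise ValueError("separation")
        return float(res.llf)
    except Exception:
        warnings.warn("degenerate logistic fit: using ridge-penalized fallback")
        return _ridge_logit_loglik(y, X)


def baseline_adjusted_lrt(candidate, baseline: pd.DataFrame, y) -> float:
    """Likelihood-ratio p for adding one candidate to the clinical baseline.

    2 * (loglik(baseline + candidate) - loglik(baseline)) against chi2(1),
    on complete cases of (candidate, baseline, y).
    """
    df = baseline.copy()
    df["_cand"] = np.asarray(candidate, float)
    df["_y"] = np.asarray(y, float)
    df = df.dropna()
    yv = df.pop("_y").to_numpy()
    cand = df.pop("_cand").to_numpy()
    Xb = sm.add_constant(df.to_numpy(float), has_constant="add")
    if len(yv) < len(df.columns) + 3 or len(np.unique(yv)) < 2:
        return 1.0
    cols = Xb.std(axis=0) > 0
    cols[0] = True
    Xb = Xb[:, cols]
    ll0 = _logit_loglik(yv, Xb)
    if np.std(cand) == 0:
        return 1.0
    ll1 = _logit_loglik(yv, np.column_stack([Xb, cand]))
    lrt = max(2 * (ll1 - ll0), 0.0)
    return float(stats.chi2.sf(lrt, df=1))


def screen_candidates(
    candidates: pd.DataFrame, baseline: pd.DataFrame, y, fdr: float = 0.10
) -> pd.DataFrame:
    """Baseline-adjusted LRT per candidate with BH-FDR across candidates."""
    pvals = {c: baseline_adjusted_lrt(candidates[c], baseline, y) for c in candidates.columns}
    names = list(pvals)
    p = np.array([pvals[c] for c in names])
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"candidate": names, "p": p, "q": q, "selected": q < fdr})


def stability_selection(
    candidates: pd.DataFrame,
    baseline: pd.DataFrame,
    y,
    B: int = 100,
    threshold: float = 0.60,
    fdr: float = 0.10,
    seed: int = 0,
):
    """Bootstrap stability of the FDR screen: selection frequency per candidate.

    Each of the B resamples redraws patients with replacement (redrawn, with
    a log message, if only one outcome class appears), reruns the
    baseline-adjusted LRT screen at the given FDR, and records which
    candidates survive.  Returns (frequencies: Series, selected: list).
    """
    if candidates.shape[1] == 0:
        raise ValueError("no candidates to screen")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    n = len(y)
    counts = pd.Series(0.0, index=candidates.columns)
    for _ in range(B):
        for _attempt in range(50):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if len(np.unique(yb[~np.isnan(yb)])) == 2:
                break
        res = screen_candidates(
            candidates.iloc[idx].reset_index(drop=True),
            baseline.iloc[idx].reset_index(drop=True),
            yb,
            fdr=fdr,
        )
        counts[res.loc[res["selected"], "candidate"].to_numpy()] += 1
    freq = counts / B
    selected = sorted(freq.index[freq >= threshold])
    return freq, selected


# ---------------------------------------------------------------------------
# blocks


def assemble_blocks(target: str) -> dict[str, BlockSpec]:
    """The three predictor blocks for one target, with leakage exclusions.

    M0 holds five preoperative clinical variables: age, sex, imaging tumor
    size, biopsy grade, and biopsy Ki-67.  For the higher-grade target
    biopsy grade is replaced by functional status (keeping five variables)
    and grade-containing signatures are excluded from MA/MB.
    """
    if target == "progression":
        m0 = ("age", "sex", "size_cm", "grade", "ki67")
        a_sigs, b_sigs = A_SIGNATURES, B_SIGNATURES
        excl: tuple[str, ...] = ()
    elif target == "higher_grade":
        m0 = ("age", "sex", "size_cm", "ki67", "functional")
        excl = _GRADE_SIGNATURES
        a_sigs = tuple(s for s in A_SIGNATURES if s not in excl)
        b_sigs = tuple(s for s in B_SIGNATURES if s not in excl)
    else:
        raise ValueError(f"unknown target {target!r}")
    return {
        "M0": BlockSpec("M0", target, m0, excl),
        "MA": BlockSpec("MA", target, m0 + a_sigs, excl),
        "MB": BlockSpec("MB", target, m0 + b_sigs, excl),
    }


# ---------------------------------------------------------------------------
# nested CV


def DEFAULT_CLASSIFIERS(seed: int = 0) -> dict[str, object]:
    return {
        "logistic": LogisticRegression(max_iter=2000),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "gradient_boosting": GradientBoostingClassifier(random_state=seed),
    }


def _make_pipeline(estimator, k):
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("select", SelectKBest(score_func=f_classif, k=k)),
            ("clf", estimator),
        ]
    )


def bootstrap_auc_ci(y, p, n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC of pooled predictions."""
    if n_boot <= 0:
        return (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    p = np.asarray(p)
    n = len(y)
    aucs = []
    attempts = 0
    while len(aucs) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        aucs.append(roc_auc_score(y[idx], p[idx]))
    return float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))


def _stratified_folds(y, n_splits, seed):
    for bump in range(20):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + bump)
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) >= 1 for tr, te in folds):
            return folds
    raise ValueError("could not stratify folds with both classes")


def nested_cv(
    block: BlockSpec,
    data: pd.DataFrame,
    y,
    classifiers: dict[str, object] | None = None,
    k_grid=(2, 3, 5),
    seed: int = 0,
    n_boot: int = 2000,
    n_outer: int = 5,
    n_inner: int = 5,
) -> dict[str, PredictionResult]:
    """Nested stratified CV: outer folds give out-of-fold probabilities,
    inner folds pick the SelectKBest k by AUC.  Returns one result per
    classifier; the best by pooled OOF AUC is conventionally reported.
    """
    y = np.asarray(y, float)
    keep = ~np.isnan(y)
    X = data.loc[keep, list(block.variables)].reset_index(drop=True)
    yv = y[keep].astype(int)
    if len(np.unique(yv)) < 2:
        raise ValueError("target needs both classes")
    if len(yv) < 10:
        raise ValueError("need >= 10 patients")
    classifiers = classifiers or DEFAULT_CLASSIFIERS(seed)
    ks = sorted({min(k, X.shape[1]) for k in k_grid})

    results = {}
    for name, est in classifiers.items():
        oof = np.full(len(yv), np.nan)
        chosen = []
        folds = _stratified_folds(yv, n_outer, seed)
        for tr, te in folds:
            grid = GridSearchCV(
                _make_pipeline(est, ks[0]),
                {"select__k": ks},
                scoring="roc_auc",
                error_score=np.nan,
                cv=StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed + 1),
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                grid.fit(X.iloc[tr], yv[tr])
            oof[te] = grid.predict_proba(X.iloc[te])[:, 1]
            chosen.append(int(grid.best_params_["select__k"]))
        oof = np.clip(oof, _EPS, 1 - _EPS)
        auc = roc_auc_score(yv, oof)
        ci = bootstrap_auc_ci(yv, oof, n_boot=n_boot, seed=seed)
        brier = brier_score_loss(yv, oof)
        try:
            calib = calibration_metrics(yv, oof, n_boot=0)
            ci_cal = (calib["intercept"], calib["slope"])
        except ValueError:
            ci_cal = (np.nan, np.nan)
        results[name] = PredictionResult(
            block=block.name,
            target=block.target,
            classifier=name,
            oof_probabilities=oof,
            y=yv,
            auc=float(auc),
            auc_ci=ci,
            brier=float(brier),
            calib_intercept=ci_cal[0],
            calib_slope=ci_cal[1],
            chosen_k=chosen,
        )
    return results


# ---------------------------------------------------------------------------
# calibration


def calibration_metrics(y, p, n_boot: int = 2000, seed: int = 0) -> dict:
    """TRIPOD calibration intercept and slope with percentile-bootstrap CIs.

    Slope b is the coefficient of logit(p) in the maximum-likelihood logistic
    regression of the outcome on logit(p) (jointly with the intercept);
    ``intercept_fixed`` re-estimates the intercept with the slope fixed at 1
    (offset model), the calibration-in-the-large variant.  Ideal values are
    intercept 0 and slope 1.
    """
    y = np.asarray(y, float)
    p = np.clip(np.asarray(p, float), _EPS, 1 - _EPS)
    lp = np.log(p / (1 - p))
    if np.std(lp) == 0:
        raise ValueError("constant predictions: calibration slope undefined")

    def _fit(yv, lpv):
        X = sm.add_constant(lpv)
        res = sm.GLM(yv, X, family=sm.families.Binomial()).fit()
        off = sm.GLM(yv, np.ones((len(yv), 1)), family=sm.families.Binomial(), offset=lpv).fit()
        return float(res.params[0]), float(res.params[1]), float(off.params[0])

    intercept, slope, intercept_fixed = _fit(y, lp)
    out = {"intercept": intercept, "slope": slope, "intercept_fixed": intercept_fixed}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(y)
        draws = []
        attempts = 0
        while len(draws) < n_boot and attempts < 10 * n_boot:
            attempts += 1
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) < 2 or np.std(lp[idx]) == 0:
                continue
            try:
                draws.append(_fit(y[idx], lp[idx])[:2])
            except Exception:
                continue
        draws = np.array(draws)
        out["intercept_ci"] = tuple(np.percentile(draws[:, 0], [2.5, 97.5]))
        out["slope_ci"] = tuple(np.percentile(draws[:, 1], [2.5, 97.5]))
    return out


# ---------------------------------------------------------------------------
# leave-one-center-out


def loco_cv(
    block: BlockSpec,
    data: pd.DataFrame,
    y,
    centers,
    classifier=None,
    k_grid=(2, 3, 5),
    seed: int = 0,
    n_boot: int = 1000,
):
    """Leave-one-center-out validation: train on one center, predict the other,
    both directions; pool all out-of-fold predictions into one AUC with a
    percentile-bootstrap CI.  Preprocessing and k-selection run inside the
    training center only.  Returns (auc, ci, pooled predictions, pooled y);
    a center missing an outcome class yields NaN with a warning.
    """
    y = np.asarray(y, float)
    centers = np.asarray(centers)
    keep = ~np.isnan(y)
    X = data.loc[keep, list(block.variables)].reset_index(drop=True)
    yv = y[keep].astype(int)
    cv = centers[keep]
    labels = sorted(np.unique(cv))
    if len(labels) != 2:
        raise ValueError("LOCO requires exactly two centers")
    for lab in labels:
        if len(np.unique(yv[cv == lab])) < 2:
            warnings.warn(f"center {lab} lacks both outcome classes: LOCO undefined")
            return np.nan, (np.nan, np.nan), None, None

    classifier = classifier if classifier is not None else LogisticRegression(max_iter=2000)
    ks = sorted({min(k, X.shape[1]) for k in k_grid})
    pooled_p = np.full(len(yv), np.nan)
    for train_lab in labels:
        tr = cv == train_lab
        te = ~tr
        grid = GridSearchCV(
            _make_pipeline(classifier, ks[0]),
            {"select__k": ks},
            scoring="roc_auc",
                error_score=np.nan,
            cv=StratifiedKFold(n_splits=min(5, int(np.bincount(yv[tr]).min())) if np.bincount(yv[tr]).min() >= 2 else 2,
                               shuffle=True, random_state=seed),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid.fit(X.loc[tr], yv[tr])
        pooled_p[te] = grid.predict_proba(X.loc[te])[:, 1]
    auc = roc_auc_score(yv, pooled_p)
    ci = bootstrap_auc_ci(yv, pooled_p, n_boot=n_boot, seed=seed)
    return float(auc), ci, pooled_p, yv
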