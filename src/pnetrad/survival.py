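"""Univariable Cox regression per signature with resampling inference.

Each signature is z-standardized on its complete cases, so hazard ratios are
per 1-SD increase.  The single-covariate Efron partial likelihood is
maximized directly, which also gives likelihood-ratio (profile) confidence
bounds by bisection on the likelihood surface.  Discrimination uses
Harrell's concordance with a percentile bootstrap CI (2000 resamples) and a
permutation p-value (1000 permutations) computed on the inverse-direction
scale |c| = max(c, 1 - c), so protective markers are judged on the same
footing as adverse ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import optimize, stats

__all__ = [
    "CoxResult",
    "KMResult",
    "z_standardize",
    "efron_loglik",
    "cox_univariable",
    "concordance_inference",
    "km_median_split",
    "signature_survival_table",
]

_CHI2_95 = stats.chi2.ppf(0.95, df=1)
_BETA_BOUND = 25.0  # |beta| at the bound flags a monotone likelihood


@dataclass
class CoxResult:
    signature: str
    n: int
    events: int
    beta: float
    hr_per_sd: float
    ci_low: float
    ci_high: float
    p: float  # Wald
    p_lrt: float
    concordance: float = np.nan
    c_ci: tuple[float, float] = (np.nan, np.nan)
    c_perm_p: float = np.nan
    separation: bool = False

    @property
    def c_abs(self) -> float:
        return max(self.concordance, 1.0 - self.concordance)


@dataclass
class KMResult:
    group: str
    timeline: np.ndarray
    survival: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n: int
    events: int
    logrank_stat: float = np.nan
    logrank_p: float = np.nan


def z_standardize(values) -> tuple[pd.Series, pd.Series]:
    """Complete-case z-scores (sample SD, ddof=1); missing entries stay missing."""
    s = pd.Series(values, dtype=float)
    mask = s.notna()
    x = s[mask]
    if mask.sum() < 2:
        raise ValueError("need >= 2 non-missing values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero standard deviation")
    out = s.copy()
    out[mask] = (x - x.mean()) / sd
    return out, mask


def efron_loglik(beta: float, z: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Efron-tie-corrected Cox partial log-likelihood for one covariate."""
    z = np.asarray(z, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    theta = np.exp(np.clip(beta * z, -700, 700))
    ll = 0.0
    for t in np.unique(time[event]):
        d_idx = event & (time == t)
        r_idx = time >= t
        d = int(d_idx.sum())
        sum_risk = theta[r_idx].sum()
        sum_tied = theta[d_idx].sum()
        ll += beta * z[d_idx].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_tied)
    return float(ll)


def _fit_beta(z, time, event):
    neg = lambda b: -efron_loglik(b, z, time, event)
    res = optimize.minimize_scalar(neg, bounds=(-_BETA_BOUND, _BETA_BOUND), method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


def _profile_ci(beta_hat, ll_hat, z, time, event):
    """Likelihood-ratio 95% bounds by bisection; infinite when monotone."""
    target = ll_hat - _CHI2_95 / 2.0
    bounds = []
    for direction in (-1.0, 1.0):
        f = lambda b: efron_loglik(b, z, time, event) - target
        hi = beta_hat + direction * _BETA_BOUND
        if f(hi) > 0:  # likelihood never drops enough: unbounded
            bounds.append(direction * np.inf)
            continue
        lo = beta_hat
        sol = optimize.brentq(f, min(lo, hi), max(lo, hi), xtol=1e-8)
        bounds.append(float(sol))
    return bounds[0], bounds[1]


def cox_univariable(z, time, event, signature: str = "") -> CoxResult:
    """Single-covariate Cox PH fit (Efron ties) with profile-likelihood CI.

    ``z`` is assumed standardized, so exp(beta) is the HR per 1-SD.  The
    reported ``p`` is the Wald test from the observed information; the
    likelihood-ratio p is also computed.  Monotone likelihoods (separation in
    every risk set) are flagged with infinite CI bounds instead of crashing.
    """
    z = np.asarray(z, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float).astype(bool)
    if event.sum() < 1:
        raise ValueError("need at least one event")

    beta = _fit_beta(z, time, event)
    ll_hat = efron_loglik(beta, z, time, event)
    separation = abs(beta) >= _BETA_BOUND - 1e-3

    h = 1e-5
    d2 = (efron_loglik(beta + h, z, time, event) - 2 * ll_hat + efron_loglik(beta - h, z, time, event)) / h**2
    if d2 < 0 and not separation:
        se = 1.0 / np.sqrt(-d2)
        p_wald = 2 * stats.norm.sf(abs(beta) / se)
    else:
        p_wald = np.nan

    ll0 = efron_loglik(0.0, z, time, event)
    p_lrt = float(stats.chi2.sf(2 * (ll_hat - ll0), df=1))

    if separation:
        lo, hi = (-np.inf, np.inf)
    else:
        lo, hi = _profile_ci(beta, ll_hat, z, time, event)

    return CoxResult(
        signature=signature,
        n=len(z),
        events=int(event.sum()),
        beta=beta,
        hr_per_sd=float(np.exp(beta)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p=float(p_wald),
        p_lrt=p_lrt,
        separation=separation,
    )


def concordance_inference(z, time, event, n_boot: int = 2000, n_perm: int = 1000, seed: int = 0):
    """Harrell's c with percentile-bootstrap CI and permutation p on |c|.

    The bootstrap resamples patients; the permutation shuffles the score
    across patients keeping (time, event) pairs fixed, and the p-value is
    (1 + #{|c_perm| >= |c_obs|}) / (n_perm + 1) with |c| = max(c, 1 - c).
    """
    z = np.asarray(z, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float).astype(int)
    c_obs = concordance_index(time, -z, event)
    rng = np.random.default_rng(seed)
    n = len(z)

    boots = []
    attempts = 0
    while len(boots) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            boots.append(concordance_index(time[idx], -z[idx], event[idx]))
        except ZeroDivisionError:  # no admissible pairs in this resample
            continue
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    c_abs_obs = max(c_obs, 1 - c_obs)
    exceed = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        cp = concordance_index(time, -zp, event)
        if max(cp, 1 - cp) >= c_abs_obs - 1e-12:
            exceed += 1
    perm_p = (1 + exceed) / (n_perm + 1)
    return float(c_obs), ci, float(perm_p)


def km_median_split(signature, time, event, label: str = "signature"):
    """Median-split Kaplan-Meier pair with Greenwood log(-log) 95% bands.

    Values <= median go to the "low" group (deterministic tie handling).
    Returns (low: KMResult, high: KMResult) with the two-group log-rank
    statistic and p stored on both.
    """
    s = pd.Series(signature, dtype=float)
    time = pd.Series(time, dtype=float)
    event = pd.Series(event, dtype=float)
    mask = s.notna() & time.notna() & event.notna()
    s, time, event = s[mask], time[mask], event[mask]
    med = s.median()
    low = s <= med
    if low.all() or (~low).all():
        raise ValueError("median split produced an empty group")

    lr = logrank_test(time[low], time[~low], event[low], event[~low])
    results = []
    for name, m in (("low", low), ("high", ~low)):
        kmf = KaplanMeierFitter(alpha=0.05)
        kmf.fit(time[m], event[m], label=f"{label}_{name}")
        ci = kmf.confidence_interval_survival_function_
        results.append(
            KMResult(
                group=name,
                timeline=kmf.survival_function_.index.to_numpy(),
                survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
                band_low=np.clip(ci.iloc[:, 0].to_numpy(), 0, 1),
                band_high=np.clip(ci.iloc[:, 1].to_numpy(), 0, 1),
                n=int(m.sum()),
                events=int(event[m].sum()),
                logrank_stat=float(lr.test_statistic),
                logrank_p=float(lr.p_value),
            )
        )
    return results[0], results[1]


def signature_survival_table(
    signatures: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    n_boot: int = 2000,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Univariable Cox + concordance inference for every panel signature.

    Complete cases per signature (signature, time, and event all present),
    mirroring the per-signature n/events bookkeeping of a clinical table.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(signatures.shape[1])
    for j, sig in enumerate(signatures.columns):
        df = pd.DataFrame({"s": signatures[sig], "t": np.asarray(time, float),
                           "e": np.asarray(event, float)}).dropna()
        if len(df) < 3 or df["e"].sum() < 1 or df["s"].std(ddof=1) == 0:
            continue
        z, _ = z_standardize(df["s"])
        res = cox_univariable(z.to_numpy(), df["t"].to_numpy(), df["e"].to_numpy(), signature=sig)
        c, ci, perm_p = concordance_inference(
            z.to_numpy(), df["t"].to_numpy(), df["e"].to_numpy(),
            n_boot=n_boot, n_perm=n_perm, seed=int(seeds[j]),
        )
        res.concordance, res.c_ci, res.c_perm_p = c, ci, perm_p
        rows.append(
            {
                "signature": sig,
                "n": res.n,
                "events": res.events,
                "hr_per_sd": res.hr_per_sd,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "p_lrt": res.p_lrt,
                "concordance": c,
                "c_ci_low": ci[0],
                "c_ci_high": ci[1],
                "c_perm_p": perm_p,
                "c_abs": res.c_abs,
                "separation": res.separation,
            }
        )
    return pd.DataFrame(rows)
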