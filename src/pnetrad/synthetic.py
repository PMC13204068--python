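"""Synthetic two-center PNET cohorts, paired-ROI feature tables, and CT-like phantoms.

The study cohort this package analyses is not public, so every downstream
stage must be exercisable on simulated data that reproduces the cohort's
published marginals (grade mix, Ki-67 median, progression rate, follow-up)
and the nuisance structure of multicenter CT radiomics:

    lesion_ij   = biology_ij + patient_i + scanner_center(i) + eps
    pancreas_ij =              patient_i + scanner_center(i) + eps'

The patient and scanner components are shared between the two ROIs of the
same patient, which is exactly what the spatial delta-radiomics subtraction
exploits, while the scanner component carries the per-center location/scale
batch effect that ComBat estimates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CohortProfile",
    "NuisanceModel",
    "PhantomSpec",
    "default_profile",
    "generate_cohort",
    "generate_feature_table",
    "generate_phantom",
    "attach_outcomes",
    "DEFAULT_FEATURE_NAMES",
    "DEFAULT_EFFECT_SPEC",
]


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class CohortProfile:
    """Marginal description of a two-center surgical PNET cohort.

    Counts are reproduced *exactly* by the generator (sampling without
    replacement); continuous variables are drawn from quantile-matched
    distributions, with the cohort Ki-67 median pinned exactly by a final
    monotone rescale.
    """

    n_patients: int = 44
    center_split: tuple[float, float] = (0.5, 0.5)
    #: patients with G1/G2/G3 at biopsy; grade_missing_count patients have no
    #: usable biopsy grade (the counts need not cover the whole cohort)
    grade_counts: tuple[int, int, int] = (24, 15, 4)
    grade_missing_count: int = 1
    ki67_missing_count: int = 5
    #: per-grade (median %, log-scale sd) of the biopsy Ki-67 index
    ki67_by_grade: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (2.0, 0.6), 2: (8.0, 0.5), 3: (30.0, 0.4)}
    )
    ki67_median_pin: float = 4.0
    male_count: int = 25
    age_quantiles: tuple[float, float, float] = (62.0, 58.0, 68.0)  # median, q1, q3
    size_quantiles: tuple[float, float, float] = (2.7, 1.5, 4.6)  # cm
    functional_count: int = 6
    #: patient counts with 0, 1, 2, 3 metastatic organs at diagnosis
    metastatic_organ_dist: tuple[int, int, int, int] = (22, 12, 7, 3)
    progression_count: int = 16
    evaluable_n: int = 43
    mortality_count: int = 8
    followup_quantiles: tuple[float, float, float] = (38.0, 14.0, 59.0)  # months
    seed: int = 0

    def validate(self) -> None:
        if any(c < 0 for c in self.grade_counts) or self.grade_missing_count < 0:
            raise ValueError("grade_counts must be non-negative")
        if sum(self.grade_counts) + self.grade_missing_count != self.n_patients:
            raise ValueError(
                f"grade_counts sum to {sum(self.grade_counts)} "
                f"(+{self.grade_missing_count} missing), expected n_patients={self.n_patients}"
            )
        if not (0 <= self.ki67_missing_count <= self.n_patients):
            raise ValueError("ki67_missing_count out of range")
        if sum(self.metastatic_organ_dist) != self.n_patients:
            raise ValueError("metastatic_organ_dist must sum to n_patients")
        if not (0 <= self.progression_count <= self.evaluable_n <= self.n_patients):
            raise ValueError(
                "require 0 <= progression_count <= evaluable_n <= n_patients "
                f"(got {self.progression_count}, {self.evaluable_n}, {self.n_patients})"
            )
        if not (0 <= self.mortality_count <= self.evaluable_n):
            raise ValueError("mortality_count out of range")
        if not (0 <= self.functional_count <= self.n_patients):
            raise ValueError("functional_count out of range")
        if not (0 <= self.male_count <= self.n_patients):
            raise ValueError("male_count out of range")
        if abs(sum(self.center_split) - 1.0) > 1e-9:
            raise ValueError("center_split must sum to 1")


def default_profile(seed: int = 0) -> CohortProfile:
    """The published two-center cohort profile (n=44) with a chosen seed."""
    return dataclasses.replace(CohortProfile(), seed=seed)


@dataclass(frozen=True)
class NuisanceModel:
    """Variance components of the additive paired-ROI feature model.

    ``center_gamma``/``center_delta`` are the per-center additive shift and
    multiplicative scale applied to the scanner component — the batch
    location/scale effects that ComBat is meant to recover.  They map center
    label -> scalar (applied to every feature) or vector of length
    n_features.
    """

    sigma_bio: float = 1.0
    sigma_patient: float = 1.0
    sigma_scanner: float = 0.5
    sigma_eps: float = 0.3
    sigma_eps_prime: float = 0.3
    center_gamma: Mapping[str, float | np.ndarray] = field(
        default_factory=lambda: {"C1": 0.0, "C2": 0.0}
    )
    center_delta: Mapping[str, float | np.ndarray] = field(
        default_factory=lambda: {"C1": 1.0, "C2": 1.0}
    )

    def validate(self) -> None:
        for name in ("sigma_bio", "sigma_patient", "sigma_scanner", "sigma_eps", "sigma_eps_prime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for c, d in self.center_delta.items():
            if np.any(np.asarray(d) <= 0):
                raise ValueError(f"center_delta[{c!r}] must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric CT-like phantom: two ellipsoidal ROIs in an HU-valued volume."""

    volume_shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)  # mm per array axis
    lesion_center: tuple[float, float, float] = (20.0, 32.0, 32.0)  # mm
    lesion_semiaxes: tuple[float, float, float] = (8.0, 8.0, 8.0)  # mm
    pancreas_center: tuple[float, float, float] = (45.0, 32.0, 32.0)
    pancreas_semiaxes: tuple[float, float, float] = (10.0, 8.0, 8.0)
    lesion_base_hu: float = 110.0
    lesion_heterogeneity: float = 0.0  # HU amplitude of the smoothed random field
    lesion_corr_length: float = 3.0  # mm
    pancreas_base_hu: float = 80.0
    pancreas_heterogeneity: float = 0.0
    pancreas_corr_length: float = 3.0
    background_hu: float = -50.0
    scanner_offset_hu: float = 0.0
    noise_sd_hu: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")
        if any(a <= 0 for a in self.lesion_semiaxes + self.pancreas_semiaxes):
            raise ValueError("ellipsoid semi-axes must be > 0")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")


# ---------------------------------------------------------------------------
# continuous samplers


def _lognormal_from_quantiles(rng, median, q1, q3, size):
    # log-scale sd from the IQR of a lognormal: (log q3 - log q1) / (2 * z_{0.75})
    sigma = (np.log(q3) - np.log(q1)) / (2 * 0.6744897501960817)
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def _normal_from_quantiles(rng, median, q1, q3, size):
    sigma = (q3 - q1) / (2 * 0.6744897501960817)
    return rng.normal(median, sigma, size=size)


def _exact_count_assign(rng, n: int, counts: Sequence[int]) -> np.ndarray:
    """Assign category labels 0..k-1 with exact counts, in random order."""
    labels = np.repeat(np.arange(len(counts)), counts)
    return rng.permutation(labels)


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(profile: CohortProfile) -> pd.DataFrame:
    """Generate one synthetic cohort table honouring the profile's marginals.

    Category counts (grade, sex, functional status, metastatic-organ
    distribution, progression/mortality events) are matched exactly for any
    seed; Ki-67 is drawn log-normally per grade and then monotonically
    rescaled so the cohort median equals ``ki67_median_pin``.  When
    ``evaluable_n == n_patients - 1`` exactly one randomly chosen patient has
    missing progression/mortality status.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    n = profile.n_patients

    center_counts = [int(round(profile.center_split[0] * n))]
    center_counts.append(n - center_counts[0])
    center = np.where(_exact_count_assign(rng, n, center_counts) == 0, "C1", "C2")

    grade_lbl = _exact_count_assign(
        rng, n, tuple(profile.grade_counts) + (profile.grade_missing_count,)
    )
    grade = np.where(grade_lbl == 3, np.nan, grade_lbl + 1.0)

    # Ki-67 is drawn from the grade-conditional distribution; patients with a
    # missing biopsy grade draw from a latent grade sampled by the grade mix
    latent = grade_lbl.copy()
    miss_g = latent == 3
    if miss_g.any():
        probs = np.asarray(profile.grade_counts, float)
        probs = probs / probs.sum()
        latent[miss_g] = rng.choice(3, size=int(miss_g.sum()), p=probs)
    ki67 = np.empty(n)
    for g, (med, sd) in profile.ki67_by_grade.items():
        idx = latent == (g - 1)
        ki67[idx] = np.exp(rng.normal(np.log(med), sd, size=int(idx.sum())))
    if profile.ki67_missing_count > 0:
        ki67[rng.choice(n, size=profile.ki67_missing_count, replace=False)] = np.nan
    med = np.nanmedian(ki67)
    if med > 0:
        ki67 = ki67 * (profile.ki67_median_pin / med)  # monotone pin of the observed median
    ki67 = np.clip(ki67, 0.1, 99.0)

    sex = np.where(
        _exact_count_assign(rng, n, [profile.male_count, n - profile.male_count]) == 0, "M", "F"
    )
    age = np.clip(_normal_from_quantiles(rng, *profile.age_quantiles, n), 20, 95)
    size_cm = _lognormal_from_quantiles(rng, *profile.size_quantiles, n)
    functional = _exact_count_assign(
        rng, n, [n - profile.functional_count, profile.functional_count]
    )
    n_met = _exact_count_assign(rng, n, profile.metastatic_organ_dist)

    evaluable = np.ones(n, dtype=bool)
    n_missing = n - profile.evaluable_n
    if n_missing > 0:
        evaluable[rng.choice(n, size=n_missing, replace=False)] = False

    event = np.full(n, np.nan)
    death = np.full(n, np.nan)
    ev_idx = np.flatnonzero(evaluable)
    event[ev_idx] = _exact_count_assign(
        rng, len(ev_idx), [len(ev_idx) - profile.progression_count, profile.progression_count]
    )
    death[ev_idx] = _exact_count_assign(
        rng, len(ev_idx), [len(ev_idx) - profile.mortality_count, profile.mortality_count]
    )

    time_months = _lognormal_from_quantiles(rng, *profile.followup_quantiles, n)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "center": center,
            "age": age,
            "sex": sex,
            "grade": grade,
            "ki67": ki67,
            "size_cm": size_cm,
            "functional": functional,
            "n_met_organs": n_met,
            "evaluable": evaluable,
            "event": event,
            "death": death,
            "time_months": time_months,
        }
    )


# ---------------------------------------------------------------------------
# paired-ROI feature tables

DEFAULT_FEATURE_NAMES: tuple[str, ...] = (
    "firstorder_Entropy",
    "firstorder_Median",
    "firstorder_Mean",
    "firstorder_Energy",
    "firstorder_TotalEnergy",
    "firstorder_Range",
    "glcm_Idmn",
    "glcm_Contrast",
    "glrlm_RunLengthNonUniformity",
    "glszm_SmallAreaHighGrayLevelEmphasis",
    "glszm_SizeZoneNonUniformity",
    "glszm_LargeAreaEmphasis",
    "gldm_DependenceNonUniformity",
    "ngtdm_Busyness",
    "ngtdm_Coarseness",
    "shape_SurfaceVolumeRatio",
    "shape_Sphericity",
    "shape_MajorAxisLength",
    "shape_Flatness",
    "shape_Maximum3DDiameter",
)

#: coefficient of each feature on the latent aggressiveness score
DEFAULT_EFFECT_SPEC: Mapping[str, float] = {
    "firstorder_Entropy": 0.8,
    "firstorder_Energy": 0.5,
    "firstorder_Median": 0.6,
    "firstorder_Range": 0.4,
    "ngtdm_Busyness": 0.8,
    "glszm_SizeZoneNonUniformity": 0.5,
    "glszm_SmallAreaHighGrayLevelEmphasis": 0.4,
    "gldm_DependenceNonUniformity": 0.3,
    "shape_SurfaceVolumeRatio": 0.4,
    "shape_Sphericity": -0.4,
    "shape_MajorAxisLength": 0.5,
    "shape_Maximum3DDiameter": 0.5,
    "shape_Flatness": -0.3,
}


#: common-mode baseline level per feature, added to both ROIs; keeps features
#: that enter nonlinear transforms (log(Energy + 1), 1 - Sphericity) on a
#: plausible scale.  Cancels exactly in the lesion-minus-pancreas delta.
DEFAULT_FEATURE_BASELINES: Mapping[str, float] = {
    "firstorder_Entropy": 4.0,
    "firstorder_Median": 80.0,
    "firstorder_Mean": 80.0,
    "firstorder_Energy": 50.0,
    "firstorder_TotalEnergy": 50.0,
    "firstorder_Range": 12.0,
    "ngtdm_Busyness": 5.0,
    "ngtdm_Coarseness": 5.0,
    "shape_SurfaceVolumeRatio": 5.0,
    "shape_Sphericity": 0.7,
    "shape_MajorAxisLength": 30.0,
    "shape_Flatness": 0.6,
    "shape_Maximum3DDiameter": 35.0,
    "glszm_SizeZoneNonUniformity": 20.0,
    "glszm_SmallAreaHighGrayLevelEmphasis": 10.0,
    "glszm_LargeAreaEmphasis": 10.0,
    "gldm_DependenceNonUniformity": 20.0,
    "glcm_Idmn": 1.0,
    "glcm_Contrast": 5.0,
    "glrlm_RunLengthNonUniformity": 20.0,
}


def biology_score(cohort: pd.DataFrame) -> np.ndarray:
    """Latent tumor-aggressiveness score: standardized blend of log Ki-67 and grade.

    Missing clinical values (allowed in the cohort table) are imputed with the
    observed median — the latent biology exists even when the biopsy value was
    not recorded.
    """
    lk = np.log(cohort["ki67"].to_numpy(float))
    lk = np.where(np.isnan(lk), np.nanmedian(lk), lk)
    lk = (lk - lk.mean()) / (lk.std() if lk.std() > 0 else 1.0)
    g = cohort["grade"].to_numpy(float)
    g = np.where(np.isnan(g), np.nanmedian(g), g)
    g = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
    s = 0.7 * lk + 0.3 * g
    return (s - s.mean()) / (s.std() if s.std() > 0 else 1.0)


def _center_param(mapping, center_labels, centers, n_features):
    out = np.zeros((len(center_labels), n_features))
    for c in centers:
        v = np.broadcast_to(np.asarray(mapping.get(c, 0.0), float), (n_features,))
        out[center_labels == c] = v
    return out


def generate_feature_table(
    cohort: pd.DataFrame,
    model: NuisanceModel,
    n_features: int | None = None,
    effect_spec: Mapping[str, float] | None = None,
    feature_names: Sequence[str] | None = None,
    feature_baselines: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a paired lesion/pancreas feature table under the additive model.

    Returns a tidy frame with one row per patient x ROI (``roi`` in
    ``{"lesion", "pancreas"}``), the patient's center, and one column per
    feature.  The biology component exists only in lesion rows; patient and
    scanner components are drawn once per patient x feature and shared by
    both ROIs, so the lesion-minus-pancreas difference cancels them exactly
    when the independent noise terms vanish.
    """
    model.validate()
    if feature_names is None:
        if n_features is None:
            feature_names = list(DEFAULT_FEATURE_NAMES)
            if feature_baselines is None:
                feature_baselines = DEFAULT_FEATURE_BASELINES
        else:
            if n_features < 1:
                raise ValueError("n_features must be >= 1")
            feature_names = [f"feat_{j:03d}" for j in range(n_features)]
    feature_names = list(feature_names)
    nf = len(feature_names)
    if effect_spec is None:
        effect_spec = {k: v for k, v in DEFAULT_EFFECT_SPEC.items() if k in feature_names}
    unknown = set(effect_spec) - set(feature_names)
    if unknown:
        raise ValueError(f"effect_spec names unknown features: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = len(cohort)
    beta = np.array([effect_spec.get(f, 0.0) for f in feature_names])
    bio_score = biology_score(cohort)

    bio = np.outer(bio_score, beta) + model.sigma_bio * rng.normal(size=(n, nf))
    patient = model.sigma_patient * rng.normal(size=(n, nf))
    centers = sorted(cohort["center"].unique())
    labels = cohort["center"].to_numpy()
    gamma = _center_param(model.center_gamma, labels, centers, nf)
    delta = _center_param(
        {c: model.center_delta.get(c, 1.0) for c in centers}, labels, centers, nf
    )
    scanner = gamma + delta * model.sigma_scanner * rng.normal(size=(n, nf))

    base = np.array([(feature_baselines or {}).get(f, 0.0) for f in feature_names])
    lesion = base + bio + patient + scanner + model.sigma_eps * rng.normal(size=(n, nf))
    pancreas = base + patient + scanner + model.sigma_eps_prime * rng.normal(size=(n, nf))

    frames = []
    for roi, vals in (("lesion", lesion), ("pancreas", pancreas)):
        df = pd.DataFrame(vals, columns=feature_names)
        df.insert(0, "patient_id", cohort["patient_id"].to_numpy())
        df.insert(1, "roi", roi)
        df.insert(2, "center", labels)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# phantoms


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm):
    grids = np.meshgrid(
        *[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semiaxes_mm))
    return d2 <= 1.0


def _textured_field(rng, shape, spacing, amplitude, corr_length_mm):
    if amplitude == 0:
        return np.zeros(shape)
    noise = rng.normal(size=shape)
    sigmas = [max(corr_length_mm / sp, 1e-6) for sp in spacing]
    smooth = ndimage.gaussian_filter(noise, sigmas)
    sd = smooth.std()
    return amplitude * smooth / (sd if sd > 0 else 1.0)


def generate_phantom(spec: PhantomSpec):
    """Build (volume, lesion_mask, pancreas_mask) for a geometric phantom.

    The volume carries HU-valued voxels: a uniform background, two
    ellipsoidal organs with optional smoothed-random-field texture, a
    common-mode scanner offset applied to the whole volume, and i.i.d.
    voxel noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.volume_shape, spec.spacing

    lesion = _ellipsoid_mask(shape, spacing, spec.lesion_center, spec.lesion_semiaxes)
    pancreas = _ellipsoid_mask(shape, spacing, spec.pancreas_center, spec.pancreas_semiaxes)
    if np.any(lesion & pancreas):
        raise ValueError("lesion and pancreas geometries overlap")

    vol = np.full(shape, spec.background_hu, dtype=float)
    vol[lesion] = spec.lesion_base_hu + _textured_field(
        rng, shape, spacing, spec.lesion_heterogeneity, spec.lesion_corr_length
    )[lesion]
    vol[pancreas] = spec.pancreas_base_hu + _textured_field(
        rng, shape, spacing, spec.pancreas_heterogeneity, spec.pancreas_corr_length
    )[pancreas]
    vol += spec.scanner_offset_hu
    if spec.noise_sd_hu > 0:
        vol += rng.normal(0, spec.noise_sd_hu, size=shape)
    return vol, lesion, pancreas


# ---------------------------------------------------------------------------
# outcomes


def attach_outcomes(
    cohort: pd.DataFrame,
    linear_predictor: np.ndarray,
    baseline_hazard: float = 0.01,
    censoring_window: float = 120.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replace outcomes with draws from an exponential proportional-hazards model.

    Event times are exponential with rate ``baseline_hazard * exp(lp)``;
    censoring is uniform on ``[0, censoring_window]`` (a zero window censors
    everyone at time 0).  Non-evaluable patients keep missing status.
    """
    lp = np.asarray(linear_predictor, float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear_predictor must be finite")
    if len(lp) != len(cohort):
        raise ValueError("linear_predictor length must match cohort")
    if censoring_window < 0:
        raise ValueError("censoring_window must be >= 0")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    rng = np.random.default_rng(seed)
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, censoring_window, size=len(lp)) if censoring_window > 0 else np.zeros(len(lp))
    out = cohort.copy()
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(float)
    out["time_months"] = time
    mask = out["evaluable"].to_numpy(bool) if "evaluable" in out else np.ones(len(lp), bool)
    new_event = np.where(mask, event, np.nan)
    out["event"] = new_event
    return out
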