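"""Synthetic MSA registry cohorts.

The real cohort lives in a government registry and cannot be distributed, so
this module generates surrogate cohorts whose per-subtype marginal
distributions match the published cohort characteristics: binary prevalences,
categorical proportions, ordinal mean +/- SD on the stated scales, age
mean +/- SD, and a male:female ratio per subtype. Items are sampled
independently given the subtype (only marginals are published); an optional
Gaussian-copula layer can induce rank correlation between graded items.

Ordinal items are drawn from a normal(mean, sd) truncated to
[lo - 0.5, hi + 0.5] and rounded to the nearest integer level, which gives a
closed-form probability for every level (used as a testing oracle).

Missingness: ``CohortSpec.missingness_rate`` is the probability that a case
has at least one missing modelled answer (the quantity the complete-case
exclusion step acts on). It is converted to a per-item rate
``q = 1 - (1 - rate)**(1/m)`` over the m modelled items and applied
independently per (case, item).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .registry import (
    ABSENCE,
    LABEL_COLUMN,
    PRESENCE,
    SUBTYPES,
    Cohort,
    form_schema,
    modelling_items,
    schema_by_id,
)

__all__ = [
    "BinarySpec",
    "OrdinalSpec",
    "CategoricalSpec",
    "SubtypeProfile",
    "CohortSpec",
    "DEFAULT_MISSINGNESS",
    "default_profiles",
    "ordinal_level_probs",
    "sample_ordinal",
    "generate_cohort",
]

#: the registry's complete-case exclusion pressure: 157 of 3377 cases dropped
DEFAULT_MISSINGNESS = 157.0 / 3377.0

#: modelled cohort sizes per subtype
DEFAULT_N = {"SND": 851, "SDS": 359, "OPCA": 2010}


@dataclass(frozen=True)
class BinarySpec:
    item_id: str
    p_presence: float

    def __post_init__(self):
        if not 0.0 <= self.p_presence <= 1.0:
            raise ValueError(f"{self.item_id}: p must be in [0,1]")


@dataclass(frozen=True)
class OrdinalSpec:
    item_id: str
    lo: int
    hi: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"{self.item_id}: lo must be <= hi")
        if not self.lo <= self.mean <= self.hi:
            raise ValueError(f"{self.item_id}: mean outside scale")
        if self.sd < 0:
            raise ValueError(f"{self.item_id}: sd must be >= 0")


@dataclass(frozen=True)
class CategoricalSpec:
    item_id: str
    levels: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        if len(self.levels) != len(self.probs):
            raise ValueError(f"{self.item_id}: levels/probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"{self.item_id}: probs must sum to 1")


@dataclass(frozen=True)
class SubtypeProfile:
    """Sampling distributions for one subtype."""

    label: str
    n_default: int
    age_mean: float
    age_sd: float
    p_male: float
    binary_specs: tuple[BinarySpec, ...]
    ordinal_specs: tuple[OrdinalSpec, ...]
    categorical_specs: tuple[CategoricalSpec, ...]

    def binary(self, item_id: str) -> BinarySpec:
        return next(s for s in self.binary_specs if s.item_id == item_id)

    def ordinal(self, item_id: str) -> OrdinalSpec:
        return next(s for s in self.ordinal_specs if s.item_id == item_id)

    def categorical(self, item_id: str) -> CategoricalSpec:
        return next(s for s in self.categorical_specs if s.item_id == item_id)


@dataclass
class CohortSpec:
    n: dict = field(default_factory=lambda: dict(DEFAULT_N))
    missingness_rate: float = DEFAULT_MISSINGNESS
    seed: int = 0
    copula_rho: float = 0.0  # rank correlation between graded items; 0 = off

    def __post_init__(self):
        if any(v < 0 for v in self.n.values()):
            raise ValueError("cohort sizes must be >= 0")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must be in [0,1)")


# --------------------------------------------------------------------------
# Published per-subtype marginals. Percentages are proportions of each
# subtype's registered denominator; male:female ratios r give p_male=r/(1+r);
# ordinals are mean +/- SD on the form's scale. Categorical rows whose
# printed proportions sum to 0.999-1.001 are renormalised.
# Order of tuples: (SND, SDS, OPCA).

_SEX_RATIO = (1.21, 0.41, 0.92)
_AGE = ((67.4, 9.7), (66.8, 10.6), (64.8, 9.3))

_BINARY_P = {
    "onset_ataxia": (0.073, 0.162, 0.906),
    "onset_parkinsonism": (0.876, 0.162, 0.077),
    "onset_autonomic": (0.064, 0.729, 0.041),
    "auto_head_up_tilt": (0.389, 0.822, 0.388),
    "auto_syncope": (0.186, 0.769, 0.128),
    "auto_urinary_disturbance": (0.520, 0.796, 0.398),
    "auto_urinary_incontinence": (0.214, 0.578, 0.246),
    "auto_erectile_dysfunction": (0.471, 0.692, 0.334),  # among males
    "auto_severe_constipation": (0.597, 0.687, 0.351),
    "oth_dementia": (0.142, 0.138, 0.101),
    "oth_hallucination": (0.041, 0.027, 0.011),
    "oth_aphasia": (0.010, 0.011, 0.009),
    "oth_apraxia": (0.018, 0.019, 0.008),
    "oth_agnosia": (0.010, 0.016, 0.008),
    "oth_alien_hand": (0.001, 0.005, 0.001),
    "oth_vertical_gaze_palsy": (0.074, 0.029, 0.033),
    "oth_nystagmus": (0.077, 0.064, 0.174),
    "oth_dysphagia": (0.356, 0.202, 0.232),
    "oth_dysarthria": (0.586, 0.515, 0.793),
    "oth_respiratory_failure": (0.196, 0.435, 0.157),
    "oth_babinski_reflex": (0.211, 0.207, 0.186),
    # CT/MRI performed-flags are not tabulated per subtype; high uniform
    # coverage is assumed for a hospital-registered cohort.
    "img_ct_examination": (0.95, 0.95, 0.95),
    "img_mri_examination": (0.90, 0.90, 0.90),
    "img_cerebellar_atrophy": (0.411, 0.578, 0.940),
    "img_brainstem_atrophy": (0.361, 0.459, 0.793),
    "img_hot_cross_bun": (0.211, 0.215, 0.479),
    "img_striatal_abnormality": (0.587, 0.117, 0.053),
    "img_third_ventricle": (0.072, 0.077, 0.067),
    "img_cerebral_atrophy": (0.130, 0.138, 0.070),
    "img_white_matter_lesion": (0.053, 0.064, 0.033),
}

# item_id -> (lo, hi, (mean, sd) x 3 subtypes)
_ORDINAL = {
    "neuro_walking_capacity": (1, 9, (5.7, 2.5), (5.0, 2.7), (4.8, 2.3)),
    "neuro_gait_parkinsonism": (1, 5, (3.3, 1.1), (2.4, 1.4), (1.9, 1.3)),
    "neuro_standing_capacity": (1, 8, (4.6, 2.3), (4.2, 2.4), (4.2, 2.0)),
    "neuro_bent_posture": (1, 5, (2.6, 1.0), (1.8, 0.9), (1.6, 0.9)),
    "neuro_posture_stability": (1, 5, (3.4, 1.2), (2.7, 1.5), (2.5, 1.5)),
    "neuro_finger_to_nose": (1, 5, (2.1, 1.1), (2.1, 0.9), (2.6, 0.8)),
    "neuro_knee_tibia": (1, 5, (2.2, 1.2), (2.2, 1.1), (2.9, 1.0)),
    "neuro_tremor_at_rest": (1, 5, (1.7, 0.9), (1.4, 0.7), (1.3, 0.6)),
    "neuro_rigidity": (1, 5, (3.0, 0.8), (2.0, 0.9), (1.7, 0.9)),
    "neuro_finger_taps": (1, 5, (2.9, 0.9), (2.1, 0.9), (2.0, 1.0)),
    "neuro_rising_from_chair": (1, 5, (3.5, 1.3), (2.8, 1.5), (2.9, 1.5)),
    "adl_eating": (1, 3, (1.5, 0.7), (1.4, 0.6), (1.3, 0.5)),
    "adl_bathing": (1, 3, (2.0, 0.7), (1.8, 0.8), (1.6, 0.7)),
    "adl_hygiene": (1, 3, (1.8, 0.7), (1.6, 0.7), (1.4, 0.6)),
    "adl_dressing": (1, 3, (1.8, 0.7), (1.6, 0.7), (1.4, 0.7)),
    "adl_toileting": (1, 3, (1.7, 0.7), (1.6, 0.7), (1.4, 0.2)),
    "adl_walking": (1, 4, (2.3, 1.0), (2.1, 1.0), (1.9, 1.0)),
    "adl_climbing_stairs": (1, 3, (2.3, 0.8), (2.1, 0.8), (2.0, 0.8)),
}

# item_id -> (levels, probs x 3 subtypes)
_CATEGORICAL = {
    "mode_of_onset": ((1, 2, 3),
                      (0.934, 0.063, 0.003),
                      (0.883, 0.103, 0.013),
                      (0.958, 0.040, 0.002)),
    "progression": ((1, 2, 3, 4),
                    (0.991, 0.009, 0.0, 0.0),
                    (0.979, 0.013, 0.005, 0.002),
                    (0.991, 0.005, 0.002, 0.002)),
    "oth_tendon_reflex": ((1, 2, 3),
                          (0.406, 0.091, 0.503),
                          (0.353, 0.133, 0.515),
                          (0.457, 0.084, 0.459)),
    "med_taltirelin": ((1, 2, 3),
                       (0.879, 0.084, 0.037),
                       (0.838, 0.127, 0.035),
                       (0.628, 0.357, 0.015)),
    "med_protirelin": ((1, 2, 3),
                       (0.922, 0.028, 0.050),
                       (0.920, 0.061, 0.045),
                       (0.858, 0.109, 0.033)),
    "med_levodopa": ((1, 2, 3),
                     (0.126, 0.867, 0.007),
                     (0.682, 0.289, 0.029),
                     (0.832, 0.137, 0.031)),
    "med_dopamine_agonist": ((1, 2, 3),
                             (0.555, 0.405, 0.040),
                             (0.843, 0.111, 0.045),
                             (0.926, 0.041, 0.033)),
    "med_amantadine": ((1, 2, 3),
                       (0.709, 0.248, 0.043),
                       (0.889, 0.069, 0.042),
                       (0.919, 0.044, 0.037)),
    "med_anticholinergic": ((1, 2, 3),
                            (0.867, 0.088, 0.045),
                            (0.905, 0.045, 0.050),
                            (0.950, 0.012, 0.038)),
    "med_maob_inhibitor": ((1, 2, 3),
                           (0.836, 0.121, 0.044),
                           (0.920, 0.029, 0.050),
                           (0.950, 0.012, 0.038)),
    "med_droxidopa": ((1, 2, 3),
                      (0.775, 0.180, 0.045),
                      (0.592, 0.377, 0.032),
                      (0.930, 0.031, 0.039)),
}


def default_profiles() -> dict[str, SubtypeProfile]:
    """The three subtype profiles parameterised from the published cohort."""
    out = {}
    for i, label in enumerate(SUBTYPES):
        r = _SEX_RATIO[i]
        binaries = tuple(BinarySpec(item, p[i]) for item, p in _BINARY_P.items())
        ordinals = tuple(
            OrdinalSpec(item, lo, hi, *msd[i])
            for item, (lo, hi, *msd) in _ORDINAL.items())
        cats = []
        for item, (levels, *probs) in _CATEGORICAL.items():
            p = np.asarray(probs[i], dtype=float)
            p = p / p.sum()
            cats.append(CategoricalSpec(item, levels, tuple(p)))
        out[label] = SubtypeProfile(
            label=label, n_default=DEFAULT_N[label],
            age_mean=_AGE[i][0], age_sd=_AGE[i][1], p_male=r / (1.0 + r),
            binary_specs=binaries, ordinal_specs=ordinals,
            categorical_specs=tuple(cats))
    return out


def ordinal_level_probs(spec: OrdinalSpec) -> np.ndarray:
    """Exact level probabilities of the rounded truncated-normal law.

    Level j gets the normal mass of (j-0.5, j+0.5] renormalised over the
    truncation window [lo-0.5, hi+0.5]. With sd == 0 the law is a point mass
    at the nearest in-range level.
    """
    levels = np.arange(spec.lo, spec.hi + 1)
    if spec.lo == spec.hi:
        return np.array([1.0])
    if spec.sd < 1e-12:  # numerically a point mass
        p = np.zeros(len(levels))
        p[np.clip(int(round(spec.mean)), spec.lo, spec.hi) - spec.lo] = 1.0
        return p
    edges = np.arange(spec.lo, spec.hi + 2) - 0.5
    cdf = norm.cdf(edges, loc=spec.mean, scale=spec.sd)
    p = np.diff(cdf)
    return p / p.sum()


def ordinal_exact_mean(spec: OrdinalSpec) -> float:
    levels = np.arange(spec.lo, spec.hi + 1)
    return float(levels @ ordinal_level_probs(spec))


def sample_ordinal(spec: OrdinalSpec, rng: np.random.Generator,
                   size: int | None = None,
                   u: np.ndarray | None = None) -> np.ndarray | int:
    """Draw integer levels from the rounded truncated-normal law.

    ``u`` optionally supplies uniforms (for the copula layer); otherwise they
    come from ``rng``. Sampling is by inverse CDF over the exact level
    probabilities, so the draw matches :func:`ordinal_level_probs` exactly.
    """
    scalar = size is None and u is None
    if u is None:
        u = rng.random(1 if size is None else size)
    p = ordinal_level_probs(spec)
    cum = np.cumsum(p)
    idx = np.searchsorted(cum, np.asarray(u), side="right")
    idx = np.clip(idx, 0, len(p) - 1)
    levels = (spec.lo + idx).astype(np.int64)
    return int(levels[0]) if scalar else levels


def _sample_subtype(profile: SubtypeProfile, n: int, rng: np.random.Generator,
                    copula_rho: float) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    male = rng.random(n) < profile.p_male
    cols["sex"] = np.where(male, 1, 2)
    age = rng.normal(profile.age_mean, profile.age_sd, size=n)
    cols["age"] = np.clip(np.round(age), 30, 100)  # adult-onset disease

    for spec in profile.binary_specs:
        present = rng.random(n) < spec.p_presence
        code = np.where(present, PRESENCE, ABSENCE)
        if spec.item_id == "auto_erectile_dysfunction":
            cols[spec.item_id] = np.where(male, code, np.nan)  # structural
        else:
            cols[spec.item_id] = code

    # graded items, optionally rank-correlated through a Gaussian copula
    ord_specs = list(profile.ordinal_specs)
    if copula_rho > 0.0 and len(ord_specs) > 1:
        k = len(ord_specs)
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(copula_rho) * shared + np.sqrt(1 - copula_rho) * \
            rng.standard_normal((n, k))
        u = norm.cdf(z)
        for j, spec in enumerate(ord_specs):
            cols[spec.item_id] = sample_ordinal(spec, rng, u=u[:, j])
    else:
        for spec in ord_specs:
            cols[spec.item_id] = sample_ordinal(spec, rng, size=n)

    for spec in profile.categorical_specs:
        cols[spec.item_id] = rng.choice(spec.levels, size=n, p=spec.probs)

    cols["oth_other_findings"] = np.full(n, np.nan)  # free text unused
    cols[LABEL_COLUMN] = np.full(n, profile.label, dtype=object)
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec,
                    profiles: dict[str, SubtypeProfile] | None = None
                    ) -> Cohort:
    """Sample a cohort with the requested per-subtype sizes.

    Reproducible given ``spec.seed``. Row order is a seeded shuffle of the
    concatenated subtype arms; case_ids encode the subtype.
    """
    profiles = default_profiles() if profiles is None else profiles
    unknown = set(spec.n) - set(profiles)
    if unknown:
        raise KeyError(f"unknown subtype keys in cohort sizes: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    frames = []
    for label in SUBTYPES:
        n = int(spec.n.get(label, 0))
        if n == 0:
            continue
        df = _sample_subtype(profiles[label], n, rng, spec.copula_rho)
        df.insert(0, "case_id", [f"{label}-{i:05d}" for i in range(n)])
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)

    if spec.missingness_rate > 0.0:
        req = modelling_items()
        by_id = schema_by_id()
        m = len(req)
        q = 1.0 - (1.0 - spec.missingness_rate) ** (1.0 / m)
        female = df["sex"].to_numpy() == 2
        for it in req:
            knock = rng.random(len(df)) < q
            if it.male_only:
                knock &= ~female
            col = df[it.item_id].to_numpy(dtype=float)
            col[knock] = np.nan
            df[it.item_id] = col

    # order columns in form order
    ordered = ["case_id"] + [it.item_id for it in form_schema()
                             if not it.is_label] + [LABEL_COLUMN]
    return Cohort(df[ordered], provenance="synthetic", seed=spec.seed)
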