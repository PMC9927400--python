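"""Synthetic study generator: clinical covariates, outcome labels, phantom CT.

Covariate marginals follow the pooled cohort table of the modeled study
(n = 479); the outcome model is logistic in CA19-9 and lobe location with
coefficients equal to the log of the published multivariate odds ratios, and
an intercept calibrated numerically to the published non-CR prevalence
(100/479). Phantom image pairs are ellipsoidal nodules / ablation zones over
a lung background, textured with Gaussian random fields of exponential
covariance; for non-CR lesions (and a non-"none" texture preset) the ablation
zone gains an off-center hyperdense remnant and a longer texture correlation
length, which shifts co-occurrence and run-length statistics by a preset-
dependent amount.
"""

from __future__ import annotations

import hashlib
import json
import math
from functools import lru_cache
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .preprocess import Volume3D

N_LESIONS_DEFAULT = 479
TARGET_PREVALENCE = 100 / 479  # non-CR

#: pooled-cohort marginals (counts out of 479, means +/- SD)
DEFAULT_MARGINALS: dict[str, object] = {
    "gender": {"male": 269 / 479, "female": 210 / 479},
    "age": {"mean": 57.9, "sd": 10.3},
    "cea": {"mean": 4.6, "sd": 4.1, "truncate_at": 0.0},
    "ca19_9": {"mean": 10.8, "sd": 6.2, "truncate_at": 0.0},
    "nodule_size_cat": {"<10": 227 / 479, "10-19": 178 / 479, "20-30": 74 / 479},
    "location": {
        "RUL": 112 / 479,
        "RML": 52 / 479,
        "RLL": 88 / 479,
        "LUL": 108 / 479,
        "LLL": 119 / 479,
    },
    "distance1": {">1cm": 399 / 479, "<1cm": 80 / 479},
    "distance2": {">1cm": 192 / 479, "<1cm": 287 / 479},
    "pneumothorax": {"yes": 115 / 479, "no": 364 / 479},
    "iah": {"yes": 124 / 479, "no": 355 / 479},
}

#: published multivariate odds ratios for the non-CR event, as log-odds
DEFAULT_LOG_ODDS: dict[str, float] = {
    "ca19_9": math.log(1.007),  # per U/ml
    "location:RLL": math.log(2.997),
    "location:LLL": math.log(2.498),
}

_TEXTURE_PRESETS = {
    # (corr-length multiplier inside non-CR ablation zone, remnant amplitude HU)
    "none": (1.0, 0.0),
    "weak": (1.6, 60.0),
    "strong": (2.8, 150.0),
}

CLINICAL_COLUMNS = (
    "gender",
    "age",
    "cea",
    "ca19_9",
    "nodule_size_cat",
    "location",
    "distance1",
    "distance2",
    "pneumothorax",
    "iah",
)


@dataclass
class GeneratorConfig:
    n_lesions: int = N_LESIONS_DEFAULT
    seed: int = 0
    covariate_marginals: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    log_odds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_ODDS))
    intercept: float | None = None  # None -> calibrated to target_prevalence
    target_prevalence: float = TARGET_PREVALENCE
    image_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.25, 0.7, 0.7)  # (z, y, x)
    texture_signal: str = "strong"
    effect_scale: float = 1.0
    lesions_per_patient: int = 1

    def __post_init__(self) -> None:
        if self.n_lesions < 10:
            raise ValueError("n_lesions must be >= 10")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.texture_signal not in _TEXTURE_PRESETS:
            raise ValueError(f"unknown texture preset {self.texture_signal!r}")
        if any(s < 32 for s in self.image_shape):
            raise ValueError("image_shape must be >= 32 per axis")

    def hash(self) -> str:
        payload = {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in self.__dict__.items()
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ClinicalRecord:
    gender: str
    age: float
    cea: float
    ca19_9: float
    nodule_size_cat: str
    location: str
    distance1: str
    distance2: str
    pneumothorax: bool
    iah: bool

    def as_dict(self) -> dict[str, object]:
        return {k: getattr(self, k) for k in CLINICAL_COLUMNS}


@dataclass
class LesionCase:
    lesion_id: str
    patient_id: str
    pre_volume: Volume3D
    pre_mask: Volume3D
    post_volume: Volume3D
    post_mask: Volume3D
    clinical: ClinicalRecord
    label: str  # "CR" | "nonCR"

    def __post_init__(self) -> None:
        if self.label not in ("CR", "nonCR"):
            raise ValueError("label must be CR or nonCR")
        for phase in ("pre", "post"):
            vol = getattr(self, f"{phase}_volume")
            msk = getattr(self, f"{phase}_mask")
            if vol.intensities.shape != msk.intensities.shape:
                raise ValueError(f"{phase} volume/mask shape mismatch")
            if not (msk.intensities > 0).any():
                raise ValueError(f"{phase} mask is empty")


# ---------------------------------------------------------------------------
# clinical covariates and outcome
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _trunc_normal_loc(target_mean: float, sd: float, lower: float) -> float:
    """Location parameter so the lower-truncated normal has the target mean."""
    if sd <= 0:
        return target_mean

    def shifted_mean(loc: float) -> float:
        a = (lower - loc) / sd
        return truncnorm.mean(a, np.inf, loc=loc, scale=sd) - target_mean

    return brentq(shifted_mean, target_mean - 6 * sd, target_mean + sd)


def _sample_trunc_normal(params: Mapping[str, float], rng: np.random.Generator) -> float:
    mean, sd = float(params["mean"]), float(params["sd"])
    lower = float(params.get("truncate_at", -np.inf))
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return mean
    if not np.isfinite(lower):
        return float(rng.normal(mean, sd))
    loc = _trunc_normal_loc(mean, sd, lower)
    # rejection sampling (acceptance is high for mild truncation)
    for _ in range(100):
        v = loc + sd * rng.standard_normal()
        if v >= lower:
            return float(v)
    a = (lower - loc) / sd
    return float(truncnorm.ppf(rng.uniform(), a, np.inf, loc=loc, scale=sd))


def _sample_categorical(levels: Mapping[str, float], rng: np.random.Generator) -> str:
    names = list(levels)
    probs = np.asarray([levels[k] for k in names], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("invalid categorical marginal")
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def sample_clinical(config: GeneratorConfig, rng: np.random.Generator) -> ClinicalRecord:
    """Draw one covariate vector from the configured marginals (independently)."""
    m = config.covariate_marginals
    age_params = m["age"]
    age = (
        float(age_params["mean"])
        if age_params["sd"] == 0
        else float(rng.normal(age_params["mean"], age_params["sd"]))
    )
    return ClinicalRecord(
        gender=_sample_categorical(m["gender"], rng),
        age=age,
        cea=_sample_trunc_normal(m["cea"], rng),
        ca19_9=_sample_trunc_normal(m["ca19_9"], rng),
        nodule_size_cat=_sample_categorical(m["nodule_size_cat"], rng),
        location=_sample_categorical(m["location"], rng),
        distance1=_sample_categorical(m["distance1"], rng),
        distance2=_sample_categorical(m["distance2"], rng),
        pneumothorax=_sample_categorical(m["pneumothorax"], rng) == "yes",
        iah=_sample_categorical(m["iah"], rng) == "yes",
    )


def _linear_predictor(record: ClinicalRecord, config: GeneratorConfig) -> float:
    s = 0.0
    for key, coef in config.log_odds.items():
        if ":" in key:
            name, level = key.split(":", 1)
            value = 1.0 if getattr(record, name) == level else 0.0
        else:
            value = float(getattr(record, key))
        s += coef * value
    return config.effect_scale * s


def _linear_predictor_samples(
    config: GeneratorConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draws of the linear predictor over the covariate distribution."""
    m = config.covariate_marginals
    total = np.zeros(n)
    by_var: dict[str, list[tuple[str, float]]] = {}
    for key, coef in config.log_odds.items():
        if ":" in key:
            name, level = key.split(":", 1)
            by_var.setdefault(name, []).append((level, coef))
        else:
            by_var.setdefault(key, []).append((None, coef))
    for name, terms in by_var.items():
        params = m[name]
        if terms[0][0] is None:
            mean, sd = float(params["mean"]), float(params["sd"])
            lower = float(params.get("truncate_at", -np.inf))
            if sd == 0:
                vals = np.full(n, mean)
            elif np.isfinite(lower):
                loc = _trunc_normal_loc(mean, sd, lower)
                a = (lower - loc) / sd
                vals = truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=n, random_state=rng)
            else:
                vals = rng.normal(mean, sd, size=n)
            total += terms[0][1] * vals
        else:
            levels = list(params)
            probs = np.asarray([params[k] for k in levels], dtype=float)
            probs /= probs.sum()
            draws = rng.choice(len(levels), size=n, p=probs)
            for level, coef in terms:
                total += coef * (draws == levels.index(level))
    return config.effect_scale * total


def calibrate_intercept(config: GeneratorConfig, n_calib: int = 100000) -> float:
    """Bisection on the intercept so marginal P(nonCR) hits the target."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA11B]))
    s = _linear_predictor_samples(config, n_calib, rng)
    target = config.target_prevalence

    def gap(b0: float) -> float:
        return float(expit(b0 + s).mean()) - target

    return float(brentq(gap, -30.0, 30.0, xtol=1e-10))


def resolve_intercept(config: GeneratorConfig) -> float:
    if config.intercept is not None:
        return float(config.intercept)
    return calibrate_intercept(config)


def noncr_probability(
    record: ClinicalRecord, config: GeneratorConfig, intercept: float | None = None
) -> float:
    b0 = resolve_intercept(config) if intercept is None else intercept
    return float(expit(b0 + _linear_predictor(record, config)))


def sample_outcome(
    record: ClinicalRecord,
    config: GeneratorConfig,
    rng: np.random.Generator,
    intercept: float | None = None,
) -> str:
    """Draw the CR/non-CR label from the logistic outcome model."""
    p = noncr_probability(record, config, intercept=intercept)
    return "nonCR" if rng.uniform() < p else "CR"


# ---------------------------------------------------------------------------
# phantom volumes
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _grf_spectrum(
    shape: tuple[int, int, int], spacing: tuple[float, float, float], length_mm: float
) -> np.ndarray:
    axes = [
        np.minimum(np.arange(n), n - np.arange(n)) * s for n, s in zip(shape, spacing)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    r = np.sqrt(zz**2 + yy**2 + xx**2)
    cov = np.exp(-r / length_mm)
    return np.clip(np.fft.fftn(cov).real, 0.0, None)


def _grf(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    length_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian random field with exponential covariance
    exp(-r / length_mm), synthesized spectrally (circulant embedding, clipped)."""
    spectrum = _grf_spectrum(tuple(shape), tuple(spacing), float(length_mm))
    noise = rng.standard_normal(shape)
    field = np.fft.ifftn(np.sqrt(spectrum) * np.fft.fftn(noise)).real
    field /= np.sqrt(np.prod(shape))
    sd = field.std()
    return field / sd if sd > 0 else field


_DIAMETER_RANGES = {"<10": (6.0, 9.5), "10-19": (10.0, 19.0), "20-30": (20.0, 30.0)}

LUNG_HU = -800.0
NODULE_HU = 20.0


def generate_phantom_pair(
    record: ClinicalRecord,
    label: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[Volume3D, Volume3D, Volume3D, Volume3D]:
    """Pre/post phantom volumes and masks for one lesion.

    Pre: ellipsoidal nodule of elevated HU with correlated texture over a
    noisy lung background. Post: concentric larger ablation zone with a
    GGO-like radial profile; non-CR lesions additionally get a remnant blob
    and longer texture correlation inside the zone when the preset is not
    "none".
    """
    shape = tuple(config.image_shape)
    spacing = tuple(config.spacing_mm)
    extent = np.asarray(shape) * np.asarray(spacing)
    lo_d, hi_d = _DIAMETER_RANGES[record.nodule_size_cat]
    diameter = float(rng.uniform(lo_d, hi_d))
    radius = diameter / 2.0
    if radius + 2.0 > extent.min() / 2.0:
        raise ValueError("nodule larger than grid")
    margin = float(min(5.0, extent.min() / 2.0 - radius - 2.0))
    zone_radius = radius + margin

    center = extent / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    axis_ratio = rng.uniform(0.75, 1.0, size=3)
    axis_ratio /= axis_ratio.max()

    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    deltas = (zz - center[0], yy - center[1], xx - center[2])
    # normalized ellipsoidal radius for nodule and zone
    r_nod = np.sqrt(sum((d / (radius * a)) ** 2 for d, a in zip(deltas, axis_ratio)))
    r_zone = np.sqrt(sum((d / (zone_radius * a)) ** 2 for d, a in zip(deltas, axis_ratio)))

    corr_mult, remnant_amp = _TEXTURE_PRESETS[config.texture_signal]
    is_noncr = label == "nonCR"

    bg = LUNG_HU + 40.0 * _grf(shape, spacing, 3.0, rng)
    nod_tex = 30.0 * _grf(shape, spacing, 1.5, rng)
    pre = np.where(r_nod <= 1.0, NODULE_HU + nod_tex, bg)
    pre_mask = (r_nod <= 1.0).astype(np.uint8)

    post_len = 2.0 * (corr_mult if is_noncr else 1.0)
    zone_tex = 70.0 * _grf(shape, spacing, post_len, rng)
    zone_profile = -450.0 + 300.0 * np.clip(1.0 - r_zone**2, 0.0, 1.0)
    post = np.where(r_zone <= 1.0, zone_profile + zone_tex, bg)
    if is_noncr and remnant_amp > 0:
        offset_dir = rng.standard_normal(3)
        offset_dir /= np.linalg.norm(offset_dir)
        rem_center = center + offset_dir * 0.35 * zone_radius
        rem_radius = max(2.0, 0.25 * zone_radius)
        r_rem = np.sqrt(
            (zz - rem_center[0]) ** 2 + (yy - rem_center[1]) ** 2 + (xx - rem_center[2]) ** 2
        )
        post = post + np.where(r_rem <= rem_radius, remnant_amp, 0.0)
    post_mask = (r_zone <= 1.0).astype(np.uint8)

    pre_v = Volume3D(pre, spacing)
    pre_m = Volume3D(pre_mask, spacing)
    post_v = Volume3D(post, spacing)
    post_m = Volume3D(post_mask, spacing)
    return pre_v, pre_m, post_v, post_m


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> tuple[list[LesionCase], dict]:
    """Generate ``n_lesions`` cases plus a manifest of per-case truth.

    Deterministic given (config, seed): per-case RNG streams are spawned from
    a single SeedSequence keyed by ``config.seed``.
    """
    intercept = resolve_intercept(config)
    root = np.random.SeedSequence(config.seed)
    case_seeds = root.spawn(config.n_lesions)
    cases: list[LesionCase] = []
    truth_rows: list[dict] = []
    for i, child in enumerate(case_seeds):
        rng = np.random.default_rng(child)
        record = sample_clinical(config, rng)
        label = sample_outcome(record, config, rng, intercept=intercept)
        pre_v, pre_m, post_v, post_m = generate_phantom_pair(record, label, config, rng)
        patient = f"P{i // max(config.lesions_per_patient, 1):04d}"
        lesion = f"L{i:04d}"
        cases.append(
            LesionCase(
                lesion_id=lesion,
                patient_id=patient,
                pre_volume=pre_v,
                pre_mask=pre_m,
                post_volume=post_v,
                post_mask=post_m,
                clinical=record,
                label=label,
            )
        )
        truth_rows.append(
            {
                "lesion_id": lesion,
                "patient_id": patient,
                "label": label,
                "p_noncr": noncr_probability(record, config, intercept=intercept),
                **record.as_dict(),
            }
        )
    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "n_lesions": config.n_lesions,
        "intercept": intercept,
        "texture_signal": config.texture_signal,
        "effect_scale": config.effect_scale,
        "cases": truth_rows,
    }
    return cases, manifest


def clinical_frame(cases: Iterable[LesionCase]) -> pd.DataFrame:
    """Cohort clinical table: one row per lesion plus the CR/non-CR label."""
    rows = []
    for case in cases:
        row = {"lesion_id": case.lesion_id, "patient_id": case.patient_id}
        row.update(case.clinical.as_dict())
        row["label"] = case.label
        rows.append(row)
    return pd.DataFrame(rows).set_index("lesion_id")


# ---------------------------------------------------------------------------
# cohort summary (percentages as printed in cohort tables)
# ---------------------------------------------------------------------------

def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Event percentage rounded as printed in cohort summary tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(np.round(100.0 * count / total, decimals))


def cohort_summary(clinical: pd.DataFrame) -> dict[str, dict[str, dict[str, float]]]:
    """Counts and percentages per categorical level, as printed in cohort characteristic tables."""
    total = len(clinical)
    out: dict[str, dict[str, dict[str, float]]] = {}
    for col in clinical.columns:
        if clinical[col].dtype.kind in "fi" and col not in ("pneumothorax", "iah"):
            continue
        counts = clinical[col].value_counts()
        out[col] = {
            str(level): {"count": int(c), "pct": percentage(int(c), total)}
            for level, c in counts.items()
        }
    return out
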