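"""Synthetic study-condition generators.

Three generators make the whole pipeline testable without clinical data:

* textured ellipsoidal tumour phantoms on noisy CT-like backgrounds, paired
  with their ground-truth binary masks;
* per-patient feature-realization tables with controllable between-patient
  (sigma_b) and intra-patient (sigma_w) spread, whose uncertainty-to-effect
  ratio is analytically sigma_w / sigma_b (the 1.349 normal-IQR factors
  cancel in the IQR/IQR estimator);
* proportional-hazards survival times with an exponential baseline and
  independent exponential censoring.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from segstress.errors import ValidationError
from segstress.uncertainty_stats import FeatureRealizations
from segstress.volumes_io import BinaryMask, ImageVolume, SurvivalRecord


@dataclass
class PhantomParams:
    """Ellipsoidal tumour phantom on a noisy background.

    Intensity defaults emulate a lung CT: air-ish background around
    -800 HU, soft-tissue tumour around 40 HU with correlated texture.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radius_mm: float = 10.0
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_mean_hu: float = 40.0
    texture_sd_hu: float = 30.0
    texture_corr_mm: float = 3.0
    background_mean_hu: float = -800.0
    background_sd_hu: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_sd_hu < 0 or self.background_sd_hu < 0:
            raise ValidationError("noise SDs must be >= 0")
        radii = np.asarray(self.axis_ratios) * self.radius_mm
        half_extent = np.asarray(self.grid_shape) * np.asarray(self.spacing) / 2
        if np.any(radii >= half_extent - 2.5):  # >= 2 tau margin at tau ~ 1.18
            raise ValidationError("tumor does not fit inside the grid with margin")


def _correlated_noise(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian field with correlation length ``corr_mm``."""
    white = rng.standard_normal(shape)
    if corr_mm <= 0:
        return white
    field_ = ndimage.gaussian_filter(white, sigma=[corr_mm / s for s in spacing])
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def make_phantom(p: PhantomParams) -> tuple[ImageVolume, BinaryMask]:
    """Textured ellipsoid tumour + mask, deterministic per seed."""
    rng = np.random.default_rng(p.seed)
    shape = tuple(p.grid_shape)
    centre = (np.asarray(shape) - 1) / 2 * np.asarray(p.spacing)
    radii = np.asarray(p.axis_ratios) * p.radius_mm
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, p.spacing)], indexing="ij"),
        axis=-1,
    )
    mask = ((coords - centre) / radii).__pow__(2).sum(axis=-1) <= 1.0
    img = p.background_mean_hu + p.background_sd_hu * rng.standard_normal(shape)
    texture = _correlated_noise(shape, p.spacing, p.texture_corr_mm, rng)
    img[mask] = p.tumor_mean_hu + p.texture_sd_hu * texture[mask]
    return (
        ImageVolume(voxels=img, spacing=p.spacing),
        BinaryMask(voxels=mask, spacing=p.spacing),
    )


# ---------------------------------------------------------------------------
# feature-realization tables


@dataclass
class FeatureSpec:
    """Gaussian additive feature: value = mean + b_i + w_ir."""

    name: str
    mean: float = 0.0
    sigma_between: float = 1.0
    sigma_within: float = 0.3


@dataclass
class SyntheticCohortParams:
    """Cohort of per-patient feature realizations plus survival generation."""

    n_patients: int = 200
    n_realizations: int = 301
    features: list[FeatureSpec] = field(
        default_factory=lambda: [FeatureSpec(name="feat_0")]
    )
    beta: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 1.0 / 500.0  # events per day
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must be in [0, 1)")
        if any(f.sigma_between < 0 or f.sigma_within < 0 for f in self.features):
            raise ValidationError("sigmas must be >= 0")


def make_feature_table(p: SyntheticCohortParams) -> FeatureRealizations:
    """value[i][r] = mean + b_i + w_ir with b ~ N(0, sigma_b^2) and
    w ~ N(0, sigma_w^2); realization 0 has w = 0 (the original mask)."""
    rng = np.random.default_rng(p.seed)
    pids = [f"P{i:04d}" for i in range(p.n_patients)]
    values = {}
    for spec in p.features:
        b = rng.normal(0.0, spec.sigma_between, size=p.n_patients)
        w = rng.normal(0.0, spec.sigma_within, size=(p.n_patients, p.n_realizations))
        w[:, 0] = 0.0
        values[spec.name] = spec.mean + b[:, None] + w
    return FeatureRealizations(patient_ids=pids, values=values)


def make_survival(
    features,  # pd.DataFrame patients x features (realization-0 "true" values)
    beta: dict[str, float],
    baseline_rate: float,
    censor_rate: float,
    rng: np.random.Generator,
) -> list[SurvivalRecord]:
    """Exponential proportional-hazards survival with independent
    exponential censoring tuned to censor roughly ``censor_rate`` of an
    average-risk patient's events."""
    lp = np.zeros(len(features))
    for name, b in beta.items():
        lp += b * features[name].to_numpy(dtype=float)
    rate = baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        c_rate = baseline_rate * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(features))
    else:
        t_cens = np.full(len(features), np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return [
        SurvivalRecord(patient_id=str(pid), time_days=float(t), event=bool(e))
        for pid, t, e in zip(features.index, time, event)
    ]


# ---------------------------------------------------------------------------
# the paired low-/high-noise study design


@dataclass
class ContrastCohort:
    """Training/testing cohorts carrying the same prognostic signal through
    a low-noise and a high-noise feature set."""

    train_fr: FeatureRealizations
    test_fr: FeatureRealizations
    train_survival: list[SurvivalRecord]
    test_survival: list[SurvivalRecord]
    low_features: list[str]
    high_features: list[str]


def make_contrast_cohort(
    n_train: int = 200,
    n_test: int = 150,
    n_realizations: int = 301,
    n_factors: int = 4,
    sigma_low: float = 0.05,
    sigma_high: float = 0.4,
    beta_per_factor: float = 0.2,
    baseline_rate: float = 1.0 / 500.0,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> ContrastCohort:
    """Paired low-/high-noise cohorts sharing identical prognostic signal.

    Each patient carries ``n_factors`` latent prognostic factors
    b_k ~ N(0, 1).  Feature ``low_k`` observes b_k with realization noise
    sigma_low (design eta ~ sigma_low); ``high_k`` observes the *same* b_k
    with noise sigma_high (design eta ~ sigma_high).  Survival depends only
    on the latent factors, so any performance difference between the two
    feature sets is attributable to contouring noise alone.

    ``beta_per_factor`` = 0.2 puts the original-mask test log-rank around
    p ~ 0.01 at the default cohort sizes — a significant but
    uncertainty-sensitive operating point.
    """
    rng = np.random.default_rng(seed)

    def build(n_patients: int, tag: str):
        b = rng.normal(0.0, 1.0, size=(n_patients, n_factors))
        pids = [f"{tag}{i:04d}" for i in range(n_patients)]
        values = {}
        for k in range(n_factors):
            for label, sigma in (("low", sigma_low), ("high", sigma_high)):
                w = rng.normal(0.0, sigma, size=(n_patients, n_realizations))
                w[:, 0] = 0.0
                values[f"{label}_{k}"] = b[:, [k]] + w
        fr = FeatureRealizations(patient_ids=pids, values=values)
        import pandas as pd

        latent = pd.DataFrame(
            {f"b_{k}": b[:, k] for k in range(n_factors)}, index=pids
        )
        surv = make_survival(
            latent,
            beta={f"b_{k}": beta_per_factor for k in range(n_factors)},
            baseline_rate=baseline_rate,
            censor_rate=censor_rate,
            rng=rng,
        )
        return fr, surv

    train_fr, train_surv = build(n_train, "TR")
    test_fr, test_surv = build(n_test, "TE")
    return ContrastCohort(
        train_fr=train_fr,
        test_fr=test_fr,
        train_survival=train_surv,
        test_survival=test_surv,
        low_features=[f"low_{k}" for k in range(n_factors)],
        high_features=[f"high_{k}" for k in range(n_factors)],
    )
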