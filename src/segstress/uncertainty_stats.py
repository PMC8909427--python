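"""Uncertainty-versus-effect statistics for image biomarkers.

Core quantities:

* Cohen's d — standardized mean difference between two patient groups with
  (n-1)-weighted variance pooling.
* Total intra-patient variance — sum of acquisition, segmentation and
  processing variance components plus twice their pairwise covariances.
* eta, the uncertainty-to-effect ratio.  In its general form eta is the
  expected intra-patient SD over the between-patient interquartile range.
  The segmentation-only estimator used throughout this package is
  internally consistent IQR-over-IQR: the median across patients of the
  within-patient IQR over mask realizations (uncertainty), divided by the
  IQR across patients of the within-patient medians (effect).  eta near 1
  means contouring noise is as large as the biological signal.
* delta, per-patient stratification agreement: (majority - minority) /
  total class counts over one patient's realization classifications.

Quantiles use linear interpolation (NumPy's default, "type 7").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from segstress.errors import UndefinedEffectError, ValidationError

logger = logging.getLogger(__name__)


def _iqr(x: np.ndarray, axis=None) -> np.ndarray:
    q1, q3 = np.quantile(x, [0.25, 0.75], axis=axis)
    return q3 - q1


# ---------------------------------------------------------------------------
# containers


@dataclass
class CohortGroup:
    """One biomarker observed across one population's patients."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("CohortGroup values must be 1D")


@dataclass
class VarianceComponents:
    """Protocol variance components and their pairwise covariances."""

    s2_acq: float = 0.0
    s2_seg: float = 0.0
    s2_proc: float = 0.0
    cov_acq_seg: float = 0.0
    cov_acq_proc: float = 0.0
    cov_seg_proc: float = 0.0

    def __post_init__(self) -> None:
        if min(self.s2_acq, self.s2_seg, self.s2_proc) < 0:
            raise ValidationError("variance components must be >= 0")


@dataclass
class FeatureRealizations:
    """Per-patient, per-mask-realization feature values.

    ``values[feature]`` is an (n_patients, n_realizations) array whose
    column 0 is the original (unperturbed) mask.
    """

    patient_ids: list[str]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != len(self.patient_ids):
                raise ValidationError(f"{name}: row count != number of patients")
            if np.isnan(arr).any():
                raise ValidationError(f"{name}: missing values not allowed")
            self.values[name] = arr

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_realizations(self) -> int:
        return next(iter(self.values.values())).shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.keys())

    def subset(self, features: Sequence[str]) -> "FeatureRealizations":
        return FeatureRealizations(
            patient_ids=list(self.patient_ids),
            values={f: self.values[f] for f in features},
        )

    def originals(self) -> pd.DataFrame:
        """Realization-0 values, patients x features."""
        return pd.DataFrame(
            {f: arr[:, 0] for f, arr in self.values.items()}, index=self.patient_ids
        )

    def to_long_df(self) -> pd.DataFrame:
        rows = []
        for fname, arr in self.values.items():
            for p, pid in enumerate(self.patient_ids):
                for r in range(arr.shape[1]):
                    rows.append((pid, r, fname, arr[p, r]))
        return pd.DataFrame(rows, columns=["patient_id", "realization_idx", "feature_name", "value"])

    @classmethod
    def from_long_df(cls, df: pd.DataFrame) -> "FeatureRealizations":
        required = {"patient_id", "realization_idx", "feature_name", "value"}
        if not required.issubset(df.columns):
            raise ValidationError(f"long feature table needs columns {sorted(required)}")
        pids = sorted(df["patient_id"].astype(str).unique())
        values = {}
        for fname, grp in df.groupby("feature_name"):
            wide = grp.pivot_table(
                index="patient_id", columns="realization_idx", values="value"
            ).reindex(pids)
            if wide.isna().any().any():
                raise ValidationError(f"{fname}: incomplete patient x realization grid")
            values[str(fname)] = wide.to_numpy()
        return cls(patient_ids=pids, values=values)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_df().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureRealizations":
        return cls.from_long_df(pd.read_csv(path, dtype={"patient_id": str}))


@dataclass
class EtaEstimate:
    """eta with its numerator (uncertainty) and denominator (effect)."""

    eta: float | None
    numerator_uncertainty: float
    denominator_effect: float
    defined: bool = True


@dataclass
class AgreementRecord:
    """Majority/minority class counts and delta for one patient."""

    patient_id: str
    n_majority: int
    n_minority: int
    delta: float


# ---------------------------------------------------------------------------
# statistics


def cohens_d(A: CohortGroup | Sequence[float], B: CohortGroup | Sequence[float]) -> float:
    """Standardized absolute mean difference with (n-1)-weighted pooled SD."""
    a = A.values if isinstance(A, CohortGroup) else np.asarray(A, dtype=float)
    b = B.values if isinstance(B, CohortGroup) else np.asarray(B, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValidationError("cohens_d needs at least two values per group")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise UndefinedEffectError("pooled variance is zero with unequal means")
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled_var))


def combine_variances(c: VarianceComponents) -> float:
    """Total intra-patient variance: component variances plus twice every
    pairwise covariance."""
    total = (
        c.s2_acq
        + c.s2_seg
        + c.s2_proc
        + 2 * c.cov_acq_seg
        + 2 * c.cov_acq_proc
        + 2 * c.cov_seg_proc
    )
    if total < 0:
        raise ValidationError(f"inconsistent covariances: total variance {total} < 0")
    return float(total)


def eta_general(expected_intrapat_sd: float, effect_iqr: float) -> float:
    """General uncertainty-to-effect ratio: E[s_intrapat] / between-patient
    IQR.  Note the numerator is an SD while the denominator is an IQR; the
    ratio is used as-is, without a 1.349 normal-consistency factor."""
    if effect_iqr <= 0:
        raise UndefinedEffectError("effect IQR must be > 0")
    if expected_intrapat_sd < 0:
        raise ValidationError("expected SD must be >= 0")
    return float(expected_intrapat_sd / effect_iqr)


def eta_segmentation(fr: FeatureRealizations, feature: str) -> EtaEstimate:
    """Segmentation-only eta for one feature.

    numerator: median over patients of the within-patient IQR across mask
    realizations (original included as realization 0);
    denominator: IQR over patients of the within-patient medians.
    A zero denominator yields a flagged undefined estimate, never a silent 0.
    """
    arr = fr.values[feature]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("eta needs >= 2 patients and >= 2 realizations")
    per_patient_iqr = _iqr(arr.T, axis=0)  # IQR across realizations, per patient
    numerator = float(np.median(per_patient_iqr))
    per_patient_median = np.median(arr, axis=1)
    denominator = float(_iqr(per_patient_median))
    if denominator == 0:
        return EtaEstimate(
            eta=None,
            numerator_uncertainty=numerator,
            denominator_effect=0.0,
            defined=False,
        )
    return EtaEstimate(
        eta=numerator / denominator,
        numerator_uncertainty=numerator,
        denominator_effect=denominator,
    )


def eta_table(fr: FeatureRealizations) -> pd.DataFrame:
    """eta per feature, ranked descending; undefined etas sort last."""
    rows = []
    for f in fr.feature_names:
        est = eta_segmentation(fr, f)
        rows.append(
            {
                "feature": f,
                "eta": est.eta if est.defined else np.nan,
                "numerator": est.numerator_uncertainty,
                "denominator": est.denominator_effect,
                "defined": est.defined,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["eta", "feature"], ascending=[False, True], na_position="last"
    )
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def rank_features(
    etas: Mapping[str, EtaEstimate], k: int
) -> tuple[list[str], list[str]]:
    """k lowest-eta and k highest-eta feature names.

    Undefined etas are excluded with a warning; ties break lexicographically
    by feature name.
    """
    defined = {f: e.eta for f, e in etas.items() if e.defined}
    dropped = set(etas) - set(defined)
    if dropped:
        warnings.warn(f"excluding features with undefined eta: {sorted(dropped)}")
    if len(defined) < 2 * k:
        raise ValidationError(
            f"need >= {2 * k} features with defined eta, have {len(defined)}"
        )
    by_low = sorted(defined.items(), key=lambda kv: (kv[1], kv[0]))
    by_high = sorted(defined.items(), key=lambda kv: (-kv[1], kv[0]))
    return [f for f, _ in by_low[:k]], [f for f, _ in by_high[:k]]


def agreement_delta(labels: Sequence, patient_id: str = "") -> AgreementRecord:
    """delta = (#majority - #minority) / (#majority + #minority) over one
    patient's realization class labels.  Binary-classification counts: the
    minority count is the total minus the majority count, so an exact tie
    gives delta = 0."""
    labels = list(labels)
    if not labels:
        raise ValidationError("agreement_delta needs at least one label")
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    n_majority = int(counts.max())
    n_minority = len(labels) - n_majority
    delta = (n_majority - n_minority) / len(labels)
    return AgreementRecord(
        patient_id=patient_id,
        n_majority=n_majority,
        n_minority=n_minority,
        delta=float(delta),
    )
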