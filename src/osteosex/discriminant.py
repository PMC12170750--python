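"""Two-group linear discriminant analysis with leave-one-out cross-validation.

The discriminant direction is w ∝ S_p⁻¹ (μ_male − μ_female) with S_p the
pooled within-group covariance (divisor n − 2). Coefficients are reported in
the "unstandardized" convention of the classical anthropometric literature:
w is rescaled so that the pooled within-group variance of the discriminant
scores equals 1, and the additive constant centres the case-weighted mean
score at zero, so the per-sex score centroids satisfy
n_f·c_f + n_m·c_m = 0. Classification uses equal priors: the threshold is
the midpoint of the two centroids, with scores above it classified male.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    FEMALE,
    MALE,
    ClassificationReport,
    StudyDataset,
    logger,
)


@dataclass(frozen=True)
class DiscriminantModel:
    """A fitted two-group linear discriminant function."""

    measurements: tuple[str, ...]
    coefficients: tuple[float, ...]
    constant: float
    centroid_female: float
    centroid_male: float
    threshold: float
    n_female: int
    n_male: int

    def __post_init__(self) -> None:
        if self.centroid_male <= self.centroid_female:
            raise ValueError("sign convention violated: male centroid must be higher")


def _complete_cases(
    dataset: StudyDataset, measurements: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-sex matrices of complete cases; returns (X_female, X_male, n_dropped)."""
    rows = {FEMALE: [], MALE: []}
    dropped = 0
    for rec in dataset:
        vals = [rec.value(m) for m in measurements]
        if any(v is None for v in vals):
            dropped += 1
            continue
        rows[rec.sex].append(vals)
    return (
        np.asarray(rows[FEMALE], dtype=float),
        np.asarray(rows[MALE], dtype=float),
        dropped,
    )


def _fit_from_matrices(
    xf: np.ndarray, xm: np.ndarray, measurements: Sequence[str]
) -> DiscriminantModel:
    nf, nm = xf.shape[0], xm.shape[0]
    p = len(measurements)
    mu_f = xf.mean(axis=0)
    mu_m = xm.mean(axis=0)
    # pooled within-group covariance, divisor n - 2
    sf = np.cov(xf, rowvar=False, ddof=1).reshape(p, p)
    sm = np.cov(xm, rowvar=False, ddof=1).reshape(p, p)
    sp = ((nf - 1) * sf + (nm - 1) * sm) / (nf + nm - 2)
    try:
        w = np.linalg.solve(sp, mu_m - mu_f)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular pooled within-group covariance; consider removing a measurement"
        ) from None
    within_var = float(w @ sp @ w)
    if within_var <= 0 or not math.isfinite(within_var):
        raise ValueError(
            "singular pooled within-group covariance; consider removing a measurement"
        )
    w = w / math.sqrt(within_var)  # pooled within-group score variance = 1
    grand_mean = (nf * mu_f + nm * mu_m) / (nf + nm)
    constant = -float(w @ grand_mean)
    c_f = float(w @ mu_f + constant)
    c_m = float(w @ mu_m + constant)
    # w'Sp^{-1}(mu_m - mu_f) > 0 guarantees c_m > c_f; assert the convention
    return DiscriminantModel(
        measurements=tuple(measurements),
        coefficients=tuple(float(c) for c in w),
        constant=constant,
        centroid_female=c_f,
        centroid_male=c_m,
        threshold=(c_f + c_m) / 2.0,
        n_female=nf,
        n_male=nm,
    )


def fit_lda(dataset: StudyDataset, measurements: Sequence[str]) -> DiscriminantModel:
    """Fit the discriminant function on the complete cases of ``dataset``.

    Records missing any selected measurement are dropped listwise (with a
    logged count). Requires at least two complete cases per sex and an
    invertible pooled covariance.
    """
    xf, xm, dropped = _complete_cases(dataset, measurements)
    if dropped:
        logger.info("fit_lda: %d incomplete case(s) dropped", dropped)
    if xf.shape[0] < 2 or xm.shape[0] < 2:
        raise ValueError("need at least 2 complete cases per sex")
    return _fit_from_matrices(xf, xm, measurements)


def _vector(model: DiscriminantModel, values) -> np.ndarray:
    if isinstance(values, Mapping):
        missing = [m for m in model.measurements if values.get(m) is None]
        if missing:
            raise ValueError(f"missing measurement(s): {', '.join(missing)}")
        return np.asarray([float(values[m]) for m in model.measurements])
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(model.measurements),):
        raise ValueError(
            f"expected {len(model.measurements)} values for {model.measurements}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite measurement value")
    return arr


def score(model: DiscriminantModel, values) -> float:
    """Discriminant score Y = Σ coefficient·value + constant."""
    x = _vector(model, values)
    return float(np.dot(model.coefficients, x) + model.constant)


def classify_lda(model: DiscriminantModel, values) -> str:
    """Classify one case: Y above the threshold → male, at or below → female."""
    return MALE if score(model, values) > model.threshold else FEMALE


def _classification_report(
    truths: list[str], predictions: list[str], n_excluded: int = 0
) -> ClassificationReport:
    correct = {FEMALE: 0, MALE: 0}
    totals = {FEMALE: 0, MALE: 0}
    for t, p in zip(truths, predictions):
        totals[t] += 1
        if t == p:
            correct[t] += 1
    for sex in (FEMALE, MALE):
        if totals[sex] == 0:
            raise ValueError(f"no usable {sex} cases")
    n_all = totals[FEMALE] + totals[MALE]
    return ClassificationReport(
        percent_correct_female=100.0 * correct[FEMALE] / totals[FEMALE],
        percent_correct_male=100.0 * correct[MALE] / totals[MALE],
        percent_correct_total=100.0 * (correct[FEMALE] + correct[MALE]) / n_all,
        n_female=totals[FEMALE],
        n_male=totals[MALE],
        n_excluded=n_excluded,
    )


def resubstitution(
    dataset: StudyDataset, measurements: Sequence[str]
) -> ClassificationReport:
    """Fit on all complete cases and classify those same cases ("original"
    accuracy in the discriminant-analysis reporting convention)."""
    model = fit_lda(dataset, measurements)
    xf, xm, dropped = _complete_cases(dataset, measurements)
    truths = [FEMALE] * xf.shape[0] + [MALE] * xm.shape[0]
    preds = [classify_lda(model, row) for row in np.vstack([xf, xm])]
    return _classification_report(truths, preds, n_excluded=dropped)


def loocv(dataset: StudyDataset, measurements: Sequence[str]) -> ClassificationReport:
    """Leave-one-out cross-validated classification.

    Each complete case is classified by a model refitted to all remaining
    complete cases (a full refit per fold — no shortcut formulas). A fold
    whose refit is singular is excluded with a warning. Fully deterministic.
    """
    xf, xm, dropped = _complete_cases(dataset, measurements)
    if xf.shape[0] < 3 or xm.shape[0] < 3:
        raise ValueError("leave-one-out needs at least 3 complete cases per sex")
    X = np.vstack([xf, xm])
    truths = np.array([FEMALE] * xf.shape[0] + [MALE] * xm.shape[0])
    kept_truths: list[str] = []
    preds: list[str] = []
    n_failed = 0
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        f_mask = mask & (truths == FEMALE)
        m_mask = mask & (truths == MALE)
        try:
            fold = _fit_from_matrices(X[f_mask], X[m_mask], measurements)
        except ValueError:
            n_failed += 1
            continue
        kept_truths.append(str(truths[i]))
        preds.append(classify_lda(fold, X[i]))
    if n_failed:
        logger.warning("loocv: %d fold(s) excluded (singular refit)", n_failed)
    return _classification_report(kept_truths, preds, n_excluded=dropped + n_failed)
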