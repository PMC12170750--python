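"""Gaussian sectioning points, the D-value overlap statistic, and cut-off
classification.

The sectioning point x0 for one measurement is where the two fitted normal
densities N(mean_f, sd_f²) and N(mean_m, sd_m²) intersect between the group
means: an individual measuring below x0 is classified female, at or above it
male. The D-value

    D = F(x0 | mean_f, sd_f²) − F(x0 | mean_m, sd_m²)

(F the normal CDF) is the area of non-overlap between the two distributions;
it ranges from 0 (identical distributions) to 1 (complete separation) and is
maximised exactly at the density intersection, so it doubles as the figure
of merit for the chosen cut-off.

With unequal variances the density-equality condition is a quadratic in x;
when neither root falls between the means (possible for strongly unequal
spreads), the cut-off falls back to the D-maximising point on the closed
interval between the means and the result is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .datamodel import (
    FEMALE,
    MALE,
    ClassificationReport,
    GroupSummary,
    StudyDataset,
    logger,
)


@dataclass(frozen=True)
class SectioningResult:
    """Fitted sectioning point and D-value for one measurement."""

    measurement: str
    cutoff_x0: float
    d_value: float
    female_summary: GroupSummary
    male_summary: GroupSummary
    #: no density crossing lay between the means; x0 maximises D instead
    fallback: bool = False
    #: female mean exceeded male mean; groups swapped internally
    polarity_reversed: bool = False


def _check_summaries(female: GroupSummary, male: GroupSummary) -> None:
    if female.sd <= 0 or male.sd <= 0:
        raise ValueError("both group standard deviations must be positive")


def d_value(x0: float, female: GroupSummary, male: GroupSummary) -> float:
    """Area of non-overlap F(x0; female) − F(x0; male) at cut-off x0."""
    _check_summaries(female, male)
    return float(
        norm.cdf(x0, loc=female.mean, scale=female.sd)
        - norm.cdf(x0, loc=male.mean, scale=male.sd)
    )


def _density_crossings(lo: GroupSummary, hi: GroupSummary) -> list[float]:
    """Roots of equal normal log-densities; 1 root for equal sds, else <= 2."""
    mf, sf, mm, sm = lo.mean, lo.sd, hi.mean, hi.sd
    a = 1.0 / sf**2 - 1.0 / sm**2
    b = -2.0 * (mf / sf**2 - mm / sm**2)
    c = mf**2 / sf**2 - mm**2 / sm**2 + 2.0 * math.log(sf / sm)
    if abs(a) < 1e-14:  # equal spreads: single crossing at the midpoint
        return [-c / b]
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    sq = math.sqrt(disc)
    return [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]


def fit_cutoff(
    female: GroupSummary, male: GroupSummary, measurement: str = ""
) -> SectioningResult:
    """Fit the sectioning point between two per-sex normal fits.

    Of the (at most two) equal-density roots, the one strictly between the
    group means is taken; if none lies there the cut-off maximising the
    D-value over the closed interval between the means is used and the
    result is flagged (``fallback=True``). If the female mean exceeds the
    male mean the groups are swapped internally and the result flags
    reversed polarity.
    """
    _check_summaries(female, male)
    if female.mean == male.mean:
        raise ValueError("group means are equal: no discriminating cut-off")

    reversed_polarity = female.mean > male.mean
    lo, hi = (male, female) if reversed_polarity else (female, male)
    if reversed_polarity:
        logger.warning(
            "measurement %s: female mean exceeds male mean; polarity reversed",
            measurement or "<unnamed>",
        )

    candidates = [lo.mean, hi.mean]
    in_interval = [r for r in _density_crossings(lo, hi) if lo.mean < r < hi.mean]
    candidates.extend(in_interval)
    d_at = [d_value(x, lo, hi) for x in candidates]
    best = int(np.argmax(d_at))
    x0 = float(candidates[best])
    fallback = not in_interval or x0 not in in_interval
    if fallback:
        logger.warning(
            "measurement %s: no density crossing between the means; "
            "cut-off set to the D-maximising point %.4f",
            measurement or "<unnamed>",
            x0,
        )
    return SectioningResult(
        measurement=measurement,
        cutoff_x0=x0,
        d_value=float(d_at[best]),
        female_summary=female,
        male_summary=male,
        fallback=fallback,
        polarity_reversed=reversed_polarity,
    )


def classify_by_cutoff(value: float, x0: float) -> str:
    """Classify one measurement against a sectioning point.

    Below the cut-off → female; at or above it → male (the boundary goes to
    male because the female rule is strictly "falls below").
    """
    if not (math.isfinite(value) and math.isfinite(x0)):
        raise ValueError("value and cut-off must be finite")
    return FEMALE if value < x0 else MALE


def evaluate_cutoff(
    dataset: StudyDataset, measurement: str, x0: float
) -> ClassificationReport:
    """Percent-correct of a sectioning point on every record with the
    measurement present; records with absent values are excluded and tallied.
    """
    correct = {FEMALE: 0, MALE: 0}
    totals = {FEMALE: 0, MALE: 0}
    excluded = 0
    for rec in dataset:
        v = rec.value(measurement)
        if v is None:
            excluded += 1
            continue
        totals[rec.sex] += 1
        if classify_by_cutoff(v, x0) == rec.sex:
            correct[rec.sex] += 1
    for sex in (FEMALE, MALE):
        if totals[sex] == 0:
            raise ValueError(f"no usable {sex} records for measurement {measurement}")
    if excluded:
        logger.info(
            "evaluate_cutoff(%s): %d record(s) excluded for absent values",
            measurement,
            excluded,
        )
    n_all = totals[FEMALE] + totals[MALE]
    return ClassificationReport(
        percent_correct_female=100.0 * correct[FEMALE] / totals[FEMALE],
        percent_correct_male=100.0 * correct[MALE] / totals[MALE],
        percent_correct_total=100.0 * (correct[FEMALE] + correct[MALE]) / n_all,
        n_female=totals[FEMALE],
        n_male=totals[MALE],
        n_excluded=excluded,
    )


def filter_calcined(dataset: StudyDataset) -> StudyDataset:
    """Retain the burnt records heated to >= 800 °C with white colour.

    Calcination — complete combustion of the organic fraction, leaving
    chalky-white bone — is operationalised as temperature >= 800 °C and
    white colour; everything else is dropped. An empty result is permitted
    (with a warning).
    """
    recs = [
        r
        for r in dataset
        if r.burn_state == "burnt"
        and r.burn_temperature is not None
        and r.burn_temperature >= 800.0
        and r.burn_colour == "white"
    ]
    if not recs:
        logger.warning("calcined filter retained no records")
    return StudyDataset(records=recs, provenance=f"{dataset.provenance} [calcined]")
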