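"""Descriptive and inferential battery for sexual dimorphism per measurement.

For each measurement the analysis reports per-sex descriptive summaries,
screens the shape of each group distribution (skewness, Shapiro–Wilk),
checks homogeneity of spread across sexes (Levene, mean-centred), and
compares the sexes with a Mann–Whitney U test. The Mann–Whitney statistic is
reported on the z scale of the normal approximation with midranks and tie
correction and no continuity correction, signed so that it is negative when
the female group tends to the smaller values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import GroupSummary


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its two-sided p-value and a method label."""

    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def summarize_group(values) -> GroupSummary:
    """n, mean, sample SD (divisor n−1), min and max of one sex group.

    Raises on fewer than two values, non-finite values, or zero spread
    (a zero SD is unusable for sectioning downstream).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("group summary requires at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite value in group")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate group: zero standard deviation")
    return GroupSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        min=float(np.min(x)),
        max=float(np.max(x)),
    )


def skewness(values) -> float:
    """Adjusted Fisher–Pearson standardized third moment G1.

    G1 = g1·sqrt(n(n−1))/(n−2) with g1 = m3/m2^1.5 on biased central moments.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires at least 3 values")
    if np.var(x) == 0.0:
        raise ValueError("skewness undefined for zero-variance sample")
    return float(stats.skew(x, bias=False))


def distribution_tests(female, male) -> dict[str, TestResult]:
    """Shapiro–Wilk normality per sex group and Levene's test across groups.

    Levene is mean-centred. A constant group is a hard error for
    Shapiro–Wilk; for Levene it yields a flagged result with NaN statistic.
    """
    f = np.asarray(list(female), dtype=float)
    m = np.asarray(list(male), dtype=float)
    if f.size < 3 or m.size < 3:
        raise ValueError("each group needs at least 3 values")
    out: dict[str, TestResult] = {}
    for label, x in (("female", f), ("male", m)):
        if np.ptp(x) == 0.0:
            raise ValueError(f"constant {label} group: Shapiro-Wilk undefined")
        w, p = stats.shapiro(x)
        out[f"shapiro_{label}"] = TestResult(float(w), float(p), "shapiro-wilk")
    if np.ptp(f) == 0.0 or np.ptp(m) == 0.0:
        out["levene"] = TestResult(
            float("nan"), float("nan"), "levene (flagged: constant group)"
        )
    else:
        w, p = stats.levene(f, m, center="mean")
        out["levene"] = TestResult(float(w), float(p), "levene")
    return out


def _u_statistic(female: np.ndarray, male: np.ndarray) -> float:
    """Female-side U from pooled midranks."""
    pooled = np.concatenate([female, male])
    ranks = stats.rankdata(pooled)
    r_f = float(np.sum(ranks[: female.size]))
    nf = female.size
    return r_f - nf * (nf + 1) / 2.0


def mann_whitney(female, male, *, method: str = "normal") -> TestResult:
    """Two-sided Mann–Whitney U comparison of the sexes.

    ``method='normal'`` (default) reports the z statistic
    z = (U_f − n_f n_m / 2) / σ_U with tie-corrected σ_U, midranks and no
    continuity correction; z is negative when the female group tends lower.
    ``method='exact'`` (each group ≤ 10) computes the p-value by exhaustive
    enumeration of group assignments of the pooled sample and reports U_f
    as the statistic.
    """
    f = np.asarray(list(female), dtype=float)
    m = np.asarray(list(male), dtype=float)
    if f.size == 0 or m.size == 0:
        raise ValueError("both groups must be non-empty")
    nf, nm = f.size, m.size
    u_f = _u_statistic(f, m)

    if method == "exact":
        if nf > 10 or nm > 10:
            raise ValueError("exact method limited to groups of size <= 10")
        pooled = np.concatenate([f, m])
        n = nf + nm
        # null: every choice of nf positions for the female group equally likely
        dev_obs = abs(u_f - nf * nm / 2.0)
        count = 0
        total = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, nf):
            comb = np.asarray(comb)
            mask = np.zeros(n, dtype=bool)
            mask[comb] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - nf * nm / 2.0) >= dev_obs - 1e-12:
                count += 1
        return TestResult(u_f, count / total, "mann-whitney (exact)")

    if method != "normal":
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate([f, m])
    n = nf + nm
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = nf * nm / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        raise ValueError("all pooled values tied: Mann-Whitney undefined")
    z = (u_f - nf * nm / 2.0) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), "mann-whitney (normal approx.)")


def u_statistic(female, male) -> float:
    """Female-side Mann–Whitney U (midranks for ties)."""
    f = np.asarray(list(female), dtype=float)
    m = np.asarray(list(male), dtype=float)
    if f.size == 0 or m.size == 0:
        raise ValueError("both groups must be non-empty")
    return _u_statistic(f, m)
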