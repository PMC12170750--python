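"""Technical error of measurement and reliability statistics.

Duplicate measurements of the same subjects (two sessions of one observer,
or one session each of two observers) quantify measurement error:

    TEM  = sqrt( Σ d_i² / (2n) )          d_i = within-subject difference
    %TEM = 100 · TEM / grand mean          (dimensionless, unit-free)
    R    = 1 − TEM² / s²                   s² = sample variance (n−1) of the
                                           per-subject mean values

TEM is in measurement units (mm here); R approaches 1 when measurement error
is negligible against between-subject variation and can go to 0 or below
when noise swamps the signal. Exactly two replicates per subject are
supported; the k-replicate generalisation is deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import logger


@dataclass(frozen=True)
class ReliabilityReport:
    """TEM, %TEM and reliability coefficient for one measurement."""

    tem: float
    percent_tem: float
    reliability_r: float
    n_subjects: int

    def __post_init__(self) -> None:
        if self.tem < 0 or self.percent_tem < 0:
            raise ValueError("TEM and %TEM cannot be negative")
        if self.reliability_r > 1.0 + 1e-12:
            raise ValueError("reliability coefficient cannot exceed 1")


def _as_pairs(pairs) -> np.ndarray:
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected exactly two replicate measurements per subject")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite replicate value")
    return arr


def tem(pairs) -> float:
    """Technical error of measurement sqrt(Σ d² / 2n), in measurement units."""
    arr = _as_pairs(pairs)
    d = arr[:, 0] - arr[:, 1]
    return float(math.sqrt(np.sum(d**2) / (2.0 * arr.shape[0])))


def percent_tem(pairs) -> float:
    """Relative TEM: 100 · TEM over the grand mean of all replicates."""
    arr = _as_pairs(pairs)
    grand = float(arr.mean())
    if grand <= 0:
        raise ValueError("grand mean must be positive for %TEM")
    return 100.0 * tem(arr) / grand


def reliability_r(pairs) -> float:
    """Coefficient of reliability R = 1 − TEM²/s² on per-subject means."""
    arr = _as_pairs(pairs)
    subject_means = arr.mean(axis=1)
    s2 = float(np.var(subject_means, ddof=1))
    if s2 == 0.0:
        raise ValueError("zero between-subject variance: R undefined")
    r = 1.0 - tem(arr) ** 2 / s2
    if r <= 0:
        logger.warning(
            "reliability coefficient %.3f <= 0: measurement error exceeds "
            "between-subject variation",
            r,
        )
    return r


def reliability_report(pairs) -> ReliabilityReport:
    """All three observer-error statistics for one measurement."""
    arr = _as_pairs(pairs)
    return ReliabilityReport(
        tem=tem(arr),
        percent_tem=percent_tem(arr),
        reliability_r=reliability_r(arr),
        n_subjects=int(arr.shape[0]),
    )


def read_replicates(path: str | Path) -> pd.DataFrame:
    """Read a long-format replicate CSV.

    Expected columns: ``subject_id, session, observer, measurement, value``.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "session", "observer", "measurement", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {', '.join(sorted(missing))}")
    return df


def make_pairs(df: pd.DataFrame, measurement: str, mode: str) -> np.ndarray:
    """Pair replicates per subject for one measurement.

    ``mode='intra'`` pairs the two sessions of a single observer;
    ``mode='inter'`` pairs the two observers (first session of each).
    Subjects lacking exactly two replicates are dropped with a warning.
    """
    sub = df[df["measurement"] == measurement]
    if mode == "intra":
        obs = sorted(sub["observer"].unique())
        sub = sub[sub["observer"] == obs[0]]
        key = "session"
    elif mode == "inter":
        sessions = sorted(sub["session"].unique())
        sub = sub[sub["session"] == sessions[0]]
        key = "observer"
    else:
        raise ValueError("mode must be 'intra' or 'inter'")
    pairs = []
    dropped = 0
    for _, grp in sub.sort_values(key).groupby("subject_id"):
        if len(grp) != 2:
            dropped += 1
            continue
        pairs.append(grp["value"].to_numpy(dtype=float))
    if dropped:
        logger.warning("make_pairs: %d subject(s) without exactly 2 replicates", dropped)
    if len(pairs) < 2:
        raise ValueError("fewer than 2 paired subjects")
    return np.asarray(pairs)
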