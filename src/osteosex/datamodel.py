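"""Domain types, CSV input/output, and embedded reference tables.

The package works on per-patella measurement records: each record is one
observation of a patella (one individual, one side, one burn state) carrying
up to three linear measurements in millimetres — maximum height (MAXH),
maximum thickness (MAXT) and maximum width (MAXW).

Reference fixtures embed published per-sex summary statistics for burnt and
unburnt patellae and two sets of externally published sectioning points, so
that every downstream computation can be exercised without access to the raw
skeletal-collection data (which is not publicly distributed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("osteosex")

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: measurement labels, in conventional reporting order
MEASUREMENTS = ("maxh", "maxt", "maxw")

SIDES = ("left", "right")
BURN_STATES = ("unburnt", "burnt")
BURN_COLOURS = ("white", "black", "other", "unknown")

#: canonical CSV column order for measurement tables
CSV_COLUMNS = (
    "individual_id",
    "sex",
    "age_at_death",
    "side",
    "burn_state",
    "burn_temperature",
    "burn_duration",
    "burn_colour",
    "maxh",
    "maxt",
    "maxw",
)

_MANDATORY_COLUMNS = ("individual_id", "sex", "side", "burn_state")

_SEX_ALIASES = {
    "f": FEMALE,
    "female": FEMALE,
    "m": MALE,
    "male": MALE,
}


@dataclass(frozen=True)
class MeasurementRecord:
    """One patella observation.

    Measurements are in mm; absent measurements are ``None`` (never zero).
    Burn metadata is only meaningful for burnt records and is optional for
    unburnt ones.
    """

    individual_id: str
    sex: str
    side: str
    burn_state: str
    age_at_death: int | None = None
    burn_temperature: float | None = None
    burn_duration: float | None = None
    burn_colour: str = "unknown"
    maxh: float | None = None
    maxt: float | None = None
    maxw: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.burn_state not in BURN_STATES:
            raise ValueError(
                f"burn_state must be one of {BURN_STATES}, got {self.burn_state!r}"
            )
        if self.burn_colour not in BURN_COLOURS:
            raise ValueError(
                f"burn_colour must be one of {BURN_COLOURS}, got {self.burn_colour!r}"
            )
        for name in MEASUREMENTS:
            v = getattr(self, name)
            if v is not None and not (0.0 < v < 100.0):
                raise ValueError(f"{name}={v} mm outside plausible range (0, 100)")
        if self.burn_temperature is not None and not (
            0.0 <= self.burn_temperature <= 1500.0
        ):
            raise ValueError(
                f"burn_temperature={self.burn_temperature} outside [0, 1500] °C"
            )

    def value(self, measurement: str) -> float | None:
        """Return one measurement by label (``maxh``/``maxt``/``maxw``)."""
        if measurement not in MEASUREMENTS:
            raise KeyError(f"unknown measurement {measurement!r}")
        return getattr(self, measurement)


@dataclass
class StudyDataset:
    """An ordered collection of measurement records with a provenance label."""

    records: list[MeasurementRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.individual_id, rec.side)
            if key in seen:
                raise ValueError(
                    f"duplicate individual_id x side: {rec.individual_id!r}/{rec.side}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MeasurementRecord]:
        return iter(self.records)

    def subset(
        self,
        *,
        sex: str | None = None,
        burn_state: str | None = None,
        side: str | None = None,
        provenance: str | None = None,
    ) -> "StudyDataset":
        recs = [
            r
            for r in self.records
            if (sex is None or r.sex == sex)
            and (burn_state is None or r.burn_state == burn_state)
            and (side is None or r.side == side)
        ]
        label = provenance if provenance is not None else self.provenance
        return StudyDataset(records=recs, provenance=label)

    def values(self, measurement: str, *, sex: str | None = None) -> np.ndarray:
        """Present (non-null) values of one measurement, optionally per sex."""
        out = [
            r.value(measurement)
            for r in self.records
            if (sex is None or r.sex == sex) and r.value(measurement) is not None
        ]
        return np.asarray(out, dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "individual_id": r.individual_id,
                    "sex": r.sex,
                    "age_at_death": r.age_at_death,
                    "side": r.side,
                    "burn_state": r.burn_state,
                    "burn_temperature": r.burn_temperature,
                    "burn_duration": r.burn_duration,
                    "burn_colour": r.burn_colour,
                    "maxh": r.maxh,
                    "maxt": r.maxt,
                    "maxw": r.maxw,
                }
            )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


@dataclass(frozen=True)
class GroupSummary:
    """Per-sex descriptive summary of one measurement (mm).

    ``sd`` is the sample standard deviation (divisor n−1); its square is the
    variance entering the sectioning-point and D-value formulas. ``min`` and
    ``max`` are carried for reporting. Summaries computed from data always
    satisfy min ≤ mean ≤ max; summaries transcribed from published tables are
    stored verbatim even where the printed extremes are internally
    inconsistent, so ordering is checked via :attr:`consistent`, not enforced.
    """

    n: int
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("sd cannot be negative")

    @property
    def variance(self) -> float:
        return self.sd**2

    @property
    def degenerate(self) -> bool:
        """True when sd == 0 (unusable for sectioning)."""
        return self.sd == 0.0

    @property
    def consistent(self) -> bool:
        return self.min <= self.mean <= self.max


@dataclass(frozen=True)
class ExternalCutoffSet:
    """Named set of published sectioning points, one per measurement (mm)."""

    source_label: str
    cutoffs: Mapping[str, float]

    def __post_init__(self) -> None:
        for m, v in self.cutoffs.items():
            if m not in MEASUREMENTS:
                raise ValueError(f"unknown measurement {m!r} in cut-off set")
            if v <= 0:
                raise ValueError(f"cut-off for {m} must be positive, got {v}")


@dataclass(frozen=True)
class ClassificationReport:
    """Per-sex and pooled percent-correct of a binary sex classifier.

    The total is case-weighted (correct cases over all cases), not the mean
    of the two per-sex rates.
    """

    percent_correct_female: float
    percent_correct_male: float
    percent_correct_total: float
    n_female: int
    n_male: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.percent_correct_female,
            self.percent_correct_male,
            self.percent_correct_total,
        ):
            if not (0.0 <= p <= 100.0):
                raise ValueError(f"percentage {p} outside [0, 100]")


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------


def _parse_optional_float(cell, row_idx: int, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if s == "" or s.lower() in {"na", "nan", "none", "null"}:
        return None
    try:
        return float(s)
    except ValueError:
        logger.warning(
            "row %d: unparseable value %r in column %s treated as absent",
            row_idx,
            cell,
            column,
        )
        return None


def read_measurements(path: str | Path) -> StudyDataset:
    """Read a measurement CSV into a :class:`StudyDataset`.

    The dialect is comma-separated UTF-8 with a mandatory header and period
    decimal separator. Sex labels are normalised case-insensitively
    (``F``/``f``/``Female`` → ``female``). Unparseable measurement cells
    become absent values with a logged warning; missing mandatory columns or
    duplicated individual/side pairs are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    bad_sex_rows = []
    records: list[MeasurementRecord] = []
    for idx, row in df.iterrows():
        raw_sex = str(row["sex"]).strip().lower()
        sex = _SEX_ALIASES.get(raw_sex)
        if sex is None:
            bad_sex_rows.append((idx, row["sex"]))
            continue
        side = str(row["side"]).strip().lower()
        burn_state = str(row["burn_state"]).strip().lower()
        colour = str(row.get("burn_colour", "unknown") or "unknown").strip().lower()
        if colour in ("", "nan"):
            colour = "unknown"
        age = _parse_optional_float(row.get("age_at_death"), idx, "age_at_death")
        records.append(
            MeasurementRecord(
                individual_id=str(row["individual_id"]).strip(),
                sex=sex,
                side=side,
                burn_state=burn_state,
                age_at_death=int(age) if age is not None else None,
                burn_temperature=_parse_optional_float(
                    row.get("burn_temperature"), idx, "burn_temperature"
                ),
                burn_duration=_parse_optional_float(
                    row.get("burn_duration"), idx, "burn_duration"
                ),
                burn_colour=colour,
                maxh=_parse_optional_float(row.get("maxh"), idx, "maxh"),
                maxt=_parse_optional_float(row.get("maxt"), idx, "maxt"),
                maxw=_parse_optional_float(row.get("maxw"), idx, "maxw"),
            )
        )
    if bad_sex_rows:
        listing = ", ".join(f"row {i} ({v!r})" for i, v in bad_sex_rows)
        raise ValueError(f"unrecognised sex label(s): {listing}")
    return StudyDataset(records=records, provenance=str(path))


def write_measurements(dataset: StudyDataset, path: str | Path) -> None:
    """Write a dataset back to the canonical CSV dialect."""
    df = dataset.to_dataframe()
    df.to_csv(path, index=False, float_format="%.2f")


# ---------------------------------------------------------------------------
# Embedded reference tables
# ---------------------------------------------------------------------------
#
# Per-sex summaries of the experimentally burnt right patellae (18 F / 14 M)
# and their unburnt left antimeres, plus externally published sectioning
# points from an Italian protohistoric cremation series (Cavazzuti et al.)
# and a modern US crematorium series (Hlad et al.). Values are transcribed
# verbatim from the published tables; a few printed min/max cells are
# internally inconsistent (e.g. a maximum below the mean) and are kept as
# printed — they feed no computation.

_T2 = {
    # measurement: (female summary, male summary)
    "maxh": (
        GroupSummary(18, 33.33, 4.53, 27.11, 42.93),
        GroupSummary(14, 38.22, 4.23, 31.42, 25.49),
    ),
    "maxt": (
        GroupSummary(18, 17.01, 1.96, 14.48, 21.82),
        GroupSummary(14, 18.26, 2.49, 14.60, 23.32),
    ),
    "maxw": (
        GroupSummary(18, 34.90, 4.43, 28.33, 44.96),
        GroupSummary(14, 39.58, 3.35, 32.32, 44.24),
    ),
}

_T3 = {
    "maxh": (
        GroupSummary(18, 37.95, 2.98, 30.17, 33.48),
        GroupSummary(14, 42.45, 2.23, 39.66, 46.38),
    ),
    "maxt": (
        GroupSummary(18, 18.83, 1.82, 16.08, 22.00),
        GroupSummary(14, 20.52, 1.39, 17.54, 22.37),
    ),
    "maxw": (
        GroupSummary(18, 38.99, 3.26, 44.39, 45.95),
        GroupSummary(14, 43.81, 2.53, 40.74, 49.13),
    ),
}

#: published sectioning points (mm) of the burnt sample, by measurement
BURNT_PUBLISHED_CUTOFFS = {"maxh": 35.87, "maxt": 17.55, "maxw": 37.53}
#: published D-values of the burnt sample
BURNT_PUBLISHED_D_VALUES = {"maxh": 0.423, "maxt": 0.220, "maxw": 0.453}
#: published sectioning points (mm) of the unburnt antimeres
UNBURNT_PUBLISHED_CUTOFFS = {"maxh": 40.20, "maxt": 19.41, "maxw": 41.28}

#: study composition: per-sex sample sizes and printed age-at-death summaries
STUDY_COMPOSITION = {
    FEMALE: {"n": 18, "age_mean": 80.1, "age_sd": 5.86, "age_range": (62, 92)},
    MALE: {"n": 14, "age_mean": 76.6, "age_sd": 10.5, "age_range": (60, 93)},
}

_CAVAZZUTI = ExternalCutoffSet(
    source_label="Cavazzuti et al.",
    cutoffs={"maxh": 35.68, "maxt": 16.10, "maxw": 36.61},
)
_HLAD = ExternalCutoffSet(
    source_label="Hlad et al.",
    cutoffs={"maxh": 36.30, "maxt": 16.30, "maxw": 38.10},
)

_FIXTURES = {
    "table2_burnt": _T2,
    "table3_unburnt": _T3,
    "table6_cavazzuti": _CAVAZZUTI,
    "table6_hlad": _HLAD,
}


def load_fixture(name: str):
    """Return an embedded reference table by name.

    ``table2_burnt`` and ``table3_unburnt`` return a mapping
    measurement → (female :class:`GroupSummary`, male :class:`GroupSummary`);
    ``table6_cavazzuti`` and ``table6_hlad`` return an
    :class:`ExternalCutoffSet`.
    """
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {sorted(_FIXTURES)}"
        ) from None


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def _round_opt(v, ndigits):
    if v is None:
        return None
    return round(float(v), ndigits)


def sectioning_table(results: Sequence) -> pd.DataFrame:
    """Tabulate dimorphism/sectioning results, one row per measurement.

    ``results`` is a sequence of objects exposing ``measurement``,
    ``female_summary``, ``male_summary``, ``cutoff_x0``, ``d_value`` and
    optionally ``test_stat``/``sig`` attributes (see the pipeline module).
    mm quantities are rounded to 2 decimals, D-values to 3.
    """
    rows = []
    for r in results:
        f, m = r.female_summary, r.male_summary
        rows.append(
            {
                "measurement": r.measurement,
                "female_n": f.n,
                "female_mean": round(f.mean, 2),
                "female_sd": round(f.sd, 2),
                "female_min": round(f.min, 2),
                "female_max": round(f.max, 2),
                "male_n": m.n,
                "male_mean": round(m.mean, 2),
                "male_sd": round(m.sd, 2),
                "male_min": round(m.min, 2),
                "male_max": round(m.max, 2),
                "test_stat": _round_opt(getattr(r, "test_stat", None), 2),
                "sig": _round_opt(getattr(r, "sig", None), 3),
                "d_value": round(r.d_value, 3),
                "cutoff_mm": round(r.cutoff_x0, 2),
            }
        )
    return pd.DataFrame(rows)


def lda_table(models_and_reports: Sequence[tuple]) -> pd.DataFrame:
    """Tabulate fitted discriminant functions, one row per function.

    Each element is ``(function_id, model, original_report, cv_report)``.
    """
    rows = []
    for fid, model, orig, cv in models_and_reports:
        rows.append(
            {
                "function": fid,
                "measurements": "+".join(model.measurements),
                "coefficients": ";".join(
                    f"{c:.3f}" for c in model.coefficients
                ),
                "constant": round(model.constant, 3),
                "centroid_female": round(model.centroid_female, 3),
                "centroid_male": round(model.centroid_male, 3),
                "original_pct": _round_opt(
                    orig.percent_correct_total if orig else None, 1
                ),
                "cv_pct": _round_opt(cv.percent_correct_total if cv else None, 1),
            }
        )
    return pd.DataFrame(rows)


def cutoff_evaluation_table(evaluations: Sequence[tuple]) -> pd.DataFrame:
    """Tabulate external cut-off evaluations.

    Each element is ``(source_label, measurement, cutoff_mm, report)``.
    """
    rows = []
    for source, measurement, cutoff, rep in evaluations:
        rows.append(
            {
                "source": source,
                "measurement": measurement,
                "cutoff_mm": round(cutoff, 2),
                "female_pct": round(rep.percent_correct_female, 1),
                "male_pct": round(rep.percent_correct_male, 1),
                "total_pct": round(rep.percent_correct_total, 1),
            }
        )
    return pd.DataFrame(rows)


def write_report_tables(results: Mapping[str, pd.DataFrame], path: str | Path) -> list[Path]:
    """Write each named table as ``<name>.csv`` under ``path``.

    Returns the written paths. An empty results mapping writes nothing and
    logs a warning.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    if not results:
        logger.warning("no report tables to write to %s", outdir)
        return []
    written = []
    for name, table in results.items():
        target = outdir / f"{name}.csv"
        table.to_csv(target, index=False)
        written.append(target)
    return written
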