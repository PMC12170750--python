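"""End-to-end analysis pipeline and its configuration.

Runs the study's analysis sequence — descriptive summaries, normality and
variance screens, Mann–Whitney comparisons, sectioning points with D-values,
discriminant functions with leave-one-out cross-validation, and evaluation of
externally published cut-offs — on three views of the data: the full burnt
set, the unburnt antimeres, and the calcined subset (>= 800 °C, white). Each
stage writes a rounded CSV report table; full-precision results go to a
machine-readable JSON alongside a run log recording the seed, a config hash
and exclusion counts, so a run is reproducible from its log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import datamodel, dimorphism, discriminant, observer_error, sectioning
from .datamodel import (
    MEASUREMENTS,
    StudyDataset,
    load_fixture,
    logger,
    read_measurements,
    write_report_tables,
)
from .synthetic import SyntheticConfig, generate

ALL_ANALYSES = ("dimorphism", "sectioning", "lda", "external-cutoffs", "reliability")


@dataclass
class PipelineConfig:
    """What to analyse, on which input, and where to write it."""

    output_dir: str
    input: str | None = None
    synthetic: SyntheticConfig | None = None
    measurements: tuple[str, ...] = MEASUREMENTS
    analyses: tuple[str, ...] = ("dimorphism", "sectioning", "lda", "external-cutoffs")
    external_cutoffs: tuple[str, ...] = ("table6_cavazzuti", "table6_hlad")
    reliability_input: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.measurements = tuple(self.measurements)
        self.analyses = tuple(self.analyses)
        self.external_cutoffs = tuple(self.external_cutoffs)
        if not self.analyses:
            raise ValueError("select at least one analysis")
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        bad = set(self.measurements) - set(MEASUREMENTS)
        if bad:
            raise ValueError(f"unknown measurements: {sorted(bad)}")
        if self.input is None and self.synthetic is None and set(self.analyses) != {"reliability"}:
            raise ValueError("either an input CSV or a synthetic config is required")

    def to_dict(self) -> dict[str, Any]:
        return {
            "output_dir": self.output_dir,
            "input": self.input,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "measurements": list(self.measurements),
            "analyses": list(self.analyses),
            "external_cutoffs": list(self.external_cutoffs),
            "reliability_input": self.reliability_input,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis settings (the output destination is excluded,
        so the same analysis written elsewhere hashes identically)."""
        d = self.to_dict()
        d.pop("output_dir")
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class _SectioningRow:
    """One report row: summaries + test + sectioning for a measurement."""

    measurement: str
    female_summary: datamodel.GroupSummary
    male_summary: datamodel.GroupSummary
    test_stat: float | None
    sig: float | None
    d_value: float
    cutoff_x0: float
    fallback: bool = False


@dataclass
class PipelineResult:
    """In-memory results plus the paths of the written report files."""

    tables: dict[str, Any] = field(default_factory=dict)
    sectioning: dict[str, dict[str, sectioning.SectioningResult]] = field(
        default_factory=dict
    )
    lda_models: list[tuple] = field(default_factory=list)
    written: list[Path] = field(default_factory=list)
    log_lines: list[str] = field(default_factory=list)


def _sectioning_stage(
    subset: StudyDataset,
    label: str,
    config: PipelineConfig,
    result: PipelineResult,
    normality_rows: list[dict],
) -> None:
    rows = []
    result.sectioning[label] = {}
    for m in config.measurements:
        f_vals = subset.values(m, sex=datamodel.FEMALE)
        m_vals = subset.values(m, sex=datamodel.MALE)
        if f_vals.size < 2 or m_vals.size < 2:
            logger.warning("%s/%s: too few values per sex; stage skipped", label, m)
            continue
        try:
            fsum = dimorphism.summarize_group(f_vals)
            msum = dimorphism.summarize_group(m_vals)
            test = dimorphism.mann_whitney(f_vals, m_vals)
            sect = sectioning.fit_cutoff(fsum, msum, measurement=m)
        except ValueError as exc:
            logger.warning("%s/%s: %s; stage skipped", label, m, exc)
            continue
        result.sectioning[label][m] = sect
        rows.append(
            _SectioningRow(
                measurement=m,
                female_summary=fsum,
                male_summary=msum,
                test_stat=test.statistic,
                sig=test.p_value,
                d_value=sect.d_value,
                cutoff_x0=sect.cutoff_x0,
                fallback=sect.fallback,
            )
        )
        if "dimorphism" in config.analyses and f_vals.size >= 3 and m_vals.size >= 3:
            checks = dimorphism.distribution_tests(f_vals, m_vals)
            normality_rows.append(
                {
                    "subset": label,
                    "measurement": m,
                    "skew_female": round(dimorphism.skewness(f_vals), 3),
                    "skew_male": round(dimorphism.skewness(m_vals), 3),
                    "shapiro_p_female": round(checks["shapiro_female"].p_value, 3),
                    "shapiro_p_male": round(checks["shapiro_male"].p_value, 3),
                    "levene_p": round(checks["levene"].p_value, 3),
                }
            )
    if rows:
        result.tables[f"sectioning_{label}"] = datamodel.sectioning_table(rows)


def _lda_stage(burnt: StudyDataset, config: PipelineConfig, result: PipelineResult) -> None:
    functions = [(i + 1, (m,)) for i, m in enumerate(config.measurements)]
    if len(config.measurements) > 1:
        functions.append((len(config.measurements) + 1, tuple(config.measurements)))
    entries = []
    for fid, meas in functions:
        try:
            model = discriminant.fit_lda(burnt, meas)
            orig = discriminant.resubstitution(burnt, meas)
            cv = discriminant.loocv(burnt, meas)
        except ValueError as exc:
            logger.warning("lda function %d (%s): %s; skipped", fid, "+".join(meas), exc)
            continue
        entries.append((fid, model, orig, cv))
    if entries:
        result.lda_models = entries
        result.tables["lda"] = datamodel.lda_table(entries)


def _external_cutoff_stage(
    calcined: StudyDataset, config: PipelineConfig, result: PipelineResult
) -> None:
    evaluations = []
    for name in config.external_cutoffs:
        cutset = load_fixture(name)
        for m in config.measurements:
            if m not in cutset.cutoffs:
                continue
            try:
                rep = sectioning.evaluate_cutoff(calcined, m, cutset.cutoffs[m])
            except ValueError as exc:
                logger.warning("external cut-off %s/%s: %s; skipped", name, m, exc)
                continue
            evaluations.append((cutset.source_label, m, cutset.cutoffs[m], rep))
    if evaluations:
        result.tables["external_cutoffs"] = datamodel.cutoff_evaluation_table(evaluations)


def _reliability_stage(config: PipelineConfig, result: PipelineResult) -> None:
    if config.reliability_input is None:
        raise ValueError("reliability analysis selected without reliability_input")
    df = observer_error.read_replicates(config.reliability_input)
    rows = []
    for m in sorted(df["measurement"].unique()):
        for mode in ("intra", "inter"):
            try:
                pairs = observer_error.make_pairs(df, m, mode)
                rep = observer_error.reliability_report(pairs)
            except (ValueError, IndexError) as exc:
                logger.warning("reliability %s/%s: %s; skipped", m, mode, exc)
                continue
            rows.append(
                {
                    "measurement": m,
                    "mode": mode,
                    "tem_mm": round(rep.tem, 3),
                    "percent_tem": round(rep.percent_tem, 2),
                    "reliability_r": round(rep.reliability_r, 3),
                    "n_subjects": rep.n_subjects,
                }
            )
    if rows:
        import pandas as pd

        result.tables["reliability"] = pd.DataFrame(rows)


def _full_precision_payload(result: PipelineResult) -> dict:
    payload: dict[str, Any] = {"sectioning": {}, "lda": []}
    for label, by_meas in result.sectioning.items():
        payload["sectioning"][label] = {
            m: {
                "cutoff_mm": s.cutoff_x0,
                "d_value": s.d_value,
                "fallback": s.fallback,
                "polarity_reversed": s.polarity_reversed,
            }
            for m, s in by_meas.items()
        }
    for fid, model, orig, cv in result.lda_models:
        payload["lda"].append(
            {
                "function": fid,
                "measurements": list(model.measurements),
                "coefficients": list(model.coefficients),
                "constant": model.constant,
                "centroid_female": model.centroid_female,
                "centroid_male": model.centroid_male,
                "threshold": model.threshold,
                "original_total_pct": orig.percent_correct_total,
                "cv_total_pct": cv.percent_correct_total,
            }
        )
    return payload


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the selected analyses and write the report bundle.

    Deterministic given (input file or synthetic seed, config): identical
    runs produce byte-identical outputs.
    """
    logging.basicConfig()
    logger.setLevel(config.log_level.upper())
    result = PipelineResult()

    dataset: StudyDataset | None = None
    if config.input is not None:
        dataset = read_measurements(config.input)
    elif config.synthetic is not None:
        dataset = generate(config.synthetic)

    normality_rows: list[dict] = []
    if dataset is not None and (
        "dimorphism" in config.analyses or "sectioning" in config.analyses
    ):
        burnt = dataset.subset(burn_state="burnt")
        unburnt = dataset.subset(burn_state="unburnt")
        calcined = sectioning.filter_calcined(dataset)
        for label, subset in (("burnt", burnt), ("unburnt", unburnt), ("calcined", calcined)):
            _sectioning_stage(subset, label, config, result, normality_rows)
    if normality_rows:
        import pandas as pd

        result.tables["normality_checks"] = pd.DataFrame(normality_rows)

    if dataset is not None and "lda" in config.analyses:
        _lda_stage(dataset.subset(burn_state="burnt"), config, result)

    if dataset is not None and "external-cutoffs" in config.analyses:
        _external_cutoff_stage(sectioning.filter_calcined(dataset), config, result)

    if "reliability" in config.analyses:
        _reliability_stage(config, result)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.written = write_report_tables(result.tables, outdir)

    payload = _full_precision_payload(result)
    results_json = outdir / "results.json"
    results_json.write_text(json.dumps(payload, indent=2, sort_keys=True))
    result.written.append(results_json)

    seed = config.synthetic.seed if config.synthetic else None
    log_lines = [
        f"config_hash: {config.config_hash()}",
        f"seed: {seed}",
        f"input: {config.input}",
        f"analyses: {','.join(config.analyses)}",
        f"measurements: {','.join(config.measurements)}",
        f"n_records: {len(dataset) if dataset is not None else 0}",
        f"tables: {','.join(sorted(result.tables))}",
    ]
    run_log = outdir / "run_log.txt"
    run_log.write_text("\n".join(log_lines) + "\n")
    result.written.append(run_log)
    config.to_yaml(outdir / "config_used.yaml")
    result.written.append(outdir / "config_used.yaml")
    result.log_lines = log_lines
    return result
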