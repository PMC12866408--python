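"""End-to-end study runner.

``run_pipeline`` ties the stages together: pooled input-function model
fitting from blood samples, per-scan metabolite-corrected IDIF construction,
per-region 2TCM + Logan + SUV quantification, the test-retest battery when
two sessions are present, and group-level statistics. All reports are
tab-separated; identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as pio
from .cohort_stats import d_for_relative_difference, effect_size, power_table, welch_tests
from .errors import PetquantError, ValidationError
from .input_function import correct_idif, fit_parent_fraction, fit_plasma_to_blood, resample_blood_curve
from .kinetics import FitOptions, compute_suv, fit_2tcm, logan_vt
from .reliability import TrtCohort, trt_report

__all__ = ["StudyConfig", "PipelineResult", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class StudyConfig:
    """Paths and analysis policy for one study run."""

    tac_dir: str
    blood_table: str
    subject_table: str
    out_dir: str
    suv_window: tuple = (100.0, 120.0)
    t_star: object = 30.0  # minutes or "auto"
    grid_step: float = 0.05
    n_restarts: int = 10
    seed: int = 0
    fix_vb: float | None = None
    weights: str = "duration"
    constrain_parent_t0: bool = True
    icc_extra_random_terms: bool = False
    planning_rel_diff: float = 0.20  # relative group difference for power planning

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "suv_window" in raw:
            raw["suv_window"] = tuple(float(v) for v in raw["suv_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["suv_window"] = list(self.suv_window)
        return out


@dataclass
class PipelineResult:
    kinetics: pd.DataFrame
    trt: pd.DataFrame | None
    group: pd.DataFrame | None
    power: pd.DataFrame | None
    failures: list = field(default_factory=list)

    @property
    def exit_status(self) -> int:
        return 1 if self.failures else 0


def _scan_path(config: StudyConfig, subject: str, session: str) -> Path:
    return Path(config.tac_dir) / f"{subject}_{session}.tsv"


def run_pipeline(config: StudyConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    subjects = pio.read_subject_table(config.subject_table)
    blood = pio.read_blood_table(config.blood_table)
    pf = fit_parent_fraction(blood, constrain_t0=config.constrain_parent_t0)
    p2wb = fit_plasma_to_blood(blood)

    options = FitOptions(
        n_restarts=config.n_restarts, seed=config.seed,
        fix_vb=config.fix_vb, weights=config.weights,
    )

    rows, failures = [], []
    for rec in subjects.itertuples(index=False):
        path = _scan_path(config, rec.subject_id, rec.session)
        try:
            tac = pio.read_tac_table(path)
            if "whole_blood" not in tac.regions:
                raise ValidationError(f"{path}: no whole_blood column for IDIF")
            schedule = tac.schedule
            grid, wb = resample_blood_curve(
                schedule.midpoints, tac.region("whole_blood"),
                config.grid_step, schedule.total_duration,
            )
            input_fn = correct_idif(grid, wb, p2wb, pf)
            brain = tac.drop_region("whole_blood")
        except PetquantError as exc:
            failures.append({"subject": rec.subject_id, "session": rec.session,
                             "region": "*", "error": str(exc)})
            continue
        for region in brain.regions:
            try:
                fit = fit_2tcm(brain, input_fn, region, options)
                logan = logan_vt(brain, input_fn, region, t_star=config.t_star)
                suv = compute_suv(
                    brain, rec.injected_dose_MBq, rec.body_weight_g,
                    region, config.suv_window,
                )
                rows.append({
                    "subject": rec.subject_id, "genotype": rec.genotype,
                    "session": rec.session, "region": region,
                    "K1": fit.params.K1, "k2": fit.params.k2,
                    "k3": fit.params.k3, "k4": fit.params.k4,
                    "vB": fit.params.vB,
                    "VT_2tcm": fit.vt, "VT_logan": logan.vt,
                    "logan_r2": logan.r_squared, "logan_t_star": logan.t_star,
                    "SUV": suv.suv, "suv_n_frames": suv.n_frames,
                    "flags": ";".join(fit.flags + logan.flags) or "-",
                })
            except PetquantError as exc:
                failures.append({"subject": rec.subject_id, "session": rec.session,
                                 "region": region, "error": str(exc)})

    kinetics = pd.DataFrame(rows)
    kinetics.to_csv(out / "kinetics_report.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    trt = group = power = None
    if not kinetics.empty:
        sessions = set(kinetics["session"])
        if {"test", "retest"} <= sessions:
            trt = _run_trt(kinetics, config)
            trt.to_csv(out / "trt_report.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        group, power = _run_group_stats(kinetics, config)
        if group is not None:
            group.to_csv(out / "group_report.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        if power is not None:
            power.to_csv(out / "power_report.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    _write_log(out, config, failures)
    return PipelineResult(kinetics=kinetics, trt=trt, group=group, power=power,
                          failures=failures)


def _cohort_from_kinetics(kinetics: pd.DataFrame) -> TrtCohort:
    long = kinetics.melt(
        id_vars=["subject", "genotype", "session", "region"],
        value_vars=["VT_logan", "SUV"],
        var_name="metric", value_name="value",
    ).rename(columns={"subject": "animal"})
    # available-case fallback: keep only complete test/retest pairs
    counts = long.groupby(["animal", "region", "metric"])["session"].transform("nunique")
    if (counts < 2).any():
        import warnings

        warnings.warn(
            f"dropping {int((counts < 2).sum())} unpaired records from the "
            "test-retest battery (unbalanced design)"
        )
    return TrtCohort(long[counts == 2].reset_index(drop=True))


def _run_trt(kinetics: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    cohort = _cohort_from_kinetics(kinetics)
    return trt_report(cohort)


def _run_group_stats(kinetics: pd.DataFrame, config: StudyConfig):
    test = kinetics[kinetics["session"] == "test"]
    if test.empty:
        test = kinetics
    if set(test["genotype"]) != {"WT", "HET"}:
        return None, None
    group_rows, planning = [], {}
    for metric in ("VT_2tcm", "VT_logan", "SUV"):
        by_region = {}
        for region in sorted(test["region"].unique()):
            sub = test[test["region"] == region]
            wt = sub[sub["genotype"] == "WT"][metric].to_numpy()
            het = sub[sub["genotype"] == "HET"][metric].to_numpy()
            if wt.size < 2 or het.size < 2:
                continue
            by_region[region] = (wt, het)
        if not by_region:
            continue
        table = welch_tests(by_region)
        table.insert(0, "metric", metric)
        group_rows.append(table)
        for region, (wt, het) in by_region.items():
            es = effect_size(wt, het)
            planning[f"{metric}:{region}:measured"] = abs(es.d)
            planning[f"{metric}:{region}:rel{int(config.planning_rel_diff * 100)}pct"] = (
                d_for_relative_difference(es.mean_wt, config.planning_rel_diff, es.sd_pooled)
            )
    if not group_rows:
        return None, None
    return pd.concat(group_rows, ignore_index=True), power_table(planning)


def _write_log(out: Path, config: StudyConfig, failures: list) -> None:
    lines = [f"petquant {__version__}", f"seed: {config.seed}", "config:"]
    for key, value in sorted(config.to_dict().items()):
        lines.append(f"  {key}: {value}")
    lines.append(f"failures: {len(failures)}")
    for f in failures:
        lines.append(f"  {f['subject']}/{f['session']}/{f['region']}: {f['error']}")
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
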