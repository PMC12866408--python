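"""Synthetic dynamic-PET study generation with known ground truth.

Every input the pipeline consumes can be generated here: bolus-shaped blood
input functions, biexponentially decaying parent fractions, noisy
frame-averaged regional TACs driven by reversible two-tissue kinetics, and
multi-animal test-retest cohorts with controlled between- and within-animal
variance components.

The defaults emulate a 120-min dynamic mouse scan with a fluorine-18
radioligand binding an aggregate target: heterozygous (HET) animals carry a
larger binding-associated rate k3 than wild-type (WT) littermates, blood
sampling happens at 5/15/30/60/90 min, and the plasma intact-parent fraction
decays to about 0.80 by 90 min. Simulated concentrations are expressed on an
SUV-like normalized scale (peak blood activity of order 5-10); the study
writer converts to kBq/mL using each subject's injected dose and weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FrameSchedule, InputFunction, TacTable, make_standard_frame_schedule
from .errors import InvalidModelError, ValidationError
from .input_function import BloodSampleTable, ParentFractionModel, PlasmaToBloodModel
from .kinetics import TwoTcmParams, twotcm_predict

__all__ = [
    "InputModelParams",
    "NoiseSpec",
    "TrtCohortSpec",
    "StudySpec",
    "make_standard_frame_schedule",
    "default_input_params",
    "default_parent_fraction",
    "default_plasma_to_blood",
    "default_kinetic_params",
    "simulate_input",
    "simulate_blood_samples",
    "simulate_tac",
    "simulate_trt_cohort",
    "write_synthetic_study",
    "BLOOD_SAMPLE_TIMES_MIN",
]

#: Discrete blood-sampling protocol (minutes after injection).
BLOOD_SAMPLE_TIMES_MIN = (5.0, 15.0, 30.0, 60.0, 90.0)


@dataclass(frozen=True)
class InputModelParams:
    """Delayed tri-exponential bolus model for the whole-blood curve.

    For t' = t - delay >= 0:

        C_wb(t) = (A1 t' - A2 - A3) e^(-lam1 t') + A2 e^(-lam2 t') + A3 e^(-lam3 t')

    (zero before the bolus arrives). A1 is the initial-rise slope
    [concentration/min]; A2, A3 are washout amplitudes [concentration];
    lam1 > lam2 > lam3 are per-minute decay rates. The form is continuous at
    t' = 0 with C = 0 and is closed-form integrable.
    """

    delay: float = 0.25
    A1: float = 60.0
    A2: float = 1.2
    A3: float = 0.35
    lam1: float = 3.5
    lam2: float = 0.35
    lam3: float = 0.012

    def __post_init__(self):
        if not (self.lam1 > self.lam2 > self.lam3 >= 0):
            raise ValidationError("decay rates must satisfy lam1 > lam2 > lam3 >= 0")
        if self.delay < 0 or self.A1 < 0 or self.A2 < 0 or self.A3 < 0:
            raise ValidationError("delay and amplitudes must be nonnegative")

    def __call__(self, t):
        tp = np.asarray(t, dtype=float) - self.delay
        tp = np.where(tp > 0, tp, 0.0)
        c = (
            (self.A1 * tp - self.A2 - self.A3) * np.exp(-self.lam1 * tp)
            + self.A2 * np.exp(-self.lam2 * tp)
            + self.A3 * np.exp(-self.lam3 * tp)
        )
        return np.where(np.asarray(t, dtype=float) > self.delay, c, 0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Count-statistics frame noise: SD_i = scale * sqrt(C_model,i / dt_i).

    ``scale = 0`` reproduces the noise-free model; the per-frame coefficient
    of variation falls as 1/sqrt(frame duration) at fixed concentration.
    """

    scale: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.scale < 0:
            raise ValidationError("noise scale must be nonnegative")


def default_input_params() -> InputModelParams:
    return InputModelParams()


def default_parent_fraction() -> ParentFractionModel:
    """Biexponential parent fraction with f(0) = 1, calibrated so the plasma
    intact fraction is 0.799 at 90 min."""
    a2, mu2 = 0.1, 0.15
    target = 0.799
    a1 = 1.0 - a2
    mu1 = -math.log((target - a2 * math.exp(-mu2 * 90.0)) / a1) / 90.0
    return ParentFractionModel(a1=a1, mu1=mu1, a2=a2, mu2=mu2)


def default_plasma_to_blood() -> PlasmaToBloodModel:
    """Mildly rising plasma partition: ratio 1.10 at injection, +0.0015/min."""
    return PlasmaToBloodModel(r0=1.10, r1=0.0015)


def default_kinetic_params(genotype: str = "WT") -> TwoTcmParams:
    """Reference 2TCM parameters; the genotype effect enters through k3
    (binding-associated rate) with delivery K1, k2 shared."""
    k3 = {"WT": 0.012, "HET": 0.075}[genotype]
    return TwoTcmParams(K1=0.3, k2=0.15, k3=k3, k4=0.03, vB=0.03)


def simulate_input(
    params: InputModelParams | None = None,
    p2wb: PlasmaToBloodModel | None = None,
    pf: ParentFractionModel | None = None,
    grid_step: float = 0.05,
    t_end: float = 120.0,
) -> InputFunction:
    """Evaluate the blood model on a uniform grid and apply the partition and
    metabolite corrections to obtain the plasma-parent curve."""
    params = params or default_input_params()
    p2wb = p2wb or default_plasma_to_blood()
    pf = pf or default_parent_fraction()
    if grid_step <= 0:
        raise ValidationError("grid step must be positive")
    n = int(round(t_end / grid_step))
    t = np.arange(n + 1) * grid_step
    wb = params(t)
    if np.any(wb < -1e-9):
        raise InvalidModelError("blood model predicts negative activity")
    wb = np.clip(wb, 0.0, None)
    ratio = p2wb(t)
    frac = pf(t)
    if np.any(ratio <= 0):
        raise InvalidModelError("plasma-to-blood ratio nonpositive on the grid")
    if np.any(frac < -1e-12) or np.any(frac > 1 + 1e-9):
        raise InvalidModelError("parent fraction leaves [0, 1] on the grid")
    return InputFunction(times=t, whole_blood=wb, plasma_parent=wb * ratio * frac)


def simulate_blood_samples(
    input_fn: InputFunction | None = None,
    p2wb: PlasmaToBloodModel | None = None,
    pf: ParentFractionModel | None = None,
    times=BLOOD_SAMPLE_TIMES_MIN,
    fraction_sd: float = 0.0,
    ratio_sd: float = 0.0,
    seed: int = 0,
) -> BloodSampleTable:
    """Discrete blood samples consistent with the continuous models, with
    optional Gaussian measurement noise on fractions and ratios."""
    p2wb = p2wb or default_plasma_to_blood()
    pf = pf or default_parent_fraction()
    input_fn = input_fn or simulate_input(p2wb=p2wb, pf=pf)
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    wb = np.interp(t, input_fn.times, input_fn.whole_blood)
    ratio = p2wb(t) + (rng.normal(0.0, ratio_sd, t.size) if ratio_sd > 0 else 0.0)
    frac = pf(t) + (rng.normal(0.0, fraction_sd, t.size) if fraction_sd > 0 else 0.0)
    return BloodSampleTable(
        time=t,
        whole_blood=wb,
        plasma=wb * ratio,
        parent_fraction=np.clip(frac, 0.0, 1.0),
    )


def simulate_tac(
    params: TwoTcmParams,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    noise: NoiseSpec = NoiseSpec(scale=0.0),
    region: str = "region",
) -> TacTable:
    """Frame-averaged 2TCM prediction plus zero-mean Gaussian frame noise.

    Shares the forward model with the kinetics module, so the zero-noise
    output equals ``twotcm_predict`` bit for bit.
    """
    clean = twotcm_predict(params, input_fn, schedule)
    if noise.scale > 0:
        rng = np.random.default_rng(noise.seed)
        sd = noise.scale * np.sqrt(np.clip(clean, 0.0, None) / schedule.durations)
        values = clean + rng.normal(0.0, 1.0, clean.size) * sd
    else:
        values = clean.copy()
    return TacTable(schedule, pd.DataFrame({region: values}))


# ---------------------------------------------------------------------------
# Test-retest cohorts

@dataclass(frozen=True)
class TrtCohortSpec:
    """Variance-component generative model for a two-session cohort.

    value(animal, session) = genotype-region mean
                             + animal effect  ~ N(0, sigma_between^2)
                             + session noise  ~ N(0, sigma_within^2)

    so the generative ICC is sigma_b^2 / (sigma_b^2 + sigma_w^2). Animal
    effects are drawn independently per region.
    """

    n_per_genotype: int = 8
    means: dict = field(
        default_factory=lambda: {"WT": {"striatum": 2.8}, "HET": {"striatum": 7.0}}
    )
    sigma_between: float = 0.5
    sigma_within: float = 0.25
    metric: str = "VT"
    seed: int = 0

    def __post_init__(self):
        if self.n_per_genotype < 2:
            raise ValidationError("need at least 2 animals per genotype")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValidationError("variance-component SDs must be nonnegative")

    @property
    def expected_icc(self) -> float:
        vb, vw = self.sigma_between**2, self.sigma_within**2
        return vb / (vb + vw) if (vb + vw) > 0 else float("nan")


def simulate_trt_cohort(spec: TrtCohortSpec):
    """Long-format cohort records (animal, genotype, session, region, metric,
    value), reproducible under the spec seed."""
    from .reliability import TrtCohort

    rng = np.random.default_rng(spec.seed)
    rows = []
    for genotype, region_means in spec.means.items():
        for i in range(spec.n_per_genotype):
            animal = f"{genotype}{i + 1:03d}"
            for region, mean in region_means.items():
                animal_effect = rng.normal(0.0, spec.sigma_between)
                for session in ("test", "retest"):
                    noise = rng.normal(0.0, spec.sigma_within)
                    rows.append(
                        (animal, genotype, session, region, spec.metric,
                         mean + animal_effect + noise)
                    )
    frame = pd.DataFrame(
        rows, columns=["animal", "genotype", "session", "region", "metric", "value"]
    )
    return TrtCohort(frame)


# ---------------------------------------------------------------------------
# Full synthetic study on disk

@dataclass(frozen=True)
class StudySpec:
    """A two-genotype, two-session synthetic imaging study.

    Biological variability enters through a lognormal animal-level factor on
    k3 (SD ``between_sd`` on the log scale) and a smaller session-level
    factor (``within_sd``); measurement noise is added per frame via
    ``noise_scale``. Doses and weights are drawn near 4.1 MBq and 28 g.
    """

    n_per_genotype: int = 8
    regions: tuple = ("striatum", "motor_cortex", "hippocampus", "thalamus", "cerebellum")
    region_k3_scale: tuple = (1.0, 0.55, 0.7, 0.9, 0.35)
    between_sd: float = 0.15
    within_sd: float = 0.06
    noise_scale: float = 0.05
    fraction_sd: float = 0.01
    ratio_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.regions) != len(self.region_k3_scale):
            raise ValidationError("one k3 scale per region is required")


def write_synthetic_study(out_dir, spec: StudySpec = StudySpec()):
    """Emit a complete study directory: subjects.tsv, blood_samples.tsv and
    one TAC table per (subject, session) with a ``whole_blood`` IDIF column.

    Returns a dict with the ground-truth per-scan V_T values for validation.
    """
    from . import io as pio

    out = Path(out_dir)
    (out / "tacs").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    schedule = make_standard_frame_schedule()
    p2wb = default_plasma_to_blood()
    pf = default_parent_fraction()
    input_fn = simulate_input(p2wb=p2wb, pf=pf)

    blood = simulate_blood_samples(
        input_fn, p2wb, pf,
        fraction_sd=spec.fraction_sd, ratio_sd=spec.ratio_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    pio.write_blood_table(blood, out / "blood_samples.tsv")

    subjects = []
    truth = {}
    for genotype in ("WT", "HET"):
        base = default_kinetic_params(genotype)
        for i in range(spec.n_per_genotype):
            subject = f"{genotype}{i + 1:03d}"
            weight = float(rng.normal(28.0, 2.0))
            animal_factor = float(np.exp(rng.normal(0.0, spec.between_sd)))
            for session in ("test", "retest"):
                dose = float(rng.normal(4.1, 0.33))
                mass = float(rng.uniform(0.2, 0.9))
                subjects.append((subject, genotype, session, dose, weight, mass))
                session_factor = float(np.exp(rng.normal(0.0, spec.within_sd)))
                cols, region_truth = {}, {}
                for region, k3s in zip(spec.regions, spec.region_k3_scale):
                    params = TwoTcmParams(
                        K1=base.K1, k2=base.k2,
                        k3=base.k3 * k3s * animal_factor * session_factor,
                        k4=base.k4, vB=base.vB,
                    )
                    region_truth[region] = params.vt
                    tac = simulate_tac(
                        params, input_fn, schedule,
                        NoiseSpec(spec.noise_scale, int(rng.integers(2**31 - 1))),
                        region=region,
                    )
                    cols[region] = tac.region(region)
                # convert SUV-scale simulation to kBq/mL via dose/weight
                scale = dose * 1000.0 / weight
                frame = pd.DataFrame({k: v * scale for k, v in cols.items()})
                wb_frames = _frame_averaged_wb(input_fn, schedule) * scale
                frame.insert(0, "whole_blood", wb_frames)
                pio.write_tac_table(
                    TacTable(schedule, frame), out / "tacs" / f"{subject}_{session}.tsv"
                )
                truth[(subject, session)] = region_truth
    pio.write_subject_table(pd.DataFrame(
        subjects,
        columns=["subject_id", "genotype", "session", "injected_dose_MBq",
                 "body_weight_g", "injected_mass_ug_per_kg"],
    ), out / "subjects.tsv")
    return {"truth_vt": truth, "schedule": schedule}


def _frame_averaged_wb(input_fn: InputFunction, schedule: FrameSchedule) -> np.ndarray:
    from .kinetics import _frame_average

    return _frame_average(input_fn.times, input_fn.whole_blood, schedule)
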