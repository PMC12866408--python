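"""Compartmental modelling and quantification of time-activity curves.

The reversible two-tissue compartment model (2TCM) describes tracer exchange
between metabolite-corrected plasma (concentration ``C_p``), a free /
nonspecifically-bound tissue compartment and a specifically-bound compartment:

    C_T(t) = h(t) * C_p(t)                              (convolution)
    h(t)   = K1/(a2 - a1) * [(k3 + k4 - a1) e^{-a1 t} + (a2 - k3 - k4) e^{-a2 t}]
    a1,2   = ( (k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4) ) / 2

with rate constants K1 [mL.cm-3.min-1] and k2, k3, k4 [min-1].  The measured
concentration adds a fractional blood-volume term:

    C_model(t) = (1 - vB) C_T(t) + vB C_wb(t)

The total volume of distribution, the primary macro-parameter, is

    V_T = (K1/k2) (1 + k3/k4) = integral of h.

Logan graphical analysis estimates the same V_T for reversible tracers as the
late-time slope of int_0^T C_obs / C_obs(T) against int_0^T C_p / C_obs(T).

SUV normalizes a late-window tissue concentration by injected dose per body
weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .core import FrameSchedule, InputFunction, TacTable
from .errors import (
    DegenerateInputError,
    FitFailureError,
    UnderDeterminedError,
    ValidationError,
)

__all__ = [
    "TwoTcmParams",
    "TwoTcmFit",
    "LoganResult",
    "SuvResult",
    "FitOptions",
    "twotcm_predict",
    "twotcm_curve",
    "fit_2tcm",
    "logan_vt",
    "time_stability",
    "compute_suv",
]


@dataclass(frozen=True)
class TwoTcmParams:
    """Rate constants of the reversible 2TCM plus fractional blood volume."""

    K1: float  # mL.cm-3.min-1
    k2: float  # min-1
    k3: float  # min-1
    k4: float  # min-1
    vB: float = 0.0  # unitless, fraction of the voxel occupied by blood

    def __post_init__(self):
        if self.K1 < 0 or self.k2 <= 0:
            raise ValidationError("require K1 >= 0 and k2 > 0")
        if self.k3 < 0 or self.k4 < 0:
            raise ValidationError("k3 and k4 must be nonnegative")
        if self.k3 > 0 and self.k4 == 0:
            raise ValidationError("reversible model requires k4 > 0 when k3 > 0")
        if not 0.0 <= self.vB <= 0.2:
            raise ValidationError("vB must lie in [0, 0.2]")

    @property
    def vt(self) -> float:
        """Total volume of distribution (K1/k2)(1 + k3/k4)."""
        ratio = self.k3 / self.k4 if self.k3 > 0 else 0.0
        return (self.K1 / self.k2) * (1.0 + ratio)


@dataclass
class TwoTcmFit:
    params: TwoTcmParams
    vt: float
    rss: float  # weighted residual sum of squares
    converged: bool
    n_restarts: int
    flags: list = field(default_factory=list)


@dataclass
class LoganResult:
    vt: float  # slope, mL/cm3
    intercept: float  # minutes
    t_star: float  # minutes
    r_squared: float
    n_points: int
    flags: list = field(default_factory=list)


@dataclass
class SuvResult:
    window: tuple
    mean_concentration: float  # kBq/mL
    suv: float  # g/mL
    injected_dose_mbq: float
    body_weight_g: float
    n_frames: int


def _exp_conv(alpha: float, times: np.ndarray, c: np.ndarray) -> np.ndarray:
    """u(t_i) = int_0^{t_i} exp(-alpha (t_i - s)) c(s) ds, exact for
    piecewise-linear ``c`` on the uniform grid ``times``.

    Implemented as a first-order IIR recursion (scipy.signal.lfilter), which
    is stable for any alpha*dt and O(n).
    """
    dt = times[1] - times[0]
    x = alpha * dt
    if x < 1e-8:  # series limit -> plain trapezoid accumulation
        e = 1.0 - x
        p = q = 0.5 * dt
    else:
        e = np.exp(-x)
        i0 = (1.0 - e) / alpha
        i1 = 1.0 / alpha - i0 / x
        p, q = i0 - i1, i1
    u = lfilter([q, p], [1.0, -e], c)
    if c[0] != 0.0:  # enforce u(0) = 0
        u = u - q * c[0] * e ** np.arange(c.size)
    return u


def _frame_average(times: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Time-average of a gridded curve over each frame interval."""
    cum = cumulative_trapezoid(curve, times, initial=0.0)
    lo = np.interp(schedule.starts, times, cum)
    hi = np.interp(schedule.ends, times, cum)
    return (hi - lo) / schedule.durations


def twotcm_curve(params: TwoTcmParams, input_fn: InputFunction) -> np.ndarray:
    """Model concentration evaluated on the input function's own grid."""
    t = input_fn.times
    s = params.k2 + params.k3 + params.k4
    disc = s * s - 4.0 * params.k2 * params.k4
    disc = max(disc, 0.0)  # numeric guard; analytically nonnegative
    root = np.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if a2 - a1 < 1e-10:  # repeated eigenvalue: nudge apart, error negligible
        a2 = a1 + 1e-10
    if params.K1 > 0:
        u1 = _exp_conv(a1, t, input_fn.plasma_parent)
        u2 = _exp_conv(a2, t, input_fn.plasma_parent)
        ct = (params.K1 / (a2 - a1)) * (
            (params.k3 + params.k4 - a1) * u1 + (a2 - params.k3 - params.k4) * u2
        )
    else:
        ct = np.zeros_like(t)
    return (1.0 - params.vB) * ct + params.vB * input_fn.whole_blood


def twotcm_predict(
    params: TwoTcmParams, input_fn: InputFunction, schedule: FrameSchedule
) -> np.ndarray:
    """Frame-averaged 2TCM prediction (one value per frame)."""
    input_fn.require_coverage(schedule.total_duration)
    return _frame_average(input_fn.times, twotcm_curve(params, input_fn), schedule)


# ---------------------------------------------------------------------------
# Fitting

@dataclass(frozen=True)
class FitOptions:
    """Bounds, weighting and multi-start policy for 2TCM fitting.

    Weights default to the frame duration (longer frames carry more counts);
    ``weights='uniform'`` disables weighting and an array supplies custom
    per-frame weights.
    """

    k1_bounds: tuple = (1e-4, 2.0)
    k_bounds: tuple = (1e-5, 1.0)  # shared for k2, k3, k4
    vb_bounds: tuple = (0.0, 0.2)
    fix_vb: float | None = None
    weights: object = "duration"
    n_restarts: int = 10
    seed: int = 0


def _fit_weights(options: FitOptions, schedule: FrameSchedule) -> np.ndarray:
    if isinstance(options.weights, str):
        if options.weights == "duration":
            return schedule.durations.copy()
        if options.weights == "uniform":
            return np.ones(schedule.n_frames)
        raise ValidationError(f"unknown weights policy {options.weights!r}")
    w = np.asarray(options.weights, dtype=float)
    if w.shape != (schedule.n_frames,) or np.any(w < 0):
        raise ValidationError("weights array must be nonnegative, one per frame")
    return w


def fit_2tcm(
    tac: TacTable,
    input_fn: InputFunction,
    region: str | None = None,
    options: FitOptions = FitOptions(),
) -> TwoTcmFit:
    """Weighted nonlinear least-squares 2TCM fit with seeded multi-start.

    Rates are optimized in log10 space (they span orders of magnitude); vB is
    optimized linearly in [0, 0.2] unless fixed. The first start is a
    mid-range heuristic; the remaining ``n_restarts - 1`` are log-uniform
    draws within bounds from a seeded generator, so the fit is deterministic.
    """
    obs = tac.region(region)
    schedule = tac.schedule
    input_fn.require_coverage(schedule.total_duration)
    if schedule.n_frames < 10:
        raise UnderDeterminedError("2TCM fit requires at least 10 frames")
    if np.allclose(obs, 0.0):
        raise DegenerateInputError("all-zero TAC cannot be fitted")

    w = np.sqrt(_fit_weights(options, schedule))
    lo = np.log10([options.k1_bounds[0]] + [options.k_bounds[0]] * 3)
    hi = np.log10([options.k1_bounds[1]] + [options.k_bounds[1]] * 3)
    fit_vb = options.fix_vb is None
    if fit_vb:
        lo = np.append(lo, options.vb_bounds[0])
        hi = np.append(hi, options.vb_bounds[1])

    def unpack(theta):
        K1, k2, k3, k4 = 10.0 ** theta[:4]
        vb = theta[4] if fit_vb else options.fix_vb
        return TwoTcmParams(K1, k2, k3, k4, vb)

    def residuals(theta):
        return w * (obs - twotcm_predict(unpack(theta), input_fn, schedule))

    rng = np.random.default_rng(options.seed)
    starts = [np.log10([0.3, 0.15, 0.05, 0.03])]
    if fit_vb:
        starts[0] = np.append(starts[0], 0.05)
    for _ in range(max(options.n_restarts - 1, 0)):
        s = lo[:4] + rng.random(4) * (hi[:4] - lo[:4])
        if fit_vb:
            s = np.append(s, rng.uniform(*options.vb_bounds))
        starts.append(s)

    best = None
    n_ok = 0
    for theta0 in starts:
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        except Exception:
            continue
        if not sol.success:
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError("2TCM fit failed to converge on every restart")

    params = unpack(best.x)
    flags = []
    if tac.has_negative:
        flags.append("negative_frames")
    if params.K1 <= options.k1_bounds[0] * 1.01:
        flags.append("K1_at_lower_bound")
    return TwoTcmFit(
        params=params,
        vt=params.vt,
        rss=float(2.0 * best.cost),
        converged=n_ok > 0,
        n_restarts=len(starts),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Logan graphical analysis

def _logan_integrals(obs, mids, input_fn):
    """Cumulative tissue and plasma integrals at every frame midpoint.

    Tissue: trapezoid over (midpoint, frame value) pairs anchored at the
    origin; plasma: accumulated on the input's fine grid, interpolated."""
    t_aug = np.concatenate([[0.0], mids])
    c_aug = np.concatenate([[0.0], obs])
    ct_int = cumulative_trapezoid(c_aug, t_aug, initial=0.0)[1:]
    cp_cum = input_fn.cumulative_plasma_integral()
    cp_int = np.interp(mids, input_fn.times, cp_cum)
    return ct_int, cp_int


def logan_vt(
    tac: TacTable,
    input_fn: InputFunction,
    region: str | None = None,
    t_star: float | str = 30.0,
) -> LoganResult:
    """Logan plot slope over frames with midpoint >= t*.

    Tissue integrals use the trapezoid rule on frame midpoints (anchored at
    the origin); the plasma integral is accumulated on the input's fine grid.
    ``t_star='auto'`` picks the smallest frame start for which the maximum
    relative residual of the linear segment is <= 10%.
    """
    obs = tac.region(region)
    schedule = tac.schedule
    input_fn.require_coverage(schedule.total_duration)
    mids = schedule.midpoints

    def fit_from(ts):
        mask = mids >= ts - 1e-9
        if mask.sum() < 3:
            raise UnderDeterminedError("Logan fit needs >= 3 frames beyond t*")
        if np.any(obs[mask] <= 0):
            raise ValidationError("nonpositive TAC values beyond t*")
        ct_int, cp_int = _logan_integrals(obs, mids, input_fn)
        x = cp_int[mask] / obs[mask]
        y = ct_int[mask] / obs[mask]
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        max_rel = float(np.max(np.abs(y - yhat) / np.abs(y)))
        return slope, intercept, r2, int(mask.sum()), max_rel

    flags = []
    if t_star == "auto":
        candidates = [s for s in schedule.starts if (mids >= s - 1e-9).sum() >= 3]
        best_ts, best_rel = None, np.inf
        chosen = None
        for ts in candidates:
            try:
                res = fit_from(ts)
            except ValidationError:
                continue
            if res[4] <= 0.10:
                chosen, t_star_val = res, float(ts)
                break
            if res[4] < best_rel:
                best_ts, best_rel, best_res = float(ts), res[4], res
        if chosen is None:
            if best_ts is None:
                raise UnderDeterminedError("no usable t* candidate for Logan analysis")
            chosen, t_star_val = best_res, best_ts
            flags.append("auto_t_star_residual_above_10pct")
    else:
        t_star_val = float(t_star)
        chosen = fit_from(t_star_val)

    slope, intercept, r2, n_pts, _ = chosen
    return LoganResult(
        vt=float(slope),
        intercept=float(intercept),
        t_star=t_star_val,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=n_pts,
        flags=flags,
    )


def time_stability(
    tac: TacTable,
    input_fn: InputFunction,
    durations,
    region: str | None = None,
    t_star: float = 30.0,
):
    """Logan V_T under scan truncation, as percent of the full-scan value.

    Returns a pandas DataFrame (duration_min, vt, percent_of_full).
    """
    import pandas as pd

    full = tac.schedule.total_duration
    durations = sorted(float(d) for d in durations)
    if any(d <= t_star for d in durations):
        raise ValidationError("every truncation duration must exceed t*")
    if any(d > full + 1e-9 for d in durations):
        raise ValidationError("truncation duration exceeds the scan length")
    vt_full = logan_vt(tac, input_fn, region, t_star=t_star).vt
    rows = []
    for d in durations:
        sub = tac.truncated(d)
        vt_d = logan_vt(sub, input_fn, region, t_star=t_star).vt
        rows.append((d, vt_d, 100.0 * vt_d / vt_full))
    return pd.DataFrame(rows, columns=["duration_min", "vt", "percent_of_full"])


# ---------------------------------------------------------------------------
# SUV

def compute_suv(
    tac: TacTable,
    injected_dose_mbq: float,
    body_weight_g: float,
    region: str | None = None,
    window: tuple = (100.0, 120.0),
) -> SuvResult:
    """Duration-weighted mean concentration over frames fully inside the
    window, divided by injected dose per body weight.

    kBq/mL divided by (MBq*1000/g = kBq/g) yields g/mL.
    """
    if injected_dose_mbq <= 0 or body_weight_g <= 0:
        raise ValidationError("dose and body weight must be positive")
    lo, hi = float(window[0]), float(window[1])
    schedule = tac.schedule
    if lo < -1e-9 or hi > schedule.total_duration + 1e-9 or hi <= lo:
        raise ValidationError("SUV window must lie within the scan span")
    mask = (schedule.starts >= lo - 1e-9) & (schedule.ends <= hi + 1e-9)
    if not np.any(mask):
        raise ValidationError("no frame lies fully inside the SUV window")
    obs = tac.region(region)
    durs = schedule.durations[mask]
    mean_conc = float(np.sum(obs[mask] * durs) / np.sum(durs))
    suv = mean_conc / (injected_dose_mbq * 1000.0 / body_weight_g)
    return SuvResult(
        window=(lo, hi),
        mean_concentration=mean_conc,
        suv=suv,
        injected_dose_mbq=float(injected_dose_mbq),
        body_weight_g=float(body_weight_g),
        n_frames=int(mask.sum()),
    )
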