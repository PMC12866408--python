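"""Group-level statistics: genotype effect sizes, power planning,
metric-agreement correlations and the four-parameter-logistic mass-dose curve.

Cohen's d uses the pooled-SD convention

    d = (mean_HET - mean_WT) / s_p,
    s_p = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)),

and the genotype percent difference is expressed relative to the WT mean
(so a HET mean above twice the WT mean reads as > 100%). Sample sizes come
from the noncentral-t power function of the two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .errors import (
    FitFailureError,
    UndefinedMetricError,
    UnderDeterminedError,
    ValidationError,
)

__all__ = [
    "EffectSizeResult",
    "PowerSpec",
    "FourPLModel",
    "CorrelationResult",
    "effect_size",
    "power_two_sample_t",
    "sample_size_two_sample_t",
    "d_for_relative_difference",
    "correlate",
    "fit_4pl",
    "welch_tests",
    "power_table",
]


@dataclass
class EffectSizeResult:
    mean_wt: float
    mean_het: float
    sd_pooled: float
    d: float
    percent_difference: float  # 100 * (HET - WT) / WT
    n_wt: int
    n_het: int


@dataclass(frozen=True)
class PowerSpec:
    d: float
    alpha: float = 0.05
    power: float = 0.80
    tails: int = 1

    def __post_init__(self):
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValidationError("alpha and power must lie in (0, 1)")
        if self.d <= 0:
            raise ValidationError("effect size d must be positive")
        if self.tails not in (1, 2):
            raise ValidationError("tails must be 1 or 2")


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    method: str
    n: int


def effect_size(wt, het) -> EffectSizeResult:
    wt = np.asarray(wt, dtype=float)
    het = np.asarray(het, dtype=float)
    if wt.size < 2 or het.size < 2:
        raise UnderDeterminedError("effect size needs >= 2 values per group")
    m_wt, m_het = float(np.mean(wt)), float(np.mean(het))
    s1, s2 = np.var(wt, ddof=1), np.var(het, ddof=1)
    n1, n2 = wt.size, het.size
    sp = float(np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)))
    if sp == 0:
        raise UndefinedMetricError("Cohen's d undefined for zero pooled SD")
    if m_wt <= 0:
        raise ValidationError("percent difference requires a positive WT mean")
    return EffectSizeResult(
        mean_wt=m_wt,
        mean_het=m_het,
        sd_pooled=sp,
        d=(m_het - m_wt) / sp,
        percent_difference=100.0 * (m_het - m_wt) / m_wt,
        n_wt=int(n1),
        n_het=int(n2),
    )


def power_two_sample_t(d: float, n: int, alpha: float = 0.05, tails: int = 1) -> float:
    """Power of an equal-n two-sample t-test at effect size d.

    df = 2n - 2, noncentrality delta = d * sqrt(n/2); exact via the
    noncentral-t distribution.
    """
    if n < 2:
        return 0.0
    df = 2 * n - 2
    delta = d * np.sqrt(n / 2.0)
    if tails == 1:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tcrit, df, delta))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta))


def sample_size_two_sample_t(spec: PowerSpec, n_cap: int = 10**6) -> int:
    """Smallest per-group n >= 2 whose t-test power reaches the target."""
    n = 2
    while power_two_sample_t(spec.d, n, spec.alpha, spec.tails) < spec.power:
        n += 1
        if n > n_cap:
            raise FitFailureError(f"sample size exceeds cap {n_cap}")
    return n


def d_for_relative_difference(mean_ref: float, rel_diff: float, sd_pooled: float) -> float:
    """Effect size implied by a relative group difference: the difference is
    taken as ``rel_diff * mean_ref`` and standardized by ``sd_pooled``."""
    if mean_ref <= 0 or sd_pooled <= 0:
        raise ValidationError("reference mean and pooled SD must be positive")
    return rel_diff * mean_ref / sd_pooled


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise UnderDeterminedError("correlation needs >= 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValidationError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(
        r=float(r), r_squared=float(r * r), p_value=float(p), method=method, n=int(x.size)
    )


# ---------------------------------------------------------------------------
# Four-parameter logistic mass-dose curve

@dataclass
class FourPLModel:
    """4PL on x = log10(mass): y(x) = a + (d - a) / (1 + 10^(b (x - c))).

    ``d`` is the upper (low-mass) asymptote, ``a`` the lower one, ``c`` the
    inflection in log10 mass units and ``b > 0`` the (descending) slope.
    """

    a: float
    b: float
    c: float
    d: float
    flat: bool = False

    def __call__(self, log_mass):
        x = np.asarray(log_mass, dtype=float)
        return self.a + (self.d - self.a) / (1.0 + 10.0 ** (self.b * (x - self.c)))

    def mass_at_drop(self, q: float):
        """Mass at which the prediction has fallen by fraction ``q`` of the
        asymptote span, i.e. where y = d - q (d - a). Returns None when the
        fit is degenerate (flat) or q is outside (0, 1)."""
        if self.flat or not (0.0 < q < 1.0) or self.d == self.a:
            return None
        return 10.0 ** (self.c + np.log10(q / (1.0 - q)) / self.b)


def fit_4pl(log_mass, values) -> FourPLModel:
    """Least-squares 4PL fit of a quantity declining with log10 injected mass."""
    x = np.asarray(log_mass, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 5:
        raise UnderDeterminedError("4PL fit needs >= 5 points")
    span = float(np.ptp(y))
    if span < 1e-12 * max(abs(float(np.mean(y))), 1.0):
        import warnings

        warnings.warn("flat response: asymptotes collapse, 4PL degenerate")
        m = float(np.mean(y))
        return FourPLModel(a=m, b=1.0, c=float(np.median(x)), d=m, flat=True)

    def model(x, a, b, c, d):
        return a + (d - a) / (1.0 + 10.0 ** (b * (x - c)))

    p0 = [float(np.min(y)), 1.0, float(np.median(x)), float(np.max(y))]
    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0,
            bounds=([-np.inf, 1e-6, np.min(x) - 5, -np.inf],
                    [np.inf, 50.0, np.max(x) + 5, np.inf]),
            maxfev=20000, xtol=1e-14, ftol=1e-14,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"4PL fit did not converge: {exc}") from exc
    return FourPLModel(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), d=float(popt[3]))


# ---------------------------------------------------------------------------
# Convenience group tests and the power table

def welch_tests(values_by_region: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Per-region Welch two-sample comparisons (WT vs HET) with Bonferroni
    scaling across regions, plus effect sizes.

    ``values_by_region`` maps region -> (wt_values, het_values).
    """
    rows = []
    m = len(values_by_region)
    for region, (wt, het) in values_by_region.items():
        t, p = stats.ttest_ind(het, wt, equal_var=False)
        es = effect_size(wt, het)
        rows.append({
            "region": region,
            "t": float(t),
            "p": float(p),
            "p_bonferroni": min(float(p) * m, 1.0),
            "cohens_d": es.d,
            "percent_difference": es.percent_difference,
            "significant": bool(p * m < alpha),
        })
    return pd.DataFrame(rows)


def power_table(effect_sizes: dict, alpha: float = 0.05, power: float = 0.80,
                tails: int = 1) -> pd.DataFrame:
    """Per-group sample size for each labelled effect size."""
    rows = []
    for label, d in effect_sizes.items():
        n = sample_size_two_sample_t(PowerSpec(d=d, alpha=alpha, power=power, tails=tails))
        rows.append({
            "label": label, "d": d, "alpha": alpha, "target_power": power,
            "tails": tails, "n_per_group": n,
            "achieved_power": power_two_sample_t(d, n, alpha, tails),
        })
    return pd.DataFrame(rows)
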