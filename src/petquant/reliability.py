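"""Test-retest reliability battery.

Metrics follow the standard imaging-biomarker definitions:

* relative test-retest variability, per animal:
  ``rTRV = 100 * (test - retest) / mean(test, retest)``;
* absolute test-retest variability ``aTRV = |rTRV|``;
* Bland-Altman agreement: bias = mean of the individual rTRV values, limits
  of agreement = bias +/- 1.96 * SD (sample SD, n-1);
* ICC from a mixed model fitted by restricted maximum likelihood: fixed
  effects genotype + session + genotype:session, a random animal intercept,
  and ICC = animal variance component over the sum of positive components.

For balanced two-session data with an intercept-only mean model the REML
animal/residual components coincide exactly with the classical one-way
ANOVA method-of-moments estimators; the profiled-REML solver here converges
to that identity at machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import (
    FitFailureError,
    UndefinedMetricError,
    UnderDeterminedError,
    ValidationError,
)

__all__ = [
    "TrtCohort",
    "BlandAltmanResult",
    "IccResult",
    "rtrv",
    "atrv",
    "bland_altman",
    "icc_reml",
    "anova_icc",
    "trt_report",
]


@dataclass
class TrtCohort:
    """Long-format test-retest records.

    Columns: animal, genotype (WT/HET), session (test/retest), region,
    metric, value. Each (animal, region, metric) must have exactly one test
    and one retest value.
    """

    frame: pd.DataFrame

    REQUIRED = ("animal", "genotype", "session", "region", "metric", "value")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"cohort frame missing columns: {sorted(missing)}")
        bad_session = set(self.frame["session"]) - {"test", "retest"}
        if bad_session:
            raise ValidationError(f"unknown sessions: {sorted(bad_session)}")
        counts = self.frame.groupby(["animal", "region", "metric"])["session"].agg(
            lambda s: sorted(s)
        )
        incomplete = counts[counts.apply(lambda s: s != ["retest", "test"])]
        if len(incomplete):
            raise ValidationError(
                f"incomplete test/retest pairs for {list(incomplete.index[:3])}"
            )
        self.frame = self.frame.reset_index(drop=True)

    @property
    def regions(self):
        return sorted(self.frame["region"].unique())

    @property
    def metrics(self):
        return sorted(self.frame["metric"].unique())

    def pairs(self, region: str, metric: str) -> pd.DataFrame:
        """Wide table (animal, genotype, test, retest) for one region/metric."""
        sub = self.frame[(self.frame["region"] == region) & (self.frame["metric"] == metric)]
        if sub.empty:
            raise ValidationError(f"no records for region={region!r} metric={metric!r}")
        wide = sub.pivot_table(
            index=["animal", "genotype"], columns="session", values="value"
        ).reset_index()
        return wide[["animal", "genotype", "test", "retest"]]

    def subset(self, region: str, metric: str) -> pd.DataFrame:
        return self.frame[
            (self.frame["region"] == region) & (self.frame["metric"] == metric)
        ].copy()


@dataclass
class BlandAltmanResult:
    bias: float  # percent
    sd: float  # percent, n-1 sample SD of individual differences
    limits: tuple  # (lower, upper) percent
    n_pairs: int


@dataclass
class IccResult:
    icc: float
    variance_components: dict  # name -> estimate (metric units squared)
    fixed_effects: dict
    converged: bool
    method: str


def rtrv(test, retest):
    """Relative test-retest variability in percent; sign preserved."""
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    mean = 0.5 * (test + retest)
    if np.any(mean == 0):
        raise UndefinedMetricError("rTRV undefined when the pair mean is zero")
    return 100.0 * (test - retest) / mean


def atrv(test, retest):
    """Absolute test-retest variability in percent: |rTRV|."""
    return np.abs(rtrv(test, retest))


def bland_altman(cohort: TrtCohort, region: str, metric: str) -> BlandAltmanResult:
    """Agreement between sessions using percent differences (rTRV scale)."""
    pairs = cohort.pairs(region, metric)
    if len(pairs) < 2:
        raise UnderDeterminedError("Bland-Altman needs >= 2 complete pairs")
    diffs = rtrv(pairs["test"].to_numpy(), pairs["retest"].to_numpy())
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        bias=bias, sd=sd, limits=(bias - 1.96 * sd, bias + 1.96 * sd), n_pairs=len(pairs)
    )


# ---------------------------------------------------------------------------
# ICC via profiled REML

def _design_matrix(sub: pd.DataFrame, structure: str) -> tuple[np.ndarray, list]:
    if structure == "intercept":
        return np.ones((len(sub), 1)), ["intercept"]
    g = (sub["genotype"] == "HET").to_numpy(dtype=float)
    s = (sub["session"] == "retest").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), g, s, g * s])
    names = ["intercept", "genotype[HET]", "session[retest]", "genotype:session"]
    # drop aliased columns (e.g. single-genotype cohorts)
    keep = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def _reml_profile(lam: float, y, X, group_idx, group_sizes):
    """Negative REML criterion for V = sigma2_e (I + lam Z Z'), profiled over
    beta and sigma2_e, using the closed-form blockwise inverse."""
    n, p = X.shape
    shrink = lam / (1.0 + group_sizes * lam)  # per group

    def vinv(M):
        gs = np.zeros((len(group_sizes), M.shape[1]))
        np.add.at(gs, group_idx, M)
        return M - (shrink[:, None] * gs)[group_idx]

    Xv = vinv(X)
    A = X.T @ Xv
    b = Xv.T @ y
    beta = np.linalg.solve(A, b)
    r = y - X @ beta
    q = float(r @ vinv(r[:, None])[:, 0])
    logdet_v = float(np.sum(np.log1p(group_sizes * lam)))
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0 or q <= 0:
        return np.inf, beta, q
    crit = logdet_v + logdet_a + (n - p) * np.log(q)
    return crit, beta, q


def _reml_score(lam: float, y, X, group_idx, group_sizes):
    """Derivative of the profiled negative REML criterion with respect to
    the variance ratio lam = sigma2_animal / sigma2_residual."""
    n, p = X.shape
    shrink = lam / (1.0 + group_sizes * lam)

    def vinv(M):
        gs = np.zeros((len(group_sizes), M.shape[1]))
        np.add.at(gs, group_idx, M)
        return M - (shrink[:, None] * gs)[group_idx]

    Xv = vinv(X)
    A = X.T @ Xv
    beta = np.linalg.solve(A, Xv.T @ y)
    rp = vinv((y - X @ beta)[:, None])[:, 0]
    q = float((y - X @ beta) @ rp)
    # group sums of V^-1 X and of P y
    sX = np.zeros((len(group_sizes), p))
    np.add.at(sX, group_idx, Xv)
    sr = np.zeros(len(group_sizes))
    np.add.at(sr, group_idx, rp)
    d_logdet_v = float(np.sum(group_sizes / (1.0 + group_sizes * lam)))
    d_logdet_a = -float(np.einsum("gi,ig->", sX, np.linalg.solve(A, sX.T)))
    d_q = -float(np.sum(sr**2))
    return d_logdet_v + d_logdet_a + (n - p) * d_q / q


def _fit_random_intercept_reml(y, X, groups):
    from scipy.optimize import brentq

    codes, _ = pd.factorize(groups)
    group_sizes = np.bincount(codes).astype(float)
    n, p = X.shape
    if n <= p:
        raise UnderDeterminedError("more fixed-effect parameters than observations")

    # degenerate case: no within-animal variability at all -> ICC = 1
    gmeans = np.zeros(len(group_sizes))
    np.add.at(gmeans, codes, y)
    gmeans /= group_sizes
    ssw = float(np.sum((y - gmeans[codes]) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if ssw <= 1e-14 * max(sst, 1e-300):
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid_means = np.zeros(len(group_sizes))
        np.add.at(resid_means, codes, y - X @ beta)
        resid_means /= group_sizes
        return float(np.var(resid_means, ddof=1)), 0.0, beta

    score0 = _reml_score(0.0, y, X, codes, group_sizes)
    if score0 >= 0:  # criterion increasing at 0: boundary solution
        lam = 0.0
    else:
        hi = 1.0
        while _reml_score(hi, y, X, codes, group_sizes) < 0:
            hi *= 4.0
            if hi > 1e12:
                raise FitFailureError("REML score has no sign change; fit diverged")
        lam = float(brentq(
            _reml_score, 0.0, hi, args=(y, X, codes, group_sizes),
            xtol=1e-14, rtol=8.9e-16, maxiter=300,
        ))
    crit, beta, q = _reml_profile(lam, y, X, codes, group_sizes)
    if not np.isfinite(crit):
        raise FitFailureError("REML criterion is not finite")
    sigma2_e = q / (n - p)
    return lam * sigma2_e, sigma2_e, beta


def icc_reml(
    cohort: TrtCohort,
    region: str,
    metric: str,
    fixed: str = "auto",
    extra_random_terms: bool = False,
) -> IccResult:
    """Variance-component ICC by restricted maximum likelihood.

    The default model has fixed effects genotype + session + interaction
    (``fixed='auto'`` drops aliased terms, e.g. for one-genotype cohorts;
    ``fixed='intercept'`` forces the structure-free mean model) and a random
    animal intercept. ICC = sigma2_animal / sum of positive components;
    negative estimates are truncated at zero and excluded from the sum.

    ``extra_random_terms`` additionally requests animal-by-genotype and
    animal-by-session random components via statsmodels MixedLM. With one
    observation per (animal, session) both terms are degenerate (the first is
    confounded with the animal intercept, the second with the residual), so
    their estimates collapse toward zero and the ICC is unchanged — they are
    provided to document exactly that.
    """
    sub = cohort.subset(region, metric)
    animals = sub["animal"].to_numpy()
    if len(np.unique(animals)) < 4:
        raise UnderDeterminedError("ICC needs >= 4 animals")
    y = sub["value"].to_numpy(dtype=float)
    structure = "full" if fixed == "auto" else fixed
    X, names = _design_matrix(sub, structure)

    if extra_random_terms:
        return _icc_mixedlm_extra(sub, y, names, X)

    var_animal, var_resid, beta = _fit_random_intercept_reml(y, X, animals)
    components = {"animal": max(var_animal, 0.0), "residual": max(var_resid, 0.0)}
    denom = sum(v for v in components.values() if v > 0)
    icc = components["animal"] / denom if denom > 0 else float("nan")
    return IccResult(
        icc=float(icc),
        variance_components=components,
        fixed_effects=dict(zip(names, np.asarray(beta, dtype=float))),
        converged=True,
        method="profiled-REML",
    )


def _icc_mixedlm_extra(sub, y, names, X):
    import statsmodels.formula.api as smf

    data = sub.copy()
    data["gs"] = data["genotype"].astype(str)
    data["ss"] = data["session"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ gs * ss" if len(set(data["gs"])) > 1 else "value ~ ss",
            data,
            groups=data["animal"],
            re_formula="1",
            vc_formula={"animal_x_session": "0 + C(ss)"},
        )
        fit = model.fit(reml=True)
    var_animal = float(fit.cov_re.iloc[0, 0])
    var_vc = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    var_resid = float(fit.scale)
    components = {
        "animal": max(var_animal, 0.0),
        "animal_x_session": max(var_vc, 0.0),
        "residual": max(var_resid, 0.0),
    }
    denom = sum(v for v in components.values() if v > 0)
    return IccResult(
        icc=components["animal"] / denom if denom > 0 else float("nan"),
        variance_components=components,
        fixed_effects=dict(fit.params.items()),
        converged=bool(fit.converged),
        method="MixedLM-REML",
    )


def anova_icc(values: np.ndarray, animals: np.ndarray) -> tuple[float, float, float]:
    """Closed-form one-way ANOVA (method-of-moments) variance components.

    Returns (icc, sigma2_between, sigma2_within) for balanced designs with k
    observations per animal; the textbook ICC(1) estimator.
    """
    df = pd.DataFrame({"a": animals, "y": np.asarray(values, dtype=float)})
    groups = df.groupby("a")["y"]
    k_each = groups.size()
    if k_each.nunique() != 1:
        raise ValidationError("anova_icc requires a balanced design")
    k = int(k_each.iloc[0])
    n = len(k_each)
    grand = df["y"].mean()
    ssb = float((k * (groups.mean() - grand) ** 2).sum())
    ssw = float(((df["y"] - groups.transform("mean")) ** 2).sum())
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    sigma2_w = msw
    sigma2_b = max((msb - msw) / k, 0.0)
    denom = sigma2_b + sigma2_w
    return (sigma2_b / denom if denom > 0 else float("nan")), sigma2_b, sigma2_w


def trt_report(cohort: TrtCohort) -> pd.DataFrame:
    """Reliability summary per region and metric: rTRV / aTRV mean and SD by
    genotype, plus the pooled-genotype ICC."""
    rows = []
    for metric in cohort.metrics:
        for region in cohort.regions:
            pairs = cohort.pairs(region, metric)
            rec = {"metric": metric, "region": region}
            for genotype in sorted(pairs["genotype"].unique()):
                g = pairs[pairs["genotype"] == genotype]
                r = rtrv(g["test"].to_numpy(), g["retest"].to_numpy())
                rec[f"rTRV_mean_{genotype}"] = float(np.mean(r))
                rec[f"rTRV_sd_{genotype}"] = float(np.std(r, ddof=1))
                rec[f"aTRV_mean_{genotype}"] = float(np.mean(np.abs(r)))
                rec[f"aTRV_sd_{genotype}"] = float(np.std(np.abs(r), ddof=1))
            rec["ICC"] = icc_reml(cohort, region, metric).icc
            ba = bland_altman(cohort, region, metric)
            rec["BA_bias"] = ba.bias
            rec["BA_lower"] = ba.limits[0]
            rec["BA_upper"] = ba.limits[1]
            rows.append(rec)
    return pd.DataFrame(rows)
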