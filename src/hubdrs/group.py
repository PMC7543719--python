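"""Group-level inference: outcome discrimination and duration models.

Outcome side: the AUC for separating not-seizure-free from seizure-free
subjects by their D_RS values (values above 0.5 mean seizure-free subjects
have *lower* D_RS), a logit-scale confidence interval built from the
Hanley–McNeil standard error, and a one-tailed Mann–Whitney rank-sum test.

Duration side: mean functional connectivity (mean of all connections of the
full epoch-mean matrix, inter-hemispheric included) regressed on log10
epilepsy duration — per segment with a Tukey-bisquare robust linear fit,
and across segments with a linear mixed model using a random intercept per
segment.  Both report a likelihood-ratio p-value against the
intercept-only null; for the robust fit the likelihood is a Gaussian
quasi-likelihood evaluated at the robust parameter estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .connectivity import ConnectivityMatrix
from .drs import rank_auc
from .simulate import OUTCOME_NOT_SEIZURE_FREE, OUTCOME_SEIZURE_FREE

BISQUARE_TUNING = 4.685  # standard 95%-efficiency constant

COHORT_COLUMNS = (
    "subject_id", "segment", "drs", "mean_fc", "outcome", "duration_years",
)


@dataclass(frozen=True)
class GroupAucResult:
    auc: float
    ci_low: float
    ci_high: float
    level: float
    n1: int  # seizure-free group size
    n2: int  # not-seizure-free group size
    p_one_tailed: float
    p_method: str

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class DurationModelResult:
    slope: float        # mean-FC units per log10(year)
    intercept: float
    slope_se: float
    adjusted_r2: float  # NaN for the mixed model
    lrt_p: float
    model_kind: str     # "robust_ols" or "lme_random_intercept"
    n_obs: int


@dataclass(frozen=True)
class RanksumResult:
    p_value: float
    method: str  # "exact", "asymptotic" or "degenerate"


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if (table["duration_years"] <= 0).any():
        raise ValueError("durations must be positive")
    bad = set(table["outcome"]) - {OUTCOME_SEIZURE_FREE, OUTCOME_NOT_SEIZURE_FREE}
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    return table


def mean_fc(fc: ConnectivityMatrix) -> float:
    """Mean of all connections: strict upper triangle of the full matrix.

    Must be called on the unmasked epoch-mean matrix — inter-hemispheric
    connections are part of the average.
    """
    n = fc.values.shape[0]
    if n < 2:
        raise ValueError("mean FC needs at least a 2x2 matrix")
    iu = np.triu_indices(n, k=1)
    vals = fc.values[iu]
    if np.isnan(vals).any():
        raise ValueError(
            "matrix contains masked entries; mean FC is defined on the full "
            "(unmasked) matrix"
        )
    return float(vals.mean())


def group_auc(
    drs_seizure_free: np.ndarray, drs_not_seizure_free: np.ndarray
) -> float:
    """AUC = P(D_RS of not-seizure-free > D_RS of seizure-free) + 0.5 ties."""
    return rank_auc(np.asarray(drs_seizure_free, float),
                    np.asarray(drs_not_seizure_free, float))


def auc_logit_ci(
    auc: float, n1: int, n2: int, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for an AUC via Hanley–McNeil SE on the logit scale.

    SE^2 = [A(1-A) + (n1-1)(Q1 - A^2) + (n2-1)(Q2 - A^2)] / (n1 n2) with
    Q1 = A/(2-A), Q2 = 2A^2/(1+A); the interval is built symmetrically on
    the logit scale with SE_logit = SE / (A(1-A)) and mapped back, so both
    bounds always lie strictly inside (0, 1).
    """
    if not (0 < auc < 1):
        raise ValueError(
            "logit CI undefined for a degenerate AUC of 0 or 1; report the "
            "degenerate interval explicitly"
        )
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    a = float(auc)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    se2 = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
    se_logit = np.sqrt(se2) / (a * (1 - a))
    z = stats.norm.ppf((1 + level) / 2)
    lo_logit = np.log(a / (1 - a)) - z * se_logit
    hi_logit = np.log(a / (1 - a)) + z * se_logit
    expit = lambda t: 1.0 / (1.0 + np.exp(-t))  # noqa: E731
    return float(expit(lo_logit)), float(expit(hi_logit))


def ranksum_one_tailed(x, y, alternative: str = "x_less") -> RanksumResult:
    """One-tailed Mann–Whitney rank-sum test.

    Tests the alternative that ``x`` is stochastically smaller than ``y``
    (pass ``alternative="x_greater"`` for the reverse).  Uses the exact null
    distribution for small tie-free samples (n1 + n2 <= 12), otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("x_less", "x_greater"):
        raise ValueError("alternative must be 'x_less' or 'x_greater'")
    alt = "less" if alternative == "x_less" else "greater"
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # every observation identical: all rank assignments are equivalent
        return RanksumResult(p_value=1.0, method="degenerate")
    if x.size + y.size <= 12 and not has_ties:
        p = stats.mannwhitneyu(x, y, alternative=alt, method="exact").pvalue
        return RanksumResult(p_value=float(p), method="exact")
    p = stats.mannwhitneyu(
        x, y, alternative=alt, method="asymptotic", use_continuity=True
    ).pvalue
    return RanksumResult(p_value=float(p), method="asymptotic")


def outcome_group_stats(
    table: pd.DataFrame, segment: int, level: float = 0.95
) -> GroupAucResult:
    """AUC, logit CI and one-tailed rank-sum p for one segment's D_RS."""
    table = validate_cohort_table(table)
    seg = table[table["segment"] == segment]
    x = seg.loc[seg["outcome"] == OUTCOME_SEIZURE_FREE, "drs"].to_numpy()
    y = seg.loc[seg["outcome"] == OUTCOME_NOT_SEIZURE_FREE, "drs"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError(f"segment {segment}: both outcome groups must be present")
    auc = group_auc(x, y)
    if 0 < auc < 1:
        lo, hi = auc_logit_ci(auc, x.size, y.size, level)
    else:
        lo, hi = auc, auc  # degenerate separation: zero-width interval
    rs = ranksum_one_tailed(x, y, alternative="x_less")
    return GroupAucResult(
        auc=auc, ci_low=lo, ci_high=hi, level=level,
        n1=int(x.size), n2=int(y.size),
        p_one_tailed=rs.p_value, p_method=rs.method,
    )


def _gaussian_loglik(resid: np.ndarray) -> float:
    """Gaussian log-likelihood at MLE scale for a residual vector."""
    n = resid.size
    s2 = float(np.mean(resid**2))
    if s2 == 0:
        return np.inf
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def fit_duration_robust(mean_fc_values, duration_years) -> DurationModelResult:
    """Tukey-bisquare robust regression of mean FC on log10 duration.

    Iteratively reweighted least squares with the standard tuning constant
    4.685.  Adjusted R^2 uses bisquare-weighted sums of squares.  The LRT
    p-value compares Gaussian quasi-likelihoods of the full fit and a
    robust intercept-only fit on one chi-square degree of freedom; it is a
    quasi-likelihood ratio, since M-estimation has no canonical likelihood.
    """
    y = np.asarray(mean_fc_values, dtype=float)
    dur = np.asarray(duration_years, dtype=float)
    if y.size != dur.size:
        raise ValueError("mean_fc and duration vectors differ in length")
    if y.size < 3:
        raise ValueError("robust duration fit needs at least 3 subjects")
    if np.any(dur <= 0):
        raise ValueError("durations must be positive")
    x = np.log10(dur)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 duration")
    X = sm.add_constant(x)
    norm = sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.RLM(y, X, M=norm).fit()
        fit0 = sm.RLM(y, np.ones((y.size, 1)), M=norm).fit()
    w = fit.weights
    ybar_w = np.sum(w * y) / np.sum(w)
    ss_res = float(np.sum(w * fit.resid**2))
    ss_tot = float(np.sum(w * (y - ybar_w) ** 2))
    r2_w = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    n = y.size
    adj_r2 = 1.0 - (1.0 - r2_w) * (n - 1) / (n - 2)
    ll1 = _gaussian_loglik(fit.resid)
    ll0 = _gaussian_loglik(fit0.resid)
    if np.isinf(ll1):
        lrt_p = 1.0 if np.isinf(ll0) else 0.0
    else:
        lr = max(0.0, 2.0 * (ll1 - ll0))
        lrt_p = float(stats.chi2.sf(lr, df=1))
    return DurationModelResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        adjusted_r2=float(adj_r2),
        lrt_p=lrt_p,
        model_kind="robust_ols",
        n_obs=int(n),
    )


def fit_duration_lme(mean_fc_values, duration_years, segment) -> DurationModelResult:
    """Mixed model: mean FC ~ 1 + log10(duration) + (1 | segment), ML fit.

    The likelihood-ratio test compares against the intercept-only mixed
    model on one degree of freedom.  A single segment makes the random
    intercept unidentifiable — use :func:`fit_duration_robust` instead.
    """
    y = np.asarray(mean_fc_values, dtype=float)
    dur = np.asarray(duration_years, dtype=float)
    seg = np.asarray(segment)
    if not (y.size == dur.size == seg.size):
        raise ValueError("mean_fc, duration and segment vectors differ in length")
    if np.unique(seg).size < 2:
        raise ValueError(
            "mixed model needs >= 2 segments; use fit_duration_robust for a "
            "single segment"
        )
    if y.size < 3:
        raise ValueError("mixed duration fit needs at least 3 subjects")
    if np.any(dur <= 0):
        raise ValueError("durations must be positive")
    x = np.log10(dur)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(y, X, groups=seg).fit(reml=False)
        null = sm.MixedLM(y, np.ones((y.size, 1)), groups=seg).fit(reml=False)
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    return DurationModelResult(
        slope=float(full.fe_params[1]),
        intercept=float(full.fe_params[0]),
        slope_se=float(full.bse_fe[1]),
        adjusted_r2=float("nan"),
        lrt_p=float(stats.chi2.sf(lr, df=1)),
        model_kind="lme_random_intercept",
        n_obs=int(y.size),
    )
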