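"""Causal estimators on a harmonized variant set.

All estimators combine per-variant Wald ratios beta_out/beta_exp.  IVW
(inverse-variance weighted meta-analysis of the ratios, equivalently weighted
least squares of beta_out on beta_exp through the origin) is the primary
estimator; MR-Egger (unconstrained intercept absorbing directional pleiotropy)
and the weighted median (consistent while <50% of instrument weight is
invalid) are the standard complementary methods.  Effects are on the log-odds
scale for binary traits, so exp(beta) is an odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .exceptions import DegenerateInstrumentError, InsufficientInstrumentsError
from .gwas import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """One method's causal estimate.

    ``beta`` is the causal effect on the log-OR scale; ``or_`` and its CI are
    the exponentiated versions.  Method-specific extras (e.g. the Egger
    intercept triple, Cochran's Q for auto-mode IVW) live in ``extras``.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))

    @classmethod
    def _from_beta_se(
        cls, method: str, beta: float, se: float, n_snp: int, df: int | None = None, **extras
    ) -> "MREstimate":
        """Build with a normal (df None) or t-distribution CI and p-value."""
        if df is None:
            crit = Z95
            pval = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
        else:
            crit = stats.t.ppf(0.975, df)
            pval = 2 * stats.t.sf(abs(beta / se), df) if se > 0 else (1.0 if beta == 0 else 0.0)
        pval = float(min(max(pval, np.finfo(float).tiny), 1.0))
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - crit * se),
            ci_high=float(beta + crit * se),
            pval=pval,
            n_snp=n_snp,
            extras=dict(extras),
        )


def _arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    return hset.beta_exp, hset.se_exp, hset.beta_out, hset.se_out


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-variant causal estimate beta_out/beta_exp.

    First-order SE (default) is se_out/|beta_exp|; the second-order option
    adds the delta-method term for sampling error in beta_exp:
    sqrt(se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4).
    """
    if beta_exp == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for beta_exp = 0")
    ratio = beta_out / beta_exp
    if second_order:
        se = np.sqrt(se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4)
    else:
        se = se_out / abs(beta_exp)
    return MREstimate._from_beta_se("wald", ratio, se, 1)


def _ratio_arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios and their first-order inverse-variance weights."""
    bx, _, by, sy = _arrays(hset)
    if np.any(bx == 0):
        raise DegenerateInstrumentError("Wald ratio undefined for beta_exp = 0")
    ratios = by / bx
    weights = bx**2 / sy**2  # = 1/se_ratio^2 with se_ratio = se_out/|beta_exp|
    return ratios, weights


def _ivw_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """Fixed-effect IVW point estimate and SE (WLS through the origin)."""
    w = 1.0 / sy**2
    den = float(np.sum(bx**2 * w))
    num = float(np.sum(bx * by * w))
    theta = num / den
    se = float(np.sqrt(1.0 / den))
    return theta, se


def ivw(hset: HarmonizedSet, mode: str = "auto") -> MREstimate:
    """Inverse-variance weighted estimate.

    theta = sum(bx*by/sy^2) / sum(bx^2/sy^2); fixed-effect SE is
    sqrt(1/sum(bx^2/sy^2)).  Random-effects uses multiplicative
    overdispersion: SE scaled by max(1, sqrt(Q/(J-1))) with Cochran's Q
    evaluated at the IVW estimate.  ``mode="auto"`` (the default, matching
    common practice of switching to random effects when heterogeneity is
    detected) selects random iff the Q p-value < 0.05.  A single retained
    pair degenerates to the Wald ratio, flagged in extras.
    """
    if mode not in ("fixed", "random", "auto"):
        raise ValueError(f"mode must be fixed|random|auto, got {mode!r}")
    bx, sx, by, sy = _arrays(hset)
    J = len(bx)
    if J == 0:
        raise InsufficientInstrumentsError("IVW requires at least one variant pair")
    if J == 1:
        est = wald_ratio(bx[0], sx[0], by[0], sy[0])
        est.method = "ivw_fixed"
        est.extras["degenerate_single_snp"] = True
        return est

    theta, se_fixed = _ivw_point(bx, by, sy)
    ratios, weights = _ratio_arrays(hset)
    q = float(np.sum(weights * (ratios - theta) ** 2))
    q_df = J - 1
    q_pval = float(stats.chi2.sf(q, q_df))
    scale = max(1.0, np.sqrt(q / q_df))
    if mode == "fixed":
        se, method = se_fixed, "ivw_fixed"
    elif mode == "random":
        se, method = se_fixed * scale, "ivw_random"
    else:
        if q_pval < 0.05:
            se, method = se_fixed * scale, "ivw_random"
        else:
            se, method = se_fixed, "ivw_fixed"
    return MREstimate._from_beta_se(
        method, theta, se, J, q=q, q_df=q_df, q_pval=q_pval, se_fixed=se_fixed
    )


def mr_egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted regression of beta_out on beta_exp with
    an unconstrained intercept.

    Each pair is first oriented so beta_exp >= 0 (both betas negated when
    beta_exp < 0).  Weights are 1/se_out^2.  The slope is the causal
    estimate; the intercept (average directional pleiotropy) with its SE and
    p-value is stored in extras.  SEs use multiplicative overdispersion
    floored at 1; inference from the t distribution with J-2 df.
    """
    bx, _, by, sy = _arrays(hset)
    J = len(bx)
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >=3 pairs, got {J}")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2

    X = np.column_stack([np.ones(J), x])
    XtW = X.T * w
    xtwx = XtW @ X
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ (XtW @ y)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (J - 2))
    scale = max(1.0, sigma2)
    se_coef = np.sqrt(np.diag(cov_unscaled) * scale)

    alpha0, slope = float(coef[0]), float(coef[1])
    se_alpha0, se_slope = float(se_coef[0]), float(se_coef[1])
    df = J - 2
    p_alpha0 = float(2 * stats.t.sf(abs(alpha0 / se_alpha0), df)) if se_alpha0 > 0 else 1.0
    return MREstimate._from_beta_se(
        "egger",
        slope,
        se_slope,
        J,
        df=df,
        intercept=alpha0,
        intercept_se=se_alpha0,
        intercept_pval=p_alpha0,
        overdispersion=sigma2,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median.

    Sort ratios; cumulative percentile p_j = 100*(S_j - w_j/2)/S_total with
    S_j the cumulative weight; linearly interpolate the ratio at the 50th
    percentile.
    """
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    s = np.cumsum(w)
    total = s[-1]
    perc = 100.0 * (s - w / 2.0) / total
    if 50.0 <= perc[0]:
        return float(r[0])
    if 50.0 >= perc[-1]:
        return float(r[-1])
    return float(np.interp(50.0, perc, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Per-variant Wald ratios receive first-order inverse-variance weights; the
    estimate is the interpolated 50th weighted percentile.  The SE is the SD
    of the estimate over ``n_boot`` parametric resamples of (beta_exp,
    beta_out) from their normal sampling distributions (seeded).
    """
    bx, sx, by, sy = _arrays(hset)
    J = len(bx)
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted median requires >=3 pairs, got {J}")
    ratios, weights = _ratio_arrays(hset)
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, J))
    by_b = rng.normal(by, sy, size=(n_boot, J))
    # degenerate resampled exposure effects would blow up the ratio; nudge off zero
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        r_i = by_b[i] / bx_b[i]
        w_i = bx_b[i] ** 2 / sy**2
        boots[i] = _weighted_median_point(r_i, w_i)
    se = float(np.std(boots, ddof=1))
    if se == 0:  # degenerate (e.g. zero SEs in input); avoid division by zero
        se = float(np.finfo(float).tiny)
    return MREstimate._from_beta_se("weighted_median", point, se, J, n_boot=n_boot)


def all_estimates(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None, ivw_mode: str = "auto"
) -> list[MREstimate]:
    """IVW plus the complementary estimators, where instrument counts allow."""
    out = [ivw(hset, mode=ivw_mode)]
    if len(hset) >= 3:
        out.append(weighted_median(hset, n_boot=n_boot, seed=seed))
        out.append(mr_egger(hset))
    return out
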