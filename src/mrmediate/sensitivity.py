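"""Sensitivity diagnostics for one harmonized MR analysis.

Four standard checks of the instrumental-variable assumptions:

- Cochran's Q: heterogeneity across per-variant ratio estimates (chi-square
  with J-1 df under homogeneity);
- MR-Egger intercept: average directional pleiotropy;
- MR-PRESSO: simulation-based residual-sum-of-squares global test, per-variant
  outlier test (Bonferroni-adjusted), and distortion test comparing the
  estimate with and without flagged outliers;
- leave-one-out: influence of each single variant on the IVW estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import _ivw_point, _ratio_arrays, mr_egger
from .exceptions import InsufficientInstrumentsError
from .gwas import HarmonizedSet


def cochran_q(hset: HarmonizedSet, theta_ref: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic.

    Q = sum_j w_j (ratio_j - theta_ref)^2 with first-order Wald-ratio weights
    w_j = beta_exp_j^2 / se_out_j^2; p-value from chi-square with J-1 df.
    ``theta_ref`` defaults to the fixed-effect IVW estimate, which minimises Q.
    """
    if len(hset) < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >=2 pairs")
    ratios, weights = _ratio_arrays(hset)
    if theta_ref is None:
        theta_ref = float(np.sum(weights * ratios) / np.sum(weights))
    q = float(np.sum(weights * (ratios - theta_ref) ** 2))
    q_df = len(ratios) - 1
    return q, q_df, float(stats.chi2.sf(q, q_df))


def egger_intercept_test(hset: HarmonizedSet) -> tuple[float, float, float]:
    """MR-Egger intercept (average directional pleiotropy), its SE and p."""
    est = mr_egger(hset)
    return est.extras["intercept"], est.extras["intercept_se"], est.extras["intercept_pval"]


def leave_one_out(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-variant table of fixed-effect IVW estimates with that variant removed.

    The ``influential`` flag marks variants whose removal changes the sign of
    the estimate, or moves its p-value across 0.05 when the full-set p was
    below 0.05 (flagged, never auto-removed).
    """
    if len(hset) < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >=3 pairs")
    bx, by, sy = hset.beta_exp, hset.beta_out, hset.se_out
    w = 1.0 / sy**2
    num_j = bx * by * w
    den_j = bx**2 * w
    num_tot, den_tot = num_j.sum(), den_j.sum()

    theta_full = num_tot / den_tot
    se_full = np.sqrt(1.0 / den_tot)
    p_full = 2 * stats.norm.sf(abs(theta_full / se_full))

    theta_loo = (num_tot - num_j) / (den_tot - den_j)
    se_loo = np.sqrt(1.0 / (den_tot - den_j))
    p_loo = 2 * stats.norm.sf(np.abs(theta_loo / se_loo))
    influential = (np.sign(theta_loo) != np.sign(theta_full)) | (
        (p_full < 0.05) & (p_loo >= 0.05)
    )
    return pd.DataFrame(
        {
            "variant_id": hset.variant_ids,
            "beta": theta_loo,
            "se": se_loo,
            "pval": p_loo,
            "influential": influential,
        }
    )


@dataclass
class PressoResult:
    global_pval: float
    outliers: list[str]
    distortion_pval: float | None
    outlier_pvals: dict[str, float] = field(default_factory=dict)
    beta_all: float | None = None
    beta_corrected: float | None = None


def _loo_theta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, vectorised over j."""
    w = 1.0 / sy**2
    num_j = bx * by * w
    den_j = bx**2 * w
    return (num_j.sum() - num_j) / (den_j.sum() - den_j)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    Global test: observed RSS = sum_j w_j (beta_out_j - theta_(-j) beta_exp_j)^2
    with w_j = 1/se_out_j^2 and theta_(-j) the leave-one-out IVW estimate; the
    null distribution simulates beta_out_j* ~ N(theta_(-j) beta_exp_j,
    se_out_j^2) for all j (``n_sim`` replicates, leave-one-out estimates
    recomputed on each simulated set).  Empirical p-values use the add-one
    convention (1 + #{sim >= obs})/(1 + n_sim), so p >= 1/(n_sim+1).

    Outlier test: each variant's observed weighted squared residual against
    its simulated distribution, Bonferroni-adjusted by J; flagged when the
    adjusted p < ``outlier_alpha``.

    Distortion test: the shift in the IVW estimate after removing flagged
    outliers, compared with a null built from 1000 random same-size subsets
    drawn from the non-flagged variants (seeded), so the null reflects the
    removal of ordinary variants only.  Absent when no outlier is flagged.
    """
    J = len(hset)
    if J < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >=4 pairs, got {J}")
    rng = np.random.default_rng(seed)
    bx, by, sy = hset.beta_exp, hset.beta_out, hset.se_out
    w = 1.0 / sy**2

    theta_loo = _loo_theta(bx, by, sy)
    resid2_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid2_obs.sum())

    # simulated null: resample outcome betas about the LOO-predicted values
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    num_j = bx * by_sim * w  # (n_sim, J)
    den_j = bx**2 * w  # (J,)
    theta_loo_sim = (num_j.sum(axis=1, keepdims=True) - num_j) / (den_j.sum() - den_j)
    resid2_sim = w * (by_sim - theta_loo_sim * bx) ** 2
    rss_sim = resid2_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    p_out = (1 + np.sum(resid2_sim >= resid2_obs, axis=0)) / (1 + n_sim)
    p_adj = np.minimum(1.0, p_out * J)
    outlier_mask = p_adj < outlier_alpha
    vids = hset.variant_ids
    outliers = [vids[j] for j in np.flatnonzero(outlier_mask)]

    beta_all, _ = _ivw_point(bx, by, sy)
    distortion_pval = None
    beta_corrected = None
    if outliers and len(outliers) < J:
        keep = ~outlier_mask
        beta_corrected, _ = _ivw_point(bx[keep], by[keep], sy[keep])
        d_obs = beta_corrected - beta_all
        k = int(outlier_mask.sum())
        nonflagged = np.flatnonzero(keep)
        if len(nonflagged) > k:
            n_subsets = 1000
            d_null = np.empty(n_subsets)
            for i in range(n_subsets):
                drop = rng.choice(nonflagged, size=k, replace=False)
                mask = np.ones(J, bool)
                mask[drop] = False
                theta_i, _ = _ivw_point(bx[mask], by[mask], sy[mask])
                d_null[i] = theta_i - beta_all
            distortion_pval = float(
                (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1 + n_subsets)
            )
    return PressoResult(
        global_pval=global_pval,
        outliers=outliers,
        distortion_pval=distortion_pval,
        outlier_pvals=dict(zip(vids, p_adj)),
        beta_all=beta_all,
        beta_corrected=beta_corrected,
    )


@dataclass
class SensitivityReport:
    """Bundle of diagnostics for one analysis, with summary flags."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_pval: float | None
    presso_global_pval: float | None
    presso_outliers: list[str]
    presso_distortion_pval: float | None
    loo: pd.DataFrame | None
    heterogeneity_detected: bool
    pleiotropy_detected: bool
    influential_snp_detected: bool

    @property
    def any_flag(self) -> bool:
        return self.heterogeneity_detected or self.pleiotropy_detected or self.influential_snp_detected

    def to_dict(self) -> dict:
        return {
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
            "presso_global_pval": self.presso_global_pval,
            "presso_outliers": list(self.presso_outliers),
            "presso_distortion_pval": self.presso_distortion_pval,
            "heterogeneity_detected": self.heterogeneity_detected,
            "pleiotropy_detected": self.pleiotropy_detected,
            "influential_snp_detected": self.influential_snp_detected,
        }


def sensitivity_report(
    hset: HarmonizedSet,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int | None = None,
    run_presso: bool = True,
) -> SensitivityReport:
    """Run the full battery that instrument counts allow and collect flags.

    Heterogeneity flag: Q p < alpha.  Pleiotropy flag: Egger intercept p <
    alpha or PRESSO global p < alpha.  Influence flag: any leave-one-out row
    flagged.  Checks requiring more instruments than available are reported
    as None and do not raise.
    """
    q, q_df, q_p = cochran_q(hset)
    a0 = a0_se = a0_p = None
    loo_df = None
    if len(hset) >= 3:
        a0, a0_se, a0_p = egger_intercept_test(hset)
        loo_df = leave_one_out(hset)
    presso = None
    if run_presso and len(hset) >= 4:
        presso = mr_presso(hset, n_sim=n_sim, outlier_alpha=alpha, seed=seed)

    het = q_p < alpha
    pleio = (a0_p is not None and a0_p < alpha) or (
        presso is not None and presso.global_pval < alpha
    )
    infl = bool(loo_df is not None and loo_df["influential"].any())
    return SensitivityReport(
        q_stat=q,
        q_df=q_df,
        q_pval=q_p,
        egger_intercept=a0,
        egger_intercept_se=a0_se,
        egger_intercept_pval=a0_p,
        presso_global_pval=None if presso is None else presso.global_pval,
        presso_outliers=[] if presso is None else presso.outliers,
        presso_distortion_pval=None if presso is None else presso.distortion_pval,
        loo=loo_df,
        heterogeneity_detected=het,
        pleiotropy_detected=pleio,
        influential_snp_detected=infl,
    )
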