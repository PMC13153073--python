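"""Two-step MR mediation: eligibility gates, indirect effect, mediated proportion.

In two-step (network) MR the exposure->mediator effect a and the
mediator->outcome effect b are estimated from separate instrument sets; the
indirect effect through the mediator is a*b and the mediated proportion is
a*b divided by the total exposure->outcome effect.  A mediation claim is only
considered robust when both steps are significant with a directionally
consistent pathway, reverse causation is excluded by bidirectional MR, and no
sensitivity flag (heterogeneity, pleiotropy, influential variant) is raised on
any of the three analyses.

All arithmetic is on the log-OR scale; odds ratios are accepted as an input
convenience and converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import Z95, MREstimate
from .exceptions import DataError
from .sensitivity import SensitivityReport


@dataclass
class MediationResult:
    """Indirect effect and mediated proportion with uncertainty.

    ``proportion`` is expressed in percent.  When the indirect and total
    effects have opposite signs the proportion is reported as-is and flagged
    ``inconsistent_mediation`` rather than truncated.
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float
    se_total: float
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    indirect: float
    se_indirect: float
    indirect_ci: tuple[float, float]
    proportion: float
    proportion_ci: tuple[float, float]
    ci_method: str
    eligible: bool | None = None
    reasons: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "exposure_id": self.exposure_id,
            "mediator_id": self.mediator_id,
            "outcome_id": self.outcome_id,
            "beta_total": self.beta_total,
            "se_total": self.se_total,
            "beta_a": self.beta_a,
            "se_a": self.se_a,
            "beta_b": self.beta_b,
            "se_b": self.se_b,
            "indirect": self.indirect,
            "se_indirect": self.se_indirect,
            "indirect_ci": list(self.indirect_ci),
            "proportion_pct": self.proportion,
            "proportion_ci_pct": list(self.proportion_ci),
            "ci_method": self.ci_method,
            "eligible": self.eligible,
            "reasons": list(self.reasons),
            "flags": list(self.flags),
        }


def or_to_beta(or_value: float) -> float:
    """Convert an odds ratio to a log-OR effect."""
    if or_value <= 0:
        raise DataError(f"odds ratio must be positive, got {or_value}")
    return float(np.log(or_value))


def se_from_or_ci(or_low: float, or_high: float) -> float:
    """Recover a log-scale SE from a printed 95% OR confidence interval."""
    if not (0 < or_low <= or_high):
        raise DataError(f"invalid OR CI ({or_low}, {or_high})")
    return float((np.log(or_high) - np.log(or_low)) / (2 * Z95))


def two_step_mediation(
    beta_a: float,
    se_a: float,
    beta_b: float,
    se_b: float,
    beta_total: float,
    se_total: float,
    ci_method: str = "delta",
    n_boot: int = 10_000,
    seed: int | None = None,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Indirect effect a*b and mediated proportion a*b/total.

    Delta-method SE of the product: sqrt(a^2 se_b^2 + b^2 se_a^2), with a
    normal CI.  The proportion (in percent) gets either a delta-method CI
    (first-order propagation through the ratio of the product to the total)
    or a seeded parametric bootstrap over (a, b, total).
    """
    for name, se in (("se_a", se_a), ("se_b", se_b), ("se_total", se_total)):
        if se <= 0:
            raise DataError(f"{name} must be > 0, got {se}")
    if ci_method not in ("delta", "bootstrap"):
        raise DataError(f"ci_method must be delta|bootstrap, got {ci_method!r}")
    if beta_total == 0:
        raise DataError("mediated proportion undefined for beta_total = 0")

    indirect = beta_a * beta_b
    se_indirect = float(np.sqrt(beta_a**2 * se_b**2 + beta_b**2 * se_a**2))
    indirect_ci = (indirect - Z95 * se_indirect, indirect + Z95 * se_indirect)

    proportion = indirect / beta_total * 100.0
    flags: list[str] = []
    if indirect != 0 and np.sign(indirect) != np.sign(beta_total):
        flags.append("inconsistent_mediation")

    if ci_method == "delta":
        # first-order propagation for p = a*b/t
        t = beta_total
        grad = np.array([beta_b / t, beta_a / t, -indirect / t**2])
        var = float(grad @ np.diag([se_a**2, se_b**2, se_total**2]) @ grad)
        se_prop = np.sqrt(var) * 100.0
        proportion_ci = (proportion - Z95 * se_prop, proportion + Z95 * se_prop)
    else:
        rng = np.random.default_rng(seed)
        a_s = rng.normal(beta_a, se_a, n_boot)
        b_s = rng.normal(beta_b, se_b, n_boot)
        t_s = rng.normal(beta_total, se_total, n_boot)
        t_s = np.where(t_s == 0, np.finfo(float).tiny, t_s)
        prop_s = a_s * b_s / t_s * 100.0
        proportion_ci = tuple(np.percentile(prop_s, [2.5, 97.5]))

    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta_total=beta_total,
        se_total=se_total,
        beta_a=beta_a,
        se_a=se_a,
        beta_b=beta_b,
        se_b=se_b,
        indirect=indirect,
        se_indirect=se_indirect,
        indirect_ci=indirect_ci,
        proportion=proportion,
        proportion_ci=proportion_ci,
        ci_method=ci_method,
        flags=flags,
    )


def two_step_mediation_from_or(
    or_a: float,
    or_a_ci: Sequence[float],
    or_b: float,
    or_b_ci: Sequence[float],
    or_total: float,
    or_total_ci: Sequence[float],
    **kwargs,
) -> MediationResult:
    """Convenience wrapper taking odds ratios with 95% CIs (as printed in
    forest tables) and converting to the log-OR scale."""
    return two_step_mediation(
        beta_a=or_to_beta(or_a),
        se_a=se_from_or_ci(*or_a_ci),
        beta_b=or_to_beta(or_b),
        se_b=se_from_or_ci(*or_b_ci),
        beta_total=or_to_beta(or_total),
        se_total=se_from_or_ci(*or_total_ci),
        **kwargs,
    )


def assess_eligibility(
    a: MREstimate,
    b: MREstimate,
    total: MREstimate,
    reverse: MREstimate | None,
    sens_a: SensitivityReport | None = None,
    sens_b: SensitivityReport | None = None,
    sens_total: SensitivityReport | None = None,
    alpha: float = 0.05,
) -> tuple[bool, list[str]]:
    """Gate a mediation claim on the full consistency battery.

    Eligible iff: both steps significant (p < alpha) with the indirect-effect
    sign matching the total effect's; the reverse-direction
    (outcome->exposure) estimate non-significant; and no heterogeneity /
    pleiotropy / influential-variant flag on any supplied sensitivity report.
    Returns the flag and the list of failed gates (empty when eligible).
    """
    reasons: list[str] = []
    if a.pval >= alpha:
        reasons.append("a_not_significant")
    if b.pval >= alpha:
        reasons.append("b_not_significant")
    indirect_sign = np.sign(a.beta * b.beta)
    if indirect_sign != 0 and indirect_sign != np.sign(total.beta):
        reasons.append("sign_inconsistent")
    if reverse is not None and reverse.pval < alpha:
        reasons.append("reverse_causation")
    for label, rep in (("a", sens_a), ("b", sens_b), ("total", sens_total)):
        if rep is None:
            continue
        if rep.heterogeneity_detected:
            reasons.append(f"heterogeneity_{label}")
        if rep.pleiotropy_detected:
            reasons.append(f"pleiotropy_{label}")
        if rep.influential_snp_detected:
            reasons.append(f"influence_{label}")
    return (len(reasons) == 0, reasons)
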