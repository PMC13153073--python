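"""statsmodels-style model/results surface.

:class:`MRModel` wraps a harmonized exposure-outcome variant set; ``fit()``
returns an :class:`MRResults` carrying the causal estimates of the requested
methods, their uncertainties, the sensitivity diagnostics, and a printable
``summary()``.  :class:`MediationModel` composes three fitted analyses (total,
exposure->mediator, mediator->outcome) into a :class:`MediationResults` with
the indirect effect and mediated proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw, mr_egger, weighted_median
from .gwas import HarmonizedSet, SummaryDataset, harmonize
from .instruments import LDInfo, select_instruments
from .mediation import MediationResult, assess_eligibility, two_step_mediation
from .sensitivity import SensitivityReport, sensitivity_report


class MRModel:
    """Two-sample MR model for one harmonized exposure-outcome analysis.

    Parameters
    ----------
    hset
        A :class:`~mrmediate.gwas.HarmonizedSet` (build one with
        :func:`~mrmediate.gwas.harmonize` or :meth:`from_datasets`).
    """

    def __init__(self, hset: HarmonizedSet):
        self.hset = hset

    @classmethod
    def from_datasets(
        cls,
        exposure: SummaryDataset,
        outcome: SummaryDataset,
        ld: LDInfo | None = None,
        p_threshold: float = 5e-8,
        clump_r2: float = 0.001,
        clump_window_kb: int = 10_000,
        palindrome_policy: str = "drop_ambiguous",
        maf_window: tuple[float, float] = (0.42, 0.58),
        missing_ld: str = "error",
    ) -> "MRModel":
        """Select instruments, clump, and harmonize in one step."""
        inst = select_instruments(
            exposure,
            ld or LDInfo(),
            p_threshold,
            r2_max=clump_r2,
            window_kb=clump_window_kb,
            missing_ld=missing_ld,
        )
        hset = harmonize(
            exposure.subset(inst.variants),
            outcome,
            palindrome_policy=palindrome_policy,
            maf_window=maf_window,
        )
        model = cls(hset)
        model.instruments = inst
        return model

    def fit(
        self,
        methods: tuple[str, ...] = ("ivw", "weighted_median", "egger"),
        ivw_mode: str = "auto",
        n_boot: int = 1000,
        seed: int | None = None,
        run_sensitivity: bool = True,
        presso_n_sim: int = 1000,
        alpha: float = 0.05,
    ) -> "MRResults":
        estimates: dict[str, MREstimate] = {}
        for m in methods:
            if m == "ivw":
                estimates["ivw"] = ivw(self.hset, mode=ivw_mode)
            elif m == "weighted_median":
                if len(self.hset) >= 3:
                    estimates["weighted_median"] = weighted_median(self.hset, n_boot=n_boot, seed=seed)
            elif m == "egger":
                if len(self.hset) >= 3:
                    estimates["egger"] = mr_egger(self.hset)
            else:
                raise ValueError(f"unknown method {m!r}")
        sens = None
        if run_sensitivity and len(self.hset) >= 2:
            sens = sensitivity_report(
                self.hset,
                alpha=alpha,
                n_sim=presso_n_sim,
                seed=seed,
                run_presso=len(self.hset) >= 4,
            )
        return MRResults(self, estimates, sens)


@dataclass
class MRResults:
    """Fitted MR results: per-method estimates plus diagnostics."""

    model: MRModel
    estimates: dict[str, MREstimate]
    sensitivity: SensitivityReport | None

    @property
    def primary(self) -> MREstimate:
        """The IVW estimate (the study's primary estimator)."""
        return self.estimates["ivw"]

    @property
    def params(self) -> pd.Series:
        return pd.Series({k: e.beta for k, e in self.estimates.items()})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({k: e.se for k, e in self.estimates.items()})

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series({k: e.pval for k, e in self.estimates.items()})

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            {k: [e.ci_low, e.ci_high] for k, e in self.estimates.items()}, index=["lower", "upper"]
        ).T

    def table(self) -> pd.DataFrame:
        """Forest-table frame: method, nSNP, beta, se, OR, 95% CI, p."""
        rows = []
        for k, e in self.estimates.items():
            rows.append(
                {
                    "method": e.method,
                    "n_snp": e.n_snp,
                    "beta": e.beta,
                    "se": e.se,
                    "or": e.or_,
                    "or_low": e.or_low,
                    "or_high": e.or_high,
                    "pval": e.pval,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        h = self.model.hset
        lines = [
            "Two-sample Mendelian randomization",
            f"  exposure: {h.exposure_id}    outcome: {h.outcome_id}",
            f"  variants: {len(h)} retained, {len(h.dropped)} dropped in harmonization",
            "",
            f"{'method':<16}{'nSNP':>5}{'beta':>10}{'se':>9}{'OR':>8}"
            f"{'95% CI':>18}{'p':>11}",
        ]
        for e in self.estimates.values():
            ci = f"[{e.or_low:.3f}, {e.or_high:.3f}]"
            lines.append(
                f"{e.method:<16}{e.n_snp:>5}{e.beta:>10.4f}{e.se:>9.4f}"
                f"{e.or_:>8.3f}{ci:>18}{e.pval:>11.3g}"
            )
        s = self.sensitivity
        if s is not None:
            lines += [
                "",
                f"Cochran's Q = {s.q_stat:.3f} (df {s.q_df}, p = {s.q_pval:.3g})",
            ]
            if s.egger_intercept is not None:
                lines.append(
                    f"Egger intercept = {s.egger_intercept:.4f} "
                    f"(se {s.egger_intercept_se:.4f}, p = {s.egger_intercept_pval:.3g})"
                )
            if s.presso_global_pval is not None:
                out = ", ".join(s.presso_outliers) or "none"
                lines.append(
                    f"MR-PRESSO global p = {s.presso_global_pval:.3g}; outliers: {out}"
                )
            flags = [
                f
                for f, on in (
                    ("heterogeneity", s.heterogeneity_detected),
                    ("pleiotropy", s.pleiotropy_detected),
                    ("influential variant", s.influential_snp_detected),
                )
                if on
            ]
            lines.append("flags: " + (", ".join(flags) if flags else "none"))
        return "\n".join(lines)


class MediationModel:
    """Two-step MR mediation composed from three fitted analyses.

    Parameters are the fitted results for the total (exposure->outcome),
    step-a (exposure->mediator), and step-b (mediator->outcome) analyses, plus
    optionally the reverse-direction (outcome->exposure) estimate used to
    exclude reverse causation.
    """

    def __init__(
        self,
        total: MRResults,
        step_a: MRResults,
        step_b: MRResults,
        reverse: MRResults | None = None,
        exposure_id: str = "exposure",
        mediator_id: str = "mediator",
        outcome_id: str = "outcome",
    ):
        self.total = total
        self.step_a = step_a
        self.step_b = step_b
        self.reverse = reverse
        self.exposure_id = exposure_id
        self.mediator_id = mediator_id
        self.outcome_id = outcome_id

    def fit(
        self, ci_method: str = "delta", n_boot: int = 10_000, seed: int | None = None, alpha: float = 0.05
    ) -> "MediationResults":
        a = self.step_a.primary
        b = self.step_b.primary
        t = self.total.primary
        res = two_step_mediation(
            beta_a=a.beta,
            se_a=a.se,
            beta_b=b.beta,
            se_b=b.se,
            beta_total=t.beta,
            se_total=t.se,
            ci_method=ci_method,
            n_boot=n_boot,
            seed=seed,
            exposure_id=self.exposure_id,
            mediator_id=self.mediator_id,
            outcome_id=self.outcome_id,
        )
        eligible, reasons = assess_eligibility(
            a,
            b,
            t,
            None if self.reverse is None else self.reverse.primary,
            sens_a=self.step_a.sensitivity,
            sens_b=self.step_b.sensitivity,
            sens_total=self.total.sensitivity,
            alpha=alpha,
        )
        res.eligible = eligible
        res.reasons = reasons
        return MediationResults(self, res)


@dataclass
class MediationResults:
    model: MediationModel
    result: MediationResult

    def __getattr__(self, name):
        return getattr(self.result, name)

    def summary(self) -> str:
        r = self.result
        lo, hi = r.indirect_ci
        plo, phi = r.proportion_ci
        lines = [
            "Two-step MR mediation",
            f"  pathway: {r.exposure_id} -> {r.mediator_id} -> {r.outcome_id}",
            f"  total effect (log-OR): {r.beta_total:.4f} (se {r.se_total:.4f})",
            f"  step a (exposure->mediator): {r.beta_a:.4f} (se {r.se_a:.4f})",
            f"  step b (mediator->outcome): {r.beta_b:.4f} (se {r.se_b:.4f})",
            f"  indirect effect: {r.indirect:.3f} (95% CI {lo:.3f} to {hi:.3f}, {r.ci_method})",
            f"  mediated proportion: {r.proportion:.1f}% (95% CI {plo:.1f}% to {phi:.1f}%)",
            f"  eligible: {r.eligible}"
            + (f" (failed gates: {', '.join(r.reasons)})" if r.reasons else ""),
        ]
        if r.flags:
            lines.append(f"  flags: {', '.join(r.flags)}")
        return "\n".join(lines)
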