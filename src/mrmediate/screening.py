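"""Panel-wide bidirectional MR screening with BH-FDR control.

The microbiome-wide design runs MR in two families: exposure -> each
microbial trait (disease instruments at genome-wide significance) and each
trait -> outcome (taxon instruments at the looser 1e-5 regime).  Raw p-values
are adjusted by the Benjamini-Hochberg step-up procedure separately within
each family; traits associated in both directions of the pathway with a
sign-consistent product are mediator candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import ivw, mr_egger, weighted_median
from .exceptions import ConfigError, DataError
from .gwas import SummaryDataset, harmonize
from .instruments import LDInfo, select_instruments
from .sensitivity import sensitivity_report

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass
class TraitPanel:
    """Manifest of screened traits: id, taxonomic rank, display name."""

    traits: list[tuple[str, str, str]]  # (trait_id, rank, display_name)

    def __post_init__(self):
        ids = [t[0] for t in self.traits]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate trait_id in panel")
        for tid, rank, _ in self.traits:
            if rank not in RANKS:
                raise ConfigError(f"unknown taxonomic rank {rank!r} for trait {tid!r}")

    def __len__(self) -> int:
        return len(self.traits)

    @property
    def counts_by_rank(self) -> dict[str, int]:
        counts = {r: 0 for r in RANKS}
        for _, rank, _ in self.traits:
            counts[rank] += 1
        return counts

    @classmethod
    def from_tsv(cls, path) -> "TraitPanel":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("trait_id", "rank", "display_name") if c not in df.columns]
        if missing:
            raise ConfigError(f"panel manifest missing columns: {missing}")
        return cls(list(df[["trait_id", "rank", "display_name"]].itertuples(index=False, name=None)))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.traits, columns=["trait_id", "rank", "display_name"]).to_csv(
            path, sep="\t", index=False
        )


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    q_i = min_{j >= rank(i)} p_(j) * m / j over the sorted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ScreenConfig:
    """Thresholds and switches for a panel screen."""

    p_threshold_exposure: float = 5e-8
    p_threshold_taxa: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    fdr_q: float = 0.1
    alpha: float = 0.05
    palindrome_policy: str = "drop_ambiguous"
    maf_window: tuple[float, float] = (0.42, 0.58)
    run_complementary: bool = True  # weighted median + Egger where J allows
    run_sensitivity: bool = True
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int | None = None
    missing_ld: str = "error"

    def validate(self) -> None:
        for name, val in (
            ("p_threshold_exposure", self.p_threshold_exposure),
            ("p_threshold_taxa", self.p_threshold_taxa),
        ):
            if not (0 < val < 1):
                raise ConfigError(f"{name} must be in (0,1), got {val}")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigError(f"clump_r2 must be in [0,1], got {self.clump_r2}")
        if not (0 < self.fdr_q < 1):
            raise ConfigError(f"fdr_q must be in (0,1), got {self.fdr_q}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass
class ScreenResult:
    """Per-(direction, trait) screen rows with raw p and BH q-values."""

    rows: pd.DataFrame
    fdr_q: float = 0.1
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.rows)

    def significant(self, gate: str = "p") -> pd.DataFrame:
        """Rows passing the chosen gate: raw p (``"p"``) or BH q (``"q"``)."""
        ok = self.rows["status"] == "ok"
        if gate == "p":
            return self.rows[ok & (self.rows["pval"] < self.alpha)]
        if gate == "q":
            return self.rows[ok & (self.rows["qval"] < self.fdr_q)]
        raise ConfigError(f"gate must be p|q, got {gate!r}")

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def _analyse_one(
    exposure_ds: SummaryDataset,
    outcome_ds: SummaryDataset,
    ld: LDInfo,
    p_threshold: float,
    cfg: ScreenConfig,
) -> dict:
    """Instruments -> harmonize -> auto IVW (+complements, +sensitivity)."""
    inst = select_instruments(
        exposure_ds,
        ld,
        p_threshold,
        r2_max=cfg.clump_r2,
        window_kb=cfg.clump_window_kb,
        missing_ld=cfg.missing_ld,
    )
    if len(inst) < 1:
        return {"status": "no_instruments", "n_snp": 0}
    hset = harmonize(
        exposure_ds.subset(inst.variants),
        outcome_ds,
        palindrome_policy=cfg.palindrome_policy,
        maf_window=cfg.maf_window,
    )
    if len(hset) < 1:
        return {"status": "no_instruments", "n_snp": 0}
    est = ivw(hset, mode="auto")
    row = {
        "status": "ok",
        "n_snp": len(hset),
        "method": est.method,
        "beta": est.beta,
        "se": est.se,
        "or": est.or_,
        "ci_low": est.or_low,
        "ci_high": est.or_high,
        "pval": est.pval,
        "mean_f": inst.mean_f,
    }
    if cfg.run_complementary and len(hset) >= 3:
        wm = weighted_median(hset, n_boot=cfg.n_boot, seed=cfg.seed)
        eg = mr_egger(hset)
        row.update(
            {"beta_wm": wm.beta, "pval_wm": wm.pval, "beta_egger": eg.beta, "pval_egger": eg.pval}
        )
    if cfg.run_sensitivity and len(hset) >= 2:
        rep = sensitivity_report(
            hset,
            alpha=cfg.alpha,
            n_sim=cfg.presso_n_sim,
            seed=cfg.seed,
            run_presso=len(hset) >= 4,
        )
        row.update(
            {
                "q_pval": rep.q_pval,
                "egger_intercept_pval": rep.egger_intercept_pval,
                "presso_global_pval": rep.presso_global_pval,
                "flags": ";".join(
                    f
                    for f, on in (
                        ("heterogeneity", rep.heterogeneity_detected),
                        ("pleiotropy", rep.pleiotropy_detected),
                        ("influence", rep.influential_snp_detected),
                    )
                    if on
                ),
            }
        )
    return row


def run_screen(
    exposure_ds: SummaryDataset,
    panel_datasets: Mapping[str, SummaryDataset],
    outcome_ds: SummaryDataset,
    config: ScreenConfig | None = None,
    panel: TraitPanel | None = None,
    ld: LDInfo | None = None,
    directions: Iterable[str] = ("exposure_to_trait", "trait_to_outcome"),
) -> ScreenResult:
    """Run the bidirectional panel screen.

    For ``exposure_to_trait`` rows the exposure's instruments are tested
    against each panel trait as outcome; for ``trait_to_outcome`` rows each
    trait's instruments are tested against the outcome.  BH-FDR is applied
    separately within each direction family (rows without instruments are
    excluded from the family).  Row order is deterministic: direction, then
    rank, then display name.
    """
    cfg = config or ScreenConfig()
    cfg.validate()
    ld = ld or LDInfo()
    if panel is None:
        panel = TraitPanel([(tid, "genus", tid) for tid in sorted(panel_datasets)])
    meta = {tid: (rank, name) for tid, rank, name in panel.traits}
    rank_order = {r: i for i, r in enumerate(RANKS)}

    rows = []
    trait_ids = sorted(
        panel_datasets,
        key=lambda t: (rank_order.get(meta.get(t, ("genus", t))[0], 99), meta.get(t, ("genus", t))[1], t),
    )
    for direction in directions:
        for tid in trait_ids:
            rank, display = meta.get(tid, ("genus", tid))
            trait_ds = panel_datasets[tid]
            if direction == "exposure_to_trait":
                row = _analyse_one(exposure_ds, trait_ds, ld, cfg.p_threshold_exposure, cfg)
            elif direction == "trait_to_outcome":
                row = _analyse_one(trait_ds, outcome_ds, ld, cfg.p_threshold_taxa, cfg)
            elif direction == "trait_to_exposure":
                row = _analyse_one(trait_ds, exposure_ds, ld, cfg.p_threshold_taxa, cfg)
            else:
                raise ConfigError(f"unknown screen direction {direction!r}")
            row.update({"direction": direction, "trait_id": tid, "rank": rank, "display_name": display})
            rows.append(row)

    base_cols = ["direction", "trait_id", "rank", "display_name", "status", "n_snp",
                 "beta", "se", "or", "ci_low", "ci_high", "pval", "qval"]
    if not rows:
        return ScreenResult(rows=pd.DataFrame(columns=base_cols), fdr_q=cfg.fdr_q,
                            alpha=cfg.alpha)
    df = pd.DataFrame(rows)
    df["qval"] = np.nan
    for direction in directions:
        fam = (df["direction"] == direction) & (df["status"] == "ok")
        if fam.any():
            df.loc[fam, "qval"] = bh_fdr(df.loc[fam, "pval"].to_numpy())
    front = ["direction", "trait_id", "rank", "display_name", "status", "n_snp"]
    df = df[front + [c for c in df.columns if c not in front]]
    return ScreenResult(rows=df.reset_index(drop=True), fdr_q=cfg.fdr_q, alpha=cfg.alpha)


def mediator_candidates(
    forward: ScreenResult,
    taxon_to_outcome: ScreenResult,
    gate: str = "p",
    total_sign: float | None = None,
) -> list[str]:
    """Traits significant in both pathway directions with a sign-consistent
    product.

    ``gate`` selects the significance rule (raw p < alpha, or BH q < fdr_q).
    When ``total_sign`` is given, the product of the two step effects must
    match it (the indirect path must push the same way as the total effect).
    """
    fwd = forward.significant(gate)
    fwd = fwd[fwd["direction"] == "exposure_to_trait"].set_index("trait_id")
    rev = taxon_to_outcome.significant(gate)
    rev = rev[rev["direction"] == "trait_to_outcome"].set_index("trait_id")
    shared = fwd.index.intersection(rev.index)
    out = []
    for tid in shared:
        product = fwd.loc[tid, "beta"] * rev.loc[tid, "beta"]
        if total_sign is not None and np.sign(product) != np.sign(total_sign):
            continue
        out.append(tid)
    return sorted(out)
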