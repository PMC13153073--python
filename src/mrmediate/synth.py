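"""Synthetic GWAS summary-statistics generator.

Emulates the statistical structure two-sample MR assumes so the whole
toolchain is testable without external downloads: per-variant exposure
effects drawn from an instrument-strength distribution, outcome effects
composed as beta_out_j = theta * beta_exp_j + alpha_j + noise (alpha_j the
per-variant horizontal-pleiotropy effect), standard errors scaled as
1/sqrt(n * 2 * eaf * (1-eaf)), optional LD blocks, palindromic variants, and
spiked outliers.  Sample-size defaults mirror the consortia whose tables the
formats emulate: a large biobank exposure GWAS, a ~18k-sample 16S microbiome
GWAS for mediator traits, and a ~50k-sample disease outcome GWAS.

A truth record accompanies every dataset so recovery tests can compare
pipeline estimates against the latent generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .exceptions import ConfigError
from .gwas import COLUMNS, SummaryDataset
from .instruments import LDInfo
from .screening import RANKS, TraitPanel

import pandas as pd

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: spacing between LD blocks (bp); larger than the +/-10 Mb clumping window so
#: only within-block pairs ever need an LD entry
_BLOCK_SPACING = 30_000_000


@dataclass
class SimConfig:
    """Generator settings; defaults are the study-scale conditions.

    Effects are on the log-OR scale.  ``instrument_effect_mean/sd`` control
    the latent per-variant exposure effects (mean 0.15 gives F well above the
    adequacy bar at the default sample sizes).  Pleiotropy modes: ``none``,
    ``balanced`` (mean-zero alpha), ``directional`` (nonzero-mean alpha), and
    ``inside_violating`` (alpha correlated 0.5 with the instrument effect, to
    demonstrate Egger failure modes).
    """

    seed: int | None = None
    n_snps_per_trait: int = 50
    n_exposure: int = 200_000
    n_mediator: int = 18_340
    n_outcome: int = 50_000
    theta_total: float = 0.159  # ~ log(1.17), a realistic disease-disease effect
    theta_a: float = 0.10
    theta_b: float = 0.21
    theta_direct: float = 0.14
    instrument_effect_mean: float = 0.15
    instrument_effect_sd: float = 0.03
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 1.0  # fraction of variants carrying the alpha term
    n_outliers: int = 0
    outlier_shift: float = 10.0  # in units of the outcome SE
    ld_block_size: int = 1
    within_block_r2: float = 0.0
    frac_palindromic: float = 0.0
    null_panel_size: int = 50
    trait_type: str = "binary"

    def validate(self) -> None:
        if self.n_snps_per_trait < 1:
            raise ConfigError("n_snps_per_trait must be >= 1")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if not (0 <= self.frac_palindromic <= 1):
            raise ConfigError("frac_palindromic must be in [0,1]")
        if not (0 <= self.within_block_r2 <= 1):
            raise ConfigError("within_block_r2 must be in [0,1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if min(self.instrument_effect_sd, self.pleiotropy_sd) < 0:
            raise ConfigError("sds must be >= 0")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ConfigError("pleiotropy_frac must be in [0,1]")


def preset(name: str, seed: int | None = None, **overrides) -> SimConfig:
    """Named study-condition presets: clean, pleiotropic, outlier, mediation,
    null-panel."""
    presets = {
        "clean": {},
        "pleiotropic": {
            "pleiotropy_mode": "directional",
            "pleiotropy_mean": 0.02,
            "pleiotropy_sd": 0.005,
            "pleiotropy_frac": 0.4,
        },
        "outlier": {"n_outliers": 1, "outlier_shift": 10.0, "n_snps_per_trait": 20},
        "mediation": {"theta_a": 0.10, "theta_b": 0.21, "theta_direct": 0.14},
        "null-panel": {"null_panel_size": 50, "n_snps_per_trait": 10},
    }
    if name not in presets:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    cfg = SimConfig(seed=seed, **presets[name])
    return replace(cfg, **overrides) if overrides else cfg


def _variant_scaffold(cfg: SimConfig, rng: np.random.Generator, prefix: str, n: int) -> dict:
    """Shared variant-level attributes: ids, positions, alleles, eaf."""
    block = np.arange(n) // cfg.ld_block_size
    within = np.arange(n) % cfg.ld_block_size
    chrom = (block % 22 + 1).astype(str)
    pos = (block // 22) * _BLOCK_SPACING + 1_000_000 + within * 1000

    palindromic = rng.random(n) < cfg.frac_palindromic
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), n)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), n)
    ea = np.where(
        palindromic,
        [_PALINDROMIC_PAIRS[i][0] for i in pal_idx],
        [_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx],
    )
    oa = np.where(
        palindromic,
        [_PALINDROMIC_PAIRS[i][1] for i in pal_idx],
        [_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx],
    )
    eaf = np.where(palindromic, rng.uniform(0.45, 0.55, n), rng.uniform(0.05, 0.95, n))
    return {
        "variant_id": np.array([f"{prefix}_snp{i:04d}" for i in range(n)]),
        "chrom": chrom,
        "pos": pos.astype(int),
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": eaf,
        "palindromic": palindromic,
    }


def _se_for(n: int, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(n * 2.0 * eaf * (1.0 - eaf))


def _gwas_table(scaffold: dict, beta_obs: np.ndarray, se: np.ndarray, n: int) -> pd.DataFrame:
    pval = 2 * stats.norm.sf(np.abs(beta_obs / se))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "variant_id": scaffold["variant_id"],
            "chrom": scaffold["chrom"],
            "pos": scaffold["pos"],
            "effect_allele": scaffold["effect_allele"],
            "other_allele": scaffold["other_allele"],
            "eaf": scaffold["eaf"],
            "beta": beta_obs,
            "se": se,
            "pval": pval,
            "n": float(n),
        },
        columns=COLUMNS,
    )


def _block_ld(cfg: SimConfig, scaffold: dict) -> LDInfo:
    ld = LDInfo()
    if cfg.ld_block_size <= 1:
        return ld
    ids = scaffold["variant_id"]
    n = len(ids)
    for start in range(0, n, cfg.ld_block_size):
        members = ids[start : start + cfg.ld_block_size]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ld.add(members[i], members[j], cfg.within_block_r2)
    return ld


def _pleiotropy(cfg: SimConfig, rng: np.random.Generator, beta_x_true: np.ndarray) -> np.ndarray:
    n = len(beta_x_true)
    alpha = np.zeros(n)
    if cfg.pleiotropy_mode == "none":
        return alpha
    carriers = rng.random(n) < cfg.pleiotropy_frac
    if cfg.pleiotropy_mode == "balanced":
        alpha[carriers] = rng.normal(0.0, cfg.pleiotropy_sd, carriers.sum())
    elif cfg.pleiotropy_mode == "directional":
        alpha[carriers] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, carriers.sum())
    else:  # inside_violating: alpha correlated 0.5 with instrument strength
        z = rng.normal(0.0, 1.0, carriers.sum())
        std_bx = (beta_x_true[carriers] - cfg.instrument_effect_mean) / max(
            cfg.instrument_effect_sd, 1e-12
        )
        alpha[carriers] = cfg.pleiotropy_mean + cfg.pleiotropy_sd * (
            0.5 * std_bx + np.sqrt(1 - 0.25) * z
        )
    return alpha


def simulate_pair(
    cfg: SimConfig, theta: float | None = None, rng: np.random.Generator | None = None
) -> tuple[SummaryDataset, SummaryDataset, LDInfo, dict]:
    """Simulate one exposure GWAS and one outcome GWAS sharing variants.

    Per variant: latent beta_exp ~ N(instrument mean, sd); observed betas add
    N(0, se^2) noise on both sides; latent beta_out = theta*beta_exp + alpha;
    the first ``n_outliers`` variants get ``outlier_shift`` outcome-SE units
    added to their observed outcome beta.  Returns (exposure, outcome, LD,
    truth record).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if theta is None:
        theta = cfg.theta_total
    n = cfg.n_snps_per_trait
    sc = _variant_scaffold(cfg, rng, "exp", n)

    beta_x_true = rng.normal(cfg.instrument_effect_mean, cfg.instrument_effect_sd, n)
    alpha = _pleiotropy(cfg, rng, beta_x_true)
    se_x = _se_for(cfg.n_exposure, sc["eaf"])
    se_y = _se_for(cfg.n_outcome, sc["eaf"])
    beta_x_obs = beta_x_true + rng.normal(0.0, se_x)
    beta_y_true = theta * beta_x_true + alpha
    beta_y_obs = beta_y_true + rng.normal(0.0, se_y)
    outlier = np.zeros(n, bool)
    if cfg.n_outliers > 0:
        outlier[: cfg.n_outliers] = True
        beta_y_obs[outlier] += cfg.outlier_shift * se_y[outlier]

    exposure = SummaryDataset("exposure", _gwas_table(sc, beta_x_obs, se_x, cfg.n_exposure), cfg.trait_type)
    outcome = SummaryDataset("outcome", _gwas_table(sc, beta_y_obs, se_y, cfg.n_outcome), cfg.trait_type)
    ld = _block_ld(cfg, sc)
    truth = {
        "theta": float(theta),
        "variant_id": sc["variant_id"].tolist(),
        "beta_x_true": beta_x_true.tolist(),
        "alpha": alpha.tolist(),
        "outlier": outlier.tolist(),
        "palindromic": sc["palindromic"].tolist(),
    }
    return exposure, outcome, ld, truth


def simulate_mediation_chain(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SummaryDataset, SummaryDataset, SummaryDataset, LDInfo, dict]:
    """Simulate an exposure -> mediator -> outcome chain with a direct effect.

    The exposure and mediator carry distinct instrument sets.  At exposure
    instruments the mediator shows theta_a * beta_x and the outcome shows the
    total effect (theta_direct + theta_a*theta_b) * beta_x; at mediator
    instruments the outcome shows theta_b * beta_m.  Each dataset contains all
    variants (null associations where no causal path exists) so bidirectional
    screens are exercised.  The truth record includes the closed-form indirect
    effect and mediated proportion.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps_per_trait
    sc_e = _variant_scaffold(cfg, rng, "exp", n)
    sc_m = _variant_scaffold(cfg, rng, "med", n)
    # shift mediator blocks away from exposure blocks to keep loci distinct
    sc_m["pos"] = sc_m["pos"] + _BLOCK_SPACING // 2

    a, b, direct = cfg.theta_a, cfg.theta_b, cfg.theta_direct
    total = direct + a * b

    bx_e = rng.normal(cfg.instrument_effect_mean, cfg.instrument_effect_sd, n)  # E instruments
    bm_m = rng.normal(cfg.instrument_effect_mean, cfg.instrument_effect_sd, n)  # M instruments

    def stack(s1, s2):
        return {k: np.concatenate([s1[k], s2[k]]) for k in s1}

    sc = stack(sc_e, sc_m)
    se_e = _se_for(cfg.n_exposure, sc["eaf"])
    se_m = _se_for(cfg.n_mediator, sc["eaf"])
    se_o = _se_for(cfg.n_outcome, sc["eaf"])

    true_e = np.concatenate([bx_e, np.zeros(n)])  # mediator does not cause exposure
    true_m = np.concatenate([a * bx_e, bm_m])
    true_o = np.concatenate([total * bx_e, b * bm_m])

    exposure = SummaryDataset(
        "exposure", _gwas_table(sc, true_e + rng.normal(0, se_e), se_e, cfg.n_exposure), cfg.trait_type
    )
    mediator = SummaryDataset(
        "mediator",
        _gwas_table(sc, true_m + rng.normal(0, se_m), se_m, cfg.n_mediator),
        "quantitative",
    )
    outcome = SummaryDataset(
        "outcome", _gwas_table(sc, true_o + rng.normal(0, se_o), se_o, cfg.n_outcome), cfg.trait_type
    )
    ld = _block_ld(cfg, sc)
    truth = {
        "theta_a": a,
        "theta_b": b,
        "theta_direct": direct,
        "theta_total": total,
        "indirect": a * b,
        "proportion_pct": 100.0 * a * b / total,
        "exposure_instruments": sc_e["variant_id"].tolist(),
        "mediator_instruments": sc_m["variant_id"].tolist(),
    }
    return exposure, mediator, outcome, ld, truth


def _panel_ranks(size: int) -> list[str]:
    """Assign taxonomic ranks in roughly the proportions of a 196-trait
    microbiome panel (phyla:classes:orders:families:genera ~ 9:16:20:32:119)."""
    weights = np.array([9, 16, 20, 32, 119], dtype=float)
    counts = np.floor(weights / weights.sum() * size).astype(int)
    counts[-1] += size - counts.sum()
    ranks: list[str] = []
    for r, c in zip(RANKS, counts):
        ranks.extend([r] * c)
    return ranks[:size]


def simulate_null_panel(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, SummaryDataset], SummaryDataset, LDInfo, TraitPanel, dict]:
    """Simulate a panel of traits with no causal link to the outcome.

    Each trait gets its own instrument set (theta = 0 on the outcome); the
    outcome dataset covers the union of all panel variants with noise-only
    associations.  Used for FDR-control experiments.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    panel_datasets: dict[str, SummaryDataset] = {}
    out_tables = []
    ld = LDInfo()
    ranks = _panel_ranks(cfg.null_panel_size)
    traits = []
    n = cfg.n_snps_per_trait
    for k in range(cfg.null_panel_size):
        tid = f"taxon{k:03d}"
        sc = _variant_scaffold(cfg, rng, tid, n)
        bm_true = rng.normal(cfg.instrument_effect_mean, cfg.instrument_effect_sd, n)
        se_m = _se_for(cfg.n_mediator, sc["eaf"])
        se_o = _se_for(cfg.n_outcome, sc["eaf"])
        panel_datasets[tid] = SummaryDataset(
            tid, _gwas_table(sc, bm_true + rng.normal(0, se_m), se_m, cfg.n_mediator), "quantitative"
        )
        out_tables.append(_gwas_table(sc, rng.normal(0, se_o), se_o, cfg.n_outcome))
        block_ld = _block_ld(cfg, sc)
        for (ida, idb), r2 in block_ld._r2.items():
            ld.add(ida, idb, r2)
        traits.append((tid, ranks[k], tid))
    outcome = SummaryDataset("outcome", pd.concat(out_tables, ignore_index=True), cfg.trait_type)
    panel = TraitPanel(traits)
    truth = {"theta": 0.0, "panel_size": cfg.null_panel_size}
    return panel_datasets, outcome, ld, panel, truth
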