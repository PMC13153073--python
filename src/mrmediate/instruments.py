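"""Instrument selection: p-value thresholding, greedy LD clumping, F statistics.

A valid MR instrument must be robustly associated with the exposure
(genome-wide significance 5e-8 for disease exposures; the looser 1e-5 regime
is conventional for microbial-abundance GWAS) and instruments must be mutually
independent, enforced by greedy LD clumping (r-squared below a threshold within
a physical window around each index variant).  Instrument strength is
summarised by the per-variant F statistic (beta/se)^2, with F > 10 the
conventional adequacy bar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import ConfigError, MissingLDError
from .gwas import SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


class LDInfo:
    """Symmetric pairwise r-squared lookup.

    Missing pairs are *not* assumed independent: within-window missing LD is
    an error in :func:`ld_clump` unless downgraded.  ``r2(a, a)`` is 1.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[tuple[str, str], float] = {}
        if isinstance(pairs, Mapping):
            items = [(a, b, v) for (a, b), v in pairs.items()]
        else:
            items = list(pairs)
        for a, b, v in items:
            self.add(a, b, v)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ConfigError(f"r2 out of [0,1] for pair ({a}, {b}): {r2}")
        self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float | None:
        """r-squared for a pair, or None if unknown."""
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b))

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDInfo":
        """Read long-format LD (columns id_a, id_b, r2; tab-delimited)."""
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("id_a", "id_b", "r2") if c not in df.columns]
        if missing:
            raise ConfigError(f"LD table missing columns: {missing}")
        return cls(zip(df["id_a"].astype(str), df["id_b"].astype(str), df["r2"].astype(float)))

    def to_tsv(self, path: str | Path) -> None:
        rows = [(a, b, v) for (a, b), v in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(path, sep="\t", index=False)


@dataclass
class InstrumentSet:
    """Clumped, threshold-passing instruments for one trait."""

    trait_id: str
    variants: list[str]
    f_stats: dict[str, float] = field(default_factory=dict)
    p_threshold: float | None = None
    clump_r2: float | None = None
    clump_window_kb: int | None = None

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def mean_f(self) -> float:
        if not self.f_stats:
            return float("nan")
        return sum(self.f_stats.values()) / len(self.f_stats)

    @property
    def weak_variants(self) -> list[str]:
        """Variants with F below the conventional strength bar (10)."""
        return [v for v in self.variants if self.f_stats.get(v, 0.0) < WEAK_F_THRESHOLD]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"variant_id": self.variants, "F": [self.f_stats.get(v) for v in self.variants]}
        ).to_csv(path, sep="\t", index=False)


def select_by_pvalue(ds: SummaryDataset, p_threshold: float) -> SummaryDataset:
    """Subset to variants with p strictly below ``p_threshold``.

    An empty result is allowed (logged), e.g. a microbial trait with no
    instrument-grade associations.
    """
    if not (0 < p_threshold < 1):
        raise ConfigError(f"p_threshold must be in (0,1), got {p_threshold}")
    keep = ds.table["pval"] < p_threshold
    out = SummaryDataset(ds.trait_id, ds.table[keep].reset_index(drop=True), ds.trait_type)
    if len(out) == 0:
        logger.info("select_by_pvalue(%s): no variants pass p<%g", ds.trait_id, p_threshold)
    return out


def f_statistic(v: VariantAssociation) -> float:
    """Per-variant instrument strength F = (beta/se)^2."""
    return (v.beta / v.se) ** 2


def ld_clump(
    ds: SummaryDataset,
    ld: LDInfo,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    missing_ld: str = "error",
) -> InstrumentSet:
    """Greedy LD clumping.

    Sort by p ascending (ties broken by chrom, pos, variant_id for
    reproducibility); repeatedly take the best remaining variant as an index
    and remove every other variant on the same chromosome within
    +/- ``window_kb`` whose r-squared with it is >= ``r2_max``.  Variants on
    different chromosomes, or outside the window, are independent by
    construction and need no LD entry.  A within-window pair lacking an LD
    entry raises :class:`MissingLDError` naming the pair (``missing_ld="warn"``
    downgrades this to a logged warning treating the pair as r2=0).
    """
    if not (0 <= r2_max <= 1):
        raise ConfigError(f"r2_max must be in [0,1], got {r2_max}")
    if window_kb < 0:
        raise ConfigError(f"window_kb must be >= 0, got {window_kb}")
    if missing_ld not in ("error", "warn"):
        raise ConfigError(f"missing_ld must be error|warn, got {missing_ld!r}")

    df = ds.table.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = window_kb * 1000
    remaining = df.to_dict("records")
    indices: list[dict] = []
    while remaining:
        index = remaining.pop(0)
        indices.append(index)
        survivors = []
        for cand in remaining:
            if cand["chrom"] != index["chrom"] or abs(cand["pos"] - index["pos"]) > window_bp:
                survivors.append(cand)
                continue
            r2 = ld.r2(index["variant_id"], cand["variant_id"])
            if r2 is None:
                msg = (
                    f"no LD entry for within-window pair "
                    f"({index['variant_id']}, {cand['variant_id']})"
                )
                if missing_ld == "error":
                    raise MissingLDError(msg)
                logger.warning("%s; treating as r2=0", msg)
                r2 = 0.0
            if r2 < r2_max:
                survivors.append(cand)
        remaining = survivors

    f_stats = {r["variant_id"]: (r["beta"] / r["se"]) ** 2 for r in indices}
    inst = InstrumentSet(
        trait_id=ds.trait_id,
        variants=[r["variant_id"] for r in indices],
        f_stats=f_stats,
        clump_r2=r2_max,
        clump_window_kb=window_kb,
    )
    weak = inst.weak_variants
    if weak:
        logger.warning("ld_clump(%s): %d weak instruments (F<10): %s", ds.trait_id, len(weak), weak)
    return inst


def select_instruments(
    ds: SummaryDataset,
    ld: LDInfo,
    p_threshold: float,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    missing_ld: str = "error",
) -> InstrumentSet:
    """Convenience: p-value selection followed by LD clumping."""
    sel = select_by_pvalue(ds, p_threshold)
    if len(sel) == 0:
        return InstrumentSet(ds.trait_id, [], {}, p_threshold, r2_max, window_kb)
    inst = ld_clump(sel, ld, r2_max=r2_max, window_kb=window_kb, missing_ld=missing_ld)
    inst.p_threshold = p_threshold
    return inst
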