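"""GWAS summary-statistic data model, I/O, and exposure-outcome harmonization.

The atoms of every MR analysis are per-variant summary associations
(effect-allele beta, SE, p, EAF).  Before any estimation, exposure and outcome
associations must be put on a common effect-allele orientation: alleles may be
reported swapped, on the opposite strand, or both, and palindromic (A/T, C/G)
variants cannot be resolved from alleles alone and are handled by an explicit
policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, EmptyIntersectionError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistic tables
COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association for one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` on the
    log-odds scale for a binary trait or the SD scale for a quantitative one.
    ``eaf`` is the effect-allele frequency and may be missing (``None``).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float
    trait_id: str = ""

    def is_valid(self) -> bool:
        """Check the record invariants (distinct single-base alleles, se > 0,
        p in (0, 1], pos >= 1)."""
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not np.isfinite(self.beta):
            return False
        if not (np.isfinite(self.se) and self.se > 0):
            return False
        if not (0 < self.pval <= 1):
            return False
        if self.pos < 1:
            return False
        if self.eaf is not None and not np.isnan(self.eaf) and not (0 <= self.eaf <= 1):
            return False
        if not (np.isfinite(self.n) and self.n > 0):
            return False
        return True

    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


class SummaryDataset:
    """Per-trait collection of :class:`VariantAssociation`, unique by variant_id.

    Backed by a pandas DataFrame with the canonical :data:`COLUMNS`.
    """

    def __init__(self, trait_id: str, table: pd.DataFrame, trait_type: str = "binary"):
        if trait_type not in ("binary", "quantitative"):
            raise ConfigError(f"trait_type must be binary|quantitative, got {trait_type!r}")
        missing = [c for c in COLUMNS if c not in table.columns]
        if missing:
            raise ConfigError(f"summary table missing columns: {missing}")
        if table["variant_id"].duplicated().any():
            dups = table.loc[table["variant_id"].duplicated(), "variant_id"].tolist()[:5]
            raise DataError(f"duplicate variant_id in dataset {trait_id!r}: {dups}")
        self.trait_id = trait_id
        self.trait_type = trait_type
        self.table = table.reset_index(drop=True)[COLUMNS].copy()
        self.n_dropped = 0

    @classmethod
    def from_records(
        cls, trait_id: str, records: Iterable[VariantAssociation], trait_type: str = "binary"
    ) -> "SummaryDataset":
        rows = [
            {
                "variant_id": r.variant_id,
                "chrom": str(r.chrom),
                "pos": int(r.pos),
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in records
        ]
        return cls(trait_id, pd.DataFrame(rows, columns=COLUMNS), trait_type)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.table["variant_id"])

    def get(self, variant_id: str) -> VariantAssociation:
        sub = self.table.loc[self.table["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        r = sub.iloc[0]
        eaf = None if pd.isna(r["eaf"]) else float(r["eaf"])
        return VariantAssociation(
            variant_id=str(r["variant_id"]),
            chrom=str(r["chrom"]),
            pos=int(r["pos"]),
            effect_allele=str(r["effect_allele"]),
            other_allele=str(r["other_allele"]),
            eaf=eaf,
            beta=float(r["beta"]),
            se=float(r["se"]),
            pval=float(r["pval"]),
            n=float(r["n"]),
            trait_id=self.trait_id,
        )

    def subset(self, variant_ids: Iterable[str]) -> "SummaryDataset":
        ids = set(variant_ids)
        out = SummaryDataset(
            self.trait_id,
            self.table[self.table["variant_id"].isin(ids)].reset_index(drop=True),
            self.trait_type,
        )
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "binary",
) -> SummaryDataset:
    """Read a delimited summary-statistic table into a :class:`SummaryDataset`.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row (delimiter
        auto-detected from the header line).
    column_map
        Optional mapping ``canonical_name -> file_column`` for files whose
        headers differ from the canonical names in :data:`COLUMNS`.  ``eaf``
        may be omitted from the file entirely (treated as missing).
    trait_id
        Identifier for the trait; defaults to the file stem.

    Rows violating the record invariants are dropped with a logged count
    (available as ``ds.n_dropped``).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise DataError(f"empty input file: {path}")
    sep = _detect_sep(header)
    raw = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    if raw.empty:
        raise DataError(f"no data rows in {path}")

    column_map = dict(column_map or {})
    rename = {}
    for canon in COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon != "eaf":  # eaf is the only optional column
            raise ConfigError(f"missing mandatory column {src!r} (for {canon!r}) in {path}")
    df = raw.rename(columns=rename)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    df = df[COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    ok = (
        ea.isin(VALID_BASES)
        & oa.isin(VALID_BASES)
        & (ea != oa)
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["pos"] >= 1)
        & (df["n"] > 0)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_summary_stats(%s): dropped %d invalid rows", path.name, n_dropped)
    df = df[ok].copy()
    df["effect_allele"] = ea[ok]
    df["other_allele"] = oa[ok]
    df["pos"] = df["pos"].astype(int)
    ds = SummaryDataset(trait_id or path.stem, df, trait_type)
    ds.n_dropped = n_dropped
    return ds


@dataclass
class HarmonizedSet:
    """Exposure-outcome variant pairs on a common effect-allele orientation.

    ``pairs`` holds the retained variants (flips already applied to the
    outcome side), ``dropped`` the excluded ones with a reason.
    """

    exposure_id: str
    outcome_id: str
    pairs: pd.DataFrame  # variant_id, beta_exp, se_exp, beta_out, se_out, eaf_exp, eaf_out, flipped
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.pairs["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.pairs["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.pairs["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.pairs["se_out"].to_numpy(float)

    @property
    def variant_ids(self) -> list[str]:
        return self.pairs["variant_id"].tolist()

    def drop_variants(self, variant_ids: Iterable[str], reason: str = "excluded") -> "HarmonizedSet":
        ids = set(variant_ids)
        keep = ~self.pairs["variant_id"].isin(ids)
        newly = pd.DataFrame(
            {"variant_id": self.pairs.loc[~keep, "variant_id"], "reason": reason}
        )
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.pairs[keep].reset_index(drop=True),
            pd.concat([self.dropped, newly], ignore_index=True),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, exposure_id: str = "exposure", outcome_id: str = "outcome"
    ) -> "HarmonizedSet":
        df = pd.read_csv(path, sep="\t")
        required = ["variant_id", "beta_exp", "se_exp", "beta_out", "se_out"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ConfigError(f"harmonized table missing columns: {missing}")
        for col in ("eaf_exp", "eaf_out"):
            if col not in df.columns:
                df[col] = np.nan
        if "flipped" not in df.columns:
            df["flipped"] = False
        if (df[["se_exp", "se_out"]] <= 0).any().any():
            raise DataError("harmonized table contains non-positive SEs")
        return cls(exposure_id, outcome_id, df)

    def write_report(self, path: str | Path) -> None:
        """Write the harmonization drop report (variant_id, reason)."""
        self.dropped.to_csv(path, sep="\t", index=False)


def _classify_orientation(e_ea: str, e_oa: str, o_ea: str, o_oa: str) -> str:
    """Classify outcome allele pair relative to exposure.

    Returns one of ``same``, ``flip``, ``palindromic``, ``incompatible``.
    Strand complements are resolved before comparison; for palindromic
    variants complementing equals swapping, so orientation is undecidable
    from alleles and frequency must arbitrate.
    """
    if {e_ea, e_oa} in ({"A", "T"}, {"C", "G"}):
        # outcome must at least carry the same (self-complementary) allele set
        if {o_ea, o_oa} == {e_ea, e_oa}:
            return "palindromic"
        return "incompatible"
    if (o_ea, o_oa) == (e_ea, e_oa):
        return "same"
    if (o_ea, o_oa) == (e_oa, e_ea):
        return "flip"
    c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        return "same"
    if (c_ea, c_oa) == (e_oa, e_ea):
        return "flip"
    return "incompatible"


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_policy: str = "drop_ambiguous",
    maf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align exposure and outcome associations to a common effect allele.

    Intersects on variant_id, then per variant: if the outcome alleles are
    swapped relative to the exposure (directly or after strand
    complementation) the outcome beta is negated and its EAF reflected with
    ``flipped=True``.  Palindromic variants are handled per policy:

    - ``drop_all``: always dropped (reason ``palindromic``);
    - ``drop_ambiguous``: dropped when either EAF is missing or either
      side's effect-allele frequency falls inside ``maf_window`` (reason
      ``palindromic_ambiguous``); otherwise aligned by frequency (same
      orientation iff both EAFs are on the same side of 0.5).

    Irreconcilable allele sets are dropped with reason
    ``incompatible_alleles``.
    """
    if palindrome_policy not in ("drop_all", "drop_ambiguous"):
        raise ConfigError(f"unknown palindrome_policy {palindrome_policy!r}")
    lo, hi = maf_window
    if not (0 <= lo <= hi <= 1):
        raise ConfigError(f"invalid maf_window {maf_window!r}")
    if len(exposure) == 0 or len(outcome) == 0:
        raise DataError("harmonize requires non-empty datasets")

    exp = exposure.table.set_index("variant_id")
    out = outcome.table.set_index("variant_id")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise EmptyIntersectionError(
            f"no shared variants between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )

    kept_rows: list[dict] = []
    dropped_rows: list[dict] = []
    for vid in shared:
        e = exp.loc[vid]
        o = out.loc[vid]
        orient = _classify_orientation(
            e["effect_allele"], e["other_allele"], o["effect_allele"], o["other_allele"]
        )
        eaf_e = float(e["eaf"]) if pd.notna(e["eaf"]) else None
        eaf_o = float(o["eaf"]) if pd.notna(o["eaf"]) else None
        if orient == "incompatible":
            dropped_rows.append({"variant_id": vid, "reason": "incompatible_alleles"})
            continue
        if orient == "palindromic":
            if palindrome_policy == "drop_all":
                dropped_rows.append({"variant_id": vid, "reason": "palindromic"})
                continue
            if eaf_e is None or eaf_o is None:
                dropped_rows.append({"variant_id": vid, "reason": "palindromic_ambiguous"})
                continue
            if lo <= eaf_e <= hi or lo <= eaf_o <= hi:
                dropped_rows.append({"variant_id": vid, "reason": "palindromic_ambiguous"})
                continue
            orient = "same" if (eaf_e < 0.5) == (eaf_o < 0.5) else "flip"
        flipped = orient == "flip"
        beta_out = -float(o["beta"]) if flipped else float(o["beta"])
        eaf_out = None if eaf_o is None else (1.0 - eaf_o if flipped else eaf_o)
        kept_rows.append(
            {
                "variant_id": vid,
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "beta_out": beta_out,
                "se_out": float(o["se"]),
                "eaf_exp": np.nan if eaf_e is None else eaf_e,
                "eaf_out": np.nan if eaf_out is None else eaf_out,
                "flipped": flipped,
            }
        )

    pairs = pd.DataFrame(
        kept_rows,
        columns=[
            "variant_id",
            "beta_exp",
            "se_exp",
            "beta_out",
            "se_out",
            "eaf_exp",
            "eaf_out",
            "flipped",
        ],
    )
    dropped = pd.DataFrame(dropped_rows, columns=["variant_id", "reason"])
    logger.info(
        "harmonize(%s ~ %s): %d shared, %d retained, %d dropped",
        exposure.trait_id,
        outcome.trait_id,
        len(shared),
        len(pairs),
        len(dropped),
    )
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, pairs, dropped)
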