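"""Locus extraction from summary statistics.

Genome-wide significant variants (-log10 P strictly above 7.30103, i.e.
P < 5e-8) are grouped per chromosome by single-linkage chaining: a gap
of more than the 500 kb window between consecutive sorted positions
starts a new locus, which is the transitive closure of the
"within +/-500 kb of each other" relation (gap exactly equal to the
window groups together). The member with the highest -log10 P is the
lead SNP; exact ties go to the smaller position, then the
lexicographically smaller id. An alternative greedy "fixed window
around the current top SNP" mode is available for comparison with
clumping tools that work that way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOME_WIDE_LOG10P = -math.log10(5e-8)  # 7.30103
SUGGESTIVE_LOG10P = 5.0
DEFAULT_WINDOW_BP = 500_000


@dataclass
class LociConfig:
    sig_log10p: float = GENOME_WIDE_LOG10P
    suggestive_log10p: float = SUGGESTIVE_LOG10P
    window_bp: int = DEFAULT_WINDOW_BP
    mode: str = "chain"  # or "lead_window"

    def validate(self) -> None:
        if self.sig_log10p < self.suggestive_log10p:
            raise ValueError("significant threshold must be >= suggestive threshold")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class Locus:
    chrom: int
    start: int
    end: int
    member_ids: list[str]
    lead_id: str
    lead_pos: int
    lead_log10p: float
    lead_alleles: tuple[str, str] = ("N", "N")

    @property
    def n_variants(self) -> int:
        return len(self.member_ids)


def filter_significant(stats: pd.DataFrame, threshold: float = GENOME_WIDE_LOG10P,
                       quality: dict | None = None) -> pd.DataFrame:
    """Variants with LOG10P strictly above ``threshold`` that pass quality.

    ``quality`` may carry ``info_min``/``maf_min`` bounds applied to INFO
    and MAF columns when present (upstream QC normally makes this a
    no-op; the hook mirrors filtering scripts that re-check here).
    """
    keep = stats["LOG10P"] > threshold
    if quality:
        if "info_min" in quality and "INFO" in stats.columns:
            keep &= stats["INFO"] >= quality["info_min"]
        if "maf_min" in quality and "MAF" in stats.columns:
            keep &= stats["MAF"] >= quality["maf_min"]
    return stats.loc[keep].reset_index(drop=True)


def _lead(group: pd.DataFrame) -> pd.Series:
    """Highest LOG10P; ties -> smaller position, then smaller id."""
    best = group.sort_values(["LOG10P", "GENPOS", "ID"],
                             ascending=[False, True, True], kind="mergesort")
    return best.iloc[0]


def cluster_loci(significant: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP,
                 mode: str = "chain") -> list[Locus]:
    """Group significant variants into loci.

    ``chain``: single-linkage chaining (transitive closure of
    |delta pos| <= window); loci can exceed the window in total span.
    ``lead_window``: repeatedly take the strongest remaining variant and
    absorb everything within +/- window of it.
    """
    loci: list[Locus] = []
    if len(significant) == 0:
        return loci
    for chrom, group in significant.groupby("CHROM", sort=True):
        g = group.sort_values(["GENPOS", "ID"], kind="mergesort").reset_index(drop=True)
        if mode == "chain":
            pos = g["GENPOS"].to_numpy()
            breaks = np.flatnonzero(np.diff(pos) > window_bp)
            bounds = np.concatenate([[0], breaks + 1, [len(g)]])
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                loci.append(_make_locus(int(chrom), g.iloc[lo:hi]))
        elif mode == "lead_window":
            remaining = g.copy()
            while len(remaining):
                lead = _lead(remaining)
                near = (remaining["GENPOS"] - lead["GENPOS"]).abs() <= window_bp
                loci.append(_make_locus(int(chrom), remaining.loc[near]))
                remaining = remaining.loc[~near]
        else:
            raise ValueError(f"unknown clumping mode {mode!r}")
    loci.sort(key=lambda L: (L.chrom, L.start))
    return loci


def _make_locus(chrom: int, members: pd.DataFrame) -> Locus:
    lead = _lead(members)
    alleles = (str(lead.get("ALLELE0", "N")), str(lead.get("ALLELE1", "N")))
    return Locus(
        chrom=chrom,
        start=int(members["GENPOS"].min()),
        end=int(members["GENPOS"].max()),
        member_ids=list(members["ID"]),
        lead_id=str(lead["ID"]),
        lead_pos=int(lead["GENPOS"]),
        lead_log10p=float(lead["LOG10P"]),
        lead_alleles=alleles,
    )


def lead_snp(locus: Locus) -> str:
    if not locus.member_ids:
        raise ValueError("empty locus")
    return locus.lead_id


def extract_loci(stats: pd.DataFrame, config: LociConfig | None = None) -> list[Locus]:
    """Significance filter + clumping in one step."""
    config = config or LociConfig()
    config.validate()
    sig = filter_significant(stats, config.sig_log10p)
    return cluster_loci(sig, config.window_bp, config.mode)


def _sci_2sf(x: float) -> str:
    """Two-significant-figure scientific notation, e.g. 3.4e-04."""
    if x == 0:
        return "0"
    exp = math.floor(math.log10(abs(x)))
    mant = round(x / 10 ** exp, 1)
    if abs(mant) >= 10:  # rounding rolled over
        mant /= 10
        exp += 1
    return f"{mant}e{exp:+03d}"


def summarize_stats(stats: pd.DataFrame, config: LociConfig | None = None) -> dict:
    """Per-strategy summary: totals, max signal, significant/suggestive yield."""
    config = config or LociConfig()
    total = len(stats)
    n_sig = int((stats["LOG10P"] > config.sig_log10p).sum())
    n_sugg = int((stats["LOG10P"] > config.suggestive_log10p).sum())
    return {
        "total_snps": total,
        "max_log10p": float(stats["LOG10P"].max()) if total else float("nan"),
        "n_significant": n_sig,
        "n_suggestive": n_sugg,
        "prop_significant": n_sig / total if total else 0.0,
        "prop_suggestive": n_sugg / total if total else 0.0,
        "prop_significant_str": _sci_2sf(n_sig / total) if total and n_sig else "0",
        "prop_suggestive_str": _sci_2sf(n_sugg / total) if total and n_sugg else "0",
    }


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "CHROM": L.chrom, "START": L.start, "END": L.end,
                "N_VARIANTS": L.n_variants, "LEAD_ID": L.lead_id,
                "LEAD_POS": L.lead_pos, "LEAD_A0": L.lead_alleles[0],
                "LEAD_A1": L.lead_alleles[1], "LEAD_LOG10P": L.lead_log10p,
            }
            for L in loci
        ],
        columns=["CHROM", "START", "END", "N_VARIANTS", "LEAD_ID", "LEAD_POS",
                 "LEAD_A0", "LEAD_A1", "LEAD_LOG10P"],
    )
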