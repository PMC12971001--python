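"""Cross-strategy concordance of GWAS results.

Locus identity across two runs is defined by lead-to-lead distance: two
loci match when their lead positions are on the same chromosome within
the clumping window, paired greedily nearest-first. A three-way Venn is
composed from the pairwise matchings by transitive closure, with a flag
for intransitive components. Discordant lead SNPs can be "rescued" by
linkage disequilibrium: the squared dosage correlation between the two
leads, computed on a reference sample panel, counts as concordant above
a threshold (r^2 > 0.8 by convention). Effect sizes are benchmarked by
OLS of study betas on a reference SNP set after allele harmonization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .loci import Locus, DEFAULT_WINDOW_BP
from .synthdata import MISSING


@dataclass
class LocusOverlap:
    pairs: list[tuple[int, int]]  # (index in A, index in B)
    unique_a: list[int]
    unique_b: list[int]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class LeadConcordance:
    n_unique: int
    n_with_reference: int
    n_high_ld: int
    high_ld_percent: float | None  # None when there is nothing to rescue
    n_unmatched_loci: int
    r2_values: list[float] = field(default_factory=list)


@dataclass
class EffectConcordance:
    n_matched: int
    n_dropped_allele_mismatch: int
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float


def match_loci(loci_a: list[Locus], loci_b: list[Locus],
               window_bp: int = DEFAULT_WINDOW_BP) -> LocusOverlap:
    """Greedy nearest-lead pairing per chromosome.

    Candidate pairs (same chromosome, |lead_a - lead_b| <= window) are
    taken in order of increasing distance, each locus used at most once.
    """
    cand: list[tuple[int, int, int, int]] = []  # (dist, ia, ib) with pos tie-break
    for ia, a in enumerate(loci_a):
        for ib, b in enumerate(loci_b):
            if a.chrom != b.chrom:
                continue
            d = abs(a.lead_pos - b.lead_pos)
            if d <= window_bp:
                cand.append((d, a.lead_pos, ia, ib))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, ia, ib in cand:
        if ia in used_a or ib in used_b:
            continue
        pairs.append((ia, ib))
        used_a.add(ia)
        used_b.add(ib)
    unique_a = [i for i in range(len(loci_a)) if i not in used_a]
    unique_b = [i for i in range(len(loci_b)) if i not in used_b]
    return LocusOverlap(pairs=pairs, unique_a=unique_a, unique_b=unique_b)


def venn_three(loci_a: list[Locus], loci_b: list[Locus], loci_c: list[Locus],
               window_bp: int = DEFAULT_WINDOW_BP) -> dict:
    """Seven-region Venn counts for loci (distance identity) and for lead
    SNP ids (exact identity).

    Locus regions come from the transitive closure of the three pairwise
    matchings; components containing two loci of the same run are
    intransitivity artifacts, counted by majority membership and flagged.
    """
    runs = {"A": loci_a, "B": loci_b, "C": loci_c}
    nodes = [(r, i) for r, ls in runs.items() for i in range(len(ls))]
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for (ra, la), (rb, lb) in itertools.combinations(runs.items(), 2):
        ov = match_loci(la, lb, window_bp)
        for ia, ib in ov.pairs:
            union((ra, ia), (rb, ib))

    comps: dict = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    region_counts = {k: 0 for k in ("A", "B", "C", "AB", "AC", "BC", "ABC")}
    n_flagged = 0
    for members in comps.values():
        run_list = [r for r, _ in members]
        if len(run_list) != len(set(run_list)):
            n_flagged += 1
        key = "".join(sorted(set(run_list)))
        region_counts[key] += 1

    leads = {r: {L.lead_id for L in ls} for r, ls in runs.items()}
    a, b, c = leads["A"], leads["B"], leads["C"]
    lead_counts = {
        "ABC": len(a & b & c),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
    }
    return {"loci": region_counts, "leads": lead_counts,
            "n_intransitive_flagged": n_flagged,
            "n_locus_union": len(comps)}


def ld_r2(dosages: np.ndarray, row1: int, row2: int,
          sample_rows: np.ndarray | None = None) -> float:
    """Squared Pearson correlation of non-missing paired dosages."""
    d1 = dosages[row1]
    d2 = dosages[row2]
    if sample_rows is not None:
        d1 = d1[sample_rows]
        d2 = d2[sample_rows]
    ok = (d1 != MISSING) & (d2 != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than two complete dosage pairs")
    x = d1[ok].astype(float)
    y = d2[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero dosage variance: r^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_consistency(run_loci: list[Locus], ref_loci: list[Locus],
                   dosages: np.ndarray, variant_rows: dict[str, int],
                   sample_rows: np.ndarray | None = None,
                   r2_threshold: float = 0.8,
                   window_bp: int = DEFAULT_WINDOW_BP) -> LeadConcordance:
    """LD rescue of the run's discordant lead SNPs against a reference run.

    For every matched locus pair whose leads differ, the lead-to-lead r^2
    is computed on the reference panel; loci with no matched reference
    locus are excluded from the denominator and counted separately.
    """
    ov = match_loci(run_loci, ref_loci, window_bp)
    r2s: list[float] = []
    n_unique = 0
    for ir, iref in ov.pairs:
        lead_run = run_loci[ir].lead_id
        lead_ref = ref_loci[iref].lead_id
        if lead_run == lead_ref:
            continue
        n_unique += 1
        if lead_run not in variant_rows or lead_ref not in variant_rows:
            continue
        try:
            r2s.append(ld_r2(dosages, variant_rows[lead_run],
                             variant_rows[lead_ref], sample_rows))
        except ValueError:
            continue
    n_high = sum(1 for v in r2s if v > r2_threshold)
    pct = round(100.0 * n_high / n_unique, 2) if n_unique else None
    return LeadConcordance(
        n_unique=n_unique,
        n_with_reference=len(r2s),
        n_high_ld=n_high,
        high_ld_percent=pct,
        n_unmatched_loci=len(ov.unique_a),
        r2_values=r2s,
    )


def rescue_percentage(n_high: int, n_unique: int) -> float | None:
    """Published-style LD-rescue percentage, two decimal places."""
    if n_unique == 0:
        return None
    return round(100.0 * n_high / n_unique, 2)


def effect_concordance(stats: pd.DataFrame, benchmark: pd.DataFrame) -> EffectConcordance:
    """OLS of study betas on benchmark betas after allele harmonization.

    Benchmark SNPs are located by id (fallback: chromosome+position).
    Betas are flipped when study alleles are swapped relative to the
    benchmark effect allele; incompatible allele pairs are dropped and
    counted. Adjusted R^2 uses the single-predictor correction
    1 - (1-R^2)(n-1)/(n-2).
    """
    st = stats.set_index("ID")
    rows = []
    n_dropped = 0
    for _, b in benchmark.iterrows():
        if b["ID"] in st.index:
            s = st.loc[b["ID"]]
        else:
            hit = stats[(stats["CHROM"] == b["CHROM"]) & (stats["GENPOS"] == b["POS"])]
            if len(hit) == 0:
                continue
            s = hit.iloc[0]
        eff, oth = b["EFFECT_ALLELE"], b.get("OTHER_ALLELE", None)
        if s["ALLELE1"] == eff and (oth is None or s["ALLELE0"] == oth):
            rows.append((b["BETA"], s["BETA"]))
        elif s["ALLELE0"] == eff and (oth is None or s["ALLELE1"] == oth):
            rows.append((b["BETA"], -s["BETA"]))
        else:
            n_dropped += 1
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} benchmark SNPs matched; need >= 3")
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    res = linregress(x, y)
    r2 = res.rvalue ** 2
    n = len(rows)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return EffectConcordance(n_matched=n, n_dropped_allele_mismatch=n_dropped,
                             slope=float(res.slope), intercept=float(res.intercept),
                             r2=float(r2), adjusted_r2=float(adj))
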