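"""Allele-specific expression at high-impact variant sites.

RNA read counts supporting the reference vs the alternative allele are
contrasted with a self-contained Mann-Whitney U test (exact enumeration
for small samples, tie- and continuity-corrected normal approximation
otherwise); the same contrast on genomic allele depths serves as the
copy-number control.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import VariantCall

P_FLOOR = 1e-300  # "p = 0" is reported as p below representable precision
DEFAULT_EXACT_LIMIT = 10
DEFAULT_MIN_RNA_DEPTH = 10


@dataclass(frozen=True)
class UTestResult:
    u: float  # U statistic of sample 1
    n1: int
    n2: int
    p_value: float
    method: str  # 'exact' | 'normal_approximation'

    def __post_init__(self) -> None:
        if not 0 <= self.u <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties replaced by their midrank."""
    _, inverse, counts = np.unique(pooled, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    mid = cum - (counts - 1) / 2.0
    return mid[inverse]


def u_statistic(sample1: Sequence[float], sample2: Sequence[float]) -> float:
    """U of sample 1: rank-sum formulation with midrank tie handling."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    ranks = _midranks(np.concatenate((x, y)))
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


_ENUMERATION_BUDGET = 400_000  # max labelings enumerated for tied samples


def _exact_p_enumerate(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all labelings of the pooled data
    (valid under ties because midranks are enumerated as observed)."""
    n = pooled_ranks.size
    offset = n1 * (n1 + 1) / 2.0
    total = comb(n, n1)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        u = pooled_ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            le += 1
        if u >= u_obs - eps:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return min(1.0, max(p, 1.0 / total))


def _exact_p_tiefree(n1: int, n2: int, u_obs: float) -> float:
    """Two-sided exact p for tie-free samples via the subset rank-sum
    count recurrence (number of size-n1 subsets of ranks 1..n with each
    possible U), feasible well beyond enumeration limits."""
    n = n1 + n2
    max_sum = n1 * n + 1  # rank sums reach n1*n at most
    # counts[k][s] = number of size-k subsets of ranks {1..r} with sum s
    counts = np.zeros((n1 + 1, max_sum), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(n1, rank), 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank]
    offset = n1 * (n1 + 1) // 2
    dist = counts[n1][offset : offset + n1 * n2 + 1]  # indexed by U = sum - offset
    total = dist.sum()
    u_int = int(round(u_obs))
    le = dist[: u_int + 1].sum()
    ge = dist[u_int:].sum()
    p = 2.0 * min(le, ge) / total
    return min(1.0, max(p, 1.0 / total))


def mann_whitney_u(
    sample1: Sequence[float],
    sample2: Sequence[float],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> UTestResult:
    """Two-sided Mann-Whitney U test.

    Exact p whenever ``max(n1, n2) <= exact_limit``: a rank-sum count
    recurrence for tie-free data, full labeling enumeration under ties
    (unless the labeling count makes enumeration infeasible). Otherwise a
    normal approximation with tie and continuity corrections. p-values
    are floored at 1e-300 rather than reported as a literal 0.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate((x, y))
    ranks = _midranks(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if max(n1, n2) <= exact_limit:
        has_ties = np.unique(pooled).size < pooled.size
        if not has_ties:
            return UTestResult(u1, n1, n2, _exact_p_tiefree(n1, n2, u1), "exact")
        if comb(n1 + n2, n1) <= _ENUMERATION_BUDGET:
            return UTestResult(u1, n1, n2, _exact_p_enumerate(ranks, n1, u1), "exact")
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    if var <= 0:  # all observations identical
        return UTestResult(u1, n1, n2, 1.0, "normal_approximation")
    diff = u1 - mu
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return UTestResult(u1, n1, n2, max(p, P_FLOOR), "normal_approximation")


# ------------------------------------------------------------ ASE records


@dataclass(frozen=True)
class AseRecord:
    """RNA and genomic allele support at one high-impact variant site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str]
    rna_ref: int
    rna_alt: int
    dna_ref: int
    dna_alt: int

    @property
    def rna_total(self) -> int:
        return self.rna_ref + self.rna_alt

    @property
    def rna_alt_fraction(self) -> float:
        return self.rna_alt / self.rna_total if self.rna_total else float("nan")

    @property
    def dna_alt_fraction(self) -> float:
        total = self.dna_ref + self.dna_alt
        return self.dna_alt / total if total else float("nan")


def collect_ase(
    high_impact: Sequence[tuple[VariantCall, str, Optional[str]]],
    rna_counts: pd.DataFrame,
    min_rna_depth: int = DEFAULT_MIN_RNA_DEPTH,
) -> tuple[list[AseRecord], int]:
    """Join high-impact (call, alt allele, gene id) triples with RNA counts.

    Returns the records with RNA total >= ``min_rna_depth`` plus the
    number of sites skipped because of allele mismatch or missing counts.
    """
    table: dict[tuple, tuple[int, int, str]] = {}
    for row in rna_counts.itertuples(index=False):
        table[(row.chrom, int(row.pos), row.ref, row.alt)] = (
            int(row.ref_count),
            int(row.alt_count),
            getattr(row, "gene_id", None),
        )
    records: list[AseRecord] = []
    skipped = 0
    for call, alt, gene_id in high_impact:
        hit = table.get((call.chrom, call.pos, call.ref, alt))
        if hit is None:
            skipped += 1
            continue
        rna_ref, rna_alt, rna_gene = hit
        if rna_ref + rna_alt < min_rna_depth:
            continue
        alt_idx = call.alts.index(alt)
        records.append(
            AseRecord(
                chrom=call.chrom,
                pos=call.pos,
                ref=call.ref,
                alt=alt,
                gene_id=gene_id or (rna_gene if rna_gene not in (None, ".") else None),
                rna_ref=int(rna_ref),
                rna_alt=int(rna_alt),
                dna_ref=int(call.ad[0]),
                dna_alt=int(call.ad[1 + alt_idx]),
            )
        )
    return records, skipped


def ase_contrast(
    records: Sequence[AseRecord], exact_limit: int = DEFAULT_EXACT_LIMIT
) -> dict:
    """Reference-vs-alternative abundance tests, RNA and genomic side by side.

    The genomic contrast on allele depths at the same positions separates
    a copy-number mechanism (both contrasts shifted alike) from transcript
    degradation (RNA only). A third test compares the per-site RNA and
    genomic alternative-allele fractions directly.
    """
    if len(records) < 2:
        raise ValueError("need >= 2 ASE records")
    rna_ref = [r.rna_ref for r in records]
    rna_alt = [r.rna_alt for r in records]
    dna_ref = [r.dna_ref for r in records]
    dna_alt = [r.dna_alt for r in records]
    rna_test = mann_whitney_u(rna_ref, rna_alt, exact_limit)
    dna_test = mann_whitney_u(dna_ref, dna_alt, exact_limit)
    rna_fracs = [r.rna_alt_fraction for r in records if r.rna_total > 0]
    dna_fracs = [
        r.dna_alt_fraction for r in records if (r.dna_ref + r.dna_alt) > 0
    ]
    mech_test = mann_whitney_u(rna_fracs, dna_fracs, exact_limit)

    def _ratios(alt, ref):
        return [a / b for a, b in zip(alt, ref) if b > 0]

    rna_ratios = _ratios(rna_alt, rna_ref)
    dna_ratios = _ratios(dna_alt, dna_ref)
    return {
        "n_records": len(records),
        "rna": {
            "u": rna_test.u,
            "p_value": rna_test.p_value,
            "method": rna_test.method,
            "median_ref": float(np.median(rna_ref)),
            "median_alt": float(np.median(rna_alt)),
            "median_alt_ref_ratio": float(np.median(rna_ratios)) if rna_ratios else float("nan"),
        },
        "genomic": {
            "u": dna_test.u,
            "p_value": dna_test.p_value,
            "method": dna_test.method,
            "median_ref": float(np.median(dna_ref)),
            "median_alt": float(np.median(dna_alt)),
            "median_alt_ref_ratio": float(np.median(dna_ratios)) if dna_ratios else float("nan"),
        },
        "rna_vs_genomic_fraction": {
            "u": mech_test.u,
            "p_value": mech_test.p_value,
            "method": mech_test.method,
            "pooled_rna_alt_fraction": float(
                np.sum(rna_alt) / max(1, np.sum(rna_alt) + np.sum(rna_ref))
            ),
            "pooled_dna_alt_fraction": float(
                np.sum(dna_alt) / max(1, np.sum(dna_alt) + np.sum(dna_ref))
            ),
        },
    }
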