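"""Zygosity classification and small-variant summaries.

A variant is *deviating-frequency* when some non-dominant allele is
supported by at least ``min_reads`` reads and at least ``min_frac`` of the
total depth (both inclusive); otherwise it is *homozygous* for the
dominant allele. Sites whose depth deviates from the mean of a flanking
window by strictly more than ``max_deviation`` are excluded beforehand.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import VariantCall, revcomp


class Zygosity(str, Enum):
    HOMOZYGOUS = "homozygous"
    DEVIATING = "deviating_frequency"


class FilterStatus(str, Enum):
    PASS = "pass"
    COVERAGE_DEVIATION = "coverage_deviation"
    FLANK_ZERO = "flank_zero_coverage"
    NON_VARIANT = "non_variant"  # dominant allele is the reference


@dataclass(frozen=True)
class ZygosityThresholds:
    min_reads: int = 5
    min_frac: float = 0.05
    flank: int = 2000
    max_deviation: float = 0.20

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0 < self.min_frac < 1:
            raise ValueError("min_frac must be in (0, 1)")
        if self.flank <= 0:
            raise ValueError("flank must be > 0")
        if not 0 < self.max_deviation < 1:
            raise ValueError("max_deviation must be in (0, 1)")


@dataclass
class ClassifiedVariant:
    call: VariantCall
    filter_status: FilterStatus
    zygosity: Optional[Zygosity] = None
    dominant_is_alt: Optional[bool] = None
    tie: bool = False


# ------------------------------------------------------------ core rules


def classify_zygosity(
    call: VariantCall, thresholds: ZygosityThresholds = ZygosityThresholds()
) -> ClassifiedVariant:
    """Apply the supporting-reads / supporting-fraction rule to one call.

    The dominant allele is the one with maximal AD. A tie between two
    top alleles is itself treated as a deviating signal whenever the tied
    depth passes the thresholds.
    """
    if call.dp <= 0:
        raise ValueError(f"DP must be positive at {call.chrom}:{call.pos}")
    ad = np.asarray(call.ad)
    if ad.sum() == 0:
        raise ValueError(f"all-zero AD at {call.chrom}:{call.pos}")
    order = np.argsort(-ad, kind="stable")
    dominant = int(order[0])
    tie = bool(ad[order[1]] == ad[dominant]) if ad.size > 1 else False
    deviating = False
    for i in order[1:]:
        depth = int(ad[i])
        if depth >= thresholds.min_reads and depth / call.dp >= thresholds.min_frac:
            deviating = True
            break
    dominant_is_alt = dominant != 0
    if deviating:
        return ClassifiedVariant(
            call, FilterStatus.PASS, Zygosity.DEVIATING, dominant_is_alt, tie
        )
    if dominant_is_alt:
        return ClassifiedVariant(
            call, FilterStatus.PASS, Zygosity.HOMOZYGOUS, dominant_is_alt, tie
        )
    # dominant allele is the reference and nothing else passes: the site
    # carries no supported variant allele
    return ClassifiedVariant(call, FilterStatus.NON_VARIANT, None, dominant_is_alt, tie)


def coverage_deviation_filter(
    call: VariantCall,
    track: Mapping[str, np.ndarray],
    thresholds: ZygosityThresholds = ZygosityThresholds(),
) -> FilterStatus:
    """Exclude a call when |DP - m| / m strictly exceeds ``max_deviation``,
    with m the mean depth of the flanking window (variant base excluded,
    window clipped at chromosome ends)."""
    arr = track[call.chrom]
    lo = max(0, call.pos0 - thresholds.flank)
    hi = min(arr.size, call.pos0 + thresholds.flank + 1)
    flank = np.concatenate((arr[lo : call.pos0], arr[call.pos0 + 1 : hi])).astype(float)
    if flank.size == 0 or flank.mean() == 0:
        return FilterStatus.FLANK_ZERO
    m = flank.mean()
    if abs(call.dp - m) / m > thresholds.max_deviation:
        return FilterStatus.COVERAGE_DEVIATION
    return FilterStatus.PASS


def classify_variants(
    calls: Sequence[VariantCall],
    track: Optional[Mapping[str, np.ndarray]] = None,
    thresholds: ZygosityThresholds = ZygosityThresholds(),
) -> list[ClassifiedVariant]:
    """Filter (when a depth track is given) then classify each call.

    Excluded calls keep their filter status and get no zygosity class.
    """
    out: list[ClassifiedVariant] = []
    for call in calls:
        if track is not None:
            status = coverage_deviation_filter(call, track, thresholds)
            if status is not FilterStatus.PASS:
                out.append(ClassifiedVariant(call, status))
                continue
        out.append(classify_zygosity(call, thresholds))
    return out


def pass_variants(classified: Sequence[ClassifiedVariant]) -> list[ClassifiedVariant]:
    return [c for c in classified if c.filter_status is FilterStatus.PASS]


# ------------------------------------------------------------ summaries


def variant_density(
    classified: Sequence[ClassifiedVariant],
    chrom_lengths: Mapping[str, int],
    block_size: int = 100_000,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-block counts of pass variants split by zygosity class."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, length in chrom_lengths.items():
        n_blocks = max(1, -(-length // block_size))
        out[chrom] = {
            Zygosity.HOMOZYGOUS.value: np.zeros(n_blocks, dtype=np.int64),
            Zygosity.DEVIATING.value: np.zeros(n_blocks, dtype=np.int64),
        }
    for cv in pass_variants(classified):
        if cv.zygosity is None or cv.call.chrom not in out:
            continue
        block = cv.call.pos0 // block_size
        out[cv.call.chrom][cv.zygosity.value][block] += 1
    return out


_PURINE_SWAP = {"G>T": "C>A", "G>C": "C>G", "G>A": "C>T",
                "A>T": "T>A", "A>G": "T>C", "A>C": "T>G"}


@dataclass
class SpectrumTable:
    """Directed and strand-collapsed substitution counts.

    The collapse convention maps purine-reference changes onto their
    reverse complement so every class is keyed by a pyrimidine reference
    base (C or T). The CG->AT share is the collapsed C>A + C>T fraction,
    i.e. directed C>A, C>T, G>T and G>A over all SNVs.
    """

    directed: dict[str, int]
    collapsed: dict[str, int]
    cg_to_at_share: float
    total: int


def substitution_spectrum(classified: Sequence[ClassifiedVariant]) -> SpectrumTable:
    """Directed 12-class and strand-collapsed 6-class spectra of pass SNVs."""
    directed: Counter = Counter()
    for cv in pass_variants(classified):
        call = cv.call
        for alt, depth in zip(call.alts, call.ad[1:]):
            if len(call.ref) != 1 or len(alt) != 1:
                raise ValueError(
                    f"non-SNV allele {call.ref}>{alt} at {call.chrom}:{call.pos}"
                )
        directed[f"{call.ref}>{call.primary_alt}"] += 1
    collapsed: Counter = Counter()
    for key, n in directed.items():
        collapsed[_PURINE_SWAP.get(key, key)] += n
    total = sum(directed.values())
    cg_at = collapsed.get("C>A", 0) + collapsed.get("C>T", 0)
    return SpectrumTable(
        directed=dict(sorted(directed.items())),
        collapsed=dict(sorted(collapsed.items())),
        cg_to_at_share=cg_at / total if total else float("nan"),
        total=total,
    )


def snv_indel_ratio(classified: Sequence[ClassifiedVariant]) -> dict:
    """Counts of pass SNVs and InDels and the SNV:InDel ratio."""
    n_snv = sum(1 for cv in pass_variants(classified) if cv.call.is_snv)
    n_indel = sum(1 for cv in pass_variants(classified) if cv.call.is_indel)
    ratio = n_snv / n_indel if n_indel else float("inf")
    return {"snv": n_snv, "indel": n_indel, "ratio": ratio}


def coverage_histogram_at_variants(
    classified: Sequence[ClassifiedVariant],
    track: Mapping[str, np.ndarray],
    bin_width: int = 5,
) -> dict[str, dict]:
    """Depth histograms (from the track) per zygosity class."""
    depths: dict[str, list[int]] = {z.value: [] for z in Zygosity}
    for cv in pass_variants(classified):
        if cv.zygosity is None:
            continue
        depths[cv.zygosity.value].append(int(track[cv.call.chrom][cv.call.pos0]))
    out: dict[str, dict] = {}
    top = max((max(v) for v in depths.values() if v), default=0)
    edges = np.arange(0, top + 2 * bin_width, bin_width)
    for cls, vals in depths.items():
        arr = np.asarray(vals)
        hist, _ = np.histogram(arr, bins=edges)
        out[cls] = {
            "bin_edges": edges.tolist(),
            "counts": hist.tolist(),
            "n": int(arr.size),
            "mean_depth": float(arr.mean()) if arr.size else float("nan"),
        }
    return out


def reverse_complement_spectrum_key(key: str) -> str:
    """'C>T' -> 'G>A' (used by symmetry tests)."""
    ref, alt = key.split(">")
    return f"{revcomp(ref)}>{revcomp(alt)}"
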