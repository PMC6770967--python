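"""Copy-number structure from read depth.

Windowed coverage, zero-coverage deletion detection, per-gene copy
classification against an estimated per-copy depth unit (the depth one
haplophase copy contributes), flanking-gene similarity flags, and the
organelle coverage ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import GeneModel

DEFAULT_MIN_DELETION_LENGTH = 100
DEFAULT_FLANK_TOLERANCE = 0.20
DEFAULT_K_MAX = 8


@dataclass(frozen=True)
class ZeroCoverageRegion:
    """A maximal run of zero depth, interpreted as a complete deletion."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneCopyEstimate:
    gene_id: str
    chrom: str
    start: int
    end: int
    mean_depth: float
    copy_number: int
    similar_to_flanking: Optional[bool] = None
    clamped: bool = False


@dataclass
class PloidyBaseline:
    """Per-copy depth unit plus the peak/valley structure it came from."""

    unit: float
    peaks: list[float] = field(default_factory=list)
    valleys: list[float] = field(default_factory=list)
    low_confidence: bool = False
    bandwidth: float = 0.0

    def __post_init__(self) -> None:
        if self.unit <= 0:
            raise ValueError("per-copy unit must be > 0")


# ------------------------------------------------------------ windows


def windowed_mean_coverage(
    track: Mapping[str, np.ndarray], window: int
) -> dict[str, np.ndarray]:
    """Mean depth per ``window``-bp tile; the final short tile is averaged
    over its actual length."""
    if window < 1:
        raise ValueError("window size must be >= 1")
    if not track:
        raise ValueError("empty coverage track")
    out: dict[str, np.ndarray] = {}
    for chrom, arr in track.items():
        arr = np.asarray(arr, dtype=float)
        n_full = arr.size // window
        means = []
        if n_full:
            means.append(arr[: n_full * window].reshape(n_full, window).mean(axis=1))
        if arr.size % window:
            means.append(np.array([arr[n_full * window :].mean()]))
        out[chrom] = np.concatenate(means) if means else np.array([])
    return out


# ------------------------------------------------------------ zero coverage


def find_zero_coverage_regions(
    track: Mapping[str, np.ndarray], min_length: int = DEFAULT_MIN_DELETION_LENGTH
) -> list[ZeroCoverageRegion]:
    """Maximal zero-depth runs strictly longer than ``min_length`` bp,
    sorted by chromosome and position."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    regions: list[ZeroCoverageRegion] = []
    for chrom in track:
        arr = np.asarray(track[chrom])
        if arr.size == 0:
            continue
        zero = np.concatenate(([0], (arr == 0).astype(np.int8), [0]))
        d = np.diff(zero)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s > min_length:
                regions.append(ZeroCoverageRegion(chrom, int(s), int(e)))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


# ------------------------------------------------------------ baseline


def estimate_ploidy_baseline(
    gene_depths: Sequence[float],
    bandwidth: Optional[float] = None,
    min_genes: int = 20,
) -> PloidyBaseline:
    """Per-copy unit from the smoothed histogram of gene mean depths.

    The unit is the location of the first peak above zero depth; valleys
    between successive peaks become copy-class boundaries. With a single
    detectable peak the unit is still returned but flagged low-confidence.
    """
    depths = np.asarray([d for d in gene_depths if d > 0], dtype=float)
    if depths.size < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes with positive depth, got {depths.size}"
        )
    if bandwidth is None:
        bandwidth = max(1.0, 0.1 * float(np.median(depths)))
    bin_width = max(bandwidth / 4.0, 1e-6)
    hi = depths.max() + 4 * bandwidth
    edges = np.arange(0.0, hi + bin_width, bin_width)
    hist, _ = np.histogram(depths, bins=edges)
    smooth = gaussian_filter1d(hist.astype(float), sigma=bandwidth / bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_idx, _ = find_peaks(smooth, prominence=0.005 * max(smooth.max(), 1.0))
    # a mode at the very first bin has no left shoulder; recover it manually
    if smooth.size > 1 and smooth[0] > smooth[1] and (peak_idx.size == 0 or peak_idx[0] != 0):
        peak_idx = np.concatenate(([0], peak_idx))
    peaks = [float(centers[i]) for i in peak_idx]
    positive_peaks = [p for p in peaks if p > bandwidth / 2]
    if not positive_peaks:
        # degenerate histogram: fall back to the depth median
        return PloidyBaseline(
            unit=float(np.median(depths)),
            peaks=peaks,
            valleys=[],
            low_confidence=True,
            bandwidth=bandwidth,
        )
    unit = positive_peaks[0]
    valleys = []
    kept = [i for i, p in zip(peak_idx, peaks) if p > bandwidth / 2]
    for left, right in zip(kept[:-1], kept[1:]):
        seg = smooth[left : right + 1]
        valleys.append(float(centers[left + int(np.argmin(seg))]))
    return PloidyBaseline(
        unit=unit,
        peaks=positive_peaks,
        valleys=valleys,
        low_confidence=len(positive_peaks) < 2,
        bandwidth=bandwidth,
    )


# ------------------------------------------------------------ per-gene copies


def classify_gene_copy_number(
    mean_depth: float, unit: float, k_max: int = DEFAULT_K_MAX
) -> tuple[int, bool]:
    """Nearest integer multiple of the per-copy unit, clamped to [0, k_max].

    Returns ``(k, clamped)``; halves round up so the k=0 class is exactly
    depths below unit/2.
    """
    if unit <= 0:
        raise ValueError("unit must be > 0")
    raw = int(np.floor(mean_depth / unit + 0.5))
    return min(raw, k_max), raw > k_max


def gene_mean_depths(
    genes: Sequence[GeneModel], track: Mapping[str, np.ndarray]
) -> list[float]:
    """Arithmetic mean depth over each gene's full span."""
    out = []
    for g in genes:
        arr = track[g.chrom]
        out.append(float(np.asarray(arr[g.start : g.end]).mean()))
    return out


def estimate_gene_copies(
    genes: Sequence[GeneModel],
    track: Mapping[str, np.ndarray],
    baseline: Optional[PloidyBaseline] = None,
    *,
    k_max: int = DEFAULT_K_MAX,
    flank_tolerance: float = DEFAULT_FLANK_TOLERANCE,
    bandwidth: Optional[float] = None,
) -> tuple[list[GeneCopyEstimate], PloidyBaseline]:
    """Full per-gene pipeline: mean depth, baseline, k estimate, flags."""
    depths = gene_mean_depths(genes, track)
    if baseline is None:
        baseline = estimate_ploidy_baseline(depths, bandwidth=bandwidth)
    estimates = []
    for g, d in zip(genes, depths):
        k, clamped = classify_gene_copy_number(d, baseline.unit, k_max)
        estimates.append(
            GeneCopyEstimate(
                gene_id=g.gene_id,
                chrom=g.chrom,
                start=g.start,
                end=g.end,
                mean_depth=d,
                copy_number=k,
                clamped=clamped,
            )
        )
    flag_flanking_similarity(estimates, flank_tolerance)
    return estimates, baseline


def flag_flanking_similarity(
    estimates: Sequence[GeneCopyEstimate], tolerance: float = DEFAULT_FLANK_TOLERANCE
) -> None:
    """Mark each gene whose mean depth lies within +-tolerance (relative)
    of at least one existing nearest neighbour's mean depth.

    The one-sided rule keeps genes at copy-block boundaries "similar"
    (they match the flanking coverage on one side) while isolating
    single-gene CNVs. Estimates must be ordered by chromosome and
    position; single-gene chromosomes get ``None`` (undefined).
    """
    by_chrom: dict[str, list[GeneCopyEstimate]] = {}
    for est in estimates:
        by_chrom.setdefault(est.chrom, []).append(est)
    for chrom, ests in by_chrom.items():
        if len(ests) < 2:
            for est in ests:
                est.similar_to_flanking = None
            continue
        for i, est in enumerate(ests):
            neighbours = []
            if i > 0:
                neighbours.append(ests[i - 1].mean_depth)
            if i < len(ests) - 1:
                neighbours.append(ests[i + 1].mean_depth)
            flags = []
            for ref in neighbours:
                if ref == 0:
                    flags.append(est.mean_depth == 0)
                else:
                    flags.append(abs(est.mean_depth - ref) <= tolerance * ref)
            est.similar_to_flanking = any(flags)


# ------------------------------------------------------------ organelles


def organelle_coverage_ratio(
    track: Mapping[str, np.ndarray],
    chondrome_ids: Sequence[str],
    plastome_ids: Sequence[str],
    reference_ratio: Optional[float] = None,
) -> dict:
    """Mean chondrome depth over mean plastome depth (and fold change
    against an optional reference ratio)."""
    if not chondrome_ids or not plastome_ids:
        raise ValueError("both organelle id sets are required")
    chond = np.concatenate([np.asarray(track[c], dtype=float) for c in chondrome_ids])
    plast = np.concatenate([np.asarray(track[c], dtype=float) for c in plastome_ids])
    plast_mean = float(plast.mean())
    if plast_mean == 0:
        raise ValueError("plastome coverage is zero; ratio undefined")
    ratio = float(chond.mean()) / plast_mean
    out = {
        "chondrome_mean": float(chond.mean()),
        "plastome_mean": plast_mean,
        "ratio": ratio,
    }
    if reference_ratio:
        out["fold_change_vs_reference"] = ratio / reference_ratio
    return out
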