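"""Simplified variant effect annotation and InDel codon-frame analysis.

One transcript per gene (its first CDS chain). SNVs inside a CDS are
classified by translating the affected codon with and without the change;
InDels overlapping a CDS are frameshift when the length change is not a
multiple of 3, in-frame otherwise. High impact = stop gain or frameshift.
Splice sites, UTRs and start-loss are deliberately out of scope.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from Bio.Seq import Seq

from .core import GeneModel, VariantCall, revcomp


class Effect(str, Enum):
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


IMPACT = {
    Effect.STOP_GAIN: "high",
    Effect.FRAMESHIFT: "high",
    Effect.MISSENSE: "moderate",
    Effect.INFRAME_INDEL: "moderate",
    Effect.SYNONYMOUS: "low",
    Effect.NONCODING: "none",
}

HIGH_IMPACT_EFFECTS = frozenset({Effect.STOP_GAIN, Effect.FRAMESHIFT})


@dataclass(frozen=True)
class EffectAnnotation:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: Optional[str]
    effect: Effect

    @property
    def impact(self) -> str:
        return IMPACT[self.effect]

    @property
    def is_high_impact(self) -> bool:
        return self.effect in HIGH_IMPACT_EFFECTS


class CdsIndex:
    """Per-chromosome sorted CDS intervals for point and span queries.

    Assumes CDS intervals of different genes do not overlap (true for the
    generated annotations; overlapping inputs resolve to the first hit).
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._genes: dict[str, list[GeneModel]] = {}
        entries: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in genes:
            for s, e in g.cds:
                entries.setdefault(g.chrom, []).append((s, e, g))
        for chrom, items in entries.items():
            items.sort()
            self._starts[chrom] = [s for s, _, _ in items]
            self._ends[chrom] = [e for _, e, _ in items]
            self._genes[chrom] = [g for _, _, g in items]

    def gene_at(self, chrom: str, pos0: int) -> Optional[GeneModel]:
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect.bisect_right(starts, pos0) - 1
        if i >= 0 and pos0 < self._ends[chrom][i]:
            return self._genes[chrom][i]
        return None

    def gene_overlapping(self, chrom: str, start0: int, end0: int) -> Optional[GeneModel]:
        """First gene whose CDS overlaps [start0, end0)."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = max(0, bisect.bisect_right(starts, start0) - 1)
        while i < len(starts) and starts[i] < end0:
            if self._ends[chrom][i] > start0:
                return self._genes[chrom][i]
            i += 1
        return None

    def union_length(self, chrom: Optional[str] = None) -> int:
        """Total CDS compartment length (union, no double counting)."""
        total = 0
        chroms = [chrom] if chrom else list(self._starts)
        for c in chroms:
            last_end = -1
            for s, e in zip(self._starts.get(c, []), self._ends.get(c, [])):
                s = max(s, last_end)
                if e > s:
                    total += e - s
                last_end = max(last_end, e)
        return total


# ------------------------------------------------------------ annotation


def coding_sequence(gene: GeneModel, seqs: Mapping[str, str]) -> str:
    """The transcript coding sequence in translation orientation."""
    plus = "".join(seqs[gene.chrom][s:e] for s, e in gene.cds)
    return plus if gene.strand == "+" else revcomp(plus)


def _coding_offset(gene: GeneModel, pos0: int) -> Optional[int]:
    """Offset of a genomic position within the coding sequence, or None."""
    off = 0
    plus_off = None
    for s, e in gene.cds:
        if s <= pos0 < e:
            plus_off = off + (pos0 - s)
            break
        off += e - s
    if plus_off is None:
        return None
    if gene.strand == "+":
        return plus_off
    return gene.cds_length - 1 - plus_off


def _indel_span(ref: str, pos0: int) -> tuple[int, int]:
    """Affected reference span of a left-aligned indel (anchor excluded
    for deletions; zero-length at the anchor for insertions)."""
    if len(ref) > 1:  # deletion: bases after the anchor are removed
        return pos0 + 1, pos0 + len(ref)
    return pos0, pos0 + 1  # insertion / SNV: the anchor base itself


def annotate_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    index: CdsIndex,
    seqs: Mapping[str, str],
) -> EffectAnnotation:
    """Classify one (chrom, pos, ref, alt); ``pos`` is 1-based."""
    pos0 = pos - 1
    seq = seqs[chrom]
    if seq[pos0 : pos0 + len(ref)].upper() != ref.upper():
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos}: "
            f"expected {seq[pos0:pos0 + len(ref)]!r}, VCF says {ref!r}"
        )
    if len(ref) == 1 and len(alt) == 1:  # SNV
        gene = index.gene_at(chrom, pos0)
        if gene is None:
            return EffectAnnotation(chrom, pos, ref, alt, None, Effect.NONCODING)
        cpos = _coding_offset(gene, pos0)
        cds = coding_sequence(gene, seqs)
        base = alt if gene.strand == "+" else revcomp(alt)
        ci = cpos // 3
        codon = cds[ci * 3 : ci * 3 + 3]
        mutated = codon[: cpos % 3] + base + codon[cpos % 3 + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutated).translate())
        if aa_alt == "*" and aa_ref != "*":
            effect = Effect.STOP_GAIN
        elif aa_alt != aa_ref:
            effect = Effect.MISSENSE
        else:
            effect = Effect.SYNONYMOUS
        return EffectAnnotation(chrom, pos, ref, alt, gene.gene_id, effect)
    # indel
    span_start, span_end = _indel_span(ref, pos0)
    if len(ref) > 1 and len(alt) > 1:
        raise ValueError(
            f"unnormalized allele pair {ref}>{alt} at {chrom}:{pos}; "
            "left-align to minimal representation first"
        )
    gene = index.gene_overlapping(chrom, span_start, span_end)
    if gene is None:
        return EffectAnnotation(chrom, pos, ref, alt, None, Effect.NONCODING)
    delta = abs(len(alt) - len(ref))
    effect = Effect.FRAMESHIFT if delta % 3 else Effect.INFRAME_INDEL
    return EffectAnnotation(chrom, pos, ref, alt, gene.gene_id, effect)


def annotate_calls(
    calls: Sequence[VariantCall],
    genes: Sequence[GeneModel],
    seqs: Mapping[str, str],
) -> list[EffectAnnotation]:
    """Annotate every alternative allele of every call."""
    index = CdsIndex(genes)
    out = []
    for call in calls:
        for alt in call.alts:
            out.append(annotate_effect(call.chrom, call.pos, call.ref, alt, index, seqs))
    return out


def genes_with_high_impact(annotations: Sequence[EffectAnnotation]) -> set[str]:
    """Distinct genes carrying at least one high-impact variant allele."""
    return {
        a.gene_id for a in annotations if a.is_high_impact and a.gene_id is not None
    }


# ------------------------------------------------------------ frame analysis


@dataclass
class IndelFrameTable:
    inside_lengths: dict[int, int]
    outside_lengths: dict[int, int]
    inside_div3: int
    inside_total: int
    outside_div3: int
    outside_total: int
    cds_length: int
    genome_length: int
    inside_density_per_mbp: float
    outside_density_per_mbp: float
    density_ratio: float  # inside / outside density (depletion when < 1)
    statistic: float
    p_value: float
    method: str

    @property
    def inside_div3_fraction(self) -> float:
        return self.inside_div3 / self.inside_total if self.inside_total else float("nan")

    @property
    def outside_div3_fraction(self) -> float:
        return self.outside_div3 / self.outside_total if self.outside_total else float("nan")


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float, str]:
    """Two-sided test of p1 == p2: pooled normal z-test, hypergeometric
    (Fisher exact) fallback when any expected cell is below 5."""
    if n1 == 0 or n2 == 0:
        return float("nan"), float("nan"), "undefined"
    p_pool = (x1 + x2) / (n1 + n2)
    expected = [
        n1 * p_pool, n1 * (1 - p_pool), n2 * p_pool, n2 * (1 - p_pool),
    ]
    if min(expected) < 5:
        table = [[x1, n1 - x1], [x2, n2 - x2]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p), "fisher_exact"
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0, "normal"
    z = (x1 / n1 - x2 / n2) / se
    return float(z), float(2 * stats.norm.sf(abs(z))), "normal"


def indel_frame_analysis(
    indels: Sequence[tuple[str, int, str, str]] | Sequence[VariantCall],
    genes: Sequence[GeneModel],
    genome_length: int,
    index: Optional[CdsIndex] = None,
) -> IndelFrameTable:
    """Length/frame comparison of InDels inside vs outside CDS.

    ``indels`` may be VariantCalls or (chrom, pos, ref, alt) tuples with
    1-based positions. Compartment membership: deletions by reference
    span overlap, insertions by their anchor base.
    """
    if index is None:
        index = CdsIndex(genes)
    cds_len = index.union_length()
    if cds_len == 0:
        raise ValueError("zero CDS compartment length")
    if genome_length <= cds_len:
        raise ValueError("genome length must exceed CDS length")
    inside: list[int] = []
    outside: list[int] = []
    for item in indels:
        if isinstance(item, VariantCall):
            chrom, pos, ref, alt = item.chrom, item.pos, item.ref, item.primary_alt
        else:
            chrom, pos, ref, alt = item
        length = abs(len(alt) - len(ref))
        if length == 0:
            raise ValueError(f"not an indel at {chrom}:{pos}")
        span = _indel_span(ref, pos - 1)
        target = inside if index.gene_overlapping(chrom, *span) else outside
        target.append(length)
    inside_hist = dict(sorted(zip(*np.unique(inside, return_counts=True)))) if inside else {}
    outside_hist = dict(sorted(zip(*np.unique(outside, return_counts=True)))) if outside else {}
    x1 = sum(1 for ln in inside if ln % 3 == 0)
    x2 = sum(1 for ln in outside if ln % 3 == 0)
    statistic, p, method = two_proportion_test(x1, len(inside), x2, len(outside))
    mbp = 1_000_000
    inside_density = len(inside) / (cds_len / mbp)
    outside_density = len(outside) / ((genome_length - cds_len) / mbp)
    return IndelFrameTable(
        inside_lengths={int(k): int(v) for k, v in inside_hist.items()},
        outside_lengths={int(k): int(v) for k, v in outside_hist.items()},
        inside_div3=x1,
        inside_total=len(inside),
        outside_div3=x2,
        outside_total=len(outside),
        cds_length=cds_len,
        genome_length=genome_length,
        inside_density_per_mbp=inside_density,
        outside_density_per_mbp=outside_density,
        density_ratio=inside_density / outside_density if outside_density else float("inf"),
        statistic=statistic,
        p_value=p,
        method=method,
    )
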