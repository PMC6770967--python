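"""Shared domain records and small sequence utilities.

Coordinate conventions: all in-memory coordinates are 0-based half-open.
VCF and GFF3 files are written/read 1-based; BED and bedGraph stay
0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC ACGTN only)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with a single CDS chain (one transcript).

    ``cds`` holds 0-based half-open intervals ordered by genomic position;
    for minus-strand genes translation runs from the last interval backwards.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad bounds for {self.gene_id}")
        for s, e in self.cds:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"CDS outside gene bounds for {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CopySegment:
    """A genomic interval present in ``copy_number`` haplophase copies."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant with known carrier count among local copies."""

    chrom: str
    pos0: int  # 0-based position of the (anchor) reference base
    ref: str
    alt: str
    vclass: str  # 'snv' | 'insertion' | 'deletion'
    carriers: int
    copy_number: int
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError("truth variants require copy_number >= 1")
        if not (1 <= self.carriers <= self.copy_number):
            raise ValueError("carriers must be in 1..copy_number")

    @property
    def fraction(self) -> float:
        """True alternative-allele fraction (carriers / copy number)."""
        return self.carriers / self.copy_number

    @property
    def pos1(self) -> int:
        return self.pos0 + 1


@dataclass
class VariantCall:
    """A small-variant site with total and per-allele read depths.

    ``ad`` lists depths for the reference allele first, then each
    alternative allele in order. ``pos`` is 1-based (VCF convention).
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    dp: int
    ad: tuple[int, ...]
    vid: Optional[str] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.alts) < 1:
            raise ValueError("a variant needs at least one alternative allele")
        if len(self.ad) != 1 + len(self.alts):
            raise ValueError("AD length must be 1 + number of alt alleles")
        if sum(self.ad) > self.dp:
            raise ValueError("sum(AD) must not exceed DP")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def primary_alt(self) -> str:
        """The alternative allele with the highest read depth."""
        alt_ads = self.ad[1:]
        return self.alts[max(range(len(self.alts)), key=lambda i: alt_ads[i])]

    @property
    def vclass(self) -> str:
        alt = self.primary_alt
        if len(self.ref) == 1 and len(alt) == 1:
            return "snv"
        if len(alt) > len(self.ref):
            return "insertion"
        if len(alt) < len(self.ref):
            return "deletion"
        return "mnv"

    @property
    def is_snv(self) -> bool:
        return self.vclass == "snv"

    @property
    def is_indel(self) -> bool:
        return self.vclass in ("insertion", "deletion")

    @property
    def indel_length(self) -> int:
        """Absolute length change of the primary alternative allele."""
        return abs(len(self.primary_alt) - len(self.ref))

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alts)
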