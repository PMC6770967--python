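"""Truth-labelled aneuploid genome simulator.

Generates a reference genome with annotated single-CDS genes, partitions
each chromosome into integer-copy-number segments, plants small variants
on a subset of the local haplophase copies, and simulates per-base depth,
VCF allele depths, and copy-proportional RNA allele counts. Every stage
is driven by a single seeded :class:`numpy.random.Generator`, so identical
inputs yield byte-identical output files.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .core import STOP_CODONS, CopySegment, GeneModel, TruthVariant, VariantCall, revcomp
from . import io

BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOP_CODONS
)
_STOPS = tuple(sorted(STOP_CODONS))

DEFAULT_ORGANELLES = {"plastome": 20_000, "chondrome": 20_000}


@dataclass
class GenomeSpec:
    """Parameters for reference-genome and annotation generation.

    Gene lengths are rounded down to the nearest multiple of 3 so that
    every CDS is a whole number of codons; each CDS starts with ATG and
    ends with a stop codon. Two small organelle replicons ("plastome",
    "chondrome") carry no genes and are excluded from the copy map.
    """

    chromosome_lengths: Mapping[str, int]
    n_genes: int = 0
    gene_length_range: tuple[int, int] = (300, 2400)
    intergenic_range: tuple[int, int] = (500, 5000)
    forward_strand_prob: float = 0.5
    gc_content: float = 0.36
    organelles: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_ORGANELLES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            raise ValueError("at least one chromosome is required")
        for name, length in {**self.chromosome_lengths, **self.organelles}.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
        lo, hi = self.gene_length_range
        if lo < 9 or hi < lo:
            raise ValueError("gene_length_range must satisfy 9 <= lo <= hi")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0.0 <= self.forward_strand_prob <= 1.0:
            raise ValueError("forward_strand_prob must be a probability")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")

    @property
    def nuclear_chroms(self) -> list[str]:
        return list(self.chromosome_lengths)

    @property
    def all_chrom_lengths(self) -> dict[str, int]:
        return {**self.chromosome_lengths, **self.organelles}


@dataclass
class NoiseModel:
    """Depth sampling model: expected depth at a base in a k-copy segment
    is ``k * depth_unit``; allele depths are binomial at the true carrier
    fraction. Organelle replicons use ``multiplier * depth_unit``."""

    depth_unit: float = 50.0
    family: str = "poisson"  # 'poisson' | 'nb'
    dispersion: float = 10.0  # NB size parameter (ignored for poisson)
    organelle_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"plastome": 0.5, "chondrome": 5.0}
    )
    rna_depth: float = 300.0

    def __post_init__(self) -> None:
        if self.depth_unit <= 0:
            raise ValueError("depth_unit must be > 0")
        if self.family not in ("poisson", "nb"):
            raise ValueError("family must be 'poisson' or 'nb'")

    def sample_depth(self, mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
        if mean <= 0:
            return np.zeros(size, dtype=np.int64)
        if self.family == "poisson":
            return rng.poisson(mean, size=size).astype(np.int64)
        r = self.dispersion
        return rng.negative_binomial(r, r / (r + mean), size=size).astype(np.int64)


# ------------------------------------------------------------ reference


def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return np.frombuffer(b"ACGT", dtype="S1")[idx].copy()


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """A CDS of ``length`` bp (multiple of 3): ATG + non-stop codons + stop."""
    n_inner = length // 3 - 2
    inner = rng.integers(0, len(_NONSTOP_CODONS), size=n_inner)
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in inner) + stop


def generate_reference(
    spec: GenomeSpec, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate reference sequences and non-overlapping gene models.

    Genes are distributed over nuclear chromosomes proportionally to
    length and packed left to right with random intergenic spacing.
    Raises ``ValueError`` when the requested genes cannot be packed.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lengths = spec.chromosome_lengths
    total = sum(lengths.values())
    # largest-remainder apportioning of genes to chromosomes
    quotas = {c: spec.n_genes * lengths[c] / total for c in lengths}
    n_per = {c: int(q) for c, q in quotas.items()}
    remainder = spec.n_genes - sum(n_per.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - n_per[c], reverse=True)[:remainder]:
        n_per[c] += 1

    seqs: dict[str, str] = {}
    genes: list[GeneModel] = []
    counter = 1
    lo_gene, hi_gene = spec.gene_length_range
    for chrom in spec.nuclear_chroms:
        length = lengths[chrom]
        arr = _random_sequence(length, spec.gc_content, rng)
        pos = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
        placed = 0
        while placed < n_per[chrom]:
            glen = int(rng.integers(lo_gene, hi_gene + 1)) // 3 * 3
            if pos + glen > length:
                raise ValueError(
                    f"cannot fit {n_per[chrom]} genes on {chrom}: ran out of space "
                    f"after {placed}"
                )
            strand = "+" if rng.random() < spec.forward_strand_prob else "-"
            cds_seq = _random_cds(glen, rng)
            genomic = cds_seq if strand == "+" else revcomp(cds_seq)
            arr[pos : pos + glen] = np.frombuffer(genomic.encode(), dtype="S1")
            gid = f"gene{counter:05d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    start=pos,
                    end=pos + glen,
                    strand=strand,
                    cds=((pos, pos + glen),),
                )
            )
            counter += 1
            placed += 1
            pos += glen + int(
                rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1)
            )
        seqs[chrom] = arr.tobytes().decode()
    for name, length in spec.organelles.items():
        seqs[name] = _random_sequence(length, spec.gc_content, rng).tobytes().decode()
    return seqs, genes


# ------------------------------------------------------------ copy map

PlanType = Mapping[str, Sequence[tuple[Optional[int], int]]]


def plant_copy_map(
    chrom_lengths: Mapping[str, int],
    plan: Optional[PlanType] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    k_weights: Optional[Mapping[int, float]] = None,
    mean_segment_length: int = 500_000,
    min_segment_length: int = 10_000,
    k_max: int = 8,
) -> list[CopySegment]:
    """Partition chromosomes into copy-number segments.

    Explicit mode: ``plan[chrom]`` is a list of ``(length, k)`` tuples that
    must tile the chromosome exactly; a single ``(None, k)`` entry takes
    the remaining length. Random mode draws approximately geometric
    segment lengths and copy numbers from ``k_weights``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    segments: list[CopySegment] = []
    if plan is not None:
        for chrom, entries in plan.items():
            length = chrom_lengths[chrom]
            pos = 0
            for seg_len, k in entries:
                if not 0 <= k <= k_max:
                    raise ValueError(f"copy number {k} outside 0..{k_max}")
                if seg_len is None:
                    seg_len = length - pos
                if seg_len <= 0 or pos + seg_len > length:
                    raise ValueError(
                        f"segments exceed {chrom} length {length} at offset {pos}"
                    )
                segments.append(CopySegment(chrom, pos, pos + seg_len, k))
                pos += seg_len
            if pos != length:
                raise ValueError(
                    f"segments do not tile {chrom}: covered {pos} of {length} bp"
                )
        return segments
    weights = dict(k_weights or {1: 0.15, 2: 0.35, 3: 0.35, 5: 0.1, 0: 0.05})
    if any(k < 0 or k > k_max for k in weights):
        raise ValueError(f"copy numbers must lie in 0..{k_max}")
    ks = np.array(sorted(weights))
    ps = np.array([weights[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    for chrom, length in chrom_lengths.items():
        pos = 0
        while pos < length:
            seg_len = min_segment_length + int(
                rng.geometric(1.0 / max(1, mean_segment_length - min_segment_length))
            )
            seg_len = min(seg_len, length - pos)
            k = int(rng.choice(ks, p=ps))
            segments.append(CopySegment(chrom, pos, pos + seg_len, k))
            pos += seg_len
    return segments


# ------------------------------------------------------------ variants

CarrierRule = Union[str, Callable[[int, np.random.Generator], int]]


def _draw_carriers(rule: CarrierRule, k: int, rng: np.random.Generator) -> int:
    if callable(rule):
        return int(rule(k, rng))
    if rule == "single":
        return 1
    if rule == "all":
        return k
    if rule == "uniform":
        return int(rng.integers(1, k + 1))
    raise ValueError(f"unknown carrier rule {rule!r}")


def plant_variants(
    seqs: Mapping[str, str],
    copy_map: Sequence[CopySegment],
    *,
    snv_rate: float = 1e-3,
    indel_rate: float = 1e-3,
    indel_mean_length: float = 3.0,
    indel_max_length: int = 30,
    carrier_rule: CarrierRule = "single",
    genes: Sequence[GeneModel] = (),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[TruthVariant]:
    """Plant SNVs and small InDels in copy-number >= 1 segments.

    Rates are per base. InDel lengths follow a truncated geometric law
    with the given mean. The carrier rule fixes how many of the local k
    copies carry the alternative allele (default: exactly one, the
    asexual single-lineage model). Overlapping plants are dropped.
    """
    if snv_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    gene_lookup = _GeneLookup(genes)
    variants: list[TruthVariant] = []
    p_geom = min(1.0, 1.0 / max(indel_mean_length, 1.0))
    for seg in copy_map:
        if seg.copy_number < 1:
            continue
        seq = seqs[seg.chrom]
        n_snv = rng.binomial(seg.length, min(snv_rate, 1.0))
        n_indel = rng.binomial(seg.length, min(indel_rate, 1.0))
        n = n_snv + n_indel
        if n == 0:
            continue
        offsets = rng.choice(seg.length, size=min(n, seg.length), replace=False)
        classes = np.array(["snv"] * n_snv + ["indel"] * n_indel)[: offsets.size]
        order = np.argsort(offsets)
        blocked_until = -1
        for off, cls in zip(offsets[order], classes[order]):
            pos0 = seg.start + int(off)
            if pos0 <= blocked_until:
                continue
            ref_base = seq[pos0]
            if ref_base not in BASES:
                continue
            carriers = _draw_carriers(carrier_rule, seg.copy_number, rng)
            if cls == "snv":
                alt = BASES[(BASES.index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
                ref, vclass, span_end = ref_base, "snv", pos0
            else:
                ln = min(int(rng.geometric(p_geom)), indel_max_length)
                if rng.random() < 0.5:
                    ref = ref_base
                    alt = ref_base + _random_sequence(ln, 0.5, rng).tobytes().decode()
                    vclass, span_end = "insertion", pos0
                else:
                    if pos0 + 1 + ln > seg.end:
                        continue  # keep deletions within their segment
                    ref = seq[pos0 : pos0 + 1 + ln]
                    alt = ref_base
                    vclass, span_end = "deletion", pos0 + ln
            variants.append(
                TruthVariant(
                    chrom=seg.chrom,
                    pos0=pos0,
                    ref=ref,
                    alt=alt,
                    vclass=vclass,
                    carriers=carriers,
                    copy_number=seg.copy_number,
                    gene_id=gene_lookup.gene_at(seg.chrom, pos0),
                )
            )
            blocked_until = span_end
    variants.sort(key=lambda v: (v.chrom, v.pos0))
    return variants


class _GeneLookup:
    """Sorted-interval point lookup: position -> gene id (genes assumed
    non-overlapping per chromosome, as the generator guarantees)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._ids: dict[str, list[str]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: g.start)
            self._starts[chrom] = np.array([g.start for g in gs])
            self._ends[chrom] = np.array([g.end for g in gs])
            self._ids[chrom] = [g.gene_id for g in gs]

    def gene_at(self, chrom: str, pos0: int) -> Optional[str]:
        starts = self._starts.get(chrom)
        if starts is None or starts.size == 0:
            return None
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < self._ends[chrom][i]:
            return self._ids[chrom][i]
        return None


# ------------------------------------------------------------ coverage


def simulate_coverage(
    chrom_lengths: Mapping[str, int],
    copy_map: Sequence[CopySegment],
    noise: NoiseModel,
    *,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    organelle_lengths: Optional[Mapping[str, int]] = None,
) -> dict[str, np.ndarray]:
    """Per-base depth track: Poisson/NB around k*c per copy segment; zero-copy
    segments get exactly zero depth; organelles use their multipliers."""
    if rng is None:
        rng = np.random.default_rng(seed)
    track = {
        chrom: np.zeros(length, dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    for seg in copy_map:
        if seg.chrom not in track:
            raise KeyError(f"copy segment on unknown chromosome {seg.chrom}")
        track[seg.chrom][seg.start : seg.end] = noise.sample_depth(
            seg.copy_number * noise.depth_unit, seg.length, rng
        )
    for name, length in (organelle_lengths or {}).items():
        mult = noise.organelle_multipliers.get(name, 1.0)
        track[name] = noise.sample_depth(mult * noise.depth_unit, length, rng)
    return track


# ------------------------------------------------------------ VCF emission


def emit_vcf(
    truth: Sequence[TruthVariant],
    track: Mapping[str, np.ndarray],
    noise: NoiseModel,
    *,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[VariantCall]:
    """Sample DP/AD at each truth site; co-located same-ref variants are
    merged into one multi-allelic record with multinomial allele depths."""
    if rng is None:
        rng = np.random.default_rng(seed)
    by_site: dict[tuple[str, int, str], list[TruthVariant]] = {}
    for v in truth:
        arr = track.get(v.chrom)
        if arr is None or v.pos0 >= arr.size:
            raise ValueError(f"truth variant {v.chrom}:{v.pos1} outside coverage track")
        by_site.setdefault((v.chrom, v.pos0, v.ref), []).append(v)
    records: list[VariantCall] = []
    for (chrom, pos0, ref), group in sorted(by_site.items()):
        k = group[0].copy_number
        dp = int(max(1, track[chrom][pos0]))
        fracs = [v.carriers / k for v in group]
        p = np.array(fracs + [max(0.0, 1.0 - sum(fracs))])
        p = p / p.sum()
        counts = rng.multinomial(dp, p)
        alt_ads = tuple(int(c) for c in counts[:-1])
        ad = (dp - sum(alt_ads),) + alt_ads
        records.append(
            VariantCall(
                chrom=chrom,
                pos=pos0 + 1,
                ref=ref,
                alts=tuple(v.alt for v in group),
                dp=dp,
                ad=ad,
            )
        )
    return records


# ------------------------------------------------------------ RNA counts


def simulate_rna_counts(
    truth: Sequence[TruthVariant],
    noise: NoiseModel,
    *,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    expressed: Optional[set[str]] = None,
) -> list[dict]:
    """Copy-proportional RNA allele counts for genic truth variants.

    Total depth per site is the model's ``rna_depth`` (deterministic);
    the alternative count is binomial at the true carrier fraction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows: list[dict] = []
    total = int(round(noise.rna_depth))
    for v in truth:
        if v.gene_id is None:
            continue
        if expressed is not None and v.gene_id not in expressed:
            continue
        if total <= 0:
            alt_n = 0
        else:
            alt_n = int(rng.binomial(total, v.fraction))
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos1,
                "ref": v.ref,
                "alt": v.alt,
                "gene_id": v.gene_id,
                "ref_count": total - alt_n,
                "alt_count": alt_n,
            }
        )
    return rows


# ------------------------------------------------------------ bundle


def simulate_bundle(
    spec: GenomeSpec,
    noise: NoiseModel,
    outdir: str,
    *,
    plan: Optional[PlanType] = None,
    k_weights: Optional[Mapping[int, float]] = None,
    mean_segment_length: int = 500_000,
    snv_rate: float = 1e-3,
    indel_rate: float = 1e-3,
    carrier_rule: CarrierRule = "single",
    seed: Optional[int] = None,
) -> dict[str, str]:
    """Run every simulation stage and write the full file bundle.

    Returns a dict of logical name -> path. All randomness flows from one
    generator seeded with ``seed`` (default: the spec's seed).
    """
    io.ensure_dir(outdir)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    seqs, genes = generate_reference(spec, rng)
    copy_map = plant_copy_map(
        spec.chromosome_lengths,
        plan,
        rng=rng,
        k_weights=k_weights,
        mean_segment_length=mean_segment_length,
    )
    truth = plant_variants(
        seqs,
        copy_map,
        snv_rate=snv_rate,
        indel_rate=indel_rate,
        carrier_rule=carrier_rule,
        genes=genes,
        rng=rng,
    )
    track = simulate_coverage(
        spec.chromosome_lengths,
        copy_map,
        noise,
        rng=rng,
        organelle_lengths=spec.organelles,
    )
    records = emit_vcf(truth, track, noise, rng=rng)
    rna_rows = simulate_rna_counts(truth, noise, rng=rng)

    paths = {
        "fasta": f"{outdir}/reference.fasta",
        "gff": f"{outdir}/annotation.gff3",
        "copy_map": f"{outdir}/copy_map.bed",
        "truth": f"{outdir}/truth_variants.tsv",
        "depth": f"{outdir}/coverage.bedgraph",
        "vcf": f"{outdir}/variants.vcf",
        "rna": f"{outdir}/rna_counts.tsv",
    }
    io.write_fasta(seqs, paths["fasta"])
    io.write_gff3(genes, spec.all_chrom_lengths, paths["gff"])
    io.write_copy_map(copy_map, paths["copy_map"])
    io.write_truth_variants(truth, paths["truth"])
    io.write_bedgraph(track, paths["depth"])
    io.write_vcf(records, spec.all_chrom_lengths, paths["vcf"])
    io.write_rna_counts(rna_rows, paths["rna"])
    return paths
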