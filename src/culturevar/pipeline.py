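"""End-to-end orchestration: simulate -> coverage -> zygosity -> effects ->
InDel frames -> allele-specific expression, with a consolidated report.

Every stage writes plain-text outputs into the run directory; rerunning
with the same configuration and seed reproduces all files byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import __version__, ase, coverage, effects, io, synthetic, zygosity
from .core import VariantCall

log = logging.getLogger("culturevar")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly via JSON."""

    outdir: str = "culturevar_run"
    seed: int = 0

    # --- inputs (leave unset to simulate) -------------------------------
    fasta: Optional[str] = None
    gff: Optional[str] = None
    vcf: Optional[str] = None
    depth: Optional[str] = None
    rna_counts: Optional[str] = None

    # --- simulation -----------------------------------------------------
    chromosome_lengths: dict = field(default_factory=lambda: {"chr1": 5_000_000})
    n_genes: int = 300
    gene_length_range: tuple = (2100, 3000)
    intergenic_range: tuple = (5000, 15000)
    gc_content: float = 0.36
    organelles: dict = field(default_factory=lambda: dict(synthetic.DEFAULT_ORGANELLES))
    # (length, copy_number) tiles per chromosome; null length = remainder
    copy_plan: Optional[dict] = field(
        default_factory=lambda: {
            "chr1": [
                [1_200_000, 2],
                [800_000, 1],
                [1_000_000, 3],
                [500_000, 5],
                [100_000, 0],
                [None, 2],
            ]
        }
    )
    k_weights: Optional[dict] = None
    mean_segment_length: int = 500_000
    snv_rate: float = 5e-4
    indel_rate: float = 5e-4
    carrier_rule: str = "single"
    depth_unit: float = 50.0
    noise_family: str = "poisson"
    dispersion: float = 10.0
    organelle_multipliers: dict = field(
        default_factory=lambda: {"plastome": 0.5, "chondrome": 5.0}
    )
    rna_depth: float = 300.0

    # --- thresholds -----------------------------------------------------
    min_reads: int = 5
    min_frac: float = 0.05
    flank: int = 2000
    max_deviation: float = 0.20
    min_deletion_length: int = 100
    block_size: int = 100_000
    flank_tolerance: float = 0.20
    k_max: int = 8
    exact_limit: int = 10
    min_rna_depth: int = 10

    # ----------------------------------------------------------------
    def thresholds(self) -> zygosity.ZygosityThresholds:
        return zygosity.ZygosityThresholds(
            min_reads=self.min_reads,
            min_frac=self.min_frac,
            flank=self.flank,
            max_deviation=self.max_deviation,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["intergenic_range"] = list(self.intergenic_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        for key in ("gene_length_range", "intergenic_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path: str) -> None:
        with open(path, "w") as out:
            json.dump(self.to_dict(), out, indent=2, sort_keys=True)
            out.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # location-independent hash
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _plan_from_config(config: RunConfig):
    if config.copy_plan is None:
        return None
    return {
        chrom: [(None if ln is None else int(ln), int(k)) for ln, k in entries]
        for chrom, entries in config.copy_plan.items()
    }


def _json_dump(obj, path: str) -> None:
    with open(path, "w") as out:
        json.dump(obj, out, indent=2, sort_keys=True, allow_nan=True)
        out.write("\n")


# ------------------------------------------------------------ validation


def validate_inputs(
    fasta: Optional[str] = None,
    gff: Optional[str] = None,
    vcf: Optional[str] = None,
    depth: Optional[str] = None,
) -> list[str]:
    """Cross-check chromosome names/lengths, coordinate order and CDS
    frames across the provided files. Always returns a (possibly empty)
    list of problem descriptions."""
    problems: list[str] = []
    seqs = io.read_fasta(fasta) if fasta else None
    lengths = {c: len(s) for c, s in seqs.items()} if seqs else None

    if gff:
        try:
            genes = io.read_gff3(gff)
        except Exception as exc:  # malformed file is itself the finding
            problems.append(f"GFF3 unreadable: {exc}")
            genes = []
        for g in genes:
            if lengths is not None:
                if g.chrom not in lengths:
                    problems.append(f"gene {g.gene_id}: chromosome {g.chrom} not in FASTA")
                elif g.end > lengths[g.chrom]:
                    problems.append(f"gene {g.gene_id}: extends past end of {g.chrom}")
            if g.cds and g.cds_length % 3 != 0:
                problems.append(
                    f"gene {g.gene_id}: CDS length {g.cds_length} not a multiple of 3"
                )
    if vcf:
        calls = io.read_vcf(vcf)
        last: dict[str, int] = {}
        for call in calls:
            if lengths is not None and call.chrom not in lengths:
                problems.append(f"VCF {call.chrom}:{call.pos}: chromosome not in FASTA")
                continue
            if call.pos < last.get(call.chrom, 0):
                problems.append(f"VCF {call.chrom}:{call.pos}: positions not sorted")
            last[call.chrom] = call.pos
            if seqs is not None:
                ref = seqs[call.chrom][call.pos0 : call.pos0 + len(call.ref)]
                if ref.upper() != call.ref.upper():
                    problems.append(
                        f"VCF {call.chrom}:{call.pos}: REF {call.ref} does not match FASTA"
                    )
    if depth:
        track = io.read_depth(depth, None)
        for chrom, arr in track.items():
            if lengths is None:
                continue
            if chrom not in lengths:
                problems.append(f"depth track chromosome {chrom} not in FASTA")
            elif arr.size != lengths[chrom]:
                problems.append(
                    f"depth track for {chrom} covers {arr.size} bp, "
                    f"FASTA says {lengths[chrom]}"
                )
    return problems


# ------------------------------------------------------------ pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the consolidated report dict."""
    outdir = io.ensure_dir(config.outdir)
    config.to_json(f"{outdir}/config.json")
    log.info("run %s seed=%d outdir=%s", config.config_hash, config.seed, outdir)

    # ---- stage 0: inputs (simulate unless all paths are provided)
    simulated = not (config.fasta and config.gff and config.vcf and config.depth)
    if simulated:
        spec = synthetic.GenomeSpec(
            chromosome_lengths=dict(config.chromosome_lengths),
            n_genes=config.n_genes,
            gene_length_range=tuple(config.gene_length_range),
            intergenic_range=tuple(config.intergenic_range),
            gc_content=config.gc_content,
            organelles=dict(config.organelles),
            seed=config.seed,
        )
        noise = synthetic.NoiseModel(
            depth_unit=config.depth_unit,
            family=config.noise_family,
            dispersion=config.dispersion,
            organelle_multipliers=dict(config.organelle_multipliers),
            rna_depth=config.rna_depth,
        )
        paths = synthetic.simulate_bundle(
            spec,
            noise,
            f"{outdir}/sim",
            plan=_plan_from_config(config),
            k_weights=config.k_weights,
            mean_segment_length=config.mean_segment_length,
            snv_rate=config.snv_rate,
            indel_rate=config.indel_rate,
            carrier_rule=config.carrier_rule,
            seed=config.seed,
        )
    else:
        paths = {
            "fasta": config.fasta,
            "gff": config.gff,
            "vcf": config.vcf,
            "depth": config.depth,
            "rna": config.rna_counts,
        }

    seqs = io.read_fasta(paths["fasta"])
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    genes = io.read_gff3(paths["gff"])
    track = io.read_depth(paths["depth"], chrom_lengths)
    calls = io.read_vcf(paths["vcf"])
    rna_table = io.read_rna_counts(paths["rna"]) if paths.get("rna") else None
    log.info("loaded %d genes, %d variant records", len(genes), len(calls))

    # ---- stage 1: coverage / copy number
    zero_regions = coverage.find_zero_coverage_regions(
        {c: track[c] for c in track}, config.min_deletion_length
    )
    with open(f"{outdir}/zero_coverage.bed", "w") as out:
        for r in zero_regions:
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.length}\n")
    nuclear_genes = [g for g in genes if g.chrom in chrom_lengths]
    estimates, baseline = coverage.estimate_gene_copies(
        nuclear_genes,
        track,
        k_max=config.k_max,
        flank_tolerance=config.flank_tolerance,
    )
    with open(f"{outdir}/gene_copies.tsv", "w") as out:
        out.write("#gene_id\tchrom\tstart\tend\tmean_depth\tcopy_number\tsimilar_to_flanking\n")
        for e in estimates:
            flag = "." if e.similar_to_flanking is None else str(int(e.similar_to_flanking))
            out.write(
                f"{e.gene_id}\t{e.chrom}\t{e.start}\t{e.end}\t"
                f"{e.mean_depth:.3f}\t{e.copy_number}\t{flag}\n"
            )
    organelle_report = None
    chond = [c for c in track if "chondrome" in c]
    plast = [c for c in track if "plastome" in c]
    if chond and plast:
        organelle_report = coverage.organelle_coverage_ratio(track, chond, plast)
    baseline_report = {
        "unit": baseline.unit,
        "peaks": baseline.peaks,
        "valleys": baseline.valleys,
        "low_confidence": baseline.low_confidence,
        "bandwidth": baseline.bandwidth,
        "organelle_ratio": organelle_report,
    }
    _json_dump(baseline_report, f"{outdir}/baseline.json")
    similar_flags = [e.similar_to_flanking for e in estimates if e.similar_to_flanking is not None]
    log.info(
        "baseline unit=%.2f, %d zero-coverage regions", baseline.unit, len(zero_regions)
    )

    # ---- stage 2: zygosity
    thresholds = config.thresholds()
    classified = zygosity.classify_variants(calls, track, thresholds)
    passed = zygosity.pass_variants(classified)
    for cv in classified:
        cv.call.info["ZYG"] = cv.zygosity.value if cv.zygosity else "."
        cv.call.info["FILT"] = cv.filter_status.value
    io.write_vcf(
        [cv.call for cv in classified],
        chrom_lengths,
        f"{outdir}/variants.annotated.vcf",
        extra_header=[
            '##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity class">',
            '##INFO=<ID=FILT,Number=1,Type=String,Description="Filter status">',
        ],
        info_fields=["ZYG", "FILT"],
    )
    density = zygosity.variant_density(classified, chrom_lengths, config.block_size)
    with open(f"{outdir}/variant_density.tsv", "w") as out:
        out.write("#chrom\tblock_start\thomozygous\tdeviating_frequency\n")
        for chrom in sorted(density):
            hom = density[chrom][zygosity.Zygosity.HOMOZYGOUS.value]
            dev = density[chrom][zygosity.Zygosity.DEVIATING.value]
            for i, (h, d) in enumerate(zip(hom, dev)):
                out.write(f"{chrom}\t{i * config.block_size}\t{h}\t{d}\n")
    snv_only = [
        cv
        for cv in passed
        if cv.call.is_snv and all(len(a) == 1 for a in cv.call.alts) and len(cv.call.ref) == 1
    ]
    spectrum = zygosity.substitution_spectrum(snv_only)
    ratio = zygosity.snv_indel_ratio(classified)
    cov_hist = zygosity.coverage_histogram_at_variants(classified, track)
    n_hom = sum(1 for cv in passed if cv.zygosity is zygosity.Zygosity.HOMOZYGOUS)
    n_dev = sum(1 for cv in passed if cv.zygosity is zygosity.Zygosity.DEVIATING)
    _json_dump(
        {
            "directed": spectrum.directed,
            "collapsed": spectrum.collapsed,
            "cg_to_at_share": spectrum.cg_to_at_share,
            "total_snvs": spectrum.total,
            "snv_indel": ratio,
            "coverage_histograms": cov_hist,
        },
        f"{outdir}/spectrum.json",
    )
    log.info("pass=%d homozygous=%d deviating=%d", len(passed), n_hom, n_dev)

    # ---- stage 3: effects + InDel frames
    annotations = effects.annotate_calls([cv.call for cv in passed], genes, seqs)
    with open(f"{outdir}/effects.tsv", "w") as out:
        out.write("#chrom\tpos\tref\talt\tgene_id\teffect\timpact\n")
        for a in annotations:
            out.write(
                f"{a.chrom}\t{a.pos}\t{a.ref}\t{a.alt}\t{a.gene_id or '.'}\t"
                f"{a.effect.value}\t{a.impact}\n"
            )
    high_genes = effects.genes_with_high_impact(annotations)
    indel_calls = [cv.call for cv in passed if cv.call.is_indel]
    frame_table = None
    if indel_calls:
        nuclear_length = sum(
            length for chrom, length in chrom_lengths.items()
            if not ("chondrome" in chrom or "plastome" in chrom)
        )
        frame_table = effects.indel_frame_analysis(indel_calls, genes, nuclear_length)
        _json_dump(
            {
                "inside_lengths": frame_table.inside_lengths,
                "outside_lengths": frame_table.outside_lengths,
                "inside_div3_fraction": frame_table.inside_div3_fraction,
                "outside_div3_fraction": frame_table.outside_div3_fraction,
                "inside_density_per_mbp": frame_table.inside_density_per_mbp,
                "outside_density_per_mbp": frame_table.outside_density_per_mbp,
                "density_ratio": frame_table.density_ratio,
                "statistic": frame_table.statistic,
                "p_value": frame_table.p_value,
                "method": frame_table.method,
            },
            f"{outdir}/indel_frames.json",
        )

    # ---- stage 4: allele-specific expression
    ase_summary = None
    ase_records: list[ase.AseRecord] = []
    if rna_table is not None:
        ann_by_key = {}
        for a in annotations:
            if a.is_high_impact:
                ann_by_key.setdefault((a.chrom, a.pos, a.ref, a.alt), a.gene_id)
        triples = []
        for cv in passed:
            for alt in cv.call.alts:
                key = (cv.call.chrom, cv.call.pos, cv.call.ref, alt)
                if key in ann_by_key:
                    triples.append((cv.call, alt, ann_by_key[key]))
        ase_records, skipped = ase.collect_ase(triples, rna_table, config.min_rna_depth)
        with open(f"{outdir}/ase_records.tsv", "w") as out:
            out.write("#chrom\tpos\tref\talt\tgene_id\trna_ref\trna_alt\tdna_ref\tdna_alt\n")
            for r in ase_records:
                out.write(
                    f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.gene_id or '.'}\t"
                    f"{r.rna_ref}\t{r.rna_alt}\t{r.dna_ref}\t{r.dna_alt}\n"
                )
        if len(ase_records) >= 2:
            ase_summary = ase.ase_contrast(ase_records, config.exact_limit)
            ase_summary["skipped_joins"] = skipped
            _json_dump(ase_summary, f"{outdir}/ase_tests.json")

    # ---- report
    copy_class_counts: dict[str, int] = {}
    for e in estimates:
        copy_class_counts[str(e.copy_number)] = copy_class_counts.get(str(e.copy_number), 0) + 1
    n_excluded = len(classified) - len(passed)
    report = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash,
            "simulated_inputs": simulated,
        },
        "counts": {
            "genes": len(genes),
            "variants_in": len(classified),
            "variants_excluded": n_excluded,
            "variants_pass": len(passed),
            "homozygous": n_hom,
            "deviating_frequency": n_dev,
            "zero_coverage_regions": len(zero_regions),
            "gene_copy_classes": dict(sorted(copy_class_counts.items())),
            "high_impact_genes": len(high_genes),
            "high_impact_annotations": sum(1 for a in annotations if a.is_high_impact),
            "ase_records": len(ase_records),
        },
        "summary": {
            "ploidy_unit": baseline.unit,
            "deviating_fraction_of_pass": n_dev / (n_hom + n_dev) if (n_hom + n_dev) else None,
            "deviating_fraction_of_all": n_dev / len(classified) if classified else None,
            "fraction_similar_to_flanking": (
                sum(similar_flags) / len(similar_flags) if similar_flags else None
            ),
            "snv_indel_ratio": None if ratio["ratio"] == float("inf") else ratio["ratio"],
            "cg_to_at_share": spectrum.cg_to_at_share if spectrum.total else None,
            "indel_inside_div3_fraction": (
                frame_table.inside_div3_fraction if frame_table else None
            ),
            "indel_outside_div3_fraction": (
                frame_table.outside_div3_fraction if frame_table else None
            ),
            "indel_density_ratio": frame_table.density_ratio if frame_table else None,
            "organelle_ratio": organelle_report["ratio"] if organelle_report else None,
            "ase": ase_summary,
        },
        "conservation": {
            "in_equals_excluded_plus_pass": len(classified) == n_excluded + len(passed),
            "pass_equals_hom_plus_dev_plus_nonvariant": len(passed) == n_hom + n_dev,
        },
    }
    _json_dump(report, f"{outdir}/report.json")
    with open(f"{outdir}/report.txt", "w") as out:
        out.write(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = [
        f"culturevar {report['provenance']['version']} "
        f"(seed {report['provenance']['seed']}, config {report['provenance']['config_hash']})",
        "",
        "counts:",
    ]
    for key, val in report["counts"].items():
        lines.append(f"  {key}: {val}")
    lines.append("summary:")
    for key, val in report["summary"].items():
        if key == "ase":
            continue
        lines.append(f"  {key}: {val}")
    if report["summary"]["ase"]:
        a = report["summary"]["ase"]
        lines.append(
            f"  ase: rna p={a['rna']['p_value']:.3g} "
            f"genomic p={a['genomic']['p_value']:.3g} "
            f"(n={a['n_records']})"
        )
    return "\n".join(lines) + "\n"
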