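"""Simulator tests: determinism, structural invariants, sampling laws."""
import hashlib

import numpy as np
import pytest
from scipy import stats

from culturevar import io, synthetic
from culturevar.core import STOP_CODONS, CopySegment, TruthVariant, revcomp
from culturevar.synthetic import GenomeSpec, NoiseModel


def _sha(path):
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


# ------------------------------------------------------------ reference


def test_empty_annotation_case(tmp_path):
    spec = GenomeSpec({"c1": 10_000}, n_genes=0, organelles={}, seed=3)
    seqs, genes = synthetic.generate_reference(spec)
    assert list(seqs) == ["c1"] and len(seqs["c1"]) == 10_000
    assert genes == []
    io.write_fasta(seqs, str(tmp_path / "r.fa"))
    io.write_gff3(genes, {"c1": 10_000}, str(tmp_path / "r.gff3"))
    lines = (tmp_path / "r.gff3").read_text().splitlines()
    assert all(line.startswith("#") for line in lines)
    assert sum(1 for line in (tmp_path / "r.fa").read_text().splitlines() if line.startswith(">")) == 1


def test_reference_determinism_byte_identical(tmp_path):
    spec = GenomeSpec(
        {"c1": 100_000, "c2": 100_000}, n_genes=20, organelles={}, seed=1
    )
    for sub in ("a", "b"):
        d = tmp_path / sub
        d.mkdir()
        seqs, genes = synthetic.generate_reference(spec)
        io.write_fasta(seqs, str(d / "r.fa"))
        io.write_gff3(genes, spec.all_chrom_lengths, str(d / "r.gff3"))
    assert _sha(tmp_path / "a/r.fa") == _sha(tmp_path / "b/r.fa")
    assert _sha(tmp_path / "a/r.gff3") == _sha(tmp_path / "b/r.gff3")


def test_cds_lengths_multiple_of_three_by_independent_scan(tmp_path):
    # oracle: raw text re-parse of the emitted GFF3, no package parser
    spec = GenomeSpec({"c1": 200_000}, n_genes=30, organelles={}, seed=1)
    seqs, genes = synthetic.generate_reference(spec)
    path = tmp_path / "r.gff3"
    io.write_gff3(genes, spec.all_chrom_lengths, str(path))
    cds_spans = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[2] == "CDS":
            cds_spans.append((fields[8], int(fields[4]) - int(fields[3]) + 1))
    assert len(cds_spans) == 30
    assert all(length % 3 == 0 for _, length in cds_spans)


def test_cds_start_and_stop_codons_strand_aware():
    spec = GenomeSpec({"c1": 300_000}, n_genes=40, organelles={}, seed=5)
    seqs, genes = synthetic.generate_reference(spec)
    assert {g.strand for g in genes} == {"+", "-"}
    for g in genes:
        cds = seqs[g.chrom][g.start : g.end]
        if g.strand == "-":
            cds = revcomp(cds)
        assert cds[:3] == "ATG"
        assert cds[-3:] in STOP_CODONS
        # no internal stop codon
        assert all(cds[i : i + 3] not in STOP_CODONS for i in range(3, len(cds) - 3, 3))


def test_gene_packing_error():
    spec = GenomeSpec({"c1": 5_000}, n_genes=50, organelles={}, seed=1)
    with pytest.raises(ValueError, match="cannot fit"):
        synthetic.generate_reference(spec)


def test_gff3_roundtrip(tmp_path):
    spec = GenomeSpec({"c1": 100_000}, n_genes=10, organelles={}, seed=2)
    seqs, genes = synthetic.generate_reference(spec)
    path = str(tmp_path / "r.gff3")
    io.write_gff3(genes, spec.all_chrom_lengths, path)
    parsed = io.read_gff3(path)
    assert [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.cds) for g in parsed] == [
        (g.gene_id, g.chrom, g.start, g.end, g.strand, g.cds) for g in genes
    ]


# ------------------------------------------------------------ copy map


def test_copy_map_identity():
    segs = synthetic.plant_copy_map({"c1": 1000}, {"c1": [(None, 2)]}, seed=0)
    assert segs == [CopySegment("c1", 0, 1000, 2)]


def test_copy_map_roundtrip_bed(tmp_path):
    plan = {"c1": [(100, 1), (200, 2), (300, 3), (150, 5), (250, 0)]}
    segs = synthetic.plant_copy_map({"c1": 1000}, plan, seed=0)
    path = str(tmp_path / "cm.bed")
    io.write_copy_map(segs, path)
    assert io.read_copy_map(path) == segs
    assert [(s.length, s.copy_number) for s in segs] == plan["c1"]


def test_copy_map_rejects_overflow_and_gaps():
    with pytest.raises(ValueError, match="exceed"):
        synthetic.plant_copy_map({"c1": 100}, {"c1": [(200, 2)]}, seed=0)
    with pytest.raises(ValueError, match="tile"):
        synthetic.plant_copy_map({"c1": 100}, {"c1": [(50, 2)]}, seed=0)


def test_copy_map_partitions_exactly():
    segs = synthetic.plant_copy_map(
        {f"c{i}": 200_000 for i in range(5)}, seed=11, mean_segment_length=40_000
    )
    by_chrom = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, ss in by_chrom.items():
        assert ss[0].start == 0 and ss[-1].end == 200_000
        assert all(a.end == b.start for a, b in zip(ss, ss[1:]))


def test_random_copy_map_length_distribution():
    # Monte-Carlo: mean segment length within 10% of request over 100 chroms
    target = 50_000
    segs = synthetic.plant_copy_map(
        {f"c{i}": 1_000_000 for i in range(100)},
        seed=1,
        mean_segment_length=target,
        min_segment_length=1000,
    )
    interior = [s.length for s in segs if s.end != 1_000_000]  # drop truncated tails
    assert np.mean(interior) == pytest.approx(target, rel=0.10)


# ------------------------------------------------------------ variants


def test_zero_rates_give_empty_truth(small_bundle):
    out = synthetic.plant_variants(
        small_bundle["seqs"], small_bundle["copy_map"], snv_rate=0, indel_rate=0, seed=1
    )
    assert out == []


def test_single_carrier_rule_in_k3_segment(small_bundle):
    segs = [s for s in small_bundle["copy_map"] if s.copy_number == 3]
    out = synthetic.plant_variants(
        small_bundle["seqs"], segs, snv_rate=1e-3, indel_rate=0, seed=2
    )
    assert out and all(v.fraction == pytest.approx(1 / 3) for v in out)


def test_no_variants_in_zero_copy_segments(small_bundle):
    zero = [
        (s.start, s.end) for s in small_bundle["copy_map"] if s.copy_number == 0
    ]
    for v in small_bundle["truth"]:
        assert not any(s <= v.pos0 < e for s, e in zero)


def test_snv_indel_ratio_binomial_bounds():
    seqs = {"c1": "ACGT" * 25_000}
    segs = [CopySegment("c1", 0, 100_000, 2)]
    out = synthetic.plant_variants(seqs, segs, snv_rate=2e-3, indel_rate=2e-3, seed=1)
    n_snv = sum(1 for v in out if v.vclass == "snv")
    total = len(out)
    # binomial oracle: equal rates => n_snv ~ Binomial(total, 0.5)
    lo, hi = stats.binom.interval(0.95, total, 0.5)
    assert lo <= n_snv <= hi


def test_variant_alleles_match_reference(small_bundle):
    seqs = small_bundle["seqs"]
    for v in small_bundle["truth"]:
        assert seqs[v.chrom][v.pos0 : v.pos0 + len(v.ref)] == v.ref
        if v.vclass == "snv":
            assert v.alt != v.ref and len(v.alt) == 1
        elif v.vclass == "insertion":
            assert v.alt[0] == v.ref and len(v.alt) > 1
        else:
            assert v.ref[0] == v.alt and len(v.ref) > 1


# ------------------------------------------------------------ coverage


def test_zero_copy_segment_depth_exactly_zero(small_bundle):
    track = small_bundle["track"]
    for seg in small_bundle["copy_map"]:
        if seg.copy_number == 0:
            assert not track[seg.chrom][seg.start : seg.end].any()


def test_poisson_mean_concentration():
    segs = [CopySegment("c1", 0, 1_000_000, 1), CopySegment("c1", 1_000_000, 2_000_000, 3)]
    track = synthetic.simulate_coverage(
        {"c1": 2_000_000}, segs, NoiseModel(depth_unit=50.0), seed=4
    )
    m1 = track["c1"][:1_000_000].mean()
    m3 = track["c1"][1_000_000:].mean()
    assert 49 <= m1 <= 51
    assert 2.9 <= m3 / m1 <= 3.1


def test_negative_binomial_family_runs():
    segs = [CopySegment("c1", 0, 100_000, 2)]
    track = synthetic.simulate_coverage(
        {"c1": 100_000}, segs, NoiseModel(family="nb", dispersion=5.0), seed=4
    )
    assert track["c1"].mean() == pytest.approx(100, rel=0.05)
    assert track["c1"].var() > track["c1"].mean()  # overdispersed


# ------------------------------------------------------------ VCF


def test_fixed_allele_when_all_copies_carry(small_bundle):
    v = TruthVariant("c1", 10, "A", "T", "snv", carriers=2, copy_number=2)
    track = {"c1": np.full(100, 100)}
    recs = synthetic.emit_vcf([v], track, NoiseModel(), seed=1)
    assert recs[0].ad == (0, 100)


def test_half_fraction_binomial_interval():
    v = TruthVariant("c1", 10, "A", "T", "snv", carriers=1, copy_number=2)
    track = {"c1": np.full(100, 100)}
    alt_depths = [
        synthetic.emit_vcf([v], track, NoiseModel(), seed=s)[0].ad[1] for s in range(30)
    ]
    lo, hi = stats.binom.interval(0.99, 100, 0.5)  # exact binomial oracle
    inside = sum(lo <= a <= hi for a in alt_depths)
    assert inside >= 27  # 99% interval, 30 draws


def test_vcf_roundtrip_conservation(bundle_dir, small_bundle):
    calls = io.read_vcf(bundle_dir["vcf"])
    truth = io.read_truth_variants(bundle_dir["truth"])
    sites = {(v.chrom, v.pos0, v.ref) for v in truth}
    assert len(calls) == len(sites)
    for call in calls:
        assert sum(call.ad) == call.dp


def test_emit_vcf_outside_track_errors():
    v = TruthVariant("c9", 10, "A", "T", "snv", carriers=1, copy_number=2)
    with pytest.raises(ValueError, match="outside coverage track"):
        synthetic.emit_vcf([v], {"c1": np.ones(5, dtype=int)}, NoiseModel(), seed=0)


def test_allele_fraction_law(small_bundle):
    """Pooled alt fraction per (carriers, k) class within 3 binomial SE."""
    by_class = {}
    truth_by_site = {(v.chrom, v.pos0): v for v in small_bundle["truth"]}
    for rec in small_bundle["records"]:
        v = truth_by_site[(rec.chrom, rec.pos0)]
        tot_alt, tot_dp = by_class.get((v.carriers, v.copy_number), (0, 0))
        by_class[(v.carriers, v.copy_number)] = (tot_alt + rec.ad[1], tot_dp + rec.dp)
    for (carriers, k), (alt, dp) in by_class.items():
        if dp < 1000:
            continue
        p = carriers / k
        se = np.sqrt(p * (1 - p) / dp)
        assert abs(alt / dp - p) <= 3 * se + 1e-9


# ------------------------------------------------------------ RNA


def test_rna_all_copies_carry_reference_zero():
    v = TruthVariant("c1", 10, "A", "T", "snv", 2, 2, gene_id="g1")
    rows = synthetic.simulate_rna_counts([v], NoiseModel(rna_depth=200), seed=1)
    assert rows[0]["ref_count"] == 0 and rows[0]["alt_count"] == 200


def test_rna_third_fraction_binomial_bounds():
    v = TruthVariant("c1", 10, "A", "T", "snv", 1, 3, gene_id="g1")
    counts = [
        synthetic.simulate_rna_counts([v], NoiseModel(rna_depth=300), seed=s)[0]["alt_count"]
        for s in range(30)
    ]
    lo, hi = stats.binom.interval(0.99, 300, 1 / 3)
    assert sum(lo <= c <= hi for c in counts) >= 27
    assert np.mean(counts) == pytest.approx(100, rel=0.15)


def test_rna_zero_depth_all_zero():
    v = TruthVariant("c1", 10, "A", "T", "snv", 1, 3, gene_id="g1")
    rows = synthetic.simulate_rna_counts([v], NoiseModel(rna_depth=0), seed=1)
    assert rows[0]["ref_count"] == 0 and rows[0]["alt_count"] == 0


def test_rna_skips_intergenic_variants():
    v = TruthVariant("c1", 10, "A", "T", "snv", 1, 3, gene_id=None)
    assert synthetic.simulate_rna_counts([v], NoiseModel(), seed=1) == []


# ------------------------------------------------------------ bundle


def test_bundle_determinism(tmp_path):
    spec = GenomeSpec({"c1": 200_000}, n_genes=10, seed=9)
    noise = NoiseModel()
    hashes = []
    for sub in ("a", "b"):
        paths = synthetic.simulate_bundle(
            spec, noise, str(tmp_path / sub), plan={"c1": [(None, 2)]}, seed=9
        )
        hashes.append({k: _sha(p) for k, p in paths.items()})
    assert hashes[0] == hashes[1]
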