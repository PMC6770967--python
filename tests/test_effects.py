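"""Effect annotation vs a full-mutant-translation oracle; frame analysis."""
import numpy as np
import pytest
from Bio.Seq import Seq

from culturevar import effects, synthetic
from culturevar.core import GeneModel, VariantCall, revcomp
from culturevar.effects import CdsIndex, Effect, annotate_effect


def make_gene(cds_seq, strand="+", offset=100, chrom="c1", pad=100, gene_id="g1"):
    """Embed a CDS into a random-free padded chromosome."""
    genomic = cds_seq if strand == "+" else revcomp(cds_seq)
    seq = "A" * offset + genomic + "C" * pad
    gene = GeneModel(
        gene_id, chrom, offset, offset + len(cds_seq), strand,
        ((offset, offset + len(cds_seq)),),
    )
    return {chrom: seq}, gene


def translation_oracle(seqs, gene, pos0, ref, alt):
    """Independent oracle: rebuild the mutant chromosome, re-extract the
    CDS (coordinates shift only downstream of an indel, which for a
    single-interval CDS is handled by slicing the mutant string), and
    compare full protein translations."""
    chrom_seq = seqs[gene.chrom]
    assert chrom_seq[pos0 : pos0 + len(ref)] == ref
    s, e = gene.cds[0]
    # compartment membership identical to the package convention
    if len(ref) > 1:  # deletion
        span = (pos0 + 1, pos0 + len(ref))
    else:
        span = (pos0, pos0 + 1)
    overlaps = span[0] < e and span[1] > s
    if len(ref) == 1 and len(alt) == 1:
        if not (s <= pos0 < e):
            return Effect.NONCODING
        mutant = chrom_seq[:pos0] + alt + chrom_seq[pos0 + 1 :]
        wt_cds = chrom_seq[s:e]
        mut_cds = mutant[s:e]
        if gene.strand == "-":
            wt_cds, mut_cds = revcomp(wt_cds), revcomp(mut_cds)
        wt = str(Seq(wt_cds).translate())
        mut = str(Seq(mut_cds).translate())
        if wt == mut:
            return Effect.SYNONYMOUS
        diff = [i for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
        if any(mut[i] == "*" and wt[i] != "*" for i in diff):
            return Effect.STOP_GAIN
        return Effect.MISSENSE
    if not overlaps:
        return Effect.NONCODING
    return Effect.FRAMESHIFT if abs(len(alt) - len(ref)) % 3 else Effect.INFRAME_INDEL


# ------------------------------------------------------------ basics


def test_stop_gain_tgg_to_tga_plus_strand():
    cds = "ATG" + "TGG" + "AAA" * 5 + "TAA"
    seqs, gene = make_gene(cds, "+")
    # TGG codon occupies offsets 103..105; G->A at middle base gives TGA
    ann = annotate_effect("c1", 105 + 0, "G", "A", CdsIndex([gene]), seqs)
    assert ann.effect is Effect.STOP_GAIN and ann.impact == "high"


def test_indel_frame_rules_in_cds():
    cds = "ATG" + "AAA" * 10 + "TAA"
    seqs, gene = make_gene(cds, "+")
    idx = CdsIndex([gene])
    seq = seqs["c1"]
    # 4 bp deletion (frameshift), 3 bp deletion (inframe), anchored at 110
    ref4 = seq[110:115]
    ann = annotate_effect("c1", 111, ref4, ref4[0], idx, seqs)
    assert ann.effect is Effect.FRAMESHIFT and ann.is_high_impact
    ref3 = seq[110:114]
    ann = annotate_effect("c1", 111, ref3, ref3[0], idx, seqs)
    assert ann.effect is Effect.INFRAME_INDEL and not ann.is_high_impact
    # insertions: anchor-in-CDS convention
    ann = annotate_effect("c1", 111, seq[110], seq[110] + "GT", idx, seqs)
    assert ann.effect is Effect.FRAMESHIFT


def test_noncoding_outside_cds():
    cds = "ATG" + "AAA" * 10 + "TAA"
    seqs, gene = make_gene(cds, "+")
    ann = annotate_effect("c1", 10, "A", "G", CdsIndex([gene]), seqs)
    assert ann.effect is Effect.NONCODING and ann.gene_id is None


def test_deletion_anchor_before_cds_overlapping_cds():
    # anchor base just before the CDS; deleted span reaches into it
    cds = "ATG" + "AAA" * 10 + "TAA"
    seqs, gene = make_gene(cds, "+")
    seq = seqs["c1"]
    ref = seq[98:103]  # deletes bases 99..102, overlapping CDS start at 100
    ann = annotate_effect("c1", 99, ref, ref[0], CdsIndex([gene]), seqs)
    assert ann.effect is Effect.FRAMESHIFT


def test_insertion_anchor_outside_cds_is_noncoding():
    cds = "ATG" + "AAA" * 10 + "TAA"
    seqs, gene = make_gene(cds, "+")
    ann = annotate_effect("c1", 99, seqs["c1"][98], seqs["c1"][98] + "GGGG",
                          CdsIndex([gene]), seqs)
    assert ann.effect is Effect.NONCODING


def test_reference_mismatch_errors():
    cds = "ATG" + "AAA" * 10 + "TAA"
    seqs, gene = make_gene(cds, "+")
    wrong = "G" if seqs["c1"][104] != "G" else "T"
    with pytest.raises(ValueError, match="mismatch"):
        annotate_effect("c1", 105, wrong, "A", CdsIndex([gene]), seqs)


# ------------------------------------------------------------ oracle sweeps


@pytest.mark.parametrize("strand", ["+", "-"])
def test_exhaustive_snvs_thirty_codon_gene(strand):
    rng = np.random.default_rng(17)
    inner = "".join(
        synthetic._NONSTOP_CODONS[i]
        for i in rng.integers(0, len(synthetic._NONSTOP_CODONS), size=28)
    )
    cds = "ATG" + inner + "TGA"
    assert len(cds) == 90
    seqs, gene = make_gene(cds, strand)
    idx = CdsIndex([gene])
    n_checked = 0
    for pos0 in range(gene.start, gene.end):
        ref = seqs["c1"][pos0]
        for alt in "ACGT":
            if alt == ref:
                continue
            got = annotate_effect("c1", pos0 + 1, ref, alt, idx, seqs).effect
            expected = translation_oracle(seqs, gene, pos0, ref, alt)
            assert got is expected, (strand, pos0, ref, alt)
            n_checked += 1
    assert n_checked == 270


def test_random_variants_match_oracle_both_strands():
    rng = np.random.default_rng(23)
    for strand in ("+", "-"):
        inner = "".join(
            synthetic._NONSTOP_CODONS[i]
            for i in rng.integers(0, len(synthetic._NONSTOP_CODONS), size=60)
        )
        seqs, gene = make_gene("ATG" + inner + "TAA", strand, offset=300, pad=300)
        idx = CdsIndex([gene])
        seq = seqs["c1"]
        for _ in range(200):
            pos0 = int(rng.integers(250, gene.end + 40))
            kind = rng.random()
            if kind < 0.5:
                ref = seq[pos0]
                alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
            elif kind < 0.75:
                ln = int(rng.integers(1, 7))
                ref = seq[pos0 : pos0 + 1 + ln]
                alt = ref[0]
            else:
                ln = int(rng.integers(1, 7))
                ref = seq[pos0]
                alt = ref + "ACGT" * 2
                alt = alt[: 1 + ln]
            got = annotate_effect("c1", pos0 + 1, ref, alt, idx, seqs).effect
            assert got is translation_oracle(seqs, gene, pos0, ref, alt)


# ------------------------------------------------------------ gene sets


def test_high_impact_gene_set_semantics():
    assert effects.genes_with_high_impact([]) == set()
    anns = [
        effects.EffectAnnotation("c1", 10, "A", "T", "g1", Effect.STOP_GAIN),
        effects.EffectAnnotation("c1", 20, "A", "AT", "g1", Effect.FRAMESHIFT),
        effects.EffectAnnotation("c1", 30, "A", "T", "g1", Effect.STOP_GAIN),
        effects.EffectAnnotation("c1", 40, "A", "T", "g2", Effect.MISSENSE),
    ]
    assert effects.genes_with_high_impact(anns) == {"g1"}


def test_planted_stop_gains_recovered_exactly(small_bundle):
    """Truth comparison: genes given a forced stop-gain SNV are recovered."""
    seqs, genes = small_bundle["seqs"], small_bundle["genes"]
    idx = CdsIndex(genes)
    planted = {}
    for gene in genes[:10]:
        # mutate the codon after ATG to TAA via a constructed SNV where possible
        cds = effects.coding_sequence(gene, seqs)
        for ci in range(1, len(cds) // 3 - 1):
            codon = cds[ci * 3 : ci * 3 + 3]
            for off, base in enumerate("TAA"):
                cand = codon[:off] + base + codon[off + 1 :]
                if cand in ("TAA", "TAG", "TGA") and cand != codon:
                    # map coding offset back to genome
                    cpos = ci * 3 + off
                    if gene.strand == "+":
                        pos0 = gene.start + cpos
                        ref, alt = seqs[gene.chrom][pos0], base
                    else:
                        pos0 = gene.end - 1 - cpos
                        ref, alt = seqs[gene.chrom][pos0], revcomp(base)
                    planted[gene.gene_id] = (pos0, ref, alt)
                    break
            if gene.gene_id in planted:
                break
    anns = [
        annotate_effect(genes[0].chrom, pos0 + 1, ref, alt, idx, seqs)
        for pos0, ref, alt in planted.values()
    ]
    assert effects.genes_with_high_impact(anns) == set(planted)


# ------------------------------------------------------------ frame analysis


def _gene_block(chrom="c1", start=1000, length=3000):
    seqs = {chrom: "A" * (start + length + 1000)}
    gene = GeneModel("g1", chrom, start, start + length, "+", ((start, start + length),))
    return seqs, gene


def test_frame_table_trivial_split():
    _, gene = _gene_block()
    indels = [("c1", 1500 + i, "A" * 4, "A") for i in range(5)]  # len-3 inside
    indels += [("c1", 10 + i, "A" * 3, "A") for i in range(5)]  # len-2 outside
    table = effects.indel_frame_analysis(indels, [gene], 100_000)
    assert table.inside_div3_fraction == 1.0
    assert table.outside_div3_fraction == 0.0
    assert table.inside_total == 5 and table.outside_total == 5


def test_frame_compartment_conservation():
    _, gene = _gene_block()
    rng = np.random.default_rng(4)
    indels = [
        ("c1", int(rng.integers(1, 4900)), "A" * int(rng.integers(2, 6)), "A")
        for _ in range(200)
    ]
    table = effects.indel_frame_analysis(indels, [gene], 100_000)
    assert table.inside_total + table.outside_total == 200


def test_density_invariance_under_genome_doubling():
    _, gene = _gene_block()
    gene2 = GeneModel("g2", "c2", 1000, 4000, "+", ((1000, 4000),))
    indels = [("c1", 1500, "AAAA", "A"), ("c1", 10, "AAA", "A")]
    doubled = indels + [("c2", 1500, "AAAA", "A"), ("c2", 10, "AAA", "A")]
    t1 = effects.indel_frame_analysis(indels, [gene], 100_000)
    t2 = effects.indel_frame_analysis(doubled, [gene, gene2], 200_000)
    assert t1.inside_density_per_mbp == pytest.approx(t2.inside_density_per_mbp)
    assert t1.outside_density_per_mbp == pytest.approx(t2.outside_density_per_mbp)


def test_frame_analysis_zero_cds_errors():
    with pytest.raises(ValueError, match="CDS"):
        effects.indel_frame_analysis([("c1", 10, "AA", "A")], [], 1000)


def test_cds_union_length_no_double_count():
    g1 = GeneModel("g1", "c1", 100, 400, "+", ((100, 400),))
    g2 = GeneModel("g2", "c1", 300, 700, "+", ((300, 700),))
    assert CdsIndex([g1, g2]).union_length() == 600


def test_two_proportion_test_fisher_fallback():
    stat, p, method = effects.two_proportion_test(1, 6, 5, 6)
    assert method == "fisher_exact" and 0 < p <= 1
    stat, p, method = effects.two_proportion_test(200, 500, 180, 500)
    assert method == "normal"


def test_enrichment_detected_on_strong_contrast():
    rng = np.random.default_rng(9)
    x1 = int(rng.binomial(500, 0.7))
    x2 = int(rng.binomial(500, 1 / 3))
    _, p, _ = effects.two_proportion_test(x1, 500, x2, 500)
    assert p < 1e-10


def test_accepts_variant_calls(small_bundle):
    calls = [
        VariantCall("c1", 1500, "AAAA", ("A",), 50, (25, 25)),
        VariantCall("c1", 10, "AAA", ("A",), 50, (25, 25)),
    ]
    _, gene = _gene_block()
    table = effects.indel_frame_analysis(calls, [gene], 100_000)
    assert table.inside_total == 1 and table.outside_total == 1
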