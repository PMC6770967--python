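"""Shared fixtures: a small simulated genome bundle reused across tests."""
from __future__ import annotations

import numpy as np
import pytest

from culturevar import synthetic


PLAN = {
    "chr1": [
        (300_000, 2),
        (200_000, 1),
        (300_000, 3),
        (100_000, 5),
        (50_000, 0),
        (None, 2),
    ]
}


@pytest.fixture(scope="session")
def small_bundle():
    """A 1 Mbp in-memory simulation with every copy class present."""
    spec = synthetic.GenomeSpec(
        chromosome_lengths={"chr1": 1_000_000},
        n_genes=60,
        gene_length_range=(2100, 3000),
        intergenic_range=(2000, 12000),
        seed=1,
    )
    noise = synthetic.NoiseModel()
    rng = np.random.default_rng(1)
    seqs, genes = synthetic.generate_reference(spec, rng)
    copy_map = synthetic.plant_copy_map(spec.chromosome_lengths, PLAN, rng=rng)
    truth = synthetic.plant_variants(
        seqs, copy_map, snv_rate=5e-4, indel_rate=5e-4, genes=genes, rng=rng
    )
    track = synthetic.simulate_coverage(
        spec.chromosome_lengths, copy_map, noise, rng=rng,
        organelle_lengths=spec.organelles,
    )
    records = synthetic.emit_vcf(truth, track, noise, rng=rng)
    rna = synthetic.simulate_rna_counts(truth, noise, rng=rng)
    return {
        "spec": spec,
        "noise": noise,
        "seqs": seqs,
        "genes": genes,
        "copy_map": copy_map,
        "truth": truth,
        "track": track,
        "records": records,
        "rna": rna,
    }


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_bundle):
    """The same bundle written out as files."""
    out = tmp_path_factory.mktemp("bundle")
    spec = small_bundle["spec"]
    paths = synthetic.simulate_bundle(
        spec,
        small_bundle["noise"],
        str(out),
        plan=PLAN,
        snv_rate=5e-4,
        indel_rate=5e-4,
        seed=1,
    )
    return paths


def truth_copy_by_gene(genes, copy_map):
    """Planted copy number per gene, taken at the gene midpoint."""
    out = {}
    for g in genes:
        mid = (g.start + g.end) // 2
        for seg in copy_map:
            if seg.chrom == g.chrom and seg.start <= mid < seg.end:
                out[g.gene_id] = seg.copy_number
                break
    return out
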