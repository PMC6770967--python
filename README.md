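# culturevar

Genome-alteration analysis for long-term (asexually propagated) cell
cultures, built around read-depth copy-number inference and allele-depth
zygosity classification:

- **`culturevar.synthetic`** — truth-labelled aneuploid genome simulator:
  reference FASTA + GFF3 with valid single-CDS genes, an integer
  copy-number segmentation (BED), planted SNVs/InDels carried by a subset
  of the local haplophase copies (truth TSV), Poisson/negative-binomial
  per-base depth (bedGraph), a VCF 4.2 with DP/AD sampled binomially at
  the true carrier fraction, and copy-proportional RNA allele counts (TSV).
- **`culturevar.coverage`** — windowed coverage, zero-coverage deletion
  detection (maximal zero runs strictly longer than a minimum length),
  per-gene copy-number estimation against a per-copy depth unit found as
  the first peak of the smoothed gene-depth histogram, flanking-gene
  similarity flags, organelle (chondrome/plastome) coverage ratio.
- **`culturevar.zygosity`** — homozygous vs deviating-frequency
  classification (a non-dominant allele with ≥ 5 reads and ≥ 5 % of the
  depth, both inclusive), a flanking-coverage exclusion filter (strictly
  more than 20 % off the 2 kb flank mean), per-block variant densities,
  substitution spectra, SNV:InDel ratio, depth histograms per class.
- **`culturevar.effects`** — simplified effect annotation (codon
  translation for SNVs; frameshift/in-frame for CDS InDels; high impact =
  stop gain or frameshift) and the InDel length/frame analysis inside vs
  outside coding sequence with a two-proportion enrichment test.
- **`culturevar.ase`** — allele-specific expression at high-impact sites
  with a self-implemented Mann–Whitney U test (exact for small samples,
  tie/continuity-corrected normal approximation otherwise), plus the
  genomic allele-depth control contrast that separates copy-number
  effects from transcript degradation.
- **`culturevar.pipeline` / `culturevar.cli`** — configured, seeded,
  byte-deterministic orchestration with a consolidated JSON/text report.

## CLI

```bash
culturevar run --seed 7 --outdir demo_run          # full simulated demo (5 Mbp)
culturevar simulate --outdir sim --seed 1          # just the synthetic bundle
culturevar coverage --depth sim/coverage.bedgraph --gff sim/annotation.gff3 \
    --fasta sim/reference.fasta --min-del-length 100 --tau 0.2
culturevar classify-variants --vcf sim/variants.vcf --depth sim/coverage.bedgraph \
    --min-reads 5 --min-frac 0.05 --flank 2000 --max-dev 0.20
culturevar annotate --vcf sim/variants.vcf --gff sim/annotation.gff3 \
    --fasta sim/reference.fasta
culturevar indel-frames --vcf sim/variants.vcf --gff sim/annotation.gff3 \
    --fasta sim/reference.fasta
culturevar ase --vcf sim/variants.vcf --gff sim/annotation.gff3 \
    --fasta sim/reference.fasta --rna-counts sim/rna_counts.tsv
culturevar validate --fasta ... --gff ... --vcf ... --depth ...
```

`run` accepts a JSON config (`--config`) mirroring
`culturevar.pipeline.RunConfig`; every threshold defaults to the
documented analysis value (min 5 reads / 5 % support, 2 kb flank, 20 %
deviation, 100 bp deletion minimum, 100 kb density blocks, τ = 0.2).
Reruns with identical config + seed reproduce every output file byte for
byte.

## Conventions

Internal coordinates are 0-based half-open; VCF/GFF3 are read and
written 1-based; BED/bedGraph stay 0-based half-open. All randomness
flows through a single seeded `numpy.random.Generator`.
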