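"""Readers and writers for the plain-text genomic formats used throughout.

FASTA I/O goes through Biopython, GFF3 parsing through gffutils and VCF
parsing through pysam; the simulator writes GFF3/VCF/bedGraph directly as
text so output bytes are fully deterministic.
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CopySegment, GeneModel, TruthVariant, VariantCall

# ---------------------------------------------------------------- FASTA


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------- GFF3


def write_gff3(
    genes: Sequence[GeneModel], chrom_lengths: Mapping[str, int], path: str
) -> None:
    """Emit gene/mRNA/CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            out.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            base = (g.chrom, "culturevar")
            attrs_gene = f"ID={g.gene_id}"
            out.write(
                "\t".join(
                    [*base, "gene", str(g.start + 1), str(g.end), ".", g.strand, ".", attrs_gene]
                )
                + "\n"
            )
            mrna_id = f"{g.gene_id}.1"
            out.write(
                "\t".join(
                    [*base, "mRNA", str(g.start + 1), str(g.end), ".", g.strand, ".",
                     f"ID={mrna_id};Parent={g.gene_id}"]
                )
                + "\n"
            )
            # phase bookkeeping along the translation direction
            intervals = list(g.cds) if g.strand == "+" else list(g.cds)[::-1]
            consumed = 0
            phased = []
            for s, e in intervals:
                phase = (3 - consumed % 3) % 3
                phased.append((s, e, phase))
                consumed += e - s
            for s, e, phase in sorted(phased):
                out.write(
                    "\t".join(
                        [*base, "CDS", str(s + 1), str(e), ".", g.strand, str(phase),
                         f"ID=cds-{mrna_id};Parent={mrna_id}"]
                    )
                    + "\n"
                )


def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene models (first CDS chain per gene) from a GFF3 file."""
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        cds = [
            (c.start - 1, c.end)
            for c in db.children(feat, featuretype="CDS", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                cds=tuple(cds),
            )
        )
    return genes


# ---------------------------------------------------------------- depth tracks


def write_bedgraph(track: Mapping[str, np.ndarray], path: str) -> None:
    """Run-length-encoded bedGraph (0-based half-open), full coverage."""
    with open(path, "w") as out:
        for chrom in track:
            arr = np.asarray(track[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr))
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [arr.size]))
            vals = arr[starts]
            df = pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "depth": vals}
            )
            df.to_csv(out, sep="\t", header=False, index=False)


def read_bedgraph(
    path: str, chrom_lengths: Optional[Mapping[str, int]] = None
) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-base integer depth arrays."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": np.int64},
    )
    track: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        length = (
            chrom_lengths[chrom] if chrom_lengths is not None else int(sub["end"].max())
        )
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["depth"].to_numpy()
        arr = np.zeros(length, dtype=np.int64)
        if starts.size and starts[0] == 0 and np.all(starts[1:] == ends[:-1]):
            # contiguous cover: single repeat expansion
            arr[: ends[-1]] = np.repeat(vals, ends - starts)
        else:
            for s, e, v in zip(starts, ends, vals):
                arr[s:e] = v
        track[chrom] = arr
    return track


def read_depth_tsv(
    path: str, chrom_lengths: Optional[Mapping[str, int]] = None
) -> dict[str, np.ndarray]:
    """Per-base depth TSV: chrom, pos (1-based), depth."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "pos", "depth"],
        dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
    )
    track: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        length = (
            chrom_lengths[chrom] if chrom_lengths is not None else int(sub["pos"].max())
        )
        arr = np.zeros(length, dtype=np.int64)
        arr[sub["pos"].to_numpy() - 1] = sub["depth"].to_numpy()
        track[chrom] = arr
    return track


def read_depth(path: str, chrom_lengths: Optional[Mapping[str, int]] = None):
    """Dispatch on extension: .bedgraph/.bg -> bedGraph, else 3-col TSV."""
    lower = path.lower()
    if lower.endswith((".bedgraph", ".bg", ".bedgraph.txt")):
        return read_bedgraph(path, chrom_lengths)
    return read_depth_tsv(path, chrom_lengths)


# ---------------------------------------------------------------- copy map


def write_copy_map(segments: Iterable[CopySegment], path: str) -> None:
    with open(path, "w") as out:
        for seg in segments:
            out.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.copy_number}\n")


def read_copy_map(path: str) -> list[CopySegment]:
    segs = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, k = line.rstrip("\n").split("\t")[:4]
            segs.append(CopySegment(chrom, int(start), int(end), int(k)))
    return segs


# ---------------------------------------------------------------- truth variants

_TRUTH_COLS = ["chrom", "pos", "ref", "alt", "class", "carriers", "copy_number", "gene_id"]


def write_truth_variants(variants: Sequence[TruthVariant], path: str) -> None:
    with open(path, "w") as out:
        out.write("#" + "\t".join(_TRUTH_COLS) + "\n")
        for v in variants:
            out.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos1),
                        v.ref,
                        v.alt,
                        v.vclass,
                        str(v.carriers),
                        str(v.copy_number),
                        v.gene_id or ".",
                    ]
                )
                + "\n"
            )


def read_truth_variants(path: str) -> list[TruthVariant]:
    out = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, ref, alt, vclass, carriers, k, gene = line.rstrip("\n").split("\t")
            out.append(
                TruthVariant(
                    chrom=chrom,
                    pos0=int(pos) - 1,
                    ref=ref,
                    alt=alt,
                    vclass=vclass,
                    carriers=int(carriers),
                    copy_number=int(k),
                    gene_id=None if gene == "." else gene,
                )
            )
    return out


# ---------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=culturevar
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Per-allele read depths">
"""


def write_vcf(
    records: Sequence[VariantCall],
    chrom_lengths: Mapping[str, int],
    path: str,
    sample: str = "SIM",
    extra_header: Sequence[str] = (),
    info_fields: Optional[Sequence[str]] = None,
) -> None:
    """Write a minimal VCF 4.2 with DP and AD sample fields."""
    with open(path, "w") as out:
        out.write(_VCF_HEADER)
        for line in extra_header:
            out.write(line.rstrip("\n") + "\n")
        for chrom, length in chrom_lengths.items():
            out.write(f"##contig=<ID={chrom},length={length}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" f"FORMAT\t{sample}\n"
        )
        for rec in records:
            if info_fields:
                info = ";".join(
                    f"{k}={rec.info[k]}" for k in info_fields if k in rec.info
                ) or "."
            else:
                info = "."
            out.write(
                "\t".join(
                    [
                        rec.chrom,
                        str(rec.pos),
                        rec.vid or ".",
                        rec.ref,
                        ",".join(rec.alts),
                        ".",
                        rec.info.get("FILTER", "."),
                        info,
                        "DP:AD",
                        f"{rec.dp}:{','.join(str(a) for a in rec.ad)}",
                    ]
                )
                + "\n"
            )


def read_vcf(path: str) -> list[VariantCall]:
    """Parse DP/AD small-variant records from a VCF via pysam."""
    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            if sample_names:
                fmt = rec.samples[sample_names[0]]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
            else:  # pragma: no cover - DP/AD in INFO fallback
                dp = rec.info.get("DP")
                ad = rec.info.get("AD")
            if dp is None or ad is None:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks DP/AD annotations"
                )
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts),
                    dp=int(dp),
                    ad=tuple(int(a) for a in ad),
                    vid=rec.id,
                    info={k: rec.info[k] for k in rec.info},
                )
            )
    return calls


# ---------------------------------------------------------------- RNA counts

_RNA_COLS = ["chrom", "pos", "ref", "alt", "gene_id", "ref_count", "alt_count"]


def write_rna_counts(rows: Sequence[dict], path: str) -> None:
    pd.DataFrame(rows, columns=_RNA_COLS).to_csv(path, sep="\t", index=False)


def read_rna_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "pos": np.int64, "ref": str, "alt": str},
    )


def read_pileup_counts(path: str) -> pd.DataFrame:
    """Build an RNA allele-count table from samtools mpileup text output.

    Counts '.'/',' as reference support and exact base matches (either
    case) as alternative support; indel and mapping marks are stripped.
    Only SNV alternatives can be counted from pileup text.
    """
    rows = []
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            chrom, pos, ref = fields[0], int(fields[1]), fields[2].upper()
            bases = fields[4]
            cleaned = []
            i = 0
            while i < len(bases):
                ch = bases[i]
                if ch == "^":  # read start: skip mapping-quality char
                    i += 2
                    continue
                if ch == "$":
                    i += 1
                    continue
                if ch in "+-":  # indel: skip length digits + inserted bases
                    j = i + 1
                    while j < len(bases) and bases[j].isdigit():
                        j += 1
                    ln = int(bases[i + 1 : j])
                    i = j + ln
                    continue
                cleaned.append(ch)
                i += 1
            counts: dict[str, int] = {}
            ref_count = 0
            for ch in cleaned:
                if ch in ".,":
                    ref_count += 1
                elif ch.upper() in "ACGT":
                    counts[ch.upper()] = counts.get(ch.upper(), 0) + 1
            for alt, n in sorted(counts.items()):
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "gene_id": ".",
                        "ref_count": ref_count,
                        "alt_count": n,
                    }
                )
    return pd.DataFrame(rows, columns=_RNA_COLS)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
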