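"""File-format reading and writing shared by all pipeline stages.

Conventions: internal coordinates are 0-based half-open everywhere;
conversion happens only here, at the format boundary (GFF3 on disk is
1-based inclusive, depth TSVs are 1-based, BED is 0-based half-open).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ancestry import AncestryResult
from .dupexon import ExonRecord
from .pooldiv import RateRegion
from .synthetic import DepthTrack

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_exons_gff3",
    "read_exons_gff3",
    "load_exons",
    "write_depth_tsv",
    "read_depth_tsv",
    "write_pool_counts_tsv",
    "read_pool_counts_tsv",
    "write_aims_tsv",
    "read_aims_tsv",
    "write_regions_bed",
    "write_segments_bed",
    "read_contig_classes_tsv",
    "write_contig_classes_tsv",
    "read_pool_counts_vcf",
    "read_single_pool_vcf",
]


# --- FASTA ---------------------------------------------------------------

def write_fasta(contigs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --- GFF3 exon annotations ----------------------------------------------

def write_exons_gff3(exons: Sequence[ExonRecord], path) -> None:
    """Write exon features (1-based inclusive coordinates per GFF3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in exons:
            attrs = f"ID={e.exon_id};Parent={e.transcript_id};gene_id={e.gene_id}"
            fh.write(
                "\t".join(
                    [e.contig, "asmqc", "exon", str(e.start + 1), str(e.end),
                     ".", e.strand, ".", attrs]
                )
                + "\n"
            )


def _parse_gff_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for field in attrs.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_exons_gff3(path) -> list[ExonRecord]:
    """Read exon features from a GFF3 file (sequences left empty)."""
    exons: list[ExonRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2].lower() != "exon":
                continue
            attrs = _parse_gff_attrs(cols[8])
            exons.append(
                ExonRecord(
                    exon_id=attrs.get("ID", f"{cols[0]}:{cols[3]}-{cols[4]}"),
                    contig=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    transcript_id=attrs.get("Parent", ""),
                    gene_id=attrs.get("gene_id", ""),
                )
            )
    return exons


def load_exons(fasta_path, gff3_path) -> list[ExonRecord]:
    """Read exons from GFF3 and attach plus-strand sequences from FASTA."""
    contigs = read_fasta(fasta_path)
    exons = []
    for e in read_exons_gff3(gff3_path):
        if e.contig not in contigs:
            raise ValueError(f"exon {e.exon_id}: contig {e.contig} absent from FASTA")
        seq = contigs[e.contig][e.start : e.end]
        exons.append(
            ExonRecord(e.exon_id, e.contig, e.start, e.end, e.strand,
                       e.transcript_id, e.gene_id, seq)
        )
    return exons


# --- depth tracks --------------------------------------------------------

def write_depth_tsv(tracks: Iterable[DepthTrack], path) -> None:
    """contig <TAB> pos (1-based) <TAB> depth."""
    frames = [
        pd.DataFrame(
            {"contig": t.contig, "pos": t.get_positions() + 1, "depth": t.depths}
        )
        for t in tracks
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_depth_tsv(path) -> list[DepthTrack]:
    df = pd.read_csv(path, sep="\t")
    tracks = []
    for contig, grp in df.groupby("contig", sort=False):
        tracks.append(
            DepthTrack(
                contig=str(contig),
                depths=grp["depth"].to_numpy(),
                positions=grp["pos"].to_numpy() - 1,
            )
        )
    return tracks


# --- pooled allele counts ------------------------------------------------

def write_pool_counts_tsv(df: pd.DataFrame, path) -> None:
    """Single-pool count table; pos written 1-based."""
    out = df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_pool_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    df["pos"] = df["pos"] - 1
    return df


def write_aims_tsv(df: pd.DataFrame, path) -> None:
    """Two-pool AIM count table; pos written 1-based."""
    out = df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_aims_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    df["pos"] = df["pos"] - 1
    return df


def read_single_pool_vcf(path, sample: str) -> pd.DataFrame:
    """Single-pool counts (contig, pos, ref, alt, ref_count, alt_count)
    from a VCF with per-sample AD fields; bi-allelic records only.
    Requires the optional cyvcf2 dependency."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    idx = list(vcf.samples).index(sample)
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None or len(rec.ALT) > 1:
            continue
        ad = np.maximum(ad[idx], 0)
        alt = int(ad[1]) if ad.shape[0] > 1 else 0
        rows.append((rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0] if rec.ALT else ".",
                     int(ad[0]), alt))
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "ref_count", "alt_count"]
    )


def read_pool_counts_vcf(path, sample_c: str, sample_h: str) -> pd.DataFrame:
    """Two-pool counts from a VCF with per-sample AD fields.

    Emits the AIM-table columns (ref_count_*, depth_*) for bi-allelic
    records; multi-allelic records get their extra-allele reads recorded in
    ``other_count`` so the bi-allelic filter can drop them.  Requires the
    optional cyvcf2 dependency.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ic, ih = samples.index(sample_c), samples.index(sample_h)
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            continue
        ad = np.maximum(ad, 0)
        ref_c, ref_h = int(ad[ic][0]), int(ad[ih][0])
        alt_c = int(ad[ic][1]) if ad.shape[1] > 1 else 0
        alt_h = int(ad[ih][1]) if ad.shape[1] > 1 else 0
        other = int(ad[ic][2:].sum() + ad[ih][2:].sum()) if ad.shape[1] > 2 else 0
        rows.append(
            (rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0] if rec.ALT else ".",
             ref_c, ref_c + alt_c, ref_h, ref_h + alt_h, other)
        )
    return pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt",
                 "ref_count_C", "depth_C", "ref_count_H", "depth_H", "other_count"],
    )


# --- BED outputs ---------------------------------------------------------

def write_regions_bed(regions: Sequence[RateRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.kind}\t{r.mean_rate:.6g}\n")


def write_segments_bed(result: AncestryResult, path) -> None:
    """Ancestry segments: name = C/H, score = mean posterior of the called state."""
    with open(path, "w") as fh:
        for row in result.segments.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.start}\t{row.end}\t{row.state}\t{row.mean_posterior:.4f}\n"
            )


# --- misc ----------------------------------------------------------------

def read_contig_classes_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "class"], comment="#")
    return dict(zip(df["contig"].astype(str), df["class"].astype(str)))


def write_contig_classes_tsv(classes: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for contig, cls in classes.items():
            fh.write(f"{contig}\t{cls}\n")
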