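"""Readers and writers for the package's file interfaces.

Formats: FASTA (genome, proteins, alignments) through Biopython; BED3
peaks / masks and BED6+3 repeat annotation (columns 7-9 = subfamily,
family, class); tab-separated gene models, variant tables, coverage
tables; the RepeatMasker ``.out`` dialect.  Aligned FASTA records carry
genomic provenance in the id as ``name::chrom:start-end(strand)``
(0-based half-open), the convention used when extracting TE copies for
alignment.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import intervals as iv
from .intervals import IntervalSet
from .msa import AlignedCopy

REPEAT_COLUMNS = ["chrom", "start", "end", "subfamily", "family", "class"]


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


_PROVENANCE = re.compile(r"^(?P<name>.+)::(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)$")


def write_aligned_fasta(copies: list[AlignedCopy], path) -> None:
    seqs = {
        f"{c.id}::{c.chrom}:{c.start}-{c.end}({c.strand})": c.aligned_seq for c in copies
    }
    write_fasta(seqs, path)


def read_aligned_fasta(path) -> list[AlignedCopy]:
    copies = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _PROVENANCE.match(rec.id)
        if m is None:
            raise ValueError(f"record {rec.id!r} lacks ::chrom:start-end(strand) provenance")
        copies.append(
            AlignedCopy(
                m["name"], m["chrom"], int(m["start"]), int(m["end"]), m["strand"], str(rec.seq)
            )
        )
    return copies


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] = ()) -> None:
    """BED3(+extras); intervals written as-is (0-based half-open)."""
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols: list[str] = ()) -> pd.DataFrame:
    names = ["chrom", "start", "end", *extra_cols]
    return pd.read_csv(path, sep="\t", header=None, names=names, usecols=range(len(names)))


def write_repeat_bed(annotation: pd.DataFrame, path) -> None:
    """BED6+3: name=subfamily, score=0, strand; cols 7-9 subfamily/family/class."""
    df = annotation.copy()
    df["name"] = df["subfamily"]
    df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    cols = ["chrom", "start", "end", "name", "score", "strand", "subfamily", "family", "class"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_repeat_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand", "subfamily", "family", "class"]
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    return df[["chrom", "start", "end", "strand", "subfamily", "family", "class"]]


def read_repeatmasker_out(path) -> pd.DataFrame:
    """Parse the whitespace-delimited RepeatMasker ``.out`` table.

    Reads the standard columns (two header lines skipped), converts
    genoStart from 1-based to 0-based half-open, and splits the
    class/family field ("LINE/L1" -> class LINE, family L1).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].replace(".", "").isdigit():
                continue  # header / blank lines
            if len(parts) < 11:
                raise ValueError(f"malformed RepeatMasker line: {line!r}")
            chrom, s, e = parts[4], int(parts[5]) - 1, int(parts[6])
            strand = "-" if parts[8] in ("C", "-") else "+"
            name = parts[9]
            cls_fam = parts[10]
            if "/" in cls_fam:
                cls, fam = cls_fam.split("/", 1)
            else:
                cls, fam = cls_fam, cls_fam
            rows.append((chrom, s, e, strand, name, fam, cls))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"]
    )


def write_gene_models(models: pd.DataFrame, path) -> None:
    models.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variants(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("filter_pass", "lof_low_confidence"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(bool)
    return df


def write_interval_set(ivs: IntervalSet, path) -> None:
    iv.to_dataframe(ivs).to_csv(path, sep="\t", header=False, index=False)


def read_interval_set(path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"],
                     usecols=[0, 1, 2])
    return iv.from_dataframe(df)


def write_track_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Per-base track as bedGraph, run-length encoding equal values."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom], dtype=float)
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def read_track_bedgraph(path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    track = {c: np.zeros(l, dtype=float) for c, l in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.chrom in track:
            track[row.chrom][row.start:row.end] = row.value
    return track
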