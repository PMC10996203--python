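"""Readers and writers for the plain-text formats the pipeline consumes and emits.

Alignments are held in a pandas DataFrame with one row per reported placement:

    read_id  str   read identifier (shared across placements of one read)
    ref      str   reference sequence name
    start    int   0-based inclusive start on the reference
    end      int   0-based exclusive end
    strand   str   '+', '-' or '.'
    nh       int   number of reported placements for this read (NH-style)

Coordinates are 0-based half-open internally; reports use 1-based closed
positions to match rRNA residue numbering conventions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALN_COLUMNS = ["read_id", "ref", "start", "end", "strand", "nh"]

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def empty_alignments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "ref": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "nh": pd.Series(dtype=np.int64),
        }
    )


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# SAM / BED alignments


def write_sam(aln: pd.DataFrame, ref_lengths: Mapping[str, int], path: str | Path) -> None:
    """Write alignments as headered SAM with NH tags (text, unsorted-by-design:
    row order is the deterministic simulation order)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in ref_lengths.items()],
    }
    ref_index = {name: i for i, name in enumerate(ref_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in aln.itertuples(index=False):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = row.read_id
            seg.reference_id = ref_index[row.ref]
            seg.reference_start = int(row.start)
            seg.mapping_quality = 255 if row.nh == 1 else 0
            seg.cigarstring = f"{int(row.end) - int(row.start)}M"
            seg.flag = 16 if row.strand == "-" else 0
            seg.set_tag("NH", int(row.nh))
            out.write(seg)


def read_sam(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            rows.append(
                (
                    seg.query_name,
                    seg.reference_name,
                    seg.reference_start,
                    seg.reference_end,
                    "-" if seg.is_reverse else "+",
                    seg.get_tag("NH") if seg.has_tag("NH") else 1,
                )
            )
    if not rows:
        return empty_alignments()
    df = pd.DataFrame(rows, columns=ALN_COLUMNS)
    return df.astype({"start": np.int64, "end": np.int64, "nh": np.int64})


def write_bed(aln: pd.DataFrame, path: str | Path) -> None:
    """BED6 with the NH multiplicity in the score column."""
    bed = aln[["ref", "start", "end", "read_id", "nh", "strand"]]
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["ref", "start", "end", "read_id", "nh", "strand"],
        dtype={"ref": str, "read_id": str},
    )
    df = df[ALN_COLUMNS].astype({"start": np.int64, "end": np.int64, "nh": np.int64})
    return df


def read_alignments(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .sam or .bed."""
    path = Path(path)
    if path.suffix == ".sam":
        return read_sam(path)
    if path.suffix == ".bed":
        return read_bed(path)
    raise ValueError(f"unsupported alignment format: {path.suffix!r} (expected .sam or .bed)")


# ---------------------------------------------------------------------------
# GFF3 annotation

def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write the internal feature table as GFF3 (1-based closed coordinates).

    Expects columns seqid/type/start/end/strand/gene_id plus optional
    transcript_id and biotype; attribute column is assembled here.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            attrs = [f"ID={row.feature_id}", f"gene_id={row.gene_id}"]
            if getattr(row, "transcript_id", ""):
                attrs.append(f"transcript_id={row.transcript_id}")
            if getattr(row, "biotype", ""):
                attrs.append(f"biotype={row.biotype}")
            fh.write(
                "\t".join(
                    [
                        row.seqid, "structrip", row.type,
                        str(int(row.start) + 1), str(int(row.end)),
                        ".", row.strand, ".", ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _source, ftype, start, end, _score, strand, _phase, attributes = (
                line.rstrip("\n").split("\t")
            )
            attrs = dict(item.split("=", 1) for item in attributes.split(";") if "=" in item)
            rows.append(
                {
                    "seqid": seqid,
                    "type": ftype,
                    "start": int(start) - 1,  # back to 0-based half-open
                    "end": int(end),
                    "strand": strand,
                    "feature_id": attrs.get("ID", ""),
                    "gene_id": attrs.get("gene_id", ""),
                    "transcript_id": attrs.get("transcript_id", ""),
                    "biotype": attrs.get("biotype", ""),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV tables


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
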