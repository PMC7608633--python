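"""Sequence and alignment I/O helpers (FASTA via Biopython, SAM via pysam)."""

from __future__ import annotations

from typing import Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALN_COLUMNS = ["qname", "mate", "ref", "start", "end", "strand", "mapq"]


def empty_alignments() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        ALN_COLUMNS, [str, int, str, int, int, str, int])})


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_sam(alignments: pd.DataFrame, ref_lengths: Mapping[str, int], path,
              seqs: Mapping[str, str] | None = None) -> None:
    """Write single-end alignment records as a plain-text SAM file.

    ``alignments`` uses the internal frame layout (qname, mate, ref, start,
    end, strand, mapq).  Sequences default to ``*``; read-length runs of
    ``M`` are emitted as CIGAR.
    """
    header = pysam.AlignmentHeader.from_references(
        list(ref_lengths.keys()), list(ref_lengths.values()))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in alignments.itertuples():
            a = pysam.AlignedSegment(header)
            a.query_name = f"{row.qname}/{row.mate}"
            a.reference_name = row.ref
            a.reference_start = int(row.start)
            a.mapping_quality = int(row.mapq)
            a.flag = 16 if row.strand == "-" else 0
            length = int(row.end - row.start)
            a.cigarstring = f"{length}M"
            if seqs is not None and row.qname in seqs:
                a.query_sequence = seqs[row.qname]
            out.write(a)


def read_sam(path) -> pd.DataFrame:
    """Read single-end SAM/BAM records into the internal alignment frame.

    Read names of the form ``name/1`` or ``name/2`` recover the mate index;
    other names get mate 1.  Unmapped and secondary/supplementary records
    are dropped.
    """
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            qname = rec.query_name
            mate = 1
            if qname[-2:] in ("/1", "/2"):
                mate = int(qname[-1])
                qname = qname[:-2]
            rows.append((qname, mate, rec.reference_name, rec.reference_start,
                         rec.reference_end, "-" if rec.is_reverse else "+",
                         rec.mapping_quality))
    if not rows:
        return empty_alignments()
    return pd.DataFrame(rows, columns=ALN_COLUMNS)


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
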