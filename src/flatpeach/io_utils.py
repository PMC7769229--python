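"""File formats: FASTA, FASTQ and TSV with the conventions used across the pipeline.

FASTA wraps at 80 columns; FASTQ uses plain four-line records; TSV files
carry a header row, UTF-8, no quoting.  Junction FASTA headers carry the
breakpoint position as key=value tags (``W_PB center=300 flank=300``) so a
junction set round-trips losslessly.  Simulated reads round-trip through
FASTQ with their truth labels encoded as header tags.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .haplotype_model import GenomeSegment, Junction, JunctionSet
from .synthetic_data import SimulatedRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tsv",
    "write_tsv",
    "write_junctions",
    "read_junctions",
    "write_segments",
    "read_segments",
]

_WRAP = 80


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    """Write (header, sequence) records, wrapping sequence lines at 80 columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), _WRAP):
                fh.write(seq[i : i + _WRAP] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA; lowercase bases are uppercased with a warning.

    Returns (full header description, sequence) tuples.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"lowercase bases in record {rec.id!r} uppercased on read")
            seq = seq.upper()
        out.append((rec.description, seq))
    return out


def write_fastq(path, reads: list[SimulatedRead]) -> None:
    """Write simulated reads as four-line FASTQ with truth tags in the header."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in reads:
            mate = f"/{r.mate}" if r.mate else ""
            fh.write(
                f"@{r.id}{mate} hap={r.truth_hap} pos={r.truth_pos} strand={r.truth_strand}\n"
                f"{r.seq}\n+\n{r.qual}\n"
            )


def read_fastq(path) -> list[SimulatedRead]:
    """Read FASTQ written by :func:`write_fastq` (or any plain FASTQ).

    Truth tags are restored when present; foreign FASTQ records get
    placeholder truth fields (hap='A', pos=0, strand='+').
    """
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        name = rec.id
        mate: int | None = None
        if name.endswith(("/1", "/2")):
            mate = int(name[-1])
            name = name[:-2]
        tags = dict(
            part.split("=", 1) for part in rec.description.split()[1:] if "=" in part
        )
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(SimulatedRead(
            id=name, seq=str(rec.seq).upper(), qual=qual, mate=mate,
            truth_hap=tags.get("hap", "A"),
            truth_pos=int(tags.get("pos", 0)),
            truth_strand=tags.get("strand", "+"),
        ))
    return reads


def read_tsv(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV with a header row; missing required columns raise a schema error."""
    df = pd.read_csv(path, sep="\t", dtype=None)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_segments(path, segments: list[GenomeSegment]) -> None:
    write_fasta(path, [(f"{s.id} origin_offset={s.origin_offset}", s.seq) for s in segments])


def read_segments(path) -> list[GenomeSegment]:
    out = []
    for desc, seq in read_fasta(path):
        fields = desc.split()
        tags = dict(p.split("=", 1) for p in fields[1:] if "=" in p)
        out.append(GenomeSegment(id=fields[0], seq=seq,
                                 origin_offset=int(tags.get("origin_offset", 0))))
    return out


def write_junctions(path, junctions: JunctionSet) -> None:
    write_fasta(path, [
        (f"{j.id} center={j.center} flank={j.flank}", j.seq) for j in junctions
    ])


def read_junctions(path) -> JunctionSet:
    records = []
    for desc, seq in read_fasta(path):
        fields = desc.split()
        tags = dict(p.split("=", 1) for p in fields[1:] if "=" in p)
        try:
            records.append(Junction(id=fields[0], seq=seq,
                                    center=int(tags["center"]), flank=int(tags["flank"])))
        except KeyError as e:
            raise ValueError(f"{path}: junction record {fields[0]!r} missing tag {e}") from None
    return JunctionSet(junctions=tuple(records))
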