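"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; tabular outputs are TSV via pandas.
Collapsed FASTA uses ``>id_xCOUNT`` headers for unique reads with counts.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import as_dna
from .preprocess import FilterReport, ReadLibrary


class ParseError(ValueError):
    pass


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    try:
        return {rec.id: as_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_collapsed_fasta(lib: ReadLibrary, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{lib.sample}_{i}_x{count}", description="")
        for i, (seq, count) in enumerate(sorted(lib.counts.items()), start=1)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_collapsed_fasta(path, condition: str = "", replicate: str = "") -> ReadLibrary:
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            count = int(rec.id.rsplit("_x", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: header {rec.id!r} lacks an _xCOUNT suffix") from exc
        seq = as_dna(str(rec.seq))
        counts[seq] = counts.get(seq, 0) + count
    return ReadLibrary(
        counts=counts, condition=condition, replicate=replicate,
        total_raw=sum(counts.values()),
    )


def write_fastq(reads: dict[str, int], path, quality: str = "I") -> None:
    """Expanded FASTQ with constant Phred-33 quality."""
    with open(path, "w") as fh:
        i = 0
        for seq, count in sorted(reads.items()):
            for _ in range(count):
                i += 1
                fh.write(f"@read{i}\n{seq}\n+\n{quality * len(seq)}\n")


def read_fastq(path) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = as_dna(str(rec.seq))
        counts[seq] = counts.get(seq, 0) + 1
    return counts


def write_report(report: FilterReport, path) -> None:
    pd.DataFrame(report.to_rows()).to_csv(path, sep="\t", index=False)


def read_report(path, sample: str = "") -> FilterReport:
    rows = pd.read_csv(path, sep="\t").to_dict("records")
    return FilterReport.from_rows(sample, rows)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_hormone_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"hormone", "phenotype", "stage", "value"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: hormone table needs columns {sorted(required)}")
    return df


def read_mirna_db(path):
    """Parse a combined mature + precursor FASTA into a PrecursorDB.

    miRBase-style headers: precursor records carry an ``MI...`` accession
    token (e.g. ``>zma-MIR159a MI0001421 precursor``); all other records are
    matures, linked to the precursor that contains them.
    """
    import re

    from .annotate import DatabaseError, build_db

    precursors: dict[str, str] = {}
    mature_seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        is_prec = any(re.fullmatch(r"MI\d+", t) for t in tokens) or "precursor" in tokens
        seq = as_dna(str(rec.seq))
        if is_prec:
            precursors[rec.id] = seq
        else:
            mature_seqs[rec.id] = seq
    matures = {}
    for name, seq in mature_seqs.items():
        for pid in sorted(precursors):
            if seq in precursors[pid]:
                matures[name] = (seq, pid)
                break
        else:
            raise DatabaseError(f"{path}: mature {name} not found in any precursor")
    return build_db(precursors, matures)


def write_ct(structure, path) -> None:
    """Connect-format (.ct) writer for a folded hairpin structure."""
    pairs = dict(structure.pairs())
    pairs.update({j: i for i, j in structure.pairs()})
    n = len(structure.sequence)
    with open(path, "w") as fh:
        fh.write(f"{n}\tdG = {structure.mfe}\n")
        for i, base in enumerate(structure.sequence):
            partner = pairs.get(i, -1) + 1
            fh.write(f"{i + 1}\t{base}\t{i}\t{i + 2 if i + 1 < n else 0}\t{partner}\t{i + 1}\n")


def write_bed(intervals, path) -> None:
    """0-based half-open loci as BED: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
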