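"""Readers and writers for the pipeline's on-disk artifacts.

FASTQ is Phred+33 only (modern Illumina/BGISEQ); paired reads are supplied as
two files (R1/R2) paired by record order.  Catalog output is a FASTA with
``name|RUL|AT%`` headers plus a tab-separated companion table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    id: str
    mate: int  # 1 or 2
    sequence: str
    qualities: List[int]
    sex_label: str  # "male" | "female"

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if self.sex_label not in ("male", "female"):
            raise ValueError(f"sex_label must be male/female, got {self.sex_label!r}")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if any(q < 0 or q > 60 for q in self.qualities):
            raise ValueError(f"read {self.id}: qualities outside [0, 60]")


def read_fastq(path: str | Path, sex_label: str, mate: int = 1) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a Phred+33 FASTQ file, preserving order.

    Raises ValueError naming the offending line on a malformed 4-line block.
    """
    record_index = 0
    try:
        with open(path) as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise ValueError(
                        f"{path}: record near line {record_index * 4 + 1}: "
                        f"sequence/quality length mismatch"
                    )
                yield ReadRecord(
                    id=title.split()[0] if title else f"read{record_index}",
                    mate=mate,
                    sequence=seq.upper(),
                    qualities=[ord(c) - PHRED_OFFSET for c in qual],
                    sex_label=sex_label,
                )
                record_index += 1
    except ValueError as exc:
        raise ValueError(
            f"{path}: malformed FASTQ near line {record_index * 4 + 1}: {exc}"
        ) from exc


def read_fastq_pairs(
    r1: str | Path, r2: str | Path, sex_label: str
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Positionally paired records from two mate files."""
    it1 = read_fastq(r1, sex_label, mate=1)
    it2 = read_fastq(r2, sex_label, mate=2)
    for rec1, rec2 in zip(it1, it2):
        yield rec1, rec2
    # flag ragged files
    for leftover, name in ((it1, r1), (it2, r2)):
        if next(leftover, None) is not None:
            raise ValueError(f"unpaired trailing reads in {name}")


def write_fastq(records: Iterable[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    """Write (id, sequence, qualities) triples as Phred+33 FASTQ."""
    with open(path, "w") as out:
        for rid, seq, quals in records:
            qstr = "".join(chr(q + PHRED_OFFSET) for q in quals)
            out.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write (name, sequence) pairs as FASTA."""
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> List[tuple[str, str]]:
    """Read a FASTA file into (name, sequence) pairs."""
    records: List[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as fa:
        for line in fa:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


# -- catalog ---------------------------------------------------------------

_TSV_COLUMNS = (
    "name\trul\tat_fraction\tabundance_male\tabundance_female\t"
    "mf_ratio\tfamily\tsuperfamily\n"
)


def _fmt_ratio(m) -> str:
    r = m.mf_ratio
    if r is None:
        return "NA"
    if math.isinf(r):
        return "Inf"
    return f"{r:.4f}"


def write_catalog(monomers: Sequence, fasta_path: str | Path, table_path: str | Path | None = None) -> None:
    """Write the satellite catalog as FASTA (+ optional companion TSV).

    FASTA headers are ``name|RUL|AT%``; the TSV has one row per monomer with
    abundances, M/F ratio and family/superfamily labels.  Decimal point,
    tab-separated, UTF-8.
    """
    names = [m.name for m in monomers]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate monomer names: {dupes}")
    with open(fasta_path, "w") as fa:
        for m in monomers:
            fa.write(f">{m.name}|{m.rul}|{m.at_fraction * 100:.1f}\n{m.sequence}\n")
    if table_path is not None:
        with open(table_path, "w", encoding="utf-8") as tsv:
            tsv.write(_TSV_COLUMNS)
            for m in monomers:
                tsv.write(
                    f"{m.name}\t{m.rul}\t{m.at_fraction:.4f}\t"
                    f"{m.abundance_male:.6g}\t{m.abundance_female:.6g}\t"
                    f"{_fmt_ratio(m)}\t{m.family or ''}\t{m.superfamily or ''}\n"
                )


def read_catalog(fasta_path: str | Path):
    """Read a catalog FASTA written by :func:`write_catalog` (or any FASTA).

    Returns a list of SatMonomer with descriptors recomputed from sequence;
    abundances are left at 0 (they live in the TSV, not the FASTA).
    """
    from .catalog import SatMonomer

    monomers = []
    name, chunks = None, []
    with open(fasta_path) as fa:
        for line in fa:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    monomers.append(SatMonomer.from_sequence(name, "".join(chunks)))
                name = line[1:].split("|")[0].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        monomers.append(SatMonomer.from_sequence(name, "".join(chunks)))
    return monomers
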