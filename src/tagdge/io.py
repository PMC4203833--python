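"""File-format helpers: FASTA/FASTQ via Biopython, plain tag lists, TSV."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: NlaIII recognition site; every genuine tag starts with it.
ANCHOR = "CATG"
#: Number of variable nucleotides released downstream by MmeI cleavage.
VARIABLE_LEN = 17
#: Full tag length: CATG anchor plus 17 variable nucleotides.
TAG_LEN = len(ANCHOR) + VARIABLE_LEN

#: Sequencing adaptor ligated to the 5' side of each tag (GEX adapter 1).
DEFAULT_ADAPTOR = "GTTCAGAGTTCTACAGTCCGACGATC"

FASTQ_SUFFIXES = {".fastq", ".fq"}


class TagFormatError(ValueError):
    """Raised for malformed read input, naming the offending record."""


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_reads(reads: Iterable[str], path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write tag reads as FASTQ (dummy quality 'I') or one-per-line text.

    ``fmt`` may be ``"fastq"`` or ``"txt"``; when omitted it is inferred
    from the file suffix (``.fastq``/``.fq`` -> FASTQ, anything else text).
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in FASTQ_SUFFIXES else "txt"
    if fmt == "fastq":
        records = []
        for i, seq in enumerate(reads):
            rec = SeqRecord(Seq(seq), id=f"read{i}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")
    elif fmt == "txt":
        with open(path, "w") as fh:
            for seq in reads:
                fh.write(seq + "\n")
    else:
        raise ValueError(f"unknown read format: {fmt!r}")


def iter_reads(source, fmt: str | None = None) -> Iterator[str]:
    """Yield read sequences (uppercase strings) from flexible input.

    ``source`` may be a path to a FASTQ or plain-text tag file, an iterable
    of strings, or an iterable of Bio.SeqRecord objects.  Malformed FASTQ
    raises :class:`TagFormatError` naming the record index.
    """
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        if fmt is None:
            fmt = "fastq" if path.suffix.lower() in FASTQ_SUFFIXES else "txt"
        if fmt == "fastq":
            parser = SeqIO.parse(str(path), "fastq")
            index = 0
            while True:
                try:
                    rec = next(parser)
                except StopIteration:
                    return
                except ValueError as exc:
                    raise TagFormatError(f"malformed FASTQ at record {index}: {exc}") from exc
                yield str(rec.seq).upper()
                index += 1
        else:
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        yield line.upper()
    else:
        for item in source:
            if isinstance(item, SeqRecord):
                yield str(item.seq).upper()
            else:
                yield str(item).upper()
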