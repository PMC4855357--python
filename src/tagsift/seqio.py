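"""FASTQ/FASTA streaming built on Biopython's low-level iterators."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["FastqParseError", "read_fastq", "write_fasta", "read_fasta"]


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 1-based record index."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"FASTQ record {record_index}: {message}")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream ``(read_id, sequence, quality)`` from a 4-line FASTQ file.

    Sequences are uppercased.  An empty file yields nothing.  Line-count
    desynchronisation raises :class:`FastqParseError` naming the record at
    which parsing failed.
    """
    n = 0
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(n + 1, str(exc)) from exc
            n += 1
            yield title.split()[0] if title else "", seq.upper(), qual


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> Path:
    """Write ``(header, sequence)`` pairs as FASTA, preserving input order."""
    path = Path(path)
    with open(path, "w") as handle:
        for header, seq in records:
            handle.write(f">{header}\n{seq}\n")
    return path


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream ``(header, sequence)`` pairs; header is the full ``>`` line."""
    header: str | None = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line.upper())
        if header is not None:
            yield header, "".join(chunks)
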