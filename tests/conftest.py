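"""Shared fixtures: a tiny hand-built design and read-construction helpers.

All fixture data is generated programmatically; reads are assembled by
concatenating tag + primer + insert + reverse-complemented primer + tag,
which doubles as the structural ground truth the sorter must invert.
"""

from __future__ import annotations

import pytest

from tagsift.design import (
    LibraryDesign,
    PCRRecord,
    PrimerSet,
    Tag,
    reverse_complement,
)

# fixed, degenerate-free except one W apiece, so primer-mismatch tests stay
# easy to reason about
FWD_PRIMER = "GGWACAGGTTGAAC"
REV_PRIMER = "TGATTTTTWGGTCA"

TAGS = {
    "1": "ACACAC",
    "2": "GTGTGT",
    "3": "TTAACC",
    "4": "CCGGAA",
}


@pytest.fixture
def tiny_design() -> LibraryDesign:
    """2 samples × 2 replicates in one pool, 4 distinct tag pairs."""
    tags = [Tag(id=i, sequence=s) for i, s in TAGS.items()]
    primers = [PrimerSet("COI", FWD_PRIMER, REV_PRIMER)]
    pcrs = [
        PCRRecord("A", "1", "1", "p1"),
        PCRRecord("A", "2", "2", "p1"),
        PCRRecord("B", "3", "3", "p1"),
        PCRRecord("B", "4", "4", "p1"),
    ]
    return LibraryDesign(tags=tags, primers=primers, pcrs=pcrs)


def build_read(fwd_tag: str, rev_tag: str, insert: str,
               fwd_primer: str = FWD_PRIMER, rev_primer: str = REV_PRIMER,
               flip: bool = False) -> str:
    """Assemble a structurally correct double-tagged read."""
    # resolve the W degeneracies to concrete bases, as a real amplicon would
    fwd_primer = fwd_primer.replace("W", "A")
    rev_primer = rev_primer.replace("W", "T")
    read = (fwd_tag + fwd_primer + insert
            + reverse_complement(rev_primer) + reverse_complement(rev_tag))
    return reverse_complement(read) if flip else read


def write_fastq(path, reads: list[str]) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")
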