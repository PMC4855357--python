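"""Replicate-consensus filtering of sorted amplicons.

After sorting, each sample's PCR replicates — possibly spread over several
sequencing pools — are merged into a :class:`SampleTable`: one copy-number
vector per unique sequence, one entry per replicate.  Filtering then applies
three thresholds in a fixed order:

1. **reproducibility** (``y``): the sequence must be present (≥1 copy) in at
   least ``y`` replicates;
2. **copy number** (``t``): the sequence must reach ≥ ``t`` copies in at
   least ``y`` replicates;
3. **length** (``l``): the trimmed insert must be at least ``l`` bp.

With ``t = 1`` steps 1 and 2 retain identical sets, so the thresholds
degenerate gracefully to presence/absence filtering.  Erroneous sequences
(PCR/sequencing errors, contamination) rarely recur across independent
replicates at appreciable copy number, which is what these thresholds
exploit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .design import LibraryDesign, combo_label
from .seqio import read_fasta, write_fasta
from .sorter import SortedPool

__all__ = [
    "FilterThresholds",
    "SampleTable",
    "StepCounts",
    "build_sample_tables",
    "apply_filters",
    "write_filtered",
    "parse_filtered",
    "decollapse",
]


@dataclass(frozen=True)
class FilterThresholds:
    """The y (reproducibility), t (per-replicate copies), l (length) knobs."""

    y: int = 1
    t: int = 1
    l: int = 0

    def __post_init__(self) -> None:
        if self.y < 1:
            raise ValueError("y must be >= 1")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.l < 0:
            raise ValueError("l must be >= 0")


@dataclass
class SampleTable:
    """Unique sequences of one sample with per-replicate copy numbers.

    ``replicate_labels`` is the ordered list of ``(pool, combo)`` pairs in
    design-file row order; ``rows`` maps each sequence to its copy-number
    vector of the same length (zeros where a replicate lacks the sequence).
    Designed replicates that yielded no reads at all keep their all-zero
    column so reproducibility denominators reflect the designed replicate
    count.
    """

    sample: str
    replicate_labels: list[tuple[str, tuple[str, str]]]
    rows: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_labels)

    def reproducibility(self, seq: str) -> int:
        """Number of replicates in which ``seq`` occurs (≥1 copy)."""
        return sum(c >= 1 for c in self.rows[seq])

    def total(self, seq: str) -> int:
        return sum(self.rows[seq])


@dataclass(frozen=True)
class StepCounts:
    """Survivor counts after each filtering step, for threshold exploration."""

    n_input: int
    n_after_y: int
    n_after_t: int
    n_after_l: int

    def __post_init__(self) -> None:
        assert self.n_input >= self.n_after_y >= self.n_after_t >= self.n_after_l


def build_sample_tables(sorted_pools: list[SortedPool],
                        design: LibraryDesign) -> list[SampleTable]:
    """Merge sorted pools into one :class:`SampleTable` per sample.

    Only designed (used) tag combinations contribute; sequences observed
    solely under unused combinations never reach a sample table.  Samples
    follow design-file first-appearance order.
    """
    by_pool = {sp.pool: sp for sp in sorted_pools}
    tables = []
    for sample in design.samples:
        records = design.sample_replicates(sample)
        labels = [(r.pool, r.combo) for r in records]
        rows: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            sp = by_pool.get(r.pool)
            seqs = sp.combos.get(r.combo, {}) if sp is not None else {}
            for seq, count in seqs.items():
                rows.setdefault(seq, [0] * len(records))[i] = count
        tables.append(SampleTable(sample=sample, replicate_labels=labels,
                                  rows=rows))
    return tables


def apply_filters(table: SampleTable, th: FilterThresholds
                  ) -> tuple[SampleTable, StepCounts]:
    """Apply y, then t, then l; survivors keep their full copy vectors."""
    if th.y > table.n_replicates:
        raise ValueError(
            f"y={th.y} exceeds the design's replicate count "
            f"({table.n_replicates})"
        )
    after_y = {s: v for s, v in table.rows.items()
               if sum(c >= 1 for c in v) >= th.y}
    after_t = {s: v for s, v in after_y.items()
               if sum(c >= th.t for c in v) >= th.y}
    after_l = {s: v for s, v in after_t.items() if len(s) >= th.l}
    counts = StepCounts(n_input=len(table.rows), n_after_y=len(after_y),
                        n_after_t=len(after_t), n_after_l=len(after_l))
    return (SampleTable(sample=table.sample,
                        replicate_labels=list(table.replicate_labels),
                        rows=after_l),
            counts)


def write_filtered(tables: list[SampleTable], outpath: str | Path) -> Path:
    """Write surviving sequences of all samples to one FASTA.

    Header: ``<sample>_seq<rank> counts=<c1,c2,...> total=<sum>``; records
    ordered by sample label, then descending total, then sequence.
    """
    def records():
        for table in sorted(tables, key=lambda t: t.sample):
            ordered = sorted(table.rows.items(),
                             key=lambda kv: (-sum(kv[1]), kv[0]))
            for i, (seq, vec) in enumerate(ordered):
                counts = ",".join(str(c) for c in vec)
                yield (f"{table.sample}_seq{i + 1} counts={counts} "
                       f"total={sum(vec)}", seq)

    return write_fasta(records(), outpath)


_HEADER_RE = re.compile(
    r"^(?P<sample>.+)_seq\d+ counts=(?P<counts>[\d,]+) total=(?P<total>\d+)$")


def parse_filtered(path: str | Path) -> dict[str, dict[str, list[int]]]:
    """Read a :func:`write_filtered` FASTA back into per-sample row maps."""
    out: dict[str, dict[str, list[int]]] = {}
    for header, seq in read_fasta(path):
        m = _HEADER_RE.match(header)
        if m is None:
            raise ValueError(f"malformed filtered-FASTA header: {header!r}")
        vec = [int(c) for c in m.group("counts").split(",")]
        if sum(vec) != int(m.group("total")):
            raise ValueError(f"header total mismatch: {header!r}")
        out.setdefault(m.group("sample"), {})[seq] = vec
    return out


def decollapse(filtered_fasta: str | Path, outpath: str | Path) -> Path:
    """Expand each collapsed record back into ``total`` identical records.

    A record with ``total=n`` becomes ``n`` records suffixed ``_1 .. _n``,
    for downstream tools that need sequence redundancy.
    """
    def records():
        for header, seq in read_fasta(filtered_fasta):
            m = _HEADER_RE.match(header)
            if m is None:
                raise ValueError(
                    f"malformed filtered-FASTA header: {header!r}")
            base = header.split()[0]
            for k in range(int(m.group("total"))):
                yield f"{base}_{k + 1}", seq

    return write_fasta(records(), outpath)
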