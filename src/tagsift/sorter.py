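"""Demultiplexing of pooled reads by tag combination.

Each merged read is expected to look like::

    <fwd tag><fwd primer><insert><revcomp(rev primer)><revcomp(rev tag)>

in either orientation.  Tags are matched exactly and anchored at the read
ends — they are the sample identifier, so no mismatch is tolerated there.
Primers may carry IUPAC degeneracy codes and are matched with a small
substitution budget (``max_primer_mismatch``, default 2; no indels).  Reads
matching in both orientations, matching more than one tag combination, or
too short to contain a non-empty insert, are discarded and counted as
tag/primer errors.

Matched reads are trimmed of tags and primers, canonicalised to forward
orientation, and collapsed per tag combination into unique sequences with
copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .design import (
    LibraryDesign,
    combo_label,
    iupac_mismatches,
    reverse_complement,
)
from .seqio import read_fastq, write_fasta

__all__ = [
    "SortedPool",
    "match_read",
    "sort_pool",
    "classify_combos",
    "write_sorted_pool",
    "read_sorted_pool",
    "write_combo_fasta",
    "ranked_uniques",
]

#: sentinel distinguishing "several conflicting matches" from "no match"
_AMBIGUOUS = object()

DEFAULT_MAX_PRIMER_MISMATCH = 2


@dataclass
class SortedPool:
    """Per-pool demultiplexing result.

    ``combos`` maps ``(fwd_tag_id, rev_tag_id)`` to ``{sequence: count}``.
    Read conservation (``n_input_reads = n_sorted_reads + n_discarded``)
    holds on every run and is assertable via :meth:`check`.
    """

    pool: str
    combos: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    n_input_reads: int = 0
    n_discarded_tag_primer_errors: int = 0
    n_removed_chimera_reads: int = 0  # set by chimera ingestion, not sorting

    @property
    def n_sorted_reads(self) -> int:
        return sum(c for seqs in self.combos.values() for c in seqs.values())

    def check(self) -> None:
        if self.n_input_reads != (self.n_sorted_reads
                                  + self.n_discarded_tag_primer_errors
                                  + self.n_removed_chimera_reads):
            raise AssertionError(
                f"read conservation violated in pool {self.pool}: "
                f"{self.n_input_reads} input != {self.n_sorted_reads} sorted "
                f"+ {self.n_discarded_tag_primer_errors} discarded"
            )


def _match_oriented(seq: str, design: LibraryDesign, max_mm: int):
    """Match one orientation; returns (fwd_id, rev_id, insert), None,
    or _AMBIGUOUS when several tag combinations fit equally well."""
    for ps in design.primers:
        fp, rp_rc = ps.forward, reverse_complement(ps.reverse)
        candidates: dict[tuple[str, str], str] = {}
        fwd_hits = []
        for t in design.tags:
            lt, lp = len(t.sequence), len(fp)
            if len(seq) >= lt + lp and seq.startswith(t.sequence):
                if iupac_mismatches(fp, seq[lt:lt + lp]) <= max_mm:
                    fwd_hits.append(t)
        if fwd_hits:
            for t in design.tags:
                lt, lp = len(t.sequence), len(rp_rc)
                if len(seq) >= lt + lp and seq.endswith(
                        reverse_complement(t.sequence)):
                    tail = seq[len(seq) - lt - lp:len(seq) - lt]
                    if iupac_mismatches(rp_rc, tail) <= max_mm:
                        for f in fwd_hits:
                            start = len(f.sequence) + len(fp)
                            end = len(seq) - lt - lp
                            if end - start >= 1:  # non-empty insert required
                                candidates[(f.id, t.id)] = seq[start:end]
        if len(candidates) == 1:
            (combo, insert), = candidates.items()
            return combo[0], combo[1], insert
        if len(candidates) > 1:
            return _AMBIGUOUS
    return None


def match_read(sequence: str, design: LibraryDesign,
               max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH):
    """Identify a read's tag combination and trim tags and primers.

    Both orientations are tried; the insert is returned in forward
    orientation.  Returns ``((fwd_tag_id, rev_tag_id), insert)`` or ``None``
    when the read carries tag/primer errors or is ambiguous (matches in
    both orientations, or several combinations at once).
    """
    fwd = _match_oriented(sequence, design, max_primer_mismatch)
    rev = _match_oriented(reverse_complement(sequence), design,
                          max_primer_mismatch)
    if fwd is _AMBIGUOUS or rev is _AMBIGUOUS:
        return None
    if fwd is not None and rev is not None:
        return None  # palindromic pathology: silently double-matching
    hit = fwd if fwd is not None else rev
    if hit is None:
        return None
    f, r, insert = hit
    return (f, r), insert


def sort_pool(fastq: str | Path, design: LibraryDesign, pool: str,
              max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH
              ) -> SortedPool:
    """Demultiplex one pool's FASTQ into a :class:`SortedPool`.

    Every matched read is assigned to exactly one tag combination; identical
    trimmed inserts are collapsed with summed copy numbers.  Combinations
    observed in the data but absent from the design (tag jumps,
    contamination) are retained — flagging them is :func:`classify_combos`'
    job.
    """
    sp = SortedPool(pool=pool)
    for _rid, seq, _qual in read_fastq(fastq):
        sp.n_input_reads += 1
        hit = match_read(seq, design, max_primer_mismatch)
        if hit is None:
            sp.n_discarded_tag_primer_errors += 1
            continue
        combo, insert = hit
        bucket = sp.combos.setdefault(combo, {})
        bucket[insert] = bucket.get(insert, 0) + 1
    sp.check()
    return sp


def classify_combos(sorted_pool: SortedPool, design: LibraryDesign):
    """Partition observed combinations into design-used and unused maps."""
    used_set = design.used_combos(sorted_pool.pool)
    used = {c: s for c, s in sorted_pool.combos.items() if c in used_set}
    unused = {c: s for c, s in sorted_pool.combos.items() if c not in used_set}
    return used, unused


def ranked_uniques(seqs: dict[str, int]) -> list[tuple[int, str, int]]:
    """Unique sequences as (rank, sequence, count), descending count then
    lexicographic sequence — the bit-stable output order used everywhere."""
    ordered = sorted(seqs.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(i + 1, s, c) for i, (s, c) in enumerate(ordered)]


def write_sorted_pool(sorted_pool: SortedPool, design: LibraryDesign,
                      outdir: str | Path) -> list[Path]:
    """Write per-combination tables and the pool summary.

    One text file per observed combination (``<combo>.txt``: commented
    header naming pool, combination and primer sets, then
    ``rank count sequence`` lines) plus ``summary.tsv`` with columns
    ``combo, used_flag, n_unique, n_total``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    used_set = design.used_combos(sorted_pool.pool)
    primer_desc = "; ".join(
        f"{p.barcode_name}:{p.forward}/{p.reverse}" for p in design.primers)
    paths = []
    for combo in sorted(sorted_pool.combos, key=lambda c: combo_label(*c)):
        label = combo_label(*combo)
        path = outdir / f"{label}.txt"
        with open(path, "w") as fh:
            fh.write(f"# pool: {sorted_pool.pool}\n")
            fh.write(f"# combo: {label}\n")
            fh.write(f"# primers: {primer_desc}\n")
            for rank, seq, count in ranked_uniques(sorted_pool.combos[combo]):
                fh.write(f"{rank}\t{count}\t{seq}\n")
        paths.append(path)
    summary = outdir / "summary.tsv"
    with open(summary, "w") as fh:
        fh.write(f"# pool: {sorted_pool.pool}\n")
        fh.write(f"# n_input_reads: {sorted_pool.n_input_reads}\n")
        fh.write(f"# n_discarded_tag_primer_errors: "
                 f"{sorted_pool.n_discarded_tag_primer_errors}\n")
        fh.write(f"# n_removed_chimera_reads: "
                 f"{sorted_pool.n_removed_chimera_reads}\n")
        fh.write("combo\tused_flag\tn_unique\tn_total\n")
        for combo in sorted(sorted_pool.combos, key=lambda c: combo_label(*c)):
            seqs = sorted_pool.combos[combo]
            flag = "used" if combo in used_set else "unused"
            fh.write(f"{combo_label(*combo)}\t{flag}\t{len(seqs)}"
                     f"\t{sum(seqs.values())}\n")
    paths.append(summary)
    return paths


def read_sorted_pool(outdir: str | Path) -> SortedPool:
    """Reload a :func:`write_sorted_pool` directory into a SortedPool."""
    outdir = Path(outdir)
    summary = outdir / "summary.tsv"
    meta: dict[str, str] = {}
    combos_listed: list[tuple[str, str]] = []
    for line in summary.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        elif line and not line.startswith("combo\t"):
            label = line.split("\t")[0]
            fwd, _, rev = label.partition("-R")
            combos_listed.append((fwd[1:], rev))
    sp = SortedPool(
        pool=meta["pool"],
        n_input_reads=int(meta["n_input_reads"]),
        n_discarded_tag_primer_errors=int(
            meta["n_discarded_tag_primer_errors"]),
        n_removed_chimera_reads=int(meta.get("n_removed_chimera_reads", 0)),
    )
    for combo in combos_listed:
        seqs: dict[str, int] = {}
        for line in (outdir / f"{combo_label(*combo)}.txt"
                     ).read_text().splitlines():
            if line.startswith("#") or not line:
                continue
            _rank, count, seq = line.split("\t")
            seqs[seq] = int(count)
        sp.combos[combo] = seqs
    sp.check()
    return sp


def write_combo_fasta(sorted_pool: SortedPool, outdir: str | Path
                      ) -> list[Path]:
    """Per-combination FASTA of unique sequences, headers ``combo|rank|count``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for combo in sorted(sorted_pool.combos, key=lambda c: combo_label(*c)):
        label = combo_label(*combo)
        records = [(f"{label}|{rank}|{count}", seq)
                   for rank, seq, count in ranked_uniques(
                       sorted_pool.combos[combo])]
        paths.append(write_fasta(records, outdir / f"{label}.fasta"))
    return paths
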