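"""Diagnostic reports on sorted pools and sample tables.

These tables are what an analyst inspects before choosing filtering
thresholds: per-combination abundance summaries, the forward × reverse tag
occurrence matrix (whose off-diagonal mass exposes tag jumping under
matched-tag designs), candidate primer mix-ups (a designed combination that
is silent while an unused combination sharing one of its tags is loud),
and reproducibility × frequency tables.  Interchange files for external
de-novo chimera detectors (the ``;size=N`` abundance dialect) are also
produced and re-ingested here.
"""

from __future__ import annotations

import statistics
from dataclasses import replace
from pathlib import Path

import pandas as pd

from .design import LibraryDesign, combo_label
from .filterer import SampleTable
from .sorter import SortedPool, ranked_uniques

__all__ = [
    "combo_summary",
    "tag_matrix",
    "diagnose_swaps",
    "reproducibility_table",
    "chimera_io",
    "ingest_chimera_labels",
]

SILENT_THRESHOLD = 0  # total copies at or below which a designed combo is "silent"
LOUD_THRESHOLD = 100  # total copies above which an unused combo is "loud"


def combo_summary(sorted_pool: SortedPool, design: LibraryDesign
                  ) -> pd.DataFrame:
    """Per observed combination: used flag, unique/total counts and the
    min/median/mean/max of the unique-sequence copy numbers."""
    used_set = design.used_combos(sorted_pool.pool)
    rows = []
    for combo in sorted(sorted_pool.combos, key=lambda c: combo_label(*c)):
        counts = list(sorted_pool.combos[combo].values())
        rows.append({
            "pool": sorted_pool.pool,
            "combo": combo_label(*combo),
            "used_flag": "used" if combo in used_set else "unused",
            "n_unique": len(counts),
            "n_total": sum(counts),
            "min_count": min(counts),
            "median_count": statistics.median(counts),
            "mean_count": statistics.mean(counts),
            "max_count": max(counts),
        })
    return pd.DataFrame(rows, columns=[
        "pool", "combo", "used_flag", "n_unique", "n_total",
        "min_count", "median_count", "mean_count", "max_count"])


def tag_matrix(sorted_pool: SortedPool, design: LibraryDesign
               ) -> pd.DataFrame:
    """Forward × reverse tag-id matrix of total read copies.

    Rows are forward tag ids, columns reverse tag ids, in tag-file order;
    every design tag appears even if unobserved (0).  Row/column marginals
    reconcile with the per-combination totals.
    """
    ids = [t.id for t in design.tags]
    mat = pd.DataFrame(0, index=pd.Index(ids, name="fwd_tag"),
                       columns=pd.Index(ids, name="rev_tag"), dtype=int)
    for (f, r), seqs in sorted_pool.combos.items():
        mat.loc[f, r] += sum(seqs.values())
    return mat


def diagnose_swaps(sorted_pools: list[SortedPool], design: LibraryDesign,
                   silent_threshold: int = SILENT_THRESHOLD,
                   loud_threshold: int = LOUD_THRESHOLD) -> list[dict]:
    """Flag designed combinations that look like primer mix-ups.

    A designed combination whose total copies across all pools are at or
    below ``silent_threshold`` is paired with every *unused* combination
    sharing exactly one of its tag ids whose total exceeds
    ``loud_threshold`` — the signature left when one tagged primer was
    swapped for another during synthesis or plate preparation.
    """
    totals: dict[tuple[str, str], int] = {}
    designed: set[tuple[str, str]] = set()
    for sp in sorted_pools:
        designed |= design.used_combos(sp.pool)
        for combo, seqs in sp.combos.items():
            totals[combo] = totals.get(combo, 0) + sum(seqs.values())
    rows = []
    for combo in sorted(designed, key=lambda c: combo_label(*c)):
        if totals.get(combo, 0) > silent_threshold:
            continue
        f, r = combo
        candidates = [
            other for other, total in totals.items()
            if other not in designed and total > loud_threshold
            and (other[0] == f) != (other[1] == r)
        ]
        candidates.sort(key=lambda c: -totals[c])
        rows.append({
            "silent_combo": combo_label(*combo),
            "silent_total": totals.get(combo, 0),
            "candidates": [combo_label(*c) for c in candidates],
            "candidate_totals": [totals[c] for c in candidates],
        })
    return rows


def reproducibility_table(table: SampleTable) -> pd.DataFrame:
    """Count unique sequences by (reproducibility, total copy number).

    Reproducibility is the number of replicates with ≥1 copy, reported as
    ``k/r``; total is the copy-number vector sum.  The counts over all rows
    sum to the table's unique-sequence count.
    """
    r = table.n_replicates
    bins: dict[tuple[int, int], int] = {}
    for vec in table.rows.values():
        key = (sum(c >= 1 for c in vec), sum(vec))
        bins[key] = bins.get(key, 0) + 1
    rows = [{"sample": table.sample, "reproducibility": f"{k}/{r}",
             "total_copies": total, "n_unique": n}
            for (k, total), n in sorted(bins.items())]
    return pd.DataFrame(rows, columns=["sample", "reproducibility",
                                       "total_copies", "n_unique"])


def _seq_ids(sorted_pool: SortedPool) -> dict[str, tuple[tuple[str, str], str]]:
    """Stable sequence ids, as written by chimera_io, back to (combo, seq)."""
    ids = {}
    for combo in sorted(sorted_pool.combos, key=lambda c: combo_label(*c)):
        for rank, seq, _count in ranked_uniques(sorted_pool.combos[combo]):
            ids[f"{combo_label(*combo)}_{rank}"] = (combo, seq)
    return ids


def chimera_io(sorted_pool: SortedPool, outdir: str | Path) -> list[Path]:
    """Write per-combination FASTA with ``;size=N`` abundance annotations.

    The headers (``<combo>_<rank>;size=<count>``) are the dialect de-novo
    chimera detectors such as UCHIME expect; the detector runs externally
    and its verdicts come back through :func:`ingest_chimera_labels`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for combo in sorted(sorted_pool.combos, key=lambda c: combo_label(*c)):
        label = combo_label(*combo)
        path = outdir / f"{label}.chimerain.fasta"
        with open(path, "w") as fh:
            for rank, seq, count in ranked_uniques(sorted_pool.combos[combo]):
                fh.write(f">{label}_{rank};size={count}\n{seq}\n")
        paths.append(path)
    return paths


def ingest_chimera_labels(labels: str | Path, sorted_pool: SortedPool
                          ) -> tuple[SortedPool, dict[tuple[str, str], int]]:
    """Remove externally flagged chimeric sequences from a sorted pool.

    ``labels`` is either one sequence id per line, or UCHIME's tabbed
    output, from which only rows whose final flag column is ``Y`` are taken.
    Returns the pruned pool (inputs untouched) and the number of unique
    sequences removed per combination.  Ids that match no sequence raise,
    listing the orphans.
    """
    known = _seq_ids(sorted_pool)
    flagged: list[str] = []
    for line in Path(labels).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) > 1:
            if fields[-1].strip().upper() != "Y":
                continue
            name = fields[1]
        else:
            name = fields[0]
        flagged.append(name.split(";", 1)[0])
    orphans = [f for f in flagged if f not in known]
    if orphans:
        raise ValueError(
            f"chimera labels reference unknown sequence ids: {orphans}")
    combos = {c: dict(seqs) for c, seqs in sorted_pool.combos.items()}
    removed: dict[tuple[str, str], int] = {}
    discarded = 0
    for name in flagged:
        combo, seq = known[name]
        if seq in combos[combo]:
            discarded += combos[combo].pop(seq)
            removed[combo] = removed.get(combo, 0) + 1
    combos = {c: seqs for c, seqs in combos.items() if seqs}
    pruned = replace(sorted_pool, combos=combos,
                     n_removed_chimera_reads=(
                         sorted_pool.n_removed_chimera_reads + discarded))
    pruned.check()
    return pruned, removed
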