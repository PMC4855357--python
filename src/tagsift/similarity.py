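"""Renkonen similarity between PCR replicates.

The Renkonen similarity index (RSI), as used here, compares the relative
frequency profiles of two PCR replicates of the same sample:

    RSI(a, b) = 1 − Σ_s min(p_a(s), p_b(s))

over the union of unique sequences s.  0 means identical profiles, 1 means
no sequence shared.  Replicates of the same extract should yield comparable
profiles; a pair scoring above 0.6 is conventionally flagged as highly
dissimilar and usually indicates a laboratory mix-up or a failed PCR.  The
profiles are taken from an unfiltered sample table (y=1, t=1) so the index
reflects the raw replicate content.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

from .design import combo_label
from .filterer import SampleTable

__all__ = [
    "ReplicateProfile",
    "DISSIMILARITY_THRESHOLD",
    "rsi",
    "profiles_from_table",
    "sample_rsi",
    "write_rsi_report",
]

#: pairs with RSI above this are flagged "dissimilar" in reports
DISSIMILARITY_THRESHOLD = 0.6


@dataclass
class ReplicateProfile:
    """Relative frequencies of unique sequences in one PCR replicate."""

    label: tuple[str, tuple[str, str]]  # (pool, combo)
    freqs: dict[str, float]

    def __post_init__(self) -> None:
        if self.freqs:
            total = math.fsum(self.freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, not 1")
            if any(f <= 0 for f in self.freqs.values()):
                raise ValueError("frequencies must be positive")


def rsi(a: ReplicateProfile, b: ReplicateProfile) -> float:
    """Renkonen dissimilarity between two replicate profiles, in [0, 1].

    One or both profiles empty returns 1.0 with a warning — nothing is
    shared, which keeps e.g. negative-control replicates visible in reports
    rather than dropping to NaN.
    """
    if not a.freqs or not b.freqs:
        warnings.warn("empty replicate profile; RSI defined as 1.0",
                      stacklevel=2)
        return 1.0
    shared = a.freqs.keys() & b.freqs.keys()
    overlap = math.fsum(min(a.freqs[s], b.freqs[s]) for s in shared)
    return min(1.0, max(0.0, 1.0 - overlap))


def profiles_from_table(table: SampleTable) -> list[ReplicateProfile]:
    """Per-replicate frequency profiles from a sample's copy-number vectors.

    Frequencies are computed within each replicate over that replicate's
    total sorted read count for its tag combination.
    """
    profiles = []
    for i, label in enumerate(table.replicate_labels):
        counts = {s: v[i] for s, v in table.rows.items() if v[i] > 0}
        total = sum(counts.values())
        freqs = {s: c / total for s, c in counts.items()} if total else {}
        profiles.append(ReplicateProfile(label=label, freqs=freqs))
    return profiles


def sample_rsi(table: SampleTable, explicit: bool = False) -> list[dict]:
    """RSI report rows for one sample.

    Default: a single row with the arithmetic mean RSI over all unordered
    replicate pairs.  ``explicit``: one row per pair, which is what exposes
    a single corrupt replicate (all its pairs near 1 while the remaining
    pairs stay low).
    """
    if table.n_replicates < 2:
        raise ValueError(
            f"sample {table.sample} has {table.n_replicates} replicate(s); "
            "RSI needs at least 2"
        )
    profiles = profiles_from_table(table)
    pairs = []
    for (i, a), (j, b) in combinations(enumerate(profiles), 2):
        pairs.append((i, j, rsi(a, b)))
    if explicit:
        rows = []
        for i, j, value in pairs:
            rows.append({
                "sample": table.sample,
                "rep_i": _rep_name(table, i),
                "rep_j": _rep_name(table, j),
                "RSI": value,
                "flag": _flag(value),
            })
        return rows
    mean = math.fsum(v for _, _, v in pairs) / len(pairs)
    return [{
        "sample": table.sample,
        "mean_RSI": mean,
        "n_pairs": len(pairs),
        "flag": _flag(mean),
    }]


def _rep_name(table: SampleTable, i: int) -> str:
    pool, combo = table.replicate_labels[i]
    return f"{pool}:{combo_label(*combo)}"


def _flag(value: float) -> str:
    return "dissimilar" if value > DISSIMILARITY_THRESHOLD else "ok"


def write_rsi_report(tables: list[SampleTable], outpath: str | Path,
                     explicit: bool = False) -> Path:
    """Write the per-sample RSI report as TSV."""
    outpath = Path(outpath)
    cols = (["sample", "rep_i", "rep_j", "RSI", "flag"] if explicit
            else ["sample", "mean_RSI", "n_pairs", "flag"])
    with open(outpath, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for table in sorted(tables, key=lambda t: t.sample):
            for row in sample_rsi(table, explicit=explicit):
                fh.write("\t".join(
                    f"{row[c]:.6f}" if isinstance(row[c], float) else str(row[c])
                    for c in cols) + "\n")
    return outpath
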