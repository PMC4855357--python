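"""Truth-set benchmarking of filtering thresholds.

Given a reference database of the sequences truly present in a mock sample,
every unfiltered unique sequence is classified as *reference-derived*
(TP class) when it matches some reference at ≥ ``identity_threshold``
(default 0.97), and as *artefact* (contamination, PCR/sequencing error,
chimera — the TN class) otherwise.  Filtering thresholds are then scored by
which class members survive:

* TPR = retained reference-derived / all reference-derived,
* FNR = 1 − TPR,
* FPR = retained artefacts / all artefacts,
* TNR = 1 − FPR,

with denominators fixed at the unfiltered classification.  A class that is
empty yields NaN rates rather than a misleading 0.

Identity is computed from a semiglobal alignment with free end gaps
(the shorter sequence aligned within the longer):
``identity = 1 − edit_distance / len(shorter)``, which tolerates the
trimmed-length variation of mini-barcodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

from .filterer import SampleTable

__all__ = [
    "RateReport",
    "identity",
    "classify_sequences",
    "benchmark_rates",
    "refs_recovered",
]

DEFAULT_IDENTITY_THRESHOLD = 0.97


def identity(a: str, b: str) -> float:
    """Pairwise identity of the shorter sequence aligned within the longer.

    Semiglobal edit distance (free end gaps on the longer sequence),
    normalised by the shorter sequence's length and clipped at 0.
    """
    if not a or not b:
        return 0.0
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    dist = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / len(query))


@dataclass(frozen=True)
class RateReport:
    n_tp: int
    n_fn: int
    n_fp: int
    n_tn: int

    @property
    def tpr(self) -> float:
        pos = self.n_tp + self.n_fn
        return self.n_tp / pos if pos else math.nan

    @property
    def fnr(self) -> float:
        pos = self.n_tp + self.n_fn
        return self.n_fn / pos if pos else math.nan

    @property
    def fpr(self) -> float:
        neg = self.n_fp + self.n_tn
        return self.n_fp / neg if neg else math.nan

    @property
    def tnr(self) -> float:
        neg = self.n_fp + self.n_tn
        return self.n_tn / neg if neg else math.nan


def _all_sequences(tables: list[SampleTable]) -> set[str]:
    out: set[str] = set()
    for t in tables:
        out |= t.rows.keys()
    return out


def classify_sequences(sequences: set[str], truth: dict[str, str],
                       identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
                       ) -> tuple[set[str], set[str]]:
    """Split sequences into (reference-derived, artefact) sets."""
    if not truth:
        raise ValueError("empty truth reference set")
    positive = {
        s for s in sequences
        if any(identity(s, ref) >= identity_threshold
               for ref in truth.values())
    }
    return positive, sequences - positive


def benchmark_rates(tables_before: list[SampleTable],
                    tables_after: list[SampleTable],
                    truth: dict[str, str],
                    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
                    ) -> RateReport:
    """Score a filtering run against the truth references.

    ``tables_before`` are the unfiltered sample tables (y=1, t=1) that fix
    the classification denominators; ``tables_after`` the same tables after
    filtering.  Sequences are pooled over samples and counted once each.
    """
    before = _all_sequences(tables_before)
    after = _all_sequences(tables_after)
    positive, negative = classify_sequences(before, truth, identity_threshold)
    return RateReport(
        n_tp=len(positive & after),
        n_fn=len(positive - after),
        n_fp=len(negative & after),
        n_tn=len(negative - after),
    )


def refs_recovered(tables: list[SampleTable], truth: dict[str, str],
                   identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
                   ) -> int:
    """Number of distinct truth references matched by surviving sequences."""
    if not truth:
        raise ValueError("empty truth reference set")
    seqs = _all_sequences(tables)
    hit = 0
    for ref in truth.values():
        if any(identity(s, ref) >= identity_threshold for s in seqs):
            hit += 1
    return hit
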