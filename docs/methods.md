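# Methods

## Data model

A double-tagged, replicated metabarcoding experiment is described by three
whitespace-delimited text files: a tag list (id → ACGT sequence), a primer
list (barcode name, forward, reverse; several rows when PCRs were
multiplexed), and a PCR design file (sample, forward tag id, reverse tag
id, pool) with one row per PCR replicate. Validation enforces unique tag
ids and sequences, a uniform replicate count across samples (the
reproducibility denominator depends on it), tag ids resolving to the tag
list, and uniqueness of (forward tag, reverse tag, pool) triples — which
also guarantees each pool-level combination belongs to exactly one sample.
Tag combinations are rendered `F<id>-R<id>` throughout. Sequences are
uppercased on ingest; IUPAC degeneracy codes are legal in primers only,
never in tags.

## Sorting

A merged read is expected to be
`tagF + primerF + insert + rc(primerR) + rc(tagR)` in either orientation.
Matching rules, and why:

* **Tags are matched exactly**, anchored at position 0 of each end. The
  tag is the sample identifier; tolerating tag mismatches risks
  misassignment between samples, which is strictly worse than losing a
  read. Reads with tag errors are counted, not rescued.
* **Primers tolerate up to `max_primer_mismatch` substitutions**
  (default 2, no indels), with IUPAC codes matching their degeneracy sets.
  Polymerase and sequencing errors inside the primer do not affect sample
  identity, so a small budget recovers reads cheaply. Set 0 for
  strictness.
* **Both orientations are tried.** A read matching in both orientations
  (palindromic pathology), or matching several tag combinations at once,
  is discarded as ambiguous rather than double-counted. Primer sets are
  tried in file order; the first set yielding a unique fit wins.
* Reads too short to contain a non-empty insert
  (< (tag+primer)×2 + 1) are counted as tag/primer errors: with no insert
  there is nothing to carry downstream.

Matched reads are trimmed, canonicalised to forward orientation, and
collapsed per combination into unique sequences with copy numbers. Output
ordering is always descending count then lexicographic sequence, so runs
are byte-stable. Read conservation
(`n_input = n_sorted + n_discarded + n_removed_chimera`) is checked on
every construction.

## Filtering

Each sample's replicates (design-file row order, merged across pools) form
a table of copy-number vectors. Replicates that produced no reads keep
all-zero columns — dropping them would silently shrink the
reproducibility denominator. Thresholds apply in a fixed order:
reproducibility (`y`), copy number (`t`), length (`l`). The copy-number
step requires **≥ t copies in at least y replicates** — not in all
replicates, and not summed across replicates. This is the only reading
under which the t=1 copy-number step retains exactly the reproducibility
survivors (a degeneracy the stepwise survivor counts make visible), and
it collapses gracefully to presence/absence at t=1. A summed-copy variant
was deliberately not offered: it changes the meaning of t and breaks that
degeneracy. Filtering is idempotent, monotone in y and t, and the
identity at y=1, t=1, l=0.

Filtered output is a single FASTA whose headers retain the evidence
(`>S01_seq1 counts=5,8 total=13`); `decollapse` expands each record back
to `total` copies for downstream tools that need redundancy.

## Renkonen similarity

RSI(a, b) = 1 − Σ_s min(p_a(s), p_b(s)) over per-replicate relative
frequencies of unique sequences, computed on unfiltered (y=1, t=1)
tables so the index reflects raw replicate content. 0 = identical,
1 = disjoint. The mean over all C(r, 2) unordered pairs is reported per
sample; `--explicit` emits every pair, which is what isolates a single
corrupt replicate. Pairs above 0.6 are flagged dissimilar (a conventional
threshold). Empty-profile comparisons are defined as 1.0 with a warning
rather than NaN, keeping negative controls visible in reports.

## Diagnostics

The forward × reverse tag matrix accumulates read copies per combination
over all design tags; under matched-tag schemes its off-diagonal mass is
the tag-jumping signal. Swap diagnosis pairs every designed combination
whose total is ≤ `silent_threshold` (default 0) with unused combinations
sharing exactly one of its tag ids whose totals exceed `loud_threshold`
(default 100) — total silence next to a strong one-tag-away signal is the
signature of a primer mix-up, and the defaults encode "absent vs clearly
present"; both are exposed as flags. Reproducibility × total-copy tables
summarise how sequence recurrence relates to abundance, the basis for
choosing y and t.

Chimera detection itself is delegated to external tools: per-combination
FASTA is written in the `;size=N` abundance dialect de-novo detectors
expect, and their verdicts (a plain id list or UCHIME tabbed output,
`Y`-flagged rows) are ingested back, pruning the sorted pool while
keeping read conservation assertable.

## Truth-set benchmarking

Unique sequences from used combinations are classed reference-derived vs
artefact at ≥ `identity_threshold` (default 0.97) against a reference
FASTA. Identity is semiglobal — the shorter sequence aligned with free
end gaps within the longer, `1 − edits/len(shorter)` — because trimmed
mini-barcodes can differ slightly in length; the implementation uses
edlib's infix mode and is pinned in tests to a brute-force dynamic
programming oracle. Rates use denominators fixed before filtering; an
empty class yields NaN, never a misleading 0. Distinct references
recovered is reported separately from the per-unique-sequence TPR: under
strict thresholds nearly all reference-derived *error variants* are
(correctly) removed, so the per-sequence TPR is small even while every
reference is still detected.

## Synthetic data

The generator emits exactly the input formats plus a per-read truth table.
Default conditions: 8 samples × 4 matched-tag replicates in one pool,
625 reads per replicate (20,000 per pool), 10 references of 157 bp at
uniform abundance with pairwise identity ≤ 0.90 (so 0.97-identity truth
matching is unambiguous), 8 bp tags at pairwise Hamming ≥ 3, degenerate
COI mini-barcode primers whose IUPAC positions are resolved per read,
per-base substitution rate 0.002, tag-jump rate 0.02, chimera rate 0.01.
Substitutions only touch the insert, keeping length-filter behaviour
orthogonal to the error model; indels are not simulated. A tag jump
replaces exactly one of the two tags with another id used in the same
pool, matching the single-jump signature a matched-tag design detects;
chimeras take two distinct abundance-weighted parents and a uniform
interior breakpoint; `swap_plant` reroutes a whole designed combination.
All randomness flows from one seeded generator in a fixed order, so
output is bit-reproducible.

What the simulation does **not** emulate: errors inside tags and primers
(so the simulated tag/primer-error count is ≈ 0, unlike real libraries
where it can reach tens of percent), platform-specific quality and indel
profiles, PCR-cycle-explicit amplification stochasticity, and
template-level contamination. Passing tests therefore demonstrate the
bookkeeping, threshold semantics and noise-model recovery of the
pipeline, not its robustness to every real-data artefact.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline at
20,000 reads per pool — large enough for binomial recovery of a 5% jump
rate within 3σ (±0.46 percentage points) while completing in seconds.
Oracle-equivalence checks run at 1,000 reads (exhaustive per-read
classifier) and 200 table rows (brute-force row evaluation); RSI is
checked against direct union-summation at 1e-12. Frequencies are summed
with `math.fsum`; profile normalisation is validated to 1e-9. Ties in
all outputs break by descending count then lexicographic sequence.

## Known limitations

Tag matching offers no error-correcting rescue, so real tag-error rates
translate directly into discarded reads. Primer matching allows
substitutions only; an indel in a primer shifts the insert frame and the
read is discarded. The benchmark reduces OTU-level reporting to counting
distinct references recovered; no clustering is performed. RSI is the
only replicate-similarity measure offered.
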