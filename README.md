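# tagsift

Initial processing of DNA-metabarcoding datasets built from **double
5′-tagged amplicons with multiple PCR replicates per sample**, possibly
spread over several sequencing pools.

In this laboratory design, every PCR replicate of every sample carries a
unique (forward tag, reverse tag) combination, so each merged read looks
like

```
<fwd tag><fwd primer><insert><revcomp(rev primer)><revcomp(rev tag)>
```

in either orientation. tagsift demultiplexes pooled reads by tag
combination, trims tags and primers, collapses identical inserts into
unique sequences with copy numbers, and then exploits the replicate
structure: erroneous sequences (PCR/sequencing errors, contamination,
chimeras) rarely recur across independent PCR replicates at appreciable
copy number, while true template sequences do. It also surfaces the
tell-tale artefacts of tagged pooled libraries — **unused tag
combinations** from tag jumping, and **primer mix-ups** where a designed
combination is silent while a neighbouring unused one is loud.

Intended users: anyone processing metabarcoding amplicons (diet analysis,
environmental DNA, bulk-sample inventories) upstream of chimera removal,
OTU clustering and taxonomy assignment.

## The core operations

* **Sorting** — each pool's reads are assigned to a tag combination
  (tags matched exactly and anchored at the read ends; primers matched
  IUPAC-aware with a small substitution budget, default 2), trimmed and
  collapsed. Reads failing tag/primer matching are counted, never
  silently dropped: `n_input = n_sorted + n_discarded` holds on every run.
* **Filtering** — per sample, the copy-number vector of each unique
  sequence across its `r` replicates is tested in a fixed order:
  1. *reproducibility*: present (≥1 copy) in ≥ `y` replicates,
  2. *copy number*: ≥ `t` copies in ≥ `y` replicates,
  3. *length*: insert ≥ `l` bp.
* **Renkonen similarity index** — for replicates a, b with per-replicate
  relative frequencies p_a, p_b over unique sequences s:

  RSI(a, b) = 1 − Σ_s min(p_a(s), p_b(s))

  0 = identical profiles, 1 = nothing shared; pairs above 0.6 are flagged
  dissimilar. One corrupt replicate shows up as all its pairs ≈ 1 while
  the remaining pairs stay low.
* **Truth-set benchmarking** — against a mock-community reference FASTA,
  unique sequences are classed reference-derived vs artefact at ≥97%
  semiglobal identity, and a filtering run is scored by TPR/FNR/FPR/TNR
  with denominators fixed before filtering.
* **Simulation** — a seeded generator emits the exact input formats plus
  a per-read truth table, with tunable substitution errors, tag jumping,
  chimeras, abundance models and planted primer swaps.

## Worked example

```bash
# simulate a pool: 2 samples x 2 matched-tag replicates, 60 reads each
tagsift simulate --seed 4 --n-samples 2 --replicates 2 \
    --reads-per-replicate 60 -o demo

# demultiplex the pool and collapse to unique sequences
tagsift sort --fastq demo/pool1.fastq --pcrs demo/pcrs.txt \
    --tags demo/tags.txt --primers demo/primers.txt \
    --pool pool1 -o demo/sorted
# INFO pool pool1: 240 reads in, 240 sorted, 0 tag/primer errors

# replicate-consensus filter: keep sequences seen in both replicates
# with at least 2 copies each
tagsift filter --sorted demo/sorted --pcrs demo/pcrs.txt \
    --tags demo/tags.txt --primers demo/primers.txt \
    -y 2 -t 2 -o demo/filtered.fasta --steps demo/steps.tsv
```

`demo/steps.tsv` then reads:

```
sample	n_input	n_after_y	n_after_t	n_after_l
S01	35	10	10	10
S02	44	10	8	8
```

Sample S01 had 35 unique sequences before filtering; 10 occurred in both
replicates, all with ≥2 copies in both (the 10 simulated references) —
the other 25 are the singleton error/chimera background the replicate
design exists to remove. `demo/filtered.fasta` headers keep the evidence,
e.g. `>S01_seq1 counts=5,8 total=13`: this sequence had 5 and 8 copies in
the two replicates. `tagsift rsi --explicit` scores replicate
comparability, `tagsift report` writes the combination summaries, the
forward×reverse tag matrix and the primer-swap diagnosis, and
`tagsift decollapse` expands records back to per-read redundancy for
downstream tools.

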