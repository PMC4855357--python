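"""Synthetic double-tagged amplicon libraries with a known truth table.

The generator emulates the laboratory setup the toolkit targets: a mock
community of reference mini-barcodes (157 bp by default, the length of the
arthropod COI fragment commonly amplified in diet studies) is amplified in
several PCR replicates per sample, each replicate carrying its own tag
combination, and the tagged products are pooled into one or more sequencing
libraries.  Reads are built as::

    <fwd tag><fwd primer><insert + substitution errors><rc(rev primer)><rc(rev tag)>

with half of them emitted reverse-complemented.  Three error processes are
modelled: per-base substitution errors, tag jumping (one of the two tags is
replaced by another tag id used in the same pool, producing unused
combinations under matched-tag schemes), and two-parent chimeras with a
uniform interior breakpoint.  A planted primer swap (``swap_plant``)
redirects a whole designed combination to a different one, the signature of
a primer synthesis/plate mix-up.

Everything is driven by a single seeded generator, so a given configuration
is bit-reproducible, and every emitted read is recorded in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .benchmark import identity
from .design import (
    LibraryDesign,
    PCRRecord,
    PrimerSet,
    Tag,
    combo_label,
    parse_combo_label,
    reverse_complement,
    IUPAC,
)

__all__ = ["SimConfig", "SimResult", "simulate", "make_reference_set"]

_BASES = "ACGT"

# Arthropod COI mini-barcode primer pair (Zeale et al. style); the W codes
# exercise IUPAC-aware primer matching.
DEFAULT_FORWARD_PRIMER = "AGATATTGGAACWTTATATTTTATTTTTGG"
DEFAULT_REVERSE_PRIMER = "WACTAATCAATTWCCAAATCCTCC"


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults mirror a mock-community benchmark: 8 samples × 4 PCR
    replicates with matched tags in a single pool, 10 references of 157 bp
    at equal abundance, 625 reads per replicate (20,000 reads per pool),
    a 0.2 % per-base substitution rate, 2 % tag jumping and 1 % chimeras.
    """

    n_samples: int = 8
    replicates_per_sample: int = 4
    n_pools: int = 1
    tag_scheme: str = "matched"  # "matched" | "combinatorial"
    n_tags: int | None = None  # None: exactly as many as the design needs
    n_refs: int = 10
    ref_length: int = 157
    min_pairwise_divergence: float = 0.10
    reads_per_replicate: int = 625
    abundance_model: str = "uniform"  # "uniform" | "lognormal"
    abundance_sigma: float = 1.0
    point_error_rate: float = 0.002
    tag_jump_rate: float = 0.02
    chimera_rate: float = 0.01
    swap_plant: dict[str, str] | None = None  # designed combo -> emitted combo
    tag_length: int = 8
    forward_primer: str = DEFAULT_FORWARD_PRIMER
    reverse_primer: str = DEFAULT_REVERSE_PRIMER
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("point_error_rate", "tag_jump_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tag_scheme not in ("matched", "combinatorial"):
            raise ValueError(f"unknown tag_scheme {self.tag_scheme!r}")
        if self.abundance_model not in ("uniform", "lognormal"):
            raise ValueError(f"unknown abundance_model {self.abundance_model!r}")


@dataclass
class SimResult:
    """Paths of everything one simulation emitted."""

    outdir: Path
    fastq_by_pool: dict[str, Path]
    pcr_file: Path
    tag_file: Path
    primer_file: Path
    refs_fasta: Path
    truth_tsv: Path
    design: LibraryDesign = field(repr=False)
    references: dict[str, str] = field(repr=False)


def make_reference_set(n_refs: int, length: int = 157,
                       min_pairwise_divergence: float = 0.10,
                       seed: int = 0, max_tries: int = 200) -> dict[str, str]:
    """Random reference sequences with bounded pairwise identity.

    All pairwise identities (semiglobal, shorter-normalised) are at most
    ``1 − min_pairwise_divergence``, so truth matching at 0.97 identity is
    unambiguous.  Raises after ``max_tries`` rejected candidates.
    """
    rng = np.random.default_rng(seed)
    max_identity = 1.0 - min_pairwise_divergence
    refs: list[str] = []
    tries = 0
    while len(refs) < n_refs:
        cand = "".join(rng.choice(list(_BASES), size=length))
        if all(identity(cand, r) <= max_identity for r in refs):
            refs.append(cand)
        else:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not draw {n_refs} references with pairwise "
                    f"identity <= {max_identity:.2f} after {max_tries} tries")
    return {f"ref{i + 1}": s for i, s in enumerate(refs)}


def _make_tags(n: int, length: int, rng: np.random.Generator,
               min_hamming: int = 3, max_tries: int = 10000) -> list[Tag]:
    tags: list[str] = []
    tries = 0
    while len(tags) < n:
        cand = "".join(rng.choice(list(_BASES), size=length))
        if all(sum(a != b for a, b in zip(cand, t)) >= min_hamming
               for t in tags):
            tags.append(cand)
        else:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not draw {n} tags of length {length} with "
                    f"pairwise Hamming distance >= {min_hamming}")
    return [Tag(id=str(i + 1), sequence=s) for i, s in enumerate(tags)]


def _assign_combos(cfg: SimConfig) -> tuple[list[PCRRecord], int]:
    """Lay out (sample, replicate) -> (fwd id, rev id, pool); returns the
    records in design order and the number of tag ids required."""
    pools = [f"pool{p + 1}" for p in range(cfg.n_pools)]
    per_pool_pairs: dict[str, list[tuple[int, int]]] = {p: [] for p in pools}
    for s in range(cfg.n_samples):
        for j in range(cfg.replicates_per_sample):
            per_pool_pairs[pools[j % cfg.n_pools]].append((s, j))
    max_pairs = max(len(v) for v in per_pool_pairs.values())
    if cfg.tag_scheme == "matched":
        n_needed = max_pairs
    else:
        n_needed = int(np.ceil(np.sqrt(max_pairs)))
    if cfg.n_tags is not None:
        if cfg.n_tags < n_needed:
            raise ValueError(
                f"tag_scheme={cfg.tag_scheme!r} with this design needs "
                f"{n_needed} tags but n_tags={cfg.n_tags}")
        n_needed = cfg.n_tags

    assignment: dict[tuple[int, int], tuple[str, str, str]] = {}
    for pool, pairs in per_pool_pairs.items():
        for k, (s, j) in enumerate(pairs):
            if cfg.tag_scheme == "matched":
                f = r = str(k + 1)
            else:
                side = int(np.ceil(np.sqrt(max_pairs)))
                f, r = str(k // side + 1), str(k % side + 1)
            assignment[(s, j)] = (f, r, pool)
    records = []
    for s in range(cfg.n_samples):
        for j in range(cfg.replicates_per_sample):
            f, r, pool = assignment[(s, j)]
            records.append(PCRRecord(sample=f"S{s + 1:02d}", fwd_tag_id=f,
                                     rev_tag_id=r, pool=pool))
    return records, n_needed


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    """Draw a concrete sequence from a degenerate primer, per read."""
    out = []
    for c in primer:
        opts = IUPAC[c]
        out.append(opts if len(opts) == 1 else opts[rng.integers(len(opts))])
    return "".join(out)


def _mutate(seq: str, rate: float, rng: np.random.Generator
            ) -> tuple[str, int]:
    if rate <= 0.0:
        return seq, 0
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, 0
    chars = list(seq)
    for i in hits:
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars), int(hits.size)


def simulate(config: SimConfig, outdir: str | Path) -> SimResult:
    """Emit FASTQ per pool, the three design files, references and truth.

    Deterministic given ``config.seed``: all randomness flows from one
    seeded generator consumed in a fixed order.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    references = make_reference_set(
        cfg.n_refs, cfg.ref_length, cfg.min_pairwise_divergence,
        seed=int(rng.integers(2**31)))
    records, n_tags = _assign_combos(cfg)
    tags = _make_tags(n_tags, cfg.tag_length, rng)
    primers = [PrimerSet(barcode_name="COI-mini",
                         forward=cfg.forward_primer,
                         reverse=cfg.reverse_primer)]
    design = LibraryDesign(tags=tags, primers=primers, pcrs=records)
    tag_seq = {t.id: t.sequence for t in tags}

    swaps: dict[tuple[str, str], tuple[str, str]] = {}
    for src, dst in (cfg.swap_plant or {}).items():
        swaps[parse_combo_label(src)] = parse_combo_label(dst)

    # per-sample abundance weights over references, drawn once
    ref_ids = list(references)
    weights = {}
    for s in design.samples:
        if cfg.abundance_model == "uniform":
            w = np.full(len(ref_ids), 1.0 / len(ref_ids))
        else:
            w = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma,
                              size=len(ref_ids))
            w /= w.sum()
        weights[s] = w

    pools = design.pools
    used_ids = {
        p: {"fwd": sorted({r.fwd_tag_id for r in records if r.pool == p},
                          key=int),
            "rev": sorted({r.rev_tag_id for r in records if r.pool == p},
                          key=int)}
        for p in pools
    }

    fastq_handles = {p: open(outdir / f"{p}.fastq", "w") for p in pools}
    truth_path = outdir / "truth.tsv"
    serial = 0
    try:
        with open(truth_path, "w") as truth:
            truth.write("read_id\tpool\tsample\treplicate\tcategory\tsource"
                        "\tn_point_errors\tintended_combo\temitted_combo"
                        "\tjumped\trevcomp\n")
            for rec in records:
                rep_index = design.sample_replicates(rec.sample).index(rec)
                w = weights[rec.sample]
                for _ in range(cfg.reads_per_replicate):
                    serial += 1
                    read_id = f"r{serial:07d}"
                    # insert: chimera or single reference with point errors
                    if cfg.chimera_rate > 0 and rng.random() < cfg.chimera_rate:
                        pa, pb = rng.choice(len(ref_ids), size=2,
                                            replace=False, p=w)
                        a, b = references[ref_ids[pa]], references[ref_ids[pb]]
                        bp = int(rng.integers(1, min(len(a), len(b))))
                        insert, category = a[:bp] + b[bp:], "chimera"
                        source = f"{ref_ids[pa]}+{ref_ids[pb]}@{bp}"
                    else:
                        ri = int(rng.choice(len(ref_ids), p=w))
                        insert, category = references[ref_ids[ri]], "ref"
                        source = ref_ids[ri]
                    insert, n_err = _mutate(insert, cfg.point_error_rate, rng)

                    intended = rec.combo
                    emitted = swaps.get(intended, intended)
                    jumped = 0
                    if cfg.tag_jump_rate > 0 and rng.random() < cfg.tag_jump_rate:
                        side = "fwd" if rng.random() < 0.5 else "rev"
                        current = emitted[0] if side == "fwd" else emitted[1]
                        others = [i for i in used_ids[rec.pool][side]
                                  if i != current]
                        if others:
                            new = others[int(rng.integers(len(others)))]
                            emitted = ((new, emitted[1]) if side == "fwd"
                                       else (emitted[0], new))
                            jumped = 1

                    fp = _resolve_iupac(cfg.forward_primer, rng)
                    rp = _resolve_iupac(cfg.reverse_primer, rng)
                    read = (tag_seq[emitted[0]] + fp + insert
                            + reverse_complement(rp)
                            + reverse_complement(tag_seq[emitted[1]]))
                    flipped = 0
                    if rng.random() < 0.5:
                        read, flipped = reverse_complement(read), 1
                    fastq_handles[rec.pool].write(
                        f"@{read_id}\n{read}\n+\n{'I' * len(read)}\n")
                    truth.write(
                        f"{read_id}\t{rec.pool}\t{rec.sample}\t{rep_index}"
                        f"\t{category}\t{source}\t{n_err}"
                        f"\t{combo_label(*intended)}\t{combo_label(*emitted)}"
                        f"\t{jumped}\t{flipped}\n")
    finally:
        for fh in fastq_handles.values():
            fh.close()

    tag_file = outdir / "tags.txt"
    tag_file.write_text("".join(f"{t.id}\t{t.sequence}\n" for t in tags))
    primer_file = outdir / "primers.txt"
    primer_file.write_text("".join(
        f"{p.barcode_name}\t{p.forward}\t{p.reverse}\n" for p in primers))
    pcr_file = outdir / "pcrs.txt"
    pcr_file.write_text("".join(
        f"{r.sample}\t{r.fwd_tag_id}\t{r.rev_tag_id}\t{r.pool}\n"
        for r in records))
    refs_fasta = outdir / "refs.fasta"
    refs_fasta.write_text("".join(
        f">{name}\n{seq}\n" for name, seq in references.items()))

    return SimResult(
        outdir=outdir,
        fastq_by_pool={p: outdir / f"{p}.fastq" for p in pools},
        pcr_file=pcr_file, tag_file=tag_file, primer_file=primer_file,
        refs_fasta=refs_fasta, truth_tsv=truth_path,
        design=design, references=references,
    )
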