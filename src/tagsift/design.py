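"""Experiment design: tags, primers and the sample ↔ tag-combination map.

A double-tagged amplicon experiment is described by three small text files:

* a **tag file** — one row per tag: ``<tag id> <sequence>``;
* a **primer file** — one row per targeted barcode:
  ``<barcode name> <forward primer> <reverse primer>`` (several rows when
  PCRs were multiplexed);
* a **PCR design file** — one row per PCR replicate:
  ``<sample> <forward tag id> <reverse tag id> <pool>``.

All three are whitespace-delimited; blank lines and lines starting with
``#`` are ignored.  :func:`load_design` parses and cross-validates them into
a single :class:`LibraryDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Tag",
    "PrimerSet",
    "PCRRecord",
    "LibraryDesign",
    "DesignError",
    "load_design",
    "combo_label",
    "parse_combo_label",
    "reverse_complement",
    "iupac_mismatches",
]

# IUPAC nucleotide degeneracy sets.  Tags must be plain ACGT; primers may
# use any code below.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R↔Y, K↔M, B↔V, D↔H; S/W/N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_mismatches(pattern: str, segment: str) -> int:
    """Count positions of ``segment`` not covered by ``pattern``'s IUPAC sets.

    Both strings must have equal length; a degenerate pattern base matches
    any base in its degeneracy set.
    """
    if len(pattern) != len(segment):
        raise ValueError("pattern and segment lengths differ")
    return sum(b not in IUPAC[a] for a, b in zip(pattern, segment))


def combo_label(fwd_tag_id: str, rev_tag_id: str) -> str:
    """Render a tag combination as ``F<id>-R<id>`` (e.g. ``F1-R3``)."""
    return f"F{fwd_tag_id}-R{rev_tag_id}"


def parse_combo_label(label: str) -> tuple[str, str]:
    """Inverse of :func:`combo_label`."""
    fwd, _, rev = label.partition("-R")
    if not fwd.startswith("F") or not rev:
        raise ValueError(f"not a combo label: {label!r}")
    return fwd[1:], rev


class DesignError(ValueError):
    """Raised when the design files are inconsistent."""


@dataclass(frozen=True)
class Tag:
    id: str
    sequence: str


@dataclass(frozen=True)
class PrimerSet:
    barcode_name: str
    forward: str
    reverse: str


@dataclass(frozen=True)
class PCRRecord:
    sample: str
    fwd_tag_id: str
    rev_tag_id: str
    pool: str

    @property
    def combo(self) -> tuple[str, str]:
        return (self.fwd_tag_id, self.rev_tag_id)


@dataclass
class LibraryDesign:
    """Validated description of a double-tagged, replicated experiment."""

    tags: list[Tag]
    primers: list[PrimerSet]
    pcrs: list[PCRRecord]
    replicates_per_sample: int = field(init=False)

    def __post_init__(self) -> None:
        self._validate()

    # -- lookups -----------------------------------------------------------
    @property
    def tag_by_id(self) -> dict[str, Tag]:
        return {t.id: t for t in self.tags}

    @property
    def pools(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.pcrs:
            seen.setdefault(r.pool, None)
        return list(seen)

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.pcrs:
            seen.setdefault(r.sample, None)
        return list(seen)

    def used_combos(self, pool: str) -> set[tuple[str, str]]:
        """Tag combinations assigned in the laboratory design for one pool."""
        return {r.combo for r in self.pcrs if r.pool == pool}

    def sample_replicates(self, sample: str) -> list[PCRRecord]:
        """A sample's PCR replicates in design-file row order."""
        return [r for r in self.pcrs if r.sample == sample]

    def combo_sample(self, pool: str, combo: tuple[str, str]) -> str | None:
        for r in self.pcrs:
            if r.pool == pool and r.combo == combo:
                return r.sample
        return None

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        if not self.tags:
            raise DesignError("no tags defined")
        if not self.primers:
            raise DesignError("no primer sets defined")
        if not self.pcrs:
            raise DesignError("no PCR records defined")

        ids = [t.id for t in self.tags]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate tag ids in tag file")
        seqs = [t.sequence for t in self.tags]
        if len(set(seqs)) != len(seqs):
            raise DesignError("duplicate tag sequences in tag file")
        for t in self.tags:
            if not t.sequence:
                raise DesignError(f"tag {t.id} has an empty sequence")
            bad = set(t.sequence) - set("ACGT")
            if bad:
                raise DesignError(
                    f"tag {t.id} contains non-ACGT characters {sorted(bad)}; "
                    "degeneracy codes are only allowed in primers"
                )
        for p in self.primers:
            for name, seq in (("forward", p.forward), ("reverse", p.reverse)):
                if not seq:
                    raise DesignError(f"{name} primer of {p.barcode_name} is empty")
                bad = set(seq) - set(IUPAC)
                if bad:
                    raise DesignError(
                        f"{name} primer of {p.barcode_name} contains "
                        f"non-IUPAC characters {sorted(bad)}"
                    )

        known = set(ids)
        triples: set[tuple[str, str, str]] = set()
        for r in self.pcrs:
            for tid in (r.fwd_tag_id, r.rev_tag_id):
                if tid not in known:
                    raise DesignError(
                        f"PCR record for sample {r.sample} references unknown "
                        f"tag id {tid!r}"
                    )
            triple = (r.fwd_tag_id, r.rev_tag_id, r.pool)
            if triple in triples:
                raise DesignError(
                    f"duplicate tag combination {combo_label(*triple[:2])} "
                    f"in pool {r.pool}"
                )
            triples.add(triple)

        counts: dict[str, int] = {}
        for r in self.pcrs:
            counts[r.sample] = counts.get(r.sample, 0) + 1
        uniq = set(counts.values())
        if len(uniq) > 1:
            most = max(uniq, key=lambda n: sum(v == n for v in counts.values()))
            offenders = sorted(s for s, n in counts.items() if n != most)
            raise DesignError(
                "unequal replicates: all samples must have the same number of "
                f"PCR replicates; offending samples: {', '.join(offenders)}"
            )
        object.__setattr__(self, "replicates_per_sample", uniq.pop())


def _rows(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split())
    return rows


def load_design(pcr_file: str | Path, tag_file: str | Path,
                primer_file: str | Path) -> LibraryDesign:
    """Parse and cross-validate the three design files.

    Sequences are uppercased on ingest.  An optional single header row is
    tolerated in each file: a tag-file row whose second column is not pure
    ACGT, a primer-file row whose primer columns contain non-IUPAC
    characters, or a first PCR-file row whose tag-id columns reference no
    known tag id.
    """
    tag_rows = _rows(Path(tag_file))
    tags: list[Tag] = []
    for i, row in enumerate(tag_rows):
        if len(row) < 2:
            raise DesignError(f"tag file row {i + 1}: expected 'id sequence'")
        seq = row[1].upper()
        if i == 0 and (set(seq) - set(IUPAC)):
            continue  # header row ("sequence", etc.)
        tags.append(Tag(id=row[0], sequence=seq))

    primer_rows = _rows(Path(primer_file))
    primers: list[PrimerSet] = []
    for i, row in enumerate(primer_rows):
        if len(row) < 3:
            raise DesignError(
                f"primer file row {i + 1}: expected 'name forward reverse'"
            )
        fwd, rev = row[1].upper(), row[2].upper()
        if i == 0 and (set(fwd + rev) - set(IUPAC)):
            continue  # header row
        primers.append(PrimerSet(barcode_name=row[0], forward=fwd, reverse=rev))

    known = {t.id for t in tags}
    pcr_rows = _rows(Path(pcr_file))
    pcrs: list[PCRRecord] = []
    for i, row in enumerate(pcr_rows):
        if len(row) < 4:
            raise DesignError(
                f"PCR file row {i + 1}: expected 'sample fwd_tag rev_tag pool'"
            )
        if i == 0 and row[1] not in known and row[2] not in known:
            continue  # header row
        pcrs.append(PCRRecord(sample=row[0], fwd_tag_id=row[1],
                              rev_tag_id=row[2], pool=row[3]))

    return LibraryDesign(tags=tags, primers=primers, pcrs=pcrs)
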