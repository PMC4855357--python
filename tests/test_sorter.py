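"""Demultiplexing: tag/primer matching, collapsing, conservation, oracle."""

import pytest

from tagsift.design import reverse_complement
from tagsift.sorter import (
    classify_combos,
    match_read,
    read_sorted_pool,
    sort_pool,
    write_sorted_pool,
)
from tagsift.synth import SimConfig, simulate
from tagsift.design import load_design

from conftest import FWD_PRIMER, REV_PRIMER, TAGS, build_read, write_fastq

INSERT = "ACGTACGTACGTACGTAAATTTCCCGGG"


# ---------------------------------------------------------------- match_read

def test_exact_read_matches_and_trims(tiny_design):
    read = build_read(TAGS["1"], TAGS["2"], INSERT)
    assert match_read(read, tiny_design) == (("1", "2"), INSERT)


def test_orientation_symmetry(tiny_design):
    read = build_read(TAGS["1"], TAGS["2"], INSERT, flip=True)
    assert match_read(read, tiny_design) == (("1", "2"), INSERT)


def test_tag_substitution_is_fatal(tiny_design):
    """Tags are the sample identifier: no mismatch budget applies to them.

    Oracle: no tag sequence equals the corrupted prefix, so exhaustive
    prefix comparison agrees that nothing can match."""
    good = build_read(TAGS["1"], TAGS["2"], INSERT)
    corrupted = "G" + good[1:]  # ACACAC -> GCACAC
    assert all(not corrupted.startswith(t.sequence)
               for t in tiny_design.tags)
    assert match_read(corrupted, tiny_design, max_primer_mismatch=2) is None


@pytest.mark.parametrize("n_subs,expected", [(1, True), (2, True), (3, False)])
def test_primer_mismatch_budget(tiny_design, n_subs, expected):
    primer = list(FWD_PRIMER.replace("W", "A"))
    for i in range(n_subs):
        pos = 1 + 2 * i  # avoid the W position (index 2)
        if pos == 2:
            pos = 3
        primer[pos] = "C" if primer[pos] != "C" else "G"
    read = (TAGS["1"] + "".join(primer) + INSERT
            + reverse_complement(REV_PRIMER.replace("W", "T"))
            + reverse_complement(TAGS["2"]))
    hit = match_read(read, tiny_design, max_primer_mismatch=2)
    assert (hit is not None) is expected


def test_empty_insert_discarded(tiny_design):
    read = build_read(TAGS["1"], TAGS["2"], "")
    assert match_read(read, tiny_design) is None


def test_short_read_discarded(tiny_design):
    assert match_read("ACACA", tiny_design) is None


def test_iupac_primer_position_matches_either_base(tiny_design):
    # W in FWD_PRIMER position 2 accepts A and T without using the budget
    for base in "AT":
        fp = FWD_PRIMER.replace("W", base)
        read = (TAGS["1"] + fp + INSERT
                + reverse_complement(REV_PRIMER.replace("W", "T"))
                + reverse_complement(TAGS["3"]))
        assert match_read(read, tiny_design, max_primer_mismatch=0) == \
            (("1", "3"), INSERT)


# ----------------------------------------------------------------- sort_pool

def test_identical_reads_collapse(tmp_path, tiny_design):
    fastq = tmp_path / "p1.fastq"
    write_fastq(fastq, [build_read(TAGS["1"], TAGS["1"], INSERT)] * 10)
    sp = sort_pool(fastq, tiny_design, "p1")
    assert sp.combos == {("1", "1"): {INSERT: 10}}
    assert sp.n_discarded_tag_primer_errors == 0
    assert sp.n_input_reads == 10


def test_corrupted_primers_counted_as_errors(tmp_path, tiny_design):
    """3 of 10 reads carry primers corrupted beyond the mismatch budget;
    oracle: per-read match_read applied independently."""
    good = build_read(TAGS["1"], TAGS["1"], INSERT)
    bad = (TAGS["1"] + "T" * len(FWD_PRIMER) + INSERT
           + reverse_complement(REV_PRIMER.replace("W", "T"))
           + reverse_complement(TAGS["1"]))
    reads = [good] * 7 + [bad] * 3
    fastq = tmp_path / "p1.fastq"
    write_fastq(fastq, reads)
    sp = sort_pool(fastq, tiny_design, "p1")
    per_read = [match_read(r, tiny_design) for r in reads]
    assert sp.n_discarded_tag_primer_errors == sum(
        h is None for h in per_read) == 3
    assert sp.n_sorted_reads == 7
    sp.check()


def test_orientation_invariance(tmp_path, tiny_design):
    """Reverse-complementing every input read changes nothing."""
    reads = [build_read(TAGS[f], TAGS[r], INSERT + "A" * k)
             for k, (f, r) in enumerate([("1", "1"), ("1", "2"),
                                         ("3", "4"), ("2", "2")])]
    fwd, rev = tmp_path / "fwd.fastq", tmp_path / "rev.fastq"
    write_fastq(fwd, reads)
    write_fastq(rev, [reverse_complement(r) for r in reads])
    a = sort_pool(fwd, tiny_design, "p1")
    b = sort_pool(rev, tiny_design, "p1")
    assert a.combos == b.combos
    assert a.n_discarded_tag_primer_errors == b.n_discarded_tag_primer_errors


def test_classify_combos(tmp_path, tiny_design):
    reads = ([build_read(TAGS["1"], TAGS["1"], INSERT)] * 5
             + [build_read(TAGS["1"], TAGS["2"], INSERT)] * 2)
    fastq = tmp_path / "p1.fastq"
    write_fastq(fastq, reads)
    sp = sort_pool(fastq, tiny_design, "p1")
    used, unused = classify_combos(sp, tiny_design)
    assert set(used) == {("1", "1")}
    assert set(unused) == {("1", "2")}  # tag-jump signature


def test_all_observed_combos_used(tmp_path, tiny_design):
    fastq = tmp_path / "p1.fastq"
    write_fastq(fastq, [build_read(TAGS["1"], TAGS["1"], INSERT)])
    used, unused = classify_combos(sort_pool(fastq, tiny_design, "p1"),
                                  tiny_design)
    assert unused == {}


# -------------------------------------------------------------- output files

def test_write_and_read_sorted_pool_round_trip(tmp_path, tiny_design):
    reads = ([build_read(TAGS["1"], TAGS["1"], INSERT)] * 5
             + [build_read(TAGS["1"], TAGS["1"], INSERT + "TT")] * 2
             + [build_read(TAGS["2"], TAGS["2"], INSERT)] * 3
             + [TAGS["1"] + "A" * 10])  # error read
    fastq = tmp_path / "p1.fastq"
    write_fastq(fastq, reads)
    sp = sort_pool(fastq, tiny_design, "p1")
    outdir = tmp_path / "out"
    paths = write_sorted_pool(sp, tiny_design, outdir)
    # one file per observed combo plus the summary
    assert len(paths) == len(sp.combos) + 1
    loaded = read_sorted_pool(outdir)
    assert loaded == sp


def test_summary_flags_and_totals(tmp_path, tiny_design):
    reads = ([build_read(TAGS["1"], TAGS["1"], INSERT)] * 4
             + [build_read(TAGS["2"], TAGS["1"], INSERT)] * 2)
    fastq = tmp_path / "p1.fastq"
    write_fastq(fastq, reads)
    sp = sort_pool(fastq, tiny_design, "p1")
    outdir = tmp_path / "out"
    write_sorted_pool(sp, tiny_design, outdir)
    lines = [l.split("\t") for l in
             (outdir / "summary.tsv").read_text().splitlines()
             if not l.startswith(("#", "combo"))]
    flags = {row[0]: row[1] for row in lines}
    assert flags == {"F1-R1": "used", "F2-R1": "unused"}
    assert sum(int(row[3]) for row in lines) == sp.n_sorted_reads


# ------------------------------------------------------------------- oracle

def _oracle_match(seq, design, mm):
    """Independent exhaustive classifier: try every (orientation, primer,
    fwd tag, rev tag) combination; unique structural fit or nothing."""
    from tagsift.design import iupac_mismatches

    hits = set()
    for s in (seq, reverse_complement(seq)):
        for ps in design.primers:
            for ft in design.tags:
                for rt in design.tags:
                    lf, lr = len(ft.sequence), len(rt.sequence)
                    lp, lq = len(ps.forward), len(ps.reverse)
                    if len(s) < lf + lp + lq + lr + 1:
                        continue
                    if s[:lf] != ft.sequence:
                        continue
                    if s[-lr:] != reverse_complement(rt.sequence):
                        continue
                    if iupac_mismatches(ps.forward, s[lf:lf + lp]) > mm:
                        continue
                    tail = s[len(s) - lr - lq:len(s) - lr]
                    if iupac_mismatches(
                            reverse_complement(ps.reverse), tail) > mm:
                        continue
                    hits.add(((ft.id, rt.id), s[lf + lp:len(s) - lr - lq]))
    if len(hits) == 1:
        return hits.pop()
    return None


def test_sort_pool_matches_exhaustive_oracle(tmp_path):
    """On a 1,000-read simulated pool, the sorter equals a brute-force
    per-read classifier trying every tag/primer/orientation combination."""
    cfg = SimConfig(n_samples=2, replicates_per_sample=4,
                    reads_per_replicate=125, tag_jump_rate=0.05,
                    point_error_rate=0.005, chimera_rate=0.02, seed=11)
    res = simulate(cfg, tmp_path / "sim")
    design = load_design(res.pcr_file, res.tag_file, res.primer_file)
    sp = sort_pool(res.fastq_by_pool["pool1"], design, "pool1")

    from tagsift.seqio import read_fastq
    expected: dict = {}
    n_discard = 0
    for _rid, seq, _q in read_fastq(res.fastq_by_pool["pool1"]):
        hit = _oracle_match(seq, design, 2)
        if hit is None:
            n_discard += 1
            continue
        combo, insert = hit
        expected.setdefault(combo, {})
        expected[combo][insert] = expected[combo].get(insert, 0) + 1
    assert sp.combos == expected
    assert sp.n_discarded_tag_primer_errors == n_discard
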