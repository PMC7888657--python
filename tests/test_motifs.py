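"""Operator scanner versus a brute-force regular-expression oracle."""

import re

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from oxcascade.motifs import (
    MOTIFS,
    generate_promoter_fixture,
    scan_fasta,
    scan_sequence,
)


def regex_oracle(sequence, tss, motif):
    """Overlap-aware exact-match scan of both strands, independent of the scanner."""
    pattern = MOTIFS[motif].replace("N", "[ACGT]")
    hits = set()
    for m in re.finditer(f"(?=({pattern}))", sequence):
        i = m.start()
        off = i - tss + 1 if i >= tss else i - tss
        hits.add((off, "forward"))
    rc = str(Seq(MOTIFS[motif]).reverse_complement()).replace("N", "[ACGT]")
    for m in re.finditer(f"(?=({rc}))", sequence):
        i = m.start()
        off = i - tss + 1 if i >= tss else i - tss
        key = (off, "reverse")
        # palindromic consensus: forward and reverse coincide, report once
        if MOTIFS[motif] == str(Seq(MOTIFS[motif]).reverse_complement()):
            key = (off, "forward")
        hits.add(key)
    return hits


@pytest.mark.parametrize(
    "motif,offset,strand",
    [
        ("anaerobox", -34, "forward"),  # fnrN distal box position
        ("anaerobox", -2, "forward"),  # fnrN proximal box position
        ("kbox", -62, "forward"),  # fixK9a / fixK9b K-box position
        ("kbox", 6, "forward"),  # fxkR9 K-box, downstream of the TSS
        ("anaerobox", 38, "forward"),  # fxkR9 downstream anaerobox
        ("kbox", -62, "reverse"),
        ("anaerobox", -90, "reverse"),  # palindrome: reported on the forward strand
    ],
)
def test_planted_operator_round_trip(motif, offset, strand):
    seq, tss = generate_promoter_fixture(motif, offset, seed=7, strand=strand)
    hits = scan_sequence(seq, tss)
    assert len(hits) == 1
    hit = hits[0]
    assert hit.motif == motif
    assert hit.offset == offset
    assert hit.mismatches == 0
    expected_strand = "forward" if motif == "anaerobox" else strand
    assert hit.strand == expected_strand


def test_motif_free_background_has_no_hits():
    seq, tss = generate_promoter_fixture("anaerobox", -34, seed=11)
    stripped = seq[: tss - 34] + "A" * 14 + seq[tss - 34 + 14 :]
    # destroying the planted site may accidentally create none; the background
    # itself was rejection-sampled to be motif-free
    assert scan_sequence(stripped, tss) == [] or all(
        h.offset != -34 for h in scan_sequence(stripped, tss)
    )


def test_no_zero_offset_convention():
    # a motif starting exactly on the TSS base reports +1
    seq, tss = generate_promoter_fixture("anaerobox", 1, seed=3)
    hits = scan_sequence(seq, tss)
    assert [h.offset for h in hits] == [1]


@given(
    motif=st.sampled_from(["anaerobox", "kbox"]),
    offset=st.integers(-180, 40).filter(lambda o: o != 0),
    seed=st.integers(0, 10_000),
    strand=st.sampled_from(["forward", "reverse"]),
)
@settings(max_examples=60, deadline=None)
def test_scanner_matches_regex_oracle_on_fixtures(motif, offset, seed, strand):
    seq, tss = generate_promoter_fixture(motif, offset, seed=seed, strand=strand)
    got = {(h.offset, h.strand) for h in scan_sequence(seq, tss, window=(-250, 250))}
    want = regex_oracle(seq, tss, "anaerobox") | regex_oracle(seq, tss, "kbox")
    assert got == want
    assert (offset, "forward" if motif == "anaerobox" else strand) in got


@given(seed=st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_reverse_complement_reflects_hit_coordinates(seed):
    seq, tss = generate_promoter_fixture("kbox", -30, seed=seed)
    rc = str(Seq(seq).reverse_complement())
    rc_tss = len(seq) - 1 - tss
    fwd = scan_sequence(seq, tss, window=(-250, 250))
    rev = scan_sequence(rc, rc_tss, window=(-250, 250))
    m = len(MOTIFS["kbox"])

    def reflect(h):
        i = tss + (h.offset - 1 if h.offset > 0 else h.offset)
        j = len(seq) - (i + m)  # start of the reflected window
        off = j - rc_tss + 1 if j >= rc_tss else j - rc_tss
        strand = "reverse" if h.strand == "forward" else "forward"
        return (off, strand)

    assert {reflect(h) for h in fwd} == {(h.offset, h.strand) for h in rev}


def test_window_limits_and_sorting():
    seq, tss = generate_promoter_fixture("anaerobox", -150, seed=5)
    assert scan_sequence(seq, tss, window=(-100, 60)) == []
    hits = scan_sequence(seq, tss, window=(-200, 60))
    assert [h.offset for h in hits] == [-150]


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        scan_sequence("ACGTXACGT", 2)
    with pytest.raises(ValueError):
        scan_sequence("ACGT", 9)
    with pytest.raises(ValueError):
        generate_promoter_fixture("anaerobox", 0)
    with pytest.raises(ValueError):
        generate_promoter_fixture("anaerobox", -300, flank=100)


def test_mismatch_tolerance_counts_degenerate_bases():
    seq, tss = generate_promoter_fixture("anaerobox", -40, seed=9)
    i = tss - 40
    mutated = seq[:i] + "A" + seq[i + 1 :]  # break the first consensus base (T)
    assert all(h.offset != -40 for h in scan_sequence(mutated, tss))
    hits = scan_sequence(mutated, tss, max_mismatches=1)
    assert any(h.offset == -40 and h.mismatches == 1 for h in hits)


def test_fasta_and_tss_table_io(tmp_path):
    seq, tss = generate_promoter_fixture("kbox", -62, seed=21)
    fasta = tmp_path / "promoters.fasta"
    fasta.write_text(f">pfixK9a\n{seq}\n")
    table = tmp_path / "tss.tsv"
    table.write_text(f"pfixK9a\t{tss}\t+\n")
    frame = scan_fasta(fasta, table)
    assert list(frame["offset"]) == [-62]
    assert list(frame["motif"]) == ["kbox"]
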