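"""Promoter operator scanning: anaeroboxes and K-boxes relative to a TSS.

Two operator consensi govern the cascade's promoters: the anaerobox
TTGAT-N4-ATCAA bound by FNR-family dimers (FixK, FnrN) and the K-box
GTTACA-N4-GTTACA bound by phosphorylated FxkR.  Operator positions are
reported relative to the transcription start site with the standard
no-zero convention: the TSS base is +1, the base immediately upstream
is -1.  A hit's offset is the position of the motif's 5'-most base on
the forward strand.

The anaerobox consensus is an exact palindrome (it equals its own
reverse complement), so forward and reverse matches coincide and each
site is reported once, on the forward strand.  The K-box is a direct
repeat and is scanned on both strands independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "MOTIFS",
    "MotifHit",
    "scan_sequence",
    "generate_promoter_fixture",
    "scan_fasta",
]

#: operator consensi; N matches any base
MOTIFS = {
    "anaerobox": "TTGATNNNNATCAA",
    "kbox": "GTTACANNNNGTTACA",
}

_VALID = set("ACGTN")


@dataclass(frozen=True)
class MotifHit:
    motif: str  # "anaerobox" or "kbox"
    strand: str  # "forward" or "reverse"
    offset: int  # TSS-relative position of the motif's first base; no zero
    sequence: str  # matched forward-strand sequence
    mismatches: int

    def __post_init__(self):
        if self.offset == 0:
            raise ValueError("offset 0 does not exist in TSS-relative coordinates")
        if len(self.sequence) != len(MOTIFS[self.motif]):
            raise ValueError("matched sequence length does not fit the motif")


def _offset_from_index(index: int, tss_index: int) -> int:
    """TSS-relative offset of a 0-based sequence index (TSS base = +1, no zero)."""
    d = index - tss_index
    return d + 1 if d >= 0 else d


def _index_from_offset(offset: int, tss_index: int) -> int:
    if offset == 0:
        raise ValueError("offset 0 does not exist in TSS-relative coordinates")
    return tss_index + (offset - 1 if offset > 0 else offset)


def _mismatches(window: str, pattern: str) -> int:
    # N in the pattern matches anything; N in the sequence never matches a
    # fixed pattern base
    return sum(1 for w, p in zip(window, pattern) if p != "N" and w != p)


def scan_sequence(
    sequence: str,
    tss: int,
    window: tuple[int, int] = (-200, 60),
    max_mismatches: int = 0,
    motifs: tuple[str, ...] = ("anaerobox", "kbox"),
) -> list[MotifHit]:
    """Exhaustive operator scan of a promoter region, both strands.

    Parameters
    ----------
    sequence
        Nucleotide string over A/C/G/T/N (case-insensitive).
    tss
        0-based index of the transcription start base within ``sequence``.
    window
        (upstream, downstream) extent of reported offsets; the default
        (-200, +60) covers the region where functional operators are
        found, with margin.
    max_mismatches
        Allowed mismatches to the consensus (default exact).

    Returns hits sorted by offset, then motif.  Palindromic anaerobox
    sites are reported once, on the forward strand.
    """
    seq = sequence.upper()
    if set(seq) - _VALID:
        raise ValueError(f"invalid characters in sequence: {sorted(set(seq) - _VALID)}")
    if not (0 <= tss < len(seq)):
        raise ValueError(f"TSS index {tss} outside the sequence (length {len(seq)})")
    lo, hi = window
    hits = []
    for motif in motifs:
        pattern = MOTIFS[motif]
        m = len(pattern)
        rc_pattern = str(Seq(pattern).reverse_complement())
        palindromic = pattern == rc_pattern
        for i in range(len(seq) - m + 1):
            offset = _offset_from_index(i, tss)
            if not (lo <= offset <= hi):
                continue
            w = seq[i : i + m]
            mm = _mismatches(w, pattern)
            if mm <= max_mismatches:
                hits.append(MotifHit(motif, "forward", offset, w, mm))
            if not palindromic:
                mm_rc = _mismatches(w, rc_pattern)
                if mm_rc <= max_mismatches:
                    hits.append(MotifHit(motif, "reverse", offset, w, mm_rc))
    hits.sort(key=lambda h: (h.offset, h.motif, h.strand))
    return hits


def generate_promoter_fixture(
    motif: str,
    offset: int,
    flank: int = 200,
    seed: int = 0,
    strand: str = "forward",
) -> tuple[str, int]:
    """Random motif-free promoter with one operator planted at a known offset.

    Background is sampled uniformly over ACGT and rejected until it
    contains no hit of either consensus; the motif (spacer bases
    randomised) is then planted with its first base at ``offset``
    relative to the TSS, optionally as its reverse complement.  Returns
    ``(sequence, tss_index)``; scanning the fixture round-trips the
    planted offset.
    """
    if offset == 0:
        raise ValueError("offset 0 does not exist in TSS-relative coordinates")
    if motif not in MOTIFS:
        raise ValueError(f"unknown motif {motif!r}")
    if strand not in ("forward", "reverse"):
        raise ValueError("strand must be 'forward' or 'reverse'")
    pattern = MOTIFS[motif]
    m = len(pattern)
    length = 2 * flank + 1
    tss_index = flank
    start = _index_from_offset(offset, tss_index)
    if start < 0 or start + m > length:
        raise ValueError(
            f"offset {offset} with motif length {m} does not fit inside flanks of {flank} bp"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        seq = "".join(rng.choice(bases, size=length))
        if not scan_sequence(seq, tss_index, window=(-length, length)):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not generate a motif-free background")
    planted = "".join(
        rng.choice(bases) if b == "N" else b for b in pattern
    )
    if strand == "reverse":
        planted = str(Seq(planted).reverse_complement())
    out = seq[:start] + planted + seq[start + m :]
    return out, tss_index


def scan_fasta(
    fasta_path,
    tss_table_path,
    window: tuple[int, int] = (-200, 60),
    max_mismatches: int = 0,
) -> pd.DataFrame:
    """Scan FASTA records against a TSS table; returns one row per hit.

    The TSS table is BED-like tab-separated text with three columns:
    sequence name, 0-based TSS coordinate, strand (only '+' entries are
    scanned as-is; '-' entries are scanned on the reverse complement
    with the TSS coordinate mapped accordingly).
    """
    tss_table = pd.read_csv(
        tss_table_path, sep="\t", comment="#", header=None, names=["name", "tss", "strand"]
    )
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    rows = []
    for _, entry in tss_table.iterrows():
        if entry["name"] not in records:
            raise KeyError(f"TSS table names {entry['name']!r} but the FASTA does not contain it")
        seq = records[entry["name"]]
        tss = int(entry["tss"])
        if entry["strand"] == "-":
            seq = str(Seq(seq).reverse_complement())
            tss = len(seq) - 1 - tss
        for hit in scan_sequence(seq, tss, window=window, max_mismatches=max_mismatches):
            rows.append(
                {
                    "name": entry["name"],
                    "motif": hit.motif,
                    "strand": hit.strand,
                    "offset": hit.offset,
                    "sequence": hit.sequence,
                    "mismatches": hit.mismatches,
                }
            )
    return pd.DataFrame(
        rows, columns=["name", "motif", "strand", "offset", "sequence", "mismatches"]
    )
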