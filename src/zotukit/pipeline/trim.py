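"""Primer trimming with IUPAC-aware matching."""

from __future__ import annotations

from typing import Optional

from .reads import ReadRecord, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(primer_base: str, read_base: str) -> bool:
    return read_base in IUPAC.get(primer_base.upper(), "")


def _mismatches_at(sequence: str, primer: str, start: int, limit: int) -> int:
    """Mismatch count of ``primer`` against ``sequence[start:]``; returns
    limit+1 as soon as the limit is exceeded (or the primer overhangs)."""
    if start + len(primer) > len(sequence):
        return limit + 1
    mismatches = 0
    for i, p in enumerate(primer):
        if not iupac_match(p, sequence[start + i]):
            mismatches += 1
            if mismatches > limit:
                return mismatches
    return mismatches


def trim_primers(
    read: ReadRecord,
    fwd_primer: str,
    rev_primer: str,
    max_mismatches: int = 1,
) -> Optional[ReadRecord]:
    """Trim amplification primers off a read.

    The forward primer must match at the 5' end (<= ``max_mismatches``,
    IUPAC-aware); its prefix is removed.  If the reverse complement of
    the reverse primer occurs downstream (read-through), it is removed
    together with everything 3' of it.  Reads without a 5' primer hit
    are discarded (None).
    """
    fwd_primer = fwd_primer.upper()
    if _mismatches_at(read.sequence, fwd_primer, 0, max_mismatches) > max_mismatches:
        return None
    start = len(fwd_primer)
    seq = read.sequence[start:]
    quals = read.qualities[start:]

    rc_rev = revcomp(rev_primer.upper())
    for pos in range(0, len(seq) - len(rc_rev) + 1):
        if _mismatches_at(seq, rc_rev, pos, max_mismatches) <= max_mismatches:
            seq = seq[:pos]
            quals = quals[:pos]
            break
    return ReadRecord(read_id=read.read_id, sequence=seq, qualities=quals)
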