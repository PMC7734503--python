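"""Paired-end read merging by best-offset overlap scan.

The reverse read is reverse-complemented and slid along the forward
read; the offset maximising the number of matching bases wins.  A merge
is accepted when the overlap is at least ``min_overlap`` bases long and
at least 90% identical.  Consensus bases at disagreeing positions come
from the higher-quality read; merged qualities follow a simple
posterior rule: min(Qf + Qr, 41) at agreements, |Qf - Qr| at
disagreements.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .reads import ReadRecord, revcomp

MERGED_Q_CAP = 41


def merge_pair(
    fwd: ReadRecord,
    rev: ReadRecord,
    min_overlap: int = 60,
    min_identity: float = 0.9,
) -> Optional[ReadRecord]:
    """Merge a read pair into a consensus read, or None on failure.

    ``rev`` is given as sequenced; it is reverse-complemented here.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    rc_seq = revcomp(rev.sequence)
    rc_quals = rev.qualities[::-1]

    f = np.frombuffer(fwd.sequence.encode("ascii"), dtype=np.uint8)
    r = np.frombuffer(rc_seq.encode("ascii"), dtype=np.uint8)
    fq = fwd.qualities
    rq = rc_quals
    lf, lr = len(f), len(r)
    if lf < min_overlap or lr < min_overlap:
        return None

    best: Optional[tuple[int, int, int]] = None  # (matches, overlap, offset)
    for offset in range(0, lf - min_overlap + 1):
        overlap = min(lf - offset, lr)
        if overlap < min_overlap:
            break
        matches = int((f[offset : offset + overlap] == r[:overlap]).sum())
        if best is None or matches > best[0]:
            best = (matches, overlap, offset)
    if best is None:
        return None
    matches, overlap, offset = best
    if matches / overlap < min_identity:
        return None

    # consensus over the overlap
    fo = f[offset : offset + overlap]
    ro = r[:overlap]
    fqo = fq[offset : offset + overlap]
    rqo = rq[:overlap]
    agree = fo == ro
    cons = np.where(agree | (fqo >= rqo), fo, ro)  # tie -> forward base
    cons_q = np.where(agree, np.minimum(fqo + rqo, MERGED_Q_CAP), np.abs(fqo - rqo))

    head_seq = fwd.sequence[:offset]
    head_q = fq[:offset]
    if offset + lr > lf:  # reverse read extends past the forward read
        tail_seq = rc_seq[overlap:]
        tail_q = rq[overlap:]
    else:  # reverse read contained within the forward read
        tail_seq = fwd.sequence[offset + overlap :]
        tail_q = fq[offset + overlap :]

    merged_seq = head_seq + cons.tobytes().decode("ascii") + tail_seq
    merged_q = np.concatenate([head_q, cons_q, tail_q])
    return ReadRecord(read_id=fwd.read_id, sequence=merged_seq, qualities=merged_q)
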