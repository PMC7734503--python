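"""Expected-error computation and read quality filtering."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .reads import ReadRecord

#: Absolute tolerance applied to the (inclusive) maxEE boundary so that
#: reads whose true expected error equals the threshold are kept
#: regardless of floating-point summation order.
EE_EPSILON = 1e-9


def expected_errors(qualities: Sequence[int]) -> float:
    """Expected number of errors: EE = sum of 10^(-Q/10) over the read."""
    q = np.asarray(qualities, dtype=np.float64)
    if q.size == 0:
        return 0.0
    return float(np.sum(10.0 ** (-q / 10.0)))


def passes_filter(read: ReadRecord, max_ee: float, min_length: int) -> bool:
    """Both boundaries inclusive: EE <= maxEE and length >= min_length."""
    if len(read) < min_length:
        return False
    return expected_errors(read.qualities) <= max_ee + EE_EPSILON


def quality_filter(
    reads: Iterable[ReadRecord], max_ee: float, min_length: int
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Keep reads with EE <= maxEE and length >= min_length.

    Returns the surviving reads and an in/out count report.
    """
    kept: list[ReadRecord] = []
    n_in = 0
    for read in reads:
        n_in += 1
        if passes_filter(read, max_ee, min_length):
            kept.append(read)
    return kept, {"reads_in": n_in, "reads_kept": len(kept), "reads_filtered_out": n_in - len(kept)}
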