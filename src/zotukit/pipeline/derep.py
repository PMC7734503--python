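"""Exact-string dereplication of filtered reads."""

from __future__ import annotations

from collections import Counter
from typing import Iterable


def dereplicate(sequences: Iterable[str]) -> list[tuple[str, int]]:
    """Group identical sequences (uppercased) into (sequence, abundance)
    pairs sorted by abundance descending, ties lexicographic.

    Abundances sum to the input count.
    """
    counts = Counter(s.upper() for s in sequences)
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))
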