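"""Shared pairwise-alignment primitives (Biopython-backed)."""

from __future__ import annotations

from Bio import Align

# Unit-cost global aligner: -score equals the Levenshtein distance.
_edit_aligner = Align.PairwiseAligner()
_edit_aligner.mode = "global"
_edit_aligner.match_score = 0
_edit_aligner.mismatch_score = -1
_edit_aligner.open_gap_score = -1
_edit_aligner.extend_gap_score = -1

# Global alignment with free end gaps for identity computation.
_identity_aligner = Align.PairwiseAligner()
_identity_aligner.mode = "global"
_identity_aligner.match_score = 1
_identity_aligner.mismatch_score = -1
_identity_aligner.open_gap_score = -1
_identity_aligner.extend_gap_score = -1
try:  # Biopython >= 1.88 naming
    _identity_aligner.end_insertion_score = 0
    _identity_aligner.end_deletion_score = 0
except AttributeError:  # pragma: no cover - older Biopython
    _identity_aligner.target_end_gap_score = 0
    _identity_aligner.query_end_gap_score = 0


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two sequences."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return int(-_edit_aligner.score(a, b))


def identity_percent(a: str, b: str) -> float:
    """Percent identity of the best global-with-free-end-gaps alignment.

    Identity = matches / alignment columns, where columns span the
    aligned core (terminal free end gaps excluded, internal gaps
    counted).
    """
    if not a or not b:
        return 0.0
    alignment = _identity_aligner.align(a, b)[0]
    a_blocks, b_blocks = alignment.aligned
    if len(a_blocks) == 0:
        return 0.0
    matches = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)
        columns += a1 - a0
        for i in range(a1 - a0):
            if a[a0 + i] == b[b0 + i]:
                matches += 1
        prev_a_end, prev_b_end = a1, b1
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns
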