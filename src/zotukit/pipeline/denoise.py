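"""Greedy abundance-ordered denoising of dereplicated amplicons.

A unique sequence either joins an established centroid -- allowed when
its abundance skew against the centroid does not exceed
``beta(d) = 1 / 2^(alpha*d + 1)`` for edit distance ``d`` -- or founds a
new centroid if its abundance reaches ``min_size``.  Skew is evaluated
against the centroid's dereplicated (pre-absorption) abundance;
absorbed read counts accumulate separately into the reported ZOTU
abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from ._align import edit_distance


@dataclass
class DenoiseParams:
    alpha: float = 2.0
    min_size: int = 8

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass
class ZotuRecord:
    """A denoised unique sequence with the reads it absorbed."""

    zotu_id: str
    sequence: str
    abundance: int
    marker: str
    length: int = 0

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")
        self.length = len(self.sequence)


@dataclass
class DenoiseResult:
    centroids: list[tuple[str, int]]  # (sequence, accumulated abundance), sorted
    assignment: dict[str, str] = field(default_factory=dict)  # unique -> centroid
    rejected_reads: int = 0  # reads in uniques below min_size that joined nothing


def beta(d: float, alpha: float = 2.0) -> float:
    """Maximum abundance skew allowed at edit distance ``d``."""
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def max_eligible_distance(skew: float, alpha: float) -> int:
    """Largest d with beta(d) >= skew (0 when even d=1 is ruled out).

    Evaluated against beta itself rather than an inverted closed form so
    boundary cases agree bit-for-bit with the skew test.
    """
    if skew <= 0:
        raise ValueError("skew must be positive")
    d = 0
    while beta(d + 1, alpha) >= skew:
        d += 1
    return d


def denoise(
    uniques: Sequence[tuple[str, int]],
    params: Optional[DenoiseParams] = None,
    distance: Callable[[str, str], int] = edit_distance,
) -> DenoiseResult:
    """Denoise dereplicated (sequence, abundance) pairs.

    ``uniques`` must be sorted by abundance descending (ties broken
    lexicographically).  Candidate centroids are ranked by edit
    distance, then by higher dereplicated abundance, then by creation
    order.
    """
    if params is None:
        params = DenoiseParams()
    order = [(-a, s) for s, a in uniques]
    if order != sorted(order):
        raise ValueError("uniques must be sorted by abundance desc, ties lexicographic")

    centroid_seqs: list[str] = []
    centroid_sizes: list[int] = []  # dereplicated abundances (skew denominator)
    accumulated: list[int] = []
    assignment: dict[str, str] = {}
    rejected = 0

    for seq, abundance in uniques:
        best: Optional[tuple[int, int, int]] = None  # (d, -size, index)
        for idx, cseq in enumerate(centroid_seqs):
            size = centroid_sizes[idx]
            skew = abundance / size
            d_max = max_eligible_distance(skew, params.alpha)
            if d_max < 1:
                continue
            d = distance(seq, cseq)
            if d > d_max:
                continue
            key = (d, -size, idx)
            if best is None or key < best:
                best = key
        if best is not None:
            idx = best[2]
            accumulated[idx] += abundance
            assignment[seq] = centroid_seqs[idx]
        elif abundance >= params.min_size:
            centroid_seqs.append(seq)
            centroid_sizes.append(abundance)
            accumulated.append(abundance)
            assignment[seq] = seq
        else:
            rejected += abundance

    centroids = sorted(
        zip(centroid_seqs, accumulated), key=lambda item: (-item[1], item[0])
    )
    return DenoiseResult(
        centroids=centroids, assignment=assignment, rejected_reads=rejected
    )


def label_zotus(result: DenoiseResult, marker: str) -> list[ZotuRecord]:
    """Assign Zotu<N> identifiers in final-abundance order."""
    return [
        ZotuRecord(zotu_id=f"Zotu{i}", sequence=seq, abundance=ab, marker=marker)
        for i, (seq, ab) in enumerate(result.centroids, start=1)
    ]
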