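"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written without the package's own
machinery (no Biopython aligners, no regex mining, no SQL): plain loops,
dynamic programming and set algebra.
"""

from __future__ import annotations

import math
from math import fsum

PREFIXES = ("SRA", "SRP", "SRS", "SRX", "SRR", "PRJNA", "PRJEB", "ERP", "ERS")


def scan_accessions(text: str) -> list[tuple[str, str, int]]:
    """Brute-force character scan with word-boundary checks.

    Returns (accession, prefix, offset) triples for prefix + 4-9 digits
    tokens bounded by non-alphanumerics.
    """
    out = []
    n = len(text)
    i = 0
    while i < n:
        if i > 0 and text[i - 1].isalnum():
            i += 1
            continue
        hit = None
        for prefix in sorted(PREFIXES, key=len, reverse=True):
            if not text.startswith(prefix, i):
                continue
            j = i + len(prefix)
            k = j
            while k < n and text[k].isdigit():
                k += 1
            n_digits = k - j
            if 4 <= n_digits <= 9 and (k == n or not text[k].isalnum()):
                hit = (text[i:k], prefix, i)
                break
        if hit:
            out.append(hit)
            i = i + len(hit[0])
        else:
            i += 1
    return out


def levenshtein(a: str, b: str) -> int:
    """Classic O(nm) edit-distance DP."""
    if a == b:
        return 0
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i]
        for j, cb in enumerate(b, start=1):
            curr.append(
                min(
                    prev[j] + 1,
                    curr[j - 1] + 1,
                    prev[j - 1] + (ca != cb),
                )
            )
        prev = curr
    return prev[-1]


def expected_errors_fsum(qualities) -> float:
    """EE by exact compensated summation."""
    return fsum(10.0 ** (-float(q) / 10.0) for q in qualities)


def overlap_identity(a: str, b: str) -> float:
    """Percent identity of the best free-end-gap global alignment.

    DP over (score, matches, -columns) tuples, lexicographically
    maximised: optimal score first, then the most matches, then the
    fewest core columns.  Unit scores: match +1, mismatch -1, gap -1,
    terminal gaps free and excluded from the column count.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0.0
    NEG = (-math.inf, 0, 0)
    prev = [(0, 0, 0)] * (m + 1)
    best = NEG
    for i in range(1, n + 1):
        curr = [(0, 0, 0)] + [NEG] * m
        for j in range(1, m + 1):
            match = a[i - 1] == b[j - 1]
            ds, dm, dc = prev[j - 1]
            cand = (ds + (1 if match else -1), dm + (1 if match else 0), dc - 1)
            us, um, uc = prev[j]
            up = (us - 1, um, uc - 1)
            ls, lm, lc = curr[j - 1]
            left = (ls - 1, lm, lc - 1)
            curr[j] = max(cand, up, left)
        # free trailing gaps: candidates are the last column of every row
        if curr[m] > best:
            best = curr[m]
        prev = curr
    for j in range(0, m + 1):  # and the last row
        if prev[j] > best:
            best = prev[j]
    _, matches, neg_cols = best
    cols = -neg_cols
    if cols == 0:
        return 0.0
    return 100.0 * matches / cols


def beta_oracle(d: int, alpha: float) -> float:
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def denoise_oracle(uniques, alpha: float, min_size: int):
    """Independent greedy denoiser: plain-DP distances, direct skew test.

    Processes uniques in descending abundance (lexicographic ties),
    ranking candidate centroids by distance, then dereplicated
    abundance, then creation order.  Returns (centroids, rejected_reads)
    with centroids as (sequence, accumulated abundance) sorted like the
    implementation's output.
    """
    ordered = sorted(uniques, key=lambda item: (-item[1], item[0]))
    centroids = []  # [sequence, derep_size, accumulated]
    rejected = 0
    for seq, abundance in ordered:
        best = None
        for idx, (cseq, size, _) in enumerate(centroids):
            d = levenshtein(seq, cseq)
            if d >= 1 and abundance / size <= beta_oracle(d, alpha):
                key = (d, -size, idx)
                if best is None or key < best:
                    best = key
        if best is not None:
            centroids[best[2]][2] += abundance
        elif abundance >= min_size:
            centroids.append([seq, abundance, abundance])
        else:
            rejected += abundance
    out = sorted(((c[0], c[2]) for c in centroids), key=lambda x: (-x[1], x[0]))
    return out, rejected


def presence_sets(contains_rows, sample_units):
    """unit -> set of ref_ids, from raw (ref_id, srs) rows and a
    srs -> unit mapping (None units dropped)."""
    sets = {}
    for ref_id, srs in contains_rows:
        unit = sample_units.get(srs)
        if unit is None:
            continue
        sets.setdefault(unit, set()).add(ref_id)
    return sets
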