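"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way and shares no
code with the package internals it checks.
"""

from __future__ import annotations

import math


def best_subread_bruteforce(
    qualities: list[int], limit: float
) -> tuple[int, int, float]:
    """O(L^2) scan for the maximal-sum window of limit - 10**(-Q/10).

    Windows are scanned end-major then start-major with strict improvement,
    so ties resolve to the earliest end, then the earliest start — the same
    rule the implementation documents.  Returns (start, end_exclusive, sum);
    (0, 0, 0.0) when every window is non-positive.
    """
    scores = [limit - 10.0 ** (-q / 10.0) for q in qualities]
    best = (0, 0, 0.0)
    for end in range(len(scores)):
        for start in range(end + 1):
            total = sum(scores[start : end + 1])
            if total > best[2]:
                best = (start, end + 1, total)
    return best


def scan_occurrences(query: str, references: list[tuple[str, str]]) -> list[tuple[str, int]]:
    """Try the query at every position of every reference, char by char."""
    hits = []
    for ref_id, seq in references:
        for pos in range(len(seq) - len(query) + 1):
            if all(seq[pos + i] == query[i] for i in range(len(query))):
                hits.append((ref_id, pos))
    return hits


def coverage_by_counting(
    intervals: list[tuple[int, int, int]], length: int
) -> list[int]:
    """Per-base coverage from (start, length, weight) triples, one base at a time."""
    cov = [0] * length
    for start, ilen, weight in intervals:
        for p in range(start, start + ilen):
            cov[p] += weight
    return cov


def information_content_by_hand(column_counts: dict[str, int]) -> float:
    """2 + sum f log2 f, recomputed spreadsheet-style from raw counts."""
    total = sum(column_counts.values())
    acc = 2.0
    for count in column_counts.values():
        if count > 0:
            f = count / total
            acc += f * math.log2(f)
    return acc


def clc_anchor_score(anchor: str, read: str) -> int:
    """Best internal-match score of the anchor inside a read under the
    legacy score model: match +1, mismatch cost 5, gap cost 5.

    Fit alignment: the anchor must be consumed in full, read bases outside
    the matched region are free.  A region is accepted as an anchor match
    when the score reaches len(anchor) (15 for the 15-nt anchor).
    """
    n, m = len(anchor), len(read)
    NEG = -(10**9)
    dp = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        dp[0][j] = 0  # leading read bases are free
    for i in range(n + 1):
        for j in range(m + 1):
            if dp[i][j] == NEG:
                continue
            if i < n and j < m:
                step = 1 if anchor[i] == read[j] else -5
                dp[i + 1][j + 1] = max(dp[i + 1][j + 1], dp[i][j] + step)
            if i < n:
                dp[i + 1][j] = max(dp[i + 1][j], dp[i][j] - 5)
            if j < m:
                dp[i][j + 1] = max(dp[i][j + 1], dp[i][j] - 5)
    return max(dp[n])  # trailing read bases are free


def single_edit_variants(seq: str, alphabet: str = "ACGT") -> set[str]:
    """All substitutions, single-base deletions and insertions of seq."""
    variants: set[str] = set()
    for i in range(len(seq)):
        for b in alphabet:
            if b != seq[i]:
                variants.add(seq[:i] + b + seq[i + 1 :])
        variants.add(seq[:i] + seq[i + 1 :])
    for i in range(len(seq) + 1):
        for b in alphabet:
            variants.add(seq[:i] + b + seq[i:])
    variants.discard(seq)
    return variants


def distinct_kmers_bruteforce(sequences: list[str], k: int) -> set[str]:
    """Distinct k-length windows, collected with explicit slicing."""
    seen: set[str] = set()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            seen.add(seq[i : i + k])
    return seen
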