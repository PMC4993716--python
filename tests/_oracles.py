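"""Independent brute-force oracles used only by the test suite.

Each oracle is implemented from first principles, without importing the
corresponding production code path, so that agreement is meaningful.
"""

from __future__ import annotations

import itertools
import re

# Independent IUPAC table (regex character classes), written out by hand.
IUPAC_REGEX_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def regex_find_sites(sequence: str, recognition: str) -> list[int]:
    """Overlapping match starts of a degenerate pattern in an ACGT string,
    via a lookahead regex built from an independent IUPAC table."""
    pattern = "(?=" + "".join(IUPAC_REGEX_CLASS[s] for s in recognition) + ")"
    return [m.start() for m in re.finditer(pattern, sequence)]


def brute_upgma_cophenetic(labels, matrix) -> dict[frozenset, float]:
    """Cophenetic distances from a from-scratch UPGMA.

    At every step the average inter-cluster distance is recomputed over all
    member pairs directly from the input matrix (no incremental updates).
    Ties break on the lexicographically smallest (key_i, key_j) pair, a
    cluster's key being its smallest member label.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    clusters: list[frozenset] = [frozenset((lab,)) for lab in labels]
    coph: dict[frozenset, float] = {}

    def avg(cx: frozenset, cy: frozenset) -> float:
        import math

        return math.fsum(
            matrix[index[a]][index[b]] for a in cx for b in cy
        ) / (len(cx) * len(cy))

    while len(clusters) > 1:
        best = None
        best_key = None
        for cx, cy in itertools.combinations(clusters, 2):
            d = avg(cx, cy)
            key = (d, tuple(sorted((min(cx), min(cy)))))
            if best_key is None or key < best_key:
                best_key = key
                best = (cx, cy)
        cx, cy = best
        d = best_key[0]
        for a in cx:
            for b in cy:
                coph[frozenset((a, b))] = d
        clusters.remove(cx)
        clusters.remove(cy)
        clusters.append(cx | cy)
    return coph


def brute_rm(columns: list[list[bool]], positions: list[int]) -> int:
    """Maximum number of pairwise-disjoint four-gamete conflicting
    intervals, by exhaustive branch-and-take recursion (take/skip each
    interval in left-endpoint order)."""
    intervals = []
    for a, b in itertools.combinations(range(len(positions)), 2):
        pa, pb = positions[a], positions[b]
        if pa > pb:
            pa, pb = pb, pa
        gametes = {(x, y) for x, y in zip(columns[a], columns[b])}
        if len(gametes) == 4:
            intervals.append((pa, pb))
    intervals.sort()

    import functools

    @functools.lru_cache(maxsize=None)
    def best_from(i: int, frontier: float) -> int:
        if i == len(intervals):
            return 0
        left, right = intervals[i]
        skip = best_from(i + 1, frontier)
        if left >= frontier:
            return max(skip, 1 + best_from(i + 1, right))
        return skip

    return best_from(0, float("-inf"))
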