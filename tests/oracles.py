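"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and shares no code with the package:
repeat detection tests every (start, unit-length) pair directly against
string equality, and UPGMA recomputes every cluster distance as the plain
mean over all cross pairs of the original matrix.
"""

from __future__ import annotations

import numpy as np

DEFAULT_MINIMA = {2: 6, 3: 5, 4: 4, 5: 4, 6: 3}


def brute_force_ssrs(seq: str, minima: dict[int, int] | None = None):
    """All maximal perfect repeats by exhaustive (start, unit) testing,
    resolved so each position belongs to at most one locus (longest run
    first, then smaller unit, then leftmost)."""
    minima = minima or DEFAULT_MINIMA
    n = len(seq)
    candidates = []
    for k, min_units in minima.items():
        for start in range(n - k * min_units + 1):
            motif = seq[start : start + k]
            if any(b not in "ACGT" for b in motif):
                continue
            if any(
                k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
            ):
                continue
            count = 0
            while seq[start + count * k : start + (count + 1) * k] == motif:
                count += 1
            if count < min_units:
                continue
            if start >= k and seq[start - k : start] == motif:
                continue  # not left-maximal
            candidates.append((start, start + count * k, motif, count))
    candidates.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    chosen = []
    for s, e, m, c in candidates:
        if all(e <= s2 or s >= e2 for s2, e2, _, _ in chosen):
            chosen.append((s, e, m, c))
    return sorted(chosen)


def naive_upgma(dist: np.ndarray, labels: list[str]):
    """UPGMA where every cluster distance is recomputed from the original
    matrix as the mean over all leaf cross pairs.  Returns a set of
    (frozenset of tip labels, merge height) pairs, one per internal node."""
    clusters = [frozenset([i]) for i in range(len(labels))]
    nodes = set()
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(
                    np.mean([[dist[a, b] for b in clusters[j]] for a in clusters[i]])
                )
                tie = tuple(
                    sorted(
                        (
                            min(labels[a] for a in clusters[i]),
                            min(labels[b] for b in clusters[j]),
                        )
                    )
                )
                key = (d, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _), i, j = best
        merged = clusters[i] | clusters[j]
        nodes.add((frozenset(labels[a] for a in merged), d / 2.0))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return nodes


def dendrogram_nodes(tree):
    """(tip-label set, height) per internal node of a package Dendrogram."""
    nodes = set()

    def walk(node):
        children, height, label = node
        if not children:
            return frozenset([label])
        tips = frozenset()
        for child in children:
            tips |= walk(child)
        nodes.add((tips, height))
        return tips

    walk(tree.root)
    return nodes
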