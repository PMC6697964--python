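"""Germplasm diversity from band presence/absence scores.

Markers are scored per allele as band presence (1) or absence (0) across
genotypes.  Per-locus informativeness is the polymorphic information
content PIC = 1 - sum(p_j^2) over the locus's allele frequencies; pairwise
genotype similarity is Jaccard's coefficient on the binary band profiles;
and the genotypes are clustered by UPGMA (size-weighted average linkage)
on the 1 - Jaccard distance, giving an ultrametric dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def pic(frequencies) -> float:
    """Polymorphic information content, 1 - sum(p^2).

    ``frequencies`` are the allele frequencies at one locus; they must be
    nonnegative and sum to 1 (tolerance 1e-9).
    """
    p = np.asarray(frequencies, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()!r}, not 1")
    return float(1.0 - np.sum(p**2))


@dataclass(frozen=True)
class AlleleMatrix:
    """Binary genotype x (locus, allele) band-score matrix.

    ``bands`` are (locus, allele) pairs; column order groups alleles by
    locus.  Entries are 0/1 band absence/presence.
    """

    genotypes: tuple[str, ...]
    bands: tuple[tuple[str, str], ...]
    scores: np.ndarray  # shape (n_genotypes, n_bands), dtype int

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.shape != (len(self.genotypes), len(self.bands)):
            raise ValueError("scores shape does not match labels")
        if not np.isin(s, (0, 1)).all():
            raise ValueError("scores must be binary")

    @property
    def loci(self) -> tuple[str, ...]:
        seen: list[str] = []
        for locus, _ in self.bands:
            if locus not in seen:
                seen.append(locus)
        return tuple(seen)

    def locus_columns(self, locus: str) -> list[int]:
        return [j for j, (l, _) in enumerate(self.bands) if l == locus]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{l}:{a}" for l, a in self.bands]
        return pd.DataFrame(self.scores, index=list(self.genotypes), columns=cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AlleleMatrix":
        bands = tuple(tuple(c.split(":", 1)) for c in frame.columns)
        return cls(tuple(frame.index), bands, frame.to_numpy(dtype=int))


def locus_frequencies(matrix: AlleleMatrix, locus: str) -> np.ndarray:
    """Allele frequencies at a locus from band presence counts.

    P_j = (presences of band j) / (total band presences at the locus), so
    genotypes with no band at the locus (null alleles) drop out of the
    denominator rather than forming an allele class.
    """
    cols = matrix.locus_columns(locus)
    if not cols:
        raise KeyError(f"unknown locus {locus!r}")
    counts = matrix.scores[:, cols].sum(axis=0).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"locus {locus!r} has no band presences")
    return counts / total


def jaccard(x, y) -> float:
    """Jaccard similarity |x & y| / |x | y| of two binary vectors.

    Two all-zero profiles are defined as identical (similarity 1).
    """
    a = np.asarray(x, dtype=bool)
    b = np.asarray(y, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class LocusStats:
    locus: str
    allele_count: int
    frequencies: tuple[float, ...]
    pic: float


class Dendrogram:
    """Ultrametric UPGMA tree over genotype labels.

    Nodes are nested ``(children, height, label)`` tuples; tips have height
    0 and no children.  Serializes to newick with branch lengths equal to
    height differences.
    """

    def __init__(self, root):
        self.root = root

    @property
    def height(self) -> float:
        return self.root[1]

    def tip_heights(self) -> dict[str, float]:
        """Root-to-tip path length per tip (all equal for an ultrametric tree)."""
        out: dict[str, float] = {}

        def walk(node, acc):
            children, height, label = node
            if not children:
                out[label] = acc + height  # height 0 at tips
                return
            for child in children:
                walk(child, acc + (height - child[1]))

        walk(self.root, 0.0)
        return out

    def tips(self) -> list[str]:
        out: list[str] = []

        def walk(node):
            children, _, label = node
            if not children:
                out.append(label)
            for child in children:
                walk(child)

        walk(self.root)
        return out

    def merge_heights(self) -> list[float]:
        out: list[float] = []

        def walk(node):
            children, height, _ = node
            if children:
                out.append(height)
                for child in children:
                    walk(child)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node, parent_height):
            children, height, label = node
            blen = parent_height - height
            if not children:
                return f"{label}:{blen:.6g}"
            inner = ",".join(fmt(c, height) for c in children)
            return f"({inner}):{blen:.6g}"

        children, height, _ = self.root
        inner = ",".join(fmt(c, height) for c in children)
        return f"({inner});"


def upgma(distance_matrix, labels) -> Dendrogram:
    """UPGMA clustering of a symmetric distance matrix.

    Iteratively merges the closest pair; the merged cluster's distance to
    any other cluster is the size-weighted arithmetic average of its
    members' distances, and each merge node sits at half the merge
    distance.  Ties are broken deterministically by the lexicographically
    smallest (sorted) label pair.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix and labels disagree")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12) or np.any(d < 0):
        raise ValueError("distances must be nonnegative with zero diagonal")
    if n == 0:
        raise ValueError("empty matrix")

    # cluster id -> (node, size, min tip label for tie-breaks)
    clusters: dict[int, tuple[tuple, int, str]] = {
        i: (((), 0.0, str(labels[i])), 1, str(labels[i])) for i in range(n)
    }
    dist: dict[frozenset, float] = {
        frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        best = None
        for pair, dij in dist.items():
            i, j = sorted(pair)
            key = (dij, tuple(sorted((clusters[i][2], clusters[j][2]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        (dij, _), i, j = best[0], best[1], best[2]
        dij = dist[frozenset((i, j))]
        node_i, size_i, min_i = clusters.pop(i)
        node_j, size_j, min_j = clusters.pop(j)
        merged = ((node_i, node_j), dij / 2.0, None)
        for k in list(clusters):
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (size_i * dik + size_j * djk) / (
                size_i + size_j
            )
        del dist[frozenset((i, j))]
        clusters[next_id] = (merged, size_i + size_j, min(min_i, min_j))
        next_id += 1
    root = next(iter(clusters.values()))[0]
    return Dendrogram(root)


@dataclass(frozen=True)
class DiversitySummary:
    locus_stats: tuple[LocusStats, ...]
    mean_alleles_per_locus: float
    pic_min: float
    pic_max: float
    pic_mean: float
    distance_matrix: np.ndarray
    genotypes: tuple[str, ...]
    dendrogram: Dendrogram


def summarize_diversity(matrix: AlleleMatrix) -> DiversitySummary:
    """Per-locus stats, panel summary, Jaccard distances and UPGMA tree."""
    stats = []
    for locus in matrix.loci:
        freqs = locus_frequencies(matrix, locus)
        observed = int(np.count_nonzero(freqs))
        stats.append(LocusStats(locus, observed, tuple(freqs), pic(freqs)))
    if not stats:
        raise ValueError("empty matrix")
    pics = np.array([s.pic for s in stats])
    n = len(matrix.genotypes)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = 1.0 - jaccard(
                matrix.scores[i], matrix.scores[j]
            )
    tree = upgma(dmat, list(matrix.genotypes))
    return DiversitySummary(
        locus_stats=tuple(stats),
        mean_alleles_per_locus=float(np.mean([s.allele_count for s in stats])),
        pic_min=float(pics.min()),
        pic_max=float(pics.max()),
        pic_mean=float(pics.mean()),
        distance_matrix=dmat,
        genotypes=matrix.genotypes,
        dendrogram=tree,
    )
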