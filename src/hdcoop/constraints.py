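"""Positional sequence-constraint analysis of homeodomain families.

Because every domain here is exactly 60 residues, the family "alignment" is
positional: column p of the alignment is HD position p. From a set of
labeled sequences this module computes

* per-position residue frequencies (:class:`FamilyProfile`),
* information-content bit maps in the sequence-logo sense
  (:class:`BitMap`): ic[p] = log2(20) - H[p] with H the Shannon entropy of
  the column, letter heights f * ic,
* a differential bit map (Paired-like letter heights minus ANTP letter
  heights) highlighting positions constrained in one family but not the
  other,
* one-hot Euclidean inter-sequence distances (d = sqrt(2 m) for m
  mismatched positions, a monotone transform of Hamming distance), and
* deterministic complete-linkage hierarchical clustering with Newick
  export.

The complete-linkage agglomeration is implemented here rather than taken
from a library so that ties are broken reproducibly (lowest cluster-index
pair); its merge heights agree with scipy's implementation whenever
distances are tie-free, which the test suite checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequences import CANONICAL_RESIDUES, HD_LENGTH, HDSequence, RESIDUE_INDEX

N_RESIDUES = len(CANONICAL_RESIDUES)
MAX_BITS = float(np.log2(N_RESIDUES))


@dataclass(frozen=True)
class FamilyProfile:
    """Residue counts per HD position over a family of sequences."""

    counts: np.ndarray  # (60, 20) integer counts
    n: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (HD_LENGTH, N_RESIDUES):
            raise ValueError(f"counts must be {HD_LENGTH}x{N_RESIDUES}")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.all(counts.sum(axis=1) == self.n):
            raise ValueError("each position's counts must sum to n")

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n


def compute_profile(seqs: Sequence[HDSequence]) -> FamilyProfile:
    """Tabulate per-position residue counts for a non-empty sequence set."""
    if not seqs:
        raise ValueError("cannot compute a profile from an empty sequence list")
    counts = np.zeros((HD_LENGTH, N_RESIDUES), dtype=int)
    for seq in seqs:
        for p, aa in enumerate(seq.residues):
            counts[p, RESIDUE_INDEX[aa]] += 1
    return FamilyProfile(counts, len(seqs))


@dataclass(frozen=True)
class BitMap:
    """Per-position information content (bits) and per-letter heights."""

    ic: np.ndarray       # (60,)
    heights: np.ndarray  # (60, 20), heights[p, a] = f[p, a] * ic[p]


def compute_bitmap(profile: FamilyProfile, small_sample_correction: bool = False) -> BitMap:
    """Information content ic[p] = log2(20) - H[p] (- e_n if corrected).

    H[p] is the Shannon entropy of the position's residue frequencies with
    0*log(0) taken as 0. The optional small-sample correction subtracts
    e_n = 19 / (2 n ln 2); ic is clamped below at 0. Letter heights are
    frequency times ic, so each column of heights sums to ic[p].
    """
    freq = profile.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log2(np.where(freq > 0, freq, 1.0)), 0.0)
    entropy = -terms.sum(axis=1)
    ic = MAX_BITS - entropy
    if small_sample_correction:
        ic = ic - (N_RESIDUES - 1) / (2.0 * profile.n * np.log(2.0))
    ic = np.clip(ic, 0.0, None)
    heights = freq * ic[:, None]
    return BitMap(ic=ic, heights=heights)


@dataclass(frozen=True)
class DifferentialBitMap:
    """Letter-height differences between two family bit maps.

    ``delta[p, a] = heights_first[p, a] - heights_second[p, a]``; positive
    values mark residues constrained in the first family, negative in the
    second. Swapping the argument order negates the matrix.
    """

    delta: np.ndarray  # (60, 20)


def differential_bitmap(bit_first: BitMap, bit_second: BitMap) -> DifferentialBitMap:
    return DifferentialBitMap(delta=bit_first.heights - bit_second.heights)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between named sequences."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


def distance_matrix(seqs: Sequence[HDSequence]) -> DistanceMatrix:
    """One-hot Euclidean distances: d(i, j) = sqrt(2 * mismatches(i, j)).

    Each position is encoded as 20 indicator coordinates; a mismatched
    position contributes 2 to the squared distance, so the distance is a
    monotone transform of Hamming distance.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    arr = np.array([[RESIDUE_INDEX[aa] for aa in s.residues] for s in seqs])
    mismatches = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return DistanceMatrix(ids=tuple(s.id for s in seqs), d=np.sqrt(2.0 * mismatches))


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge tree in scipy linkage-matrix form.

    ``linkage`` rows are (cluster_i, cluster_j, height, size) with leaves
    numbered 0..n-1 and merged clusters n, n+1, ... in merge order. Complete
    linkage is monotone, so heights are non-decreasing.
    """

    ids: tuple[str, ...]
    linkage: np.ndarray  # (n - 1, 4)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the tree."""
        n = len(self.ids)

        def leaves(node: int) -> list[int]:
            if node < n:
                return [node]
            i, j = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
            return leaves(i) + leaves(j)

        return [self.ids[i] for i in leaves(2 * n - 2)]

    def cut(self, k: int) -> dict[str, int]:
        """Assign each leaf to one of ``k`` flat clusters (1-based labels)."""
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.ids, (int(c) for c in labels)))

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        n = len(self.ids)
        heights = np.concatenate([np.zeros(n), self.linkage[:, 2]])

        def render(node: int, parent_height: float) -> str:
            branch = parent_height - heights[node]
            if node < n:
                return f"{self.ids[node]}:{branch:.6g}"
            i, j = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
            h = heights[node]
            return f"({render(i, h)},{render(j, h)}):{branch:.6g}"

        root = 2 * n - 2
        i, j = int(self.linkage[root - n, 0]), int(self.linkage[root - n, 1])
        h = heights[root]
        return f"({render(i, h)},{render(j, h)});"


def complete_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with the maximum-linkage update rule.

    Deterministic: among all active cluster pairs at the current minimum
    distance, the lexicographically lowest (i, j) cluster-index pair merges
    first (cluster indices follow the scipy convention).
    """
    d0 = np.asarray(dm.d, dtype=float)
    if not np.all(np.isfinite(d0)):
        raise ValueError("distance matrix contains non-finite entries")
    n = len(dm.ids)
    # dist maps active cluster-id pairs (i < j) to their linkage distance
    dist: dict[tuple[int, int], float] = {
        (i, j): d0[i, j] for i in range(n) for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    rows = []
    next_id = n
    while len(active) > 1:
        (i, j) = min(dist, key=lambda p: (dist[p], p))
        h = dist[(i, j)]
        rows.append([i, j, h, sizes[i] + sizes[j]])
        for k in sorted(active - {i, j}):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(k, next_id)] = max(dik, djk)
        del dist[(i, j)]
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return Dendrogram(ids=dm.ids, linkage=np.array(rows, dtype=float))
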