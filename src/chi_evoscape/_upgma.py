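"""Deterministic UPGMA (average-linkage agglomeration) on a dissimilarity matrix.

Leaves are numbered 0..n-1, internal nodes n, n+1, ...; merge heights are half
the between-cluster average dissimilarity (ultrametric node heights).  Ties are
broken by the lexicographically smallest pair of cluster member-id minima, so
the dendrogram is a pure function of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import format_branch_length, quote_newick_label


@dataclass
class Merge:
    left: int
    right: int
    height: float
    size: int


@dataclass
class Dendrogram:
    ids: list[str]
    merges: list[Merge]
    group_labels: dict[str, int] = field(default_factory=dict)

    @property
    def heights(self) -> list[float]:
        return [m.height for m in self.merges]


def upgma(dissim: np.ndarray, ids: list[str]) -> Dendrogram:
    """Agglomerate with size-weighted average linkage (UPGMA)."""
    d = np.asarray(dissim, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix shape does not match ids")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    # active clusters: node index -> (member leaf set, size, min id)
    active: dict[int, tuple[int, str]] = {i: (1, ids[i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[Merge] = []
    next_node = n
    while len(active) > 1:
        # smallest distance; ties by lexicographic (min_id_a, min_id_b) sorted pair
        best_key = None
        best = None
        for (i, j), dij in dist.items():
            mi, mj = active[i][1], active[j][1]
            tie = tuple(sorted((mi, mj)))
            cand = (dij, tie)
            if best is None or cand < best:
                best = cand
                best_key = (i, j)
        i, j = best_key
        dij = dist[(i, j)]
        ni, idi = active[i]
        nj, idj = active[j]
        new = next_node
        next_node += 1
        merges.append(Merge(i, j, dij / 2.0, ni + nj))
        del active[i], active[j]
        new_dist = {}
        for k in list(active):
            a, b = (i, k) if i < k else (k, i)
            c, e = (j, k) if j < k else (k, j)
            dk = (ni * dist[(a, b)] + nj * dist[(c, e)]) / (ni + nj)
            new_dist[(k, new)] = dk
        dist = {
            key: v for key, v in dist.items() if i not in key and j not in key
        }
        dist.update(new_dist)
        active[new] = (ni + nj, min(idi, idj))
    return Dendrogram(ids=list(ids), merges=merges)


def cut(dendrogram: Dendrogram, k: int | None = None, height: float | None = None) -> dict[str, int]:
    """Cut into groups: exactly ``k`` groups, or at merge ``height``.

    Group labels are 0-based, ordered by the smallest member id.
    """
    n = len(dendrogram.ids)
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        n_merges = n - k
    else:
        n_merges = sum(1 for m in dendrogram.merges if m.height <= height)
    parent = list(range(n + len(dendrogram.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, merge in enumerate(dendrogram.merges[:n_merges]):
        node = n + m
        parent[find(merge.left)] = node
        parent[find(merge.right)] = node
    roots: dict[int, list[str]] = {}
    for leaf, name in enumerate(dendrogram.ids):
        roots.setdefault(find(leaf), []).append(name)
    groups = sorted(roots.values(), key=lambda members: min(members))
    return {name: g for g, members in enumerate(groups) for name in members}


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with ultrametric branch lengths (6 significant digits)."""
    n = len(dendrogram.ids)
    height = {i: 0.0 for i in range(n)}
    text = {i: quote_newick_label(dendrogram.ids[i]) for i in range(n)}
    for m, merge in enumerate(dendrogram.merges):
        node = n + m
        parts = []
        for child in (merge.left, merge.right):
            bl = merge.height - height[child]
            parts.append(f"{text[child]}:{format_branch_length(bl)}")
        text[node] = "(" + ",".join(parts) + ")"
        height[node] = merge.height
    root = n + len(dendrogram.merges) - 1 if dendrogram.merges else 0
    return text[root] + ";"
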