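"""Structural similarity (TM-score) and UPGMA clustering of CA traces.

Residue correspondence comes from a global sequence alignment with free end
gaps (adequate for homologous family members; a sequence-independent
structural search is out of scope).  Superposition is iterative Kabsch with a
shrinking inclusion-distance schedule, maximizing

    TM = (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2),     d0(L) = 1.24 (L-15)^(1/3) - 1.8

with L_norm the average of the two chain lengths (the "-a" averaging
convention) and d0 floored at 0.5 A for short chains.  Low-confidence models
are excluded before the matrix is assembled; the matrix is min-max scaled over
off-diagonal entries, and structures are clustered by UPGMA on the
Bray-Curtis dissimilarity between their scaled similarity profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _upgma
from ._upgma import Dendrogram
from .io_formats import Structure

_DELTA_SCHEDULE = (3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5)


@dataclass
class SimilarityMatrix:
    ids: list[str]
    raw: np.ndarray  # TM similarities in [0, 1], diagonal 1
    scaled: np.ndarray  # min-max scaled over off-diagonal entries


def d0_tm(l_norm: float) -> float:
    """TM-score distance scale; floored at 0.5 A (formula is negative below ~21)."""
    if l_norm <= 15:
        return 0.5
    d0 = 1.24 * (l_norm - 15.0) ** (1.0 / 3.0) - 1.8
    return max(d0, 0.5)


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimizing |R p + t - q|."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    h = (p - cp).T @ (q - cq)
    u, _s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    return r, cq - r @ cp


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _correspondence(s1: Structure, s2: Structure) -> tuple[np.ndarray, np.ndarray]:
    aln = _ALIGNER.align(s1.seq, s2.seq)[0]
    idx1, idx2 = [], []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        idx1.extend(range(a0, a1))
        idx2.extend(range(b0, b1))
    return np.asarray(idx1, dtype=int), np.asarray(idx2, dtype=int)


def tm_align_pair(s1: Structure, s2: Structure) -> float:
    """TM similarity in (0, 1] of two structures (sequence-guided superposition)."""
    if len(s1.seq) < 20 or len(s2.seq) < 20:
        raise ValueError("structures must have at least 20 residues")
    idx1, idx2 = _correspondence(s1, s2)
    if idx1.size == 0:
        raise ValueError(f"no aligned residue pairs between {s1.id} and {s2.id}")
    p_all = s1.ca_coords[idx1]
    q_all = s2.ca_coords[idx2]
    l_norm = (len(s1.seq) + len(s2.seq)) / 2.0
    if l_norm <= 21:
        warnings.warn("d0 floor applied for short chains", stacklevel=2)
    d0 = d0_tm(l_norm)

    def tm_of(r: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
        d = np.linalg.norm(p_all @ r.T + t - q_all, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm), d

    # several initial correspondence seeds (whole chain plus contiguous
    # fragments) guard against locking onto a bad initial superposition
    n_pairs = len(p_all)
    seeds = [np.ones(n_pairs, dtype=bool)]
    for lo, hi in ((0.0, 0.5), (0.5, 1.0), (0.25, 0.75)):
        frag = np.zeros(n_pairs, dtype=bool)
        frag[int(lo * n_pairs) : int(hi * n_pairs)] = True
        if frag.sum() >= 3:
            seeds.append(frag)
    best_tm = 0.0
    for sel in seeds:
        for delta in _DELTA_SCHEDULE:
            for _ in range(20):
                r, t = kabsch(p_all[sel], q_all[sel])
                tm, d = tm_of(r, t)
                best_tm = max(best_tm, tm)
                new_sel = d < d0 + delta
                if new_sel.sum() < 3:
                    break
                if np.array_equal(new_sel, sel):
                    break
                sel = new_sel
    return min(best_tm, 1.0)


def build_similarity_matrix(
    structures: list[Structure], conf_min: float = 0.7
) -> SimilarityMatrix:
    """Confidence-filter, compute all pairwise TM values, min-max scale.

    The raw matrix is symmetrized by averaging the two orderings (with length
    averaging they agree up to numerics).
    """
    excluded = [s.id for s in structures if s.confidence < conf_min]
    kept = [s for s in structures if s.confidence >= conf_min]
    if len(kept) < 3:
        raise ValueError(
            f"fewer than 3 structures pass confidence >= {conf_min} "
            f"(excluded: {excluded})"
        )
    n = len(kept)
    raw = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            tm = 0.5 * (tm_align_pair(kept[i], kept[j]) + tm_align_pair(kept[j], kept[i]))
            raw[i, j] = raw[j, i] = tm
    off = raw[~np.eye(n, dtype=bool)]
    lo, hi = float(off.min()), float(off.max())
    if hi - lo < 1e-12:
        raise ValueError("degenerate scaling: all off-diagonal similarities equal")
    scaled = (raw - lo) / (hi - lo)
    np.fill_diagonal(scaled, 1.0)
    scaled = np.clip(scaled, 0.0, 1.0)
    return SimilarityMatrix([s.id for s in kept], raw, scaled)


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """Sum |u - v| / sum (u + v) between nonnegative vectors."""
    denom = float(np.sum(u + v))
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for all-zero vectors")
    return float(np.sum(np.abs(u - v)) / denom)


def profile_dissimilarity(matrix: SimilarityMatrix, metric: str = "profile") -> np.ndarray:
    """Pairwise dissimilarity between structures.

    ``profile``: Bray-Curtis between scaled-similarity row vectors, excluding
    the two structures' own columns; ``direct``: 1 - scaled TM.
    """
    n = len(matrix.ids)
    if metric == "direct":
        d = 1.0 - matrix.scaled
        np.fill_diagonal(d, 0.0)
        return d
    if metric != "profile":
        raise ValueError(f"unknown metric {metric!r}")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            d[i, j] = d[j, i] = bray_curtis(
                matrix.scaled[i, mask], matrix.scaled[j, mask]
            )
    return d


def cluster_structures(
    matrix: SimilarityMatrix,
    k: int | None = 5,
    height: float | None = None,
    metric: str = "profile",
) -> Dendrogram:
    """UPGMA on the structure dissimilarities; cut into groups.

    Merge heights are checked monotone non-decreasing on every run.
    """
    d = profile_dissimilarity(matrix, metric=metric)
    dendro = _upgma.upgma(d, matrix.ids)
    heights = dendro.heights
    if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
        raise AssertionError("UPGMA merge heights are not monotone")
    dendro.group_labels = _upgma.cut(dendro, k=k, height=height)
    return dendro


def dendrogram_to_newick(dendro: Dendrogram) -> str:
    return _upgma.to_newick(dendro)
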