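"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately re-derive quantities by brute force (exhaustive
enumeration, naive recursion, or a second library's implementation) and stay
independent of the code paths they check.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}
NT = "ACGT"


def oracle_translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(seq: str) -> tuple[float, float]:
    """Brute-force NG86 site counts via Biopython translation."""
    s_total = 0.0
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for codon in codons:
        aa = oracle_translate(codon)
        for pos in range(3):
            syn = 0
            nonstop = 0
            for nt in NT:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if alt in STOPS:
                    continue
                nonstop += 1
                if oracle_translate(alt) == aa:
                    syn += 1
            if nonstop:
                s_total += syn / nonstop
    return 3.0 * len(codons) - s_total, s_total


def oracle_differences(ca: str, cb: str):
    """Brute-force pathway averaging; returns None if all pathways hit stops."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return 0.0, 0.0
    totals = []
    for order in permutations(pos):
        cur = ca
        nd = sd = 0
        valid = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOPS:
                valid = False
                break
            if oracle_translate(nxt) == oracle_translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            totals.append((nd, sd))
    if not totals:
        return None
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


def oracle_nw_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Naive recursive global affine-gap alignment score (small inputs only)."""
    from functools import lru_cache

    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # state: 0 = last was match, 1 = gap in b, 2 = gap in a
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        best = NEG
        if i > 0 and j > 0:
            if state == 0:
                prev = max(rec(i - 1, j - 1, s) for s in (0, 1, 2))
                best = max(best, prev + sub[a[i - 1]][b[j - 1]])
        if state == 1 and i > 0:
            best = max(best, rec(i - 1, j, 0) - gap_open, rec(i - 1, j, 1) - gap_extend)
        if state == 2 and j > 0:
            best = max(best, rec(i, j - 1, 0) - gap_open, rec(i, j - 1, 2) - gap_extend)
        return best

    return max(rec(len(a), len(b), s) for s in (0, 1, 2))


def blosum62_dict() -> dict:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    return {
        a: {b: float(m[a, b]) for b in "ACDEFGHIKLMNPQRSTVWY"}
        for a in "ACDEFGHIKLMNPQRSTVWY"
    }


def oracle_upgma_scipy(d: np.ndarray):
    """scipy average-linkage as the independent agglomeration oracle.

    Returns (heights, flat cluster labels at k) helpers.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    return linkage(squareform(d, checks=False), method="average")


def random_codon(rng: np.random.Generator) -> str:
    while True:
        c = "".join(rng.choice(list(NT), size=3))
        if c not in STOPS:
            return c


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
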