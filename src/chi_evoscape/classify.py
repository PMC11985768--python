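"""Family alignment, trimming, working tree, CHI typing and protein properties.

The aligner is a deterministic progressive MSA: a UPGMA guide tree on 3-mer
cosine distances, then Gotoh affine-gap profile-profile merges under BLOSUM62.
Trees are neighbor-joining on Poisson-corrected p-distances, midpoint-rooted.

Typing follows the active-site residue rule: within the clade of catalytic
(group 3) exemplars, the residue homologous to position 190 of the reference
decides the type - T -> type II, S -> type I, any other amino acid -> type V,
a gap -> unclassified; the clades anchored by group 1 / group 2 exemplars are
type III and type IV respectively.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from . import _upgma
from .io_formats import AA20, SeqRecord

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


def _blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            out[i, j] = mat[a, b]
    return out


_B62 = _blosum62()


@dataclass
class Msa:
    """A gapped alignment; rows are equal-length strings in ``ids`` order."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def colmap(self, seq_id: str) -> list[int]:
        """Map each ungapped position of ``seq_id`` to its alignment column."""
        row = self.rows[self.ids.index(seq_id)]
        return [c for c, ch in enumerate(row) if ch != "-"]


@dataclass
class CHIAssignment:
    seq_id: str
    chi_type: str  # I | II | III | IV | V | unclassified
    active_site_residue: str  # single letter or '-'
    clade: str  # group1 | group2 | group3 | none
    evidence: str = ""


# ---------------------------------------------------------------- alignment

_NEG = -1e30


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(L, 20) per-column residue frequencies; gaps and X carry no mass."""
    L = len(rows[0])
    freqs = np.zeros((L, 20))
    for row in rows:
        for c, ch in enumerate(row):
            i = _AA_INDEX.get(ch)
            if i is not None:
                freqs[c, i] += 1.0
    return freqs / len(rows)


def _gotoh_profiles(
    f1: np.ndarray, f2: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[float, list[tuple[int | None, int | None]]]:
    """Global affine-gap alignment of two column-frequency profiles.

    Returns the optimal score and the column path (i, j) with None marking a
    gap.  Vectorized row by row; the horizontal gap state is closed over with
    a running-max identity so each row is O(L2).
    """
    L1, L2 = f1.shape[0], f2.shape[0]
    S = f1 @ _B62 @ f2.T
    go, ge = float(gap_open), float(gap_extend)

    M = np.full((L1 + 1, L2 + 1), _NEG)
    Ix = np.full((L1 + 1, L2 + 1), _NEG)
    Iy = np.full((L1 + 1, L2 + 1), _NEG)
    M[0, 0] = 0.0
    j = np.arange(1, L2 + 1)
    Iy[0, 1:] = -go - (j - 1) * ge
    i_arr = np.arange(1, L1 + 1)
    Ix[1:, 0] = -go - (i_arr - 1) * ge
    ge_j = np.arange(L2 + 1) * ge
    for i in range(1, L1 + 1):
        h_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1] + h_prev[:-1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - ge)
        # Iy[i, j] = max_{k<j} M[i, k] - go - (j-1-k) ge, via running max
        a = np.maximum.accumulate(M[i] + ge_j)
        Iy[i, 1:] = a[:-1] - go - (j - 1) * ge

    end = np.array([M[L1, L2], Ix[L1, L2], Iy[L1, L2]])
    state = int(np.argmax(end))
    score = float(end[state])
    path: list[tuple[int | None, int | None]] = []
    i_, j_ = L1, L2
    eps = 1e-9
    while i_ > 0 or j_ > 0:
        if state == 0:  # M
            if i_ == 0 or j_ == 0:
                raise RuntimeError("traceback escaped matrix")
            path.append((i_ - 1, j_ - 1))
            prev = np.array([M[i_ - 1, j_ - 1], Ix[i_ - 1, j_ - 1], Iy[i_ - 1, j_ - 1]])
            state = int(np.argmax(prev))
            i_, j_ = i_ - 1, j_ - 1
        elif state == 1:  # gap in profile 2, consume column of profile 1
            path.append((i_ - 1, None))
            state = 0 if abs(Ix[i_, j_] - (M[i_ - 1, j_] - go)) < eps else 1
            i_ -= 1
        else:  # gap in profile 1
            path.append((None, j_ - 1))
            state = 0 if abs(Iy[i_, j_] - (M[i_, j_ - 1] - go)) < eps else 2
            j_ -= 1
        if state == 1 and i_ == 0:
            state = 2
        elif state == 2 and j_ == 0:
            state = 1
    path.reverse()
    return score, path


def _merge_alignments(
    rows1: list[str], rows2: list[str], path: list[tuple[int | None, int | None]]
) -> tuple[list[str], list[str]]:
    out1 = ["" for _ in rows1]
    out2 = ["" for _ in rows2]
    for i, j in path:
        for k, row in enumerate(rows1):
            out1[k] += row[i] if i is not None else "-"
        for k, row in enumerate(rows2):
            out2[k] += row[j] if j is not None else "-"
    return out1, out2


def pairwise_global_score(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Optimal global affine-gap BLOSUM62 alignment score of two sequences."""
    score, _ = _gotoh_profiles(
        _profile_freqs([a]), _profile_freqs([b]), gap_open, gap_extend
    )
    return score


def _kmer_cosine_distances(seqs: list[str], k: int = 3) -> np.ndarray:
    vecs = []
    vocab: dict[str, int] = {}
    counts = []
    for s in seqs:
        c: dict[int, float] = {}
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            idx = vocab.setdefault(km, len(vocab))
            c[idx] = c.get(idx, 0.0) + 1.0
        counts.append(c)
    n = len(seqs)
    dense = np.zeros((n, len(vocab)))
    for i, c in enumerate(counts):
        for idx, v in c.items():
            dense[i, idx] = v
    norms = np.linalg.norm(dense, axis=1)
    norms[norms == 0] = 1.0
    sim = (dense @ dense.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def build_msa(
    records: list[SeqRecord], gap_open: float = 10.0, gap_extend: float = 0.5
) -> Msa:
    """Progressive multiple alignment (UPGMA 3-mer guide tree, Gotoh merges)."""
    if not records:
        raise ValueError("no sequences to align")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(records) == 1:
        return Msa(ids=[records[0].id], rows=[records[0].seq])
    seqs = [r.seq for r in records]
    guide = _upgma.upgma(_kmer_cosine_distances(seqs), ids)
    n = len(records)
    node_aln: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(n)
    }
    for m, merge in enumerate(guide.merges):
        ids1, rows1 = node_aln.pop(merge.left)
        ids2, rows2 = node_aln.pop(merge.right)
        _, path = _gotoh_profiles(
            _profile_freqs(rows1), _profile_freqs(rows2), gap_open, gap_extend
        )
        new1, new2 = _merge_alignments(rows1, rows2, path)
        node_aln[n + m] = (ids1 + ids2, new1 + new2)
    final_ids, final_rows = node_aln.popitem()[1]
    order = {sid: i for i, sid in enumerate(final_ids)}
    return Msa(ids=list(ids), rows=[final_rows[order[sid]] for sid in ids])


# ----------------------------------------------------------------- trimming


def trim_msa_columns(msa: Msa, gt: float = 0.5) -> tuple[Msa, list[int]]:
    """Trim and also return the kept source-column indices."""
    if not 0 < gt <= 1:
        raise ValueError("gt must be in (0, 1]")
    n = len(msa.rows)
    keep = [
        c
        for c in range(msa.n_cols)
        if sum(row[c] != "-" for row in msa.rows) / n >= gt
    ]
    if not keep:
        raise ValueError("alignment fully trimmed")
    trimmed = Msa(ids=list(msa.ids), rows=["".join(r[c] for c in keep) for r in msa.rows])
    return trimmed, keep


def trim_msa(msa: Msa, gt: float = 0.5) -> Msa:
    """Keep exactly the columns whose non-gap fraction is >= ``gt``."""
    return trim_msa_columns(msa, gt)[0]


# --------------------------------------------------------------------- tree

_P_CAP = 0.95


def msa_distances(msa: Msa) -> np.ndarray:
    """Poisson-corrected p-distances over shared non-gap columns."""
    n = len(msa.ids)
    enc = [np.frombuffer(row.encode(), dtype=np.uint8) for row in msa.rows]
    gap = ord("-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] != gap) & (enc[j] != gap)
            m = int(both.sum())
            if m == 0:
                p = _P_CAP
            else:
                p = float((enc[i][both] != enc[j][both]).sum()) / m
            if p >= _P_CAP:
                warnings.warn(
                    f"p-distance saturated for {msa.ids[i]}/{msa.ids[j]}; capped",
                    stacklevel=2,
                )
                p = _P_CAP
            d[i, j] = d[j, i] = -math.log(1.0 - p)
    return d


def build_nj_tree(msa: Msa) -> str:
    """Neighbor-joining Newick tree, midpoint-rooted; deterministic."""
    if len(msa.ids) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    d = msa_distances(msa)
    if np.all(d == 0):  # identical sequences: star tree
        inner = ",".join(f"{sid}:0.0" for sid in msa.ids)
        return f"({inner});"
    tree = nj(DistanceMatrix(d, msa.ids))
    tree = tree.root_at_midpoint()
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ------------------------------------------------------------------- typing

_CLADES = ("group1", "group2", "group3")
_RESIDUE_TYPE = {"T": "II", "S": "I"}


def _clade_members(tree: TreeNode, exemplar_ids: list[str]) -> set[str]:
    if len(exemplar_ids) == 1:
        return set(exemplar_ids)
    node = tree.lca(exemplar_ids)
    if node.is_tip():
        return {node.name}
    return {t.name for t in node.tips()}


def assign_types(
    msa: Msa,
    tree_newick: str,
    reference_id: str,
    ref_position: int,
    exemplars: dict[str, list[str]],
) -> list[CHIAssignment]:
    """Type every sequence by clade membership and the active-site residue rule.

    ``ref_position`` is 1-based in the ungapped coordinate system of
    ``reference_id``; ``exemplars`` anchors the three clades (smallest tree
    clade containing each exemplar set).
    """
    if reference_id not in msa.ids:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    colmap = msa.colmap(reference_id)
    if not 1 <= ref_position <= len(colmap):
        raise ValueError(
            f"ref_position {ref_position} outside reference length {len(colmap)}"
        )
    col = colmap[ref_position - 1]
    for g in _CLADES:
        if not exemplars.get(g):
            raise ValueError(f"no exemplars for {g}")
    missing = [
        e for g in _CLADES for e in exemplars[g] if e not in msa.ids
    ]
    if missing:
        raise ValueError(f"exemplars not in alignment: {missing}")
    tree = TreeNode.read(_io.StringIO(tree_newick))
    members = {g: _clade_members(tree, exemplars[g]) for g in _CLADES}
    conflicts = [
        sid
        for sid in msa.ids
        if sum(sid in members[g] for g in _CLADES) > 1
    ]
    if conflicts:
        raise ValueError(f"exemplar clades overlap (non-monophyletic): {conflicts}")

    out = []
    for sid, row in zip(msa.ids, msa.rows):
        residue = row[col]
        if sid in members["group1"]:
            out.append(CHIAssignment(sid, "III", residue, "group1", "group1 clade"))
        elif sid in members["group2"]:
            out.append(CHIAssignment(sid, "IV", residue, "group2", "group2 clade"))
        elif sid in members["group3"]:
            if residue == "-":
                t, why = "unclassified", "gap at active-site column"
            elif residue in _RESIDUE_TYPE:
                t = _RESIDUE_TYPE[residue]
                why = f"active-site residue {residue}"
            elif residue == "X":
                t, why = "unclassified", "ambiguous residue at active-site column"
            else:
                t, why = "V", f"non-S/T active-site residue {residue}"
            out.append(CHIAssignment(sid, t, residue, "group3", why))
        else:
            out.append(
                CHIAssignment(sid, "unclassified", residue, "none", "outside exemplar clades")
            )
    return out


# -------------------------------------------------------------- properties

# Average residue masses (Da); X contributes a nominal 110.0 and no charge.
_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
    "X": 110.0,
}
WATER_MASS = 18.0153

# Electrophoresis-calibrated pKa set (termini + ionizable side chains).
_PKA_POSITIVE = {"nterm": 9.094, "K": 9.052, "R": 11.84, "H": 5.637}
_PKA_NEGATIVE = {"cterm": 2.869, "D": 3.872, "E": 4.412, "C": 7.555, "Y": 10.85}


def net_charge(seq: str, ph: float) -> float:
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}
    pos = sum(
        n / (1.0 + 10.0 ** (ph - pka))
        for n, pka in [(1, _PKA_POSITIVE["nterm"])]
        + [(counts[aa], _PKA_POSITIVE[aa]) for aa in "KRH"]
    )
    neg = sum(
        n / (1.0 + 10.0 ** (pka - ph))
        for n, pka in [(1, _PKA_NEGATIVE["cterm"])]
        + [(counts[aa], _PKA_NEGATIVE[aa]) for aa in "DECY"]
    )
    return pos - neg


def compute_properties(record: SeqRecord) -> tuple[int, float, float]:
    """(length in aa, average molecular weight in Da, isoelectric point).

    The pI solves net_charge(pH) = 0 by bisection to |charge| < 1e-4 under the
    fixed pKa table above.
    """
    seq = record.seq.upper()
    if not seq:
        raise ValueError(f"{record.id}: empty sequence")
    try:
        mw = sum(_RESIDUE_MASS[ch] for ch in seq) + WATER_MASS
    except KeyError as e:
        raise ValueError(f"{record.id}: unknown residue {e}") from None
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid)
        if abs(q) < 1e-4:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return len(seq), mw, mid
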