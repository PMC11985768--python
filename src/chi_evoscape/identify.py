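"""Family identification by position-specific log-odds (PSSM) scanning.

A profile is built from a seed alignment of the CHI domain; each proteome
sequence is scored by its maximum ungapped window, and membership is a
bit-score threshold calibrated on a seeded decoy null (the desk-scale
replacement for a BLASTP + profile-HMM cascade with E-value cutoffs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AA20, SeqRecord

_AA_INDEX = {a: i for i, a in enumerate(AA20)}
N_AA = 20


@dataclass
class ProfileModel:
    """Per-column log-odds scores (bits) over the 20 amino acids.

    ``freqs`` holds the pseudocount-smoothed column frequencies the scores
    derive from (also used to sample synthetic domain instances).
    """

    scores: np.ndarray  # (width, 20) bits
    background: np.ndarray  # (20,) frequencies summing to 1
    pseudocount: float
    freqs: np.ndarray  # (width, 20) frequencies, rows sum to 1

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA20[i] for i in np.argmax(self.scores, axis=1))


@dataclass
class DomainHit:
    seq_id: str
    start: int  # 0-based offset of the best-scoring window
    score: float  # bits; -inf for sequences shorter than the profile
    passed: bool


def build_profile(
    seed_alignment: list[SeqRecord],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> ProfileModel:
    """Build a PSSM from an aligned FASTA seed.

    Columns with gap fraction > 0.5 are dropped before counting; scores are
    log2((count + pseudocount*bg) / (nongap + pseudocount) / bg).  X residues
    are treated as missing data.
    """
    if not seed_alignment:
        raise ValueError("empty seed alignment")
    if background is None:
        background = np.full(N_AA, 1.0 / N_AA)
    background = np.asarray(background, dtype=float)
    if background.shape != (N_AA,) or np.any(background <= 0):
        raise ValueError("background must be 20 strictly positive frequencies")
    background = background / background.sum()
    rows = [r.seq.upper() for r in seed_alignment]
    width_in = len(rows[0])
    if any(len(r) != width_in for r in rows):
        raise ValueError("seed alignment rows have unequal lengths")
    n_rows = len(rows)
    kept_freqs = []
    kept_scores = []
    for c in range(width_in):
        col = [r[c] for r in rows]
        gaps = sum(ch == "-" for ch in col)
        if gaps / n_rows > 0.5:
            continue
        counts = np.zeros(N_AA)
        for ch in col:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
        nongap = counts.sum()
        if nongap == 0:
            continue
        freqs = (counts + pseudocount * background) / (nongap + pseudocount)
        kept_freqs.append(freqs)
        kept_scores.append(np.log2(freqs / background))
    if not kept_freqs:
        raise ValueError("alignment fully gapped; no profile columns")
    if len(kept_freqs) < 10:
        raise ValueError(f"profile width {len(kept_freqs)} < 10")
    return ProfileModel(
        scores=np.asarray(kept_scores),
        background=background,
        pseudocount=pseudocount,
        freqs=np.asarray(kept_freqs),
    )


def _encode(seq: str) -> np.ndarray:
    """Amino-acid indices; X and unknowns map to a neutral 21st slot."""
    return np.fromiter(
        (_AA_INDEX.get(ch, N_AA) for ch in seq), dtype=np.intp, count=len(seq)
    )


def window_scores(seq: str, profile: ProfileModel) -> np.ndarray:
    """Scores of all ungapped windows of ``seq`` under the profile (bits)."""
    w = profile.width
    idx = _encode(seq)
    if len(idx) < w:
        return np.empty(0)
    padded = np.hstack([profile.scores, np.zeros((w, 1))])  # neutral X column
    n_win = len(idx) - w + 1
    total = np.zeros(n_win)
    for c in range(w):
        total += padded[c, idx[c : c + n_win]]
    return total


def scan_proteome(
    records: list[SeqRecord], profile: ProfileModel, threshold: float
) -> list[DomainHit]:
    """Best ungapped-window hit per sequence; pass iff score >= threshold (bits)."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    hits = []
    for rec in records:
        scores = window_scores(rec.seq, profile)
        if scores.size == 0:
            hits.append(DomainHit(rec.id, 0, -math.inf, False))
            continue
        best = int(np.argmax(scores))
        score = float(scores[best])
        hits.append(DomainHit(rec.id, best, score, score >= threshold))
    return hits


def calibrate_threshold(
    profile: ProfileModel,
    decoy_length: int = 300,
    n_decoys: int = 1000,
    quantile: float = 0.999,
    seed: int = 0,
) -> float:
    """Bit-score threshold at a quantile of the null of i.i.d. background decoys."""
    rng = np.random.default_rng(seed)
    null = np.empty(n_decoys)
    letters = np.array(list(AA20))
    for i in range(n_decoys):
        seq = "".join(rng.choice(letters, size=decoy_length, p=profile.background))
        null[i] = window_scores(seq, profile).max()
    return float(np.quantile(null, quantile))


def filter_family(hits: list[DomainHit], records: list[SeqRecord]) -> list[SeqRecord]:
    """Keep passing records, dropping exact duplicate sequences (content dedup).

    Mirrors redundancy removal by sequence content; order is stable.
    """
    passed = {h.seq_id for h in hits if h.passed}
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id not in passed or rec.seq in seen:
            continue
        seen.add(rec.seq)
        out.append(rec)
    return out
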