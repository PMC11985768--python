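"""Conserved-motif discovery and occurrence analysis.

Single-motif ZOOPS (zero-or-one occurrence per sequence) expectation-
maximization over a position weight matrix, with a 0-order background
estimated from the input; multiple motifs are discovered sequentially by
masking the occurrences of each found motif (up to 15 rounds).  Presence/
absence scanning and the shared/exclusive summary operationalize the
qualitative motif-distribution statements of the family analysis:
a motif is "characteristic" of a type when >= 90% of that type's members
carry it and "absent" when <= 10% do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AA20, SeqRecord

_AA_INDEX = {a: i for i, a in enumerate(AA20)}
N_AA = 20
MAX_MOTIFS = 15
MIN_WIDTH, MAX_WIDTH = 6, 50
_PSEUDO = 1e-3


@dataclass
class MotifModel:
    """PWM over the 20 amino acids with a ZOOPS occurrence prior ``lam``."""

    motif_id: str
    pwm: np.ndarray  # (width, 20), rows sum to 1
    lam: float
    background: np.ndarray  # (20,)
    loglik: float = float("-inf")
    #: EM objective per iteration: data log-likelihood plus the Dirichlet
    #: smoothing term (guaranteed non-decreasing; asserted every iteration).
    loglik_history: list[float] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA20[i] for i in np.argmax(self.pwm, axis=1))


@dataclass
class PresenceMatrix:
    ids: list[str]
    motif_ids: list[str]
    values: np.ndarray  # (n_seqs, n_motifs) bool

    def __post_init__(self) -> None:
        if len(self.motif_ids) > MAX_MOTIFS:
            raise ValueError(f"at most {MAX_MOTIFS} motifs")


def _encode(seq: str) -> np.ndarray:
    """Indices with X/unknown mapped to a neutral 21st slot."""
    return np.fromiter(
        (_AA_INDEX.get(ch, N_AA) for ch in seq), dtype=np.intp, count=len(seq)
    )


def estimate_background(records: list[SeqRecord]) -> np.ndarray:
    counts = np.full(N_AA, _PSEUDO)
    for rec in records:
        for ch in rec.seq:
            i = _AA_INDEX.get(ch)
            if i is not None:
                counts[i] += 1.0
    return counts / counts.sum()


def _window_log_ratios(idx: np.ndarray, log_ratio: np.ndarray, w: int) -> np.ndarray:
    """log(PWM/background) of every window; X positions contribute 0."""
    padded = np.vstack([log_ratio.T, np.zeros(w)]).T  # (w, 21)
    n_win = len(idx) - w + 1
    out = np.zeros(n_win)
    for c in range(w):
        out += padded[c, idx[c : c + n_win]]
    return out


def zoops_loglik_and_posteriors(
    encoded: list[np.ndarray], pwm: np.ndarray, lam: float, background: np.ndarray
) -> tuple[float, list[np.ndarray], np.ndarray]:
    """Relative log-likelihood and per-sequence offset posteriors.

    The common background factor of each sequence is dropped (it cancels in
    EM); returns (loglik, [posterior over offsets], P(present) per sequence).
    """
    w = pwm.shape[0]
    log_ratio = np.log(pwm) - np.log(background)
    ll = 0.0
    posteriors = []
    p_present = np.empty(len(encoded))
    for s, idx in enumerate(encoded):
        lr = _window_log_ratios(idx, log_ratio, w)
        m = len(lr)
        # joint (unnormalized): absent -> (1-lam); offset j -> (lam/m) exp(lr_j)
        log_terms = np.concatenate(([math.log(max(1.0 - lam, 1e-300))],
                                    math.log(max(lam, 1e-300) / m) + lr))
        top = log_terms.max()
        probs = np.exp(log_terms - top)
        z = probs.sum()
        ll += top + math.log(z)
        post = probs / z
        posteriors.append(post[1:])
        p_present[s] = post[1:].sum()
    return ll, posteriors, p_present


def discover_motif_zoops(
    records: list[SeqRecord],
    width: int,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    motif_id: str = "motif_1",
) -> MotifModel:
    """Fit a single ZOOPS motif by EM; best of ``n_restarts`` by log-likelihood.

    The log-likelihood is asserted non-decreasing at every iteration (up to a
    1e-8 numerical slack from the tiny Dirichlet pseudocounts).
    """
    if not MIN_WIDTH <= width <= MAX_WIDTH:
        raise ValueError(f"width must be in [{MIN_WIDTH}, {MAX_WIDTH}]")
    if len(records) < 5:
        raise ValueError("need at least 5 sequences")
    short = [r.id for r in records if len(r.seq) < width]
    if short:
        raise ValueError(f"sequences shorter than width: {short}")
    rng = np.random.default_rng(seed)
    background = estimate_background(records)
    encoded = [_encode(r.seq) for r in records]

    def run_em(
        pwm: np.ndarray, lam: float, n_iter: int
    ) -> tuple[np.ndarray, float, float, float, list[float]]:
        prev_obj = -math.inf
        ll = -math.inf
        history: list[float] = []
        for _ in range(n_iter):
            ll, posteriors, p_present = zoops_loglik_and_posteriors(
                encoded, pwm, lam, background
            )
            # Dirichlet-smoothed EM objective: non-decreasing by construction
            obj = ll + _PSEUDO * float(np.sum(np.log(pwm)))
            if obj < prev_obj - 1e-9:
                raise AssertionError(f"EM objective decreased: {prev_obj} -> {obj}")
            history.append(obj)
            gained = obj - prev_obj
            prev_obj = obj
            # M-step (exact for the smoothed objective)
            counts = np.full((width, N_AA), _PSEUDO)
            for idx, post in zip(encoded, posteriors):
                for c in range(width):
                    sub = idx[c : c + len(post)]
                    np.add.at(counts[c], sub[sub < N_AA], post[sub < N_AA])
            pwm = counts / counts.sum(axis=1, keepdims=True)
            lam = float(p_present.mean())
            if gained < tol:
                break
        return pwm, lam, prev_obj, ll, history

    def seed_pwm(idx: np.ndarray, j: int) -> np.ndarray:
        pwm = np.tile(background, (width, 1)) * 0.3
        for c, aa in enumerate(idx[j : j + width]):
            if aa < N_AA:
                pwm[c, aa] += 0.7
            else:
                pwm[c] += 0.7 * background
        return pwm / pwm.sum(axis=1, keepdims=True)

    # substring seeding: probe every window of n_restarts sequences with a
    # short EM, then polish the best probe to convergence
    n_seed_seqs = min(max(n_restarts, 1), len(records))
    seed_seqs = rng.choice(len(records), size=n_seed_seqs, replace=False)
    best_probe = None
    for s in seed_seqs:
        idx = encoded[s]
        for j in range(len(idx) - width + 1):
            pwm, lam, obj, _ll, _h = run_em(seed_pwm(idx, j), 0.5, 2)
            if best_probe is None or obj > best_probe[2]:
                best_probe = (pwm, lam, obj)
    pwm, lam, _obj, ll, history = run_em(best_probe[0], best_probe[1], max_iter)
    return MotifModel(motif_id, pwm, lam, background, ll, history)


def motif_offsets(records: list[SeqRecord], motif: MotifModel) -> dict[str, int | None]:
    """Posterior-mode occurrence offset per sequence (None when absent wins)."""
    encoded = [_encode(r.seq) for r in records]
    _, posteriors, p_present = zoops_loglik_and_posteriors(
        encoded, motif.pwm, motif.lam, motif.background
    )
    out: dict[str, int | None] = {}
    for rec, post, pp in zip(records, posteriors, p_present):
        out[rec.id] = int(np.argmax(post)) if pp > 0.5 else None
    return out


def discover_motifs(
    records: list[SeqRecord],
    width: int,
    n_motifs: int = MAX_MOTIFS,
    n_restarts: int = 5,
    seed: int = 0,
    min_lambda: float = 0.2,
) -> list[MotifModel]:
    """Sequential discovery with masking of found occurrences (up to 15 rounds)."""
    n_motifs = min(n_motifs, MAX_MOTIFS)
    working = [SeqRecord(r.id, r.seq, r.species, r.description) for r in records]
    motifs: list[MotifModel] = []
    for round_ in range(n_motifs):
        motif = discover_motif_zoops(
            working,
            width,
            n_restarts=n_restarts,
            seed=seed + round_,
            motif_id=f"motif_{round_ + 1}",
        )
        if motif.lam < min_lambda:
            break
        motifs.append(motif)
        offsets = motif_offsets(working, motif)
        for rec in working:
            off = offsets[rec.id]
            if off is not None:
                rec.seq = rec.seq[:off] + "X" * motif.width + rec.seq[off + motif.width :]
    return motifs


def best_window_score(seq: str, motif: MotifModel) -> float:
    """Best log2-odds window score of ``seq`` under the motif (bits)."""
    idx = _encode(seq)
    if len(idx) < motif.width:
        return -math.inf
    log_ratio = (np.log(motif.pwm) - np.log(motif.background)) / math.log(2.0)
    return float(_window_log_ratios(idx, log_ratio, motif.width).max())


def scan_motifs(
    records: list[SeqRecord], motifs: list[MotifModel], score_min: float = 8.0
) -> PresenceMatrix:
    """Presence/absence: best-window log-odds >= ``score_min`` bits."""
    if not motifs:
        raise ValueError("no motifs to scan")
    values = np.zeros((len(records), len(motifs)), dtype=bool)
    for i, rec in enumerate(records):
        for j, motif in enumerate(motifs):
            values[i, j] = best_window_score(rec.seq, motif) >= score_min
    return PresenceMatrix([r.id for r in records], [m.motif_id for m in motifs], values)


def summarize_motif_sharing(
    matrix: PresenceMatrix,
    types: dict[str, str],
    characteristic_min: float = 0.9,
    absent_max: float = 0.1,
) -> dict[str, dict]:
    """Per-motif characteristic/absent types and shared/exclusive status."""
    untyped = [sid for sid in matrix.ids if sid not in types]
    if untyped:
        raise ValueError(f"untyped sequences: {untyped}")
    all_types = sorted(set(types[sid] for sid in matrix.ids))
    report: dict[str, dict] = {}
    for j, mid in enumerate(matrix.motif_ids):
        fractions = {}
        for t in all_types:
            members = [i for i, sid in enumerate(matrix.ids) if types[sid] == t]
            fractions[t] = float(matrix.values[members, j].mean()) if members else 0.0
        characteristic = [t for t in all_types if fractions[t] >= characteristic_min]
        absent = [t for t in all_types if fractions[t] <= absent_max]
        if len(characteristic) == len(all_types):
            status = "shared"
        elif len(characteristic) == 1:
            status = f"exclusive:{characteristic[0]}"
        else:
            status = "other"
        report[mid] = {
            "fractions": fractions,
            "characteristic": characteristic,
            "absent": absent,
            "status": status,
        }
    return report


def write_meme_minimal(motifs: list[MotifModel], path) -> None:
    """MEME minimal text format (letter-probability matrix blocks)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA20 + "\n\n")
        if motifs:
            fh.write("Background letter frequencies\n")
            fh.write(
                " ".join(f"{a} {f:.5f}" for a, f in zip(AA20, motifs[0].background))
                + "\n\n"
            )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= {N_AA} w= {m.width} "
                f"nsites= 0 E= 0\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme_minimal(path) -> list[MotifModel]:
    motifs: list[MotifModel] = []
    background = np.full(N_AA, 1.0 / N_AA)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[k]) for k in range(1, len(parts), 2)])
            i += 2
        elif ln.startswith("MOTIF"):
            mid = ln.split()[1]
            header = lines[i + 1]
            w = int(header.split("w=")[1].split()[0])
            pwm = np.array(
                [[float(v) for v in lines[i + 2 + r].split()] for r in range(w)]
            )
            motifs.append(MotifModel(mid, pwm, 0.5, background))
            i += 2 + w
        else:
            i += 1
    return motifs
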