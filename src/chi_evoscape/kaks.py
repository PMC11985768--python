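"""Nei-Gojobori (1986) Ka/Ks estimation for duplicate gene pairs.

The counting method with fractional synonymous-site counting, exhaustive
mutational-pathway averaging for multi-hit codons, and Jukes-Cantor multiple-
hit correction.  Conventions (variants of NG86 differ here, so they are fixed
explicitly):

* single-nucleotide changes that create a stop codon are excluded from the
  site denominators;
* mutational pathways that pass through a stop codon are discarded; a codon
  pair whose every pathway crosses a stop is flagged and excluded from the
  comparison entirely;
* the standard genetic code only.

Selection regime: ratio > 1 positive, < 1 purifying, exactly 1 neutral-ish;
undefined when Ks = 0 or a correction saturates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log

from Bio.Data.CodonTable import standard_dna_table

from .io_formats import SeqRecord

_NT = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_FORWARD = dict(standard_dna_table.forward_table)


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return _FORWARD[codon]
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}") from None


def _codon_syn_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of synonymous changes among non-stop single-nt changes."""
    aa = translate_codon(codon)
    fracs = []
    for pos in range(3):
        syn = nonstop = 0
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            nonstop += 1
            if translate_codon(alt) == aa:
                syn += 1
        fracs.append(syn / nonstop if nonstop else 0.0)
    return tuple(fracs)


_SYN_FRACTIONS: dict[str, tuple[float, float, float]] = {}


def _syn_fractions(codon: str) -> tuple[float, float, float]:
    try:
        return _SYN_FRACTIONS[codon]
    except KeyError:
        f = _codon_syn_fractions(codon)
        _SYN_FRACTIONS[codon] = f
        return f


class StopCodonError(ValueError):
    """An internal stop codon in a coding sequence."""


class StopPathwayError(ValueError):
    """All mutational pathways between two codons pass through a stop codon."""


def _check_codons(seq: str, name: str = "sequence") -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise StopCodonError(f"{name}: internal stop codon at codon {i}")
    return codons


def ng86_sites(seq: str) -> tuple[float, float]:
    """Nonsynonymous (N) and synonymous (S) site counts of a coding sequence.

    Each codon position contributes the fraction of its non-stop
    single-nucleotide changes that are synonymous; N + S = 3 x codons.
    """
    codons = _check_codons(seq)
    s = 0.0
    for c in codons:
        s += sum(_syn_fractions(c))
    n = 3.0 * len(codons) - s
    return n, s


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Nonsynonymous (Nd) and synonymous (Sd) differences between two codons.

    For k mismatched positions, averages over the valid mutational pathways
    (orderings of the k single-nucleotide steps); pathways crossing a stop
    codon are discarded.
    """
    if len(codon_a) != 3 or len(codon_b) != 3:
        raise ValueError("codons must have length 3")
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise StopCodonError("stop codon in comparison")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    nd_total = sd_total = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        cur = codon_a
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(nxt) == translate_codon(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            nd_total += nd
            sd_total += sd
            n_valid += 1
    if n_valid == 0:
        raise StopPathwayError(f"all pathways {codon_a}->{codon_b} pass through a stop")
    return nd_total / n_valid, sd_total / n_valid


@dataclass
class KaKsResult:
    pair_id: str
    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pn: float
    ps: float
    ka: float | None
    ks: float | None
    ratio: float | None
    regime: str  # purifying | positive | neutral-ish | undefined
    note: str = ""
    n_flagged_codons: int = 0


def _jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when the correction saturates (argument <= 0)."""
    if p == 0.0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * log(arg)


def kaks_pair(cds_a: SeqRecord, cds_b: SeqRecord, pair_id: str | None = None) -> KaKsResult:
    """NG86 Ka, Ks and Ka/Ks for one codon-aligned pair of coding sequences.

    Codon columns containing a gap in either sequence are dropped pairwise;
    codon pairs whose every mutational pathway crosses a stop are flagged and
    excluded from both the site and difference totals.
    """
    if pair_id is None:
        pair_id = f"{cds_a.id}|{cds_b.id}"
    a, b = cds_a.seq.upper(), cds_b.seq.upper()
    if len(a) != len(b):
        raise ValueError(f"{pair_id}: sequence length mismatch ({len(a)} vs {len(b)})")
    if len(a) % 3 != 0:
        raise ValueError(f"{pair_id}: aligned length {len(a)} not divisible by 3")
    codons_a, codons_b = [], []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue  # gapped codon column dropped in whole codons
        codons_a.append(ca)
        codons_b.append(cb)

    kept_a, kept_b = [], []
    nd = sd = 0.0
    flagged = 0
    for ca, cb in zip(codons_a, codons_b):
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise StopCodonError(f"{pair_id}: internal stop codon")
        try:
            d_n, d_s = ng86_differences(ca, cb)
        except StopPathwayError:
            flagged += 1
            continue
        nd += d_n
        sd += d_s
        kept_a.append(ca)
        kept_b.append(cb)

    n_codons = len(kept_a)
    if n_codons == 0:
        raise ValueError(f"{pair_id}: no comparable codons")
    # Sites averaged over the two sequences, per NG86.
    na, sa = ng86_sites("".join(kept_a))
    nb, sb = ng86_sites("".join(kept_b))
    n_sites, s_sites = (na + nb) / 2.0, (sa + sb) / 2.0

    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    ka = _jukes_cantor(pn)
    ks = _jukes_cantor(ps)

    note = ""
    if ka is None or ks is None:
        ratio, regime, note = None, "undefined", "Jukes-Cantor correction saturated"
    elif ks == 0.0:
        ratio, regime, note = None, "undefined", "ks = 0"
    else:
        ratio = ka / ks
        regime = "positive" if ratio > 1 else ("purifying" if ratio < 1 else "neutral-ish")
    return KaKsResult(
        pair_id=pair_id,
        n_codons=n_codons,
        N=n_sites,
        S=s_sites,
        Nd=nd,
        Sd=sd,
        pn=pn,
        ps=ps,
        ka=ka,
        ks=ks,
        ratio=ratio,
        regime=regime,
        note=note,
        n_flagged_codons=flagged,
    )


def thread_protein_alignment(cds: str, aligned_protein: str) -> str:
    """Back-thread a gapped protein row onto its ungapped CDS (codon-aligned CDS)."""
    out = []
    pos = 0
    for ch in aligned_protein:
        if ch == "-":
            out.append("---")
        else:
            out.append(cds[pos : pos + 3])
            pos += 3
    if pos != len(cds):
        raise ValueError("protein alignment does not match CDS length")
    return "".join(out)
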