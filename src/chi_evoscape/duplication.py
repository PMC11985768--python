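"""Gene duplication-mode classification and per-mode enrichment testing.

Re-implements, at desk scale, the documented decision rules of the
DupGen_finder-style classifier: every paralogous pair is assigned the highest-
priority mode among WGD > TD > PD > TRD > DSD, where

* WGD  - the pair is an anchor of a self-collinearity block;
* TD   - same chromosome, adjacent gene order ranks (|gap| = 1);
* PD   - same chromosome, 2 <= |gap| <= ``proximal_max_rank_gap``;
* TRD  - exactly one member sits in an outgroup-collinear block
         (a transposed copy at a novel locus);
* DSD  - any remaining paralogous pair.

Collinearity detection itself is not re-implemented: anchors are inputs.
Enrichment of each mode in a gene family against the genome background uses a
2x2 chi-square with Yates continuity correction, family genes removed from
the background cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import chi2_contingency

from .io_formats import GeneModel

MODES = ("WGD", "TD", "PD", "TRD", "DSD")
_PRIORITY = {m: i for i, m in enumerate(MODES)}


@dataclass
class DuplicationCall:
    gene_id: str
    mode: str  # WGD | TD | PD | TRD | DSD | singleton
    partner: str | None = None


@dataclass
class EnrichmentResult:
    species: str
    mode: str
    a: int  # family genes in mode
    b: int  # family genes not in mode
    c: int  # background genes in mode
    d: int  # background genes not in mode
    chi2: float
    p: float
    direction: str  # enriched | reduced | ns
    low_expected: bool = False


def classify_pair_mode(
    g1: GeneModel,
    g2: GeneModel,
    self_anchor_pairs: set[frozenset[str]],
    outgroup_genes: set[str],
    proximal_max_rank_gap: int = 10,
) -> str:
    """Mode of a single paralogous pair under the priority rule table."""
    if frozenset((g1.gene_id, g2.gene_id)) in self_anchor_pairs:
        return "WGD"
    if g1.chrom == g2.chrom:
        gap = abs(g1.order_rank - g2.order_rank)
        if gap == 1:
            return "TD"
        if 2 <= gap <= proximal_max_rank_gap:
            return "PD"
    in_out = (g1.gene_id in outgroup_genes) + (g2.gene_id in outgroup_genes)
    if in_out == 1:
        return "TRD"
    return "DSD"


def classify_duplications(
    family_ids: set[str],
    genes: list[GeneModel],
    paralog_pairs: list[tuple[str, str]],
    self_anchors: list[tuple[str, str]],
    outgroup_anchors: list[tuple[str, str]],
    proximal_max_rank_gap: int = 10,
) -> list[DuplicationCall]:
    """Assign every gene its highest-priority duplication mode.

    Returns one call per gene in ``genes`` (input order): genes without any
    paralogous pair are singletons.  ``family_ids`` is validated against the
    gene table but does not influence the mode of an individual gene; it is
    consumed downstream by the enrichment test.
    """
    by_id = {g.gene_id: g for g in genes}
    unknown = [gid for pair in paralog_pairs for gid in pair if gid not in by_id]
    if unknown:
        raise ValueError(f"paralog pairs reference unknown genes: {sorted(set(unknown))}")
    missing_family = family_ids - set(by_id)
    if missing_family:
        raise ValueError(f"family ids not in gene table: {sorted(missing_family)}")
    anchor_set = {frozenset(p) for p in self_anchors}
    outgroup_genes = {a for a, _b in outgroup_anchors}

    # best (priority, partner) per gene over its pairs; ties by smaller partner id
    best: dict[str, tuple[int, str]] = {}
    for a, b in sorted(set(map(tuple, map(sorted, paralog_pairs)))):
        if a == b:
            continue
        mode = classify_pair_mode(
            by_id[a], by_id[b], anchor_set, outgroup_genes, proximal_max_rank_gap
        )
        pr = _PRIORITY[mode]
        for gid, partner in ((a, b), (b, a)):
            cur = best.get(gid)
            if cur is None or (pr, partner) < cur:
                best[gid] = (pr, partner)
    calls = []
    for g in genes:
        if g.gene_id in best:
            pr, partner = best[g.gene_id]
            calls.append(DuplicationCall(g.gene_id, MODES[pr], partner))
        else:
            calls.append(DuplicationCall(g.gene_id, "singleton"))
    return calls


def yates_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """2x2 chi-square with continuity correction (scipy's chi2_contingency)."""
    stat, p, _dof, _exp = chi2_contingency([[a, b], [c, d]], correction=True)
    return float(stat), float(p)


def test_mode_enrichment(
    family_calls: list[DuplicationCall],
    genome_calls: list[DuplicationCall],
    alpha: float = 0.05,
    species: str = "",
) -> list[EnrichmentResult]:
    """Per-mode 2x2 enrichment of the family against the genome background.

    Background cells exclude family genes.  A table with any expected cell
    count below 1 is flagged low-expected and its direction forced to ``ns``.
    """
    family_ids = {c.gene_id for c in family_calls}
    background = [c for c in genome_calls if c.gene_id not in family_ids]
    n_fam, n_bg = len(family_calls), len(background)
    results = []
    for mode in MODES:
        a = sum(1 for c in family_calls if c.mode == mode)
        b = n_fam - a
        c_ = sum(1 for c in background if c.mode == mode)
        d = n_bg - c_
        n = a + b + c_ + d
        row1, row2, col1, col2 = a + b, c_ + d, a + c_, b + d
        low = any(
            r * c / n < 1.0 for r in (row1, row2) for c in (col1, col2)
        ) if n > 0 else True
        if n == 0 or row1 == 0 or row2 == 0 or col1 == 0 or col2 == 0:
            chi2, p = 0.0, 1.0
            low = True
        else:
            chi2, p = yates_chi2(a, b, c_, d)
        if low:
            warnings.warn(
                f"{species or 'genome'}/{mode}: expected cell count < 1, direction forced ns",
                stacklevel=2,
            )
            direction = "ns"
        elif p < alpha:
            direction = "enriched" if a / row1 > c_ / row2 else "reduced"
        else:
            direction = "ns"
        results.append(
            EnrichmentResult(species, mode, a, b, c_, d, chi2, p, direction, low)
        )
    return results
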