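"""Seeded generators for every input class the pipeline consumes.

These stand in for the study's real genomes at desk scale: proteomes with
implanted CHI-domain instances among decoys (typed by a forced active-site
residue and clade-marker blocks), codon pairs evolved at a controlled dN/dS
by acceptance thinning, gene tables with planted tandem/proximal/WGD/
transposed/dispersed duplicates plus their collinearity anchors, and toy
CA-trace structures sharing a central 3-layer sandwich core with
group-specific N-terminal segments.  Every generator is deterministic under a
fixed seed and records machine-readable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import exp
from pathlib import Path

import numpy as np

from . import kaks as _kaks
from .identify import ProfileModel, build_profile
from .io_formats import AA20, GeneModel, SeqRecord, Structure

# ---------------------------------------------------------------- truth


@dataclass
class TruthBundle:
    """Ground truth for planted entities, keyed by generated ids."""

    implanted_family_ids: set[str] = field(default_factory=set)
    type_labels: dict[str, str] = field(default_factory=dict)
    dup_mode_labels: dict[str, str] = field(default_factory=dict)
    omega_true: dict[str, float] = field(default_factory=dict)
    motif_positions: dict[str, int] = field(default_factory=dict)
    struct_group_labels: dict[str, int] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "implanted_family_ids": sorted(self.implanted_family_ids),
            "type_labels": self.type_labels,
            "dup_mode_labels": self.dup_mode_labels,
            "omega_true": self.omega_true,
            "motif_positions": self.motif_positions,
            "struct_group_labels": self.struct_group_labels,
            "extra": self.extra,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthBundle":
        d = json.loads(Path(path).read_text())
        return cls(
            implanted_family_ids=set(d["implanted_family_ids"]),
            type_labels=d["type_labels"],
            dup_mode_labels=d["dup_mode_labels"],
            omega_true=d["omega_true"],
            motif_positions=d["motif_positions"],
            struct_group_labels=d["struct_group_labels"],
            extra=d["extra"],
        )


# ------------------------------------------------------- proteome / typing

DOMAIN_WIDTH = 60
ACTIVE_SITE_OFFSET = 29  # 0-based column of the active site within the domain
_CLADE_BLOCK_LEN = 40
_LETTERS = np.array(list(AA20))

# Type composition of the published family census (fractions of 1,738 members).
DEFAULT_TYPE_MIX = {"III": 0.585, "I": 0.200, "IV": 0.162, "II": 0.032, "V": 0.021}
_GROUP_OF_TYPE = {"I": "group3", "II": "group3", "V": "group3", "III": "group1", "IV": "group2"}


def make_seed_alignment(
    width: int = DOMAIN_WIDTH, n_seqs: int = 12, conservation: float = 0.85, seed: int = 0
) -> list[SeqRecord]:
    """A synthetic gap-free seed alignment for the family domain."""
    rng = np.random.default_rng(seed)
    consensus = rng.choice(_LETTERS, size=width)
    records = []
    for i in range(n_seqs):
        row = consensus.copy()
        mutate = rng.random(width) > conservation
        row[mutate] = rng.choice(_LETTERS, size=int(mutate.sum()))
        records.append(SeqRecord(id=f"seed{i:03d}", seq="".join(row)))
    return records


def default_profile(seed: int = 0) -> ProfileModel:
    return build_profile(make_seed_alignment(seed=seed))


def _sample_from_profile(profile: ProfileModel, rng: np.random.Generator) -> list[str]:
    return [
        str(rng.choice(_LETTERS, p=profile.freqs[c] / profile.freqs[c].sum()))
        for c in range(profile.width)
    ]


def _largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    keys = sorted(fractions)
    raw = {k: fractions[k] * n for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (counts[k] > 0, raw[k] - counts[k]), reverse=True)[:short]:
        counts[k] += 1
    return counts


def make_chi_proteome(
    n_family: int,
    n_decoy: int,
    profile: ProfileModel | None = None,
    type_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[SeqRecord], TruthBundle]:
    """A proteome of implanted family members among i.i.d. background decoys.

    Family sequences are profile samples in random flanks with the active-site
    residue forced (T for type II, S for type I, any other residue for type V)
    and a same-length clade-marker block appended after the domain (one block
    per clade, so the three clades are tree-separable).  Truth records the
    planted type labels, the typing reference and per-clade exemplars.
    """
    if n_family < 0 or n_decoy < 0:
        raise ValueError("counts must be nonnegative")
    if profile is None:
        profile = default_profile()
    if type_mix is None:
        type_mix = dict(DEFAULT_TYPE_MIX)
    bad = set(type_mix) - set(_GROUP_OF_TYPE)
    if bad:
        raise ValueError(f"unknown CHI types in mix: {sorted(bad)}")
    if n_family > 0 and abs(sum(type_mix.values()) - 1.0) > 1e-6:
        raise ValueError("type fractions must sum to 1")
    if profile.width <= ACTIVE_SITE_OFFSET:
        raise ValueError("profile shorter than the active-site offset")
    rng = np.random.default_rng(seed)
    # Clade-marker blocks share a base pattern (so they align column-wise and
    # survive gap trimming) and differ by clade-specific substitutions at the
    # even positions (the phylogenetic signal separating the three clades).
    base_block = rng.choice(_LETTERS, size=_CLADE_BLOCK_LEN)
    blocks = {}
    for g in ("group1", "group2", "group3"):
        block = base_block.copy()
        block[::2] = rng.choice(_LETTERS, size=len(block[::2]))
        blocks[g] = block
    non_st = np.array([a for a in AA20 if a not in "ST"])

    counts = _largest_remainder(type_mix, n_family) if n_family else {}
    plan = [t for t in sorted(counts) for _ in range(counts[t])]
    rng.shuffle(plan)

    truth = TruthBundle()
    records: list[SeqRecord] = []
    ref_id, ref_pos = None, None
    exemplars: dict[str, list[str]] = {"group1": [], "group2": [], "group3": []}
    for i, chi_type in enumerate(plan):
        domain = _sample_from_profile(profile, rng)
        if chi_type == "II":
            domain[ACTIVE_SITE_OFFSET] = "T"
        elif chi_type == "I":
            domain[ACTIVE_SITE_OFFSET] = "S"
        elif chi_type == "V":
            domain[ACTIVE_SITE_OFFSET] = str(rng.choice(non_st))
        group = _GROUP_OF_TYPE[chi_type]
        block = blocks[group].copy()
        mutate = rng.random(_CLADE_BLOCK_LEN) < 0.02
        block[mutate] = rng.choice(_LETTERS, size=int(mutate.sum()))
        n_flank = int(rng.integers(5, 21))
        c_flank = int(rng.integers(5, 16))
        seq = (
            "".join(rng.choice(_LETTERS, size=n_flank))
            + "".join(domain)
            + "".join(block)
            + "".join(rng.choice(_LETTERS, size=c_flank))
        )
        sid = f"fam{i:04d}"
        records.append(SeqRecord(id=sid, seq=seq, species="synthetica"))
        truth.implanted_family_ids.add(sid)
        truth.type_labels[sid] = chi_type
        if group == "group3" and ref_id is None:
            ref_id = sid
            ref_pos = n_flank + ACTIVE_SITE_OFFSET + 1  # 1-based ungapped
        # every planted member anchors its clade, so the smallest clade
        # containing the exemplars spans the whole planted group
        exemplars[group].append(sid)
    for j in range(n_decoy):
        length = int(rng.integers(100, 161))
        records.append(
            SeqRecord(id=f"dec{j:04d}", seq="".join(rng.choice(_LETTERS, size=length)))
        )
    truth.extra.update(
        {
            "reference_id": ref_id,
            "ref_position": ref_pos,
            "exemplars": exemplars,
            "active_site_offset": ACTIVE_SITE_OFFSET,
        }
    )
    return records, truth


def make_motif_set(
    motif: str = "DEADEL",
    n_seqs: int = 20,
    length: int = 50,
    seed: int = 0,
) -> tuple[list[SeqRecord], TruthBundle]:
    """Uniform-background sequences with one motif instance planted per sequence."""
    if len(motif) > length:
        raise ValueError("motif longer than sequence length")
    rng = np.random.default_rng(seed)
    truth = TruthBundle()
    records = []
    for i in range(n_seqs):
        seq = list(rng.choice(_LETTERS, size=length))
        off = int(rng.integers(0, length - len(motif) + 1))
        seq[off : off + len(motif)] = list(motif)
        sid = f"m{i:03d}"
        records.append(SeqRecord(id=sid, seq="".join(seq)))
        truth.motif_positions[sid] = off
    return records, truth


# -------------------------------------------------------------- codon pairs

_SENSE_CODONS = sorted(set("".join(c) for c in
                           (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT"))
                       - _kaks.STOP_CODONS)
_NT = "ACGT"


def make_codon_pair_set(
    omega: float,
    t_s: float = 0.3,
    n_pairs: int = 100,
    n_codons: int = 300,
    seed: int = 0,
) -> tuple[list[SeqRecord], TruthBundle]:
    """Codon-aligned CDS pairs diverged at a controlled dN/dS by thinning.

    Each pair starts from a random stop-free codon sequence; candidate
    single-nucleotide changes arrive as Poisson events and are accepted with
    probability 1 if synonymous and ``omega`` if nonsynonymous (for
    ``omega`` > 1 the synonymous acceptance is scaled down by 1/omega
    instead); changes creating stops are rejected.  ``t_s`` is the expected
    number of accepted synonymous substitutions per synonymous site.  Truth
    records the realized substitution counts, which is exactly what the NG86
    estimator counts.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if n_codons < 30:
        raise ValueError("n_codons must be >= 30")
    if t_s < 0:
        raise ValueError("t_s must be >= 0")
    exp_ps = 0.75 * (1.0 - exp(-4.0 * t_s / 3.0))
    if exp_ps >= 0.74:
        raise ValueError(
            f"expected ps ~ {exp_ps:.2f} >= 0.74: JC correction would saturate; "
            "reduce t_s below ~3.2"
        )
    rng = np.random.default_rng(seed)
    acc_syn = 1.0 if omega <= 1.0 else 1.0 / omega
    acc_non = min(omega, 1.0)
    truth = TruthBundle()
    records: list[SeqRecord] = []
    codon_arr = np.array(_SENSE_CODONS)
    for p in range(n_pairs):
        anc = "".join(rng.choice(codon_arr, size=n_codons))
        L = 3 * n_codons
        _, s_sites = _kaks.ng86_sites(anc)
        # candidate census on the ancestor (first-order rate calibration)
        n_syn_cand = 0
        for i in range(0, L, 3):
            cod = anc[i : i + 3]
            aa = _kaks.translate_codon(cod)
            for pos in range(3):
                for nt in _NT:
                    if nt == cod[pos]:
                        continue
                    alt = cod[:pos] + nt + cod[pos + 1 :]
                    if alt not in _kaks.STOP_CODONS and _kaks.translate_codon(alt) == aa:
                        n_syn_cand += 1
        p_syn_cand = n_syn_cand / (9 * n_codons)
        lam = t_s * s_sites / (p_syn_cand * acc_syn) if p_syn_cand > 0 else 0.0
        n_events = int(rng.poisson(lam)) if lam > 0 else 0
        seq = list(anc)
        nd_real = sd_real = 0
        for _ in range(n_events):
            site = int(rng.integers(L))
            cur = seq[site]
            alt_nt = str(rng.choice([n for n in _NT if n != cur]))
            ci = site - site % 3
            cod = "".join(seq[ci : ci + 3])
            alt = cod[: site % 3] + alt_nt + cod[site % 3 + 1 :]
            if alt in _kaks.STOP_CODONS:
                continue
            syn = _kaks.translate_codon(alt) == _kaks.translate_codon(cod)
            accept_p = acc_syn if syn else acc_non
            if rng.random() < accept_p:
                seq[site] = alt_nt
                if syn:
                    sd_real += 1
                else:
                    nd_real += 1
        pid = f"pair{p:04d}"
        records.append(SeqRecord(id=f"{pid}_a", seq=anc))
        records.append(SeqRecord(id=f"{pid}_b", seq="".join(seq)))
        truth.omega_true[pid] = omega
        truth.extra.setdefault("realized", {})[pid] = {"nd": nd_real, "sd": sd_real}
    truth.extra["t_s"] = t_s
    return records, truth


# --------------------------------------------------------- duplicated genome

_DUP_MODES = ("WGD", "TD", "PD", "TRD", "DSD")


def _mutate_protein(base: str, rng: np.random.Generator, rate: float = 0.05) -> str:
    arr = np.array(list(base))
    mutate = rng.random(len(arr)) < rate
    arr[mutate] = rng.choice(_LETTERS, size=int(mutate.sum()))
    return "".join(arr)


def make_duplicated_genome(
    n_background: int,
    mode_counts: dict[str, int],
    proximal_max_rank_gap: int = 10,
    background_mode_counts: dict[str, int] | None = None,
    n_chroms: int = 4,
    seed: int = 0,
) -> tuple[list[GeneModel], list[tuple[str, str]], list[tuple[str, str]], list[SeqRecord], TruthBundle]:
    """A gene table with planted duplicate pairs of each mode, plus anchors.

    Planting uses disjoint chromosome segments so constructs cannot disturb
    each other: TD pairs are adjacent, PD pairs sit 2..``proximal_max_rank_gap``
    ranks apart, WGD pairs are embedded in >= 5-anchor self-collinearity
    blocks spanning two chromosomes, TRD pairs have exactly one member in an
    outgroup-collinear block, DSD pairs sit on different chromosomes with no
    anchors.  ``background_mode_counts`` plants additional non-family pairs
    (for enrichment backgrounds).  Returns (genes, self_anchors,
    outgroup_anchors, protein records, truth).
    """
    mode_counts = {m: int(mode_counts.get(m, 0)) for m in _DUP_MODES}
    bg_counts = {m: int((background_mode_counts or {}).get(m, 0)) for m in _DUP_MODES}
    if any(v < 0 for v in list(mode_counts.values()) + list(bg_counts.values())):
        raise ValueError("mode counts must be nonnegative")
    rng = np.random.default_rng(seed)
    per_pair_need = {
        "TD": 4,
        "PD": proximal_max_rank_gap + 3,
        "WGD": 12,
        "TRD": 8,
        "DSD": 6,
    }
    need = sum(per_pair_need[m] * (mode_counts[m] + bg_counts[m]) for m in _DUP_MODES)
    if need > n_background:
        raise ValueError(
            f"cannot place planted constructs: need ~{need} background genes, "
            f"have {n_background}"
        )

    # per-chromosome background pools; planted constructs claim disjoint
    # windows of consecutive background genes so they cannot disturb each other
    chrom_names = [f"chr{c + 1}" for c in range(n_chroms)]
    per_chrom = n_background // n_chroms
    bg_iter = iter(f"bg{i:05d}" for i in range(n_background))
    chrom_bg: dict[str, list[str]] = {}
    cursor: dict[str, int] = {}
    used_blocks: dict[str, list[list[str]]] = {}
    for c, chrom in enumerate(chrom_names):
        n_here = per_chrom if c < n_chroms - 1 else n_background - per_chrom * (n_chroms - 1)
        chrom_bg[chrom] = [next(bg_iter) for _ in range(n_here)]
        cursor[chrom] = 0
        used_blocks[chrom] = []

    def alloc(w: int, exclude_chrom: str | None = None) -> tuple[str, list[str]]:
        candidates = [
            c
            for c in chrom_names
            if c != exclude_chrom and len(chrom_bg[c]) - cursor[c] >= w
        ]
        if not candidates:
            raise ValueError("placement failed: background exhausted on all chromosomes")
        c = candidates[int(rng.integers(len(candidates)))]
        block = chrom_bg[c][cursor[c] : cursor[c] + w]
        cursor[c] += w
        used_blocks[c].append(block)
        return c, block

    truth = TruthBundle()
    self_anchors: list[tuple[str, str]] = []
    outgroup_anchors: list[tuple[str, str]] = []
    pairs: list[tuple[str, str]] = []
    records: list[SeqRecord] = []
    og_counter = 0

    def plant_pair(mode: str, tag: str, k: int, is_family: bool) -> None:
        nonlocal og_counter
        ga, gb = f"{tag}{mode}{k:03d}_a", f"{tag}{mode}{k:03d}_b"
        if mode == "TD":
            _, block = alloc(4)
            block[2:2] = [ga, gb]
        elif mode == "PD":
            gap = int(rng.integers(2, proximal_max_rank_gap + 1))
            _, block = alloc(gap + 3)
            block.insert(1, ga)
            block.insert(1 + gap, gb)
        elif mode == "WGD":
            ch1, b1 = alloc(6)
            _, b2 = alloc(6, exclude_chrom=ch1)
            # flanking background anchors make a >= 5-pair collinear block
            for off in (-2, -1, 1, 2):
                self_anchors.append((b1[3 + off], b2[3 + off]))
            b1.insert(3, ga)
            b2.insert(3, gb)
            self_anchors.append((ga, gb))
        elif mode == "TRD":
            ch1, b1 = alloc(3)
            _, b2 = alloc(5, exclude_chrom=ch1)
            b1.insert(1, ga)  # novel locus
            # parental locus collinear with the outgroup
            for off in (-1, 0, 1):
                outgroup_anchors.append((b2[2 + off], f"og{og_counter:05d}"))
                og_counter += 1
            b2.insert(2, gb)
            outgroup_anchors.append((gb, f"og{og_counter:05d}"))
            og_counter += 1
        elif mode == "DSD":
            ch1, b1 = alloc(3)
            _, b2 = alloc(3, exclude_chrom=ch1)
            b1.insert(1, ga)
            b2.insert(1, gb)
        pairs.append((ga, gb))
        truth.dup_mode_labels[ga] = mode
        truth.dup_mode_labels[gb] = mode
        if is_family:
            truth.implanted_family_ids.update((ga, gb))
        base = "".join(rng.choice(_LETTERS, size=120))
        records.append(SeqRecord(id=ga, seq=_mutate_protein(base, rng)))
        records.append(SeqRecord(id=gb, seq=_mutate_protein(base, rng)))

    for mode in _DUP_MODES:
        for k in range(mode_counts[mode]):
            plant_pair(mode, "fam", k, is_family=True)
    for mode in _DUP_MODES:
        for k in range(bg_counts[mode]):
            plant_pair(mode, "bgdup", k, is_family=False)

    # materialize gene models
    genes: list[GeneModel] = []
    planted = set(truth.dup_mode_labels)
    for chrom in chrom_names:
        ordered = [g for blk in used_blocks[chrom] for g in blk] + chrom_bg[chrom][cursor[chrom]:]
        for idx, gid in enumerate(ordered):
            start = 10_000 * (idx + 1)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gid, chrom, start, start + 2_000, strand, idx))

    # some plain background genes also sit in outgroup-collinear blocks
    plain_bg = [
        g.gene_id
        for g in genes
        if g.gene_id.startswith("bg") and g.gene_id not in planted
    ]
    n_og_bg = len(plain_bg) // 5
    for gid in rng.choice(np.array(plain_bg), size=n_og_bg, replace=False):
        outgroup_anchors.append((str(gid), f"og{og_counter:05d}"))
        og_counter += 1

    for gid in sorted(set(g.gene_id for g in genes) - set(r.id for r in records)):
        records.append(
            SeqRecord(id=gid, seq="".join(rng.choice(_LETTERS, size=120)))
        )
    records.sort(key=lambda r: r.id)
    truth.extra.update(
        {
            "pairs": [[a, b, truth.dup_mode_labels[a]] for a, b in pairs],
            "proximal_max_rank_gap": proximal_max_rank_gap,
        }
    )
    return genes, self_anchors, outgroup_anchors, records, truth


# ----------------------------------------------------------------- structures

# Aperiodic synthetic sequences (fixed, deterministic): a repetitive core
# sequence would let the residue-correspondence alignment mis-register the
# chain by one repeat period, which no real protein sequence invites.
_CORE_SEQ_FULL = "".join(
    np.random.default_rng(9001).choice(np.array(list(AA20)), size=512)
)


def _coil_seq(group: int, n: int) -> str:
    return "".join(
        np.random.default_rng(77_000 + group).choice(np.array(list(AA20)), size=n)
    )


def _helix(n: int, origin: np.ndarray, direction: int) -> np.ndarray:
    i = np.arange(n)
    ang = np.deg2rad(100.0) * i
    pts = np.stack(
        [origin[0] + direction * 1.5 * i,
         origin[1] + 2.3 * np.cos(ang),
         origin[2] + 2.3 * np.sin(ang)],
        axis=1,
    )
    return pts


def _strand(n: int, origin: np.ndarray, direction: int) -> np.ndarray:
    i = np.arange(n)
    pts = np.stack(
        [origin[0] + direction * 3.3 * i,
         origin[1] + 0.6 * (i % 2),
         np.full(n, origin[2])],
        axis=1,
    )
    return pts


def sandwich_core(core_len: int, n_layers: int = 3) -> np.ndarray:
    """Idealized 3-layer sandwich CA trace: strand-helix-strand layers."""
    if core_len < 20:
        raise ValueError("core_len must be >= 20 to represent the sandwich")
    n_seg = 2 * n_layers
    per = core_len // n_seg
    lens = [per] * (n_seg - 1) + [core_len - per * (n_seg - 1)]
    layer_z = [0.0, 5.0, 10.0][:n_layers]
    specs = []
    for li, z in enumerate(layer_z):
        kind = _helix if li == 1 else _strand
        specs.append((kind, np.array([0.0, 0.0, z])))
        specs.append((kind, np.array([0.0, 5.2, z])))
    coords = []
    for k, ((kind, origin), n) in enumerate(zip(specs, lens)):
        coords.append(kind(n, origin, direction=1 if k % 2 == 0 else -1))
    return np.vstack(coords)


def _coil(n: int, start: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pts = [start]
    direction = np.array([-1.0, 0.0, 0.0])
    for _ in range(n):
        direction = 0.6 * direction + 0.4 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pts.append(pts[-1] + 3.8 * direction)
    return np.array(pts[1:][::-1])  # N-terminus outward, chain runs into the core


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_structure_set(
    n_groups: int = 5,
    n_per_group: int = 4,
    core_len: int = 60,
    term_len_by_group: list[int] | None = None,
    noise_sd: float = 0.5,
    fraction_low_conf: float = 0.0,
    n_outgroup: int = 0,
    seed: int = 0,
) -> tuple[list[Structure], TruthBundle]:
    """Toy structures: one shared sandwich core, group-specific N-terminal coils.

    Each instance is the core plus its group's coil, rigidly transformed at
    random and perturbed by i.i.d. Gaussian noise of sd ``noise_sd`` (A).
    Confidence is 0.9 except a ``fraction_low_conf`` subset set below 0.7 to
    exercise the filter.  ``n_outgroup`` adds structures lacking the core's
    third layer (distant fold relatives), labeled as an extra group.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    core = sandwich_core(core_len)
    if core_len > len(_CORE_SEQ_FULL):
        raise ValueError(f"core_len must be <= {len(_CORE_SEQ_FULL)}")
    core_seq = _CORE_SEQ_FULL[:core_len]
    if term_len_by_group is None:
        term_len_by_group = [4 + 7 * g for g in range(n_groups)]
    if len(term_len_by_group) != n_groups:
        raise ValueError("term_len_by_group length must equal n_groups")

    coils = []
    for g in range(n_groups):
        n_term = term_len_by_group[g]
        coils.append(
            _coil(n_term, core[0], rng) if n_term > 0 else np.empty((0, 3))
        )
    truth = TruthBundle()
    structures: list[Structure] = []

    def instance(template: np.ndarray, seq: str, sid: str, group: int) -> None:
        r = _random_rotation(rng)
        t = rng.uniform(-20, 20, size=3)
        coords = template @ r.T + t + rng.normal(0.0, noise_sd, size=template.shape)
        structures.append(Structure(id=sid, ca_coords=coords, confidence=0.9, seq=seq))
        truth.struct_group_labels[sid] = group

    for g in range(n_groups):
        coil_seq = _coil_seq(g, term_len_by_group[g])
        template = np.vstack([coils[g], core]) if len(coils[g]) else core
        seq = coil_seq + core_seq
        for k in range(n_per_group):
            instance(template, seq, f"s{g}_{k}", g)
    if n_outgroup > 0:
        og_core = sandwich_core(max(core_len * 2 // 3, 20), n_layers=2)
        og_seq = _CORE_SEQ_FULL[: len(og_core)]
        for k in range(n_outgroup):
            instance(og_core, og_seq, f"out_{k}", n_groups)

    n_total = len(structures)
    n_low = int(round(fraction_low_conf * n_total))
    if n_low > 0:
        low_idx = rng.choice(n_total, size=n_low, replace=False)
        for i in low_idx:
            structures[i].confidence = 0.55
    truth.extra["term_len_by_group"] = list(term_len_by_group)
    return structures, truth
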