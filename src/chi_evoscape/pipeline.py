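"""End-to-end orchestration of the family-evolution analysis.

``simulate`` writes every synthetic input (with ground truth JSON) into a
workspace; ``run_pipeline`` executes identify -> classify -> motifs ->
duplication -> kaks -> structclust on the configured inputs, emits per-stage
TSVs and a consolidated ``summary.json``, and recomputes the summary counts
from the written TSVs as a consistency check.  Every stochastic stage derives
its seed from the single pipeline seed, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import comb

from . import classify, duplication, identify, io_formats, kaks, motifs, structclust
from . import synthetic_data as sd

log = logging.getLogger("chi_evoscape")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str = "chi_evoscape_run"
    seed: int = 7
    # stage toggles
    do_identify: bool = True
    do_classify: bool = True
    do_motifs: bool = True
    do_duplication: bool = True
    do_kaks: bool = True
    do_structclust: bool = True
    # synthetic-data sizes
    n_family: int = 30
    n_decoy: int = 150
    type_mix: dict | None = None
    kaks_omega: float = 0.2
    kaks_pairs: int = 40
    kaks_codons: int = 300
    genome_background: int = 2000
    # family skewed toward tandem duplication; background duplicates uniform
    genome_mode_counts: dict = field(
        default_factory=lambda: {"WGD": 3, "TD": 10, "PD": 3, "TRD": 2, "DSD": 2}
    )
    genome_bg_mode_counts: dict = field(
        default_factory=lambda: {"WGD": 30, "TD": 30, "PD": 30, "TRD": 30, "DSD": 30}
    )
    struct_groups: int = 5
    struct_per_group: int = 4
    struct_noise_sd: float = 0.5
    struct_fraction_low_conf: float = 0.1
    # thresholds
    threshold_quantile: float = 0.999
    null_decoys: int = 1000
    gt: float = 0.5
    alpha: float = 0.05
    conf_min: float = 0.7
    proximal_max_rank_gap: int = 10
    k_groups: int = 5
    motif_width: int = 10
    n_motifs: int = 3
    motif_score_min: float = 10.0

    @property
    def inputs(self) -> Path:
        return Path(self.out_dir) / "inputs"

    @property
    def outputs(self) -> Path:
        return Path(self.out_dir)


_DEMO_TYPE_MIX = {"I": 0.3, "II": 0.25, "V": 0.15, "III": 0.15, "IV": 0.15}


def simulate(cfg: PipelineConfig) -> None:
    """Generate every input class into ``<out_dir>/inputs`` with truth JSON."""
    inputs = cfg.inputs
    inputs.mkdir(parents=True, exist_ok=True)
    mix = cfg.type_mix or dict(_DEMO_TYPE_MIX)
    log.info("simulate: seed=%d n_family=%d n_decoy=%d", cfg.seed, cfg.n_family, cfg.n_decoy)

    seed_aln = sd.make_seed_alignment(seed=cfg.seed)
    io_formats.write_fasta(seed_aln, inputs / "seed_alignment.faa")
    recs, truth = sd.make_chi_proteome(
        cfg.n_family,
        cfg.n_decoy,
        profile=identify.build_profile(seed_aln),
        type_mix=mix,
        seed=cfg.seed,
    )
    io_formats.write_fasta(recs, inputs / "proteome.faa")
    truth.save(inputs / "truth_proteome.json")

    cds, ktruth = sd.make_codon_pair_set(
        cfg.kaks_omega, n_pairs=cfg.kaks_pairs, n_codons=cfg.kaks_codons, seed=cfg.seed + 1
    )
    io_formats.write_fasta(cds, inputs / "cds_pairs.fna")
    ktruth.save(inputs / "truth_kaks.json")

    genes, self_anchors, outgroup_anchors, gprot, gtruth = sd.make_duplicated_genome(
        cfg.genome_background,
        cfg.genome_mode_counts,
        proximal_max_rank_gap=cfg.proximal_max_rank_gap,
        background_mode_counts=cfg.genome_bg_mode_counts,
        seed=cfg.seed + 2,
    )
    io_formats.write_gene_table(genes, inputs / "genome.gff3")
    io_formats.write_anchor_pairs(self_anchors, inputs / "self_anchors.tsv")
    io_formats.write_anchor_pairs(outgroup_anchors, inputs / "outgroup_anchors.tsv")
    io_formats.write_fasta(gprot, inputs / "genome_proteins.faa")
    io_formats.write_anchor_pairs(
        [(a, b) for a, b, _m in gtruth.extra["pairs"]], inputs / "paralog_pairs.tsv"
    )
    gtruth.save(inputs / "truth_genome.json")

    structs, struth = sd.make_structure_set(
        n_groups=cfg.struct_groups,
        n_per_group=cfg.struct_per_group,
        noise_sd=cfg.struct_noise_sd,
        fraction_low_conf=cfg.struct_fraction_low_conf,
        seed=cfg.seed + 3,
    )
    pdb_dir = inputs / "structures"
    pdb_dir.mkdir(exist_ok=True)
    for s in structs:
        io_formats.write_pdb_ca(s, pdb_dir / f"{s.id}.pdb")
    struth.save(inputs / "truth_structures.json")


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(f"{v:.6g}" if isinstance(v, float) else str(v) for v in row)
                + "\n"
            )


def stage_identify(cfg: PipelineConfig) -> list[io_formats.SeqRecord]:
    seed_aln = io_formats.read_fasta(cfg.inputs / "seed_alignment.faa")
    proteome = io_formats.read_fasta(cfg.inputs / "proteome.faa")
    profile = identify.build_profile(seed_aln)
    threshold = identify.calibrate_threshold(
        profile,
        decoy_length=max(int(np.median([len(r) for r in proteome])), profile.width + 10),
        n_decoys=cfg.null_decoys,
        quantile=cfg.threshold_quantile,
        seed=cfg.seed + 10,
    )
    log.info("identify: profile width=%d threshold=%.2f bits", profile.width, threshold)
    hits = identify.scan_proteome(proteome, profile, threshold)
    family = identify.filter_family(hits, proteome)
    _write_tsv(
        cfg.outputs / "hits.tsv",
        ["seq_id", "start", "score_bits", "passed"],
        [[h.seq_id, h.start, float(h.score), int(h.passed)] for h in hits],
    )
    io_formats.write_fasta(family, cfg.outputs / "family.faa")
    return family


def stage_classify(
    cfg: PipelineConfig, family: list[io_formats.SeqRecord]
) -> list[classify.CHIAssignment]:
    truth = sd.TruthBundle.load(cfg.inputs / "truth_proteome.json")
    reference_id = truth.extra["reference_id"]
    ref_position = truth.extra["ref_position"]
    exemplars = {
        g: [e for e in ids if any(r.id == e for r in family)]
        for g, ids in truth.extra["exemplars"].items()
    }
    msa = classify.build_msa(family)
    trimmed, kept = classify.trim_msa_columns(msa, cfg.gt)
    active_col = msa.colmap(reference_id)[ref_position - 1]
    if active_col not in kept:
        raise PipelineError("classify: active-site column removed by trimming")
    tree = classify.build_nj_tree(trimmed)
    (cfg.outputs / "tree.nwk").write_text(tree + "\n")
    assignments = classify.assign_types(msa, tree, reference_id, ref_position, exemplars)
    rows = []
    for rec, asg in zip(family, assignments):
        length, mw, pi = classify.compute_properties(rec)
        rows.append(
            [asg.seq_id, asg.chi_type, asg.active_site_residue, asg.clade,
             length, round(mw, 4), round(pi, 4)]
        )
    _write_tsv(
        cfg.outputs / "types.tsv",
        ["seq_id", "chi_type", "residue", "clade", "length", "mw", "pi"],
        rows,
    )
    return assignments


def stage_motifs(
    cfg: PipelineConfig,
    family: list[io_formats.SeqRecord],
    assignments: list[classify.CHIAssignment],
) -> dict:
    found = motifs.discover_motifs(
        family, width=cfg.motif_width, n_motifs=cfg.n_motifs, n_restarts=2,
        seed=cfg.seed + 20,
    )
    motifs.write_meme_minimal(found, cfg.outputs / "motifs.txt")
    if not found:
        return {}
    matrix = motifs.scan_motifs(family, found, score_min=cfg.motif_score_min)
    _write_tsv(
        cfg.outputs / "motif_presence.tsv",
        ["seq_id"] + matrix.motif_ids,
        [[sid] + [int(v) for v in row] for sid, row in zip(matrix.ids, matrix.values)],
    )
    types = {a.seq_id: a.chi_type for a in assignments}
    report = motifs.summarize_motif_sharing(matrix, types)
    (cfg.outputs / "motif_summary.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    return report


def stage_duplication(cfg: PipelineConfig) -> list[duplication.EnrichmentResult]:
    genes = io_formats.read_gene_table(cfg.inputs / "genome.gff3")
    self_anchors = io_formats.read_anchor_pairs(cfg.inputs / "self_anchors.tsv")
    outgroup_anchors = io_formats.read_anchor_pairs(cfg.inputs / "outgroup_anchors.tsv")
    pairs = io_formats.read_anchor_pairs(cfg.inputs / "paralog_pairs.tsv")
    truth = sd.TruthBundle.load(cfg.inputs / "truth_genome.json")
    family_ids = truth.implanted_family_ids
    calls = duplication.classify_duplications(
        family_ids, genes, pairs, self_anchors, outgroup_anchors,
        proximal_max_rank_gap=cfg.proximal_max_rank_gap,
    )
    _write_tsv(
        cfg.outputs / "dup_calls.tsv",
        ["gene_id", "mode", "partner"],
        [[c.gene_id, c.mode, c.partner or "-"] for c in calls],
    )
    family_calls = [c for c in calls if c.gene_id in family_ids]
    enrich = duplication.test_mode_enrichment(
        family_calls, calls, alpha=cfg.alpha, species="synthetica"
    )
    _write_tsv(
        cfg.outputs / "enrichment.tsv",
        ["species", "mode", "a", "b", "c", "d", "chi2", "p", "direction"],
        [[e.species, e.mode, e.a, e.b, e.c, e.d, e.chi2, e.p, e.direction] for e in enrich],
    )
    return enrich


def stage_kaks(cfg: PipelineConfig) -> list[kaks.KaKsResult]:
    cds = {r.id: r for r in io_formats.read_fasta(cfg.inputs / "cds_pairs.fna", "dna")}
    truth = sd.TruthBundle.load(cfg.inputs / "truth_kaks.json")
    results = []
    for pid in sorted(truth.omega_true):
        results.append(kaks.kaks_pair(cds[f"{pid}_a"], cds[f"{pid}_b"], pid))
    _write_tsv(
        cfg.outputs / "kaks.tsv",
        ["pair_id", "N", "S", "Nd", "Sd", "ka", "ks", "ratio", "regime"],
        [
            [r.pair_id, r.N, r.S, r.Nd, r.Sd,
             r.ka if r.ka is not None else "NA",
             r.ks if r.ks is not None else "NA",
             r.ratio if r.ratio is not None else "NA",
             r.regime]
            for r in results
        ],
    )
    return results


def adjusted_rand_index(labels_a: dict[str, int], labels_b: dict[str, int]) -> float:
    """Adjusted Rand index between two labelings over the same keys."""
    keys = sorted(labels_a)
    if sorted(labels_b) != keys:
        raise ValueError("labelings cover different ids")
    from collections import Counter

    pairs = Counter((labels_a[k], labels_b[k]) for k in keys)
    a_counts = Counter(labels_a[k] for k in keys)
    b_counts = Counter(labels_b[k] for k in keys)
    n = len(keys)
    sum_ij = sum(comb(v, 2) for v in pairs.values())
    sum_a = sum(comb(v, 2) for v in a_counts.values())
    sum_b = sum(comb(v, 2) for v in b_counts.values())
    expected = sum_a * sum_b / comb(n, 2)
    max_idx = (sum_a + sum_b) / 2.0
    if max_idx == expected:
        return 1.0
    return float((sum_ij - expected) / (max_idx - expected))


def stage_structclust(cfg: PipelineConfig) -> dict[str, int]:
    pdb_dir = cfg.inputs / "structures"
    structures = [
        io_formats.read_pdb_ca(p) for p in sorted(pdb_dir.glob("*.pdb"))
    ]
    matrix = structclust.build_similarity_matrix(structures, conf_min=cfg.conf_min)
    io_formats.write_tsv_matrix(matrix.ids, matrix.scaled, cfg.outputs / "similarity.tsv")
    dendro = structclust.cluster_structures(matrix, k=cfg.k_groups)
    (cfg.outputs / "dendrogram.nwk").write_text(
        structclust.dendrogram_to_newick(dendro) + "\n"
    )
    _write_tsv(
        cfg.outputs / "structure_groups.tsv",
        ["structure_id", "group"],
        [[sid, g] for sid, g in sorted(dendro.group_labels.items())],
    )
    return dendro.group_labels


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all enabled stages; returns (and writes) the summary."""
    cfg.outputs.mkdir(parents=True, exist_ok=True)
    if not (cfg.inputs / "proteome.faa").exists():
        raise PipelineError("simulate: inputs missing; run simulate first")
    summary: dict = {"seed": cfg.seed, "stages": []}
    family: list[io_formats.SeqRecord] = []
    assignments: list[classify.CHIAssignment] = []

    def run_stage(name: str, fn):
        log.info("stage %s: start", name)
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"{name}: {e}") from e

    if cfg.do_identify:
        family = run_stage("identify", lambda: stage_identify(cfg))
        truth = sd.TruthBundle.load(cfg.inputs / "truth_proteome.json")
        fam_ids = {r.id for r in family}
        planted = truth.implanted_family_ids
        n_decoy_total = sum(
            1 for line in open(cfg.inputs / "proteome.faa") if line.startswith(">dec")
        )
        summary["identify"] = {
            "n_detected": len(family),
            "recall": len(fam_ids & planted) / len(planted) if planted else None,
            "decoy_fp_rate": len(fam_ids - planted) / n_decoy_total if n_decoy_total else 0.0,
        }
        summary["stages"].append("identify")
    if cfg.do_classify and family:
        assignments = run_stage("classify", lambda: stage_classify(cfg, family))
        truth = sd.TruthBundle.load(cfg.inputs / "truth_proteome.json")
        by_type: dict[str, list] = {}
        for rec, asg in zip(family, assignments):
            length, mw, pi = classify.compute_properties(rec)
            by_type.setdefault(asg.chi_type, []).append((length, mw, pi))
        correct = sum(
            1 for a in assignments if truth.type_labels.get(a.seq_id) == a.chi_type
        )
        summary["classify"] = {
            "type_counts": {t: len(v) for t, v in sorted(by_type.items())},
            "mean_length": round(float(np.mean([l for v in by_type.values() for l, _, _ in v])), 2),
            "mean_mw": round(float(np.mean([m for v in by_type.values() for _, m, _ in v])), 2),
            "mean_pi": round(float(np.mean([p for v in by_type.values() for _, _, p in v])), 3),
            "typing_accuracy": correct / len(assignments),
        }
        summary["stages"].append("classify")
    if cfg.do_motifs and family:
        report = run_stage("motifs", lambda: stage_motifs(cfg, family, assignments))
        summary["motifs"] = {
            mid: info["status"] for mid, info in sorted(report.items())
        }
        summary["stages"].append("motifs")
    if cfg.do_duplication:
        enrich = run_stage("duplication", lambda: stage_duplication(cfg))
        truth = sd.TruthBundle.load(cfg.inputs / "truth_genome.json")
        calls_tsv = (cfg.outputs / "dup_calls.tsv").read_text().splitlines()[1:]
        modes = {ln.split("\t")[0]: ln.split("\t")[1] for ln in calls_tsv}
        recovered = sum(
            1 for g, m in truth.dup_mode_labels.items() if modes.get(g) == m
        )
        summary["duplication"] = {
            "mode_recovery": recovered / len(truth.dup_mode_labels),
            "enrichment": {e.mode: e.direction for e in enrich},
        }
        summary["stages"].append("duplication")
    if cfg.do_kaks:
        results = run_stage("kaks", lambda: stage_kaks(cfg))
        defined = [r.ratio for r in results if r.ratio is not None]
        summary["kaks"] = {
            "n_pairs": len(results),
            "n_undefined": sum(1 for r in results if r.ratio is None),
            "median_ratio": round(float(np.median(defined)), 4) if defined else None,
            "fraction_ratio_gt_1": round(
                sum(1 for x in defined if x > 1) / len(defined), 4
            ) if defined else None,
            "regimes": {
                reg: sum(1 for r in results if r.regime == reg)
                for reg in ("purifying", "positive", "neutral-ish", "undefined")
            },
        }
        summary["stages"].append("kaks")
    if cfg.do_structclust:
        labels = run_stage("structclust", lambda: stage_structclust(cfg))
        truth = sd.TruthBundle.load(cfg.inputs / "truth_structures.json")
        truth_labels = {
            sid: g for sid, g in truth.struct_group_labels.items() if sid in labels
        }
        summary["structclust"] = {
            "n_clustered": len(labels),
            "k": cfg.k_groups,
            "ari_vs_truth": round(adjusted_rand_index(labels, truth_labels), 4),
        }
        summary["stages"].append("structclust")

    _check_summary_consistency(cfg, summary)
    (cfg.outputs / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary


def _check_summary_consistency(cfg: PipelineConfig, summary: dict) -> None:
    """Recompute summary counts from the stage TSVs and assert equality."""
    if "classify" in summary:
        lines = (cfg.outputs / "types.tsv").read_text().splitlines()[1:]
        counts: dict[str, int] = {}
        for ln in lines:
            t = ln.split("\t")[1]
            counts[t] = counts.get(t, 0) + 1
        if counts != summary["classify"]["type_counts"]:
            raise PipelineError("report: type counts inconsistent with types.tsv")
    if "kaks" in summary:
        lines = (cfg.outputs / "kaks.tsv").read_text().splitlines()[1:]
        n_undef = sum(1 for ln in lines if ln.split("\t")[7] == "NA")
        if n_undef != summary["kaks"]["n_undefined"]:
            raise PipelineError("report: undefined Ka/Ks count inconsistent with kaks.tsv")


def demo(seed: int = 7, out_dir: str = "chi_evoscape_demo") -> dict:
    """One-command synthetic end-to-end run."""
    cfg = PipelineConfig(out_dir=out_dir, seed=seed)
    simulate(cfg)
    return run_pipeline(cfg)
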