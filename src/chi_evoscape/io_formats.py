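"""Readers and writers for the on-disk formats the pipeline touches.

Covers protein/CDS FASTA, GFF3 gene rows, CA-only PDB, tab-separated
collinearity anchor-pair files and TSV matrices, plus longest-isoform
reduction.  Coordinates are 1-based inclusive (GFF3 convention); all
gene-proximity arithmetic downstream uses the per-chromosome order rank,
never base pairs.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA20_SET = frozenset(AA20)
# Ambiguity / rare codes sanitized to X; anything else is a parse error.
_AA_TO_X = frozenset("BZJUO")
_DNA_SET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised on malformed input files (message names the offending line)."""


@dataclass
class SeqRecord:
    """A protein or nucleotide sequence with a stable identifier."""

    id: str
    seq: str
    species: str = ""
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene locus; ``order_rank`` is its 0-based index along the chromosome by start."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    order_rank: int = -1


@dataclass
class Structure:
    """CA trace of a predicted model with a per-model confidence in [0, 1]."""

    id: str
    ca_coords: np.ndarray  # (n, 3) in Angstrom
    confidence: float
    seq: str

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError(f"{self.id}: ca_coords must be (n, 3)")
        if len(self.seq) != len(self.ca_coords):
            raise ValueError(f"{self.id}: sequence/coordinate length mismatch")
        if len(self.seq) < 3:
            raise ValueError(f"{self.id}: need at least 3 residues")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")


def _sanitize_protein(seq: str, rec_id: str, line_no: int) -> str:
    seq = seq.upper()
    # Terminal stop codons are stripped; an internal stop is a real error.
    while seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise FormatError(f"line {line_no}: internal stop codon '*' in record '{rec_id}'")
    out = []
    for ch in seq:
        if ch in _AA20_SET or ch == "X":
            out.append(ch)
        elif ch in _AA_TO_X:
            out.append("X")
        else:
            raise FormatError(f"line {line_no}: illegal residue {ch!r} in record '{rec_id}'")
    return "".join(out)


def _sanitize_dna(seq: str, rec_id: str, line_no: int) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _DNA_SET
    if bad:
        raise FormatError(
            f"line {line_no}: illegal nucleotide {sorted(bad)[0]!r} in record '{rec_id}'"
        )
    return seq


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Parameters
    ----------
    path:
        FASTA file path.
    alphabet:
        ``"protein"`` (sanitized to the 20 canonical letters plus X) or ``"dna"``.

    Raises
    ------
    FormatError
        On duplicate ids, empty sequences or illegal residues; the message
        names the line number of the record header.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    text = Path(path).read_text()
    header_lines = [i + 1 for i, ln in enumerate(text.splitlines()) if ln.startswith(">")]
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for k, rec in enumerate(SeqIO.parse(_io.StringIO(text), "fasta")):
        line_no = header_lines[k] if k < len(header_lines) else 0
        rid = rec.id
        if not rid:
            raise FormatError(f"line {line_no}: empty record id")
        if rid in seen:
            raise FormatError(f"line {line_no}: duplicate id '{rid}'")
        seen.add(rid)
        raw = str(rec.seq)
        seq = (
            _sanitize_protein(raw, rid, line_no)
            if alphabet == "protein"
            else _sanitize_dna(raw, rid, line_no)
        )
        if not seq:
            raise FormatError(f"line {line_no}: empty sequence for record '{rid}'")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rid, seq=seq, description=desc))
    return records


def write_fasta(records: list[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def select_longest_isoform(
    records: list[SeqRecord], gene_of: dict[str, str]
) -> list[SeqRecord]:
    """Keep one transcript per gene: the longest, ties broken by smaller id.

    Mirrors the convention of retaining only the longest transcript of each
    gene before family identification.
    """
    orphans = [r.id for r in records if r.id not in gene_of]
    if orphans:
        raise ValueError(f"records missing from gene_of: {orphans}")
    best: dict[str, SeqRecord] = {}
    order: list[str] = []
    for rec in records:
        gene = gene_of[rec.id]
        cur = best.get(gene)
        if cur is None:
            best[gene] = rec
            order.append(gene)
        elif len(rec.seq) > len(cur.seq) or (
            len(rec.seq) == len(cur.seq) and rec.id < cur.id
        ):
            best[gene] = rec
    return [best[g] for g in order]


_GFF_COLS = 9


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read ``gene`` rows of a GFF3-subset file; order_rank recomputed per chromosome."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise FormatError(f"line {line_no}: expected 9 tab-separated columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = parts
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"line {line_no}: non-integer coordinates") from None
            if start > end:
                raise FormatError(f"line {line_no}: start {start} > end {end}")
            gid = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gid = kv[3:].strip()
                    break
            if not gid:
                raise FormatError(f"line {line_no}: gene row missing ID attribute")
            if gid in seen:
                raise FormatError(f"line {line_no}: duplicate gene ID '{gid}'")
            seen.add(gid)
            if strand not in ("+", "-"):
                raise FormatError(f"line {line_no}: strand must be '+' or '-'")
            genes.append(GeneModel(gid, chrom, start, end, strand))
    assign_order_ranks(genes)
    return genes


def assign_order_ranks(genes: list[GeneModel]) -> None:
    """Recompute 0-based order_rank per chromosome by ascending start (ties by id)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(members):
            g.order_rank = rank


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tchi_evoscape\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_anchor_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a tab-separated anchor-pair file (``geneA<TAB>geneB``, '#' comments)."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {line_no}: expected two tab-separated gene ids")
            pairs.append((parts[0], parts[1]))
    return pairs


def write_anchor_pairs(pairs: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pdb_ca(path: str | Path) -> Structure:
    """Read the CA trace of a (single-model) PDB file.

    Confidence is the mean CA B-factor; pLDDT-style values on the 0-100 scale
    are rescaled to [0, 1].  Chain breaks are allowed; residue order is the
    file order.
    """
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    coords, letters, bvals = [], [], []
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":  # skip HETATM / water
                continue
            if "CA" not in residue:
                continue
            atom = residue["CA"]
            coords.append(atom.coord)
            bvals.append(atom.bfactor)
            letters.append(protein_letters_3to1.get(residue.resname, "X"))
    if not coords:
        raise FormatError(f"{path}: no CA atoms")
    mean_b = float(np.mean(bvals))
    confidence = mean_b / 100.0 if mean_b > 1.0 else mean_b
    return Structure(
        id=Path(path).stem,
        ca_coords=np.asarray(coords, dtype=float),
        confidence=float(np.clip(confidence, 0.0, 1.0)),
        seq="".join(letters),
    )


_ONE_TO_THREE = {v: k for k, v in protein_letters_3to1.items()}


def write_pdb_ca(structure: Structure, path: str | Path) -> None:
    """Write a CA-only PDB; per-atom B-factor carries confidence on the 0-100 scale."""
    b = structure.confidence * 100.0
    with open(path, "w") as fh:
        for i, (letter, (x, y, z)) in enumerate(
            zip(structure.seq, structure.ca_coords), start=1
        ):
            resname = _ONE_TO_THREE.get(letter, "UNK")
            fh.write(
                f"ATOM  {i:5d}  CA  {resname:>3s} A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           C\n"
            )
        fh.write("END\n")


def write_tsv_matrix(ids: list[str], values: np.ndarray, path: str | Path) -> None:
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(ids)) + "\n")
        for rid, row in zip(ids, values):
            fh.write("\t".join([rid] + [f"{v:.6g}" for v in row]) + "\n")


def read_tsv_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return header, np.asarray(rows)


def quote_newick_label(label: str) -> str:
    """Quote a Newick label if it contains whitespace or reserved characters."""
    if any(c.isspace() for c in label) or any(c in label for c in "():;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def format_branch_length(x: float) -> str:
    """Branch lengths with 6 significant digits."""
    return f"{x:.6g}"
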