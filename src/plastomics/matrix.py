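"""Occupancy-filtered, codon-partitioned phylogenomic supermatrices.

Per-gene codon-aware nucleotide alignments come from external aligners; this
module filters them by occupancy, concatenates them into an nt123 supermatrix
with a partition map, derives the nt12 (third positions removed) and AA
(translation table 11) matrices, and writes FASTA / relaxed PHYLIP matrices
plus RAxML- and NEXUS-style partition files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

from .panel import EXCLUDED_GENES

_NT_ALPHABET = set("ACGTN-")


@dataclass
class GeneAlignment:
    """One gene's aligned nucleotide sequences (gap '-', '?' normalized)."""

    gene: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        norm = {}
        lengths = set()
        for acc, s in self.sequences.items():
            s = s.upper().replace("?", "-")
            bad = set(s) - _NT_ALPHABET
            if bad:
                raise ValueError(f"{self.gene}/{acc}: illegal characters {bad}")
            norm[acc] = s
            lengths.add(len(s))
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: ragged alignment lengths {lengths}")
        self.sequences = norm

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def taxa(self) -> set[str]:
        return set(self.sequences)


@dataclass
class Supermatrix:
    """Concatenated alignment with a gene → column-interval partition map."""

    kind: str  # nt123 | nt12 | AA
    sequences: dict[str, str]
    partitions: dict[str, tuple[int, int]]
    n_columns: int

    def validate(self) -> None:
        spans = sorted(self.partitions.values())
        pos = 0
        for s, e in spans:
            if s != pos:
                raise ValueError("partitions do not tile the matrix")
            pos = e
        if pos != self.n_columns:
            raise ValueError("partitions do not cover all columns")
        for acc, s in self.sequences.items():
            if len(s) != self.n_columns:
                raise ValueError(f"{acc}: row length {len(s)} != {self.n_columns}")


def read_gene_alignment(path: str | Path, gene: str | None = None) -> GeneAlignment:
    """Read one per-gene FASTA alignment; duplicate accessions are an error."""
    path = Path(path)
    gene = gene or path.stem
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split("|")[0]
        if acc in seqs:
            raise ValueError(f"{gene}: duplicate accession {acc}")
        seqs[acc] = str(rec.seq)
    return GeneAlignment(gene, seqs)


def read_alignment_dir(path: str | Path) -> dict[str, GeneAlignment]:
    out = {}
    for f in sorted(Path(path).glob("*.fa*")):
        aln = read_gene_alignment(f)
        out[aln.gene] = aln
    return out


def occupancy_filter(
    alignments: Mapping[str, GeneAlignment],
    excluded_genes: set[str] = frozenset(EXCLUDED_GENES),
    max_missing: float = 0.5,
    taxa: Sequence[str] | None = None,
) -> tuple[dict[str, GeneAlignment], "pd.DataFrame"]:
    """Drop hard-excluded genes, then genes whose missing-cell fraction
    strictly exceeds ``max_missing``.

    Missing cells are gap characters plus whole rows of taxa absent from the
    gene, measured against the taxon universe (union of all alignments by
    default). Exactly-at-threshold genes are kept. Raises when nothing
    survives.
    """
    import pandas as pd

    universe = set(taxa) if taxa is not None else set().union(
        *(a.taxa for a in alignments.values())
    )
    n_taxa = len(universe)
    kept: dict[str, GeneAlignment] = {}
    rows = []
    for gene in sorted(alignments):
        aln = alignments[gene]
        ncol = aln.n_columns
        total = n_taxa * ncol
        gaps = sum(s.count("-") for acc, s in aln.sequences.items()
                   if acc in universe)
        absent = (n_taxa - len(aln.taxa & universe)) * ncol
        frac = (gaps + absent) / total if total else 1.0
        hard = gene in excluded_genes
        drop = hard or frac > max_missing
        rows.append({"gene": gene, "n_columns": ncol,
                     "missing_fraction": frac,
                     "hard_excluded": hard, "retained": not drop})
        if not drop:
            kept[gene] = aln
    if not kept:
        raise ValueError("occupancy filter removed every gene")
    return kept, pd.DataFrame(rows)


def concatenate(
    alignments: Mapping[str, GeneAlignment],
    taxa: Sequence[str] | None = None,
    gene_order: str = "alpha",
    kind: str = "nt123",
) -> Supermatrix:
    """Concatenate per-gene alignments; taxa missing a gene are gap-filled."""
    if gene_order == "alpha":
        genes = sorted(alignments)
    elif gene_order == "input":
        genes = list(alignments)
    else:
        raise ValueError(f"unknown gene_order {gene_order!r}")
    if taxa is None:
        taxa = sorted(set().union(*(alignments[g].taxa for g in genes)))
    parts: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for g in genes:
        aln = alignments[g]
        ncol = aln.n_columns
        parts[g] = (pos, pos + ncol)
        pos += ncol
        for t in taxa:
            chunks[t].append(aln.sequences.get(t, "-" * ncol))
    seqs = {t: "".join(c) for t, c in chunks.items()}
    sm = Supermatrix(kind, seqs, parts, pos)
    sm.validate()
    return sm


def codon_split(matrix: Supermatrix) -> Supermatrix:
    """Remove third codon positions (keep columns ≡ 0,1 mod 3 within each
    gene partition). Every partition must be codon-complete."""
    keep: list[int] = []
    new_parts: dict[str, tuple[int, int]] = {}
    pos = 0
    for gene, (s, e) in sorted(matrix.partitions.items(), key=lambda kv: kv[1]):
        width = e - s
        if width % 3:
            raise ValueError(f"partition {gene} length {width} not divisible by 3")
        keep.extend(c for c in range(s, e) if (c - s) % 3 != 2)
        new_parts[gene] = (pos, pos + 2 * width // 3)
        pos += 2 * width // 3
    seqs = {}
    for acc, row in matrix.sequences.items():
        seqs[acc] = "".join(row[c] for c in keep)
    sm = Supermatrix("nt12", seqs, new_parts, pos)
    sm.validate()
    return sm


def _codon_map(table_id: int = 11) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate_matrix(matrix: Supermatrix, table_id: int = 11) -> Supermatrix:
    """Translate a codon-aligned nucleotide supermatrix to amino acids.

    All-gap codons become '-'; codons with partial gaps or ambiguity become
    'X'; stop codons translate to '*'.
    """
    codons = _codon_map(table_id)
    new_parts: dict[str, tuple[int, int]] = {}
    pos = 0
    for gene, (s, e) in sorted(matrix.partitions.items(), key=lambda kv: kv[1]):
        width = e - s
        if width % 3:
            raise ValueError(f"partition {gene} length {width} not divisible by 3")
        new_parts[gene] = (pos, pos + width // 3)
        pos += width // 3
    seqs = {}
    for acc, row in matrix.sequences.items():
        aas = []
        for i in range(0, len(row), 3):
            codon = row[i:i + 3]
            if codon == "---":
                aas.append("-")
            else:
                aas.append(codons.get(codon, "X"))
        seqs[acc] = "".join(aas)
    sm = Supermatrix("AA", seqs, new_parts, pos)
    sm.validate()
    return sm


def write_fasta(matrix: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(matrix.sequences):
            fh.write(f">{acc}\n{matrix.sequences[acc]}\n")


def write_phylip(matrix: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP (name, two spaces, full row)."""
    with open(path, "w") as fh:
        fh.write(f" {len(matrix.sequences)} {matrix.n_columns}\n")
        for acc in sorted(matrix.sequences):
            fh.write(f"{acc}  {matrix.sequences[acc]}\n")


def write_partitions_raxml(matrix: Supermatrix, path: str | Path) -> None:
    dtype = "WAG" if matrix.kind == "AA" else "DNA"
    lines = [f"{dtype}, {g} = {s + 1}-{e}"
             for g, (s, e) in sorted(matrix.partitions.items(),
                                     key=lambda kv: kv[1])]
    Path(path).write_text("\n".join(lines) + "\n")


def write_partitions_nexus(matrix: Supermatrix, path: str | Path) -> None:
    lines = ["#nexus", "begin sets;"]
    for g, (s, e) in sorted(matrix.partitions.items(), key=lambda kv: kv[1]):
        lines.append(f"    charset {g} = {s + 1}-{e};")
    lines.append("end;")
    Path(path).write_text("\n".join(lines) + "\n")
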