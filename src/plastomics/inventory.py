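"""Gene copy-number, intron and genome-size summaries.

All tables are plain pandas DataFrames so they can be written straight to TSV
and regrouped at any taxonomic level (order, family, major clade).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import GENE_FAMILIES, PANEL_72
from .records import PlastomeRecord, TaxonomyLabel


def build_copy_matrix(
    cohort: Sequence[PlastomeRecord],
    panel: Sequence[str] = PANEL_72,
    include_pseudo: bool = False,
) -> pd.DataFrame:
    """Accession × gene matrix of physical copy counts.

    IR-duplicated genes count once per annotated copy; pseudogene copies are
    excluded unless ``include_pseudo``.
    """
    accs = [rec.accession for rec in cohort]
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate accessions in cohort")
    mat = pd.DataFrame(0, index=accs, columns=list(panel), dtype=int)
    for rec in cohort:
        for feat in rec.genes(include_pseudo):
            if feat.gene in mat.columns:
                mat.loc[rec.accession, feat.gene] += 1
    mat.index.name = "accession"
    return mat


def intron_counts(
    cohort: Sequence[PlastomeRecord],
    policy: str = "max",
    include_pseudo: bool = False,
) -> pd.DataFrame:
    """Intron number per (accession, gene).

    Intron number of a copy is ``len(exons) - 1`` (origin-wrapped pieces count
    as one exon); trans-spliced copies contribute NA. Multi-copy genes are
    reduced with ``policy`` ("max" | "min"); ``policy="all"`` returns a long
    table with one row per copy.
    """
    if policy not in ("max", "min", "all"):
        raise ValueError(f"unknown intron policy {policy!r}")
    rows = []
    for rec in cohort:
        counter: dict[str, int] = {}
        for feat in sorted(rec.genes(include_pseudo), key=lambda f: (f.gene, f.start)):
            counter[feat.gene] = counter.get(feat.gene, 0) + 1
            rows.append({
                "accession": rec.accession,
                "gene": feat.gene,
                "copy": counter[feat.gene],
                "introns": np.nan if feat.n_introns is None else feat.n_introns,
            })
    long = pd.DataFrame(rows, columns=["accession", "gene", "copy", "introns"])
    if policy == "all":
        return long
    agg = "max" if policy == "max" else "min"
    wide = long.pivot_table(index="accession", columns="gene", values="introns",
                            aggfunc=agg)
    return wide


def loss_report(
    matrix: pd.DataFrame,
    taxonomy: Mapping[str, TaxonomyLabel],
    level: str = "major_clade",
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-group absence counts and fractions for every gene.

    ``gene_sets`` adds rows for whole gene families (e.g. all ndh genes,
    from the explicit family lists) — a family is absent from a genome when
    every member has zero copies.
    """
    groups = pd.Series(
        {acc: taxonomy[acc].group(level) if acc in taxonomy else "unknown"
         for acc in matrix.index},
        name=level,
    )
    targets: dict[str, pd.Series] = {g: matrix[g] for g in matrix.columns}
    if gene_sets:
        for name, members in gene_sets.items():
            cols = [m for m in members if m in matrix.columns]
            if cols:
                targets[name] = matrix[cols].sum(axis=1)
    rows = []
    for name, copies in targets.items():
        absent = (copies == 0).groupby(groups).agg(["sum", "count"])
        for grp, (n_absent, n_total) in absent.iterrows():
            rows.append({
                "gene": name, level: grp,
                "n_absent": int(n_absent), "n_genomes": int(n_total),
                "fraction_absent": n_absent / n_total,
            })
    return pd.DataFrame(rows)


def default_gene_sets() -> dict[str, tuple[str, ...]]:
    """The explicit functional family lists (ndh, psb, ...)."""
    return dict(GENE_FAMILIES)


def clade_summaries(
    cohort: Sequence[PlastomeRecord],
    level: str = "major_clade",
    panel: Sequence[str] = PANEL_72,
) -> pd.DataFrame:
    """Genome-size and gene-number summaries per taxonomic group.

    ``mean_genes_distinct`` counts distinct panel genes present (copy ≥ 1),
    matching the usual "average gene number" usage; ``mean_gene_copies``
    counts total annotated copies, reported alongside for transparency.
    """
    if not cohort:
        raise ValueError("empty cohort")
    panel_set = set(panel)
    rows = []
    for rec in cohort:
        feats = [f for f in rec.genes() if f.gene in panel_set]
        rows.append({
            "group": rec.taxonomy.group(level),
            "size_bp": rec.length,
            "n_distinct": len({f.gene for f in feats}),
            "n_copies": len(feats),
        })
    df = pd.DataFrame(rows)
    out = df.groupby("group").agg(
        n_genomes=("size_bp", "size"),
        mean_size_bp=("size_bp", "mean"),
        median_size_bp=("size_bp", "median"),
        min_size_bp=("size_bp", "min"),
        max_size_bp=("size_bp", "max"),
        mean_genes_distinct=("n_distinct", "mean"),
        mean_gene_copies=("n_copies", "mean"),
    )
    out["mean_size_kb"] = (out["mean_size_bp"] / 1000).round(2)
    out.index.name = level
    return out.reset_index()


def mean_copy_by_group(
    matrix: pd.DataFrame,
    taxonomy: Mapping[str, TaxonomyLabel],
    level: str = "major_clade",
) -> pd.DataFrame:
    """Per-gene mean copy number within each taxonomic group."""
    groups = pd.Series(
        {acc: taxonomy[acc].group(level) if acc in taxonomy else "unknown"
         for acc in matrix.index}
    )
    return matrix.groupby(groups).mean()


def mean_introns_by_group(
    cohort: Sequence[PlastomeRecord],
    level: str = "major_clade",
    policy: str = "max",
) -> pd.DataFrame:
    """Per-gene mean intron number within each taxonomic group."""
    wide = intron_counts(cohort, policy=policy)
    groups = pd.Series(
        {rec.accession: rec.taxonomy.group(level) for rec in cohort}
    )
    return wide.groupby(groups.reindex(wide.index)).mean()
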