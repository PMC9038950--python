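"""GenBank ingestion, taxonomy tables, cohort filtering and FASTA export.

Only CDS features are consumed — tRNA and rRNA annotations are ignored by
design, mirroring a protein-coding-gene-only analysis. Gene symbols are
normalized onto the 72-gene panel at parse time; symbols outside the panel
are logged and dropped, so downstream modules only ever see panel genes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .panel import PANEL_72, normalize_gene_name
from .records import (GeneFeature, PlastomeRecord, TaxonomyLabel,
                      UNKNOWN_TAXONOMY)

logger = logging.getLogger(__name__)

#: Exon gap (bp) beyond which a discontiguous CDS is treated as trans-spliced
#: even without an explicit /trans_splicing qualifier.
TRANS_SPLICE_GAP = 20_000


class GenBankParseError(ValueError):
    """Raised when a flat file cannot be turned into a PlastomeRecord."""


def load_taxonomy(path: str | Path) -> dict[str, TaxonomyLabel]:
    """Read a taxonomy TSV (accession, taxon, order, family, major_clade)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    required = {"accession", "order", "family", "major_clade"}
    missing = required - set(df.columns)
    if missing:
        raise GenBankParseError(f"taxonomy table missing columns: {sorted(missing)}")
    return {
        row.accession: TaxonomyLabel(row.order, row.family, row.major_clade)
        for row in df.itertuples()
    }


def _merge_origin_wrap(parts: list[tuple[int, int]], length: int) -> bool:
    """Detect a wrap split: an exon piece ending at ``length`` immediately
    followed (in transcript order, either direction) by one starting at 0."""
    for a, b in zip(parts, parts[1:]):
        if (a[1] == length and b[0] == 0) or (b[1] == length and a[0] == 0):
            return True
    return False


def _feature_from_seqfeature(sf, length: int, circular: bool) -> GeneFeature | None:
    quals = sf.qualifiers
    raw = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or [""])[0]
    try:
        gene = normalize_gene_name(raw)
    except ValueError:
        logger.warning("CDS with no usable gene symbol skipped")
        return None
    if gene is None:
        logger.info("gene symbol %r outside the 72-gene panel; rejected", raw)
        return None

    parts = list(sf.location.parts)
    exons = [(int(p.start), int(p.end)) for p in parts]
    for s, e in exons:
        if s < 0 or e > length:
            if not circular:
                raise GenBankParseError(
                    f"feature {raw} at [{s},{e}) exceeds sequence bounds on a "
                    "non-circular record"
                )
    strand = sf.location.strand
    mixed_strand = strand is None
    if mixed_strand:
        strand = parts[0].strand or 1
    if strand == -1:
        # Biopython returns parts in file order; ensure transcript order
        # (descending genome coordinates) for simple minus-strand joins.
        if len({p.strand for p in parts}) == 1 and exons == sorted(exons):
            exons = exons[::-1]

    wraps = circular and _merge_origin_wrap(exons, length)
    trans = "trans_splicing" in quals or mixed_strand
    if not trans and not wraps and len(exons) > 1:
        gaps = []
        order = sorted(exons)
        for (s1, e1), (s2, e2) in zip(order, order[1:]):
            gaps.append(s2 - e1)
        if any(g > TRANS_SPLICE_GAP for g in gaps):
            trans = True

    return GeneFeature(
        gene=gene,
        raw_name=raw,
        strand=int(strand),
        exons=tuple(exons),
        trans_spliced=trans,
        pseudo="pseudo" in quals or "pseudogene" in quals,
        wraps_origin=wraps,
    )


def parse_genbank(
    path: str | Path,
    taxonomy: Mapping[str, TaxonomyLabel] | None = None,
) -> list[PlastomeRecord]:
    """Parse one GenBank flat file (possibly multi-record) into
    :class:`PlastomeRecord` objects.

    GenBank 1-based inclusive locations become 0-based half-open intervals;
    ``join()`` parts become exons and ``complement()`` sets strand −1.
    Accessions absent from the taxonomy table are labeled "unknown" with a
    warning rather than raising.
    """
    out: list[PlastomeRecord] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except GenBankParseError:
        raise
    except Exception as exc:  # malformed flat file
        raise GenBankParseError(f"{path}: {exc}") from exc
    for rec in records:
        try:
            seq = str(rec.seq).upper()
        except Exception as exc:  # undefined/contentless sequence
            raise GenBankParseError(f"{path}: record {rec.id} has no sequence") from exc
        if not seq:
            raise GenBankParseError(f"{path}: record {rec.id} has no sequence")
        circular = rec.annotations.get("topology", "circular") == "circular"
        accession = rec.id or rec.name
        tax = UNKNOWN_TAXONOMY
        if taxonomy is not None:
            tax = taxonomy.get(accession, None) or taxonomy.get(accession.split(".")[0], None) or UNKNOWN_TAXONOMY
            if tax is UNKNOWN_TAXONOMY:
                logger.warning("accession %s missing from taxonomy table", accession)
        features = []
        for sf in rec.features:
            if sf.type != "CDS":
                continue
            feat = _feature_from_seqfeature(sf, len(seq), circular)
            if feat is not None:
                features.append(feat)
        record = PlastomeRecord(
            accession=accession,
            taxon_name=rec.annotations.get("organism", rec.description or accession),
            taxonomy=tax,
            seq=seq,
            circular=circular,
            features=features,
        )
        record.validate()
        out.append(record)
    if not out:
        raise GenBankParseError(f"{path}: no GenBank records found")
    return out


def read_cohort(
    paths: Iterable[str | Path] | str | Path,
    taxonomy: Mapping[str, TaxonomyLabel] | str | Path | None = None,
) -> list[PlastomeRecord]:
    """Read a cohort from a directory of .gb/.gbk files or an explicit list."""
    if isinstance(taxonomy, (str, Path)):
        taxonomy = load_taxonomy(taxonomy)
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        files = sorted(p for p in root.iterdir()
                       if p.suffix.lower() in (".gb", ".gbk", ".genbank"))
        if not files:
            raise GenBankParseError(f"no GenBank files under {root}")
    else:
        files = [Path(p) for p in paths]
    cohort: list[PlastomeRecord] = []
    seen: set[str] = set()
    for f in files:
        for rec in parse_genbank(f, taxonomy):
            if rec.accession in seen:
                raise GenBankParseError(f"duplicate accession {rec.accession}")
            seen.add(rec.accession)
            cohort.append(rec)
    return cohort


def filter_taxa(
    cohort: Sequence[PlastomeRecord],
    panel: Sequence[str] = PANEL_72,
    max_missing: float = 0.5,
) -> tuple[list[PlastomeRecord], pd.DataFrame]:
    """Drop genomes missing strictly more than ``max_missing`` of the panel.

    A gene is "missing" when the genome carries zero (non-pseudo) copies.
    Returns the retained cohort and a rejection report listing, for every
    genome, its missing-gene count and whether it was removed.
    """
    if not panel:
        raise ValueError("empty gene panel")
    panel_set = set(panel)
    threshold = max_missing * len(panel_set)
    rows, kept = [], []
    for rec in cohort:
        present = rec.gene_set() & panel_set
        n_missing = len(panel_set) - len(present)
        removed = n_missing > threshold
        rows.append({"accession": rec.accession, "taxon": rec.taxon_name,
                     "n_missing": n_missing, "removed": removed})
        if not removed:
            kept.append(rec)
    return kept, pd.DataFrame(rows)


def write_gene_fastas(
    cohort: Sequence[PlastomeRecord],
    outdir: str | Path,
    panel: Sequence[str] = PANEL_72,
    first_copy_only: bool = False,
) -> list[Path]:
    """Write one multi-FASTA per gene with headers ``accession|gene|copyN``.

    ``first_copy_only`` keeps only the first copy by coordinate per genome
    (one sequence per taxon, as alignment pipelines expect).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_gene: dict[str, list[str]] = {g: [] for g in panel}
    for rec in cohort:
        counts: dict[str, int] = {}
        for feat in sorted(rec.genes(), key=lambda f: f.start):
            if feat.gene not in by_gene:
                continue
            counts[feat.gene] = counts.get(feat.gene, 0) + 1
            if first_copy_only and counts[feat.gene] > 1:
                continue
            header = f">{rec.accession}|{feat.gene}|copy{counts[feat.gene]}"
            by_gene[feat.gene].append(f"{header}\n{feat.spliced_cds(rec.seq)}\n")
    written = []
    for gene, entries in by_gene.items():
        if not entries:
            continue
        path = outdir / f"{gene}.fasta"
        path.write_text("".join(entries))
        written.append(path)
    return written
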