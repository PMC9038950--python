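"""In-memory model of an annotated circular plastome.

Coordinates are 0-based half-open genome coordinates throughout the package;
GenBank's 1-based inclusive convention is converted at the I/O boundary.
Features that wrap the circular origin are stored as two exon intervals with
``wraps_origin`` set, so every stored interval lies in ``[0, length)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .util import revcomp


@dataclass(frozen=True)
class TaxonomyLabel:
    """order / family / major-clade assignment of one genome."""

    order: str
    family: str
    major_clade: str

    def group(self, level: str) -> str:
        if level in ("order", "family", "major_clade"):
            return getattr(self, level)
        raise ValueError(f"unknown grouping level: {level!r}")


UNKNOWN_TAXONOMY = TaxonomyLabel("unknown", "unknown", "unknown")


@dataclass
class GeneFeature:
    """One annotated gene copy.

    ``exons`` are [start, end) intervals in genome coordinates, ordered 5'→3'
    in *transcript* order (descending genome coordinates for minus-strand
    genes). For a feature wrapping the origin the two flanking pieces count as
    a single exon (``wraps_origin``); for trans-spliced genes intron counting
    is undefined and ``n_introns`` is ``None``.
    """

    gene: str
    raw_name: str
    strand: int
    exons: tuple[tuple[int, int], ...]
    trans_spliced: bool = False
    pseudo: bool = False
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")
        if not self.exons:
            raise ValueError(f"{self.gene}: empty exon list")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene}: empty exon interval [{s},{e})")

    @property
    def n_introns(self) -> int | None:
        if self.trans_spliced:
            return None
        n = len(self.exons) - 1
        if self.wraps_origin:
            n -= 1
        return n

    @property
    def start(self) -> int:
        """Leftmost genome coordinate touched by the feature."""
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        """Rightmost (exclusive) genome coordinate touched by the feature."""
        return max(e for _, e in self.exons)

    def span(self, genome_length: int) -> tuple[int, int]:
        """Covering interval on the circle as (start, end); end may exceed
        ``genome_length`` when the feature wraps the origin.

        The cover is the complement of the largest inter-exon gap on the
        circle, so it is well defined for wrapped and unwrapped features
        alike.
        """
        ivs = sorted(self.exons)
        best_gap, best_i = -1, 0
        for i, (_, e_cur) in enumerate(ivs):
            s_next = ivs[(i + 1) % len(ivs)][0]
            if i == len(ivs) - 1:
                s_next += genome_length
            gap = s_next - e_cur
            if gap > best_gap:
                best_gap, best_i = gap, i
        start = ivs[(best_i + 1) % len(ivs)][0]
        end = ivs[best_i][1]
        if end <= start:
            end += genome_length
        return start, end

    def spliced_cds(self, seq: str) -> str:
        """Splice the coding sequence (exons in transcript order,
        reverse-complemented for minus-strand features)."""
        parts = []
        for s, e in self.exons:
            piece = seq[s:e]
            parts.append(revcomp(piece) if self.strand == -1 else piece)
        return "".join(parts)


@dataclass
class PlastomeRecord:
    """One annotated circular plastid genome."""

    accession: str
    taxon_name: str
    taxonomy: TaxonomyLabel
    seq: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        if self.length == 0:
            raise ValueError(f"{self.accession}: empty sequence")
        for f in self.features:
            for s, e in f.exons:
                if not (0 <= s < e <= self.length):
                    raise ValueError(
                        f"{self.accession}/{f.gene}: exon [{s},{e}) outside "
                        f"[0,{self.length})"
                    )

    def genes(self, include_pseudo: bool = False) -> list[GeneFeature]:
        """Panel gene features, excluding pseudogene copies by default."""
        return [f for f in self.features if include_pseudo or not f.pseudo]

    def gene_set(self, include_pseudo: bool = False) -> set[str]:
        return {f.gene for f in self.genes(include_pseudo)}
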