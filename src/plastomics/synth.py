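"""Synthetic annotated plastome cohorts with known ground truth.

The generator emits GenBank flat files for circular quadripartite genomes —
LSC, an inverted-repeat pair, SSC — built from a configurable reference order
of the 72-gene panel. Gene losses, segment inversions, IR boundary expansions
and per-codon-position GC shifts are planted per genome through an event
schedule, and every planted fact (signed order, IR coordinates, copy numbers,
intron counts, GC targets, block presence) is recorded in a truth object so
pipeline output can be checked exactly.

What it emulates: gene arrangement, strandedness, IR duplication,
clade-structured losses/inversions, and codon-position base composition.
What it does not: substitution processes along a phylogeny, indels, or
intergenic sequence realism (spacers are random low-GC sequence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .blocks import DEFAULT_BLOCKS, GeneBlock, GeneOrder, block_present
from .records import TaxonomyLabel
from .util import revcomp

Element = tuple[str, int]

# ---------------------------------------------------------------------------
# reference arrangement

#: Single-copy reference order (LSC then SSC), modeled on the canonical
#: angiosperm arrangement; signs are simplified so that the classic named
#: blocks are strand-consistent.
DEFAULT_LSC: tuple[Element, ...] = tuple((g, s) for g, s in [
    ("psbA", -1), ("matK", -1), ("rps16", -1), ("psbK", 1), ("psbI", 1),
    ("atpA", 1), ("atpF", 1), ("atpH", 1), ("atpI", 1), ("rps2", 1),
    ("petN", 1), ("psbM", 1), ("psbD", 1), ("psbC", 1), ("psbZ", 1),
    ("rps14", 1), ("ycf3", -1), ("rps4", -1), ("ndhJ", -1), ("ndhK", -1),
    ("ndhC", -1), ("atpE", 1), ("atpB", 1), ("rbcL", 1), ("accD", 1),
    ("psaI", 1), ("ycf4", 1), ("cemA", 1), ("petA", 1), ("psbJ", 1),
    ("psbL", 1), ("psbF", 1), ("psbE", 1), ("petL", 1), ("petG", 1),
    ("psaJ", 1), ("rpl33", 1), ("rps18", 1), ("rpl20", 1), ("clpP", -1),
    ("psbB", 1), ("psbT", 1), ("psbN", 1), ("psbH", 1), ("petB", 1),
    ("petD", 1), ("rpoA", 1), ("rps11", 1), ("rpl36", 1), ("infA", 1),
    ("rps8", 1), ("rpl14", 1), ("rpl16", 1), ("rps3", 1), ("rpl22", 1),
    ("rps19", 1),
])

#: Genes duplicated in the inverted repeats (IRA order, LSC-proximal first).
DEFAULT_IR: tuple[Element, ...] = tuple((g, s) for g, s in [
    ("rpl2", 1), ("rpl23", 1), ("ndhB", 1), ("rps7", 1), ("rps12", 1),
])

DEFAULT_SSC: tuple[Element, ...] = tuple((g, s) for g, s in [
    ("rpl32", 1), ("ccsA", 1), ("ndhD", -1), ("psaC", -1), ("ndhE", -1),
    ("ndhG", -1), ("ndhI", -1), ("ndhA", -1), ("ndhH", -1), ("rps15", -1),
    ("ycf1", -1),
])

#: Coding lengths (bp, multiples of 3) within the 300–1500 default range.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "psbA": 1062, "matK": 1500, "rps16": 330, "psbK": 300, "psbI": 300,
    "atpA": 1500, "atpF": 555, "atpH": 300, "atpI": 744, "rps2": 711,
    "petN": 300, "psbM": 300, "psbD": 1062, "psbC": 1386, "psbZ": 300,
    "rps14": 303, "ycf3": 507, "rps4": 606, "ndhJ": 477, "ndhK": 678,
    "ndhC": 363, "atpE": 402, "atpB": 1497, "rbcL": 1428, "accD": 1464,
    "psaI": 300, "ycf4": 555, "cemA": 690, "petA": 963, "psbJ": 300,
    "psbL": 300, "psbF": 300, "psbE": 300, "petL": 300, "petG": 300,
    "psaJ": 300, "rpl33": 300, "rps18": 306, "rpl20": 354, "clpP": 591,
    "psbB": 1500, "psbT": 300, "psbN": 300, "psbH": 300, "petB": 648,
    "petD": 483, "rpoA": 1014, "rps11": 417, "rpl36": 300, "infA": 300,
    "rps8": 405, "rpl14": 369, "rpl16": 408, "rps3": 657, "rpl22": 450,
    "rps19": 300, "rpl2": 825, "rpl23": 300, "ndhB": 1500, "rps7": 468,
    "rps12": 372, "rpl32": 300, "ccsA": 966, "ndhD": 1500, "psaC": 300,
    "ndhE": 306, "ndhG": 531, "ndhI": 504, "ndhA": 1092, "ndhH": 1182,
    "rps15": 300, "ycf1": 1500,
}

#: Default intron counts (genes not listed are intron-free).
DEFAULT_INTRONS: dict[str, int] = {
    "atpF": 1, "ndhA": 1, "ndhB": 1, "petB": 1, "petD": 1,
    "rpl16": 1, "rps16": 1, "ycf3": 1, "rpl2": 1, "clpP": 2,
}

#: Per-codon-position GC targets per gene class; genes not listed use the
#: global targets. The psb classes reproduce the conserved (~42%) vs
#: non-conserved (~33.8%) GC contrast.
DEFAULT_CLASS_GC: dict[str, tuple[float, float, float]] = {
    "conserved_psb": (0.47, 0.45, 0.34),
    "nonconserved_psb": (0.37, 0.35, 0.295),
}
DEFAULT_GC_CLASSES: dict[str, str] = {
    **{g: "conserved_psb" for g in ("psbB", "psbT", "psbN", "psbH")},
    **{g: "nonconserved_psb" for g in ("psbA", "psbI", "psbK", "psbL")},
}

#: A rotation of (order, family, major clade) triples for default labeling.
DEFAULT_TAXA: tuple[tuple[str, str, str], ...] = (
    ("Poales", "Poaceae", "monocots"),
    ("Asparagales", "Orchidaceae", "monocots"),
    ("Fabales", "Fabaceae", "eudicots"),
    ("Lamiales", "Lamiaceae", "eudicots"),
    ("Pinales", "Pinaceae", "gymnosperms"),
    ("Polypodiales", "Polypodiaceae", "ferns"),
    ("Funariales", "Funariaceae", "mosses"),
    ("Marchantiales", "Marchantiaceae", "liverworts"),
    ("Chlamydomonadales", "Chlamydomonadaceae", "chlorophytes"),
    ("Zygnematales", "Zygnemataceae", "charophytes"),
)


# ---------------------------------------------------------------------------
# events

@dataclass(frozen=True)
class Loss:
    gene: str


@dataclass(frozen=True)
class Inversion:
    """Reverse (and strand-flip) LSC elements i..j inclusive."""
    i: int
    j: int


@dataclass(frozen=True)
class IRExpand:
    """Move genes from the IR-adjacent end of the LSC into the repeat, so
    they become duplicated."""
    genes: tuple[str, ...]


@dataclass(frozen=True)
class GCShift:
    """Add ``delta`` to the GC target at codon position (1, 2 or 3)."""
    position: int
    delta: float


Event = Loss | Inversion | IRExpand | GCShift


def apply_inversion(order: Sequence[Element], i: int, j: int) -> list[Element]:
    """Signed reversal of the segment i..j (inclusive) of a circular order.

    ``i > j`` wraps through the origin. Indices must lie in [0, n).
    """
    n = len(order)
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"inversion indices ({i}, {j}) outside [0, {n})")
    order = list(order)
    if i <= j:
        seg = [(g, -s) for g, s in reversed(order[i:j + 1])]
        return order[:i] + seg + order[j + 1:]
    # wrapping segment: rotate so the segment is contiguous, invert, rotate back
    rot = order[i:] + order[:i]
    length = (j - i) % n + 1
    seg = [(g, -s) for g, s in reversed(rot[:length])]
    new_rot = seg + rot[length:]
    return new_rot[-i:] + new_rot[:-i] if i else new_rot


# ---------------------------------------------------------------------------
# configuration and truth

@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort; the defaults are the
    package's reference conditions, not tuning knobs."""

    n_genomes: int
    seed: int
    lsc: tuple[Element, ...] = DEFAULT_LSC
    ir: tuple[Element, ...] = DEFAULT_IR
    ssc: tuple[Element, ...] = DEFAULT_SSC
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    introns: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_INTRONS))
    intron_len: int = 150
    spacer_len: int = 200
    spacer_gc: float = 0.30
    ir_extra_len: int = 3000
    gc_targets: tuple[float, float, float] = (0.45, 0.40, 0.30)
    class_gc: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_GC))
    gc_classes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GC_CLASSES))
    taxa: tuple[tuple[str, str, str], ...] = DEFAULT_TAXA
    events: tuple[tuple[tuple[int, ...], Event], ...] = ()
    blocks: tuple[str, ...] = DEFAULT_BLOCKS

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        for k, (g1, g2, g3) in [("global", self.gc_targets)] + list(self.class_gc.items()):
            for v in (g1, g2, g3):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"GC target out of [0,1] for class {k}")
        for g, L in self.gene_lengths.items():
            if L % 3:
                raise ValueError(f"{g}: gene length {L} not a multiple of 3")


@dataclass
class GenomeTruth:
    accession: str
    taxonomy: TaxonomyLabel
    length: int
    order: tuple[Element, ...]
    ira: tuple[int, int]
    irb: tuple[int, int]
    copy_numbers: dict[str, int]
    introns: dict[str, int]
    gc_targets: dict[str, tuple[float, float, float]]


@dataclass
class CohortTruth:
    genomes: dict[str, GenomeTruth]
    block_presence: dict[str, dict[str, bool]]  # block label -> accession -> bool
    block_frequency_pct: dict[str, float]

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (GenomeTruth,)):
                d = o.__dict__.copy()
                d["taxonomy"] = o.taxonomy.__dict__
                return d
            raise TypeError(type(o))
        payload = {
            "genomes": {a: enc(g) for a, g in self.genomes.items()},
            "block_presence": self.block_presence,
            "block_frequency_pct": self.block_frequency_pct,
        }
        return json.dumps(payload, indent=1, default=list)


# ---------------------------------------------------------------------------
# sequence synthesis

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    gc_draw = rng.random(length) < gc
    pick = rng.integers(0, 2, length)
    idx = np.where(gc_draw, 1 + pick, 3 * pick)  # C/G vs A/T
    return bytes(_BASES[idx]).decode()


def _draw_coding(rng: np.random.Generator, length: int,
                 targets: tuple[float, float, float]) -> str:
    p = np.asarray(targets)[np.arange(length) % 3]
    gc_draw = rng.random(length) < p
    pick = rng.integers(0, 2, length)
    idx = np.where(gc_draw, 1 + pick, 3 * pick)
    return bytes(_BASES[idx]).decode()


def _split_exons(length: int, n_introns: int) -> list[int]:
    n_ex = n_introns + 1
    base = length // n_ex
    lens = [base] * n_ex
    lens[-1] += length - base * n_ex
    return lens


class _GenomeBuilder:
    def __init__(self, cfg: CohortConfig, rng: np.random.Generator,
                 gc_targets, class_gc):
        self.cfg = cfg
        self.rng = rng
        self.gc_targets = gc_targets
        self.class_gc = class_gc
        self.chunks: list[str] = []
        self.pos = 0
        # features: (gene, strand, [(s, e), ...] transcript order)
        self.features: list[tuple[str, int, list[tuple[int, int]]]] = []

    def targets_for(self, gene: str) -> tuple[float, float, float]:
        cls = self.cfg.gc_classes.get(gene)
        return self.class_gc.get(cls, self.gc_targets)

    def add(self, s: str) -> None:
        self.chunks.append(s)
        self.pos += len(s)

    def spacer(self) -> None:
        self.add(_random_seq(self.rng, self.cfg.spacer_len, self.cfg.spacer_gc))

    def gene(self, gene: str, sign: int) -> None:
        cfg = self.cfg
        length = cfg.gene_lengths[gene]
        coding = _draw_coding(self.rng, length, self.targets_for(gene))
        exon_lens = _split_exons(length, cfg.introns.get(gene, 0))
        # plus-strand gene segment with relative exon intervals
        segment, rel_exons, off = [], [], 0
        start = 0
        for i, el in enumerate(exon_lens):
            segment.append(coding[off:off + el])
            rel_exons.append((start, start + el))
            start += el
            off += el
            if i < len(exon_lens) - 1:
                intron = _random_seq(self.rng, cfg.intron_len, cfg.spacer_gc)
                segment.append(intron)
                start += cfg.intron_len
        seg = "".join(segment)
        if sign == -1:
            L = len(seg)
            seg = revcomp(seg)
            rel_exons = [(L - e, L - s) for s, e in rel_exons]
            # transcript order on the minus strand: descending coordinates
        abs_exons = [(self.pos + s, self.pos + e) for s, e in rel_exons]
        self.features.append((gene, sign, abs_exons))
        self.add(seg)


def _build_genome(cfg: CohortConfig, idx: int, rng: np.random.Generator,
                  accession: str, taxonomy: TaxonomyLabel) -> tuple[str, list, GenomeTruth]:
    lsc = list(cfg.lsc)
    ir = list(cfg.ir)
    ssc = list(cfg.ssc)
    gc_targets = tuple(cfg.gc_targets)
    class_gc = {k: tuple(v) for k, v in cfg.class_gc.items()}

    for targets, event in cfg.events:
        if idx not in targets:
            continue
        if isinstance(event, Loss):
            hit = False
            for region in (lsc, ir, ssc):
                kept = [e for e in region if e[0] != event.gene]
                if len(kept) != len(region):
                    region[:] = kept
                    hit = True
            if not hit:
                import logging
                logging.getLogger(__name__).warning(
                    "loss of %s is a no-op (already absent)", event.gene)
        elif isinstance(event, Inversion):
            lsc = apply_inversion(lsc, event.i, event.j)
        elif isinstance(event, IRExpand):
            want = list(event.genes)
            tail = [g for g, _ in lsc[-len(want):]]
            if tail != want:
                import logging
                logging.getLogger(__name__).warning(
                    "IR expansion %s not at LSC tail; skipped", want)
            else:
                moved = lsc[-len(want):]
                lsc = lsc[:-len(want)]
                ir = moved + ir
        elif isinstance(event, GCShift):
            k = event.position - 1
            gt = list(gc_targets)
            gt[k] = min(1.0, max(0.0, gt[k] + event.delta))
            gc_targets = tuple(gt)
            class_gc = {
                c: tuple(min(1.0, max(0.0, t + (event.delta if i == k else 0)))
                         for i, t in enumerate(v))
                for c, v in class_gc.items()
            }
        else:  # pragma: no cover
            raise TypeError(f"unknown event {event!r}")

    b = _GenomeBuilder(cfg, rng, gc_targets, class_gc)
    for gene, sign in lsc:
        b.spacer()
        b.gene(gene, sign)
    b.spacer()

    ira_start = b.pos
    ira_builder_start = len(b.chunks)
    ir_feat_start = len(b.features)
    for gene, sign in ir:
        b.gene(gene, sign)
        b.spacer()
    if cfg.ir_extra_len:
        b.add(_random_seq(rng, cfg.ir_extra_len, 0.40))
    ira_end = b.pos
    ira_seq = "".join(b.chunks[ira_builder_start:])
    ira_feats = [(g, s, [(xs - ira_start, xe - ira_start) for xs, xe in ex])
                 for g, s, ex in b.features[ir_feat_start:]]

    for gene, sign in ssc:
        b.spacer()
        b.gene(gene, sign)
    b.spacer()

    irb_start = b.pos
    L = len(ira_seq)
    b.add(revcomp(ira_seq))
    irb_end = b.pos
    for g, s, ex in ira_feats:
        mirrored = [(irb_start + L - xe, irb_start + L - xs) for xs, xe in ex]
        b.features.append((g, -s, mirrored))

    seq = "".join(b.chunks)
    # keep the planted repeat maximal: break any chance extension at both
    # boundary pairs so detection recovers the exact planted coordinates
    seq = _enforce_ir_maximality(seq, (ira_start, ira_end),
                                 (irb_start, irb_end))

    order = tuple(lsc) + tuple(ir) + tuple(ssc) + tuple(
        (g, -s) for g, s in reversed(ir))
    copy_numbers: dict[str, int] = {}
    for g, _ in order:
        copy_numbers[g] = copy_numbers.get(g, 0) + 1
    introns = {g: cfg.introns.get(g, 0) for g, _ in order}
    truth = GenomeTruth(
        accession=accession,
        taxonomy=taxonomy,
        length=len(seq),
        order=order,
        ira=(ira_start, ira_end),
        irb=(irb_start, irb_end),
        copy_numbers=copy_numbers,
        introns=introns,
        gc_targets={g: b.targets_for(g) for g, _ in order},
    )
    return seq, b.features, truth


def _enforce_ir_maximality(seq: str, ira: tuple[int, int],
                           irb: tuple[int, int]) -> str:
    """Mutate one spacer base at each repeat boundary so the planted pair
    cannot be extended by a chance match."""
    n = len(seq)
    s = list(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def fix(pos_a: int, pos_b: int) -> None:
        # ensure s[pos_a] != complement(s[pos_b]) by mutating pos_a
        pos_a %= n
        pos_b %= n
        if s[pos_a] == comp[s[pos_b]]:
            for alt in "ACGT":
                if alt != s[pos_a] and alt != comp[s[pos_b]]:
                    s[pos_a] = alt
                    break

    # left of IRA pairs with right of IRB; right of IRA pairs with left of IRB
    fix(ira[0] - 1, irb[1])
    fix(ira[1], irb[0] - 1)
    return "".join(s)


# ---------------------------------------------------------------------------
# emission

def _to_seqrecord(accession: str, taxon: str, seq: str,
                  features: list[tuple[str, int, list[tuple[int, int]]]],
                  ) -> SeqRecord:
    rec = SeqRecord(
        Seq(seq), id=accession, name=accession,
        description=f"{taxon} plastid genome, synthetic",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "date": "01-JAN-2000",
            "organism": taxon,
            "accessions": [accession],
        },
    )
    rec.features.append(SeqFeature(SimpleLocation(0, len(seq)), type="source",
                                   qualifiers={"organism": [taxon]}))
    for gene, strand, exons in features:
        locs = [SimpleLocation(s, e, strand=strand) for s, e in exons]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        rec.features.append(SeqFeature(loc, type="CDS",
                                       qualifiers={"gene": [gene]}))
    return rec


def generate_cohort(cfg: CohortConfig, outdir: str | Path) -> CohortTruth:
    """Emit the cohort (one GenBank file per genome, taxonomy.tsv,
    truth.json) and return the truth record. Deterministic given the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genomes: dict[str, GenomeTruth] = {}
    tax_lines = ["accession\ttaxon\torder\tfamily\tmajor_clade"]
    for i in range(cfg.n_genomes):
        acc = f"SYN{i:05d}"
        o, f, c = cfg.taxa[i % len(cfg.taxa)]
        taxonomy = TaxonomyLabel(o, f, c)
        taxon = f"Synthetica specimen{i}"
        seq, feats, truth = _build_genome(cfg, i, rng, acc, taxonomy)
        rec = _to_seqrecord(acc, taxon, seq, feats)
        SeqIO.write(rec, str(outdir / f"{acc}.gb"), "genbank")
        genomes[acc] = truth
        tax_lines.append(f"{acc}\t{taxon}\t{o}\t{f}\t{c}")
    (outdir / "taxonomy.tsv").write_text("\n".join(tax_lines) + "\n")

    presence: dict[str, dict[str, bool]] = {}
    freq: dict[str, float] = {}
    for label in cfg.blocks:
        block = GeneBlock.from_label(label)
        pres = {
            acc: block_present(GeneOrder(acc, t.order), block)
            for acc, t in genomes.items()
        }
        presence[label] = pres
        freq[label] = 100.0 * sum(pres.values()) / len(pres)
    truth = CohortTruth(genomes, presence, freq)
    (outdir / "truth.json").write_text(truth.to_json())
    return truth


def load_truth(path: str | Path) -> dict:
    """Load a truth.json back as plain dictionaries."""
    return json.loads(Path(path).read_text())
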