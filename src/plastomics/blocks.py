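"""Signed circular gene orders, block frequencies and conserved-block chains.

A genome's gene order is the circular sequence of (gene, strand) pairs in
genome-coordinate order, IR copies included. Orders are compared through a
canonical form — the lexicographically smallest representation over all
rotations and the global mirror (reversal with all strands flipped) — so two
genomes with the same circular arrangement hash identically no matter how
their sequences were linearized or oriented.

A gene block matches a genome when some window of consecutive elements equals
the block (same genes, same signs) or its mirror; windows may wrap the
origin. Conserved blocks are discovered by chaining gene adjacencies whose
cohort frequency clears a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel import PANEL_72
from .records import PlastomeRecord, TaxonomyLabel

Element = tuple[str, int]  # (gene, sign)


def mirror(elements: Sequence[Element]) -> tuple[Element, ...]:
    """Reverse the sequence and flip every sign (viewing the circle from the
    opposite strand)."""
    return tuple((g, -s) for g, s in reversed(elements))


def canonical_form(elements: Sequence[Element]) -> tuple[Element, ...]:
    """Lexicographically minimal representation over all rotations of the
    sequence and of its mirror."""
    elems = tuple(elements)
    n = len(elems)
    best = None
    for variant in (elems, mirror(elems)):
        for i in range(n):
            rot = variant[i:] + variant[:i]
            if best is None or rot < best:
                best = rot
    return best


@dataclass
class GeneOrder:
    """Signed circular permutation (duplicates allowed) of one genome."""

    accession: str
    elements: tuple[Element, ...]
    _canonical: tuple[Element, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"{self.accession}: empty gene order")
        self.elements = tuple((g, int(s)) for g, s in self.elements)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def canonical(self) -> tuple[Element, ...]:
        if self._canonical is None:
            self._canonical = canonical_form(self.elements)
        return self._canonical

    @property
    def content(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.elements)


@dataclass(frozen=True)
class GeneBlock:
    """Ordered, strand-aware tuple of >= 2 genes; ``circular`` marks a chain
    closing on itself around the whole genome."""

    genes: tuple[str, ...]
    signs: tuple[int, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a gene block needs at least two genes")
        if len(self.genes) != len(self.signs):
            raise ValueError("genes and signs differ in length")
        for a, b in zip(self.genes, self.genes[1:]):
            if a == b:
                raise ValueError(f"immediate self-adjacency {a}-{b} in block")

    @classmethod
    def from_label(cls, label: str) -> "GeneBlock":
        """Parse "atpA-atpF-atpH-atpI" or "+atpA,-atpF"-style labels; genes
        without an explicit sign are taken as forward."""
        sep = "," if "," in label else "-"
        genes, signs = [], []
        for tok in label.split(sep):
            tok = tok.strip()
            if tok.startswith(("+", "-")) and sep == ",":
                signs.append(1 if tok[0] == "+" else -1)
                tok = tok[1:]
            else:
                signs.append(1)
            genes.append(tok)
        return cls(tuple(genes), tuple(signs))

    @property
    def label(self) -> str:
        return "-".join(self.genes)

    @property
    def elements(self) -> tuple[Element, ...]:
        return tuple(zip(self.genes, self.signs))


#: Named blocks reported in large plastome surveys (strands forward by
#: convention since published block labels carry none).
DEFAULT_BLOCKS: tuple[str, ...] = (
    "atpA-atpF-atpH-atpI",
    "atpE-atpB",
    "petA-psbJ-psbL-psbF-psbE-petL-petG",
    "psbB-psbT-psbN-psbH-petB-petD",
    "psbB-psbT-psbN-psbH",
    "psbJ-psbL-psbF-psbE",
    "psbM-psbD-psbC-psbZ",
    "rps8-rpl14-rpl16-rps3",
    "rpl33-rps18-rpl20",
    "rpoA-rps11-rpl36",
)


def _order_position(feat, genome_length: int) -> int:
    """Coordinate used to place a gene copy on the circle: its 5'-most
    position, or the start of the 3' exon cluster for trans-spliced genes."""
    if not feat.trans_spliced:
        return feat.span(genome_length)[0] % genome_length
    # cluster exons by genomic proximity; take the cluster holding the
    # 3'-most transcript exon
    last = feat.exons[-1]
    cluster = [last]
    for iv in feat.exons[:-1]:
        if min(abs(iv[0] - last[0]), genome_length - abs(iv[0] - last[0])) < 20_000:
            cluster.append(iv)
    return min(s for s, _ in cluster)


def extract_gene_order(
    record: PlastomeRecord,
    panel: Sequence[str] = PANEL_72,
    include_pseudo: bool = False,
) -> GeneOrder:
    """Signed circular gene order of one genome (both IR copies retained)."""
    panel_set = set(panel)
    feats = [f for f in record.genes(include_pseudo) if f.gene in panel_set]
    if not feats:
        raise ValueError(f"{record.accession}: no panel genes annotated")
    feats.sort(key=lambda f: (_order_position(f, record.length), f.gene))
    return GeneOrder(record.accession,
                     tuple((f.gene, f.strand) for f in feats))


def dedupe_orders(
    orders: Sequence[GeneOrder],
    taxonomy: Mapping[str, TaxonomyLabel],
    level: str = "order",
    signature: str = "order",
) -> list[GeneOrder]:
    """Collapse genomes with identical arrangement within a taxonomic group.

    Within each group at ``level``, genomes sharing a signature collapse to
    the lexicographically smallest accession; different groups never collapse
    together. ``signature="order"`` uses the canonical signed order (default,
    strictest); ``"content"`` uses the gene set only.
    """
    if signature not in ("order", "content"):
        raise ValueError(f"unknown signature mode {signature!r}")
    best: dict[tuple, GeneOrder] = {}
    for o in orders:
        tax = taxonomy.get(o.accession)
        group = tax.group(level) if tax is not None else "unknown"
        sig = o.canonical if signature == "order" else o.content
        key = (group, sig)
        cur = best.get(key)
        if cur is None or o.accession < cur.accession:
            best[key] = o
    return sorted(best.values(), key=lambda o: o.accession)


def block_present(order: GeneOrder, block: GeneBlock,
                  sign_sensitive: bool = True) -> bool:
    """Does the block occur as a window of consecutive elements?

    A window matches forward (same genes, same signs) or as the mirror
    (reversed order, flipped signs); windows may wrap the circular origin.
    With ``sign_sensitive=False`` strands are ignored entirely.
    """
    m = len(block.genes)
    n = order.n_elements
    if m > n:
        return False
    elems = order.elements
    targets = [block.elements, mirror(block.elements)]
    for start in range(n):
        window = tuple(elems[(start + j) % n] for j in range(m))
        if sign_sensitive:
            if window in targets:
                return True
        else:
            wgenes = tuple(g for g, _ in window)
            if wgenes == block.genes or wgenes == tuple(reversed(block.genes)):
                return True
    return False


def block_frequency(
    orders: Sequence[GeneOrder],
    blocks: Iterable[GeneBlock | str],
    denominator_policy: str = "all",
    sign_sensitive: bool = True,
) -> pd.DataFrame:
    """Percentage of genomes in which each block is contiguous.

    ``denominator_policy="all"`` divides by every genome supplied;
    ``"present-only"`` divides by genomes containing all the block's genes
    (NA when no genome qualifies).
    """
    if not orders:
        raise ValueError("empty representative set")
    if denominator_policy not in ("all", "present-only"):
        raise ValueError(f"unknown denominator policy {denominator_policy!r}")
    rows = []
    for blk in blocks:
        block = GeneBlock.from_label(blk) if isinstance(blk, str) else blk
        if denominator_policy == "all":
            denom_orders = list(orders)
        else:
            need = set(block.genes)
            denom_orders = [o for o in orders if need <= set(o.content)]
        count = sum(block_present(o, block, sign_sensitive) for o in denom_orders)
        denom = len(denom_orders)
        rows.append({
            "block": block.label,
            "count_present": count,
            "denominator": denom,
            "frequency_pct": 100.0 * count / denom if denom else float("nan"),
            "policy": denominator_policy,
        })
    return pd.DataFrame(rows)


def _canonical_adjacency(u: Element, v: Element) -> tuple[Element, Element]:
    """Orientation-normalized adjacency: (u→v) and (−v→−u) pool together."""
    alt = ((v[0], -v[1]), (u[0], -u[1]))
    return min((u, v), alt)


def adjacency_frequencies(orders: Sequence[GeneOrder]) -> dict[tuple[Element, Element], float]:
    """Fraction of genomes in which each signed adjacency occurs (wrap
    adjacency included, presence counted once per genome)."""
    counts: dict[tuple[Element, Element], int] = {}
    for o in orders:
        seen = set()
        elems = o.elements
        n = len(elems)
        for i in range(n):
            u, v = elems[i], elems[(i + 1) % n]
            seen.add(_canonical_adjacency(u, v))
        for adj in seen:
            counts[adj] = counts.get(adj, 0) + 1
    total = len(orders)
    return {adj: c / total for adj, c in counts.items()}


def _token(e: Element, sign_sensitive: bool) -> str:
    return f"{e[0]}{'+' if e[1] > 0 else '-'}" if sign_sensitive else e[0]


class _WindowIndex:
    """Substring index over the cohort's circular orders for fast counting of
    contiguous (possibly wrapping) windows."""

    def __init__(self, orders: Sequence[GeneOrder], sign_sensitive: bool):
        self.sign_sensitive = sign_sensitive
        self.sizes = [o.n_elements for o in orders]
        self.texts = []
        for o in orders:
            doubled = list(o.elements) + list(o.elements[:-1])
            self.texts.append(
                "|" + "|".join(_token(e, sign_sensitive) for e in doubled) + "|"
            )

    def _needle(self, word: Sequence[Element]) -> str:
        return "|" + "|".join(_token(e, self.sign_sensitive) for e in word) + "|"

    def count(self, word: Sequence[Element]) -> int:
        """Number of genomes containing the word (or its mirror) as a
        contiguous circular window."""
        fwd = self._needle(word)
        rev = self._needle(mirror(word))
        m = len(word)
        return sum(
            1 for size, text in zip(self.sizes, self.texts)
            if m <= size and (fwd in text or rev in text)
        )


def _is_circular_subword(small: Sequence[Element], cycle: Sequence[Element],
                         sign_sensitive: bool) -> bool:
    """Is ``small`` (or its mirror) a contiguous window of the circular word
    ``cycle``?"""
    if len(small) > len(cycle):
        return False
    doubled = tuple(cycle) + tuple(cycle)[:-1]
    text = "|" + "|".join(_token(e, sign_sensitive) for e in doubled) + "|"
    for variant in (tuple(small), mirror(small)):
        needle = "|" + "|".join(_token(e, sign_sensitive) for e in variant) + "|"
        if needle in text:
            return True
    return False


def find_conserved_blocks(
    orders: Sequence[GeneOrder],
    min_freq: float = 60.0,
    sign_sensitive: bool = True,
) -> list[tuple[GeneBlock, float]]:
    """Discover maximal conserved gene chains.

    Builds the signed adjacency graph over the cohort (orientation-normalized
    so a→b pools with −b→−a), keeps adjacencies whose cohort frequency is at
    least ``min_freq`` percent, and grows simple chains along qualifying
    adjacencies, requiring every intermediate chain to occur contiguously in
    at least one genome. Reported chains are maximal: no one-gene extension
    both qualifies and occurs. A chain closing around an entire genome is
    reported once as a circular block. Each chain carries its whole-block
    frequency (share of genomes where the full chain is contiguous), which
    never exceeds its weakest internal adjacency frequency. Results sort by
    length, then frequency, descending.
    """
    if not orders:
        raise ValueError("empty representative set")
    if not (0 < min_freq <= 100):
        raise ValueError("min_freq must lie in (0, 100]")
    freqs = adjacency_frequencies(orders)
    thresh = min_freq / 100.0 - 1e-12
    fwd_edges: dict[Element, list[Element]] = {}
    rev_edges: dict[Element, list[Element]] = {}
    qual: set[tuple[Element, Element]] = set()
    for (u, v), f in freqs.items():
        if f < thresh:
            continue
        for a, b in ((u, v), ((v[0], -v[1]), (u[0], -u[1]))):
            if (a, b) in qual:
                continue
            qual.add((a, b))
            fwd_edges.setdefault(a, []).append(b)
            rev_edges.setdefault(b, []).append(a)
    for d in (fwd_edges, rev_edges):
        for key in d:
            d[key] = sorted(d[key])

    index = _WindowIndex(orders, sign_sensitive)
    n_total = len(orders)

    # conserved full circles: genomes whose every adjacency (wrap included)
    # qualifies form a closed chain covering the whole genome
    cycle_words: dict[tuple[Element, ...], int] = {}
    for o in orders:
        if o.n_elements < 2:
            continue
        elems = o.elements
        genes = [g for g, _ in elems]
        if len(set(genes)) != len(genes):
            continue  # a simple chain may not repeat a gene
        if all((elems[i], elems[(i + 1) % len(elems)]) in qual
               for i in range(len(elems))):
            canon = o.canonical
            cycle_words.setdefault(canon, 0)
    kept_cycles: list[tuple[tuple[Element, ...], float]] = []
    for cyc in sorted(cycle_words):
        hits = sum(1 for o in orders if o.n_elements == len(cyc)
                   and o.canonical == cyc)
        kept_cycles.append((cyc, 100.0 * hits / n_total))

    # grow realized simple chains from qualifying 2-gene seeds
    seeds = sorted((u, v) for (u, v) in qual if u[0] != v[0])
    visited: set[tuple[Element, ...]] = set()
    maximal: list[tuple[tuple[Element, ...], float]] = []
    stack: list[tuple[Element, ...]] = []
    for u, v in seeds:
        word = (u, v)
        if index.count(word) > 0 and word not in visited:
            visited.add(word)
            stack.append(word)
    while stack:
        word = stack.pop()
        genes = {g for g, _ in word}
        extendable = False
        for nxt in fwd_edges.get(word[-1], ()):
            if nxt[0] in genes:
                continue
            ext = word + (nxt,)
            if index.count(ext) > 0:
                extendable = True
                if ext not in visited:
                    visited.add(ext)
                    stack.append(ext)
        for prv in rev_edges.get(word[0], ()):
            if prv[0] in genes:
                continue
            ext = (prv,) + word
            if index.count(ext) > 0:
                extendable = True
                if ext not in visited:
                    visited.add(ext)
                    stack.append(ext)
        if extendable:
            continue
        if any(_is_circular_subword(word, cyc, sign_sensitive)
               for cyc, _ in kept_cycles):
            continue
        if mirror(word) < word:
            continue  # mirror representative reported instead
        maximal.append((word, 100.0 * index.count(word) / n_total))

    out = [(GeneBlock(tuple(g for g, _ in w), tuple(s for _, s in w),
                      circular=True), f) for w, f in kept_cycles]
    out += [(GeneBlock(tuple(g for g, _ in w), tuple(s for _, s in w)), f)
            for w, f in sorted(set(maximal))]
    out.sort(key=lambda bf: (-len(bf[0].genes), -bf[1], bf[0].label))
    return out


def read_orders(path: str | Path) -> list[GeneOrder]:
    """Read an order file: one line per genome,
    ``accession<TAB>+geneA,-geneB,...``."""
    orders = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        acc, elems = line.split("\t")
        parsed = []
        for tok in elems.split(","):
            tok = tok.strip()
            sign = -1 if tok.startswith("-") else 1
            parsed.append((tok.lstrip("+-"), sign))
        orders.append(GeneOrder(acc, tuple(parsed)))
    return orders


def write_orders(orders: Sequence[GeneOrder], path: str | Path) -> None:
    lines = []
    for o in orders:
        elems = ",".join(f"{'+' if s > 0 else '-'}{g}" for g, s in o.elements)
        lines.append(f"{o.accession}\t{elems}")
    Path(path).write_text("\n".join(lines) + "\n")
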