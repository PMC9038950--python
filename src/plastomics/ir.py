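"""Quadripartite structure: inverted-repeat detection and gene localization.

The detector finds the longest pair of disjoint segments on the circular
sequence where one segment equals the reverse complement of the other
(seeded k-mer matching with run merging along anti-diagonals). The two
single-copy segments between the repeats are named by length: the longer is
the LSC, the shorter the SSC.

Intervals are (start, end) with 0 <= start < length and start < end <=
start + length; end beyond the sequence length denotes wrapping past the
circular origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gc import GroupComparison, compare_groups
from .panel import FOCAL_IR_GENES
from .records import PlastomeRecord
from .util import complement_codes, encode_bases

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class IRAnnotation:
    """IRA/IRB/LSC/SSC partition of one circular genome."""

    found: bool
    ira: Interval | None = None
    irb: Interval | None = None
    lsc: Interval | None = None
    ssc: Interval | None = None
    ir_length: int = 0

    def intervals(self) -> dict[str, Interval]:
        if not self.found:
            return {}
        return {"IRA": self.ira, "IRB": self.irb, "LSC": self.lsc, "SSC": self.ssc}


@dataclass(frozen=True)
class GeneLocation:
    """Partition assignment of one gene copy plus its genome-level status."""

    accession: str
    gene: str
    copy: int
    partition: str  # LSC | SSC | IR | junction
    ir_status: str  # "in-IRs" | "out-IRs"


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 2-bit-packed hashes of all circular k-mers; second array flags
    windows containing ambiguous bases (to be excluded)."""
    n = len(codes)
    ext = np.concatenate([codes, codes[: k - 1]])
    win = np.lib.stride_tricks.sliding_window_view(ext, k)
    powers = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    hashes = (win.astype(np.uint64) * powers).sum(axis=1)
    valid = (win < 4).all(axis=1)
    return hashes[:n], valid[:n]


def detect_ir(
    seq: str,
    min_ir_len: int = 1000,
    max_mismatch: int = 0,
    k: int = 25,
) -> IRAnnotation:
    """Locate the inverted-repeat pair of a circular plastome sequence.

    Returns ``found=False`` when the best disjoint reverse-complement pair is
    shorter than ``min_ir_len`` (including when the sequence itself is shorter
    than two repeats). Ties are broken toward the longer repeat, then the
    smaller start coordinate. ``max_mismatch > 0`` lets seed runs bridge short
    mismatch gaps (approximate, for degraded repeats); the default demands
    exact repeats.
    """
    n = len(seq)
    if n < max(2 * min_ir_len, k + 1):
        return IRAnnotation(found=False)

    s = encode_bases(seq)
    rc = complement_codes(s)[::-1]
    hs, vs = _kmer_hashes(s, k)
    hr, vr = _kmer_hashes(rc, k)

    order = np.argsort(hs, kind="stable")
    hs_sorted = hs[order]
    lo = np.searchsorted(hs_sorted, hr, side="left")
    hi = np.searchsorted(hs_sorted, hr, side="right")
    counts = hi - lo
    b_idx = np.repeat(np.arange(n), counts)
    if len(b_idx) == 0:
        return IRAnnotation(found=False)
    # expand the [lo, hi) ranges into seq positions
    a_idx = order[np.concatenate([np.arange(l, h) for l, h in
                                  zip(lo[counts > 0], hi[counts > 0])])]
    keep = vs[a_idx] & vr[b_idx]
    a_idx, b_idx = a_idx[keep], b_idx[keep]
    if len(a_idx) == 0:
        return IRAnnotation(found=False)

    diag = (a_idx - b_idx) % n
    sort = np.lexsort((a_idx, diag))
    d_sorted, a_sorted = diag[sort], a_idx[sort]

    # maximal runs of consecutive a on a constant diagonal
    brk = np.flatnonzero((np.diff(d_sorted) != 0) | (np.diff(a_sorted) != 1))
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [len(a_sorted) - 1]])
    runs = []  # (diag, a_start, a_end_inclusive, mismatches)
    for st, en in zip(starts, ends):
        runs.append([int(d_sorted[st]), int(a_sorted[st]), int(a_sorted[en]), 0])

    # merge runs across the circular a-boundary (a = n-1 -> a = 0)
    by_diag: dict[int, list[list[int]]] = {}
    for r in runs:
        by_diag.setdefault(r[0], []).append(r)
    merged: list[list[int]] = []
    for d, rs in by_diag.items():
        rs.sort(key=lambda r: r[1])
        first, last = rs[0], rs[-1]
        if len(rs) > 1 and last[2] == n - 1 and first[1] == 0:
            rs[0] = [d, last[1], first[2] + n, 0]
            rs.pop()
        if max_mismatch > 0:
            fused = [rs[0]]
            for r in rs[1:]:
                prev = fused[-1]
                gap = r[1] - prev[2] - 1
                est = max(1, gap - k + 1)  # mismatches implied by the seed gap
                if gap > 0 and prev[3] + est <= max_mismatch:
                    prev[2], prev[3] = r[2], prev[3] + est
                else:
                    fused.append(r)
            rs = fused
        merged.extend(rs)

    best: tuple[int, int, Interval, Interval] | None = None
    for d, a0, a1, _mm in merged:
        length = a1 - a0 + k
        if length < min_ir_len or length > n // 2:
            continue
        x = a0 % n
        b0 = (a0 - d) % n
        y = (n - b0 - length) % n
        one = (x, x + length)
        two = (y, y + length)
        if _circular_overlap(one, two, n):
            continue
        lo_iv, hi_iv = sorted([one, two], key=lambda iv: iv[0] % n)
        cand = (length, -(lo_iv[0] % n), lo_iv, hi_iv)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    if best is None:
        return IRAnnotation(found=False)

    length, _negstart, ira, irb = best
    lsc, ssc = _single_copy_segments(ira, irb, n)
    return IRAnnotation(found=True, ira=ira, irb=irb, lsc=lsc, ssc=ssc,
                        ir_length=length)


def _circular_overlap(a: Interval, b: Interval, n: int) -> bool:
    """Do two circular intervals (end may exceed n) overlap?"""
    for shift in (-n, 0, n):
        if a[0] < b[1] + shift and b[0] + shift < a[1]:
            return True
    return False


def _single_copy_segments(ira: Interval, irb: Interval, n: int) -> tuple[Interval, Interval]:
    """Name the two gaps between the repeats: longer = LSC, shorter = SSC."""
    g1 = (ira[1] % n, irb[0] if irb[0] >= ira[1] % n else irb[0] + n)
    g2 = (irb[1] % n, ira[0] if ira[0] >= irb[1] % n else ira[0] + n)
    len1, len2 = g1[1] - g1[0], g2[1] - g2[0]
    if len1 >= len2:
        return g1, g2
    return g2, g1


def _contains(outer: Interval, inner: Interval, n: int) -> bool:
    """Circular containment test for (start, end) intervals."""
    for shift in (-n, 0, n):
        if outer[0] <= inner[0] + shift and inner[1] + shift <= outer[1]:
            return True
    return False


def classify_gene_locations(
    record: PlastomeRecord,
    ir: IRAnnotation,
    focal: Sequence[str] | None = None,
) -> list[GeneLocation]:
    """Assign every gene copy to LSC / SSC / IR / junction.

    A copy wholly inside IRA∪IRB is "IR"; wholly inside a single-copy region
    takes that region's name; anything straddling a boundary is "junction".
    A gene's genome-level ``ir_status`` is "in-IRs" iff at least one copy is
    IR-located. With ``ir.found == False`` every gene is out-IRs (warned).
    If ``focal`` is given, only those genes are reported.
    """
    n = record.length
    focal_set = set(focal) if focal is not None else None
    feats = [f for f in record.genes()
             if focal_set is None or f.gene in focal_set]
    if not ir.found:
        logger.warning("%s: no IR found; all genes classified out-IRs",
                       record.accession)
    partitions: list[tuple[str, Interval]] = []
    if ir.found:
        partitions = [("IR", ir.ira), ("IR", ir.irb),
                      ("LSC", ir.lsc), ("SSC", ir.ssc)]

    by_gene: dict[str, list[str]] = {}
    prelim: list[tuple[str, int, str]] = []
    counter: dict[str, int] = {}
    for feat in sorted(feats, key=lambda f: f.start):
        counter[feat.gene] = counter.get(feat.gene, 0) + 1
        span = feat.span(n)
        part = "junction"
        if not ir.found:
            part = "LSC"
        else:
            for name, iv in partitions:
                if _contains(iv, span, n):
                    part = name
                    break
        prelim.append((feat.gene, counter[feat.gene], part))
        by_gene.setdefault(feat.gene, []).append(part)

    out = []
    for gene, copy_idx, part in prelim:
        status = "in-IRs" if "IR" in by_gene[gene] else "out-IRs"
        out.append(GeneLocation(record.accession, gene, copy_idx, part, status))
    return out


def ir_gc_comparison(
    gc_table,
    locations: Sequence[GeneLocation],
    focal: Sequence[str] = FOCAL_IR_GENES,
    min_per_class: int = 2,
    equal_var: bool = True,
) -> dict[str, GroupComparison | None]:
    """Per focal gene, compare GC123 of genomes carrying it inside vs outside
    the IRs. Genes whose in/out classes are too small are skipped (``None``).
    """
    status: dict[tuple[str, str], str] = {}
    for loc in locations:
        status[(loc.accession, loc.gene)] = loc.ir_status
    results: dict[str, GroupComparison | None] = {}
    for gene in focal:
        sub = gc_table[gc_table["gene"] == gene]
        in_vals, out_vals = [], []
        for _, row in sub.iterrows():
            st = status.get((row["accession"], gene))
            if st == "in-IRs":
                in_vals.append(row["gc123"])
            elif st == "out-IRs":
                out_vals.append(row["gc123"])
        if len(in_vals) < min_per_class or len(out_vals) < min_per_class:
            logger.info("%s: degenerate in/out-IR class sizes (%d/%d); skipped",
                        gene, len(in_vals), len(out_vals))
            results[gene] = None
            continue
        results[gene] = compare_groups(in_vals, out_vals, "in-IRs", "out-IRs",
                                       equal_var=equal_var)
    return results
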