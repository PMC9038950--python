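"""Codon-position-stratified GC content and two-sample group comparisons.

GC1/GC2/GC3 are the G+C fractions at first/second/third codon positions of a
coding sequence read in frame from position 0. GC12 and GC123 are pooled over
positions {1,2} and {1,2,3}; for clean sequences (length divisible by three,
no ambiguity codes) they coincide with the arithmetic means of the per-position
fractions. Ambiguous bases are excluded from both numerator and denominator;
a trailing partial codon is ignored. Stop codons are counted like any other
codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PANEL_72
from .records import PlastomeRecord

_GC_CODES = (1, 2)  # C, G in the 0..3 encoding


@dataclass(frozen=True)
class GCProfile:
    """GC fractions by codon position plus the base counts behind them."""

    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc123: float
    n1: int
    n2: int
    n3: int

    def as_dict(self) -> dict[str, float]:
        return {"gc1": self.gc1, "gc2": self.gc2, "gc3": self.gc3,
                "gc12": self.gc12, "gc123": self.gc123}


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test result with significance stars."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float

    @property
    def stars(self) -> str:
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return "ns"


def gc_by_codon_position(cds: str) -> GCProfile:
    """Compute GC1/GC2/GC3/GC12/GC123 for one coding sequence.

    Raises ``ValueError`` for sequences shorter than one codon.
    """
    if len(cds) < 3:
        raise ValueError(f"coding sequence shorter than one codon ({len(cds)} nt)")
    from .util import encode_bases

    codes = encode_bases(cds)
    n_codons = len(codes) // 3
    codes = codes[: 3 * n_codons].reshape(n_codons, 3)
    valid = codes < 4
    is_gc = (codes == 1) | (codes == 2)
    n = valid.sum(axis=0)
    g = (is_gc & valid).sum(axis=0)

    def frac(gs: int, ns: int) -> float:
        return float(gs) / ns if ns else float("nan")

    return GCProfile(
        gc1=frac(g[0], n[0]), gc2=frac(g[1], n[1]), gc3=frac(g[2], n[2]),
        gc12=frac(g[0] + g[1], n[0] + n[1]),
        gc123=frac(g.sum(), n.sum()),
        n1=int(n[0]), n2=int(n[1]), n3=int(n[2]),
    )


def gene_gc_table(
    cohort: Sequence[PlastomeRecord],
    panel: Sequence[str] = PANEL_72,
    copy_policy: str = "first",
) -> pd.DataFrame:
    """Per-(accession, gene) GC profiles over the cohort.

    Coding sequences are spliced from exons in transcript order and
    reverse-complemented for minus-strand genes. With ``copy_policy="first"``
    the copy with the smallest start coordinate is measured (IR copies are
    identical in practice); ``"mean"`` averages all copies.
    """
    if copy_policy not in ("first", "mean"):
        raise ValueError(f"unknown copy policy {copy_policy!r}")
    panel_set = set(panel)
    rows = []
    for rec in cohort:
        by_gene: dict[str, list] = {}
        for feat in sorted(rec.genes(), key=lambda f: f.start):
            if feat.gene in panel_set:
                by_gene.setdefault(feat.gene, []).append(feat)
        for gene, feats in by_gene.items():
            if copy_policy == "first":
                feats = feats[:1]
            profs = [gc_by_codon_position(f.spliced_cds(rec.seq)) for f in feats]
            row = {
                "accession": rec.accession,
                "gene": gene,
                "order": rec.taxonomy.order,
                "family": rec.taxonomy.family,
                "major_clade": rec.taxonomy.major_clade,
            }
            for key in ("gc1", "gc2", "gc3", "gc12", "gc123"):
                row[key] = float(np.mean([getattr(p, key) for p in profs]))
            row["n_codons"] = int(np.mean([(p.n1 + p.n2 + p.n3) // 3 if p else 0
                                           for p in profs]))
            rows.append(row)
    return pd.DataFrame(rows)


def clade_gc(
    table: pd.DataFrame,
    by: str = "major_clade",
    mode: str = "mean",
) -> pd.DataFrame:
    """Aggregate per-genome GC profiles into clade-level values.

    ``mode="mean"`` (default) averages per-genome fractions so every species
    counts once; ``mode="pooled"`` recomputes fractions from pooled codon
    counts, weighting long genes and gene-rich genomes more heavily.
    """
    cols = ["gc1", "gc2", "gc3", "gc12", "gc123"]
    if mode == "mean":
        return table.groupby(by)[cols].mean().reset_index()
    if mode == "pooled":
        t = table.copy()
        w = t["n_codons"].astype(float)
        for c in cols:
            t[c] = t[c] * w
        agg = t.groupby(by)[cols + ["n_codons"]].sum()
        for c in cols:
            agg[c] = agg[c] / agg["n_codons"]
        return agg.drop(columns="n_codons").reset_index()
    raise ValueError(f"unknown aggregation mode {mode!r}")


def _student_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float, float]:
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = len(a) + len(b) - 2
    else:
        df = float(res.df) if hasattr(res, "df") else np.nan
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):
        # zero pooled variance: identical constants ⇒ no evidence of difference
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
    return t, float(df), p


def compare_groups(
    values_a: Iterable[float],
    values_b: Iterable[float],
    label_a: str = "A",
    label_b: str = "B",
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample t-test (Student pooled-variance by default, Welch optional).

    Each group needs at least two values; otherwise the test is undefined and
    a ``ValueError`` is raised.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values for a t-test")
    t, df, p = _student_t(a, b, equal_var)
    return GroupComparison(label_a, label_b, len(a), len(b),
                           float(a.mean()), float(b.mean()), t, df, p)


def compare_gene_groups(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    label_a: str = "group A",
    label_b: str = "group B",
    value: str = "gc123",
    equal_var: bool = True,
) -> GroupComparison:
    """Compare two gene sets on per-genome-per-gene GC values.

    Values are the individual (accession, gene) entries of ``table`` falling
    in each gene set, i.e. every genome contributes one observation per gene.
    """
    va = table.loc[table["gene"].isin(set(group_a)), value]
    vb = table.loc[table["gene"].isin(set(group_b)), value]
    return compare_groups(va, vb, label_a, label_b, equal_var=equal_var)
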