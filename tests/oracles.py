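"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles — plain counting, closed
forms, exhaustive enumeration — and deliberately avoids the code paths it
checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# GC counting

def gc_counts_oracle(cds: str) -> dict[str, float]:
    """Direct per-codon-position base counting with a Python loop."""
    g = [0, 0, 0]
    n = [0, 0, 0]
    usable = 3 * (len(cds) // 3)
    for i in range(usable):
        base = cds[i].upper()
        k = i % 3
        if base in "ACGT":
            n[k] += 1
            if base in "GC":
                g[k] += 1
    out = {}
    for k in range(3):
        out[f"gc{k + 1}"] = g[k] / n[k] if n[k] else float("nan")
    out["gc12"] = (g[0] + g[1]) / (n[0] + n[1]) if (n[0] + n[1]) else float("nan")
    out["gc123"] = sum(g) / sum(n) if sum(n) else float("nan")
    return out


# ---------------------------------------------------------------------------
# pooled-variance t-test closed form

def pooled_t_oracle(a, b) -> tuple[float, float, float]:
    """Hand-computed Student's t (pooled variance), df and two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# inverted repeats: exhaustive anti-diagonal scan

def brute_force_ir(seq: str, min_ir_len: int):
    """Longest disjoint reverse-complement segment pair on a circular
    sequence, by scanning every anti-diagonal with numpy.

    Returns (ira, irb, length) with the same (longer, then smaller start)
    tie-break as the detector, or None.
    """
    from plastomics.util import complement_codes, encode_bases

    s = encode_bases(seq)
    n = len(s)
    rc = complement_codes(s)[::-1]
    rc2 = np.concatenate([rc, rc])
    best = None
    for d in range(n):
        m = s == rc2[n - d: 2 * n - d]  # m[a] == (seq[a] matches rc[(a-d) % n])
        if m.all():
            continue  # full-circle palindrome; copies cannot be disjoint
        mm = np.concatenate([m, m])
        gaps = np.flatnonzero(~mm)
        # longest possible run on this diagonal: widest window between misses
        if len(gaps) < 2 or int(np.diff(gaps).max()) - 1 < min_ir_len:
            continue
        padded = np.concatenate([[0], mm.astype(np.int8), [0]])
        steps = np.diff(padded)
        run_starts = np.flatnonzero(steps == 1)
        run_ends = np.flatnonzero(steps == -1)
        runs = []
        for a0, a1 in zip(run_starts, run_ends):
            if a0 >= n:
                continue  # circular duplicate of a run already seen
            runs.append((int(a0), int(min(a1 - a0, n))))
        for a0, length in runs:
            if length < min_ir_len:
                continue
            x = a0 % n
            b0 = (a0 - d) % n
            y = (n - b0 - length) % n
            one, two = (x, x + length), (y, y + length)
            if _circ_overlap(one, two, n):
                continue
            lo, hi = sorted([one, two], key=lambda iv: iv[0])
            cand = (length, -lo[0], lo, hi)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    if best is None:
        return None
    return best[2], best[3], best[0]


def _circ_overlap(a, b, n):
    for shift in (-n, 0, n):
        if a[0] < b[1] + shift and b[0] + shift < a[1]:
            return True
    return False


# ---------------------------------------------------------------------------
# gene blocks: exhaustive window enumeration

def mirror(elems):
    return tuple((g, -s) for g, s in reversed(elems))


def canonical(elems):
    elems = tuple(elems)
    best = None
    for var in (elems, mirror(elems)):
        for i in range(len(var)):
            rot = var[i:] + var[:i]
            if best is None or rot < best:
                best = rot
    return best


def occurs(order_elems, word) -> bool:
    """Window scan over every rotation, forward and mirrored."""
    e = tuple(order_elems)
    n, m = len(e), len(word)
    if m > n:
        return False
    for var in (tuple(word), mirror(word)):
        for i in range(n):
            if tuple(e[(i + j) % n] for j in range(m)) == var:
                return True
    return False


def block_frequency_oracle(orders, block_elems) -> float:
    """Percent of genomes containing the block, by exhaustive rotation scan."""
    hits = sum(occurs(o.elements, block_elems) for o in orders)
    return 100.0 * hits / len(orders)


def conserved_blocks_oracle(orders, min_freq: float):
    """Exhaustive window enumerator for conserved chains.

    Enumerates every contiguous circular window of every genome, keeps
    distinct-gene windows whose internal adjacencies all reach ``min_freq``
    percent of genomes, collapses full-circle all-qualifying genomes into
    canonical cycles, and removes windows that are subwords (mirror-aware)
    of longer kept windows or of a cycle. Returns a set of
    (elements, circular, frequency) triples for comparison.
    """
    n_total = len(orders)

    def canon_adj(u, v):
        return min((u, v), ((v[0], -v[1]), (u[0], -u[1])))

    adj_counts: dict = {}
    for o in orders:
        e = o.elements
        n = len(e)
        seen = {canon_adj(e[i], e[(i + 1) % n]) for i in range(n)}
        for a in seen:
            adj_counts[a] = adj_counts.get(a, 0) + 1
    qual = {a for a, c in adj_counts.items()
            if 100.0 * c / n_total >= min_freq - 1e-9}

    def adj_ok(u, v):
        return canon_adj(u, v) in qual

    # full-circle cycles
    cycles = {}
    for o in orders:
        e = o.elements
        n = len(e)
        genes = [g for g, _ in e]
        if n >= 2 and len(set(genes)) == len(genes) and all(
                adj_ok(e[i], e[(i + 1) % n]) for i in range(n)):
            cycles.setdefault(canonical(e), None)
    kept_cycles = []
    for c in sorted(cycles):
        hits = sum(1 for o in orders
                   if len(o.elements) == len(c) and canonical(o.elements) == c)
        kept_cycles.append((c, 100.0 * hits / n_total))

    # qualifying windows
    window_set = set()
    for o in orders:
        e = o.elements
        n = len(e)
        for m in range(2, n + 1):
            for i in range(n):
                w = tuple(e[(i + j) % n] for j in range(m))
                genes = [g for g, _ in w]
                if len(set(genes)) != len(genes):
                    continue
                if all(adj_ok(w[j], w[j + 1]) for j in range(m - 1)):
                    window_set.add(min(w, mirror(w)))

    def circ_subword(w, cyc):
        doubled = tuple(cyc) + tuple(cyc)[:-1]
        for var in (tuple(w), mirror(w)):
            m = len(var)
            if m > len(cyc):
                continue
            for i in range(len(doubled) - m + 1):
                if doubled[i:i + m] == var:
                    return True
        return False

    def lin_subword(w, big):
        for var in (tuple(w), mirror(w)):
            m = len(var)
            for i in range(len(big) - m + 1):
                if big[i:i + m] == var:
                    return True
        return False

    words = [w for w in window_set
             if not any(circ_subword(w, c) for c, _ in kept_cycles)]
    result = set()
    for w in words:
        if any(len(w2) > len(w) and lin_subword(w, w2) for w2 in words):
            continue
        freq = 100.0 * sum(occurs(o.elements, w) for o in orders) / n_total
        result.add((w, False, round(freq, 9)))
    for c, f in kept_cycles:
        result.add((c, True, round(f, 9)))
    return result


# ---------------------------------------------------------------------------
# random cohorts for oracle-equivalence sweeps

def random_cohort(rng: np.random.Generator, max_genes: int = 20,
                  max_genomes: int = 15):
    """Related signed circular orders: a shared base arrangement perturbed by
    inversions, occasional duplications/deletions, random rotation and
    mirroring."""
    from plastomics.blocks import GeneOrder
    from plastomics.synth import apply_inversion

    n_genes = int(rng.integers(3, max_genes + 1))
    n_genomes = int(rng.integers(2, max_genomes + 1))
    base = [(f"g{i:02d}", 1 if rng.random() < 0.5 else -1)
            for i in range(n_genes)]
    orders = []
    for k in range(n_genomes):
        elems = list(base)
        for _ in range(int(rng.integers(0, 3))):
            i, j = sorted(rng.integers(0, len(elems), 2))
            elems = apply_inversion(elems, int(i), int(j))
        if rng.random() < 0.3:  # IR-like duplication
            src = int(rng.integers(0, len(elems)))
            dst = int(rng.integers(0, len(elems) + 1))
            elems.insert(dst, elems[src])
        if rng.random() < 0.2 and len(elems) > 3:
            del elems[int(rng.integers(0, len(elems)))]
        r = int(rng.integers(0, len(elems)))
        elems = elems[r:] + elems[:r]
        if rng.random() < 0.5:
            elems = list(mirror(elems))
        orders.append(GeneOrder(f"R{k:03d}", tuple(elems)))
    return orders
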