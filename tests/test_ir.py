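"""Inverted-repeat detection and gene localization."""

from __future__ import annotations

import numpy as np
import pytest

from plastomics import (classify_gene_locations, detect_ir, gene_gc_table,
                        ir_gc_comparison, revcomp)
from plastomics.ir import IRAnnotation
from plastomics.util import rotate

from oracles import brute_force_ir


def _random_seq(rng, n, gc=0.35):
    return "".join(rng.choice(list("ACGT"), p=[(1 - gc) / 2, gc / 2, gc / 2,
                                               (1 - gc) / 2], size=n))


def _plant_ir(rng, n, ir_len, lsc_frac=0.6):
    """Random circular sequence with one maximal planted IR pair; returns
    (seq, ira, irb)."""
    ir = _random_seq(rng, ir_len)
    lsc_len = int((n - 2 * ir_len) * lsc_frac)
    ssc_len = n - 2 * ir_len - lsc_len
    lsc = _random_seq(rng, lsc_len)
    ssc = _random_seq(rng, ssc_len)
    seq = list(lsc + ir + ssc + revcomp(ir))
    ira = (lsc_len, lsc_len + ir_len)
    irb = (n - ir_len, n)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # stop chance extensions at both boundary pairs
    for pos_a, pos_b in ((ira[0] - 1, irb[1] % n), (ira[1], irb[0] - 1)):
        if seq[pos_a] == comp[seq[pos_b]]:
            seq[pos_a] = next(c for c in "ACGT"
                              if c != seq[pos_a] and c != comp[seq[pos_b]])
    return "".join(seq), ira, irb


class TestDetectIR:
    def test_planted_pair_recovered_exactly(self):
        rng = np.random.default_rng(4)
        seq, ira, irb = _plant_ir(rng, 120_000, 25_000)
        ann = detect_ir(seq)
        assert ann.found
        assert (ann.ira, ann.irb) == (ira, irb)
        assert ann.ir_length == 25_000

    def test_random_sequence_has_no_ir(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 150_000)
        assert not detect_ir(seq).found

    def test_sequence_shorter_than_two_repeats_not_found(self):
        rng = np.random.default_rng(6)
        assert not detect_ir(_random_seq(rng, 1500), min_ir_len=1000).found

    def test_larger_of_two_planted_pairs_wins_and_matches_oracle(self):
        rng = np.random.default_rng(8)
        small = _random_seq(rng, 500)
        big = _random_seq(rng, 2000)
        filler = [_random_seq(rng, 1500) for _ in range(4)]
        seq = (filler[0] + small + filler[1] + big + filler[2]
               + revcomp(small) + filler[3] + revcomp(big))
        ann = detect_ir(seq, min_ir_len=300)
        ref = brute_force_ir(seq, min_ir_len=300)
        assert ann.found and ref is not None
        assert (ann.ira, ann.irb, ann.ir_length) == ref
        assert ann.ir_length >= 2000

    def test_agrees_with_brute_force_on_planted_10kb_instances(self):
        for seed in (21, 22, 23):
            rng = np.random.default_rng(seed)
            seq, ira, irb = _plant_ir(rng, 10_000, 1500)
            ann = detect_ir(seq, min_ir_len=800)
            ref = brute_force_ir(seq, min_ir_len=800)
            assert ann.found
            assert (ann.ira, ann.irb, ann.ir_length) == ref
            assert (ann.ira, ann.irb) == (ira, irb)

    def test_rotation_shifts_coordinates_consistently(self):
        rng = np.random.default_rng(9)
        seq, ira, irb = _plant_ir(rng, 40_000, 6000)
        offset = 1234
        ann = detect_ir(rotate(seq, offset), min_ir_len=1000)
        assert ann.found
        n = len(seq)
        starts = sorted(iv[0] for iv in (ann.ira, ann.irb))
        expect = sorted(((ira[0] - offset) % n, (irb[0] - offset) % n))
        assert starts == expect
        assert ann.ir_length == 6000

    def test_reverse_complement_finds_mirrored_pair(self):
        rng = np.random.default_rng(10)
        seq, _, _ = _plant_ir(rng, 40_000, 6000)
        fwd = detect_ir(seq, min_ir_len=1000)
        rev = detect_ir(revcomp(seq), min_ir_len=1000)
        n = len(seq)
        assert rev.found and rev.ir_length == fwd.ir_length
        mirrored = sorted(((n - e) % n) for (_, e) in (fwd.ira, fwd.irb))
        assert sorted(iv[0] for iv in (rev.ira, rev.irb)) == mirrored

    def test_partitions_tile_the_circle(self):
        rng = np.random.default_rng(11)
        seq, _, _ = _plant_ir(rng, 50_000, 8000)
        ann = detect_ir(seq)
        total = sum((e - s) for s, e in ann.intervals().values())
        assert total == len(seq)


class TestClassifyGeneLocations:
    def test_gene_inside_ira_is_ir(self, demo_parsed, demo_truth):
        rec = next(r for r in demo_parsed if r.accession == "SYN00000")
        t = demo_truth.genomes[rec.accession]
        ann = detect_ir(rec.seq)
        assert (ann.ira, ann.irb) == (t.ira, t.irb)
        locs = classify_gene_locations(rec, ann)
        by_gene = {}
        for loc in locs:
            by_gene.setdefault(loc.gene, []).append(loc.partition)
        for gene in ("rpl2", "rpl23", "ndhB", "rps7", "rps12"):
            assert by_gene[gene] == ["IR", "IR"]
        assert by_gene["rps19"] == ["LSC"]

    def test_planted_ir_expansion_flips_rps19(self, demo_parsed, demo_truth):
        rec = next(r for r in demo_parsed if r.accession == "SYN00006")
        ann = detect_ir(rec.seq)
        t = demo_truth.genomes[rec.accession]
        assert (ann.ira, ann.irb) == (t.ira, t.irb)
        locs = classify_gene_locations(rec, ann, focal=("rps19", "rpl22"))
        status = {(l.gene): l.ir_status for l in locs}
        assert status["rps19"] == "in-IRs"
        assert status["rpl22"] == "out-IRs"

    def test_junction_gene_flagged(self):
        from plastomics.records import (GeneFeature, PlastomeRecord,
                                        UNKNOWN_TAXONOMY)
        ann = IRAnnotation(found=True, ira=(100, 200), irb=(400, 500),
                           lsc=(500, 1100), ssc=(200, 400), ir_length=100)
        feat = GeneFeature("rps19", "rps19", 1, ((90, 130),))  # spans LSC/IRA
        rec = PlastomeRecord("J1", "J1", UNKNOWN_TAXONOMY, "A" * 1000,
                             features=[feat])
        locs = classify_gene_locations(rec, ann)
        assert locs[0].partition == "junction"

    def test_no_ir_means_all_out(self, demo_parsed):
        rec = demo_parsed[0]
        locs = classify_gene_locations(rec, IRAnnotation(found=False))
        assert all(l.ir_status == "out-IRs" for l in locs)


class TestIRGCComparison:
    def test_degenerate_class_skipped(self, demo_parsed):
        table = gene_gc_table(demo_parsed)
        locations = []
        for rec in demo_parsed:
            ann = detect_ir(rec.seq)
            locations.extend(classify_gene_locations(rec, ann))
        res = ir_gc_comparison(table, locations)
        # every genome keeps ndhB inside the repeat -> one class only
        assert res["ndhB"] is None

    def test_planted_gc_shift_detected(self):
        rng = np.random.default_rng(12)
        import pandas as pd
        from plastomics.ir import GeneLocation
        rows, locs = [], []
        for i in range(80):
            acc = f"G{i:03d}"
            in_ir = i < 40
            gc = rng.normal(0.42 if in_ir else 0.37, 0.01)
            rows.append({"accession": acc, "gene": "rps19", "gc123": gc})
            locs.append(GeneLocation(acc, "rps19", 1,
                                     "IR" if in_ir else "LSC",
                                     "in-IRs" if in_ir else "out-IRs"))
        res = ir_gc_comparison(pd.DataFrame(rows), locs, focal=("rps19",))
        comp = res["rps19"]
        assert comp is not None and comp.p < 0.001
        assert comp.mean_a > comp.mean_b

    def test_null_shift_rarely_significant(self):
        rng = np.random.default_rng(13)
        import pandas as pd
        from plastomics.ir import GeneLocation
        false_pos = 0
        reps = 300
        for rep in range(reps):
            rows, locs = [], []
            for i in range(40):
                acc = f"G{i:03d}"
                in_ir = i < 20
                rows.append({"accession": acc, "gene": "rps7",
                             "gc123": rng.normal(0.40, 0.01)})
                locs.append(GeneLocation(acc, "rps7", 1,
                                         "IR" if in_ir else "LSC",
                                         "in-IRs" if in_ir else "out-IRs"))
            res = ir_gc_comparison(pd.DataFrame(rows), locs, focal=("rps7",))
            if res["rps7"].p < 0.05:
                false_pos += 1
        assert false_pos / reps <= 0.07  # ~5% nominal, allow sampling slack
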