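"""Pair classification, fragment assignment, deduplication, aggregation."""

import numpy as np
import pandas as pd
import pytest

import capture3c as c3
from capture3c.extract import (PAIR_COLUMNS, ClassifiedPair, PairRecord,
                               aggregate, assign_end, canonicalize,
                               classify_pair, classify_table, dedup)


def brute_force_assign(sites, L, pos):
    """Linear-scan oracle for fragment index and nearest-site distance."""
    frag = 0
    for s in sites:
        if pos >= s:
            frag += 1
    if sites and sites[0] == 0:
        frag -= 1  # empty leading fragment dropped
    dist = min((abs(pos - s) for s in sites), default=np.iinfo(np.int64).max)
    return frag, dist


class TestAssignEnd:
    def test_examples(self):
        rmap = c3.RestrictionMap(chrom_sites={"c": np.array([1000, 5000])},
                                 chrom_lengths={"c": 10_000})
        frag, dist = assign_end(rmap, "c", 1200)
        assert (frag, dist) == (1, 200)          # inside [1000, 5000)
        assert assign_end(rmap, "c", 1000)[1] == 0
        assert assign_end(rmap, "c", 3000)[1] == 2000  # equidistant midpoint

    def test_out_of_range(self):
        rmap = c3.RestrictionMap(chrom_sites={"c": np.array([10])},
                                 chrom_lengths={"c": 100})
        with pytest.raises(ValueError):
            assign_end(rmap, "c", 100)
        with pytest.raises(ValueError):
            assign_end(rmap, "c", -1)

    def test_matches_brute_force_on_random_positions(self, toy_map):
        rng = np.random.default_rng(5)
        for chrom in toy_map.chromosomes:
            sites = [int(s) for s in toy_map.sites(chrom)]
            L = toy_map.chrom_lengths[chrom]
            for pos in rng.integers(0, L, size=5000):
                assert assign_end(toy_map, chrom, int(pos)) == \
                    brute_force_assign(sites, L, int(pos))


def make_pairs(rows):
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


class TestClassify:
    def test_informative_cis(self, toy_design):
        rmap, loci, baits = toy_design
        # end A 200 bp before the site at 5000, end B 80% of chrA away
        pair = PairRecord("chrA", 4800, "+", "chrA", 11_000, "-")
        cp = classify_pair(rmap, baits, loci, pair)
        assert cp.category == "on_target_cis"
        assert cp.anchor_baits == ["E2U"]
        assert cp.anchor_distance == 200

    def test_beyond_flank_is_off_target(self, toy_design):
        rmap, loci, baits = toy_design
        cp = classify_pair(rmap, baits, loci,
                           PairRecord("chrA", 4700, "+", "chrB", 100, "-"))
        assert cp.category == "off_target"

    def test_trans(self, toy_design):
        rmap, loci, baits = toy_design
        cp = classify_pair(rmap, baits, loci,
                           PairRecord("chrA", 5000, "+", "chrB", 100, "-"))
        assert cp.category == "on_target_trans"
        assert cp.anchor_distance == 0
        assert "E2D" in cp.anchor_baits  # tie at the cut site resolves to D

    def test_outside_locus_not_informative(self, toy_map):
        # same map, but locus only covers the first site
        loci = [c3.TargetLocus(name="l", chrom="chrA", start=750, end=1250)]
        baits = c3.design_baits(toy_map, loci)
        cp = classify_pair(toy_map, baits, loci,
                           PairRecord("chrA", 4900, "+", "chrA", 300, "-"))
        assert cp.category == "off_target"

    def test_both_ends_anchored_credit_both_baits(self, toy_design):
        rmap, loci, baits = toy_design
        df = make_pairs([("chrA", 950, "+", "chrA", 5100, "+")])
        out = classify_table(rmap, baits, loci, df)
        row = out.iloc[0]
        assert {row["anchor1"], row["anchor2"]} == {"E1U", "E2D"}
        table = aggregate(out, rmap, baits)
        assert table.per_bait_total["E1U"] == 1
        assert table.per_bait_total["E2D"] == 1

    def test_unmapped_end_is_unmapped_category(self, toy_design):
        rmap, loci, baits = toy_design
        df = make_pairs([(".", -1, ".", "chrA", 5100, "+")])
        out = classify_table(rmap, baits, loci, df)
        assert out.iloc[0]["category"] == "unmapped"


class TestDedup:
    def test_three_identical(self):
        pairs = [ClassifiedPair(PairRecord("c", 1, "+", "c", 2, "-"), "x")
                 for _ in range(3)]
        out, removed = dedup(pairs)
        assert removed == 2
        assert [p.duplicate for p in out] == [False, True, True]

    def test_swapped_twin_is_duplicate(self):
        a = ClassifiedPair(PairRecord("c", 1, "+", "c", 2, "-"), "x")
        b = ClassifiedPair(PairRecord("c", 2, "-", "c", 1, "+"), "x")
        _, removed = dedup([a, b])
        assert removed == 1

    def test_random_distinct_pairs_untouched(self):
        rng = np.random.default_rng(9)
        seen = set()
        pairs = []
        while len(pairs) < 1000:
            t = ("c", int(rng.integers(0, 10**6)), "+",
                 "c", int(rng.integers(0, 10**6)), "-")
            if t in seen or (t[3:], t[:3]) in seen:
                continue
            seen.add(t)
            pairs.append(ClassifiedPair(PairRecord(*t), "x"))
        _, removed = dedup(pairs)
        assert removed == 0

    def test_order_independent_counts(self, toy_design):
        rmap, loci, baits = toy_design
        rng = np.random.default_rng(2)
        base = make_pairs([("chrA", int(rng.integers(0, 12000)), "+",
                            "chrA", int(rng.integers(0, 12000)), "-")
                           for _ in range(200)])
        df = pd.concat([base, base.iloc[:50]], ignore_index=True)
        c1 = classify_table(rmap, baits, loci, df)
        shuffled = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        c2 = classify_table(rmap, baits, loci, shuffled)
        assert c1["duplicate"].sum() == c2["duplicate"].sum()
        s1 = aggregate(c1, rmap, baits).library_stats
        s2 = aggregate(c2, rmap, baits).library_stats
        assert s1 == s2


class TestAggregate:
    def test_cis_percentage(self, toy_design):
        rmap, loci, baits = toy_design
        rows = [("chrA", 4900, "+", "chrA", 10_500 + i, "-") for i in range(9)]
        rows.append(("chrA", 4900, "+", "chrB", 7000, "-"))
        table = aggregate(classify_table(rmap, baits, loci, make_pairs(rows)),
                          rmap, baits)
        s = table.library_stats
        assert s["cis"] == 9 and s["trans"] == 1
        assert 100 * s["cis"] / s["on_target"] == 90.0

    def test_empty_input(self, toy_design):
        rmap, loci, baits = toy_design
        table = aggregate(classify_table(rmap, baits, loci, make_pairs([])),
                          rmap, baits)
        assert all(v == 0 for v in table.library_stats.values())

    def test_every_pair_in_exactly_one_tally(self, default_contact_table,
                                             default_library):
        classified, table = default_contact_table
        s = table.library_stats
        assert s["raw"] == len(default_library["pairs"])
        assert s["raw"] == s["unmapped"] + s["duplicates"] + \
            s["off_target"] + s["cis"] + s["trans"]
        assert s["mapped"] == s["off_target"] + s["on_target"]
        assert s["on_target"] == s["cis"] + s["trans"]

    def test_trans_fraction_within_binomial_error(self, default_contact_table,
                                                  default_library):
        _, table = default_contact_table
        s = table.library_stats
        tau = default_library["truth"].config["trans_rate"]
        n = s["on_target"]
        sd = np.sqrt(tau * (1 - tau) / n)
        assert abs(s["trans"] / n - tau) <= 3 * sd


class TestCanonicalize:
    def test_swapped_rows_become_identical(self):
        df = make_pairs([("chrB", 5, "+", "chrA", 9, "-"),
                         ("chrA", 9, "-", "chrB", 5, "+")])
        out = canonicalize(df)
        assert out.iloc[0].tolist() == out.iloc[1].tolist()

    def test_record_canonical_order(self):
        p = PairRecord("chrB", 5, "+", "chrA", 9, "-")
        assert (p.chrom1, p.pos1) == ("chrA", 9)
        q = PairRecord("chrA", 9, "-", "chrB", 5, "+")
        assert p.key == q.key
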