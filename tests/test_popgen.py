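import itertools
import random

import numpy as np
import pandas as pd
import pytest

from haplopipe.haplotable import HaploTable, OTU
from haplopipe.denoise import Haplotype
from haplopipe.popgen import (
    TruthSet,
    build_network,
    classify_against_truth,
    haplotypes_per_otu,
    replicate_r2,
    site_frequencies,
)

from .conftest import random_seq


def table_from(rows, seqs, totals, otu_of=None):
    """rows: hap id -> counts per sample; all haps in one OTU by default."""
    samples = sorted(totals)
    counts = pd.DataFrame(
        {s: [rows[h].get(s, 0) for h in rows] for s in samples}, index=list(rows)
    )
    otu_of = otu_of or {h: "o1" for h in rows}
    otu_ids = sorted(set(otu_of.values()))
    otus = [
        OTU(id=o, centroid_seq="", haplotype_ids=[h for h in rows if otu_of[h] == o])
        for o in otu_ids
    ]
    return HaploTable(
        counts=counts,
        otu_of=otu_of,
        seqs=dict(seqs),
        otus=otus,
        sample_totals=pd.Series(totals, dtype=float),
    )


class TestHaplotypesPerOtu:
    def test_mean_and_sample_sd(self):
        rows = {f"h{i}": {"s1": 10} for i in range(6)}
        otu_of = {
            "h0": "o1",
            "h1": "o2", "h2": "o2", "h3": "o2",
            "h4": "o3", "h5": "o3",
        }
        t = table_from(rows, {h: f"S{h}" for h in rows}, {"s1": 60}, otu_of)
        mean, sd, per_otu, degenerate = haplotypes_per_otu(t)
        assert per_otu == {"o1": 1, "o2": 3, "o3": 2}
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)
        assert not degenerate

    def test_all_singletons(self):
        rows = {f"h{i}": {"s1": 10} for i in range(4)}
        otu_of = {f"h{i}": f"o{i}" for i in range(4)}
        t = table_from(rows, {h: h for h in rows}, {"s1": 40}, otu_of)
        mean, sd, _, degenerate = haplotypes_per_otu(t)
        assert mean == 1.0 and sd == 0.0 and not degenerate

    def test_single_otu_degenerate(self):
        t = table_from({"h1": {"s1": 5}}, {"h1": "AAAA"}, {"s1": 5})
        mean, sd, _, degenerate = haplotypes_per_otu(t)
        assert mean == 1.0 and sd == 0.0 and degenerate

    def test_empty_table_errors(self):
        t = table_from({}, {}, {"s1": 0})
        with pytest.raises(ValueError):
            haplotypes_per_otu(t)


def mst_weight_bruteforce(nodes, weights):
    """Minimum spanning-tree weight by enumerating all edge subsets."""
    all_edges = list(itertools.combinations(nodes, 2))
    best = None
    for subset in itertools.combinations(all_edges, len(nodes) - 1):
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            w = sum(weights[e] for e in subset)
            best = w if best is None else min(best, w)
    return best


class TestBuildNetwork:
    def test_two_haplotypes_single_edge(self):
        t = table_from(
            {"h1": {"s1": 10}, "h2": {"s1": 5}},
            {"h1": "AAAA", "h2": "AAAT"},
            {"s1": 15},
        )
        net = build_network(t, "o1")
        assert net.edges == [("h1", "h2", 1)]

    def test_star_topology(self):
        # ancestor plus 3 derived, each d=1 from the ancestor, d=2 pairwise:
        # the MST is the 3-edge star of total weight 3
        t = table_from(
            {"h1": {"s1": 50}, "h2": {"s1": 5}, "h3": {"s1": 4}, "h4": {"s1": 3}},
            {"h1": "AAAAAA", "h2": "TAAAAA", "h3": "AATAAA", "h4": "AAAAAT"},
            {"s1": 62},
        )
        net = build_network(t, "o1")
        assert len(net.edges) == 3
        assert sum(d for _, _, d in net.edges) == 3
        assert all("h1" in (a, b) for a, b, _ in net.edges)

    def test_single_haplotype_no_edges(self):
        t = table_from({"h1": {"s1": 5}}, {"h1": "ACGT"}, {"s1": 5})
        net = build_network(t, "o1")
        assert net.edges == []

    def test_novel_flagging(self):
        t = table_from(
            {"h1": {"s1": 10}, "h2": {"s1": 5}},
            {"h1": "AAAA", "h2": "AAAT"},
            {"s1": 15},
        )
        ref = TruthSet(expected=[("t1", "AAAA")])
        net = build_network(t, "o1", reference=ref)
        assert net.novel == {"h2"}

    def test_mst_weight_matches_bruteforce(self, rng):
        for _ in range(30):
            n = rng.randint(2, 6)
            seqs = {f"h{i}": random_seq(rng, 12) for i in range(n)}
            rows = {h: {"s1": rng.randint(1, 100)} for h in seqs}
            t = table_from(rows, seqs, {"s1": sum(r["s1"] for r in rows.values())})
            net = build_network(t, "o1")
            from haplopipe.denoise import edit_distance

            weights = {
                (a, b): edit_distance(seqs[a], seqs[b])
                for a, b in itertools.combinations(sorted(seqs), 2)
            }
            got = sum(d for _, _, d in net.edges)
            want = mst_weight_bruteforce(sorted(seqs), weights)
            assert got == want
            # spanning: n-1 edges over n nodes
            assert len(net.edges) == n - 1


class TestSiteFrequencies:
    def test_sums_to_one_per_site(self):
        t = table_from(
            {"h1": {"s1": 10, "s2": 0}, "h2": {"s1": 30, "s2": 8}},
            {"h1": "AAAA", "h2": "AAAT"},
            {"s1": 40, "s2": 8},
        )
        recs = site_frequencies(t, "o1")
        by_site = {}
        for r in recs:
            by_site.setdefault(r["site"], 0.0)
            by_site[r["site"]] += r["frequency"]
        assert all(abs(v - 1.0) < 1e-9 for v in by_site.values())

    def test_counts_10_30(self):
        t = table_from(
            {"h1": {"s1": 10}, "h2": {"s1": 30}},
            {"h1": "AAAA", "h2": "AAAT"},
            {"s1": 40},
        )
        recs = {r["haplotype"]: r["frequency"] for r in site_frequencies(t, "o1")}
        assert recs == {"h1": pytest.approx(0.25), "h2": pytest.approx(0.75)}

    def test_empty_site_omitted(self):
        t = table_from(
            {"h1": {"s1": 10, "s2": 0}},
            {"h1": "AAAA"},
            {"s1": 10, "s2": 100},
        )
        recs = site_frequencies(t, "o1")
        assert {r["site"] for r in recs} == {"s1"}
        assert recs[0]["frequency"] == 1.0


class TestReplicateR2:
    def sample_tables(self):
        seqs = {"h1": "AAAA", "h2": "AAAT", "h3": "AATT"}
        rows = {
            "h1": {"s1": 50, "s2": 40, "s3": 10},
            "h2": {"s1": 30, "s2": 40, "s3": 60},
            "h3": {"s1": 20, "s2": 20, "s3": 30},
        }
        totals = {"s1": 100, "s2": 100, "s3": 100}
        return table_from(rows, seqs, totals), seqs, rows, totals

    def test_identical_tables_give_exactly_one(self):
        t, *_ = self.sample_tables()
        results, mean, sd, excluded = replicate_r2(t, t)
        assert results and all(r2 == 1.0 for _, r2 in results)
        assert mean == 1.0 and sd == 0.0 and not excluded

    def test_scaled_counts_still_one(self):
        t, seqs, rows, totals = self.sample_tables()
        doubled = table_from(
            {h: {s: 2 * v for s, v in c.items()} for h, c in rows.items()},
            seqs,
            {s: 2 * v for s, v in totals.items()},
        )
        _, mean, _, _ = replicate_r2(t, doubled)
        assert mean == pytest.approx(1.0)

    def test_four_point_hand_example(self):
        # frozen from the closed-form OLS on these 4 points:
        # x = (.1,.2,.3,.4), y = (.12,.19,.33,.38) -> R2 = 0.96842...,
        # adjusted R2 = 1 - (1-R2)*3/2 = 0.9526315789...
        seqs = {"h1": "AAAA", "h2": "AAAT", "h3": "AATT", "h4": "ATTT"}
        ta = table_from(
            {"h1": {"s1": 10}, "h2": {"s1": 20}, "h3": {"s1": 30}, "h4": {"s1": 40}},
            seqs,
            {"s1": 100},
        )
        tb = table_from(
            {"h1": {"s1": 12}, "h2": {"s1": 19}, "h3": {"s1": 33}, "h4": {"s1": 38}},
            seqs,
            {"s1": 100},
        )
        results, mean, sd, _ = replicate_r2(ta, tb)
        assert len(results) == 1
        assert results[0][1] == pytest.approx(0.9526315789473683, abs=1e-12)

    def test_zero_variance_excluded(self):
        seqs = {"h1": "AAAA", "h2": "AAAT", "h3": "AATT"}
        ta = table_from(
            {"h1": {"s1": 10, "s2": 10}, "h2": {"s1": 10, "s2": 10},
             "h3": {"s1": 10, "s2": 10}},
            seqs,
            {"s1": 30, "s2": 30},
        )
        tb = table_from(
            {"h1": {"s1": 50, "s2": 40}, "h2": {"s1": 30, "s2": 40},
             "h3": {"s1": 20, "s2": 20}},
            seqs,
            {"s1": 100, "s2": 100},
        )
        results, mean, sd, excluded = replicate_r2(ta, tb)
        assert excluded == ["o1"] and not results


class TestClassifyAgainstTruth:
    def haps(self, sizes):
        return [
            Haplotype(seq=s, counts={"run": n}, centroid_size=n)
            for s, n in sizes.items()
        ]

    def test_exact_recovery(self):
        truth = TruthSet(expected=[("t1", "AAAA"), ("t2", "CCCC")])
        out = classify_against_truth(self.haps({"AAAA": 50, "CCCC": 50}), truth)
        assert len(out.expected_hits) == 2
        assert not out.unexpected and not out.missed

    def test_missed_truth_listed(self):
        truth = TruthSet(expected=[("t1", "AAAA"), ("t2", "CCCC")])
        out = classify_against_truth(self.haps({"AAAA": 100}), truth)
        assert out.missed == [("t2", "CCCC")]

    def test_one_off_variant_is_unexpected(self):
        truth = TruthSet(expected=[("t1", "AAAA")])
        out = classify_against_truth(self.haps({"AAAA": 90, "AAAT": 10}), truth)
        assert [s for s, _ in out.unexpected] == ["AAAT"]

    def test_floor_monotonicity(self):
        truth = TruthSet(expected=[("t1", "AAAA"), ("t2", "CCCC")])
        haps = self.haps({"AAAA": 990, "CCCC": 10})
        hits = [
            len(classify_against_truth(haps, truth, floor=f).expected_hits)
            for f in (0.0, 0.005, 0.02, 0.5)
        ]
        assert hits == sorted(hits, reverse=True)

    def test_replicate_concordance(self):
        truth = TruthSet(expected=[("t1", "AAAA")])
        out = classify_against_truth(
            self.haps({"AAAA": 50, "TTTT": 50}),
            truth,
            second_run=self.haps({"AAAA": 70, "GGGG": 30}),
        )
        assert out.in_both_replicates == {"AAAA"}
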