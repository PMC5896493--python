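"""Intraspecific-diversity outputs from a filtered haplotype table.

Per-OTU haplotype richness, minimum-spanning haplotype networks (edges
weighted in base-pair differences), per-site haplotype frequency tables,
replicate-consistency adjusted R-squared, and classification of observed
haplotypes against a known truth set (for mock-community validation).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .denoise import Haplotype, edit_distance
from .haplotable import HaploTable

__all__ = [
    "HaploNetwork",
    "TruthSet",
    "TruthComparison",
    "haplotypes_per_otu",
    "build_network",
    "replicate_r2",
    "classify_against_truth",
    "site_frequencies",
]


@dataclass
class TruthSet:
    """Known haplotype sequences, e.g. the Sanger-typed mock specimens."""

    expected: list[tuple[str, str]]  # (haplotype id, seq)
    source: str = ""

    def __post_init__(self) -> None:
        seqs = [s for _, s in self.expected]
        if len(set(seqs)) != len(seqs):
            raise ValueError("truth-set sequences must be unique")

    @property
    def seqs(self) -> set[str]:
        return {s for _, s in self.expected}


@dataclass
class HaploNetwork:
    """Minimum-spanning haplotype network for one OTU.

    Edges carry base-pair differences (edit distance); a d-step edge is drawn
    as d crosslines in the conventional rendering. ``novel`` marks haplotypes
    whose sequence is absent from the supplied reference set.
    """

    otu_id: str
    nodes: dict[str, dict[str, float]]  # hap id -> per-site relative frequency
    edges: list[tuple[str, str, int]]  # (hap_a, hap_b, d)
    novel: set[str] = field(default_factory=set)


def haplotypes_per_otu(table: HaploTable) -> tuple[float, float, dict[str, int], bool]:
    """Mean and sample SD of haplotype richness across OTUs.

    Counts haplotypes with any nonzero count, per OTU. With a single OTU the
    SD is undefined and reported as 0.0 with the degenerate flag set.
    """
    if table.counts.empty:
        raise ValueError("haplotypes_per_otu: empty table")
    nonzero = table.counts.loc[table.counts.sum(axis=1) > 0]
    per_otu: dict[str, int] = {}
    for hap in nonzero.index:
        otu = table.otu_of[hap]
        per_otu[otu] = per_otu.get(otu, 0) + 1
    values = np.array(list(per_otu.values()), dtype=float)
    degenerate = len(values) < 2
    mean = float(values.mean())
    sd = 0.0 if degenerate else float(values.std(ddof=1))
    return mean, sd, per_otu, degenerate


def _mst(
    nodes: list[str],
    weights: dict[tuple[str, str], int],
    abundance: dict[str, float],
) -> list[tuple[str, str, int]]:
    """Kruskal MST with deterministic tie-breaking: lighter edges first, then
    edges touching the more abundant haplotype, then lexicographic pair."""
    edges = sorted(
        ((a, b) for a, b in combinations(nodes, 2)),
        key=lambda e: (
            weights[e],
            -max(abundance[e[0]], abundance[e[1]]),
            e,
        ),
    )
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = []
    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            out.append((a, b, weights[(a, b)]))
            if len(out) == len(nodes) - 1:
                break
    return out


def build_network(
    table: HaploTable, otu_id: str, reference: TruthSet | None = None
) -> HaploNetwork:
    """Minimum spanning tree over the OTU's haplotypes, weighted by base-pair
    differences; nodes carry per-site relative frequencies within the OTU."""
    haps = [h for h in table.counts.index if table.otu_of[h] == otu_id]
    if not haps:
        raise ValueError(f"no haplotypes for OTU {otu_id!r}")
    weights = {
        (a, b): edit_distance(table.seqs[a], table.seqs[b])
        for a, b in combinations(haps, 2)
    }
    abundance = table.counts.loc[haps].sum(axis=1).astype(float).to_dict()
    edges = _mst(haps, weights, abundance)
    freqs = site_frequencies(table, otu_id)
    nodes = {h: {} for h in haps}
    for rec in freqs:
        nodes[rec["haplotype"]][rec["site"]] = rec["frequency"]
    novel = set()
    if reference is not None:
        novel = {h for h in haps if table.seqs[h] not in reference.seqs}
    return HaploNetwork(otu_id=otu_id, nodes=nodes, edges=edges, novel=novel)


def site_frequencies(table: HaploTable, otu_id: str) -> list[dict]:
    """Per-site haplotype frequencies within one OTU; empty sites omitted.

    Frequencies are counts over the OTU's site total, so they sum to 1 for
    every occupied site.
    """
    haps = [h for h in table.counts.index if table.otu_of[h] == otu_id]
    if not haps:
        raise ValueError(f"no haplotypes for OTU {otu_id!r}")
    sub = table.counts.loc[haps]
    out = []
    for site in sub.columns:
        total = int(sub[site].sum())
        if total == 0:
            continue
        for hap in haps:
            n = int(sub.at[hap, site])
            if n > 0:
                out.append(
                    {"otu": otu_id, "site": site, "haplotype": hap, "frequency": n / total}
                )
    return out


def _relative(table: HaploTable) -> pd.DataFrame:
    totals = table.sample_totals.reindex(table.counts.columns).replace(0, np.nan)
    return table.counts.div(totals, axis=1).fillna(0.0)


def _match_otus(table_a: HaploTable, table_b: HaploTable) -> list[tuple[str, str]]:
    """Pair OTUs across replicate tables by shared haplotype sequences,
    greedily by the summed abundance of the shared haplotypes."""
    seq_otu_a = {table_a.seqs[h]: table_a.otu_of[h] for h in table_a.counts.index}
    seq_otu_b = {table_b.seqs[h]: table_b.otu_of[h] for h in table_b.counts.index}
    score: dict[tuple[str, str], float] = {}
    for h in table_a.counts.index:
        seq = table_a.seqs[h]
        if seq in seq_otu_b:
            key = (seq_otu_a[seq], seq_otu_b[seq])
            score[key] = score.get(key, 0.0) + float(table_a.counts.loc[h].sum())
    pairs = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    for (oa, ob), _ in sorted(score.items(), key=lambda kv: (-kv[1], kv[0])):
        if oa not in used_a and ob not in used_b:
            pairs.append((oa, ob))
            used_a.add(oa)
            used_b.add(ob)
    return pairs


def replicate_r2(
    table_a: HaploTable,
    table_b: HaploTable,
    min_pairs: int = 3,
    raw_counts: bool = False,
) -> tuple[list[tuple[str, float]], float, float, list[str]]:
    """Replicate consistency as adjusted R-squared of per-OTU OLS fits.

    For each OTU matched across the two tables (by shared haplotype
    sequences), (haplotype, site) abundances of replicate A are regressed
    against replicate B (A as predictor); haplotypes absent from one table
    count 0 there. Relative abundances are used unless ``raw_counts``.
    Returns per-OTU (id, adjusted R2), their mean and sample SD, and the ids
    of OTUs excluded for having fewer than ``min_pairs`` informative pairs or
    zero variance.

    Adjusted R2 for the single-predictor fit is
    ``1 - (1 - R2) * (n - 1) / (n - 2)``.
    """
    values_a = _relative(table_a) if not raw_counts else table_a.counts.astype(float)
    values_b = _relative(table_b) if not raw_counts else table_b.counts.astype(float)
    seq_rows_a = {table_a.seqs[h]: h for h in table_a.counts.index}
    seq_rows_b = {table_b.seqs[h]: h for h in table_b.counts.index}
    sites = sorted(set(values_a.columns) | set(values_b.columns))
    results: list[tuple[str, float]] = []
    excluded: list[str] = []
    for oa, ob in _match_otus(table_a, table_b):
        seqs = {table_a.seqs[h] for h, o in table_a.otu_of.items() if o == oa}
        seqs |= {table_b.seqs[h] for h, o in table_b.otu_of.items() if o == ob}
        xs, ys = [], []
        for seq in sorted(seqs):
            for site in sites:
                xa = (
                    float(values_a.at[seq_rows_a[seq], site])
                    if seq in seq_rows_a and site in values_a.columns
                    else 0.0
                )
                yb = (
                    float(values_b.at[seq_rows_b[seq], site])
                    if seq in seq_rows_b and site in values_b.columns
                    else 0.0
                )
                if xa > 0 or yb > 0:
                    xs.append(xa)
                    ys.append(yb)
        x = np.array(xs)
        y = np.array(ys)
        if len(x) < min_pairs or x.std() == 0 or y.std() == 0:
            excluded.append(oa)
            continue
        fit = sps.linregress(x, y)
        r2 = fit.rvalue**2
        n = len(x)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        results.append((oa, float(adj)))
    if results:
        vals = np.array([r for _, r in results])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    else:
        mean, sd = float("nan"), float("nan")
    return results, mean, sd, excluded


@dataclass
class TruthComparison:
    expected_hits: list[tuple[str, str]]  # (truth id, seq) recovered exactly
    unexpected: list[tuple[str, float]]  # (seq, relative abundance) above floor
    missed: list[tuple[str, str]]  # truth entries absent from the output
    in_both_replicates: set[str] | None = None  # seqs found in both runs


def classify_against_truth(
    haplotypes: list[Haplotype],
    truth: TruthSet,
    floor: float = 0.0,
    second_run: list[Haplotype] | None = None,
) -> TruthComparison:
    """Partition observed haplotypes into expected (exact truth match) and
    unexpected, above a relative-abundance floor computed per run against
    that run's total mapped reads."""
    if floor < 0:
        raise ValueError("floor must be >= 0")

    def _above(haps: list[Haplotype]) -> dict[str, float]:
        total = sum(h.total for h in haps)
        if total == 0:
            return {}
        return {
            h.seq: h.total / total for h in haps if h.total / total >= floor
        }

    observed = _above(haplotypes)
    truth_seqs = truth.seqs
    expected_hits = [(tid, s) for tid, s in truth.expected if s in observed]
    unexpected = sorted(
        ((s, f) for s, f in observed.items() if s not in truth_seqs),
        key=lambda t: (-t[1], t[0]),
    )
    missed = [(tid, s) for tid, s in truth.expected if s not in observed]
    in_both = None
    if second_run is not None:
        in_both = set(observed) & set(_above(second_run))
    return TruthComparison(
        expected_hits=expected_hits,
        unexpected=unexpected,
        missed=missed,
        in_both_replicates=in_both,
    )
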