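"""Abundance-skew denoising of pooled amplicon reads.

The chain implemented here: a per-sample abundance prefilter (absolute and
relative floors), pooling of per-sample uniques, a greedy single-pass
denoiser in which a low-abundance unique is absorbed as sequencing noise of
an accepted centroid when its abundance skew falls below
``beta(d) = 1 / 2^(alpha * d + 1)`` at edit distance d, and a de novo
two-parent single-crossover chimera flagger.

Lower alpha shrinks beta and therefore merges more variants into centroids
(stricter denoising); higher alpha leaves more variants standing as
independent haplotypes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .seqio import UniqueSeq

__all__ = [
    "DenoiseParams",
    "Haplotype",
    "edit_distance",
    "prefilter",
    "pool",
    "skew_threshold",
    "denoise",
    "flag_chimeras",
]


@dataclass
class DenoiseParams:
    """Knobs of the denoising chain.

    alpha       skew strictness; beta(d) = 1/2^(alpha*d + 1)
    min_abs     per-sample minimum copy number (reads) for a unique to count
    min_rel     per-sample minimum relative abundance (fraction of the
                sample's post-preprocessing reads); 1e-5 is 0.001%
    chimera_check  flag and exclude exact two-parent splices
    """

    alpha: float = 5.0
    min_abs: int = 10
    min_rel: float = 1e-5
    chimera_check: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.min_abs < 1:
            raise ValueError("min_abs must be >= 1")
        if not 0 <= self.min_rel < 1:
            raise ValueError("min_rel must be in [0, 1)")


@dataclass
class Haplotype:
    """A denoised centroid with full noise-assignment provenance.

    ``counts`` holds the centroid's own dereplicated reads plus the reads of
    every absorbed noise member; ``centroid_size`` is the founding unique's
    own total, the denominator used for skew decisions.
    """

    seq: str
    counts: dict[str, int]
    centroid_size: int
    members: list[tuple[str, int, int]] = field(default_factory=list)  # (seq, size, d)
    flags: set[str] = field(default_factory=set)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def edit_distance(a: str, b: str, k: int | None = None) -> int:
    """Unit-cost Levenshtein distance; -1 when a cap k is given and exceeded."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance", k=-1 if k is None else k)["editDistance"]


def prefilter(
    uniques: list[UniqueSeq],
    sample_totals: dict[str, int],
    min_abs: int = 10,
    min_rel: float = 1e-5,
) -> list[UniqueSeq]:
    """Zero per-sample counts that miss either abundance floor; drop empty uniques.

    A count survives in a sample only when it is both >= min_abs copies and
    >= min_rel of that sample's total reads (boundaries inclusive).
    """
    out = []
    for u in uniques:
        kept: dict[str, int] = {}
        for sample, n in u.counts.items():
            if sample not in sample_totals:
                raise KeyError(f"unknown sample id {sample!r} in unique counts")
            tot = sample_totals[sample]
            if n >= min_abs and tot > 0 and n / tot >= min_rel:
                kept[sample] = n
        if kept:
            out.append(UniqueSeq(seq=u.seq, counts=kept))
    return out


def pool(per_sample_uniques: list[list[UniqueSeq]]) -> list[UniqueSeq]:
    """Merge per-sample unique lists: identical sequences union their counts."""
    merged: dict[str, dict[str, int]] = {}
    for uniques in per_sample_uniques:
        for u in uniques:
            bucket = merged.setdefault(u.seq, {})
            for sample, n in u.counts.items():
                bucket[sample] = bucket.get(sample, 0) + n
    out = [UniqueSeq(seq=s, counts=c) for s, c in merged.items()]
    out.sort(key=lambda u: (-u.total, u.seq))
    return out


def skew_threshold(d: int, alpha: float) -> float:
    """beta(d) = 1 / 2^(alpha*d + 1); the maximum noise/parent abundance ratio
    at edit distance d. Identical sequences (d=0) are merged by dereplication,
    never by skew."""
    if d < 1:
        raise ValueError("skew threshold is defined for d >= 1 only")
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def _max_absorbable_d(size_u: int, size_c: int, alpha: float) -> int:
    """Largest d at which size_u/size_c <= beta(d); 0 when none."""
    ratio = size_u / size_c
    if ratio > 0.5:
        return 0
    # beta is decreasing in d, so walk up from 1; d is bounded by
    # (log2(size_c/size_u) - 1) / alpha which is small in practice
    d = 0
    while ratio <= skew_threshold(d + 1, alpha):
        d += 1
    return d


def denoise(pooled: list[UniqueSeq], params: DenoiseParams) -> list[Haplotype]:
    """Greedy single-pass abundance-skew denoising.

    Uniques are visited by total count descending (ties lexicographic by
    sequence). The first always founds a centroid. Each later unique u is
    absorbed by the qualifying centroid (skew size_u/size_c <= beta(d)) with
    the smallest edit distance d, ties broken by larger centroid size then
    lexicographic centroid sequence; with no qualifying centroid, u founds a
    new one. Absorption adds u's per-sample counts to the centroid and records
    (seq, size, d) in the centroid's members.
    """
    order = sorted(pooled, key=lambda u: (-u.total, u.seq))
    centroids: list[Haplotype] = []
    for u in order:
        size_u = u.total
        best: tuple[int, int, str] | None = None  # (d, -size_c, seq)
        best_c: Haplotype | None = None
        for c in centroids:
            k = _max_absorbable_d(size_u, c.centroid_size, params.alpha)
            if k < 1:
                continue
            if best is not None and best[0] == 1:
                # cannot beat d=1 on distance; only better ties remain
                k = 1
            d = edit_distance(u.seq, c.seq, k=k)
            if d <= 0:
                continue  # -1: beyond cap; 0 impossible after dereplication
            key = (d, -c.centroid_size, c.seq)
            if best is None or key < best:
                best, best_c = key, c
        if best_c is None:
            centroids.append(
                Haplotype(seq=u.seq, counts=dict(u.counts), centroid_size=size_u)
            )
        else:
            for sample, n in u.counts.items():
                best_c.counts[sample] = best_c.counts.get(sample, 0) + n
            best_c.members.append((u.seq, size_u, best[0]))
    return centroids


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def flag_chimeras(centroids: list[Haplotype]) -> list[Haplotype]:
    """Flag centroids that are exact two-parent single-crossover splices.

    x gains the ``chimera`` flag when two distinct centroids a, b exist, each
    with total abundance >= 2x that of x, and a crossover 1 <= k < len(x) with
    x == a[:k] + b[k:] exactly. Flagged centroids stay in the returned list;
    downstream table building excludes them.
    """
    totals = [c.total for c in centroids]
    for i, x in enumerate(centroids):
        L = len(x.seq)
        if L < 2:
            continue
        parents = [c for j, c in enumerate(centroids) if j != i and totals[j] >= 2 * totals[i]]
        if len(parents) < 2:
            continue
        # x == a[:k] + b[k:]  <=>  lcp(x,a) >= k and lcs(x,b) >= L-k (len(b)==L)
        pref = [(_common_prefix_len(x.seq, a.seq), a) for a in parents]
        suf = [
            (_common_prefix_len(x.seq[::-1], b.seq[::-1]), b)
            for b in parents
            if len(b.seq) == L
        ]
        pref.sort(key=lambda t: -t[0])
        suf.sort(key=lambda t: -t[0])
        flagged = False
        for lp, a in pref[:2]:
            if lp == 0 or flagged:
                break
            for ls, b in suf[:2]:
                if b is not a and ls >= 1 and lp + ls >= L:
                    flagged = True
                    break
        if flagged:
            x.flags.add("chimera")
    return centroids
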