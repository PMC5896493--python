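"""Read pre-processing: pair merging, primer trimming with orientation
normalization, expected-error filtering, exact-length filtering, and
depth-equalizing subsampling.

Every stage is a pure function over lists of :class:`~haplopipe.seqio.QualityRead`;
:func:`preprocess_reads` chains them and accounts for every read
(kept + rejected == input at each boundary).
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .seqio import QualityRead, revcomp

__all__ = [
    "PrimerPair",
    "PreprocessParams",
    "SubsampleDepthError",
    "merge_pairs",
    "trim_and_orient",
    "expected_error",
    "filter_ee",
    "filter_exact_length",
    "subsample",
    "preprocess_reads",
]

# IUPAC degenerate base -> set of plain bases it matches
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass
class PrimerPair:
    """Forward/reverse amplification primers and the expected insert length.

    ``max_mismatch`` of None means ceil(10% of primer length), evaluated per
    primer. Primers are matched anchored at the read ends, IUPAC-aware.
    """

    fwd: str
    rev: str
    target_len: int
    max_mismatch: int | None = None

    def __post_init__(self) -> None:
        self.fwd = self.fwd.upper()
        self.rev = self.rev.upper()
        if not self.fwd or not self.rev:
            raise ValueError("primers must be non-empty")
        if self.target_len <= 0:
            raise ValueError("target_len must be positive")
        for p in (self.fwd, self.rev):
            bad = set(p) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"non-IUPAC characters in primer: {sorted(bad)}")

    def allowance(self, primer: str) -> int:
        if self.max_mismatch is not None:
            return self.max_mismatch
        return math.ceil(0.1 * len(primer))


@dataclass
class PreprocessParams:
    max_ee: float = 0.5
    subsample_n: int | None = None
    seed: int = 0
    min_overlap: int = 16
    max_overlap_mismatch_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.max_ee < 0:
            raise ValueError("max_ee must be >= 0")
        if self.subsample_n is not None and self.subsample_n < 1:
            raise ValueError("subsample_n must be >= 1")


class SubsampleDepthError(ValueError):
    pass


def _mismatches(primer: str, region: str) -> int:
    """IUPAC-aware mismatch count; an N in the read only matches primer N."""
    return sum(base not in IUPAC_SETS[p] for p, base in zip(primer, region))


def merge_pairs(
    fwd: QualityRead,
    rev: QualityRead,
    min_overlap: int = 16,
    max_overlap_mismatch_frac: float = 0.25,
) -> QualityRead | None:
    """Merge a read pair by the best ungapped overlap, or None on reject.

    The reverse read is reverse-complemented (qualities reversed), then every
    3'-overlap of length >= min_overlap is scored by matches minus mismatches.
    In the winning overlap, agreeing bases keep the higher Phred score and
    disagreements take the higher-Phred base with quality ``|Q1 - Q2|``
    (forward base on an exact quality tie). Rejected when no overlap reaches
    min_overlap or the best overlap's mismatch fraction exceeds the ceiling.
    """
    if not fwd.seq or not rev.seq:
        return None
    rc_seq = revcomp(rev.seq)
    rc_qual = rev.qual[::-1]
    lf, lr = len(fwd.seq), len(rc_seq)
    best: tuple[int, int] | None = None  # (score, overlap_len)
    for ov in range(min_overlap, min(lf, lr) + 1):
        a = fwd.seq[lf - ov:]
        b = rc_seq[:ov]
        matches = sum(x == y for x, y in zip(a, b))
        score = 2 * matches - ov  # matches - mismatches
        if best is None or score > best[0] or (score == best[0] and ov > best[1]):
            best = (score, ov)
    if best is None:
        return None
    score, ov = best
    mismatches = (ov - score) // 2
    if ov and mismatches / ov > max_overlap_mismatch_frac:
        return None
    seq = list(fwd.seq[: lf - ov])
    qual = list(fwd.qual[: lf - ov])
    for i in range(ov):
        fa, qa = fwd.seq[lf - ov + i], int(fwd.qual[lf - ov + i])
        fb, qb = rc_seq[i], int(rc_qual[i])
        if fa == fb:
            seq.append(fa)
            qual.append(max(qa, qb))
        elif qb > qa:
            seq.append(fb)
            qual.append(qb - qa)
        else:
            seq.append(fa)
            qual.append(qa - qb)
    seq.extend(rc_seq[ov:])
    qual.extend(rc_qual[ov:])
    return QualityRead(id=fwd.id, seq="".join(seq), qual=np.array(qual, dtype=np.int16))


def trim_and_orient(read: QualityRead, primers: PrimerPair) -> QualityRead | None:
    """Strip primers, reverse-complementing the read first if needed.

    A read in forward orientation starts with the forward primer and ends with
    the reverse complement of the reverse primer; in reverse orientation the
    roles are swapped. Reads matching neither orientation within the mismatch
    allowance are rejected (None).
    """
    nf, nr = len(primers.fwd), len(primers.rev)
    if len(read.seq) < nf + nr + 1:
        return None
    rc_rev = revcomp(primers.rev)

    def _attempt(seq: str, qual: np.ndarray) -> QualityRead | None:
        head = _mismatches(primers.fwd, seq[:nf])
        if head > primers.allowance(primers.fwd):
            return None
        # the 3' end carries revcomp(rev primer); compare against the rev
        # primer on the reverse-complemented tail for IUPAC correctness
        tail = _mismatches(primers.rev, revcomp(seq[len(seq) - nr:]))
        if tail > primers.allowance(primers.rev):
            return None
        return QualityRead(id=read.id, seq=seq[nf:len(seq) - nr], qual=qual[nf:len(seq) - nr])

    out = _attempt(read.seq, read.qual)
    if out is not None:
        return out
    return _attempt(revcomp(read.seq), read.qual[::-1])


def expected_error(read: QualityRead) -> float:
    """Sum of per-base error probabilities, ee = sum_i 10^(-Q_i / 10)."""
    if len(read.qual) == 0:
        return 0.0
    return float(np.sum(10.0 ** (-read.qual / 10.0)))


def filter_ee(reads: list[QualityRead], max_ee: float) -> list[QualityRead]:
    """Keep reads with expected error <= max_ee (boundary inclusive)."""
    return [r for r in reads if expected_error(r) <= max_ee]


def filter_exact_length(reads: list[QualityRead], target_len: int) -> list[QualityRead]:
    """Keep only reads of exactly the length targeted by the primer set."""
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    return [r for r in reads if len(r.seq) == target_len]


def subsample(reads: list[QualityRead], n: int, seed: int) -> list[QualityRead]:
    """Uniform sample of n reads without replacement, preserving input order."""
    if n > len(reads):
        raise SubsampleDepthError(
            f"cannot subsample {n} reads from {len(reads)}: lower the target "
            "depth so all samples can be equalized to it"
        )
    idx = sorted(random.Random(seed).sample(range(len(reads)), n))
    return [reads[i] for i in idx]


@dataclass
class StageStats:
    """Read accounting per preprocessing stage."""

    counts: dict[str, int] = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_kept: int) -> None:
        self.counts[f"{stage}_in"] = n_in
        self.counts[f"{stage}_kept"] = n_kept
        self.counts[f"{stage}_rejected"] = n_in - n_kept


def preprocess_reads(
    reads: list[QualityRead],
    primers: PrimerPair,
    params: PreprocessParams,
    pairs: list[tuple[QualityRead, QualityRead]] | None = None,
) -> tuple[list[QualityRead], StageStats]:
    """Run the full per-sample chain: [merge] -> trim -> ee -> length -> [subsample].

    Pass pre-merged reads via *reads*, or raw pairs via *pairs* (then *reads*
    is ignored). Returns kept reads plus per-stage accounting.
    """
    stats = StageStats()
    if pairs is not None:
        merged = []
        for f, r in pairs:
            m = merge_pairs(f, r, params.min_overlap, params.max_overlap_mismatch_frac)
            if m is not None:
                merged.append(m)
        stats.record("merge", len(pairs), len(merged))
        reads = merged

    trimmed = []
    for r in reads:
        t = trim_and_orient(r, primers)
        if t is not None:
            trimmed.append(t)
    stats.record("trim", len(reads), len(trimmed))

    ee_kept = filter_ee(trimmed, params.max_ee)
    stats.record("ee", len(trimmed), len(ee_kept))

    len_kept = filter_exact_length(ee_kept, primers.target_len)
    stats.record("length", len(ee_kept), len(len_kept))

    if params.subsample_n is not None:
        out = subsample(len_kept, params.subsample_n, params.seed)
        stats.record("subsample", len(len_kept), len(out))
    else:
        out = len_kept
    return out, stats
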