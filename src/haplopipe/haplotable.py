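"""OTU clustering of denoised haplotypes and multi-threshold table filtering.

Haplotypes are clustered into OTUs by greedy centroid clustering at a fixed
identity (default 97%), tabulated into a haplotype x sample count matrix, and
filtered by a cascade of relative-abundance and presence thresholds:

1. a haplotype must reach ``minhaplosize`` % of a sample's reads in at least
   one sample;
2. an OTU must reach ``OTUmin`` % in at least one sample;
3. within each OTU and sample, haplotypes below ``withinOTU`` % of that OTU's
   reads in that sample are zeroed;
4. rows zero everywhere are dropped;
5. haplotypes/OTUs present in fewer than ``minHaploPresence`` /
   ``minOTUPresence`` samples are dropped.

All thresholds retain the boundary (>= keeps). The cascade is re-applied
until the table is stable, which makes the filter idempotent by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .denoise import Haplotype, edit_distance

__all__ = ["OTU", "HaploTable", "FilterParams", "cluster_otus", "build_table", "filter_table"]


@dataclass
class OTU:
    id: str
    centroid_seq: str
    haplotype_ids: list[str]


@dataclass
class FilterParams:
    """Thresholds of the table filter; percentages are on a 0-100 scale."""

    minhaplosize: float = 0.01
    otumin: float = 0.1
    within_otu: float = 5.0
    min_haplo_presence: int = 1
    min_otu_presence: int = 1

    def __post_init__(self) -> None:
        for name in ("minhaplosize", "otumin", "within_otu"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        if self.min_haplo_presence < 1 or self.min_otu_presence < 1:
            raise ValueError("presence thresholds must be >= 1")


@dataclass
class HaploTable:
    """Haplotype x sample count matrix with OTU grouping.

    counts        integer DataFrame, index = haplotype ids, columns = samples
    otu_of        haplotype id -> OTU id
    seqs          haplotype id -> sequence
    otus          list of OTU (centroids and membership)
    sample_totals reads entering the table per sample (the relative-abundance
                  denominator for table-level thresholds)
    params_applied record of filters already applied
    """

    counts: pd.DataFrame
    otu_of: dict[str, str]
    seqs: dict[str, str]
    otus: list[OTU]
    sample_totals: pd.Series
    params_applied: dict = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.counts)

    @property
    def n_otus(self) -> int:
        return len({self.otu_of[h] for h in self.counts.index})

    def otu_counts(self) -> pd.DataFrame:
        """Column-wise sums of member haplotype rows, per OTU."""
        if self.counts.empty:
            return self.counts.copy()
        return self.counts.groupby(
            self.counts.index.map(self.otu_of)
        ).sum()


def cluster_otus(haplotypes: list[Haplotype], identity: float = 0.97) -> list[OTU]:
    """Greedy centroid clustering of haplotypes into OTUs.

    Haplotypes are processed by total abundance descending (ties
    lexicographic); each joins the first OTU (in founding order) whose
    centroid identity, 1 - editdist/max(len), meets the threshold, else
    founds a new OTU. Chimera-flagged haplotypes must be excluded upstream.
    Haplotype ids ("h1", ...) follow abundance order; OTU ids ("otu1", ...)
    follow founding order.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    order = sorted(haplotypes, key=lambda h: (-h.total, h.seq))
    hap_id = {h.seq: f"h{i}" for i, h in enumerate(order, 1)}
    otus: list[OTU] = []
    centroid_seqs: list[str] = []
    for h in order:
        joined = False
        for otu, cseq in zip(otus, centroid_seqs):
            max_len = max(len(h.seq), len(cseq))
            k = math.floor((1.0 - identity) * max_len)
            d = edit_distance(h.seq, cseq, k=k) if k >= 0 else (0 if h.seq == cseq else -1)
            if d >= 0 and 1.0 - d / max_len >= identity:
                otu.haplotype_ids.append(hap_id[h.seq])
                joined = True
                break
        if not joined:
            otus.append(
                OTU(id=f"otu{len(otus) + 1}", centroid_seq=h.seq, haplotype_ids=[hap_id[h.seq]])
            )
            centroid_seqs.append(h.seq)
    return otus


def build_table(
    otus: list[OTU],
    haplotypes: list[Haplotype],
    sample_totals: dict[str, int] | pd.Series,
) -> HaploTable:
    """Assemble the haplotype x sample table from clustered haplotypes.

    Chimera-flagged haplotypes are excluded. Every remaining haplotype must
    belong to exactly one OTU.
    """
    order = sorted(haplotypes, key=lambda h: (-h.total, h.seq))
    hap_id = {h.seq: f"h{i}" for i, h in enumerate(order, 1)}
    id_to_otu: dict[str, str] = {}
    for otu in otus:
        for hid in otu.haplotype_ids:
            id_to_otu[hid] = otu.id
    kept = [h for h in order if "chimera" not in h.flags]
    for h in kept:
        if hap_id[h.seq] not in id_to_otu:
            raise ValueError(f"haplotype {hap_id[h.seq]} has no OTU assignment")
    samples = sorted(
        set(sample_totals.keys() if isinstance(sample_totals, dict) else sample_totals.index)
        | {s for h in kept for s in h.counts}
    )
    rows = {
        hap_id[h.seq]: [h.counts.get(s, 0) for s in samples] for h in kept
    }
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples).astype(int)
    totals = pd.Series(sample_totals, dtype=float).reindex(samples).fillna(0.0)
    kept_ids = set(counts.index)
    otus_kept = [
        replace(otu, haplotype_ids=[h for h in otu.haplotype_ids if h in kept_ids])
        for otu in otus
    ]
    otus_kept = [o for o in otus_kept if o.haplotype_ids]
    return HaploTable(
        counts=counts,
        otu_of={h: id_to_otu[h] for h in counts.index},
        seqs={hap_id[h.seq]: h.seq for h in kept},
        otus=otus_kept,
        sample_totals=totals,
    )


def _one_pass(table: HaploTable, params: FilterParams) -> HaploTable:
    df = table.counts.copy()
    totals = table.sample_totals.reindex(df.columns).astype(float)
    safe_totals = totals.replace(0, float("nan"))

    # (1) haplotype-level floor: reach minhaplosize% in at least one sample
    if not df.empty:
        rel = df.div(safe_totals, axis=1) * 100.0
        df = df.loc[rel.max(axis=1).fillna(0) >= params.minhaplosize]

    # (2) OTU-level floor on summed member rows
    if not df.empty:
        otu_idx = df.index.map(table.otu_of)
        otu_sum = df.groupby(otu_idx).sum()
        otu_rel = otu_sum.div(safe_totals, axis=1) * 100.0
        good_otus = set(otu_rel.index[otu_rel.max(axis=1).fillna(0) >= params.otumin])
        df = df.loc[[o in good_otus for o in otu_idx]]

    # (3) within-OTU share per sample, on post-(2) OTU counts
    if not df.empty:
        otu_idx = df.index.map(table.otu_of)
        otu_sum = df.groupby(otu_idx).sum()
        denom = otu_sum.reindex(otu_idx).to_numpy().astype(float)
        share = df.to_numpy() / pd.DataFrame(denom).replace(0, float("nan")).to_numpy() * 100.0
        keep_mask = pd.DataFrame(share, index=df.index, columns=df.columns) >= params.within_otu
        df = df.where(keep_mask.fillna(False), 0)

    # (4) drop rows now zero everywhere
    if not df.empty:
        df = df.loc[df.sum(axis=1) > 0]

    # (5) presence filters
    if not df.empty:
        present = (df > 0).sum(axis=1)
        df = df.loc[present >= params.min_haplo_presence]
    if not df.empty:
        otu_idx = df.index.map(table.otu_of)
        otu_present = (df.groupby(otu_idx).sum() > 0).sum(axis=1)
        good_otus = set(otu_present.index[otu_present >= params.min_otu_presence])
        df = df.loc[[o in good_otus for o in otu_idx]]

    kept_ids = set(df.index)
    otus_kept = [
        replace(o, haplotype_ids=[h for h in o.haplotype_ids if h in kept_ids])
        for o in table.otus
    ]
    otus_kept = [o for o in otus_kept if o.haplotype_ids]
    return HaploTable(
        counts=df.astype(int),
        otu_of={h: table.otu_of[h] for h in df.index},
        seqs={h: table.seqs[h] for h in df.index},
        otus=otus_kept,
        sample_totals=table.sample_totals,
        params_applied=dict(table.params_applied),
    )


def filter_table(table: HaploTable, params: FilterParams) -> HaploTable:
    """Apply the threshold cascade; re-run until stable so the operation is
    idempotent (zeroing in step 3 can re-expose rows to steps 1-2)."""
    current = table
    for _ in range(max(1, len(table.counts) + 1)):
        nxt = _one_pass(current, params)
        if nxt.counts.shape == current.counts.shape and (
            nxt.counts.empty or nxt.counts.equals(current.counts)
        ):
            current = nxt
            break
        current = nxt
    current.params_applied.update(
        {
            "minhaplosize": params.minhaplosize,
            "otumin": params.otumin,
            "within_otu": params.within_otu,
            "min_haplo_presence": params.min_haplo_presence,
            "min_otu_presence": params.min_otu_presence,
        }
    )
    return current
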