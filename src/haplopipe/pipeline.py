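"""End-to-end pipeline: preprocess -> prefilter -> pool -> denoise ->
chimera flag -> OTU clustering -> haplotype table -> threshold filter ->
population-genetic exports, with per-stage read accounting.

Also houses the on-disk table format used by the command-line interface:
a TSV whose first data row (id ``TOTAL``) carries the per-sample read totals
that serve as relative-abundance denominators.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .denoise import (
    DenoiseParams,
    Haplotype,
    denoise as _denoise,
    flag_chimeras,
    pool as _pool,
    prefilter as _prefilter,
)
from . import haplotable as ht
from . import popgen
from .preprocess import PreprocessParams, PrimerPair, preprocess_reads
from .seqio import (
    QualityRead,
    UniqueSeq,
    dereplicate,
    read_fastq,
    write_fasta_sized,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_pipeline_reads",
           "save_table", "load_table", "save_network"]


@dataclass
class RunConfig:
    manifest_path: str
    primers: PrimerPair
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    filter: ht.FilterParams = field(default_factory=ht.FilterParams)
    otu_identity: float = 0.97
    out_dir: str = "run"
    seed: int = 0
    phred_offset: int = 33

    def to_dict(self) -> dict:
        return {
            "manifest_path": self.manifest_path,
            "primers": {
                "fwd": self.primers.fwd,
                "rev": self.primers.rev,
                "target_len": self.primers.target_len,
                "max_mismatch": self.primers.max_mismatch,
            },
            "preprocess": vars(self.preprocess).copy(),
            "denoise": vars(self.denoise).copy(),
            "filter": vars(self.filter).copy(),
            "otu_identity": self.otu_identity,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "phred_offset": self.phred_offset,
        }


@dataclass
class PipelineResult:
    table: ht.HaploTable
    filtered: ht.HaploTable
    haplotypes: list[Haplotype]
    otus: list[ht.OTU]
    sample_totals: dict[str, int]
    stage_summary: dict

    @property
    def report(self) -> dict:
        mean, sd, per_otu, degenerate = (
            popgen.haplotypes_per_otu(self.filtered)
            if not self.filtered.counts.empty
            else (0.0, 0.0, {}, True)
        )
        return {
            "n_otus": self.filtered.n_otus,
            "n_haplotypes": self.filtered.n_haplotypes,
            "mean_haplotypes_per_otu": mean,
            "sd_haplotypes_per_otu": sd,
            "sd_degenerate": degenerate,
        }


def run_pipeline_reads(
    per_sample_reads: dict[str, list[QualityRead]],
    primers: PrimerPair,
    preprocess_params: PreprocessParams,
    denoise_params: DenoiseParams,
    filter_params: ht.FilterParams | None = None,
    otu_identity: float = 0.97,
) -> PipelineResult:
    """Run the whole chain on in-memory reads keyed by sample id."""
    stage_summary: dict = {"samples": {}}
    per_sample_uniques: list[list[UniqueSeq]] = []
    sample_totals: dict[str, int] = {}
    uniques_by_sample: dict[str, list[UniqueSeq]] = {}
    for sample_id in sorted(per_sample_reads):
        kept, stats = preprocess_reads(
            per_sample_reads[sample_id], primers, preprocess_params
        )
        sample_totals[sample_id] = len(kept)
        uniques_by_sample[sample_id] = dereplicate(kept, sample_id)
        stage_summary["samples"][sample_id] = {
            **stats.counts,
            "unique_sequences": len(uniques_by_sample[sample_id]),
        }
    # the prefilter's relative floor needs every sample's final total, so it
    # runs only after the whole preprocessing sweep
    for sample_id in sorted(per_sample_reads):
        filtered_uniques = _prefilter(
            uniques_by_sample[sample_id],
            sample_totals,
            min_abs=denoise_params.min_abs,
            min_rel=denoise_params.min_rel,
        )
        stage_summary["samples"][sample_id]["uniques_after_prefilter"] = len(
            filtered_uniques
        )
        per_sample_uniques.append(filtered_uniques)

    pooled = _pool(per_sample_uniques)
    stage_summary["pooled_uniques"] = len(pooled)
    stage_summary["pooled_reads"] = sum(u.total for u in pooled)

    haplotypes = _denoise(pooled, denoise_params)
    if denoise_params.chimera_check:
        haplotypes = flag_chimeras(haplotypes)
    clean = [h for h in haplotypes if "chimera" not in h.flags]
    stage_summary["centroids"] = len(haplotypes)
    stage_summary["chimera_flagged"] = len(haplotypes) - len(clean)
    stage_summary["chimera_reads"] = sum(
        h.total for h in haplotypes if "chimera" in h.flags
    )

    otus = ht.cluster_otus(clean, identity=otu_identity)
    table_totals = {
        s: sum(h.counts.get(s, 0) for h in clean) for s in sample_totals
    }
    table = ht.build_table(otus, clean, table_totals)
    filtered = (
        ht.filter_table(table, filter_params) if filter_params is not None else table
    )
    stage_summary["otus"] = len(otus)
    stage_summary["haplotypes_after_filter"] = filtered.n_haplotypes
    return PipelineResult(
        table=table,
        filtered=filtered,
        haplotypes=haplotypes,
        otus=otus,
        sample_totals=sample_totals,
        stage_summary=stage_summary,
    )


def run_pipeline(config: RunConfig) -> Path:
    """File-based end-to-end run; returns the run directory.

    Samples are read from the manifest (paired files are merged), replicates
    are treated as separate samples named ``<sample>.<replicate>``, and all
    outputs plus per-stage summaries land under ``config.out_dir``.
    """
    from .seqio import read_manifest

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest_path)
    per_sample: dict[str, list[QualityRead]] = {}
    pairs_of: dict[str, list[tuple[QualityRead, QualityRead]]] = {}
    for entry in manifest:
        name = f"{entry.sample_id}.{entry.replicate_id}"
        if entry.reverse_path:
            fwd = list(read_fastq(entry.forward_path, config.phred_offset))
            rev = list(read_fastq(entry.reverse_path, config.phred_offset))
            if len(fwd) != len(rev):
                raise ValueError(f"{name}: unpaired FASTQ files")
            pairs_of[name] = list(zip(fwd, rev))
            per_sample[name] = []
        else:
            per_sample[name] = list(read_fastq(entry.forward_path, config.phred_offset))

    # merge pairs up front so the in-memory driver sees single reads
    from .preprocess import merge_pairs

    merge_stats = {}
    for name, pairs in pairs_of.items():
        merged = []
        for f, r in pairs:
            m = merge_pairs(
                f,
                r,
                config.preprocess.min_overlap,
                config.preprocess.max_overlap_mismatch_frac,
            )
            if m is not None:
                merged.append(m)
        merge_stats[name] = {"pairs_in": len(pairs), "merged": len(merged)}
        per_sample[name] = merged

    result = run_pipeline_reads(
        per_sample,
        config.primers,
        config.preprocess,
        config.denoise,
        config.filter,
        config.otu_identity,
    )
    for name, ms in merge_stats.items():
        result.stage_summary["samples"][name].update(ms)

    clean = [h for h in result.haplotypes if "chimera" not in h.flags]
    write_fasta_sized(
        [UniqueSeq(seq=h.seq, counts=h.counts) for h in clean],
        out / "haplotype_centroids.fasta",
    )
    members = [
        {"centroid": h.seq, "member": m_seq, "size": m_size, "distance": m_d}
        for h in result.haplotypes
        for m_seq, m_size, m_d in h.members
    ]
    pd.DataFrame(members, columns=["centroid", "member", "size", "distance"]).to_csv(
        out / "members.tsv", sep="\t", index=False
    )
    save_table(result.table, out / "haplotype_table.tsv")
    save_table(result.filtered, out / "haplotype_table.filtered.tsv")
    result.filtered.otu_counts().to_csv(out / "otu_table.tsv", sep="\t")
    for otu in result.filtered.otus:
        net = popgen.build_network(result.filtered, otu.id)
        save_network(net, out / f"network_{otu.id}.tsv")
    freq_records = [
        rec
        for otu in result.filtered.otus
        for rec in popgen.site_frequencies(result.filtered, otu.id)
    ]
    pd.DataFrame(
        freq_records, columns=["otu", "site", "haplotype", "frequency"]
    ).to_csv(out / "site_frequencies.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "config": config.to_dict(),
                "stages": result.stage_summary,
                "report": result.report,
            },
            fh,
            indent=2,
        )
    return out


# ---------------------------------------------------------------------------
# on-disk table format

def save_table(table: ht.HaploTable, path: str | Path) -> None:
    samples = list(table.counts.columns)
    rows = [
        {
            "haplotype": "TOTAL",
            "otu": "-",
            "seq": "-",
            **{s: int(table.sample_totals.get(s, 0)) for s in samples},
        }
    ]
    for hap in table.counts.index:
        rows.append(
            {
                "haplotype": hap,
                "otu": table.otu_of[hap],
                "seq": table.seqs[hap],
                **{s: int(table.counts.at[hap, s]) for s in samples},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> ht.HaploTable:
    df = pd.read_csv(path, sep="\t", dtype={"haplotype": str, "otu": str, "seq": str})
    samples = [c for c in df.columns if c not in ("haplotype", "otu", "seq")]
    totals_row = df[df["haplotype"] == "TOTAL"]
    data = df[df["haplotype"] != "TOTAL"].set_index("haplotype")
    sample_totals = (
        totals_row[samples].iloc[0].astype(float)
        if len(totals_row)
        else data[samples].sum().astype(float)
    )
    otu_of = data["otu"].to_dict()
    seqs = data["seq"].to_dict()
    counts = data[samples].astype(int)
    otu_ids: dict[str, list[str]] = {}
    for hap, otu in otu_of.items():
        otu_ids.setdefault(otu, []).append(hap)
    otus = []
    for otu, haps in otu_ids.items():
        centroid = max(haps, key=lambda h: (counts.loc[h].sum(), h))
        otus.append(ht.OTU(id=otu, centroid_seq=seqs[centroid], haplotype_ids=haps))
    return ht.HaploTable(
        counts=counts,
        otu_of=otu_of,
        seqs=seqs,
        otus=otus,
        sample_totals=pd.Series(sample_totals),
    )


def save_network(net: popgen.HaploNetwork, path: str | Path) -> None:
    pd.DataFrame(
        net.edges, columns=["haplotype_a", "haplotype_b", "bp_differences"]
    ).to_csv(path, sep="\t", index=False)
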