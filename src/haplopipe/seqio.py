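"""Sequence I/O and sample bookkeeping.

Reads 4-line FASTQ (plain or gzipped), writes/reads size-annotated FASTA in
the dereplicated-amplicon dialect (``>id;size=N``), dereplicates reads into
per-sample unique sequences, and parses tab-separated sample manifests.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "QualityRead",
    "UniqueSeq",
    "ManifestEntry",
    "SampleManifest",
    "FastqParseError",
    "revcomp",
    "read_fastq",
    "write_fastq",
    "write_fasta_sized",
    "read_fasta_sized",
    "dereplicate",
    "read_manifest",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; message names the offending line."""


@dataclass
class QualityRead:
    """A single read with per-base Phred quality scores."""

    id: str
    seq: str
    qual: np.ndarray  # integer Phred scores, same length as seq

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if len(self.qual) and self.qual.min() < 0:
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class UniqueSeq:
    """A dereplicated sequence with read counts attributed per sample."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def has_ambiguous(self) -> bool:
        """True if the sequence contains any non-ACGT character."""
        return any(c not in "ACGT" for c in self.seq)


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    replicate_id: str
    forward_path: str
    reverse_path: str | None = None


@dataclass
class SampleManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        keys = [(e.sample_id, e.replicate_id) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sample_id, replicate_id) in manifest")

    def __iter__(self) -> Iterator[ManifestEntry]:
        return iter(self.entries)


def read_manifest(path: str | Path) -> SampleManifest:
    """Parse a tab/whitespace-separated manifest: sample, replicate, path[, path2]."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"manifest line {lineno}: expected at least 3 fields, got {len(parts)}"
                )
            entries.append(
                ManifestEntry(
                    sample_id=parts[0],
                    replicate_id=parts[1],
                    forward_path=parts[2],
                    reverse_path=parts[3] if len(parts) > 3 else None,
                )
            )
    return SampleManifest(entries)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[QualityRead]:
    """Yield reads from a 4-line FASTQ file, gzipped or plain.

    Sequences are uppercase-normalized. Malformed records raise
    :class:`FastqParseError` naming the line number.
    """
    if phred_offset not in (33, 64):
        raise ValueError(f"phred_offset must be 33 or 64, got {phred_offset}")
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@' header")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqParseError(f"line {lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(f"line {lineno - 1}: expected '+' separator")
            seq = seq.strip().upper()
            qual = qual.strip()
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int16
            ) - phred_offset
            if len(scores) and scores.min() < 0:
                raise FastqParseError(
                    f"line {lineno}: quality character below Phred offset {phred_offset}"
                )
            yield QualityRead(id=header[1:].strip(), seq=seq, qual=scores)


def write_fastq(reads: Iterable[QualityRead], path: str | Path, phred_offset: int = 33) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = (r.qual + phred_offset).astype(np.uint8).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_fasta_sized(uniques: list[UniqueSeq], path: str | Path) -> None:
    """Write uniques as FASTA with ``;size=N`` header annotations.

    Records are sorted by total count descending, ties broken by sequence
    (lexicographic), matching the convention of dereplicated-amplicon tools.
    """
    ordered = sorted(uniques, key=lambda u: (-u.total, u.seq))
    records = [
        SeqRecord(Seq(u.seq), id=f"u{i};size={u.total}", description="")
        for i, u in enumerate(ordered, 1)
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def read_fasta_sized(path: str | Path) -> list[tuple[str, int]]:
    """Parse a size-annotated FASTA; returns (seq, size) in file order.

    Accepts ``;size=N`` and ``;size=N;`` header dialects; a record without a
    size annotation counts as size 1.
    """
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            size = 1
            for token in rec.id.split(";"):
                if token.startswith("size="):
                    size = int(token[5:])
            out.append((str(rec.seq).upper(), size))
    return out


def dereplicate(reads: Iterable[QualityRead], sample_id: str) -> list[UniqueSeq]:
    """Collapse reads into unique sequences by exact string identity.

    Counts are attributed to *sample_id*; the sum of totals equals the number
    of input reads. Output is sorted by count descending, ties lexicographic.
    """
    tally: dict[str, int] = {}
    for r in reads:
        tally[r.seq] = tally.get(r.seq, 0) + 1
    uniques = [UniqueSeq(seq=s, counts={sample_id: n}) for s, n in tally.items()]
    uniques.sort(key=lambda u: (-u.total, u.seq))
    return uniques
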