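"""Mock-community and multi-species read simulators with full ground truth.

Two designs are emulated. The single-species mock follows the validation
experiment this pipeline is calibrated on: 31 specimens carrying 15 distinct
178-bp COI haplotypes, specimen biomass spanning three orders of magnitude,
read share proportional to biomass, sequenced in two PCR replicates. The
multi-species community generator produces divergent OTUs, each carrying a
handful of closely related haplotypes whose frequencies vary across sites
(optionally with a monotone north-south cline for one focal haplotype).

Error model: per-base substitutions whose probability varies mildly along
the read (higher toward the 3' end), rare indels, and two-template chimeras
spliced at a uniform crossover. Emitted Phred scores report the per-base
substitution probability actually used (capped at the profile mean), so
expected-error filtering sees honest qualities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import IUPAC_SETS
from .seqio import QualityRead, revcomp

__all__ = [
    "QualityProfile",
    "ErrorModel",
    "MockSpec",
    "CommunitySpec",
    "MockTruth",
    "CommunityTruth",
    "make_haplotypes",
    "assign_biomass",
    "sequence_reads",
    "simulate_mock",
    "make_community",
    "DEFAULT_FWD_PRIMER",
    "DEFAULT_REV_PRIMER",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i

# Short degenerate COI primers of the style used for 178-bp fragments
DEFAULT_FWD_PRIMER = "YTCHACWAAYCAYAARGA"
DEFAULT_REV_PRIMER = "ARYATDGTRATDGCHCCDGC"


@dataclass
class QualityProfile:
    """Phred emission: ``mean_q`` at the 5' end decaying by ``end_decay``
    toward the 3' end."""

    mean_q: int = 35
    end_decay: int = 5

    def baseline(self, length: int) -> np.ndarray:
        pos = np.linspace(0.0, 1.0, length) if length > 1 else np.zeros(1)
        return np.round(self.mean_q - self.end_decay * pos).astype(np.int16)


@dataclass
class ErrorModel:
    """Per-read error process.

    sub_rate      mean per-base substitution probability (position-shaped)
    indel_rate    per-base insertion/deletion probability
    chimera_frac  fraction of reads spliced from two distinct templates
    """

    sub_rate: float = 0.002
    indel_rate: float = 0.0002
    chimera_frac: float = 0.01
    quality_profile: QualityProfile = field(default_factory=QualityProfile)

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate", "chimera_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def position_error(self, length: int) -> np.ndarray:
        """Per-position substitution probability: sub_rate shaped by a mild
        exponential ramp (about 0.6x at the 5' end to 1.6x at the 3' end),
        normalized to mean sub_rate."""
        if self.sub_rate == 0.0:
            return np.zeros(length)
        pos = np.linspace(-0.5, 0.5, length) if length > 1 else np.zeros(1)
        shape = np.exp(pos)
        return self.sub_rate * shape / shape.mean()

    def position_quality(self, length: int) -> np.ndarray:
        """Emitted Phred per position: the Phred of the substitution
        probability, capped at the profile baseline (honest in expectation)."""
        base = self.quality_profile.baseline(length)
        p = self.position_error(length)
        with np.errstate(divide="ignore"):
            phred = np.where(p > 0, -10.0 * np.log10(np.maximum(p, 1e-9)), np.inf)
        return np.minimum(base, np.floor(phred)).astype(np.int16)


@dataclass
class MockSpec:
    """Design of the single-species mock community."""

    n_specimens: int = 31
    n_haplotypes: int = 15
    amplicon_len: int = 178
    biomass_decades: float = 3.0
    haplotype_divergence: int = 4  # max substitutions from the common ancestor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes > self.n_specimens:
            raise ValueError("n_haplotypes must be <= n_specimens")
        if self.amplicon_len <= 0 or self.biomass_decades < 0:
            raise ValueError("invalid mock spec")


@dataclass
class CommunitySpec:
    """Design of the multi-species, multi-site community."""

    n_otus: int = 8
    haplos_per_otu: int = 3
    amplicon_len: int = 178
    interspecific_divergence: float = 0.10  # min pairwise fraction between OTUs
    intra_divergence: int = 1  # max substitutions from the OTU ancestor (<=2% pairwise)
    n_sites: int = 6
    cline: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interspecific_divergence * self.amplicon_len <= 2 * self.intra_divergence:
            raise ValueError("interspecific divergence must exceed the intra-OTU radius")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class MockTruth:
    """Ground truth of a simulated mock run."""

    haplotypes: dict[str, str]  # hap id -> sequence (insert only, no primers)
    specimens: list[tuple[str, str, float]]  # (specimen id, hap id, biomass)
    shares: np.ndarray  # expected read share per specimen (sums to 1)

    def haplotype_shares(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (spec_id, hap, _bm), share in zip(self.specimens, self.shares):
            out[hap] = out.get(hap, 0.0) + float(share)
        return out


@dataclass
class CommunityTruth:
    otus: dict[str, dict[str, str]]  # otu id -> hap id -> sequence
    otu_weights: dict[str, np.ndarray]  # site id -> weight per OTU (sums to 1)
    hap_freqs: dict[tuple[str, str], np.ndarray]  # (otu, site) -> per-hap freqs
    sites: list[str]


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    idx = _BASE_INDEX[arr[positions]].astype(np.int64)
    arr[positions] = _BASES[(idx + rng.integers(1, 4, size=len(positions))) % 4]
    return bytes(arr).decode("ascii")


def make_haplotypes(
    n: int, length: int, divergence: int, rng: np.random.Generator
) -> list[str]:
    """A random ancestor plus n-1 variants, each within ``divergence``
    substitutions of the ancestor, all pairwise distinct (so pairwise
    distances lie in [1, 2*divergence]). Deterministic under the generator
    state."""
    if divergence < 1 and n > 1:
        raise ValueError("divergence must be >= 1 to place distinct haplotypes")
    ancestor = _random_seq(length, rng)
    return _haplotypes_from_ancestor(ancestor, n, max(divergence, 1), rng)


def assign_biomass(n_specimens: int, decades: float, rng: np.random.Generator) -> np.ndarray:
    """Log-uniform biomasses over [1, 10^decades], rescaled to sum to 1."""
    if decades == 0:
        return np.full(n_specimens, 1.0 / n_specimens)
    biomass = 10.0 ** (rng.uniform(0.0, decades, size=n_specimens))
    return biomass / biomass.sum()


def _apply_indels(
    seq_arr: np.ndarray, qual: np.ndarray, n_events: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    seq = list(seq_arr)
    q = list(qual)
    for _ in range(n_events):
        if not seq:
            break
        pos = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5:  # deletion
            del seq[pos]
            del q[pos]
        else:  # insertion of a random base, quality copied from neighbor
            seq.insert(pos, int(_BASES[rng.integers(0, 4)]))
            q.insert(pos, q[pos] if pos < len(q) else q[-1])
    return np.array(seq, dtype=np.uint8), np.array(q, dtype=np.int16)


def sequence_reads(
    templates: list[str],
    shares: np.ndarray,
    n_reads: int,
    error_model: ErrorModel,
    seed: int,
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
    id_prefix: str = "read",
) -> tuple[list[QualityRead], np.ndarray]:
    """Simulate merged, primer-flanked amplicon reads.

    Template counts are drawn multinomially by ``shares``; each read is the
    primer-flanked template with per-base substitutions, rare indels, and
    (with probability chimera_frac) a two-template splice at a uniform
    crossover. Returns the reads and the realized per-template draw.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    shares = np.asarray(shares, dtype=float)
    shares = shares / shares.sum()
    rng = np.random.default_rng(seed)

    # degenerate primer bases are instantiated once per run (one synthesized
    # primer batch), keeping all templates co-identical over the primer region
    def _instantiate(p: str) -> str:
        return "".join(
            sorted(IUPAC_SETS[c])[int(rng.integers(0, len(IUPAC_SETS[c])))] for c in p
        )

    fwd_inst = _instantiate(fwd_primer)
    rev_inst = _instantiate(rev_primer)
    full = [fwd_inst + t + revcomp(rev_inst) for t in templates]

    n_chim = (
        rng.binomial(n_reads, error_model.chimera_frac) if len(full) >= 2 else 0
    )
    draw = rng.multinomial(n_reads - n_chim, shares)
    reads: list[QualityRead] = []
    counter = 0

    def _emit_batch(template: str, m: int) -> None:
        nonlocal counter
        if m == 0:
            return
        L = len(template)
        p = error_model.position_error(L)
        qual = error_model.position_quality(L)
        base = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
        mat = np.tile(base, (m, 1))
        if error_model.sub_rate > 0:
            mask = rng.random((m, L)) < p
            n_sub = int(mask.sum())
            if n_sub:
                idx = _BASE_INDEX[mat[mask]].astype(np.int64)
                mat[mask] = _BASES[(idx + rng.integers(1, 4, size=n_sub)) % 4]
        if error_model.indel_rate > 0:
            events = rng.binomial(L, error_model.indel_rate, size=m)
        else:
            events = np.zeros(m, dtype=int)
        for row in range(m):
            counter += 1
            if events[row]:
                s_arr, q_arr = _apply_indels(mat[row], qual, int(events[row]), rng)
            else:
                s_arr, q_arr = mat[row], qual
            reads.append(
                QualityRead(
                    id=f"{id_prefix}_{counter}",
                    seq=bytes(s_arr).decode("ascii"),
                    qual=q_arr.copy(),
                )
            )

    for t_idx, template in enumerate(full):
        _emit_batch(template, int(draw[t_idx]))
    if n_chim > 0:
        for _ in range(n_chim):
            counter += 1
            i = int(rng.choice(len(full), p=shares))
            j = int(rng.choice(len(full), p=shares))
            while j == i:
                j = int(rng.choice(len(full), p=shares))
            a, b = full[i], full[j]
            L = min(len(a), len(b))
            k = int(rng.integers(1, L))
            template = a[:k] + b[k:]
            Lc = len(template)
            p = error_model.position_error(Lc)
            qual = error_model.position_quality(Lc)
            arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8).copy()
            if error_model.sub_rate > 0:
                mask = rng.random(Lc) < p
                n_sub = int(mask.sum())
                if n_sub:
                    idx = _BASE_INDEX[arr[mask]].astype(np.int64)
                    arr[mask] = _BASES[(idx + rng.integers(1, 4, size=n_sub)) % 4]
            reads.append(
                QualityRead(
                    id=f"{id_prefix}_{counter}_chimera",
                    seq=bytes(arr).decode("ascii"),
                    qual=qual.copy(),
                )
            )
    return reads, draw


def simulate_mock(
    spec: MockSpec,
    error_model: ErrorModel | None = None,
    n_reads: int = 200_000,
    n_replicates: int = 2,
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
) -> tuple[MockTruth, dict[str, list[QualityRead]], dict[str, np.ndarray]]:
    """Simulate the single-species mock: specimens drawn over haplotypes,
    biomass log-uniform over the stated decades, read share proportional to
    biomass, independent replicates differing only by seed.

    Returns the truth, reads per replicate ("A", "B", ...), and the realized
    per-specimen multinomial draw per replicate.
    """
    if error_model is None:
        error_model = ErrorModel()
    rng = np.random.default_rng(spec.seed)
    hap_seqs = make_haplotypes(
        spec.n_haplotypes, spec.amplicon_len, spec.haplotype_divergence, rng
    )
    hap_ids = [f"mock_h{i}" for i in range(1, spec.n_haplotypes + 1)]
    haplotypes = dict(zip(hap_ids, hap_seqs))
    # every haplotype gets at least one specimen; the rest are assigned randomly
    assignment = list(range(spec.n_haplotypes)) + [
        int(rng.integers(0, spec.n_haplotypes))
        for _ in range(spec.n_specimens - spec.n_haplotypes)
    ]
    rng.shuffle(assignment)
    shares = assign_biomass(spec.n_specimens, spec.biomass_decades, rng)
    specimens = [
        (f"sp{i + 1}", hap_ids[assignment[i]], float(shares[i]))
        for i in range(spec.n_specimens)
    ]
    truth = MockTruth(haplotypes=haplotypes, specimens=specimens, shares=shares)
    templates = [haplotypes[hap] for _, hap, _ in specimens]
    replicate_reads: dict[str, list[QualityRead]] = {}
    replicate_draws: dict[str, np.ndarray] = {}
    for r in range(n_replicates):
        rep = chr(ord("A") + r)
        reads, draw = sequence_reads(
            templates,
            shares,
            n_reads,
            error_model,
            seed=(spec.seed * 1_000 + 7 * (r + 1)) % 2**31,
            fwd_primer=fwd_primer,
            rev_primer=rev_primer,
            id_prefix=f"{rep.lower()}",
        )
        replicate_reads[rep] = reads
        replicate_draws[rep] = draw
    return truth, replicate_reads, replicate_draws


def make_community(
    spec: CommunitySpec,
    error_model: ErrorModel | None = None,
    depth_per_site: int = 30_000,
    n_replicates: int = 2,
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
) -> tuple[CommunityTruth, dict[tuple[str, str], list[QualityRead]]]:
    """Simulate a multi-species, multi-site community.

    Each OTU is an independent random ancestor (pairwise divergence checked
    against the spec) carrying closely related haplotypes. Haplotype
    frequencies per site come from a Dirichlet around the OTU's baseline;
    with ``cline``, the first haplotype of the first OTU ramps linearly
    across the site index. Returns the truth and reads keyed by
    (site, replicate).
    """
    if error_model is None:
        error_model = ErrorModel()
    rng = np.random.default_rng(spec.seed)
    from .denoise import edit_distance

    # divergent OTU ancestors
    ancestors: list[str] = []
    guard = 0
    while len(ancestors) < spec.n_otus:
        guard += 1
        if guard > 100 * spec.n_otus:
            raise RuntimeError("cannot place sufficiently divergent OTU ancestors")
        cand = _random_seq(spec.amplicon_len, rng)
        if all(
            edit_distance(cand, a) / spec.amplicon_len >= spec.interspecific_divergence
            for a in ancestors
        ):
            ancestors.append(cand)

    otus: dict[str, dict[str, str]] = {}
    for o, anc in enumerate(ancestors, 1):
        sub_rng = np.random.default_rng(rng.integers(0, 2**31))
        seqs = [anc]
        if spec.haplos_per_otu > 1:
            seqs = _haplotypes_from_ancestor(
                anc, spec.haplos_per_otu, spec.intra_divergence, sub_rng
            )
        otus[f"sim_otu{o}"] = {
            f"sim_otu{o}_h{i}": s for i, s in enumerate(seqs, 1)
        }

    sites = [f"site{s + 1}" for s in range(spec.n_sites)]
    otu_ids = sorted(otus)
    otu_weights: dict[str, np.ndarray] = {}
    hap_freqs: dict[tuple[str, str], np.ndarray] = {}
    baselines = {o: rng.dirichlet(np.full(len(otus[o]), 2.0)) for o in otu_ids}
    for s_idx, site in enumerate(sites):
        otu_weights[site] = rng.dirichlet(np.full(len(otu_ids), 5.0))
        for o_idx, o in enumerate(otu_ids):
            n_h = len(otus[o])
            if n_h == 1:
                freqs = np.array([1.0])
            else:
                freqs = rng.dirichlet(baselines[o] * 20.0 + 0.5)
            if spec.cline and o_idx == 0 and n_h > 1:
                # focal haplotype ramps strictly from 10% to 90% across sites
                f = 0.1 + 0.8 * (s_idx / max(1, spec.n_sites - 1))
                rest = freqs[1:] / freqs[1:].sum() * (1.0 - f)
                freqs = np.concatenate([[f], rest])
            hap_freqs[(o, site)] = freqs
    truth = CommunityTruth(
        otus=otus, otu_weights=otu_weights, hap_freqs=hap_freqs, sites=sites
    )

    templates: list[str] = []
    key_order: list[tuple[str, str]] = []
    for o in otu_ids:
        for h in sorted(otus[o]):
            templates.append(otus[o][h])
            key_order.append((o, h))
    reads_out: dict[tuple[str, str], list[QualityRead]] = {}
    for s_idx, site in enumerate(sites):
        weights = []
        for o_idx, (o, h) in enumerate(key_order):
            hap_list = sorted(otus[o])
            freqs = hap_freqs[(o, site)]
            weights.append(
                otu_weights[site][otu_ids.index(o)] * freqs[hap_list.index(h)]
            )
        weights = np.array(weights)
        for r in range(n_replicates):
            rep = chr(ord("A") + r)
            reads, _ = sequence_reads(
                templates,
                weights,
                depth_per_site,
                error_model,
                seed=(spec.seed * 100_003 + 13 * (s_idx + 1) + 7919 * (r + 1)) % 2**31,
                fwd_primer=fwd_primer,
                rev_primer=rev_primer,
                id_prefix=f"{site}_{rep.lower()}",
            )
            reads_out[(site, rep)] = reads
    return truth, reads_out


def _haplotypes_from_ancestor(
    ancestor: str, n: int, divergence: int, rng: np.random.Generator
) -> list[str]:
    """Like make_haplotypes but starting from a given ancestor."""
    seqs = [ancestor]
    seen = {ancestor}
    attempts = 0
    length = len(ancestor)
    while len(seqs) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("cannot place distinct haplotypes within budget")
        k = int(rng.integers(1, divergence + 1))
        pos = rng.choice(length, size=k, replace=False)
        variant = _mutate(ancestor, pos, rng)
        if variant not in seen:
            seen.add(variant)
            seqs.append(variant)
    return seqs
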