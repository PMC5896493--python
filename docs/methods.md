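# Methods

This note documents the models and procedures implemented in `haplopipe`,
the parameters that matter, and the design choices made where more than one
reasonable implementation exists.

## Problem setting

A COI metabarcode amplified from a bulk community sample yields reads from
many species at very different abundances (specimen biomass in
macroinvertebrate samples commonly spans several orders of magnitude), with
errors introduced by PCR (substitutions, chimeras) and sequencing
(substitutions, rare indels). Recovering *intraspecific* haplotypes means
separating true low-frequency sequence variants from error variants that
can be orders of magnitude more numerous. The package's chain does this with
abundance-based reasoning only: it never uses a reference database and
treats the marker as an anonymous fixed-length amplicon.

## Preprocessing

- **Pair merging.** Best ungapped 3′ overlap (≥ `min_overlap`, default 16),
  scored by matches − mismatches; ties prefer the longer overlap. In the
  overlap, agreeing bases keep the higher Phred score; disagreements take
  the higher-Phred base with quality |Q₁ − Q₂| (forward base on an exact
  tie). Pairs whose best overlap has a mismatch fraction above
  `max_overlap_mismatch_frac` (default 0.25) are rejected. Gapped overlap
  merging is out of scope.
- **Primer trimming and orientation.** Primers are matched anchored at the
  read ends, IUPAC-aware, with a per-primer mismatch allowance of
  ⌈10 % of primer length⌉ unless set explicitly. A read whose 5′ end matches
  the reverse primer is reverse-complemented (qualities reversed) before
  trimming; reads matching neither orientation are rejected. An `N` in the
  read matches only an `N` in the primer.
- **Expected-error filter.** ee = Σᵢ 10^(−Qᵢ/10); reads with ee ≤ `max_ee`
  are kept (boundary inclusive, matching the "maximum expected error"
  semantics). Default `max_ee` = 0.5.
- **Exact-length filter.** Only reads of exactly the primer set's target
  length survive; this removes most indel-bearing reads.
- **Subsampling.** Uniform without replacement, seeded, order-preserving.
  A sample shallower than the requested depth is an error, not a silent
  pass-through — depth equalization is the point of the step.

Every stage records kept/rejected counts; kept + rejected = input at every
boundary.

## Abundance prefilter

After per-sample dereplication, a unique's count in a sample is zeroed
unless it is both ≥ `min_abs` copies (default 10) and ≥ `min_rel` of the
sample's post-preprocessing reads (default 10⁻⁵, i.e. 0.001 %); uniques
zeroed everywhere are dropped. Keeping a count requires *both* conditions
("discard below X reads **or** Y %" reads as discard-if-either-fails).
Dereplication is per sample, before pooling — required so the per-sample
floors are well defined.

## Denoising

Pooled uniques are visited in order of decreasing total count (ties broken
lexicographically by sequence — determinism matters for testing). The first
unique founds a centroid. Each later unique *u* is compared against all
accepted centroids; it is absorbed as noise of the qualifying centroid
(skew size(u)/size(c) ≤ β(d) = 1/2^(αd+1), d = unit-cost Levenshtein
distance ≥ 1) with the smallest d, ties broken by larger centroid size then
lexicographic sequence; with no qualifying centroid it founds a new one.

Design choices worth stating:

- **Skew denominator** is the founding unique's own dereplicated total, not
  the growing cluster size. This makes every absorption auditable after the
  fact (each recorded member satisfies size/centroid_size ≤ β(d) under the
  run's α) and keeps the greedy pass order-independent of absorption
  history.
- **Single pass, no reassignment.** Once absorbed, a unique stays with its
  centroid even if a closer centroid appears later; this matches the greedy
  character of skew-based denoisers and keeps the exhaustive test oracle
  tractable.
- **Distance caps.** β(d) decays so fast that for a given size ratio only
  small d can qualify; edit distances are computed with a per-pair cap
  derived from the ratio (exact — distances beyond the cap can never
  qualify), which makes the greedy pass fast on realistic inputs.
- **α semantics.** β(d) shrinks as α shrinks, so *lower* α absorbs more
  variants (stricter denoising) and higher α leaves more centroids
  standing. Default α = 5; mock validation uses α = 10 ("relaxed").

A centroid's per-sample counts are its own dereplicated counts plus those
of all absorbed members; this defines the haplotype × sample table without
a separate read-mapping pass (an explicit re-mapping mode was considered
and rejected as redundant at this package's scale, since membership already
assigns every surviving read).

### Chimera flagging

A centroid x is flagged when two distinct centroids a, b exist, each with
total ≥ 2 × total(x), and a crossover 1 ≤ k < len(x) with
x = a[1..k] + b[k+1..]. This is a deliberately simple exact-splice model of
de novo chimera detection. **Limitation:** on single-species data where all
haplotypes descend from a recent common ancestor, the *ancestral* haplotype
is itself an exact splice of any two descendants whose private substitutions
lie on opposite sides of a crossover, so it is flagged whenever two
descendants are ≥ 2× more abundant. Mock-community validation therefore
runs with `chimera_check=False`; the flagger is intended for multi-species
tables where parents are typically divergent. Flagged centroids are
excluded from table building; their read counts are reported in stage
statistics.

## OTU clustering and table filtering

Greedy centroid clustering by decreasing haplotype abundance; identity
= 1 − editdist/max(len); a haplotype joins the *first* OTU (founding order)
whose centroid meets the threshold (default 0.97, exposed as
`--otu-identity`). The table filter applies, in order: (1) haplotype rows
must reach `minhaplosize` % of a sample's reads in at least one sample;
(2) OTU sums must reach `OTUmin` % in at least one sample; (3) within each
OTU and sample, haplotypes below `withinOTU` % of that OTU's reads in that
sample are zeroed (shares computed on post-step-2 counts); (4) all-zero
rows are dropped; (5) presence filters (`minHaploPresence`,
`minOTUPresence`, both default 1 = off). All boundaries are inclusive:
"less than X" is discarded, ≥ X is retained.

The cascade is **re-applied until the table stops changing**. A single pass
is not idempotent: step-3 zeroing can push a row below the step-1 floor,
which only a second pass would catch. The fixpoint usually arrives after
one extra pass and makes the filter idempotent by construction; it removes
at most what repeated manual application would remove. The
relative-abundance denominator for steps 1–2 is the sample's total reads
entering the table (post-denoise), recorded in the table itself.

## Population-genetic outputs

- **Haplotypes per OTU:** mean and sample SD (ddof = 1) of per-OTU richness;
  a single-OTU table reports SD = 0 with a degeneracy flag.
- **Networks:** complete pairwise edit-distance graph reduced to a minimum
  spanning tree by Kruskal with deterministic tie-breaking (lighter edge,
  then the edge touching the more abundant haplotype, then lexicographic
  pair). A single MST is used rather than a multi-tree minimum spanning
  network: ties are rare at COI scale and determinism enables exhaustive
  testing. Nodes carry per-site within-OTU frequencies; haplotypes absent
  from an optional reference set are marked novel.
- **Replicate R²:** OTUs are matched across two tables by shared haplotype
  sequences (greedy, by shared abundance). Per matched OTU, (haplotype,
  site) relative abundances of replicate A (predictor) vs B are fit by
  ordinary least squares; adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).
  OTUs with fewer than 3 informative pairs or zero variance are excluded
  and reported. Relative abundances are the default (`--raw-counts`
  switches to counts); identical tables give exactly 1.
- **Truth classification:** exact sequence matching against a truth set
  above a per-run relative-abundance floor; reports expected hits, missed
  truth sequences, unexpected variants, and cross-replicate concordance.

## The simulator

`simulate_mock` emulates a single-species mock community: 31 specimens
carrying 15 distinct haplotypes of a 178-bp amplicon (defaults), specimen
biomass log-uniform over three orders of magnitude, expected read share
strictly proportional to biomass, and independent replicates differing only
by seed. Haplotypes are a random ancestor plus variants within
`haplotype_divergence` substitutions (default 4; pairwise distances 1–8 bp,
a realistic intraspecific spread for a short COI fragment). Every haplotype
is carried by at least one specimen.

`make_community` emulates a multi-species, multi-site design: divergent
random OTU ancestors (pairwise divergence checked against the spec), each
carrying a handful of ≤ ~2 %-divergent haplotypes; per-site OTU weights and
within-OTU haplotype frequencies drawn from Dirichlet distributions around
a per-OTU baseline; optionally one focal haplotype's frequency ramps
linearly across the site index (a north–south cline analogue).

**Error model.** Per-base substitution probability = `sub_rate`
(default 0.002) shaped by a mild exponential ramp along the read (~0.6× at
the 5′ end to ~1.6× at the 3′ end, mean = `sub_rate`); indels at
`indel_rate` (default 2 × 10⁻⁴) per base; chimeras with probability
`chimera_frac` (default 0.01) formed by splicing two distinct templates at
a uniform crossover. Emitted Phred scores report the per-base substitution
probability actually used, capped at the profile mean (default Q35), so
expected-error filtering sees honest qualities; in the noiseless limit the
profile mean is emitted. Degenerate primer positions are instantiated once
per run, as a synthesized primer batch would be.

**What the simulator does not emulate:** PCR amplification bias, tag
switching, numts/heteroplasmy, platform-specific error motifs, and
quality-score miscalibration. Passing tests on simulated data therefore
demonstrate the *algorithmic* correctness of the chain (recovery,
thresholds, conservation, determinism) but not robustness to those
real-data artifacts; an optional per-specimen amplification-efficiency
multiplier is the only nod to PCR bias and is off by default.

## Problem sizes and numerics

Validation runs use two replicates of 200,000 reads for the mock design
and six sites × 20,000 reads × two replicates for the community design —
large enough that the rarest specimen (share ~10⁻⁴) clears the relaxed
per-sample floor with tens of reads, and small enough to iterate on
quickly. Determinism: every stochastic component takes an explicit seed;
reruns are byte-identical. Edit distances are exact (edlib); skew
comparisons are floating-point with β values that are exact powers of two
for integer α. Degenerate inputs: empty tables raise on statistics that
need data (haplotypes/OTU), return empty results elsewhere; single-OTU SDs
are flagged rather than NaN.

## Known limitations

- Rare true haplotypes at edit distance 1 from an abundant haplotype are
  absorbed whenever their abundance ratio falls below β(1) — at α = 5 that
  is 1/64, so within-species variants rarer than ~1.6 % of their neighbor
  are invisible by construction. This mirrors the documented behavior of
  skew-based denoisers on low-biomass specimens.
- The exact-splice chimera model over-flags ancestral haplotypes on
  single-species data (see above).
- The within-OTU 5 % rule removes genuinely rare haplotypes; the filtered
  table understates diversity at every site, trading sensitivity for
  reliability.
- OTU matching across replicates for R² relies on shared haplotype
  sequences; OTUs with no shared haplotypes are dropped from the statistic.
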